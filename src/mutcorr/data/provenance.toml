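# Provenance of the shipped FCIDUMP fixtures (all generated by
# scripts/make_molecular_fixtures.py with the bundled integral engine).

[h2_ccpvdz_re]
geometry_angstrom = 0.74144
basis = "cc-pVDZ (spherical)"
orbitals = "RHF canonical, full space (10 orbitals)"
rhf_energy = -1.12871534
fci_energy = -1.16341520

[h2_ccpvdz_3re]
geometry_angstrom = 2.22432
basis = "cc-pVDZ (spherical)"
orbitals = "RHF canonical, full space (10 orbitals)"
rhf_energy = -0.89393055
fci_energy = -1.00878936

[n2_cas10e8o_re]
geometry_angstrom = 1.098
basis = "cc-pVDZ (Cartesian d)"
orbitals = "CASSCF(10e,8o) converged, |orbital gradient| < 1e-6"
casscf_energy = -109.1032016145

[n2_cas10e8o_2re]
geometry_angstrom = 2.196
basis = "cc-pVDZ (Cartesian d)"
orbitals = "CASSCF(10e,8o) converged, |orbital gradient| < 1e-6"
casscf_energy = -108.7825926385
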