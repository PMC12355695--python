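"""Generate the molecular FCIDUMP fixtures shipped under mutcorr/data/.

H2: full-space cc-pVDZ MO integrals at the RHF orbitals (the full-space CI
is orbital-invariant, so RHF orbitals define the canonical basis).
N2: CASSCF(10e,8o)/cc-pVDZ active-space effective Hamiltonians at the
converged CASSCF orbitals; FCI on these integrals reproduces the CASSCF
wave function exactly.

Run from the repository root:  python scripts/make_molecular_fixtures.py
The N2 orbital optimization takes some minutes per geometry.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np

from minichem import (ANGSTROM_TO_BOHR, Molecule, active_space_integrals,
                      casscf, mo_transform, rhf)
from mutcorr.fci import SecondQuantizedHamiltonian, write_fcidump

DATA = Path(__file__).parent.parent / "src" / "mutcorr" / "data"
R_H2 = 0.74144   # angstrom, experimental
R_N2 = 1.098     # angstrom, experimental


def h2_fixture(name: str, r_ang: float) -> None:
    r = r_ang * ANGSTROM_TO_BOHR
    mol = Molecule([("H", [0, 0, 0]), ("H", [0, 0, r])])
    E, C, eps, (h_ao, g_ao, S) = rhf(mol)
    h, g = mo_transform(h_ao, g_ao, C)
    ham = SecondQuantizedHamiltonian(
        h=h, g=g, e_core=mol.e_nuc, n_electrons=2, ms2=0
    )
    write_fcidump(DATA / name, ham, tol=1e-10)
    print(f"{name}: RHF E = {E:.8f}")


def n2_fixture(name: str, r_ang: float, C0=None):
    # Cartesian (6-component) d shells: this convention reproduces the
    # reference total-correlation values at both geometries
    r = r_ang * ANGSTROM_TO_BOHR
    mol = Molecule([("N", [0, 0, 0]), ("N", [0, 0, r])], cartesian_d=True)
    E, C, info = casscf(mol, ncore=2, nact=8, nelecas=10, C0=C0,
                        gtol=1e-6, max_iter=6000, verbose=False)
    if not info.get("converged"):
        raise RuntimeError(f"N2 CASSCF at {r_ang} A did not converge: {info}")
    _, _, _, (h_ao, g_ao, S) = rhf(mol)
    h, g = mo_transform(h_ao, g_ao, C)
    h_eff, g_act, e_core = active_space_integrals(h, g, mol.e_nuc, 2, 8)
    ham = SecondQuantizedHamiltonian(
        h=h_eff, g=g_act, e_core=e_core, n_electrons=10, ms2=0
    )
    write_fcidump(DATA / name, ham, tol=1e-12)
    print(f"{name}: CASSCF E = {E:.10f} ({info['iterations']} iterations)")
    return C


if __name__ == "__main__":
    DATA.mkdir(parents=True, exist_ok=True)
    h2_fixture("h2_ccpvdz_re.fcidump", R_H2)
    h2_fixture("h2_ccpvdz_3re.fcidump", 3 * R_H2)
    C = n2_fixture("n2_cas10e8o_re.fcidump", R_N2)
    n2_fixture("n2_cas10e8o_2re.fcidump", 2 * R_N2, C0=C)
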