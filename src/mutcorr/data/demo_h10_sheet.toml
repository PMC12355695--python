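# Demo config (best effort): planar triangular-pattern H10 sheet,
# nearest-neighbor distance 1.5 angstrom, full-valence active space
# (10e,10o).  The geometry is a reconstruction from the verbal
# description only and is NOT used by any test.
[system]
elements = ["H","H","H","H","H","H","H","H","H","H"]
# two staggered rows of 5 atoms, nearest-neighbor distance 1.5 A
# row spacing = 1.5*sqrt(3)/2
coords_angstrom = [
  [0.00, 0.000, 0.0], [1.50, 0.000, 0.0], [3.00, 0.000, 0.0],
  [4.50, 0.000, 0.0], [6.00, 0.000, 0.0],
  [0.75, 1.299, 0.0], [2.25, 1.299, 0.0], [3.75, 1.299, 0.0],
  [5.25, 1.299, 0.0], [6.75, 1.299, 0.0],
]
[active_space]
n_electrons = 10
n_orbitals = 10
basis = "cc-pVDZ"
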