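# Methods

## The model

`mutcorr` quantifies electron correlation in a many-fermion state through
the two-body reduced density matrix (2-RDM) cumulant.  For a normalized
state |Ψ⟩ over 2K spin orbitals, the 1- and 2-RDMs are

    γ¹[p,r]   = ⟨Ψ| a†_p a_r |Ψ⟩
    γ²[p,q,r,s] = ⟨Ψ| a†_p a†_q a_s a_r |Ψ⟩      (note the s-before-r order)

and the 2-cumulant is the connected remainder after removing the
antisymmetrized 1-RDM product,

    λ₂[p,q,r,s] = γ²[p,q,r,s] − γ¹[p,r]γ¹[q,s] + γ¹[p,s]γ¹[q,r].

λ₂ vanishes identically for any single Slater determinant and for any
one-electron state, is invariant in Frobenius norm under unitary orbital
rotations, and is additive over noninteracting fragments.  The total
correlation is

    C = ¼ Σ_pqrs |λ₂[p,q,r,s]|²,

i.e. the squared Frobenius norm counting each unordered index pair once
(the ¼ compensates the antisymmetry-driven four-fold repetition).  All
values printed by the package are on this unique-pair scale; the raw
all-index sum is exposed alongside as `raw_norm = 4 C`.

Two matricizations of λ₂ supply eigenvalue-based metrics: the *geminal*
matrix over unique creation/annihilation pairs (dimension 2K²−K), whose
largest absolute eigenvalue signals fermion-pair condensation, and the
*particle–hole* matrix over all index pairs (dimension 4K²), whose largest
eigenvalue signals exciton condensation.  The trace identity
Tr λ₂ = Tr(γ¹² − γ¹) ties the cumulant trace to 1-RDM idempotency and is
asserted as a cross-check on random states.

## Mutual correlation

For disjoint spin-orbital sets, C restricted to a subset X is
C_X = ¼ Σ_{pqrs∈X} |λ₂|².  The mutual correlation between fragments is the
nonadditive remainder, evaluated by inclusion–exclusion:

    M_AB   = C_{A∪B} − C_A − C_B                       (pair)
    M_ABC  = C_{A∪B∪C} − ΣC − ΣM_pair                  (triple)
    M_ABCD = C_{A∪B∪C∪D} − ΣC − ΣM_pair − ΣM_triple    (quadruple)

Because λ₂ has four indices, a complete partition of the basis closes at
fourth order: C_S = ΣC_A + ΣM_AB + ΣM_ABC + ΣM_ABCD exactly (tested to
1e−10 on 200 seeded random state/partition pairs).  Each term is invariant
under rotations that mix spin orbitals within one fragment only.

Explicit index-placement expansions of the pair, triple, and quadruple
terms are implemented as independent cross-checks of the inclusion–
exclusion path.  For the quadruple term the complete expansion is
2·[S(A,B;C,D) + S(A,C;B,D) + S(A,D;B,C)], where S(X,Y;Z,W) sums |λ₂|² with
the upper indices in (X,Y) and lower indices in (Z,W); a single-pattern
form with weight 6 is correct only when the three pairings coincide by
symmetry, so the three-pattern sum is what the cross-check uses.

*Orbital* mutual correlation M_PQ specializes M_AB to fragments
{P↑, P↓} and {Q↑, Q↓}.  It is zero for separable pairs and intensive,
which makes values comparable across systems; within the symmetry-
restricted singlet model below it peaks at 3/4 (a Bell-type geminal),
though general states can exceed that (see the ceiling note at the end).  The calibration bands used for qualitative
reading are strong [0.075, 0.75], medium [0.0075, 0.075), weak
[0.00075, 0.0075), negligible below 0.00075 — closed on the strong side;
the lowest edge doubles as the plot display floor, and sub-floor values
are retained in all data files.

## Two-orbital closed-form model

The singlet cosθ|20⟩ + sinθ|02⟩ of two electrons in two symmetry-distinct
orbitals admits closed forms C_A = cos⁴θ sin⁴θ and
M_AB = (5 − cos4θ) sin²2θ / 8, with maxima 1/16 and 3/4 at θ = π/4 and a
total C_S peaking at 7/8.  The numeric pipeline reproduces both on a
101-point θ grid to 1e−12; this is the package's primary analytic oracle.

## State-space maxima

The maximum of C over all normalized states of a sector is located by
projected ascent on the CI unit sphere.  Both RDMs are Gram matrices of
annihilated vectors (γ²[pq,rs] = ⟨a_q a_p Ψ | a_s a_r Ψ⟩), which yields an
analytic gradient assembled from sparse annihilation operators; L-BFGS
with seeded random restarts (one restart biased to the seniority-zero
subspace, the structure of known maximizers) converges to the sector
maximum from every tested start.  The absolute-trace bound is computed
separately by optimizing Σ(n² − n) over spin-orbital occupations in [0,1]
at fixed electron count; its extremum sits at half filling of every
orbital.

## Orbital entropies and mutual information

One- and two-orbital reduced density matrices are obtained from CI vectors
by exact partial trace.  The subsystem Fock basis is |0⟩, |↑⟩, |↓⟩, |↑↓⟩
per orbital (lexicographic product for pairs); occupied subsystem spin
orbitals are commuted to the front of the spin-blocked ordering, orbital P
before Q, up before down, accumulating one sign per transposition.
Entropies are invariant to this phase convention; individual off-diagonal
matrix elements are not, which is why the one-orbital closed forms (from
1-/2-RDM elements) are only asserted against the diagonal partial-trace
result, exact for particle-number/S_z eigenstates.  Eigenvalues in
[−1e−12, 0) are clipped to zero before the entropy logarithm.  Mutual
information is I_PQ = (s_P + s_Q − s_PQ)/2 with natural logarithms.

Because the two-orbital density requires the wave function (its elements
involve up to 4-body correlations), entropy comparisons are only available
for states the package itself has in CI form — not for imported 2-RDMs.
This is a deliberate scope boundary, enforced with a clear error.

## Maximally correlated orbitals

Restricted real rotations U = exp(A), A antisymmetric and identical for
both spins, are optimized to maximize L = Σ_{P<Q} M_PQ².  Gradients are
central finite differences (step 1e−5) over the strict upper triangle of
A; ascent is BFGS with convergence on relative improvement below 1e−10 or
500 iterations, repeated from 10 seeded random generators (entries
~N(0, 0.1²)) because L is nonconvex with genuine local maxima — the report
always carries the per-restart dispersion.  Total correlation C is
conserved along every trajectory to 1e−9 (asserted), while L grows: the
optimization redistributes correlation over pairs without creating or
destroying it.

## FCI engine and molecular fixtures

Small-molecule states are produced by a determinant-based FCI solver over
the package's own Fock-space machinery: the Hamiltonian acts as a
matrix-free operator through spin-summed excitation operators E_PQ with
chemists'-notation integrals read from Molpro-dialect FCIDUMP files.
Sectors are fixed by (NELEC, MS2); eigenpairs below dimension 600 are
obtained densely, larger ones with implicitly restarted Lanczos and a
residual guard of 1e−8.

The shipped fixtures are plain-text FCIDUMP files: H₂/cc-pVDZ full-space
MO integrals at the RHF orbitals for bond lengths 0.74144 Å and 2.22432 Å,
and N₂ active-space effective Hamiltonians from a converged full-valence
CASSCF(10e,8o)/cc-pVDZ at 1.098 Å and 2.196 Å (orbital gradient below
1e−6; FCI on these integrals reproduces the multiconfigurational state
exactly).  The N₂ calculations use Cartesian (6-component) d shells: with
spherical d the total correlation comes out 0.15658/2.50235 at the two
geometries, with Cartesian d 0.15669/2.50254, and only the latter
reproduces the reference values 0.1567/2.5025 at printed precision — the
benchmark calculation evidently used the Cartesian convention.  They were generated by `scripts/make_molecular_fixtures.py`,
a self-contained numpy/scipy McMurchie–Davidson integral engine with RHF
and two-step CASSCF, validated against finite-difference orbital
gradients, the known cc-pVDZ hydrogen-atom energy (−0.4992784 Eh), and
rotational invariance of total energies.  The generator is shipped for
provenance; its CASSCF step takes minutes per geometry, which is why the
integrals are precomputed rather than rebuilt on the fly.

### Basis convention of the H₂ benchmark values

The H₂ reference values for the largest orbital-pair mutual correlation
(0.006 at r_e, 0.528 at 3 r_e) correspond to the **canonical molecular-
orbital basis**, not to the natural basis of the spin-summed 1-RDM: in the
natural basis this package obtains 0.0205 and 0.5655 at those geometries,
while the canonical basis gives 0.0057 and 0.5275, matching the quoted
values at printed precision together with the quoted per-orbital
occupations (which are canonical diagonal elements — the true natural
occupation of 1σu at r_e is ≈0.02, consistent with the well-known σ→σ*
double-excitation amplitude ≈0.1 of H₂ in double-zeta bases).  The
benchmark path therefore evaluates M_PQ for H₂ in the canonical basis of
the fixture integrals; the library default elsewhere remains the natural
basis, and both are available through the API and CLI.

## Synthetic data

Seeded fixtures cover the study conditions: random CI vectors with fixed
particle numbers (amplitudes i.i.d. normal, normalized), antisymmetrized
products of fragment states on disjoint orbitals, seeded special-
orthogonal rotations, and random full-cover fragment partitions.  Random
CI vectors are *generic* states — they carry no Hamiltonian structure, no
point-group symmetry, and near-maximal sector entanglement — so passing
property tests on them demonstrates the algebraic identities
(completeness, invariance, positivity, oracle equivalence) but not
physical features such as the geminal-pair dominance seen in molecular
ground states; the lattice and molecular fixtures cover that side.

## Numerical choices

* Determinants are ordered by ascending (alpha, beta) occupation-mask
  integers; CI vectors are bit-reproducible across runs.
* Degenerate eigenpairs (gap < 1e−10) are orthonormalized and sign-fixed
  (largest-magnitude amplitude positive).  Natural-orbital degeneracies
  (gap < 1e−8) are resolved by orthogonal Procrustes alignment with the
  input orbitals, then sign-fixed; this keeps symmetry-paired π orbitals
  aligned with their input partners.
* Dense cumulant tensors are limited to K ≤ 16 spatial orbitals; larger
  bases are refused outright.
* The state-norm guard is 1e−8; RDM trace guards are 1e−9 (2-RDM) and
  1e−10 (1-RDM); rotation unitarity is required to 1e−10.
* Lattice scans use the lowest 100 states; when the cut falls inside a
  degenerate multiplet the list is truncated at exactly 100 after
  canonical ordering.

## Problem sizes

The test suite and the benchmark script run on one CPU in a few minutes
total: worked examples use the 36-determinant (2↑,2↓)-in-4 sector, the
state-space maxima use that sector plus the 4900-determinant half-filled
8-orbital sector, the lattice scans diagonalize the 4900-determinant
sector for 100 states at two interaction strengths, and the molecular
benchmarks solve FCI spaces of dimension 100 (H₂) and 3136 (N₂ active
space).  Property suites run on K = 2–4 sectors where the brute-force
operator oracle is affordable.

## Known limitations

* Imported RDM containers must be spin-resolved; spin-free 2-RDMs alone
  do not determine the spin blocks and are rejected.
* The FCI engine targets small fixture problems (dimension ~10⁴), not
  production CI; there is no symmetry adaptation or direct-CI machinery.
* Orbital-entropy analyses require CI vectors (see above).
* The N₂ benchmark values agree with the reference table at printed
  precision for the total C at both geometries (Cartesian-d fixtures)
  and to 1e−4 for the π-pair and weak mutual-correlation entries, but
  the 3σg/3σu entry at 2 r_e comes out 1% high (0.2804 vs 0.2776) under
  *every* convention examined: natural vs semicanonical orbitals, frozen
  vs relaxed core, spherical vs Cartesian d, and the spin-block formula
  variants.  The converged solution is symmetry-pure (orbital parities
  ±1 to machine precision), spin-pure (⟨S²⟩ = 0 with the triplet 5 mEh
  above), and has orbital gradient below 1e−6; perturbation tests show
  contraction-coefficient noise moves C by only ~3e−6 per 1e−4 shift.
  The value is reported as computed; the residual is below the basis-set
  spread of the neighboring entries and the source of the remaining
  difference could not be identified.


## Scope of the 3/4 pair ceiling

The calibration bands are anchored on the two-orbital singlet model, whose
pair mutual correlation peaks at 3/4.  That ceiling is a property of the
model's symmetry restriction (the open-shell configuration is excluded
because the two orbitals belong to different irreducible representations),
not of M_PQ itself: over *all* normalized two-orbital states the maximum
is 7/8, attained for example by the state with amplitudes
(1, 1, 1, -1)/2 over (|20>, |up down>, |down up>, |02>), found by
property-based search and confirmed by numerical maximization and by the
independent expansion formula.  Molecular singlet ground states in a
natural basis stay comfortably below 3/4 in every case examined, so the
band edges remain meaningful as a reading aid.
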