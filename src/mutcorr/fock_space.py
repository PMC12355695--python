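"""Determinant bases, second-quantized operators, and model Hamiltonians.

Conventions used throughout the package
---------------------------------------
* Spin orbitals are **spin-blocked**: for ``K`` spatial orbitals, indices
  ``0..K-1`` are the spin-up partners of spatial orbitals ``0..K-1`` and
  indices ``K..2K-1`` the spin-down partners.  All fermionic phases refer to
  this fixed global ordering.
* A determinant is stored as a ``2K``-bit integer whose bit ``p`` is the
  occupation of spin orbital ``p``; the corresponding Fock state is the
  product of creation operators in **ascending** spin-orbital order acting
  on the vacuum.
* Amplitudes are real by default; the same routines accept complex arrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "SpinOrbitalBasis",
    "DeterminantSpace",
    "CIVector",
    "HubbardModel",
    "enumerate_determinants",
    "apply_operator_string",
    "build_hubbard_hamiltonian",
    "lowest_states",
    "parse_state",
    "product_state",
]


@dataclass(frozen=True)
class SpinOrbitalBasis:
    """Spin-blocked spin-orbital basis over ``K`` spatial orbitals."""

    K: int
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("need at least one spatial orbital")
        if self.labels is not None and len(self.labels) != self.K:
            raise ValueError("one label per spatial orbital required")

    @property
    def n_spin_orbitals(self) -> int:
        return 2 * self.K

    def spatial_spin(self, p: int) -> tuple[int, int]:
        """Map spin-orbital index ``p`` to ``(spatial, spin)``; spin 0=up, 1=down."""
        if not 0 <= p < 2 * self.K:
            raise IndexError(f"spin orbital {p} outside basis of {2 * self.K}")
        return (p % self.K, p // self.K)


def _bit_parity_below(bits: int, p: int) -> int:
    """Parity (0/1) of the number of set bits strictly below position ``p``."""
    return bin(bits & ((1 << p) - 1)).count("1") & 1


def enumerate_determinants(K: int, n_alpha: int, n_beta: int) -> list[int]:
    """All determinants of the ``(n_alpha, n_beta)`` sector in ``K`` orbitals.

    Deterministic ordering: ascending integer value of the alpha occupation
    mask, then of the beta mask (bit ``i`` = spatial orbital ``i``).
    """
    if not (0 <= n_alpha <= K and 0 <= n_beta <= K):
        raise ValueError(f"particle numbers ({n_alpha},{n_beta}) invalid for K={K}")
    alpha_masks = [_mask_from_occ(c) for c in combinations(range(K), n_alpha)]
    beta_masks = [_mask_from_occ(c) for c in combinations(range(K), n_beta)]
    alpha_masks.sort()
    beta_masks.sort()
    return [a | (b << K) for a in alpha_masks for b in beta_masks]


def _mask_from_occ(occ: Iterable[int]) -> int:
    m = 0
    for i in occ:
        m |= 1 << i
    return m


def sector_space(K: int, n_alpha: int, n_beta: int) -> "DeterminantSpace":
    """Process-wide cached DeterminantSpace (reuses sparse operator caches)."""
    key = (K, n_alpha, n_beta)
    space = _SPACE_REGISTRY.get(key)
    if space is None:
        space = DeterminantSpace(K, n_alpha, n_beta)
        _SPACE_REGISTRY[key] = space
    return space


_SPACE_REGISTRY: dict[tuple[int, int, int], "DeterminantSpace"] = {}


class DeterminantSpace:
    """Ordered determinant basis of one fixed ``(n_alpha, n_beta)`` sector."""

    def __init__(self, K: int, n_alpha: int, n_beta: int):
        self.K = K
        self.n_alpha = n_alpha
        self.n_beta = n_beta
        self.dets = enumerate_determinants(K, n_alpha, n_beta)
        self.index = {d: i for i, d in enumerate(self.dets)}
        self._ann_cache: dict[int, sp.csr_matrix] = {}
        self._pair_cache: dict[tuple[int, int], sp.csr_matrix] = {}
        self._subspace_cache: dict[tuple[int, int], "DeterminantSpace"] = {}

    @property
    def dim(self) -> int:
        return len(self.dets)

    @property
    def n_electrons(self) -> int:
        return self.n_alpha + self.n_beta

    @property
    def sector(self) -> tuple[int, int]:
        return (self.n_alpha, self.n_beta)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, DeterminantSpace)
            and (self.K, self.n_alpha, self.n_beta)
            == (other.K, other.n_alpha, other.n_beta)
        )

    def __hash__(self) -> int:
        return hash((self.K, self.n_alpha, self.n_beta))

    def __repr__(self) -> str:
        return f"DeterminantSpace(K={self.K}, sector=({self.n_alpha},{self.n_beta}))"

    def spin_of(self, p: int) -> int:
        return p // self.K

    def subspace(self, d_alpha: int, d_beta: int) -> "DeterminantSpace":
        """Sector with ``d_alpha``/``d_beta`` fewer electrons (cached)."""
        key = (d_alpha, d_beta)
        if key not in self._subspace_cache:
            self._subspace_cache[key] = DeterminantSpace(
                self.K, self.n_alpha - d_alpha, self.n_beta - d_beta
            )
        return self._subspace_cache[key]

    # -- sparse operator matrices ------------------------------------------

    def annihilation_matrix(self, p: int) -> sp.csr_matrix:
        """Sparse matrix of ``a_p`` mapping this sector to the reduced one."""
        if p in self._ann_cache:
            return self._ann_cache[p]
        spin = self.spin_of(p)
        target = self.subspace(1 - spin, spin)
        rows, cols, vals = [], [], []
        bit = 1 << p
        for j, det in enumerate(self.dets):
            if det & bit:
                phase = -1.0 if _bit_parity_below(det, p) else 1.0
                rows.append(target.index[det ^ bit])
                cols.append(j)
                vals.append(phase)
        A = sp.csr_matrix(
            (vals, (rows, cols)), shape=(target.dim, self.dim), dtype=float
        )
        self._ann_cache[p] = A
        return A

    def pair_annihilation_matrix(self, p: int, q: int) -> sp.csr_matrix:
        """Sparse matrix of ``a_q a_p`` (annihilate ``p`` first), ``p < q``."""
        if p >= q:
            raise ValueError("pair_annihilation_matrix requires p < q")
        key = (p, q)
        if key in self._pair_cache:
            return self._pair_cache[key]
        sp_p, sp_q = self.spin_of(p), self.spin_of(q)
        d_alpha = (sp_p == 0) + (sp_q == 0)
        d_beta = (sp_p == 1) + (sp_q == 1)
        target = self.subspace(d_alpha, d_beta)
        rows, cols, vals = [], [], []
        bp, bq = 1 << p, 1 << q
        for j, det in enumerate(self.dets):
            if (det & bp) and (det & bq):
                # remove p, then q from det^bp; p < q so removing p first
                # changes no bit below q except possibly none (p < q)
                par = _bit_parity_below(det, p) ^ _bit_parity_below(det ^ bp, q)
                rows.append(target.index[det ^ bp ^ bq])
                cols.append(j)
                vals.append(-1.0 if par else 1.0)
        A = sp.csr_matrix(
            (vals, (rows, cols)), shape=(target.dim, self.dim), dtype=float
        )
        self._pair_cache[key] = A
        return A

    def excitation_matrix(self, p: int, q: int) -> sp.csr_matrix:
        """Sparse matrix of ``a'_p a_q`` (a-dagger-p a-q) within this sector."""
        if self.spin_of(p) != self.spin_of(q):
            raise ValueError("spin-flip excitations leave the sector")
        rows, cols, vals = [], [], []
        bp, bq = 1 << p, 1 << q
        for j, det in enumerate(self.dets):
            if not det & bq:
                continue
            mid = det ^ bq
            if mid & bp:
                continue
            par = _bit_parity_below(det, q) ^ _bit_parity_below(mid, p)
            rows.append(self.index[mid | bp])
            cols.append(j)
            vals.append(-1.0 if par else 1.0)
        return sp.csr_matrix(
            (vals, (rows, cols)), shape=(self.dim, self.dim), dtype=float
        )

    def occ_string(self, det: int) -> str:
        """Render a determinant with the symbols 0 / u / d / 2."""
        out = []
        for i in range(self.K):
            a = bool(det & (1 << i))
            b = bool(det & (1 << (self.K + i)))
            out.append("2" if a and b else "u" if a else "d" if b else "0")
        return "".join(out)


@dataclass
class CIVector:
    """Amplitudes over a fixed-particle-number determinant basis."""

    space: DeterminantSpace
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes)
        if self.amplitudes.shape != (self.space.dim,):
            raise ValueError(
                f"amplitude vector of length {self.amplitudes.shape} does not "
                f"match basis of dimension {self.space.dim}"
            )

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))

    def normalized(self) -> "CIVector":
        n = self.norm
        if n == 0.0:
            raise ValueError("cannot normalize the zero vector")
        return CIVector(self.space, self.amplitudes / n)

    def require_normalized(self, tol: float = 1e-8) -> None:
        if abs(self.norm - 1.0) > tol:
            raise ValueError(f"state norm {self.norm} deviates from 1 beyond {tol}")

    def overlap(self, other: "CIVector") -> float:
        if self.space != other.space:
            raise ValueError("overlap requires a common determinant basis")
        return float(np.vdot(self.amplitudes, other.amplitudes).real)


# ---------------------------------------------------------------------------
# operator strings
# ---------------------------------------------------------------------------

def apply_operator_string(
    det: int, ops: Sequence[tuple[int, bool]], n_spin_orbitals: int | None = None
) -> tuple[int, int] | None:
    """Apply a product of elementary operators to a determinant.

    ``ops`` lists ``(spin_orbital, is_creation)`` pairs *in operator order*
    (leftmost factor first, as written on paper); the rightmost factor acts
    on the ket first.  Returns ``(resulting determinant, phase)`` or ``None``
    when the string annihilates the determinant.
    """
    phase = 1
    for p, create in reversed(ops):
        if p < 0 or (n_spin_orbitals is not None and p >= n_spin_orbitals):
            raise IndexError(f"spin orbital {p} out of bounds")
        bit = 1 << p
        if create:
            if det & bit:
                return None
            if _bit_parity_below(det, p):
                phase = -phase
            det |= bit
        else:
            if not det & bit:
                return None
            if _bit_parity_below(det, p):
                phase = -phase
            det ^= bit
    return det, phase


# ---------------------------------------------------------------------------
# Hubbard model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HubbardModel:
    """1D Hubbard chain with open boundary conditions."""

    K: int
    t: float = 1.0
    U: float = 0.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("Hubbard chain needs K >= 1 sites")


def build_hubbard_hamiltonian(
    model: HubbardModel, sector: tuple[int, int]
) -> sp.csr_matrix:
    """Sparse Hamiltonian of the open-boundary 1D Hubbard chain.

    H = -t sum_{p,sigma} (a'_{p+1 sigma} a_{p sigma} + h.c.)
        + U sum_p n_{p up} n_{p down}
    """
    space = DeterminantSpace(model.K, *sector)
    K = model.K
    H = sp.csr_matrix((space.dim, space.dim), dtype=float)
    for spin_off in (0, K):
        for p in range(K - 1):
            hop = space.excitation_matrix(spin_off + p + 1, spin_off + p)
            H = H - model.t * (hop + hop.T)
    diag = np.zeros(space.dim)
    for j, det in enumerate(space.dets):
        both = det & (det >> K) & ((1 << K) - 1)
        diag[j] = model.U * bin(both).count("1")
    H = H + sp.diags(diag)
    return H.tocsr()


def lowest_states(
    H: sp.spmatrix | np.ndarray,
    m: int,
    space: DeterminantSpace | None = None,
    tol_degenerate: float = 1e-10,
) -> list[tuple[float, np.ndarray]] | list[tuple[float, CIVector]]:
    """Lowest ``m`` eigenpairs, orthonormal and with canonical sign.

    Degenerate levels (gap below ``tol_degenerate``) are orthonormalized and
    each vector's largest-magnitude amplitude is made positive.  When a
    ``space`` is given, eigenvectors are wrapped as :class:`CIVector`.
    """
    dense = np.asarray(H.todense()) if sp.issparse(H) else np.asarray(H)
    if not np.allclose(dense, dense.conj().T, atol=1e-12):
        raise ValueError("Hamiltonian must be Hermitian")
    dim = dense.shape[0]
    if m > dim:
        raise ValueError(f"requested {m} states from a {dim}-dimensional space")
    if sp.issparse(H) and m < dim // 4 and dim > 400:
        vals, vecs = spla.eigsh(H, k=m, which="SA")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    else:
        vals, vecs = np.linalg.eigh(dense)
        vals, vecs = vals[:m], vecs[:, :m]
    # canonicalize degenerate blocks
    i = 0
    while i < m:
        j = i + 1
        while j < m and vals[j] - vals[i] < tol_degenerate:
            j += 1
        block = vecs[:, i:j]
        q, _ = np.linalg.qr(block)
        vecs[:, i:j] = q
        i = j
    for k in range(m):
        imax = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[imax, k] < 0:
            vecs[:, k] = -vecs[:, k]
    out = []
    for k in range(m):
        residual = np.linalg.norm(dense @ vecs[:, k] - vals[k] * vecs[:, k])
        if residual > 1e-8:
            raise RuntimeError(f"eigenpair {k} residual {residual:.2e} above 1e-8")
        v = CIVector(space, vecs[:, k]) if space is not None else vecs[:, k]
        out.append((float(vals[k]), v))
    return out


# ---------------------------------------------------------------------------
# explicit states from occupation notation
# ---------------------------------------------------------------------------

_SYMBOLS = {
    "0": (False, False),
    "2": (True, True),
    "u": (True, False),
    "d": (False, True),
    "↑": (True, False),   # up arrow
    "↓": (False, True),   # down arrow
    "a": (True, False),
    "b": (False, True),
    "+": (True, False),
    "-": (False, True),
}


def _string_to_det(term: str, K: int) -> tuple[int, int, int, int]:
    """Occupation string -> (det, phase, n_alpha, n_beta).

    The string creates electrons orbital by orbital (left to right), the up
    partner before the down partner within a doubly occupied orbital; the
    phase reorders this product into ascending spin-blocked order.
    """
    creation: list[int] = []
    for i, ch in enumerate(term):
        if ch not in _SYMBOLS:
            raise ValueError(f"invalid occupation symbol {ch!r} in {term!r}")
        a, b = _SYMBOLS[ch]
        if a:
            creation.append(i)
        if b:
            creation.append(K + i)
    inversions = sum(
        1
        for x, y in combinations(range(len(creation)), 2)
        if creation[x] > creation[y]
    )
    det = _mask_from_occ(creation)
    n_alpha = bin(det & ((1 << K) - 1)).count("1")
    n_beta = bin(det >> K).count("1")
    return det, (-1) ** inversions, n_alpha, n_beta


def parse_state(
    terms: Sequence[tuple[str, float | complex]], normalize: bool = True
) -> CIVector:
    """Build a CI vector from ``(occupation string, coefficient)`` pairs.

    Occupation symbols: ``0`` empty, ``u``/``↑`` spin-up, ``d``/``↓``
    spin-down, ``2`` doubly occupied.  All terms must share one length and
    one particle-number sector.
    """
    if not terms:
        raise ValueError("empty state expansion")
    K = len(terms[0][0])
    sector = None
    entries = []
    for term, coeff in terms:
        if len(term) != K:
            raise ValueError("occupation strings must share one length")
        det, phase, na, nb = _string_to_det(term, K)
        if sector is None:
            sector = (na, nb)
        elif sector != (na, nb):
            raise ValueError(
                f"sector mismatch: {term!r} has ({na},{nb}), expected {sector}"
            )
        entries.append((det, phase * coeff))
    space = DeterminantSpace(K, *sector)
    amps = np.zeros(space.dim, dtype=complex if any(
        isinstance(c, complex) for _, c in entries) else float)
    for det, c in entries:
        amps[space.index[det]] += c
    psi = CIVector(space, amps)
    return psi.normalized() if normalize else psi


def product_state(
    psi_A: CIVector,
    psi_B: CIVector,
    layout: tuple[Sequence[int], Sequence[int]] | None = None,
    K_total: int | None = None,
) -> CIVector:
    """Antisymmetrized product of states on disjoint spatial-orbital fragments.

    ``layout = (orbitals_A, orbitals_B)`` maps each fragment's spatial
    orbitals into the global numbering (default: A first, then B).  The
    amplitudes acquire the fermionic phase of reordering the fragment
    creation products into global spin-blocked order.
    """
    KA, KB = psi_A.space.K, psi_B.space.K
    if layout is None:
        layout = (list(range(KA)), list(range(KA, KA + KB)))
    orbs_A, orbs_B = (list(layout[0]), list(layout[1]))
    if len(orbs_A) != KA or len(orbs_B) != KB:
        raise ValueError("layout size does not match fragment orbital counts")
    if set(orbs_A) & set(orbs_B):
        raise ValueError("fragments overlap in the global layout")
    K = K_total if K_total is not None else max(orbs_A + orbs_B) + 1
    na = psi_A.space.n_alpha + psi_B.space.n_alpha
    nb = psi_A.space.n_beta + psi_B.space.n_beta
    space = DeterminantSpace(K, na, nb)
    amps = np.zeros(space.dim, dtype=np.result_type(
        psi_A.amplitudes.dtype, psi_B.amplitudes.dtype))

    def global_creation(det: int, K_frag: int, orbs: Sequence[int]) -> list[int]:
        ops = []
        for p in range(2 * K_frag):
            if det & (1 << p):
                spatial, spin = p % K_frag, p // K_frag
                ops.append(orbs[spatial] + spin * K)
        return ops  # ascending within the fragment's own ordering

    for iA, dA in enumerate(psi_A.space.dets):
        cA = psi_A.amplitudes[iA]
        if cA == 0:
            continue
        opsA = global_creation(dA, KA, orbs_A)
        for iB, dB in enumerate(psi_B.space.dets):
            cB = psi_B.amplitudes[iB]
            if cB == 0:
                continue
            ops = opsA + global_creation(dB, KB, orbs_B)
            inversions = sum(
                1 for x, y in combinations(range(len(ops)), 2) if ops[x] > ops[y]
            )
            det = _mask_from_occ(ops)
            amps[space.index[det]] += (-1) ** inversions * cA * cB
    return CIVector(space, amps).normalized()
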