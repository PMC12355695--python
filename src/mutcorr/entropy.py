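"""Orbital reduced density matrices, entropies, and mutual information.

One- and two-orbital density matrices are obtained from CI vectors by exact
partial trace.  The subsystem Fock-space basis is ordered |0>, |up>, |down>,
|up down> per orbital (lexicographic product for pairs), and the fermionic
phase convention commutes the occupied spin orbitals of orbital P (up before
down), then of Q, to the front of the global spin-blocked ordering.
Entropies are invariant to this choice; individual matrix elements are not.

The closed forms expressing the one-orbital density from 1-/2-RDM elements
are also provided; they are exact for eigenstates of particle number and
S_z, for which the one-orbital density is diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fock_space import CIVector

__all__ = [
    "one_orbital_rdm_from_rdms",
    "one_orbital_rdm_from_ci",
    "two_orbital_rdm",
    "von_neumann_entropy",
    "mutual_information",
    "EntropyReport",
    "entropy_report",
]


def one_orbital_rdm_from_rdms(
    g1: np.ndarray, g2: np.ndarray, P: int
) -> np.ndarray:
    """Diagonal one-orbital density of spatial orbital P from RDM elements.

    rho_P = diag(1 - n_up - n_dn + D,  n_up - D,  n_dn - D,  D)
    with n_sigma the spin-orbital occupations and D the double-occupancy
    expectation <a'_Pu a'_Pd a_Pd a_Pu>.
    """
    n = g1.shape[0]
    K = n // 2
    if not 0 <= P < K:
        raise IndexError(f"orbital {P} outside basis of {K}")
    n_up = float(np.real(g1[P, P]))
    n_dn = float(np.real(g1[K + P, K + P]))
    # gamma2[p,q,r,s] = <a'_p a'_q a_s a_r> so the pair density is [u,d,u,d]
    D = float(np.real(g2[P, K + P, P, K + P]))
    rho = np.diag([1.0 - n_up - n_dn + D, n_up - D, n_dn - D, D])
    if abs(np.trace(rho) - 1.0) > 1e-8:
        raise ValueError(f"one-orbital density trace {np.trace(rho)} is not 1")
    return rho


def _subsystem_phase(det: int, sub_bits: list[int], K: int) -> int:
    """Sign of commuting the occupied ``sub_bits`` (in order) to the front."""
    phase = 0
    moved = 0
    for rank, p in enumerate(sub_bits):
        if det & (1 << p):
            below = bin(det & ((1 << p) - 1)).count("1")
            # orbitals of the subsystem already moved out sit in front
            sub_below = sum(
                1 for q in sub_bits[:rank] if det & (1 << q) and q < p
            )
            phase ^= (below - sub_below) & 1
            moved += 1
    return -1 if phase else 1


def _partial_trace(psi: CIVector, orbitals: list[int]) -> np.ndarray:
    """Reduced density over the Fock space of the given spatial orbitals."""
    space = psi.space
    K = space.K
    sub_bits: list[int] = []
    for P in orbitals:
        if not 0 <= P < K:
            raise IndexError(f"orbital {P} outside basis of {K}")
        sub_bits.extend([P, K + P])  # up partner then down partner
    nsub = len(orbitals)
    dim_sub = 4 ** nsub
    blocks: dict[int, list[tuple[int, int, float]]] = {}
    # local Fock index: per orbital (n_up + 2 n_dn), lexicographic product
    amp_by_env: dict[int, dict[int, complex]] = {}
    for j, det in enumerate(space.dets):
        c = psi.amplitudes[j]
        if c == 0:
            continue
        local = 0
        for r, P in enumerate(orbitals):
            occ_u = bool(det & (1 << P))
            occ_d = bool(det & (1 << (K + P)))
            local += (int(occ_u) + 2 * int(occ_d)) * 4 ** (nsub - 1 - r)
        env = det
        for p in sub_bits:
            env &= ~(1 << p)
        phase = _subsystem_phase(det, sub_bits, K)
        amp_by_env.setdefault(env, {})[local] = phase * c
    rho = np.zeros((dim_sub, dim_sub), dtype=psi.amplitudes.dtype)
    for env, entries in amp_by_env.items():
        idx = list(entries.keys())
        vec = np.array([entries[i] for i in idx])
        rho[np.ix_(idx, idx)] += np.outer(vec, vec.conj())
    return rho


def one_orbital_rdm_from_ci(psi: CIVector, P: int) -> np.ndarray:
    """4 x 4 one-orbital density by exact partial trace (oracle path)."""
    psi.require_normalized()
    return _partial_trace(psi, [P])


def two_orbital_rdm(psi: CIVector, P: int, Q: int) -> np.ndarray:
    """16 x 16 two-orbital density over the product basis |n_P n_Q>."""
    if P == Q:
        raise ValueError("two-orbital density requires distinct orbitals")
    psi.require_normalized()
    rho = _partial_trace(psi, [P, Q])
    tr = float(np.real(np.trace(rho)))
    if abs(tr - 1.0) > 1e-10:
        raise RuntimeError(f"partial trace lost probability: trace = {tr}")
    return rho


def trace_out_second(rho_pq: np.ndarray) -> np.ndarray:
    """Marginal of the first orbital from a two-orbital density."""
    return np.einsum("aibi->ab", rho_pq.reshape(4, 4, 4, 4))


def von_neumann_entropy(rho: np.ndarray, clip: float = 1e-12) -> float:
    """-Tr(rho ln rho) with eigenvalues in [-clip, 0) clipped to zero."""
    evals = np.linalg.eigvalsh(rho)
    if evals.min() < -1e-8:
        raise ValueError(f"density matrix has negative eigenvalue {evals.min()}")
    evals = np.clip(evals, 0.0, None)
    nz = evals[evals > 0.0]
    return float(-np.sum(nz * np.log(nz)))


def mutual_information(s_P: float, s_Q: float, s_PQ: float) -> float:
    """I_PQ = (s_P + s_Q - s_PQ) / 2 for distinct orbitals."""
    return 0.5 * (s_P + s_Q - s_PQ)


@dataclass
class EntropyReport:
    """Per-orbital entropies and the pairwise mutual-information matrix."""

    s_orbital: np.ndarray        # (K,)
    s_pair: np.ndarray           # (K, K), zero diagonal
    I: np.ndarray                # (K, K), zero diagonal


def entropy_report(psi: CIVector) -> EntropyReport:
    """All one-/two-orbital entropies and I_PQ of a CI vector."""
    K = psi.space.K
    s1 = np.array(
        [von_neumann_entropy(one_orbital_rdm_from_ci(psi, P)) for P in range(K)]
    )
    s2 = np.zeros((K, K))
    I = np.zeros((K, K))
    for P in range(K):
        for Q in range(P + 1, K):
            s2[P, Q] = s2[Q, P] = von_neumann_entropy(two_orbital_rdm(psi, P, Q))
            I[P, Q] = I[Q, P] = mutual_information(s1[P], s1[Q], s2[P, Q])
    return EntropyReport(s_orbital=s1, s_pair=s2, I=I)
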