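"""Reduced density matrices, the 2-cumulant, and cumulant-based metrics.

Index convention (the classic failure mode — read this first)
-------------------------------------------------------------
The 2-RDM element stored at ``gamma2[p, q, r, s]`` is

    < a'_p a'_q a_s a_r >        (note the annihilator order: s before r)

so that the cumulant decomposition transcribes literally as

    lambda2[p,q,r,s] = gamma2[p,q,r,s] - g1[p,r] g1[q,s] + g1[p,s] g1[q,r]

Both tensors are antisymmetric under p<->q and r<->s separately and
Hermitian under (p,q)<->(r,s) with complex conjugation.

All tensors are dense; bases beyond K = 16 spatial orbitals (32 spin
orbitals) are refused outright rather than allowed to thrash.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fock_space import CIVector, DeterminantSpace

__all__ = [
    "MetricReport",
    "one_rdm",
    "two_rdm",
    "two_rdm_direct",
    "cumulant",
    "metrics",
    "raw_frobenius_sq",
    "matricize_geminal",
    "matricize_ph",
    "spin_summed_one_rdm",
    "natural_orbitals",
    "rotate_one_rdm",
    "rotate_two_index_tensor",
    "spin_orbital_rotation",
]

MAX_SPATIAL_ORBITALS = 16


def _check_size(K: int) -> None:
    if K > MAX_SPATIAL_ORBITALS:
        raise ValueError(
            f"dense cumulant tensors are limited to K <= {MAX_SPATIAL_ORBITALS} "
            f"spatial orbitals; got K = {K}"
        )


def one_rdm(psi: CIVector) -> np.ndarray:
    """One-body RDM ``g1[p, r] = < a'_p a_r >`` over 2K spin orbitals."""
    psi.require_normalized()
    space = psi.space
    _check_size(space.K)
    n = 2 * space.K
    c = psi.amplitudes
    g1 = np.zeros((n, n), dtype=c.dtype)
    for spin in (0, 1):
        if (space.n_alpha if spin == 0 else space.n_beta) == 0:
            continue
        idx = range(spin * space.K, (spin + 1) * space.K)
        vecs = np.stack([space.annihilation_matrix(p) @ c for p in idx])
        # g1[p,r] = <a_p psi | a_r psi> = sum_x conj(v_p[x]) v_r[x]
        g1[np.ix_(idx, idx)] = vecs.conj() @ vecs.T
    return g1


def two_rdm(psi: CIVector) -> np.ndarray:
    """Two-body RDM as a 4-index tensor via the pair-annihilation Gram matrix.

    ``g2[p,q,r,s] = <W_pq | W_rs>`` with ``W_xy = a_y a_x |psi>`` for x < y,
    extended to all index orders by antisymmetry.
    """
    psi.require_normalized()
    space = psi.space
    _check_size(space.K)
    n = 2 * space.K
    c = psi.amplitudes
    g2 = np.zeros((n, n, n, n), dtype=c.dtype)
    groups = _pair_groups(space)
    for pairs in groups.values():
        if not pairs:
            continue
        W = np.stack(
            [space.pair_annihilation_matrix(p, q) @ c for (p, q) in pairs]
        )
        gram = W.conj() @ W.T
        for i, (p, q) in enumerate(pairs):
            for j, (r, s) in enumerate(pairs):
                v = gram[i, j]
                g2[p, q, r, s] = v
                g2[q, p, r, s] = -v
                g2[p, q, s, r] = -v
                g2[q, p, s, r] = v
    return g2


def _pair_groups(space: DeterminantSpace) -> dict[str, list[tuple[int, int]]]:
    """Ordered pairs p < q grouped by spin type (fixed-Sz selection rule)."""
    K, na, nb = space.K, space.n_alpha, space.n_beta
    groups: dict[str, list[tuple[int, int]]] = {"aa": [], "ab": [], "bb": []}
    for p in range(2 * K):
        for q in range(p + 1, 2 * K):
            tp, tq = p // K, q // K
            key = "aa" if (tp, tq) == (0, 0) else "bb" if (tp, tq) == (1, 1) else "ab"
            groups[key].append((p, q))
    if na < 2:
        groups["aa"] = []
    if nb < 2:
        groups["bb"] = []
    if na < 1 or nb < 1:
        groups["ab"] = []
    return groups


def two_rdm_direct(psi: CIVector) -> np.ndarray:
    """Brute-force 2-RDM by applying explicit operator strings (test oracle)."""
    from .fock_space import apply_operator_string

    psi.require_normalized()
    space = psi.space
    n = 2 * space.K
    c = psi.amplitudes
    g2 = np.zeros((n, n, n, n), dtype=c.dtype)
    for p in range(n):
        for q in range(n):
            for r in range(n):
                for s in range(n):
                    acc = 0.0
                    for j, det in enumerate(space.dets):
                        if c[j] == 0:
                            continue
                        res = apply_operator_string(
                            det,
                            [(p, True), (q, True), (s, False), (r, False)],
                            n_spin_orbitals=n,
                        )
                        if res is None:
                            continue
                        out, phase = res
                        i = space.index.get(out)
                        if i is not None:
                            acc += np.conj(c[i]) * phase * c[j]
                    g2[p, q, r, s] = acc
    return g2


def cumulant(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Connected part of the 2-RDM (the 2-cumulant)."""
    n = g1.shape[0]
    if g2.shape != (n, n, n, n):
        raise ValueError("1-RDM and 2-RDM dimensions are inconsistent")
    return (
        g2
        - np.einsum("pr,qs->pqrs", g1, g1)
        + np.einsum("ps,qr->pqrs", g1, g1)
    )


def raw_frobenius_sq(lam: np.ndarray) -> float:
    """Squared Frobenius norm of the cumulant, without the 1/4 factor."""
    return float(np.sum(np.abs(lam) ** 2))


def matricize_geminal(lam: np.ndarray, all_pairs: bool = False) -> np.ndarray:
    """Geminal matricization: rows/columns indexed by ordered pairs p < q.

    The unique-pair form (dimension ``2K^2 - K`` for 2K spin orbitals) is the
    default; ``all_pairs=True`` uses every (p, q) tuple, which changes the
    spectrum.
    """
    n = lam.shape[0]
    if all_pairs:
        return lam.reshape(n * n, n * n)
    pairs = [(p, q) for p in range(n) for q in range(p + 1, n)]
    m = np.empty((len(pairs), len(pairs)), dtype=lam.dtype)
    for i, (p, q) in enumerate(pairs):
        for j, (r, s) in enumerate(pairs):
            m[i, j] = lam[p, q, r, s]
    return m


def matricize_ph(lam: np.ndarray) -> np.ndarray:
    """Particle-hole matricization over all pairs: M[[pq],[rs]] = lam[p,r,q,s]."""
    return np.ascontiguousarray(lam.transpose(0, 2, 1, 3)).reshape(
        lam.shape[0] ** 2, lam.shape[0] ** 2
    )


def _lambda_max(m: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvalsh(m))))


@dataclass(frozen=True)
class MetricReport:
    """Cumulant-based correlation metrics of one state.

    ``raw_norm`` is ||lambda2||_F^2 as printed in the worked examples; ``C``
    carries the extra factor 1/4 used by the total-correlation tables.
    """

    raw_norm: float
    C: float
    trace_lambda2: float
    lambda_max_gem: float
    lambda_max_ph: float


def metrics(lam: np.ndarray) -> MetricReport:
    """Evaluate all cumulant metrics: norms, trace, extremal eigenvalues."""
    raw = raw_frobenius_sq(lam)
    trace = float(np.real(np.einsum("pqpq->", lam)))
    return MetricReport(
        raw_norm=raw,
        C=raw / 4.0,
        trace_lambda2=trace,
        lambda_max_gem=_lambda_max(matricize_geminal(lam)),
        lambda_max_ph=_lambda_max(matricize_ph(lam)),
    )


# ---------------------------------------------------------------------------
# natural orbitals and rotations
# ---------------------------------------------------------------------------

def spin_summed_one_rdm(g1: np.ndarray) -> np.ndarray:
    """Spin-summed K x K 1-RDM from the spin-blocked 2K x 2K one."""
    n = g1.shape[0]
    if n % 2:
        raise ValueError("spin-blocked 1-RDM must have even dimension")
    K = n // 2
    return g1[:K, :K] + g1[K:, K:]


def natural_orbitals(
    g1: np.ndarray, degeneracy_tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Natural orbitals of the spin-summed 1-RDM.

    Returns ``(spin_summed_rdm, U, noons)`` where the columns of the K x K
    unitary ``U`` are the natural orbitals, sorted by descending occupation.
    Within degenerate blocks the orbitals are canonicalized by maximizing
    overlap with the input orbitals, and phases are fixed by making the
    largest coefficient positive.
    """
    ss = spin_summed_one_rdm(g1)
    if not np.allclose(ss, ss.conj().T, atol=1e-10):
        raise ValueError("spin-summed 1-RDM is not Hermitian")
    vals, vecs = np.linalg.eigh(ss)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    K = ss.shape[0]
    i = 0
    while i < K:
        j = i + 1
        while j < K and vals[i] - vals[j] < degeneracy_tol:
            j += 1
        if j - i > 1:
            block = vecs[:, i:j]
            # orthogonal Procrustes against the coordinate axes the block
            # overlaps most strongly: keeps symmetry-paired orbitals aligned
            # with the input basis instead of arbitrarily mixed
            rows = np.argsort(np.linalg.norm(block, axis=1))[::-1][: j - i]
            u_svd, _, vt = np.linalg.svd(block[np.sort(rows), :])
            vecs[:, i:j] = block @ (u_svd @ vt).conj().T
        i = j
    for k in range(K):
        imax = int(np.argmax(np.abs(vecs[:, k])))
        if np.real(vecs[imax, k]) < 0:
            vecs[:, k] = -vecs[:, k]
    return ss, vecs, vals


def _require_unitary(U: np.ndarray, tol: float = 1e-10) -> None:
    if not np.allclose(U.conj().T @ U, np.eye(U.shape[0]), atol=tol):
        raise ValueError("rotation matrix is not unitary")


def spin_orbital_rotation(U_spatial: np.ndarray) -> np.ndarray:
    """Expand a restricted K x K spatial rotation to the 2K spin orbitals."""
    _require_unitary(U_spatial)
    K = U_spatial.shape[0]
    U2 = np.zeros((2 * K, 2 * K), dtype=U_spatial.dtype)
    U2[:K, :K] = U_spatial
    U2[K:, K:] = U_spatial
    return U2


def rotate_one_rdm(g1: np.ndarray, U_spatial: np.ndarray) -> np.ndarray:
    """1-RDM in the rotated basis: g1' = U2+ g1 U2."""
    U2 = spin_orbital_rotation(U_spatial)
    return U2.conj().T @ g1 @ U2


def rotate_two_index_tensor(t4: np.ndarray, U_spatial: np.ndarray) -> np.ndarray:
    """Rotate a 4-index tensor (2-RDM or cumulant) by a spatial unitary.

    Upper (creation) indices transform with the conjugate, lower indices
    plainly, so every metric in :func:`metrics` is preserved.
    """
    U2 = spin_orbital_rotation(U_spatial)
    out = np.einsum("ap,abcd->pbcd", U2.conj(), t4, optimize=True)
    out = np.einsum("bq,pbcd->pqcd", U2.conj(), out, optimize=True)
    out = np.einsum("cr,pqcd->pqrd", U2, out, optimize=True)
    out = np.einsum("ds,pqrd->pqrs", U2, out, optimize=True)
    return out
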