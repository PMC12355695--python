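"""Maximization of the cumulant norm over all states of a sector.

The squared Frobenius norm of the 2-cumulant is a smooth function of the CI
amplitudes c on the unit sphere.  Both RDMs are Gram matrices of annihilated
vectors,

    gamma1[p, r]    = <B_p c, B_r c>,        B_p = a_p
    gamma2[pq, rs]  = <A_pq c, A_rs c>,      A_pq = a_q a_p   (p < q)

which gives a cheap analytic gradient: with Lambda the unique-pair matrix of
the cumulant and G[p,r] = sum_{qs} lambda[p,q,r,s] gamma1[q,s],

    d(raw)/dc = 16 sum_{p<q} A_pq^T (Lambda Phi)_pq - 16 sum_p B_p^T (G Psi)_p

projected onto the tangent space of the sphere.  Ascent uses L-BFGS over
seeded random restarts; the maximizers are degenerate (any unitary image of
a maximizer is one), so only the maximum value is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .density import cumulant, matricize_geminal, one_rdm, two_rdm, _pair_groups
from .fock_space import CIVector, DeterminantSpace

__all__ = ["cumulant_norm_and_grad", "maximize_cumulant_norm", "max_abs_trace_lambda2"]


def _operator_stacks(space: DeterminantSpace):
    """Per spin-type group: ordered pair list and stacked sparse operators."""
    groups = _pair_groups(space)
    pair_ops = {
        key: [(pq, space.pair_annihilation_matrix(*pq)) for pq in pairs]
        for key, pairs in groups.items()
    }
    single_ops = []
    for p in range(2 * space.K):
        spin = p // space.K
        n_el = space.n_alpha if spin == 0 else space.n_beta
        single_ops.append(
            space.annihilation_matrix(p) if n_el > 0 else None
        )
    return pair_ops, single_ops


def cumulant_norm_and_grad(
    c: np.ndarray, space: DeterminantSpace, ops=None
) -> tuple[float, np.ndarray]:
    """raw ||lambda2||_F^2 of the normalized state and its c-gradient.

    The input need not be normalized; the function evaluates on c/|c| and
    returns the gradient of the composition (tangent-projected chain rule).
    """
    if ops is None:
        ops = _operator_stacks(space)
    pair_ops, single_ops = ops
    r = np.linalg.norm(c)
    u = c / r
    n = 2 * space.K
    psi = CIVector(space, u)
    g1 = one_rdm(psi)
    g2 = two_rdm(psi)
    lam = cumulant(g1, g2)
    raw = float(np.sum(lam**2))

    # gamma2 part: 16 sum_{p<q} A_pq^T (Lambda Phi)_pq, block by spin type
    grad = np.zeros_like(u)
    all_pairs = [(p, q) for p in range(n) for q in range(p + 1, n)]
    pair_index = {pq: i for i, pq in enumerate(all_pairs)}
    Lam = matricize_geminal(lam)
    for key, entries in pair_ops.items():
        if not entries:
            continue
        idx = [pair_index[pq] for pq, _ in entries]
        Phi = np.stack([A @ u for _, A in entries])
        T = Lam[np.ix_(idx, idx)] @ Phi
        for row, (_, A) in enumerate(entries):
            grad += 16.0 * (A.T @ T[row])

    # gamma1 part: -16 sum_p B_p^T (G Psi)_p
    G = np.einsum("pqrs,qs->pr", lam, g1, optimize=True)
    # annihilated vectors live in spin-dependent sectors; G is block
    # diagonal in spin for fixed-Sz states, so treat each spin separately
    K = space.K
    for spin in (0, 1):
        singles = [
            (p, single_ops[p], single_ops[p] @ u)
            for p in range(spin * K, (spin + 1) * K)
            if single_ops[p] is not None
        ]
        if not singles:
            continue
        W = np.stack([w for _, _, w in singles])
        ps = [p for p, _, _ in singles]
        S = G[np.ix_(ps, ps)] @ W
        for row, (_, B, _) in enumerate(singles):
            grad -= 16.0 * (B.T @ S[row])

    # pull back through the normalization c -> c/|c|
    grad = (grad - (u @ grad) * u) / r
    return raw, grad


def maximize_cumulant_norm(
    space: DeterminantSpace,
    restarts: int = 20,
    seed: int = 0,
    maxiter: int = 500,
    include_seniority_zero_start: bool = True,
) -> tuple[float, CIVector, list[float]]:
    """Best raw ||lambda2||_F^2 over the sector's unit sphere.

    Projected-gradient / L-BFGS ascent from seeded random states; one
    restart (optionally) starts from a random seniority-zero superposition
    of doubly occupied determinants, the structure of known maximizers.
    Returns (best raw value, maximizing state, per-restart values).
    """
    rng = np.random.default_rng(seed)
    ops = _operator_stacks(space)

    def objective(c):
        raw, grad = cumulant_norm_and_grad(c, space, ops)
        return -raw, -grad

    values = []
    best: tuple[float, np.ndarray] | None = None
    for restart in range(restarts):
        c0 = rng.normal(size=space.dim)
        if include_seniority_zero_start and restart == 0:
            mask = np.array(
                [
                    (d & ((1 << space.K) - 1)) == (d >> space.K)
                    for d in space.dets
                ]
            )
            if mask.any():
                c0 = np.where(mask, c0, 0.0)
        c0 /= np.linalg.norm(c0)
        res = minimize(
            objective,
            c0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10},
        )
        val = -res.fun
        values.append(val)
        if best is None or val > best[0]:
            best = (val, res.x / np.linalg.norm(res.x))
    return best[0], CIVector(space, best[1]), values


def max_abs_trace_lambda2(n_spin_orbitals: int, n_electrons: int) -> float:
    """Maximum of |Tr lambda2| over admissible 1-RDM spectra.

    Tr lambda2 = Tr(gamma1^2 - gamma1) = sum_p (n_p^2 - n_p) with spin-orbital
    occupations n_p in [0, 1] summing to N; the extremum is found numerically
    over the occupation simplex.
    """
    from scipy.optimize import minimize as _min

    n = n_spin_orbitals
    N = n_electrons
    if not 0 <= N <= n:
        raise ValueError("electron count outside the basis capacity")

    def f(x):  # minimize sum(n^2 - n) -> most negative trace
        return np.sum(x**2 - x)

    x0 = np.full(n, N / n)
    res = _min(
        f,
        x0,
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda x: np.sum(x) - N}],
        method="SLSQP",
    )
    return float(abs(res.fun))
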