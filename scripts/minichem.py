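"""Minimal Gaussian-integral / RHF / CASSCF machinery for fixture generation.

This module exists to produce the molecular integral fixtures shipped with
the package (FCIDUMP files for H2 and the N2 valence active space).  It is
self-contained on numpy/scipy and is NOT part of the analysis library: the
package itself consumes FCIDUMP files and never performs SCF.

Integrals use the McMurchie-Davidson scheme over contracted Cartesian
Gaussians, with d shells transformed to real solid harmonics (5 functions),
matching the spherical-harmonic convention of mainstream quantum-chemistry
programs.  The cc-pVDZ parameters below are the standard published values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import hyp1f1
from scipy.linalg import eigh, expm

ANGSTROM_TO_BOHR = 1.0 / 0.529177210903

# --------------------------------------------------------------------------
# cc-pVDZ basis data (exponents / contraction coefficients, per element)
# --------------------------------------------------------------------------

CC_PVDZ = {
    "H": [
        ("s", [13.0100000, 1.9620000, 0.4446000, 0.1220000],
              [0.0196850, 0.1379770, 0.4781480, 0.5012400]),
        ("s", [0.1220000], [1.0]),
        ("p", [0.7270000], [1.0]),
    ],
    "N": [
        ("s", [9046.0000000, 1357.0000000, 309.3000000, 87.7300000,
               28.5600000, 10.2100000, 3.8380000, 0.7466000, 0.2248000],
              [0.0007000, 0.0053890, 0.0274060, 0.1032070, 0.2787230,
               0.4485400, 0.2782380, 0.0154400, -0.0028640]),
        ("s", [9046.0000000, 1357.0000000, 309.3000000, 87.7300000,
               28.5600000, 10.2100000, 3.8380000, 0.7466000, 0.2248000],
              [-0.0001530, -0.0012080, -0.0059920, -0.0245440, -0.0674590,
               -0.1580780, -0.1218310, 0.5490030, 0.5788150]),
        ("s", [0.2248000], [1.0]),
        ("p", [13.5500000, 2.9170000, 0.7973000, 0.2185000],
              [0.0399190, 0.2171690, 0.5103190, 0.4622140]),
        ("p", [0.2185000], [1.0]),
        ("d", [0.8170000], [1.0]),
    ],
}

CHARGE = {"H": 1, "N": 7}
L_OF = {"s": 0, "p": 1, "d": 2}


@dataclass
class Shell:
    l: int
    center: np.ndarray
    exps: np.ndarray
    coefs: np.ndarray  # primitive norms folded in; contracted normalized


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def build_shells(atoms: list[tuple[str, np.ndarray]]) -> list[Shell]:
    shells = []
    for el, xyz in atoms:
        for ltype, exps, coefs in CC_PVDZ[el]:
            l = L_OF[ltype]
            e = np.asarray(exps, float)
            c = np.asarray(coefs, float)
            # normalize primitives as the (l,0,0) Cartesian component
            norms = (2 * e / np.pi) ** 0.75 * np.sqrt(
                (4 * e) ** l / _double_factorial(2 * l - 1)
            )
            c = c * norms
            # normalize the contracted (l,0,0) function
            ee = e[:, None] + e[None, :]
            s = (
                np.pi ** 1.5
                * _double_factorial(2 * l - 1)
                / (2.0 ** l)
                / ee ** (l + 1.5)
            )
            nrm = np.einsum("i,j,ij->", c, c, s)
            shells.append(Shell(l, np.asarray(xyz, float), e, c / math.sqrt(nrm)))
    return shells


def cart_components(l: int) -> list[tuple[int, int, int]]:
    return [
        (lx, ly, l - lx - ly)
        for lx in range(l, -1, -1)
        for ly in range(l - lx, -1, -1)
    ]


# spherical-harmonic coefficients acting on (l,0,0)-normalized Cartesians
_D_CART = cart_components(2)  # xx, xy, xz, yy, yz, zz
_SPH_D = np.zeros((5, 6))
_SPH_D[0, _D_CART.index((1, 1, 0))] = math.sqrt(3.0)            # m=-2: xy
_SPH_D[1, _D_CART.index((0, 1, 1))] = math.sqrt(3.0)            # m=-1: yz
_SPH_D[2, _D_CART.index((0, 0, 2))] = 1.0                       # m=0
_SPH_D[2, _D_CART.index((2, 0, 0))] = -0.5
_SPH_D[2, _D_CART.index((0, 2, 0))] = -0.5
_SPH_D[3, _D_CART.index((1, 0, 1))] = math.sqrt(3.0)            # m=+1: xz
_SPH_D[4, _D_CART.index((2, 0, 0))] = math.sqrt(3.0) / 2.0      # m=+2
_SPH_D[4, _D_CART.index((0, 2, 0))] = -math.sqrt(3.0) / 2.0


# Cartesian d option: keep all six components, renormalized (the xy-type
# components need sqrt(3) relative to the xx-type normalization)
_CART_D = np.diag([1.0, math.sqrt(3.0), math.sqrt(3.0), 1.0,
                   math.sqrt(3.0), 1.0])


def sph_transform(l: int, cartesian_d: bool = False) -> np.ndarray:
    if l == 0:
        return np.eye(1)
    if l == 1:
        return np.eye(3)
    if l == 2:
        return _CART_D if cartesian_d else _SPH_D
    raise NotImplementedError


# --------------------------------------------------------------------------
# McMurchie-Davidson primitives
# --------------------------------------------------------------------------

def _e_coeffs_1d(l1: int, l2: int, a: float, b: float, AB: float) -> np.ndarray:
    """Hermite expansion coefficients E[i, j, t] for one Cartesian direction."""
    p = a + b
    mu = a * b / p
    E = np.zeros((l1 + 1, l2 + 1, l1 + l2 + 1))
    E[0, 0, 0] = math.exp(-mu * AB * AB)
    PA = -b * AB / p   # P - A with A at origin-shifted coords: P = (aA+bB)/p
    PB = a * AB / p    # P - B
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                for t in range(i + j + 1):
                    v = 0.0
                    if t - 1 >= 0:
                        v += E[i - 1, j, t - 1] / (2 * p)
                    v += PA * E[i - 1, j, t] if t <= (i - 1 + j) else 0.0
                    if t + 1 <= i - 1 + j:
                        v += (t + 1) * E[i - 1, j, t + 1]
                    E[i, j, t] = v
            else:
                for t in range(i + j + 1):
                    v = 0.0
                    if t - 1 >= 0:
                        v += E[i, j - 1, t - 1] / (2 * p)
                    v += PB * E[i, j - 1, t] if t <= (i + j - 1) else 0.0
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * E[i, j - 1, t + 1]
                    E[i, j, t] = v
    return E


def boys(n_max: int, x: np.ndarray) -> np.ndarray:
    """Boys functions F_0..F_n, vectorized over x; shape (n_max+1, len(x))."""
    x = np.atleast_1d(np.asarray(x, float))
    out = np.empty((n_max + 1, x.size))
    for n in range(n_max + 1):
        out[n] = hyp1f1(n + 0.5, n + 1.5, -x) / (2 * n + 1)
    return out


def _hermite_R(Lt: int, p, PQ: np.ndarray) -> np.ndarray:
    """Hermite Coulomb integrals R^0_{tuv}, batch over the last axis of PQ.

    PQ: (3, nbatch); p scalar or (nbatch,).  Returns (Lt+1,)*3 + (nbatch,).
    Recursion: R^n_{000} = (-2p)^n F_n(p |PQ|^2);
    R^n_{t+1,u,v} = t R^{n+1}_{t-1,u,v} + X_PQ R^{n+1}_{t,u,v}   (etc).
    """
    nb = PQ.shape[1]
    p = np.broadcast_to(np.asarray(p, float), (nb,))
    r2 = np.einsum("xn,xn->n", PQ, PQ)
    F = boys(Lt, p * r2)
    base = (-2.0 * p[None, :]) ** np.arange(Lt + 1)[:, None] * F
    cache: dict[tuple[int, int, int, int], np.ndarray] = {}

    def R(n: int, t: int, u: int, v: int) -> np.ndarray:
        if t < 0 or u < 0 or v < 0:
            return 0.0
        key = (n, t, u, v)
        if key in cache:
            return cache[key]
        if t == u == v == 0:
            val = base[n]
        elif t >= 1:
            val = (t - 1) * R(n + 1, t - 2, u, v) + PQ[0] * R(n + 1, t - 1, u, v)
        elif u >= 1:
            val = (u - 1) * R(n + 1, t, u - 2, v) + PQ[1] * R(n + 1, t, u - 1, v)
        else:
            val = (v - 1) * R(n + 1, t, u, v - 2) + PQ[2] * R(n + 1, t, u, v - 1)
        cache[key] = val
        return val

    out = np.zeros((Lt + 1, Lt + 1, Lt + 1, nb))
    for t in range(Lt + 1):
        for u in range(Lt + 1 - t):
            for v in range(Lt + 1 - t - u):
                out[t, u, v] = R(0, t, u, v)
    return out


# --------------------------------------------------------------------------
# shell-pair data and integral drivers
# --------------------------------------------------------------------------

class ShellPair:
    """Primitive-pair data for one (shell, shell) combination."""

    def __init__(self, sh1: Shell, sh2: Shell):
        self.sh1, self.sh2 = sh1, sh2
        l1, l2 = sh1.l, sh2.l
        AB = sh1.center - sh2.center
        pairs = []
        for i, a in enumerate(sh1.exps):
            for j, b in enumerate(sh2.exps):
                p = a + b
                P = (a * sh1.center + b * sh2.center) / p
                E3 = [_e_coeffs_1d(l1, l2 + 2, a, b, AB[x]) for x in range(3)]
                pairs.append((p, P, E3, sh1.coefs[i] * sh2.coefs[j]))
        self.pairs = pairs
        c1, c2 = cart_components(l1), cart_components(l2)
        self.c1, self.c2 = c1, c2
        Lt = l1 + l2
        # Hermite product tensor per primitive pair: (npp, nc1*nc2, T,U,V)
        Eb = np.zeros((len(pairs), len(c1) * len(c2), Lt + 1, Lt + 1, Lt + 1))
        self.p_arr = np.array([p for p, _, _, _ in pairs])
        self.P_arr = np.array([P for _, P, _, _ in pairs])
        self.cc_arr = np.array([cc for _, _, _, cc in pairs])
        for n, (p, P, E3, cc) in enumerate(pairs):
            for a, (lx1, ly1, lz1) in enumerate(c1):
                for b, (lx2, ly2, lz2) in enumerate(c2):
                    ab = a * len(c2) + b
                    ex = E3[0][lx1, lx2, : Lt + 1]
                    ey = E3[1][ly1, ly2, : Lt + 1]
                    ez = E3[2][lz1, lz2, : Lt + 1]
                    Eb[n, ab] = (
                        ex[:, None, None] * ey[None, :, None] * ez[None, None, :]
                    )
        self.hermite = Eb
        self.Lt = Lt


def overlap_kinetic(sp: ShellPair) -> tuple[np.ndarray, np.ndarray]:
    l1, l2 = sp.sh1.l, sp.sh2.l
    c1, c2 = sp.c1, sp.c2
    S = np.zeros((len(c1), len(c2)))
    T = np.zeros((len(c1), len(c2)))
    for (p, P, E3, cc), (a_exp, b_exp) in zip(
        sp.pairs,
        [(a, b) for a in sp.sh1.exps for b in sp.sh2.exps],
    ):
        w = math.sqrt(math.pi / p)
        for ia, (lx1, ly1, lz1) in enumerate(c1):
            for ib, (lx2, ly2, lz2) in enumerate(c2):
                sx = E3[0][lx1, lx2, 0] * w
                sy = E3[1][ly1, ly2, 0] * w
                sz = E3[2][lz1, lz2, 0] * w
                S[ia, ib] += cc * sx * sy * sz

                def t1d(E, li, lj):
                    val = -2.0 * b_exp**2 * E[li, lj + 2, 0]
                    val += b_exp * (2 * lj + 1) * E[li, lj, 0]
                    if lj >= 2:
                        val -= 0.5 * lj * (lj - 1) * E[li, lj - 2, 0]
                    return val * w

                tx = t1d(E3[0], lx1, lx2)
                ty = t1d(E3[1], ly1, ly2)
                tz = t1d(E3[2], lz1, lz2)
                T[ia, ib] += cc * (tx * sy * sz + sx * ty * sz + sx * sy * tz)
    return S, T


def nuclear(sp: ShellPair, atoms: list[tuple[str, np.ndarray]]) -> np.ndarray:
    c1, c2 = sp.c1, sp.c2
    Lt = sp.Lt
    centers = np.array([xyz for _, xyz in atoms]).T  # (3, natoms)
    charges = np.array([CHARGE[el] for el, _ in atoms], float)
    out = np.zeros((len(c1) * len(c2),))
    for n, (p, P, E3, cc) in enumerate(sp.pairs):
        PC = P[:, None] - centers
        R = _hermite_R(Lt, p, PC)  # (T,U,V, natoms)
        Rw = -np.einsum("tuvn,n->tuv", R, charges)
        out += cc * (2 * math.pi / p) * np.einsum(
            "atuv,tuv->a", sp.hermite[n], Rw
        )
    return out.reshape(len(c1), len(c2))


def eri_quartet(spb: ShellPair, spk: ShellPair) -> np.ndarray:
    """Contracted Cartesian ERI block (nc1*nc2, nc3*nc4), chemists' (12|34)."""
    Lb, Lk = spb.Lt, spk.Lt
    nk = len(spk.pairs)
    # ket Hermite tensors with (-1)^(t+u+v) folded in
    sign = np.fromfunction(
        lambda t, u, v: (-1.0) ** (t + u + v), (Lk + 1, Lk + 1, Lk + 1)
    )
    Ek = spk.hermite * sign[None, None]
    tb = np.arange(Lb + 1)
    tk = np.arange(Lk + 1)
    It = tb[:, None, None, None, None, None] + tk[None, :, None, None, None, None]
    Iu = tb[None, None, :, None, None, None] + tk[None, None, None, :, None, None]
    Iv = tb[None, None, None, None, :, None] + tk[None, None, None, None, None, :]
    G = np.zeros((spb.hermite.shape[1], spk.hermite.shape[1]))
    for n1, (p1, P1, _, cc1) in enumerate(spb.pairs):
        q = spk.p_arr
        alpha = p1 * q / (p1 + q)
        PQ = (P1[None, :] - spk.P_arr).T  # (3, nk)
        R = _hermite_R(Lb + Lk, alpha, PQ)  # (L+1,L+1,L+1,nk)
        pref = (
            2.0 * math.pi ** 2.5
            / (p1 * q * np.sqrt(p1 + q))
            * spk.cc_arr
            * cc1
        )
        R4 = R[It, Iu, Iv, :]  # (Tb,Tk,Ub,Uk,Vb,Vk,nk)
        G += np.einsum(
            "aijk,nbxyz,ixjykzn,n->ab",
            spb.hermite[n1], Ek, R4, pref, optimize=True,
        )
    return G


# --------------------------------------------------------------------------
# molecule-level integrals (spherical AO basis)
# --------------------------------------------------------------------------

class Molecule:
    def __init__(self, atoms: list[tuple[str, np.ndarray]],
                 cartesian_d: bool = False):
        self.atoms = [(el, np.asarray(xyz, float)) for el, xyz in atoms]
        self.cartesian_d = cartesian_d
        self.shells = build_shells(self.atoms)
        self.nbf = sum(
            sph_transform(sh.l, cartesian_d).shape[0] for sh in self.shells
        )
        self.ncart = sum(len(cart_components(sh.l)) for sh in self.shells)
        # block-diagonal cartesian->spherical map
        self.c2s = np.zeros((self.nbf, self.ncart))
        ro = co = 0
        for sh in self.shells:
            t = sph_transform(sh.l, cartesian_d)
            self.c2s[ro : ro + t.shape[0], co : co + t.shape[1]] = t
            ro += t.shape[0]
            co += t.shape[1]
        self.e_nuc = 0.0
        for i, (el1, x1) in enumerate(self.atoms):
            for j, (el2, x2) in enumerate(self.atoms[:i]):
                self.e_nuc += CHARGE[el1] * CHARGE[el2] / np.linalg.norm(x1 - x2)
        self.n_electrons = sum(CHARGE[el] for el, _ in self.atoms)

    def one_electron(self):
        n = self.ncart
        S = np.zeros((n, n))
        T = np.zeros((n, n))
        V = np.zeros((n, n))
        offs = np.cumsum([0] + [len(cart_components(sh.l)) for sh in self.shells])
        for i, sh1 in enumerate(self.shells):
            for j, sh2 in enumerate(self.shells):
                if j > i:
                    continue
                sp = ShellPair(sh1, sh2)
                s, t = overlap_kinetic(sp)
                v = nuclear(sp, self.atoms)
                S[offs[i]:offs[i+1], offs[j]:offs[j+1]] = s
                T[offs[i]:offs[i+1], offs[j]:offs[j+1]] = t
                V[offs[i]:offs[i+1], offs[j]:offs[j+1]] = v
                if i != j:
                    S[offs[j]:offs[j+1], offs[i]:offs[i+1]] = s.T
                    T[offs[j]:offs[j+1], offs[i]:offs[i+1]] = t.T
                    V[offs[j]:offs[j+1], offs[i]:offs[i+1]] = v.T
        C = self.c2s
        return C @ S @ C.T, C @ T @ C.T, C @ V @ C.T

    def eri(self):
        nsh = len(self.shells)
        offs = np.cumsum([0] + [len(cart_components(sh.l)) for sh in self.shells])
        pairs = [(i, j) for i in range(nsh) for j in range(i + 1)]
        sps = {ij: ShellPair(self.shells[ij[0]], self.shells[ij[1]]) for ij in pairs}
        g = np.zeros((self.ncart,) * 4)
        for m1, ij in enumerate(pairs):
            for ij2 in pairs[: m1 + 1]:
                block = eri_quartet(sps[ij], sps[ij2])
                i, j = ij
                k, l = ij2
                b4 = block.reshape(
                    offs[i+1]-offs[i], offs[j+1]-offs[j],
                    offs[k+1]-offs[k], offs[l+1]-offs[l],
                )
                si, sj = slice(offs[i], offs[i+1]), slice(offs[j], offs[j+1])
                sk, sl = slice(offs[k], offs[k+1]), slice(offs[l], offs[l+1])
                g[si, sj, sk, sl] = b4
                g[sj, si, sk, sl] = b4.transpose(1, 0, 2, 3)
                g[si, sj, sl, sk] = b4.transpose(0, 1, 3, 2)
                g[sj, si, sl, sk] = b4.transpose(1, 0, 3, 2)
                g[sk, sl, si, sj] = b4.transpose(2, 3, 0, 1)
                g[sl, sk, si, sj] = b4.transpose(3, 2, 0, 1)
                g[sk, sl, sj, si] = b4.transpose(2, 3, 1, 0)
                g[sl, sk, sj, si] = b4.transpose(3, 2, 1, 0)
        C = self.c2s
        g = np.einsum("pa,abcd->pbcd", C, g, optimize=True)
        g = np.einsum("qb,pbcd->pqcd", C, g, optimize=True)
        g = np.einsum("rc,pqcd->pqrd", C, g, optimize=True)
        g = np.einsum("sd,pqrd->pqrs", C, g, optimize=True)
        return g


# --------------------------------------------------------------------------
# RHF
# --------------------------------------------------------------------------

def rhf(mol: Molecule, max_iter: int = 200, conv: float = 1e-10):
    S, T, V = mol.one_electron()
    g = mol.eri()
    h = T + V
    nocc = mol.n_electrons // 2
    sval, svec = eigh(S)
    X = svec @ np.diag(sval**-0.5) @ svec.T
    F = h.copy()
    E_old = 0.0
    diis_F, diis_E = [], []
    D = None
    for it in range(max_iter):
        e, cmo = eigh(X @ F @ X)
        C = X @ cmo
        Cocc = C[:, :nocc]
        D = 2.0 * Cocc @ Cocc.T
        J = np.einsum("pqrs,rs->pq", g, D, optimize=True)
        Kx = np.einsum("prqs,rs->pq", g, D, optimize=True)
        F = h + J - 0.5 * Kx
        E = 0.5 * np.einsum("pq,pq->", D, h + F) + mol.e_nuc
        err = F @ D @ S - S @ D @ F
        diis_F.append(F.copy())
        diis_E.append(err.copy())
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_E.pop(0)
        if np.max(np.abs(err)) < conv and abs(E - E_old) < conv:
            return E, C, e, (h, g, S)
        E_old = E
        if len(diis_F) > 1:
            nd = len(diis_F)
            B = -np.ones((nd + 1, nd + 1))
            B[nd, nd] = 0.0
            for a in range(nd):
                for b in range(nd):
                    B[a, b] = np.einsum("pq,pq->", diis_E[a], diis_E[b])
            rhs = np.zeros(nd + 1)
            rhs[nd] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:nd]
                F = sum(wi * Fi for wi, Fi in zip(w, diis_F))
            except np.linalg.LinAlgError:
                pass
    raise RuntimeError(f"RHF did not converge; last E = {E}")


def mo_transform(h_ao, g_ao, C):
    h = C.T @ h_ao @ C
    g = np.einsum("pa,abcd->pbcd", C.T, g_ao, optimize=True)
    g = np.einsum("qb,pbcd->pqcd", C.T, g, optimize=True)
    g = np.einsum("rc,pqcd->pqrd", C.T, g, optimize=True)
    g = np.einsum("sd,pqrd->pqrs", C.T, g, optimize=True)
    return h, g


# --------------------------------------------------------------------------
# CASSCF (two-step: exact CASCI each macro-iteration + orbital rotations)
# --------------------------------------------------------------------------

def _cas_energy_and_rdms(h, g, e_nuc, ncore, nact, nelecas, ci_guess=None):
    """CASCI in the active window of the current MO basis.

    Returns (energy, spin-summed active 1-RDM, chemists' active 2-RDM,
    CI vector) using the package FCI machinery.
    """
    from mutcorr.fci import SecondQuantizedHamiltonian, fci
    from mutcorr.density import one_rdm, two_rdm

    act = slice(ncore, ncore + nact)
    core = slice(0, ncore)
    e_core = e_nuc + 2.0 * np.trace(h[core, core])
    e_core += np.einsum("iijj->", 2.0 * g[core, core, core, core]) \
        - np.einsum("ijji->", g[core, core, core, core])
    h_eff = h[act, act] + 2.0 * np.einsum("tuii->tu", g[act, act, core, core]) \
        - np.einsum("tiiu->tu", g[act, core, core, act])
    g_act = g[act, act, act, act]
    ham = SecondQuantizedHamiltonian(
        h=h_eff, g=g_act, e_core=e_core, n_electrons=nelecas, ms2=0
    )
    e, psi = fci(ham, v0=ci_guess, tol=1e-11)[0]
    g1so = one_rdm(psi)
    g2so = two_rdm(psi)
    K = nact
    D1 = g1so[:K, :K] + g1so[K:, K:]
    # chemists' d[P,Q,R,S] = sum_st <a+_Ps a+_Rt a_St a_Qs> = g2so[Ps, Rt, Qs, St]
    D2 = np.zeros((K, K, K, K))
    for o1 in (0, K):
        for o2 in (0, K):
            D2 += g2so[o1:o1+K, o2:o2+K, o1:o1+K, o2:o2+K].transpose(0, 2, 1, 3)
    return e, D1, D2, psi


def _full_rdms(K, ncore, D1a, D2a):
    """Embed active-space RDMs into the full MO space (closed-shell core)."""
    nact = D1a.shape[0]
    act = slice(ncore, ncore + nact)
    D1 = np.zeros((K, K))
    D1[:ncore, :ncore] = 2.0 * np.eye(ncore)
    D1[act, act] = D1a
    D2 = np.zeros((K, K, K, K))
    # core-core
    for i in range(ncore):
        for j in range(ncore):
            D2[i, i, j, j] += 4.0
            D2[i, j, j, i] -= 2.0
    # core-active cross (product-state structure)
    for i in range(ncore):
        D2[i, i, act, act] += 2.0 * D1a
        D2[act, act, i, i] += 2.0 * D1a
        D2[act, i, i, act] -= D1a
        D2[i, act, act, i] -= D1a.T
    D2[act, act, act, act] = D2a
    return D1, D2


def _orbital_gradient(h, g, D1, D2):
    """Gradient of E wrt antisymmetric rotation parameters, g_pq = 2(F_pq - F_qp)."""
    F = D1 @ h.T  # sum_r D1[p,r] h[q,r] with h symmetric
    F += np.einsum("prst,qrst->pq", D2, g, optimize=True)
    # convention: dE/d kappa_pq = grad[p,q] for C -> C expm(kappa)
    return 2.0 * (F.T - F), F


def casscf(
    mol,
    ncore: int,
    nact: int,
    nelecas: int,
    C0=None,
    max_iter: int = 2000,
    gtol: float = 1e-5,
    verbose: bool = True,
    freeze_core: bool = False,
):
    """Two-step CASSCF: exact CASCI + Riemannian BB gradient steps.

    Redundant rotations (within core, active, virtual) are projected out.
    Returns (E, C_mo, info dict).
    """
    E_rhf, C_rhf, eps, (h_ao, g_ao, S) = rhf(mol)
    if C0 is not None:
        # symmetric orthonormalization against the current overlap, so a
        # guess from a neighboring geometry is valid in this AO basis
        M = C0.T @ S @ C0
        w, V = np.linalg.eigh(M)
        C = C0 @ (V @ np.diag(w**-0.5) @ V.T)
    else:
        C = C_rhf.copy()
    K = C.shape[1]
    spaces = np.zeros(K, dtype=int)  # 0 core, 1 active, 2 virtual
    spaces[ncore : ncore + nact] = 1
    spaces[ncore + nact :] = 2
    mask = spaces[:, None] != spaces[None, :]
    if freeze_core:
        mask[:ncore, :] = False
        mask[:, :ncore] = False

    ci_prev = {"v": None}

    def energy_grad(C):
        h, g = mo_transform(h_ao, g_ao, C)
        e, D1a, D2a, psi = _cas_energy_and_rdms(
            h, g, mol.e_nuc, ncore, nact, nelecas, ci_guess=ci_prev["v"]
        )
        ci_prev["v"] = psi.amplitudes
        D1, D2 = _full_rdms(K, ncore, D1a, D2a)
        grad, F = _orbital_gradient(h, g, D1, D2)
        grad = grad * mask  # only inter-space rotations are non-redundant
        return e, grad

    E, grad = energy_grad(C)
    prev_grad = None
    prev_kappa = None
    alpha = 0.02
    hist = [E]
    for it in range(max_iter):
        gnorm = np.max(np.abs(grad))
        if verbose and (it % 10 == 0 or gnorm < gtol):
            print(f"  macro {it:3d}  E = {E:.10f}  |g|max = {gnorm:.2e}", flush=True)
        if gnorm < gtol:
            return E, C, {"iterations": it, "grad_max": gnorm,
                          "converged": True}
        kappa = -alpha * grad
        # Barzilai-Borwein step after the first iteration (non-monotone)
        if prev_grad is not None:
            sk = prev_kappa.ravel()
            yk = (grad - prev_grad).ravel()
            denom = sk @ yk
            if denom > 1e-14:
                alpha_bb = (sk @ sk) / denom
                cap = 0.3 if gnorm < 1e-3 else 2.0
                alpha_bb = min(max(alpha_bb, 1e-4), cap)
                kappa = -alpha_bb * grad
        U = expm(0.5 * (kappa - kappa.T))
        C_new = C @ U
        E_new, grad_new = energy_grad(C_new)
        # accept unless the step rises above the recent-energy watermark
        n_bt = 0
        while E_new > max(hist[-6:]) + 1e-10 and n_bt < 15:
            kappa *= 0.5
            U = expm(0.5 * (kappa - kappa.T))
            C_new = C @ U
            E_new, grad_new = energy_grad(C_new)
            n_bt += 1
        prev_grad = grad
        prev_kappa = kappa
        C, E, grad = C_new, E_new, grad_new
        hist.append(E)
    return E, C, {"iterations": max_iter,
                  "grad_max": float(np.max(np.abs(grad))), "converged": False}


def active_space_integrals(h, g, e_nuc, ncore, nact):
    """Effective active-space Hamiltonian (h_eff, g_act, e_core) in MO basis."""
    act = slice(ncore, ncore + nact)
    core = slice(0, ncore)
    e_core = e_nuc + 2.0 * np.trace(h[core, core])
    e_core += np.einsum("iijj->", 2.0 * g[core, core, core, core]) \
        - np.einsum("ijji->", g[core, core, core, core])
    h_eff = h[act, act] + 2.0 * np.einsum("tuii->tu", g[act, act, core, core]) \
        - np.einsum("tiiu->tu", g[act, core, core, act])
    return h_eff, g[act, act, act, act].copy(), float(e_core)
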