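"""FCIDUMP-driven full configuration interaction for small molecules.

The Hamiltonian is the standard restricted second-quantized form

    H = e_core + sum_PQ h_PQ E_PQ
        + 1/2 sum_PQRS (PQ|RS) (E_PQ E_RS - delta_QR E_PS)

with spatial-orbital one-electron integrals ``h``, chemists'-notation
two-electron integrals ``(PQ|RS)`` with eightfold permutational symmetry,
and spin-summed excitation operators ``E_PQ``.  FCIDUMP files follow the
Molpro dialect (1-based indices, ``value i j k l`` records); indices are
0-based everywhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fock_space import CIVector, DeterminantSpace, lowest_states

__all__ = [
    "SecondQuantizedHamiltonian",
    "read_fcidump",
    "write_fcidump",
    "ci_matvec_operator",
    "fci",
    "fci_from_fcidump",
]


@dataclass
class SecondQuantizedHamiltonian:
    """Spatial-orbital integrals defining a molecular (or lattice) Hamiltonian."""

    h: np.ndarray                      # (K, K) one-electron integrals
    g: np.ndarray                      # (K, K, K, K) chemists' (PQ|RS)
    e_core: float = 0.0
    n_electrons: int | None = None
    ms2: int = 0
    orbsym: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        K = self.h.shape[0]
        if self.h.shape != (K, K) or self.g.shape != (K, K, K, K):
            raise ValueError("integral arrays have inconsistent shapes")
        if not np.allclose(self.h, self.h.T, atol=1e-10):
            raise ValueError("one-electron integrals are not Hermitian")

    @property
    def K(self) -> int:
        return self.h.shape[0]

    def sector(self) -> tuple[int, int]:
        if self.n_electrons is None:
            raise ValueError("electron count not set")
        if (self.n_electrons + self.ms2) % 2:
            raise ValueError("NELEC and MS2 have incompatible parity")
        n_alpha = (self.n_electrons + self.ms2) // 2
        n_beta = self.n_electrons - n_alpha
        return (n_alpha, n_beta)


_HEADER_INT = re.compile(r"(\w+)\s*=\s*([0-9-]+)")
_HEADER_LIST = re.compile(r"ORBSYM\s*=\s*([0-9,\s]+)", re.IGNORECASE)


def read_fcidump(path) -> SecondQuantizedHamiltonian:
    """Parse a Molpro-dialect FCIDUMP file."""
    with open(path) as fh:
        text = fh.read()
    m = re.search(r"(&END|/)", text, re.IGNORECASE)
    if m is None:
        raise ValueError(f"{path}: missing FCIDUMP header terminator")
    header, body = text[: m.start()], text[m.end():]
    fields = {k.upper(): int(v) for k, v in _HEADER_INT.findall(
        re.sub(r"ORBSYM\s*=\s*[0-9,\s]+", "", header, flags=re.IGNORECASE))}
    if "NORB" not in fields or "NELEC" not in fields:
        raise ValueError(f"{path}: FCIDUMP header lacks NORB/NELEC")
    K = fields["NORB"]
    orbsym = None
    lm = _HEADER_LIST.search(header)
    if lm:
        orbsym = tuple(
            int(x) for x in lm.group(1).replace(",", " ").split() if x
        )
    h = np.zeros((K, K))
    g = np.zeros((K, K, K, K))
    e_core = 0.0
    for lineno, line in enumerate(body.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{lineno}: malformed record {line!r}")
        try:
            val = float(parts[0])
            i, j, k, l = (int(x) for x in parts[1:])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed record {line!r}") from exc
        if i == 0 and j == 0 and k == 0 and l == 0:
            e_core = val
        elif k == 0 and l == 0:
            h[i - 1, j - 1] = h[j - 1, i - 1] = val
        else:
            _set_eri(g, i - 1, j - 1, k - 1, l - 1, val)
    return SecondQuantizedHamiltonian(
        h=h, g=g, e_core=e_core,
        n_electrons=fields["NELEC"], ms2=fields.get("MS2", 0), orbsym=orbsym,
    )


def _set_eri(g: np.ndarray, i: int, j: int, k: int, l: int, val: float) -> None:
    for a, b, c, d in (
        (i, j, k, l), (j, i, k, l), (i, j, l, k), (j, i, l, k),
        (k, l, i, j), (l, k, i, j), (k, l, j, i), (l, k, j, i),
    ):
        g[a, b, c, d] = val


def write_fcidump(
    path, ham: SecondQuantizedHamiltonian, tol: float = 1e-12
) -> None:
    """Write unique eightfold-symmetry records of a real Hamiltonian."""
    K = ham.K
    orbsym = ham.orbsym or tuple([1] * K)
    with open(path, "w") as fh:
        fh.write(
            f"&FCI NORB={K},NELEC={ham.n_electrons},MS2={ham.ms2},\n"
            f"  ORBSYM={','.join(str(s) for s in orbsym)},\n  ISYM=1,\n&END\n"
        )
        for i in range(K):
            for j in range(i + 1):
                for k in range(i + 1):
                    lmax = j if k == i else k
                    for l in range(lmax + 1):
                        v = ham.g[i, j, k, l]
                        if abs(v) > tol:
                            fh.write(
                                f"{v:23.16e} {i+1:3d} {j+1:3d} {k+1:3d} {l+1:3d}\n"
                            )
        for i in range(K):
            for j in range(i + 1):
                if abs(ham.h[i, j]) > tol:
                    fh.write(f"{ham.h[i, j]:23.16e} {i+1:3d} {j+1:3d}   0   0\n")
        fh.write(f"{ham.e_core:23.16e}   0   0   0   0\n")


# ---------------------------------------------------------------------------
# CI Hamiltonian
# ---------------------------------------------------------------------------

def _spin_summed_excitations(space: DeterminantSpace) -> list[list[sp.csr_matrix]]:
    """Cached sparse E_PQ = sum_sigma a'_{P sigma} a_{Q sigma} matrices."""
    cache = getattr(space, "_exc_sum_cache", None)
    if cache is not None:
        return cache
    K = space.K
    mats = [[None] * K for _ in range(K)]
    for P in range(K):
        for Q in range(K):
            E = space.excitation_matrix(P, Q) + space.excitation_matrix(
                K + P, K + Q
            )
            mats[P][Q] = E.tocsr()
    space._exc_sum_cache = mats
    return mats


def ci_matvec_operator(
    ham: SecondQuantizedHamiltonian, space: DeterminantSpace
) -> spla.LinearOperator:
    """Matrix-free CI Hamiltonian (excluding ``e_core``) on a sector basis."""
    if ham.K != space.K:
        raise ValueError("orbital counts of integrals and basis differ")
    K, dim = ham.K, space.dim
    E = _spin_summed_excitations(space)
    h_eff = ham.h - 0.5 * np.einsum("prrq->pq", ham.g)
    g_mat = ham.g.reshape(K * K, K * K)

    def matvec(c: np.ndarray) -> np.ndarray:
        c = np.asarray(c).ravel()
        X = np.empty((K * K, dim))
        for P in range(K):
            for Q in range(K):
                X[P * K + Q] = E[P][Q] @ c
        out = h_eff.ravel() @ X
        Y = g_mat @ X
        for P in range(K):
            for Q in range(K):
                out += 0.5 * (E[P][Q] @ Y[P * K + Q])
        return out

    return spla.LinearOperator((dim, dim), matvec=matvec, dtype=float)


def ci_hamiltonian_dense(
    ham: SecondQuantizedHamiltonian, space: DeterminantSpace
) -> np.ndarray:
    op = ci_matvec_operator(ham, space)
    return op @ np.eye(space.dim)


def fci(
    ham: SecondQuantizedHamiltonian,
    n_roots: int = 1,
    sector: tuple[int, int] | None = None,
    tol: float = 1e-10,
    v0: np.ndarray | None = None,
) -> list[tuple[float, CIVector]]:
    """Lowest ``n_roots`` eigenstates; energies include ``e_core``.

    Degenerate roots are orthonormalized and sign-canonicalized exactly as
    in :func:`mutcorr.fock_space.lowest_states`.
    """
    if sector is None:
        sector = ham.sector()
    from .fock_space import sector_space

    space = sector_space(ham.K, *sector)
    dim = space.dim
    if n_roots > dim:
        raise ValueError(f"requested {n_roots} roots from dimension {dim}")
    if dim <= 600:
        H = ci_hamiltonian_dense(ham, space)
        pairs = lowest_states(H, n_roots, space=space)
        return [(e + ham.e_core, v) for e, v in pairs]
    op = ci_matvec_operator(ham, space)
    k = min(max(n_roots + 2, 6), dim - 1)
    if v0 is not None and n_roots == 1:
        k = 1
    vals, vecs = spla.eigsh(op, k=k, which="SA", tol=tol, v0=v0)
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]
    out = []
    for i in range(n_roots):
        v = vecs[:, i]
        resid = np.linalg.norm(op @ v - vals[i] * v)
        if resid > 1e-8:
            raise RuntimeError(f"FCI root {i} residual {resid:.2e} above 1e-8")
        imax = int(np.argmax(np.abs(v)))
        if v[imax] < 0:
            v = -v
        out.append((float(vals[i] + ham.e_core), CIVector(space, v)))
    return out


def fci_from_fcidump(path, n_roots: int = 1) -> list[tuple[float, CIVector]]:
    """Solve FCI for the sector declared in an FCIDUMP file."""
    return fci(read_fcidump(path), n_roots=n_roots)
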