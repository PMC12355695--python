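"""File formats: RDM containers, state files, edge lists, and fixtures.

RDM container layout (HDF5): datasets ``/gamma1/aa``, ``/gamma1/bb``,
``/gamma2/aaaa``, ``/gamma2/abab``, ``/gamma2/bbbb`` and root attributes
``K``, ``n_alpha``, ``n_beta``, ``convention`` (must be
``"pqsr-annihilators"``), ``version``.  Spin blocks are indexed by spatial
orbitals; the abab block stores ``<a'_{P up} a'_{Q dn} a_{S dn} a_{R up}>``
at ``[P, Q, R, S]``.  A plain-text fallback stores one ``p q r s value``
record per line (0-based spin-orbital indices) per section.

State files are JSON lists of ``[occupation string, coefficient]`` pairs in
the notation of :func:`mutcorr.fock_space.parse_state`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fock_space import CIVector, parse_state, product_state, sector_space

__all__ = [
    "write_rdm_container",
    "read_rdm_container",
    "write_rdm_text",
    "read_rdm_text",
    "read_state_file",
    "write_state_file",
    "write_edge_list",
    "random_ci_fixture",
    "product_fixture",
    "random_rotation_fixture",
    "random_partition_fixture",
    "assemble_spin_blocked",
    "split_spin_blocks",
]

_CONVENTION = "pqsr-annihilators"
_BLOCKS_G2 = ("aaaa", "abab", "bbbb")


def split_spin_blocks(g1: np.ndarray, g2: np.ndarray) -> dict[str, np.ndarray]:
    """Extract the stored spin blocks from spin-blocked global tensors."""
    n = g1.shape[0]
    K = n // 2
    a, b = slice(0, K), slice(K, 2 * K)
    return {
        "g1_aa": g1[a, a],
        "g1_bb": g1[b, b],
        "g2_aaaa": g2[a, a, a, a],
        "g2_abab": g2[a, b, a, b],
        "g2_bbbb": g2[b, b, b, b],
    }


def assemble_spin_blocked(
    blocks: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Rebuild spin-blocked global g1, g2 from stored spin blocks.

    The mixed-spin sector of the 2-RDM is filled from the abab block using
    antisymmetry; same-spin blocks are used as given.
    """
    K = blocks["g1_aa"].shape[0]
    n = 2 * K
    g1 = np.zeros((n, n))
    g1[:K, :K] = blocks["g1_aa"]
    g1[K:, K:] = blocks["g1_bb"]
    g2 = np.zeros((n, n, n, n))
    a, b = slice(0, K), slice(K, n)
    g2[a, a, a, a] = blocks["g2_aaaa"]
    g2[b, b, b, b] = blocks["g2_bbbb"]
    ab = blocks["g2_abab"]
    g2[a, b, a, b] = ab
    g2[b, a, b, a] = ab.transpose(1, 0, 3, 2)
    g2[a, b, b, a] = -ab.transpose(0, 1, 3, 2)
    g2[b, a, a, b] = -ab.transpose(1, 0, 2, 3)
    return g1, g2


def write_rdm_container(
    path, g1: np.ndarray, g2: np.ndarray, n_alpha: int, n_beta: int
) -> None:
    """Write the spin-resolved HDF5 container."""
    import h5py

    blocks = split_spin_blocks(g1, g2)
    K = blocks["g1_aa"].shape[0]
    with h5py.File(path, "w") as f:
        f.attrs["K"] = K
        f.attrs["n_alpha"] = n_alpha
        f.attrs["n_beta"] = n_beta
        f.attrs["convention"] = _CONVENTION
        f.attrs["version"] = 1
        grp1 = f.create_group("gamma1")
        grp1.create_dataset("aa", data=blocks["g1_aa"])
        grp1.create_dataset("bb", data=blocks["g1_bb"])
        grp2 = f.create_group("gamma2")
        for name in _BLOCKS_G2:
            grp2.create_dataset(name, data=blocks[f"g2_{name}"])


def read_rdm_container(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read the HDF5 container -> (g1, g2, metadata); validates layout."""
    import h5py

    with h5py.File(path, "r") as f:
        conv = f.attrs.get("convention")
        if isinstance(conv, bytes):
            conv = conv.decode()
        if conv != _CONVENTION:
            raise ValueError(
                f"{path}: unsupported RDM convention {conv!r}; "
                f"expected {_CONVENTION!r}"
            )
        meta = {
            "K": int(f.attrs["K"]),
            "n_alpha": int(f.attrs["n_alpha"]),
            "n_beta": int(f.attrs["n_beta"]),
        }
        blocks = {}
        for name in ("aa", "bb"):
            if f"gamma1/{name}" not in f:
                raise ValueError(f"{path}: missing spin block /gamma1/{name}")
            blocks[f"g1_{name}"] = f[f"gamma1/{name}"][()]
        for name in _BLOCKS_G2:
            if f"gamma2/{name}" not in f:
                raise ValueError(f"{path}: missing spin block /gamma2/{name}")
            blocks[f"g2_{name}"] = f[f"gamma2/{name}"][()]
    g1, g2 = assemble_spin_blocked(blocks)
    N = meta["n_alpha"] + meta["n_beta"]
    if abs(np.trace(g1) - N) > 1e-6:
        raise ValueError(
            f"{path}: Tr gamma1 = {np.trace(g1):.8f} does not match "
            f"n_alpha + n_beta = {N}"
        )
    return g1, g2, meta


def write_rdm_text(path, g1: np.ndarray, g2: np.ndarray,
                   n_alpha: int, n_beta: int, tol: float = 1e-14) -> None:
    """Plain-text fallback container (one record per nonzero element)."""
    blocks = split_spin_blocks(g1, g2)
    K = blocks["g1_aa"].shape[0]
    with open(path, "w") as fh:
        fh.write(f"# mutcorr rdm container v1 convention={_CONVENTION}\n")
        fh.write(f"K {K}\nn_alpha {n_alpha}\nn_beta {n_beta}\n")
        for name in ("aa", "bb"):
            fh.write(f"section gamma1/{name}\n")
            m = blocks[f"g1_{name}"]
            for (p, r), v in np.ndenumerate(m):
                if abs(v) > tol:
                    fh.write(f"{p} {r} {float(v)!r}\n")
        for name in _BLOCKS_G2:
            fh.write(f"section gamma2/{name}\n")
            m = blocks[f"g2_{name}"]
            for (p, q, r, s), v in np.ndenumerate(m):
                if abs(v) > tol:
                    fh.write(f"{p} {q} {r} {s} {float(v)!r}\n")


def read_rdm_text(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read the plain-text container."""
    meta: dict = {}
    blocks: dict[str, np.ndarray] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] in ("K", "n_alpha", "n_beta"):
                meta[parts[0]] = int(parts[1])
                continue
            if parts[0] == "section":
                K = meta["K"]
                name = parts[1]
                key = name.replace("gamma1/", "g1_").replace("gamma2/", "g2_")
                blocks[key] = np.zeros(
                    (K, K) if name.startswith("gamma1") else (K, K, K, K)
                )
                current = blocks[key]
                continue
            *idx, val = parts
            current[tuple(int(i) for i in idx)] = float(val)
    for name in ("g1_aa", "g1_bb") + tuple(f"g2_{b}" for b in _BLOCKS_G2):
        if name not in blocks:
            raise ValueError(f"{path}: missing section {name}")
    g1, g2 = assemble_spin_blocked(blocks)
    return g1, g2, meta


# ---------------------------------------------------------------------------
# state files
# ---------------------------------------------------------------------------

def read_state_file(path) -> CIVector:
    terms = json.loads(Path(path).read_text())
    return parse_state([(t, float(c)) for t, c in terms])


def write_state_file(path, terms) -> None:
    Path(path).write_text(json.dumps([[t, c] for t, c in terms], indent=1))


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

def write_edge_list(path, M: np.ndarray, noons=None, bands=True) -> None:
    """CSV of (P, Q, M_PQ, band[, noon_P, noon_Q]); all values retained."""
    from .partition import classify

    K = M.shape[0]
    with open(path, "w") as fh:
        cols = "P,Q,M_PQ,band"
        if noons is not None:
            cols += ",noon_P,noon_Q"
        fh.write(cols + "\n")
        for P in range(K):
            for Q in range(P + 1, K):
                row = f"{P},{Q},{M[P, Q]:.12e},{classify(max(M[P, Q], 0.0))}"
                if noons is not None:
                    row += f",{noons[P]:.6f},{noons[Q]:.6f}"
                fh.write(row + "\n")


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

def random_ci_fixture(seed: int, K: int, n_alpha: int, n_beta: int) -> CIVector:
    """Seeded random normalized CI vector of one sector."""
    space = sector_space(K, n_alpha, n_beta)
    rng = np.random.default_rng(seed)
    amps = rng.normal(size=space.dim)
    return CIVector(space, amps / np.linalg.norm(amps))


def product_fixture(
    seed: int,
    K_A: int,
    sector_A: tuple[int, int],
    K_B: int,
    sector_B: tuple[int, int],
) -> CIVector:
    """Product of two seeded random fragment states on disjoint orbitals."""
    rng = np.random.default_rng(seed)
    psi_A = random_ci_fixture(int(rng.integers(2**31)), K_A, *sector_A)
    psi_B = random_ci_fixture(int(rng.integers(2**31)), K_B, *sector_B)
    return product_state(psi_A, psi_B)


def random_rotation_fixture(seed: int, K: int) -> np.ndarray:
    """Seeded random K x K special-orthogonal rotation."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(K, K))
    q, r = np.linalg.qr(A)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_partition_fixture(seed: int, n: int, n_fragments: int):
    """Seeded random full-cover partition of n spin orbitals."""
    from .partition import FragmentPartition

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cuts = np.sort(rng.choice(np.arange(1, n), size=n_fragments - 1, replace=False))
    frags = tuple(
        tuple(int(i) for i in part)
        for part in np.split(perm, cuts)
    )
    return FragmentPartition(frags)
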