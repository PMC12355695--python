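"""Circular mutual-correlation plots.

Orbitals are placed on a circle ordered by decreasing occupation number and
joined by edges colored on a logarithmic scale from 0.00075 (yellow) to
0.75 (dark violet), with line width growing with M_PQ.  Edges below the
display floor are omitted from the figure but always written to the edge
list, which accompanies every plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import write_edge_list

__all__ = ["PlotSpec", "render_plot"]


@dataclass(frozen=True)
class PlotSpec:
    floor: float = 0.00075
    ceiling: float = 0.75
    cmap: str = "viridis_r"          # yellow -> dark violet, log scale
    min_width: float = 0.6
    max_width: float = 6.0
    radius: float = 1.0
    annotate: bool = True


def render_plot(M: np.ndarray, noons=None, spec: PlotSpec | None = None,
                out=None, labels=None):
    """Render the circular correlation diagram; returns the figure.

    When ``out`` is given the figure is saved there and an edge-list CSV
    with the same stem (suffix ``.csv``) is always written alongside.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    if spec is None:
        spec = PlotSpec()
    K = M.shape[0]
    if K < 2:
        raise ValueError("need at least two orbitals to plot")
    order = np.argsort(noons)[::-1] if noons is not None else np.arange(K)
    angles = np.pi / 2 - 2 * np.pi * np.arange(K) / K
    pos = {
        int(orb): (spec.radius * np.cos(a), spec.radius * np.sin(a))
        for orb, a in zip(order, angles)
    }
    fig, ax = plt.subplots(figsize=(5, 5))
    norm = LogNorm(vmin=spec.floor, vmax=spec.ceiling)
    cmap = plt.get_cmap(spec.cmap)
    for P in range(K):
        for Q in range(P + 1, K):
            v = M[P, Q]
            if v < spec.floor:
                continue
            v_cl = min(v, spec.ceiling)
            frac = (np.log(v_cl) - np.log(spec.floor)) / (
                np.log(spec.ceiling) - np.log(spec.floor)
            )
            width = spec.min_width + frac * (spec.max_width - spec.min_width)
            ax.plot(
                *zip(pos[P], pos[Q]),
                color=cmap(norm(v_cl)),
                linewidth=width,
                zorder=1,
            )
            if spec.annotate and v >= 0.075:
                mx = (pos[P][0] + pos[Q][0]) / 2
                my = (pos[P][1] + pos[Q][1]) / 2
                ax.annotate(f"{v:.3f}", (mx, my), fontsize=8,
                            fontweight="bold", ha="center")
    for orb, (x, y) in pos.items():
        ax.scatter([x], [y], s=260, color="white", edgecolor="black", zorder=2)
        txt = labels[orb] if labels is not None else str(orb)
        ax.annotate(txt, (x, y), ha="center", va="center", fontsize=8, zorder=3)
        if noons is not None:
            ax.annotate(
                f"{noons[orb]:.2f}", (1.18 * x, 1.18 * y),
                ha="center", va="center", fontsize=7, color="gray", zorder=3,
            )
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
    fig.colorbar(sm, ax=ax, shrink=0.7, label="$M_{PQ}$")
    ax.set_xlim(-1.45, 1.45)
    ax.set_ylim(-1.45, 1.45)
    ax.set_aspect("equal")
    ax.axis("off")
    if out is not None:
        out = str(out)
        fig.savefig(out, dpi=150, bbox_inches="tight")
        stem = out.rsplit(".", 1)[0]
        write_edge_list(stem + ".csv", M, noons=noons)
    return fig
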