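"""Optional plots: embedding scatter and the Poincaré-disk view.

In the Poincaré representation of the hyperbolic plane, nodes near the rim
are effectively at infinite distance from interior nodes; interactions
drawn as chords toward the rim are visual candidates for bottlenecks.
"""

from __future__ import annotations

import numpy as np

from .embedding import EmbeddingResult


def embedding_scatter(emb: EmbeddingResult, ax=None, annotate: bool = True):
    """2-D scatter of embedding coordinates (first two columns)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xy = emb.coords[:, :2]
    ax.scatter(xy[:, 0], xy[:, 1], s=40, zorder=3)
    if annotate:
        for lab, (x, y) in zip(emb.labels, xy):
            ax.annotate(lab, (x, y), textcoords="offset points", xytext=(4, 4))
    ax.set_title(f"{emb.space} embedding (stress {emb.stress:.4g})")
    ax.set_aspect("equal")
    return ax


def poincare_disk_plot(
    emb: EmbeddingResult,
    interacting_pairs: list[tuple[str, str]] | None = None,
    bottlenecks: list[tuple[str, str]] | None = None,
    ax=None,
):
    """Nodes on the Poincaré disk with dotted chords for interactions.

    Bottleneck pairs, when given, are drawn in red.  Requires a hyperbolic
    embedding (one that exported Poincaré coordinates).
    """
    import matplotlib.pyplot as plt

    if emb.poincare is None:
        raise ValueError("embedding has no Poincaré coordinates")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    theta = np.linspace(0, 2 * np.pi, 256)
    ax.plot(np.cos(theta), np.sin(theta), color="black", lw=1)
    U = emb.poincare
    if U.shape[1] < 2:
        U = np.column_stack([U[:, 0], np.zeros(len(U))])
    index = {lab: i for i, lab in enumerate(emb.labels)}
    red = {frozenset(p) for p in (bottlenecks or [])}
    for a, b in interacting_pairs or []:
        i, j = index[a], index[b]
        color = "red" if frozenset((a, b)) in red else "gray"
        ax.plot(
            [U[i, 0], U[j, 0]], [U[i, 1], U[j, 1]],
            linestyle=":", color=color, lw=1.5, zorder=2,
        )
    ax.scatter(U[:, 0], U[:, 1], s=40, zorder=3)
    for lab, (x, y) in zip(emb.labels, U[:, :2]):
        ax.annotate(lab, (x, y), textcoords="offset points", xytext=(4, 4))
    ax.set_aspect("equal")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_title("Poincaré disk")
    return ax
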