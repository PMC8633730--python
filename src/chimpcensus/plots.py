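"""Minimal figures: PC scatter and stacked ancestry bars."""

from __future__ import annotations

import numpy as np
import pandas as pd

SUBSPECIES_COLORS = {
    "western": "#d95f02",
    "central": "#1b9e77",
    "eastern": "#7570b3",
    "nigeria_cameroon": "#e7298a",
}


def pca_scatter(coords: pd.DataFrame, out_path, pcs=("PC1", "PC2")) -> None:
    """Panel samples colored by subspecies, projected unknowns in grey.

    ``coords`` is the census ``pca_coordinates.tsv`` table (columns PC1..,
    set, label).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    unknown = coords[coords["set"] == "unknown"]
    ax.scatter(unknown[pcs[0]], unknown[pcs[1]], s=12, c="0.7",
               label="unknown", zorder=1)
    for label, grp in coords[coords["set"] == "panel"].groupby("label"):
        ax.scatter(grp[pcs[0]], grp[pcs[1]], s=24,
                   c=SUBSPECIES_COLORS.get(label, "k"), label=label, zorder=2)
    ax.set_xlabel(pcs[0])
    ax.set_ylabel(pcs[1])
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def ancestry_bars(profiles: pd.DataFrame, out_path) -> None:
    """Stacked per-sample ancestry proportions, sorted by major component."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    qcols = [c for c in profiles.columns if c.startswith("q_")]
    pops = [c[2:] for c in qcols]
    q = profiles[qcols].to_numpy()
    order = np.lexsort((-q.max(1), np.argmax(q, 1)))
    fig, ax = plt.subplots(figsize=(max(4, 0.12 * len(profiles)), 2.5))
    bottom = np.zeros(len(profiles))
    for k, pop in enumerate(pops):
        vals = q[order, k]
        ax.bar(range(len(vals)), vals, bottom=bottom, width=1.0,
               color=SUBSPECIES_COLORS.get(pop, "k"), label=pop)
        bottom += vals
    ax.set_xlim(-0.5, len(profiles) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry")
    ax.set_xticks([])
    ax.legend(fontsize=6, ncol=2, frameon=False)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
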