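"""Lightweight publication-style figures (matplotlib).

Only the two displays the pipeline's consumers routinely want: the MDS
scatter of libraries and a clustered log-CPM heatmap.  Imports are lazy so
headless batch runs without plotting never touch matplotlib.
"""

from __future__ import annotations

import pandas as pd

from .containers import NormalizedExpression

_MARKERS = {"F": "o", "M": "^"}
_FILL = {"control": "none", "cold": "full"}


def plot_mds(coords: pd.DataFrame, design: pd.DataFrame, path=None):
    """Scatter of MDS dims 1-2; shape = sex, fill = temperature."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for lib, row in coords.iterrows():
        sex = design.loc[lib, "sex"]
        temp = design.loc[lib, "temperature"]
        ax.plot(
            row.iloc[0], row.iloc[1], marker=_MARKERS.get(sex, "s"),
            fillstyle=_FILL.get(temp, "full"), color="C0" if sex == "M" else "C3",
            markersize=9, linestyle="none",
        )
        ax.annotate(lib, (row.iloc[0], row.iloc[1]), fontsize=6, alpha=0.6)
    ax.set_xlabel("leading log2FC dim 1")
    ax.set_ylabel("leading log2FC dim 2")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_heatmap(expr: NormalizedExpression, top: int = 500, path=None):
    """Heatmap of the ``top`` most variable genes' log2 CPM, libraries ordered
    by average-linkage clustering."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list, linkage

    lcpm = expr.log_cpm
    var = lcpm.var(axis=1)
    sub = lcpm.loc[var.sort_values(ascending=False).index[: min(top, len(var))]]
    order = leaves_list(linkage(sub.to_numpy().T, method="average"))
    sub = sub.iloc[:, order]

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(sub.to_numpy(), aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(sub.shape[1]), sub.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log2 CPM")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
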