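"""Optional plain plotting: a score-correlation heatmap and a forest plot.

Requires matplotlib (``pip install 'pleioscore[plot]'``); imported lazily so
the rest of the package has no plotting dependency.
"""

from __future__ import annotations

from typing import Iterable

from .association import AssociationResult
from .scores import CorrelationResult


def correlation_heatmap(corr: CorrelationResult, path) -> None:
    """Diverging-palette heatmap of score correlations, annotated with the
    q-value significance tiers (* / ** / *** at 0.01 / 0.001 / 0.0001)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ids = list(corr.rho.columns)
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(ids)),) * 2)
    im = ax.imshow(corr.rho.values, cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(ids)), ids, rotation=90, fontsize=7)
    ax.set_yticks(range(len(ids)), ids, fontsize=7)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                ax.text(j, i, corr.significance_tier(a, b),
                        ha="center", va="center", fontsize=6)
            elif i > j:
                ax.text(j, i, f"{corr.rho.iloc[i, j]:.2f}",
                        ha="center", va="center", fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.7, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def forest_plot(results: Iterable[AssociationResult], path,
                fdr: float = 0.01) -> None:
    """Log odds ratios with 95% CIs, one row per score/variant."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [r for r in results if r.error is None]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(rows))))
    for y, r in enumerate(rows):
        lo, hi = r.ci95
        color = "firebrick" if r.q < fdr else "gray"
        ax.plot([lo, hi], [y, y], color=color, lw=1.2)
        ax.plot(r.lor, y, "s", color=color, ms=4)
    ax.axvline(0.0, color="black", lw=0.8, ls="--")
    ax.set_yticks(range(len(rows)), [r.target_id for r in rows], fontsize=7)
    ax.set_xlabel("log odds ratio (95% CI)")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
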