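"""Quick matplotlib views of the analysis outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .disparity import DisparityReport
from .morphospace import Morphospace

__all__ = ["morphospace_scatter", "disparity_strip", "null_histogram", "richness_plot"]

_DIET_COLORS = {
    "Folivore_1": "#2a7e43",
    "Folivore_2": "#10451d",
    "Frugivore": "#d1495b",
    "Nucivore": "#c58c2f",
    "Generalist": "#3d5a80",
    "NoInfo": "#9b9b9b",
}


def morphospace_scatter(space: Morphospace, metadata: pd.DataFrame, axes=(0, 1), sizes=None, path=None):
    """PC scatter, points coloured by diet and scaled by centroid size."""
    diet = metadata.set_index("species")["diet"]
    fig, ax = plt.subplots(figsize=(6, 5))
    for sp, (x, y) in zip(space.labels, space.scores[:, list(axes)]):
        d = diet.get(sp, "NoInfo")
        s = 30.0
        if sizes is not None:
            s = 10 + 60 * (sizes[sp] - min(sizes.values())) / (
                max(sizes.values()) - min(sizes.values()) + 1e-12
            )
        ax.scatter(x, y, color=_DIET_COLORS.get(d, "gray"), s=s, label=d)
        ax.annotate(sp, (x, y), fontsize=6, alpha=0.7)
    ax.set_xlabel(f"PC{axes[0] + 1} ({space.variance_explained[axes[0]]:.1%})")
    ax.set_ylabel(f"PC{axes[1] + 1} ({space.variance_explained[axes[1]]:.1%})")
    handles, labels = ax.get_legend_handles_labels()
    seen = dict(zip(labels, handles))
    ax.legend(seen.values(), seen.keys(), fontsize=7)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def disparity_strip(reports: list[DisparityReport], path=None):
    """Per-biome strip plot of species distances to the biome mean."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, r in enumerate(reports):
        if not r.defined:
            continue
        x = np.full(len(r.distances), i) + np.linspace(-0.12, 0.12, len(r.distances))
        ax.plot(x, r.distances, "o", ms=5, alpha=0.8)
        ax.annotate(f"N={r.n_species}\nD={r.D_observed:.2e}", (i, max(r.distances)),
                    ha="center", fontsize=7)
    ax.set_xticks(range(len(reports)), [r.biome for r in reports])
    ax.set_ylabel("distance to biome mean")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def null_histogram(report: DisparityReport, path=None):
    """Null disparity distribution with the one-sided 95% bound and the observed value."""
    if report.null_distribution is None:
        raise ValueError("report has no null distribution; run biome_null_test first")
    fig, ax = plt.subplots(figsize=(5, 3.5))
    null = report.null_distribution
    ax.hist(null, bins=40, color="#bfc8d4")
    q = np.quantile(null, 0.95 if report.side_tested == "upper" else 0.05)
    ax.axvline(q, color="black", lw=2, label="one-sided 95% bound")
    ax.axvline(report.D_observed, color="#d1495b", ls="--", lw=2, label="observed")
    ax.set_title(f"{report.biome} ({report.metric}): p = {report.p_stated:.3f}")
    ax.legend(fontsize=7)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def richness_plot(null_table: pd.DataFrame, reports: list[DisparityReport], path=None):
    """Null disparity vs richness with the regression line and observed biomes."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.plot(null_table["richness"], null_table["disparity"], ".", ms=2, alpha=0.15, color="gray")
    means = null_table.groupby("richness")["disparity"].mean()
    ax.plot(means.index, means.values, "-", color="black", label="null mean")
    for r in reports:
        if r.defined:
            ax.plot(r.n_species, r.D_observed, "o", ms=8, label=r.biome)
    ax.set_xlabel("species richness")
    ax.set_ylabel("disparity")
    ax.legend(fontsize=7)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
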