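"""Biome-level morphological disparity and its richness-conditioned null.

Shape disparity of a set of species is their Procrustes variance: the
per-species Procrustes distances to the group mean shape, summarised as
the sample variance (sum of squared distances over n - 1).  Size disparity
is the sample variance of log centroid sizes.  Observed per-biome
disparities are tested against a Monte Carlo null built by repeatedly
drawing the same number of species at random from the full species pool,
so that differences in richness alone cannot masquerade as differences in
disparity.  Tropical biomes are tested one-sided for higher-than-expected
disparity, temperate/boreal biomes for lower, each with the reverse-side
p-value reported as a check on the opposite hypothesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .procrustes import AlignedSet, procrustes_distances_to, standardize

__all__ = [
    "DisparityReport",
    "disparity_of",
    "biome_disparity",
    "disparity_anova",
    "richness_null",
    "richness_regression",
    "biome_null_test",
    "TROPICAL_HYPOTHESIS",
    "TEMPERATE_HYPOTHESIS",
]

TROPICAL_HYPOTHESIS = "tropical_higher"
TEMPERATE_HYPOTHESIS = "temperate_lower"


@dataclass
class DisparityReport:
    biome: str
    n_species: int
    species: list[str]
    distances: np.ndarray          # per-species distance to the biome mean
    D_observed: float
    metric: str                    # shape | size
    stat: str                      # variance | mean_abs
    defined: bool = True
    low_power: bool = False
    null_distribution: np.ndarray | None = None
    p_upper: float = float("nan")  # Pr(null >= observed)
    p_lower: float = float("nan")  # Pr(null <= observed)
    side_tested: str | None = None
    p_stated: float = float("nan")
    reverse_p: float = float("nan")
    significant: bool | None = None


def _shape_distances(shapes: np.ndarray) -> np.ndarray:
    """Procrustes distance of each shape to the rescaled group mean."""
    mean, _ = standardize(shapes.mean(axis=0))
    return procrustes_distances_to(shapes, mean)


def disparity_of(values: np.ndarray, metric: str, stat: str = "variance") -> tuple[np.ndarray, float]:
    """Distances to the group mean and the disparity scalar D.

    ``values``: (m, k, 2) aligned shapes for ``metric='shape'`` or an (m,)
    log-size vector for ``metric='size'``.  ``stat='variance'`` gives the
    sample variance (sum of squared distances / (m - 1)); ``'mean_abs'``
    the mean distance.
    """
    if metric == "shape":
        d = _shape_distances(np.asarray(values, dtype=float))
    elif metric == "size":
        x = np.asarray(values, dtype=float)
        d = np.abs(x - x.mean())
    else:
        raise ValueError(f"unknown metric {metric!r}")
    m = len(d)
    if m < 2:
        return d, float("nan")
    if stat == "variance":
        D = float((d**2).sum() / (m - 1))
    elif stat == "mean_abs":
        D = float(d.mean())
    else:
        raise ValueError(f"unknown disparity stat {stat!r}")
    return d, D


def biome_disparity(
    species_shapes: AlignedSet,
    metadata: pd.DataFrame,
    biome: str,
    metric: str = "shape",
    stat: str = "variance",
) -> DisparityReport:
    """Observed disparity of the species occupying one biome.

    Species occupying several biomes contribute to each of them.  A biome
    with fewer than two occupants gets an undefined (flagged) report;
    two-occupant biomes are flagged low-power.
    """
    if biome not in metadata.columns:
        raise ValueError(f"biome {biome!r} not in metadata")
    occupants = metadata.loc[metadata[biome] == 1, "species"].tolist()
    idx = [species_shapes.labels.index(s) for s in occupants if s in species_shapes.labels]
    present = [species_shapes.labels[i] for i in idx]
    if len(idx) < 2:
        warnings.warn(f"biome {biome!r} has {len(idx)} occupant(s); disparity undefined")
        return DisparityReport(
            biome=biome, n_species=len(idx), species=present,
            distances=np.array([]), D_observed=float("nan"),
            metric=metric, stat=stat, defined=False,
        )
    values = species_shapes.shapes[idx] if metric == "shape" else species_shapes.log_sizes[idx]
    d, D = disparity_of(values, metric, stat)
    return DisparityReport(
        biome=biome, n_species=len(idx), species=present, distances=d,
        D_observed=D, metric=metric, stat=stat, low_power=len(idx) <= 2,
    )


def disparity_anova(reports: list[DisparityReport]) -> tuple[float, float]:
    """One-way ANOVA of per-species distances with biome as the factor.

    Species present in several biomes enter once per biome.  Returns
    (F, p); identical distances everywhere make F undefined.
    """
    groups = [r.distances for r in reports if r.defined and len(r.distances) >= 2]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 biomes with >= 2 species")
    allv = np.concatenate(groups)
    if np.allclose(allv, allv[0]):
        warnings.warn("all distances identical; F undefined")
        return float("nan"), float("nan")
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)


def richness_null(
    species_shapes: AlignedSet,
    metric: str = "shape",
    richness_range=None,
    n_rep: int = 1000,
    seed: int | None = None,
    stat: str = "variance",
) -> pd.DataFrame:
    """Monte Carlo disparity null conditioned on species richness.

    For each richness k, ``n_rep`` uniform without-replacement draws from
    the full species pool; disparity of each draw is computed with the same
    metric and statistic as the observed biomes.  Returns a long DataFrame
    (richness, rep, disparity).
    """
    pool = species_shapes.n
    if richness_range is None:
        richness_range = range(2, pool + 1)
    richness_range = list(richness_range)
    if max(richness_range) > pool:
        raise ValueError(f"richness {max(richness_range)} exceeds pool size {pool}")
    if n_rep < 100:
        warnings.warn(f"n_rep={n_rep} is low for a 95% test")
    rng = np.random.default_rng(seed)
    values = species_shapes.shapes if metric == "shape" else species_shapes.log_sizes
    rows = {"richness": [], "rep": [], "disparity": []}
    for k in richness_range:
        for r in range(n_rep):
            idx = rng.choice(pool, size=k, replace=False)
            _, D = disparity_of(values[idx], metric, stat)
            rows["richness"].append(k)
            rows["rep"].append(r)
            rows["disparity"].append(D)
    return pd.DataFrame(rows)


def richness_regression(null_table: pd.DataFrame):
    """Least-squares regression of null disparity on richness.

    Returns (slope, intercept, per-richness mean table).  A pool with
    constant disparity yields slope 0 (flagged by a warning).
    """
    ks = null_table["richness"].to_numpy(dtype=float)
    D = null_table["disparity"].to_numpy(dtype=float)
    if len(np.unique(ks)) < 3:
        raise ValueError("need null replicates at >= 3 richness values")
    if np.allclose(D, D[0]):
        warnings.warn("constant disparity in the null table; slope is 0")
        slope, intercept = 0.0, float(D[0])
    else:
        slope, intercept = np.polyfit(ks, D, 1)
    means = null_table.groupby("richness", as_index=False)["disparity"].mean()
    return float(slope), float(intercept), means


def biome_null_test(
    report: DisparityReport,
    null_table: pd.DataFrame,
    hypothesis: str,
    alpha: float = 0.05,
) -> DisparityReport:
    """Complete a disparity report with its richness-matched null test.

    One-sided p-values with add-one correction: p = (#{replicates at least
    as extreme} + 1) / (n_rep + 1), the observed arrangement counting as a
    replicate, so p is never exactly zero.  ``hypothesis`` picks the stated
    side ('tropical_higher' tests the upper tail, 'temperate_lower' the
    lower); the reverse side is reported too.  Significance means the
    observed value lies outside the one-sided 95% bound of the null.
    """
    if not report.defined:
        return report
    null = null_table.loc[null_table["richness"] == report.n_species, "disparity"].to_numpy()
    if len(null) == 0:
        raise ValueError(
            f"no null replicates at richness {report.n_species} for biome {report.biome!r}"
        )
    n = len(null)
    obs = report.D_observed
    p_upper = ((null >= obs).sum() + 1) / (n + 1)
    p_lower = ((null <= obs).sum() + 1) / (n + 1)
    if hypothesis == TROPICAL_HYPOTHESIS:
        side, p_stated, reverse_p = "upper", p_upper, p_lower
    elif hypothesis == TEMPERATE_HYPOTHESIS:
        side, p_stated, reverse_p = "lower", p_lower, p_upper
    else:
        raise ValueError(f"unknown hypothesis {hypothesis!r}")
    report.null_distribution = null
    report.p_upper = float(p_upper)
    report.p_lower = float(p_lower)
    report.side_tested = side
    report.p_stated = float(p_stated)
    report.reverse_p = float(reverse_p)
    report.significant = bool(p_stated <= alpha)
    return report
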