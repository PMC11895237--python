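"""Procrustes PGLS with randomised-residual permutation (RRPP) inference.

Shape (a species x coordinates matrix of Procrustes coordinates) or log
centroid size is regressed on diet and size under a phylogenetic error
model: response and design are premultiplied by the inverse square root of
the (optionally lambda-rescaled) Brownian-motion covariance, and sums of
squares are Procrustes-style — summed squared residual distances between
nested models, not covariances between variables.

Inference is by RRPP: for each model term, the residuals of its reduced
model are randomly permuted across species, added back to the reduced
fitted values, and the term's F is recomputed; the p-value is the fraction
of permutations (the observed arrangement included) with F at least as
large, and the effect size Z is the standard-normal position of log F in
the permutation distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import PhyloCovariance, inv_sqrt

__all__ = [
    "ComparativeFit",
    "parse_formula",
    "pgls_fit",
    "pairwise_dispersion",
    "allometry_scores",
]


@dataclass
class ComparativeFit:
    """A Procrustes ANOVA/PGLS table plus the fitted pieces."""

    response: str
    terms: list[str]
    df: np.ndarray
    SS: np.ndarray
    MS: np.ndarray
    r2: np.ndarray
    F: np.ndarray
    Z: np.ndarray
    p: np.ndarray
    residual_df: int
    residual_SS: float
    total_df: int
    total_SS: float
    n_perm: int
    coefficients: np.ndarray | None = None  # full-model GLS coefficients
    transformed_response: np.ndarray | None = None
    transformed_residuals: np.ndarray | None = None
    design_columns: list[str] = field(default_factory=list)

    def anova_table(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.terms):
            rows.append(
                dict(term=t, Df=int(self.df[i]), SS=self.SS[i], MS=self.MS[i],
                     r2=self.r2[i], F=self.F[i], Z=self.Z[i], p=self.p[i])
            )
        rows.append(
            dict(term="Residuals", Df=self.residual_df, SS=self.residual_SS,
                 MS=self.residual_SS / max(self.residual_df, 1),
                 r2=self.residual_SS / self.total_SS if self.total_SS > 0 else np.nan,
                 F=np.nan, Z=np.nan, p=np.nan)
        )
        rows.append(
            dict(term="Total", Df=self.total_df, SS=self.total_SS, MS=np.nan,
                 r2=np.nan, F=np.nan, Z=np.nan, p=np.nan)
        )
        return pd.DataFrame(rows)


def parse_formula(formula: str) -> tuple[str, list[str]]:
    """Parse e.g. ``"shape ~ diet * size"`` into (response, term list).

    ``a * b`` expands to ``a + b + a:b``; term order is kept as written
    (sequential sums of squares are order-sensitive).
    """
    if "~" not in formula:
        raise ValueError(f"formula {formula!r} has no '~'")
    lhs, rhs = (s.strip() for s in formula.split("~", 1))
    terms: list[str] = []
    for chunk in rhs.split("+"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "*" in chunk:
            parts = [p.strip() for p in chunk.split("*")]
            for p in parts:
                if p not in terms:
                    terms.append(p)
            inter = ":".join(parts)
            if inter not in terms:
                terms.append(inter)
        elif chunk not in terms:
            terms.append(chunk)
    if not terms:
        raise ValueError(f"formula {formula!r} has an empty right-hand side")
    return lhs, terms


def _term_block(term: str, diet, log_size, levels) -> tuple[np.ndarray, list[str]]:
    if term == "diet":
        cols = [np.asarray(diet) == lv for lv in levels[1:]]
        X = np.column_stack(cols).astype(float) if cols else np.empty((len(diet), 0))
        return X, [f"diet[{lv}]" for lv in levels[1:]]
    if term == "size":
        return np.asarray(log_size, dtype=float)[:, None], ["size"]
    if term in ("diet:size", "size:diet"):
        base, names = _term_block("diet", diet, log_size, levels)
        X = base * np.asarray(log_size, dtype=float)[:, None]
        return X, [n + ":size" for n in names]
    raise ValueError(f"unknown model term {term!r}")


def _rss(Y: np.ndarray, H: np.ndarray) -> float:
    R = Y - H @ Y
    return float((R * R).sum())


def _hat(X: np.ndarray) -> np.ndarray:
    # pseudo-inverse based hat matrix; tolerant of near-collinearity
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def pgls_fit(
    response: np.ndarray,
    formula: str,
    cov: PhyloCovariance,
    diet=None,
    log_size=None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ComparativeFit:
    """Fit a Procrustes PGLS model and run RRPP inference.

    ``response`` is (n, q) shape coordinates or an (n,) size vector, rows
    ordered as ``cov.taxa``.  ``n_perm`` counts the permutations including
    the observed arrangement.
    """
    Y = np.asarray(response, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if n != cov.n:
        raise ValueError("response rows must match covariance taxa")
    resp_name, terms = parse_formula(formula)
    if 1 < n_perm < 99:
        warnings.warn(f"n_perm={n_perm} is very low; p-values will be coarse")

    levels = None
    if any("diet" in t for t in terms):
        if diet is None:
            raise ValueError("formula uses 'diet' but no diet labels given")
        levels = sorted(set(diet))
    if any("size" in t for t in terms) and log_size is None:
        raise ValueError("formula uses 'size' but no log sizes given")

    P = inv_sqrt(cov)
    Yt = P @ Y

    # nested sequence of transformed design matrices (intercept first)
    ones = np.ones((n, 1))
    blocks: list[np.ndarray] = [P @ ones]
    names: list[str] = ["(Intercept)"]
    dfs: list[int] = []
    for t in terms:
        X, cn = _term_block(t, diet, log_size, levels)
        if np.linalg.matrix_rank(np.column_stack([ones, X])) <= 1 and X.shape[1] > 0:
            warnings.warn(f"term {t!r} is confounded with the intercept")
        blocks.append(P @ X)
        names.extend(cn)
        dfs.append(X.shape[1])
    X_nested = [np.column_stack(blocks[: i + 1]) for i in range(len(blocks))]
    rank_full = np.linalg.matrix_rank(X_nested[-1])
    if rank_full < X_nested[-1].shape[1]:
        raise ValueError("design matrix is rank deficient after encoding")
    H = [_hat(X) for X in X_nested]

    df = np.array(dfs, dtype=int)
    total_df = n - 1
    residual_df = total_df - int(df.sum())
    if residual_df <= 0:
        raise ValueError("no residual degrees of freedom")

    rss = np.array([_rss(Yt, h) for h in H])
    total_SS = rss[0]
    SS = rss[:-1] - rss[1:]
    residual_SS = rss[-1]
    MS = SS / df
    with np.errstate(divide="ignore", invalid="ignore"):
        F_obs = MS / (residual_SS / residual_df)

    rng = np.random.default_rng(seed)
    n_terms = len(terms)
    F_perm = np.empty((n_perm, n_terms))
    F_perm[0] = F_obs
    fitted_red = [h @ Yt for h in H[:-1]]
    resid_red = [Yt - f for f in fitted_red]
    for b in range(1, n_perm):
        perm = rng.permutation(n)
        for i in range(n_terms):
            Ystar = fitted_red[i] + resid_red[i][perm]
            rss_red = _rss(Ystar, H[i])
            rss_cur = _rss(Ystar, H[i + 1])
            rss_full = _rss(Ystar, H[-1])
            ss = max(rss_red - rss_cur, 0.0)
            denom = rss_full / residual_df
            F_perm[b, i] = (ss / df[i]) / denom if denom > 0 else np.inf

    if n_perm > 1:
        p = (F_perm >= F_obs[None, :] - 1e-12).mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logF = np.log(np.maximum(F_perm, 1e-300))
            mu = logF.mean(axis=0)
            sd = logF.std(axis=0, ddof=1)
            Z = np.where(sd > 0, (np.log(np.maximum(F_obs, 1e-300)) - mu) / sd, np.nan)
    else:  # no permutations requested: point estimates only
        p = np.full(n_terms, np.nan)
        Z = np.full(n_terms, np.nan)

    beta = np.linalg.pinv(X_nested[-1]) @ Yt
    resid_full = Yt - X_nested[-1] @ beta
    return ComparativeFit(
        response=resp_name,
        terms=terms,
        df=df,
        SS=SS,
        MS=MS,
        r2=SS / total_SS if total_SS > 0 else np.full_like(SS, np.nan),
        F=F_obs,
        Z=Z,
        p=p,
        residual_df=residual_df,
        residual_SS=residual_SS,
        total_df=total_df,
        total_SS=total_SS,
        n_perm=n_perm,
        coefficients=beta,
        transformed_response=Yt,
        transformed_residuals=resid_full,
        design_columns=names,
    )


def pairwise_dispersion(
    shapes: np.ndarray,
    groups,
    cov: PhyloCovariance,
    n_perm: int = 1000,
    seed: int | None = None,
    stat: str = "mean",
) -> pd.DataFrame:
    """Pairwise tests of group dispersion around mean shapes.

    Dispersion of a group is the mean (or root-mean-square, ``stat='rms'``)
    distance of its members' PGLS-transformed residuals from the group
    mean; the test statistic d is the absolute difference between two
    groups' dispersions, with a group-label permutation null.  Groups with
    a single member have undefined dispersion and are dropped with a
    warning.  Returns a long DataFrame (group_1, group_2, d, Z, p).
    """
    Y = np.asarray(shapes, dtype=float)
    if Y.ndim == 3:
        Y = Y.reshape(Y.shape[0], -1)
    groups = np.asarray(groups)
    P = inv_sqrt(cov)
    Yt = P @ Y
    levels0 = sorted(set(groups))
    counts = {g: int((groups == g).sum()) for g in levels0}
    singletons = [g for g in levels0 if counts[g] < 2]
    if singletons:
        warnings.warn(f"groups with a single member excluded: {singletons}")
    keep = np.isin(groups, [g for g in levels0 if counts[g] >= 2])
    Yt, groups = Yt[keep], groups[keep]
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups with >= 2 members")

    # residuals from the transformed group-means model
    X = np.column_stack([np.ones(len(groups))] + [(groups == g).astype(float) for g in levels[1:]])
    resid = Yt - _hat(X) @ Yt

    def dispersions(lab: np.ndarray) -> np.ndarray:
        out = np.empty(len(levels))
        for i, g in enumerate(levels):
            rows = resid[lab == g]
            centred = rows - rows.mean(axis=0)
            dist = np.sqrt((centred**2).sum(axis=1))
            out[i] = np.sqrt((dist**2).mean()) if stat == "rms" else dist.mean()
        return out

    rng = np.random.default_rng(seed)
    disp_obs = dispersions(groups)
    iu = np.triu_indices(len(levels), k=1)
    d_obs = np.abs(disp_obs[:, None] - disp_obs[None, :])[iu]
    d_perm = np.empty((n_perm, len(d_obs)))
    d_perm[0] = d_obs
    for b in range(1, n_perm):
        lab = rng.permutation(groups)
        dp = dispersions(lab)
        d_perm[b] = np.abs(dp[:, None] - dp[None, :])[iu]
    p = (d_perm >= d_obs[None, :] - 1e-12).mean(axis=0)
    sd = d_perm.std(axis=0, ddof=1)
    Z = np.where(sd > 0, (d_obs - d_perm.mean(axis=0)) / sd, np.nan)
    rows = []
    for idx, (i, j) in enumerate(zip(*iu)):
        rows.append(
            dict(group_1=levels[i], group_2=levels[j], d=d_obs[idx], Z=Z[idx], p=p[idx])
        )
    out = pd.DataFrame(rows)
    out.attrs["dispersions"] = dict(zip(levels, disp_obs))
    return out


def allometry_scores(
    shapes: np.ndarray,
    log_sizes: np.ndarray,
    cov: PhyloCovariance,
) -> tuple[np.ndarray, np.ndarray]:
    """Regression scores of shape on log centroid size under PGLS.

    Each species' score is the projection of its transformed, centred shape
    onto the fitted allometric regression vector (the standard
    regression-score construction for visualising allometry).  Returns
    (scores, regression vector); a zero regression vector (no allometry)
    yields all-zero scores and a warning.
    """
    Y = np.asarray(shapes, dtype=float)
    if Y.ndim == 3:
        Y = Y.reshape(Y.shape[0], -1)
    fit = pgls_fit(Y, "shape ~ size", cov, log_size=log_sizes, n_perm=1, seed=0)
    b = fit.coefficients[1]  # size row: (Intercept) is row 0
    norm = np.linalg.norm(b)
    Yt = fit.transformed_response
    if norm < 1e-12 * max(1.0, np.abs(Yt).max()):
        warnings.warn("allometric regression vector is zero; scores undefined")
        return np.zeros(Y.shape[0]), b
    centred = Yt - Yt.mean(axis=0)
    return centred @ (b / norm), b
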