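"""Brownian-motion covariance matrices and Pagel's lambda.

Under Brownian motion on a phylogeny, the expected covariance between two
tips equals the depth of their most recent common ancestor (the shared
root-to-MRCA path length).  Pagel's lambda scales the off-diagonal entries
— equivalently the internal branches — and measures phylogenetic signal:
0 is a star phylogeny (no signal), 1 is pure Brownian motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "PhyloCovariance",
    "bm_covariance",
    "lambda_transform",
    "estimate_lambda",
    "inv_sqrt",
    "read_tree",
]


@dataclass(frozen=True)
class PhyloCovariance:
    taxa: tuple[str, ...]
    C: np.ndarray  # (n, n) symmetric positive definite
    lam: float = 1.0

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if C.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("covariance shape does not match taxon list")
        if not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        object.__setattr__(self, "C", C)

    @property
    def n(self) -> int:
        return len(self.taxa)

    def reorder(self, taxa) -> "PhyloCovariance":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(tuple(taxa), self.C[np.ix_(idx, idx)], self.lam)


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def _tip_depths(tree: dendropy.Tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        edge = node.edge.length or 0.0
        depths[node] = (depths.get(node.parent_node, 0.0)) + (
            edge if node.parent_node is not None else 0.0
        )
    return depths


def bm_covariance(tree: dendropy.Tree, taxa=None) -> PhyloCovariance:
    """Brownian-motion covariance: C[i, j] = depth of MRCA(i, j).

    ``taxa`` fixes the row order; defaults to the tree's tip-label order.
    Zero-length terminal branches that make C singular are rejected.
    """
    tips = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    if taxa is None:
        taxa = sorted(tips)
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    depths = _tip_depths(tree)
    # ancestor chains (including the tip itself), root first
    chains = {}
    for t in taxa:
        chain = []
        node = tips[t]
        while node is not None:
            chain.append(node)
            node = node.parent_node
        chains[t] = chain[::-1]
    n = len(taxa)
    C = np.zeros((n, n))
    for i, a in enumerate(taxa):
        C[i, i] = depths[tips[a]]
        for j in range(i + 1, n):
            b = taxa[j]
            mrca = None
            for x, y in zip(chains[a], chains[b]):
                if x is y:
                    mrca = x
                else:
                    break
            C[i, j] = C[j, i] = depths[mrca] if mrca is not None else 0.0
    cov = PhyloCovariance(tuple(taxa), C)
    if np.linalg.matrix_rank(C) < n:
        raise ValueError(
            "BM covariance is singular (identical tips or zero-length terminal branches)"
        )
    return cov


def lambda_transform(cov: PhyloCovariance, lam: float, max_lambda: float = 1.0) -> PhyloCovariance:
    """Multiply off-diagonal covariances by lambda (diagonal untouched).

    Equivalent to rescaling the internal branches of the tree by lambda
    while stretching terminal branches to preserve tip depths.
    """
    if not 0.0 <= lam <= max_lambda:
        raise ValueError(f"lambda {lam} outside [0, {max_lambda}]")
    C = cov.C * lam
    np.fill_diagonal(C, np.diag(cov.C))
    return PhyloCovariance(cov.taxa, C, lam=lam)


def _neg_loglik(lam: float, resid: np.ndarray, cov: PhyloCovariance) -> float:
    n, q = resid.shape
    V = lambda_transform(cov, lam).C
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * np.log(np.diag(L)).sum()
    z = np.linalg.solve(L, resid)  # (n, q); quad form per column = ||z_j||^2
    quad = (z**2).sum(axis=0)
    quad = np.maximum(quad, 1e-300)
    sigma2 = quad / n  # per-column MLE of the rate
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n).sum()
    return -ll


def estimate_lambda(
    residuals: np.ndarray,
    cov: PhyloCovariance,
    tol: float = 1e-6,
) -> float:
    """Maximum-likelihood Pagel's lambda in [0, 1] for a residual matrix.

    A single lambda is shared across the q residual columns; each column
    gets its own profiled Brownian rate.  Deterministic bounded scalar
    optimisation, with both interval endpoints checked explicitly.
    """
    resid = np.atleast_2d(np.asarray(residuals, dtype=float))
    if resid.shape[0] == 1:
        resid = resid.T
    if resid.shape[0] != cov.n:
        raise ValueError("residual rows must match covariance taxa")
    res = minimize_scalar(
        _neg_loglik,
        bounds=(0.0, 1.0),
        args=(resid, cov),
        method="bounded",
        options={"xatol": tol},
    )
    candidates = [(res.fun, float(res.x))]
    for lam in (0.0, 1.0):
        candidates.append((_neg_loglik(lam, resid, cov), lam))
    best = min(candidates, key=lambda c: c[0])
    if not np.isfinite(best[0]):
        raise ValueError("likelihood undefined: transformed covariance singular")
    return best[1]


def inv_sqrt(cov: PhyloCovariance) -> np.ndarray:
    """Symmetric inverse square root of the covariance (the GLS transform)."""
    w, E = np.linalg.eigh(cov.C)
    if w.min() <= 1e-12 * w.max():
        raise ValueError("covariance is singular; cannot form GLS transform")
    return (E * (1.0 / np.sqrt(w))) @ E.T
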