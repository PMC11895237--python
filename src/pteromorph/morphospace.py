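"""Principal-component morphospace of aligned shapes.

PCA of the flattened Procrustes coordinates about their mean.  Because the
shapes live on the (near-flat, at these scales) Procrustes tangent space,
ordinary PCA of the coordinates is the standard morphospace construction;
axis endpoints can be folded back into landmark configurations to display
the deformations each component describes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .procrustes import AlignedSet

__all__ = ["Morphospace", "pca", "axis_endpoint_shapes"]


@dataclass
class Morphospace:
    scores: np.ndarray              # (n, p), zero column means
    variance_explained: np.ndarray  # (p,), sums to 1, non-increasing
    axes: np.ndarray                # (p, 2k), orthonormal rows
    mean_shape: np.ndarray          # (k, 2)
    labels: list[str]

    @property
    def n_axes(self) -> int:
        return self.axes.shape[0]


def pca(aligned: AlignedSet) -> Morphospace:
    """Eigen-decomposition of the coordinate covariance of an aligned set.

    Null axes (singular values indistinguishable from zero) are dropped,
    so the explained-variance proportions sum to one.  Each axis is
    oriented so that its largest-magnitude loading is positive, making the
    output deterministic across platforms.
    """
    if aligned.n < 3:
        raise ValueError("PCA needs at least 3 shapes")
    X = aligned.flat()
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > s[0] * 1e-10 if s[0] > 0 else np.zeros_like(s, dtype=bool)
    s, Vt, U = s[keep], Vt[keep], U[:, keep]
    # deterministic sign: largest-|loading| entry of each axis positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U * s
    var = s**2
    return Morphospace(
        scores=scores,
        variance_explained=var / var.sum(),
        axes=Vt,
        mean_shape=mean.reshape(-1, 2),
        labels=list(aligned.labels),
    )


def axis_endpoint_shapes(space: Morphospace, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Shapes at the observed min and max score along one axis.

    The mean shape displaced along the axis loading vector by the extreme
    observed scores — the deformation grids drawn at the ends of a
    morphospace axis.
    """
    if not 0 <= axis < space.n_axes:
        raise IndexError(f"axis {axis} out of range (0..{space.n_axes - 1})")
    flat_mean = space.mean_shape.reshape(-1)
    lo = space.scores[:, axis].min()
    hi = space.scores[:, axis].max()
    shape_min = (flat_mean + lo * space.axes[axis]).reshape(-1, 2)
    shape_max = (flat_mean + hi * space.axes[axis]).reshape(-1, 2)
    return shape_min, shape_max
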