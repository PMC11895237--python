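"""Generalised Procrustes Analysis with sliding semilandmarks.

Superimposition removes position, scale and orientation: every
configuration is centred, scaled to unit centroid size, and rotated to the
iteratively updated mean shape.  Semilandmarks, which carry no point-wise
homology along their curve, are additionally slid along their local tangent
directions to the positions that minimise the thin-plate-spline bending
energy of the deformation from the mean — the standard minimum-bending-
energy criterion.

Full Procrustes distances are computed directly on the aligned (unit-size)
coordinates after an optimal rotation; reflections are never allowed, since
bilateral configurations make the reflected fit a genuine hazard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Configuration
from .template import LandmarkTemplate

__all__ = [
    "AlignedSet",
    "centroid_size",
    "center",
    "standardize",
    "optimal_superposition",
    "procrustes_distance",
    "procrustes_distances_to",
    "bending_energy_matrix",
    "bending_energy",
    "slide_semilandmarks",
    "gpa",
    "species_means",
    "GPAConvergenceError",
    "DegenerateShapeError",
]


class GPAConvergenceError(RuntimeError):
    def __init__(self, change: float, max_iter: int):
        self.change = change
        super().__init__(
            f"GPA did not converge in {max_iter} iterations (last mean change {change:.3e})"
        )


class DegenerateShapeError(ValueError):
    pass


# ------------------------------------------------------------- basics --


def centroid_size(points: np.ndarray) -> float:
    """Square root of the summed squared distances of points to their centroid."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("centroid size needs a k x d matrix with k >= 2")
    if not np.all(np.isfinite(points)):
        raise ValueError("non-finite coordinates")
    return float(np.sqrt(((points - points.mean(axis=0)) ** 2).sum()))


def center(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    return points - points.mean(axis=0)


def standardize(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Centre and scale to unit centroid size; returns (shape, original CS)."""
    c = center(points)
    cs = float(np.sqrt((c**2).sum()))
    if cs == 0.0:
        raise DegenerateShapeError("all points coincide; centroid size is zero")
    return c / cs, cs


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Rotation R (det +1) minimising ||A - B R||_F for centred A, B."""
    H = B.T @ A
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    return U @ D @ Vt


def optimal_superposition(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal (reflection-free) rotation of B onto A and the residual distance.

    Both inputs must already be centred with unit centroid size.  The
    residual is the square root of the summed squared point distances after
    rotation — the (partial) Procrustes distance.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    for M, name in ((A, "A"), (B, "B")):
        if np.linalg.matrix_rank(M - M.mean(axis=0), tol=1e-12) < 2:
            raise DegenerateShapeError(f"configuration {name} is rank-deficient (collinear points)")
    R = _optimal_rotation(A, B)
    resid = float(np.sqrt(((A - B @ R) ** 2).sum()))
    return R, resid


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Procrustes distance between two centred, unit-size shapes."""
    return optimal_superposition(a, b)[1]


def procrustes_distances_to(shapes: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Procrustes distance of each shape in an (n, k, 2) stack to ``ref``.

    Vectorised over specimens via batched 2x2 SVD: with unit-size centred
    shapes, d^2 = 2 - 2 (s1 + sign(det H) s2) where s are the singular
    values of H = shape^T ref.
    """
    shapes = np.asarray(shapes, dtype=float)
    ref = np.asarray(ref, dtype=float)
    H = np.einsum("nkd,ke->nde", shapes, ref)
    s = np.linalg.svd(H, compute_uv=False)
    sign = np.sign(np.linalg.det(H))
    sign[sign == 0] = 1.0
    na = (shapes**2).sum(axis=(1, 2))
    nb = (ref**2).sum()
    d2 = na + nb - 2.0 * (s[:, 0] + sign * s[:, 1])
    return np.sqrt(np.clip(d2, 0.0, None))


# ------------------------------------------------- thin-plate splines --


def bending_energy_matrix(ref: np.ndarray) -> np.ndarray:
    """TPS bending-energy matrix L_k^-1 (k x k) of a reference shape.

    The kernel is U(r) = r^2 log r^2; the returned matrix is the upper-left
    block of the inverse of the bordered system [[K, Q], [Q^T, 0]] with
    Q = [1 | x | y].  It is positive semi-definite with the affine
    deformations in its null space, so affine deformations have zero
    bending energy.
    """
    ref = np.asarray(ref, dtype=float)
    k = ref.shape[0]
    diff = ref[:, None, :] - ref[None, :, :]
    r2 = (diff**2).sum(axis=-1)
    if np.any((r2 + np.eye(k)) == 0.0):
        i, j = np.argwhere((r2 == 0.0) & ~np.eye(k, dtype=bool))[0]
        raise DegenerateShapeError(
            f"reference points {i} and {j} coincide; bending-energy matrix is singular"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(r2 > 0.0, r2 * np.log(r2), 0.0)
    Q = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = Q
    L[k:, :k] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise DegenerateShapeError("bending-energy system is singular") from exc
    Lk = Linv[:k, :k]
    return 0.5 * (Lk + Lk.T)


def bending_energy(ref: np.ndarray, target: np.ndarray, Lk: np.ndarray | None = None) -> float:
    """Bending energy of the TPS deformation taking ``ref`` onto ``target``."""
    if Lk is None:
        Lk = bending_energy_matrix(ref)
    D = np.asarray(target, dtype=float) - np.asarray(ref, dtype=float)
    return float(np.einsum("id,ij,jd->", D, Lk, D))


def _tangent_directions(points: np.ndarray, template: LandmarkTemplate) -> tuple[np.ndarray, np.ndarray]:
    """Unit tangents at every semilandmark, from the specimen's own curve.

    Central differences of the neighbouring chain points; open-curve
    semilandmarks adjacent to a fixed landmark use that landmark as the
    neighbour, closed curves wrap around.
    Returns (semilandmark point indices, matching unit tangent vectors).
    """
    idx_all: list[int] = []
    tan_all: list[np.ndarray] = []
    for chain, closed in template.curve_chains():
        m = len(chain)
        for pos, p in enumerate(chain):
            if not closed and (pos == 0 or pos == m - 1):
                continue  # bounding fixed landmarks never slide
            prev_p = chain[(pos - 1) % m]
            next_p = chain[(pos + 1) % m]
            t = points[next_p] - points[prev_p]
            norm = np.linalg.norm(t)
            if norm == 0.0:
                raise DegenerateShapeError(
                    f"coincident curve neighbours around point {p}; tangent undefined"
                )
            idx_all.append(int(p))
            tan_all.append(t / norm)
    return np.array(idx_all, dtype=int), np.array(tan_all)


def slide_semilandmarks(
    shapes: np.ndarray,
    mean_shape: np.ndarray,
    template: LandmarkTemplate,
) -> np.ndarray:
    """Slide each specimen's semilandmarks to minimise TPS bending energy.

    For specimen Y and reference X, semilandmark j moves by t_j along its
    unit tangent; the vector t solves the normal equations of minimising
    the bending energy of the deformation X -> Y + U t jointly over all
    semilandmarks (U maps sliding amounts into coordinate space).  Fixed
    landmarks never move, and the quadratic objective guarantees the energy
    after sliding is no larger than before.
    """
    shapes = np.asarray(shapes, dtype=float)
    single = shapes.ndim == 2
    if single:
        shapes = shapes[None]
    Lk = bending_energy_matrix(mean_shape)
    out = shapes.copy()
    for i, Y in enumerate(shapes):
        sl_idx, T = _tangent_directions(Y, template)
        if len(sl_idx) == 0:
            continue
        D = Y - mean_shape  # (k, 2)
        Lsub = Lk[np.ix_(sl_idx, sl_idx)]
        M = Lsub * (T @ T.T)  # (m, m): U^T (I2 (x) Lk) U
        g = np.einsum("md,md->m", (Lk @ D)[sl_idx], T)  # U^T (I2 (x) Lk) d
        try:
            t = -np.linalg.solve(M, g)
        except np.linalg.LinAlgError:
            t = -np.linalg.lstsq(M, g, rcond=None)[0]
        out[i, sl_idx] = Y[sl_idx] + t[:, None] * T
    return out[0] if single else out


# ---------------------------------------------------------------- GPA --


@dataclass
class AlignedSet:
    """Superimposed shapes in a common coordinate frame.

    Each shape is centred with unit centroid size; ``centroid_sizes`` keeps
    the pre-scaling sizes and ``log_sizes`` their natural logs.
    ``mean_shape`` is the coordinate-wise mean rescaled to unit size.
    """

    shapes: np.ndarray  # (n, k, 2)
    centroid_sizes: np.ndarray  # (n,)
    log_sizes: np.ndarray  # (n,)
    mean_shape: np.ndarray  # (k, 2)
    labels: list[str]
    species: list[str] | None = None
    n_iterations: int = 0
    final_change: float = float("nan")

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1]

    def flat(self) -> np.ndarray:
        """Shapes flattened to (n, 2k), x/y interleaved per point."""
        return self.shapes.reshape(self.n, -1)


def _mean_of(shapes: np.ndarray) -> np.ndarray:
    m = shapes.mean(axis=0)
    m, _ = standardize(m)
    return m


def _align_to_mean(shapes: np.ndarray, mean: np.ndarray) -> np.ndarray:
    out = np.empty_like(shapes)
    for i, s in enumerate(shapes):
        R = _optimal_rotation(mean, s)
        out[i] = s @ R
    return out


def gpa(
    configs,
    template: LandmarkTemplate | None = None,
    slide: bool = False,
    tol: float = 1e-10,
    max_iter: int = 200,
    max_slide_rounds: int = 10,
    sliding_reference: str = "iterated",
) -> AlignedSet:
    """Generalised Procrustes Analysis of a sample of configurations.

    ``configs`` may be a list of :class:`Configuration` or an (n, k, 2)
    array.  With ``slide=True`` (requires a template with curves),
    semilandmark sliding against the current mean is interleaved with the
    alignment iterations; ``sliding_reference='grand'`` slides once against
    the initial converged mean instead of the iterated one.
    """
    if isinstance(configs, np.ndarray):
        raw = np.asarray(configs, dtype=float)
        labels = [f"specimen_{i}" for i in range(raw.shape[0])]
        species = None
    else:
        raw = np.array([c.points for c in configs], dtype=float)
        labels = [c.specimen_id for c in configs]
        species = [c.species for c in configs]
    if raw.ndim != 3 or raw.shape[0] < 2:
        raise ValueError("GPA needs at least 2 configurations with equal point counts")
    if slide and (template is None or not template.curves):
        raise ValueError("sliding requires a template with semilandmark curves")

    n = raw.shape[0]
    shapes = np.empty_like(raw)
    sizes = np.empty(n)
    for i, p in enumerate(raw):
        shapes[i], sizes[i] = standardize(p)

    def converge(shapes: np.ndarray, mean: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, float]:
        change = np.inf
        it = 0
        while it < max_iter:
            it += 1
            shapes = _align_to_mean(shapes, mean)
            new_mean = _mean_of(shapes)
            # compare in a common orientation
            R = _optimal_rotation(mean, new_mean)
            change = float(np.sqrt(((new_mean @ R - mean) ** 2).sum()))
            mean = new_mean
            if change < tol:
                return shapes, mean, it, change
        raise GPAConvergenceError(change, max_iter)

    mean = _mean_of(_align_to_mean(shapes, shapes[0]))
    shapes, mean, total_it, change = converge(shapes, mean)

    if slide:
        reference = mean
        for _ in range(max_slide_rounds):
            shapes = slide_semilandmarks(shapes, reference, template)
            # sliding perturbs centring/size; re-standardise and re-align
            for i in range(n):
                shapes[i], _ = standardize(shapes[i])
            new_shapes, new_mean, it, change = converge(shapes, mean)
            total_it += it
            shift = float(np.sqrt(((new_mean - mean) ** 2).sum()))
            shapes, mean = new_shapes, new_mean
            if sliding_reference == "iterated":
                reference = mean
            if shift < max(tol, 1e-9):
                break

    return AlignedSet(
        shapes=shapes,
        centroid_sizes=sizes,
        log_sizes=np.log(sizes),
        mean_shape=mean,
        labels=labels,
        species=species,
        n_iterations=total_it,
        final_change=change,
    )


def species_means(aligned: AlignedSet, by=None) -> AlignedSet:
    """Per-species mean shapes and mean log centroid sizes.

    ``by`` defaults to the aligned set's own species labels.  Mean shapes
    are rescaled to unit centroid size so the result is itself a valid
    aligned set; species size is the mean of the specimens' log sizes.
    Species with zero specimens are skipped with a warning.
    """
    if by is None:
        by = aligned.species
    if by is None:
        raise ValueError("no species labels available")
    by = list(by)
    if len(by) != aligned.n:
        raise ValueError("label length does not match number of specimens")
    order = list(dict.fromkeys(by))
    shapes, logs, labels = [], [], []
    for sp in order:
        idx = [i for i, b in enumerate(by) if b == sp]
        if not idx:
            warnings.warn(f"species {sp!r} has no specimens; skipped")
            continue
        m, _ = standardize(aligned.shapes[idx].mean(axis=0))
        shapes.append(m)
        logs.append(float(aligned.log_sizes[idx].mean()))
        labels.append(sp)
    shapes = np.array(shapes)
    logs = np.array(logs)
    return AlignedSet(
        shapes=shapes,
        centroid_sizes=np.exp(logs),
        log_sizes=logs,
        mean_shape=_mean_of(shapes),
        labels=labels,
        species=labels,
    )
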