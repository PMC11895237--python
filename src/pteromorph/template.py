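"""Digitization templates for 2D landmark/semilandmark configurations.

A template describes how a specimen was digitized: the fixed (homologous)
landmarks, the semilandmark curves strung between them, and which landmarks
lie on the sagittal midline (used when a one-sided digitization is mirrored
into a full bilateral configuration).

Point-ordering convention: the ``n_landmarks`` fixed landmarks come first,
followed by the semilandmarks of each curve in curve order.  Curve
semilandmarks never include the bounding fixed landmarks; a closed curve has
no bounding landmarks at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Curve",
    "LandmarkTemplate",
    "pteromyini_template",
    "template_mean_shape",
    "mirror_template",
]


@dataclass(frozen=True)
class Curve:
    """A semilandmark curve.

    ``start``/``end`` are 0-based ids of the bounding fixed landmarks, or
    ``None`` for a closed outline (the curve wraps onto itself).
    """

    start: int | None
    end: int | None
    n_semilandmarks: int
    closed: bool = False

    def __post_init__(self) -> None:
        if self.n_semilandmarks < 1:
            raise ValueError("a curve needs at least one semilandmark")
        if self.closed:
            if self.start is not None or self.end is not None:
                raise ValueError("closed curves have no bounding landmarks")
        elif self.start is None or self.end is None:
            raise ValueError("open curves need both bounding landmark ids")


@dataclass(frozen=True)
class LandmarkTemplate:
    n_landmarks: int
    curves: tuple[Curve, ...] = ()
    midline: frozenset[int] = frozenset()
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_landmarks < 1:
            raise ValueError("template needs at least one landmark")
        for c in self.curves:
            for endpoint in (c.start, c.end):
                if endpoint is not None and not 0 <= endpoint < self.n_landmarks:
                    raise ValueError(
                        f"curve endpoint {endpoint} is not a landmark id "
                        f"(template has {self.n_landmarks} landmarks)"
                    )
        for m in self.midline:
            if not 0 <= m < self.n_landmarks:
                raise ValueError(f"midline id {m} is not a landmark id")
        if self.labels and len(self.labels) != self.n_landmarks:
            raise ValueError("labels must match n_landmarks")

    # -- layout ---------------------------------------------------------

    @property
    def n_semilandmarks(self) -> int:
        return sum(c.n_semilandmarks for c in self.curves)

    @property
    def n_points(self) -> int:
        """Total points in a one-sided configuration."""
        return self.n_landmarks + self.n_semilandmarks

    @property
    def n_points_bilateral(self) -> int:
        """Points after mirroring: everything duplicated except the midline."""
        return 2 * self.n_points - len(self.midline)

    def curve_semilandmark_indices(self, i: int) -> np.ndarray:
        """Point indices of curve *i*'s semilandmarks (template order)."""
        offset = self.n_landmarks
        for j, c in enumerate(self.curves):
            if j == i:
                return np.arange(offset, offset + c.n_semilandmarks)
            offset += c.n_semilandmarks
        raise IndexError(f"no curve {i}")

    def curve_chains(self) -> list[tuple[np.ndarray, bool]]:
        """Per curve, the full ordered chain of point indices.

        Open curves are returned as start-landmark, semilandmarks,
        end-landmark; closed curves as the semilandmark cycle alone.  The
        boolean marks closure.
        """
        chains = []
        for i, c in enumerate(self.curves):
            semis = self.curve_semilandmark_indices(i)
            if c.closed:
                chains.append((semis, True))
            else:
                chains.append(
                    (np.concatenate(([c.start], semis, [c.end])), False)
                )
        return chains

    def semilandmark_indices(self) -> np.ndarray:
        return np.arange(self.n_landmarks, self.n_points)


def pteromyini_template() -> LandmarkTemplate:
    """The ventral-cranium digitization scheme used for flying squirrels.

    19 fixed landmarks and four curves: the snout contour (8 semilandmarks,
    between landmarks 1 and 19), the outer (landmarks 19 to 18) and inner
    (7 to 9) outlines of the zygomatic arch with 18 semilandmarks each, and
    the closed outline of the fourth upper premolar (18 semilandmarks).
    Landmarks 1, 10, 11, 13 and 14 lie on the mid-sagittal plane; 81 points
    one-sided, 157 after mirroring.
    """
    labels = (
        "anterior mid-sagittal point of premaxilla",
        "midpoint of incisor tooth sockets",
        "anterior end of incisor foramen",
        "posterior end of incisor foramen",
        "tip of masseter tubercle",
        "anterior end of P4",
        "maximum curvature of internal zygomatic arch",
        "posterior end of tooth row",
        "alisphenoid-squamosal suture, anterior end",
        "maxilla-palatine suture on mid-sagittal plane",
        "posterior end of interpalatine suture",
        "pterygoid apophysis",
        "anterior edge of foramen magnum",
        "posterior edge of foramen magnum",
        "occipital condyle x internal foramen magnum edge",
        "outermost point of occipital condyle",
        "anterior tip of external auditory meatus",
        "posterior tip of zygomatic arch",
        "most lateral rostrum point on premaxilla-maxilla suture",
    )
    curves = (
        Curve(start=0, end=18, n_semilandmarks=8),     # snout contour
        Curve(start=18, end=17, n_semilandmarks=18),   # outer zygomatic arch
        Curve(start=6, end=8, n_semilandmarks=18),     # inner zygomatic arch
        Curve(start=None, end=None, n_semilandmarks=18, closed=True),  # P4
    )
    return LandmarkTemplate(
        n_landmarks=19,
        curves=curves,
        midline=frozenset({0, 9, 10, 12, 13}),
        labels=labels,
    )


# Plausible one-sided ventral-view coordinates for a cranium in template
# order.  The midline runs along x = 0, the rostrum points toward +y; the
# digitized side sits at x > 0.  Used as the grand-mean shape by the
# synthetic-data generator.
_PTEROMYINI_LANDMARKS = np.array(
    [
        [0.00, 1.00],   # 1  premaxilla (midline)
        [0.06, 0.94],   # 2
        [0.08, 0.80],   # 3
        [0.10, 0.55],   # 4
        [0.22, 0.48],   # 5  masseter tubercle
        [0.24, 0.42],   # 6  anterior P4
        [0.42, 0.12],   # 7  inner zygomatic, max curvature
        [0.26, 0.05],   # 8  posterior tooth row
        [0.40, -0.30],  # 9
        [0.00, 0.20],   # 10 (midline)
        [0.00, 0.00],   # 11 (midline)
        [0.12, -0.10],  # 12 pterygoid
        [0.00, -0.55],  # 13 (midline)
        [0.00, -0.78],  # 14 (midline)
        [0.05, -0.62],  # 15
        [0.16, -0.68],  # 16
        [0.30, -0.45],  # 17 auditory meatus
        [0.52, -0.35],  # 18 posterior zygomatic tip
        [0.38, 0.72],   # 19 lateral rostrum
    ]
)


def _bezier(p0: np.ndarray, p1: np.ndarray, ctrl: np.ndarray, n: int) -> np.ndarray:
    """n interior points of a quadratic Bezier arc from p0 to p1."""
    t = np.linspace(0.0, 1.0, n + 2)[1:-1, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1


def template_mean_shape(template: LandmarkTemplate | None = None) -> np.ndarray:
    """A smooth, non-degenerate one-sided mean configuration (k x 2).

    Only defined for the flying-squirrel template layout (19 landmarks,
    8+18+18+18 semilandmarks); other templates must supply their own mean.
    """
    if template is None:
        template = pteromyini_template()
    lms = _PTEROMYINI_LANDMARKS
    expected = pteromyini_template()
    if (template.n_landmarks, tuple(c.n_semilandmarks for c in template.curves)) != (
        expected.n_landmarks,
        tuple(c.n_semilandmarks for c in expected.curves),
    ):
        raise ValueError("built-in mean shape only exists for the cranial template")
    c1 = _bezier(lms[0], lms[18], np.array([0.30, 1.04]), 8)
    c2 = _bezier(lms[18], lms[17], np.array([0.72, 0.20]), 18)
    c3 = _bezier(lms[6], lms[8], np.array([0.30, -0.08]), 18)
    theta = np.linspace(0.0, 2 * np.pi, 19)[:-1]  # counterclockwise P4 outline
    c4 = np.column_stack(
        [0.255 + 0.055 * np.cos(theta), 0.33 + 0.075 * np.sin(theta)]
    )
    return np.vstack([lms, c1, c2, c3, c4])


def mirror_template(template: LandmarkTemplate) -> LandmarkTemplate:
    """The bilateral template implied by mirroring a one-sided one.

    Layout of the bilateral configuration: the original fixed landmarks,
    then the mirrored copies of the non-midline landmarks (in original
    order), then the original curves' semilandmarks, then the mirrored
    curves' semilandmarks.  Midline landmarks appear once and stay midline.
    """
    lateral = [i for i in range(template.n_landmarks) if i not in template.midline]
    lm_map = {i: template.n_landmarks + r for r, i in enumerate(lateral)}
    for m in template.midline:
        lm_map[m] = m
    mirrored_curves = tuple(
        replace(
            c,
            start=None if c.closed else lm_map[c.start],
            end=None if c.closed else lm_map[c.end],
        )
        for c in template.curves
    )
    labels = ()
    if template.labels:
        labels = tuple(template.labels) + tuple(
            template.labels[i] + " (mirrored)" for i in lateral
        )
    return LandmarkTemplate(
        n_landmarks=template.n_landmarks + len(lateral),
        curves=tuple(template.curves) + mirrored_curves,
        midline=frozenset(template.midline),
        labels=labels,
    )
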