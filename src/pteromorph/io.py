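"""Reading, writing and assembling landmark configurations.

Supports the two plain-text formats used in practice for 2D landmark data:
TPS files (``LM=``, ``ID=`` records, one block per specimen) and a long
CSV with columns ``specimen, species, point, x, y``.  Species metadata
(diet category and biome occupancy) travels as a separate CSV.

Mirroring: crania are bilaterally symmetric, so digitizing one side and
reflecting it across the sagittal axis builds the full structure without
introducing spurious asymmetry.  The axis is the total-least-squares line
through the midline landmarks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .template import LandmarkTemplate, mirror_template

__all__ = [
    "Configuration",
    "LandmarkFormatError",
    "LandmarkCountError",
    "read_landmarks",
    "write_landmarks",
    "read_metadata",
    "write_metadata",
    "mirror_configuration",
    "reflect_across_line",
    "midline_axis",
    "BIOME_LABELS",
    "DIET_LABELS",
]

BIOME_LABELS = ("I", "II", "II/III", "V", "VI", "VIII")
DIET_LABELS = ("Folivore_1", "Folivore_2", "Frugivore", "Nucivore", "Generalist", "NoInfo")


class LandmarkFormatError(ValueError):
    """A landmark file could not be parsed; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class LandmarkCountError(ValueError):
    """Point count of a specimen does not match the template."""

    def __init__(self, specimen: str, expected, found: int):
        self.specimen, self.expected, self.found = specimen, expected, found
        super().__init__(
            f"specimen {specimen!r}: expected {expected} points, found {found}"
        )


@dataclass
class Configuration:
    """One specimen's digitized 2D points plus identity metadata."""

    specimen_id: str
    species: str
    points: np.ndarray  # (k, 2) float
    side: str = "left"  # left | right | bilateral

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be a k x 2 matrix")
        if np.isnan(self.points).any():
            raise ValueError(
                f"specimen {self.specimen_id!r} has missing coordinates"
            )
        if self.side not in ("left", "right", "bilateral"):
            raise ValueError(f"unknown side {self.side!r}")

    @property
    def k(self) -> int:
        return self.points.shape[0]


def _check_count(config: Configuration, template: LandmarkTemplate) -> None:
    expected = (
        template.n_points_bilateral if config.side == "bilateral" else template.n_points
    )
    if config.k != expected:
        raise LandmarkCountError(config.specimen_id, expected, config.k)


# ---------------------------------------------------------------- TPS --


def _read_tps(path: Path, side: str) -> list[Configuration]:
    configs: list[Configuration] = []
    lm: int | None = None
    rows: list[list[float]] = []
    spec_id: str | None = None
    species = ""
    start_line = 0

    def flush(line_no: int) -> None:
        nonlocal lm, rows, spec_id, species
        if lm is None:
            return
        if len(rows) != lm:
            raise LandmarkFormatError(
                f"block starting at line {start_line} declares LM={lm} "
                f"but has {len(rows)} coordinate pairs",
                line=line_no,
            )
        configs.append(
            Configuration(
                specimen_id=spec_id or f"specimen_{len(configs)}",
                species=species,
                points=np.array(rows, dtype=float),
                side=side,
            )
        )
        lm, rows, spec_id, species = None, [], None, ""

    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush(i)
                start_line = i
                try:
                    lm = int(line[3:])
                except ValueError as exc:
                    raise LandmarkFormatError(f"bad LM record {line!r}", line=i) from exc
            elif upper.startswith("ID="):
                spec_id = line[3:].strip()
            elif upper.startswith("COMMENT="):
                species = line[8:].strip()
            elif upper.startswith(("IMAGE=", "SCALE=")):
                continue
            else:
                parts = line.split()
                if len(parts) != 2:
                    raise LandmarkFormatError(
                        f"expected 'x y' coordinate pair, got {line!r}", line=i
                    )
                try:
                    rows.append([float(parts[0]), float(parts[1])])
                except ValueError as exc:
                    raise LandmarkFormatError(
                        f"non-numeric coordinate in {line!r}", line=i
                    ) from exc
    flush(-1)
    return configs


def _write_tps(configs: list[Configuration], path: Path) -> None:
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM={c.k}\n")
            for x, y in c.points:
                fh.write(f"{x:.12g} {y:.12g}\n")
            if c.species:
                fh.write(f"COMMENT={c.species}\n")
            fh.write(f"ID={c.specimen_id}\n")


# ---------------------------------------------------------------- CSV --


def _read_csv(path: Path, side: str) -> list[Configuration]:
    df = pd.read_csv(path)
    required = {"specimen", "point", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise LandmarkFormatError(
            f"CSV is missing columns {sorted(missing)} (long format "
            "'specimen,species,point,x,y' expected)"
        )
    if "species" not in df.columns:
        df["species"] = ""
    df["species"] = df["species"].fillna("")
    configs = []
    for spec_id, block in df.groupby("specimen", sort=False):
        if block[["x", "y"]].isna().any().any():
            raise LandmarkFormatError(
                f"specimen {spec_id!r} has missing x/y cells"
            )
        block = block.sort_values("point")
        pts = block[["x", "y"]].to_numpy(dtype=float)
        species = str(block["species"].iloc[0])
        configs.append(
            Configuration(specimen_id=str(spec_id), species=species, points=pts, side=side)
        )
    return configs


def _write_csv(configs: list[Configuration], path: Path) -> None:
    frames = []
    for c in configs:
        frames.append(
            pd.DataFrame(
                {
                    "specimen": c.specimen_id,
                    "species": c.species,
                    "point": np.arange(c.k),
                    "x": c.points[:, 0],
                    "y": c.points[:, 1],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def read_landmarks(
    path: str | Path,
    format: str | None = None,
    template: LandmarkTemplate | None = None,
    side: str = "left",
) -> list[Configuration]:
    """Read specimen configurations from a TPS or long-CSV file.

    When a template is given, every specimen's point count is validated
    against it (one-sided or bilateral, according to ``side``).
    """
    path = Path(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv"
    if format == "tps":
        configs = _read_tps(path, side)
    elif format == "csv":
        configs = _read_csv(path, side)
    else:
        raise ValueError(f"unknown landmark format {format!r}")
    if template is not None:
        for c in configs:
            _check_count(c, template)
    return configs


def write_landmarks(
    configs: list[Configuration], path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    if format is None:
        format = "tps" if path.suffix.lower() == ".tps" else "csv"
    if format == "tps":
        _write_tps(configs, path)
    elif format == "csv":
        _write_csv(configs, path)
    else:
        raise ValueError(f"unknown landmark format {format!r}")


# ----------------------------------------------------------- metadata --


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Species metadata CSV: species, N, diet, and one 0/1 column per biome."""
    df = pd.read_csv(path)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "species" not in df.columns or "diet" not in df.columns:
        raise ValueError("metadata needs 'species' and 'diet' columns")
    bad = set(df["diet"]) - set(DIET_LABELS)
    if bad:
        raise ValueError(f"unknown diet categories: {sorted(bad)}")
    biome_cols = [b for b in BIOME_LABELS if b in df.columns]
    if not biome_cols:
        raise ValueError("metadata has no biome occupancy columns")
    df[biome_cols] = df[biome_cols].fillna(0).astype(int)
    return df


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------- mirroring --


def midline_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through the given points.

    Returns (centroid, unit direction).  Needs at least two distinct points.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("at least 2 midline landmarks are needed to define an axis")
    c = points.mean(axis=0)
    dev = points - c
    if np.allclose(dev, 0.0):
        raise ValueError("midline landmarks are coincident; axis undefined")
    # principal direction of the scatter = TLS fit
    _, _, vt = np.linalg.svd(dev, full_matrices=False)
    return c, vt[0]


def reflect_across_line(points: np.ndarray, centre: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Reflect points across the line through ``centre`` along ``direction``."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    R = 2.0 * np.outer(u, u) - np.eye(2)
    return (np.asarray(points) - centre) @ R.T + centre


def mirror_configuration(
    config: Configuration, template: LandmarkTemplate
) -> Configuration:
    """Build the bilateral configuration from a one-sided digitization.

    Non-midline points are reflected across the TLS line through the
    midline landmarks; midline landmarks appear once.  Output ordering
    follows :func:`pteromorph.template.mirror_template`: original fixed
    landmarks, mirrored fixed landmarks, original semilandmarks, mirrored
    semilandmarks.
    """
    if config.side == "bilateral":
        raise ValueError(f"specimen {config.specimen_id!r} is already bilateral")
    if not template.midline:
        raise ValueError("template has no midline landmarks; cannot mirror")
    _check_count(config, template)
    mid = sorted(template.midline)
    centre, direction = midline_axis(config.points[mid])
    reflected = reflect_across_line(config.points, centre, direction)

    lateral_lms = [i for i in range(template.n_landmarks) if i not in template.midline]
    semis = template.semilandmark_indices()
    pts = np.vstack(
        [
            config.points[: template.n_landmarks],
            reflected[lateral_lms],
            config.points[semis],
            reflected[semis],
        ]
    )
    return replace(config, points=pts, side="bilateral")


def mirror_all(
    configs: list[Configuration], template: LandmarkTemplate
) -> tuple[list[Configuration], LandmarkTemplate]:
    """Mirror every configuration; returns them with the bilateral template."""
    out = [mirror_configuration(c, template) for c in configs]
    return out, mirror_template(template)
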