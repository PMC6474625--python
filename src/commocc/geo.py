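"""Covariate construction on planar geometric inputs.

Site covariates for the occupancy model are derived from simple GIS
layers: nearest-feature distances (to settlements, rivers, protected
area boundaries) and percent land-cover within a circular buffer.
Coordinates are assumed planar (projected, metres); the study extents
this targets (tens of km) make geodesic corrections negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiPoint, Point
from shapely.ops import unary_union

__all__ = [
    "PointSet",
    "LandCoverRaster",
    "nearest_distance",
    "percent_cover",
    "correlation_screen",
    "read_points_csv",
    "read_segments_csv",
    "read_ascii_grid",
]


@dataclass(frozen=True)
class PointSet:
    """A set of planar points (x, y) in metres."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) == 0:
            raise ValueError("PointSet must be non-empty")
        arr = np.asarray(self.points, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("PointSet coordinates must be finite")

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "PointSet":
        return cls(tuple(map(tuple, np.asarray(arr, dtype=float))))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


@dataclass
class LandCoverRaster:
    """Categorical land-cover grid.

    ``origin`` is the (x, y) of the *lower-left corner* of the grid;
    cell centres sit at ``origin + (col + 0.5, row + 0.5) * cell_size``
    with row 0 the southernmost row.
    """

    origin: tuple[float, float]
    cell_size: float
    classes: np.ndarray  # int (rows, cols)
    legend: dict[int, str]

    def __post_init__(self) -> None:
        if not (self.cell_size > 0):
            raise ValueError("cell_size must be > 0")
        self.classes = np.asarray(self.classes, dtype=int)
        codes = set(np.unique(self.classes).tolist())
        unknown = codes - set(self.legend)
        if unknown:
            raise ValueError(f"raster codes missing from legend: {sorted(unknown)}")

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = self.classes.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


def nearest_distance(
    sites: PointSet,
    features: PointSet | Sequence[tuple[tuple[float, float], tuple[float, float]]],
) -> np.ndarray:
    """Minimum Euclidean distance from each site to the nearest feature.

    ``features`` may be a :class:`PointSet` or a sequence of line
    segments given as ((x1, y1), (x2, y2)) pairs.
    """
    if isinstance(features, PointSet):
        geom = MultiPoint([Point(p) for p in features.points])
    else:
        segs = list(features)
        if len(segs) == 0:
            raise ValueError("feature set is empty")
        geom = unary_union([LineString([a, b]) for a, b in segs])
    return np.array([geom.distance(Point(p)) for p in sites.points], dtype=float)


def percent_cover(
    raster: LandCoverRaster,
    site: tuple[float, float],
    radius: float = 500.0,
    target_class: int = 1,
) -> float:
    """Fraction of the buffer around ``site`` covered by ``target_class``.

    Membership is by cell centre: a cell counts if its centre lies
    within ``radius`` of the site. Cells outside the raster extent are
    excluded from the denominator; a buffer that contains no cell
    centre at all is rejected.
    """
    if not (radius > 0):
        raise ValueError("radius must be > 0")
    gx, gy = raster.cell_centres()
    inside = (gx - site[0]) ** 2 + (gy - site[1]) ** 2 <= radius**2
    n_in = int(inside.sum())
    if n_in == 0:
        raise ValueError("buffer does not intersect the raster extent")
    return float((raster.classes[inside] == target_class).sum() / n_in)


def correlation_screen(
    table: pd.DataFrame, threshold: float = 0.7
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations with flags for collinear pairs.

    Returns the symmetric correlation matrix and the list of column
    pairs with ``|r| >= threshold`` (candidates for dropping one of the
    two before model fitting).
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 3:
        raise ValueError("need at least 3 rows to screen correlations")
    sds = num.std(ddof=0)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance columns: {zero}")
    corr = num.corr(method="pearson")
    flagged = []
    cols = list(corr.columns)
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            r = float(corr.iloc[a, b])
            if abs(r) >= threshold:
                flagged.append((cols[a], cols[b], r))
    return corr, flagged


# ---------------------------------------------------------------------------
# plain-text layer formats

def read_points_csv(path: str | Path) -> PointSet:
    df = pd.read_csv(path)
    return PointSet.from_array(df[["x", "y"]].to_numpy())


def read_segments_csv(path: str | Path) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    df = pd.read_csv(path)
    return [
        ((row["x1"], row["y1"]), (row["x2"], row["y2"])) for _, row in df.iterrows()
    ]


def read_ascii_grid(path: str | Path, legend: dict[int, str]) -> LandCoverRaster:
    """ASCII grid: line 1 ``x0 y0 cell_size``, then rows of codes
    (first line of the matrix is the northernmost row, as printed)."""
    lines = Path(path).read_text().strip().splitlines()
    x0, y0, cs = (float(v) for v in lines[0].split())
    rows = [list(map(int, ln.split())) for ln in lines[1:]]
    classes = np.asarray(rows[::-1], dtype=int)  # store south-up
    return LandCoverRaster(origin=(x0, y0), cell_size=cs, classes=classes, legend=legend)
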