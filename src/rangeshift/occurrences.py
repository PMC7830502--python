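"""Occurrence records: CSV I/O, cleaning, and predictor extraction.

Cleaning mirrors standard SDM practice for presence records: drop
duplicates (at most one record per analysis grid cell), drop points
outside the analysis extent, and drop points falling on implausible
land-cover classes (water, built-up), which typically indicate
georeferencing errors.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .grids import GridDefinition, PredictorStack, RasterGrid

__all__ = [
    "OccurrenceSet",
    "read_occurrences",
    "write_occurrences",
    "clean_occurrences",
    "extract_at_points",
    "build_sample_table",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class OccurrenceSet:
    """Presence coordinates for one species (WGS84 decimal degrees)."""

    species: str
    points: np.ndarray  # shape (n, 2): lon, lat

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": self.species, "lon": self.points[:, 0], "lat": self.points[:, 1]}
        )


def write_occurrences(occurrences: list[OccurrenceSet] | OccurrenceSet, path) -> Path:
    if isinstance(occurrences, OccurrenceSet):
        occurrences = [occurrences]
    path = Path(path)
    pd.concat([o.to_frame() for o in occurrences]).to_csv(path, index=False)
    return path


def read_occurrences(path) -> dict[str, OccurrenceSet]:
    """Read a ``species,lon,lat`` CSV into one OccurrenceSet per species."""
    df = pd.read_csv(path)
    missing = {"species", "lon", "lat"} - set(df.columns)
    if missing:
        raise IOError(f"occurrence CSV {path} lacks columns: {sorted(missing)}")
    return {
        str(sp): OccurrenceSet(str(sp), grp[["lon", "lat"]].to_numpy())
        for sp, grp in df.groupby("species", sort=True)
    }


def clean_occurrences(
    raw: OccurrenceSet,
    extent: shapely.Geometry | None = None,
    landcover: RasterGrid | None = None,
    excluded_classes: set[int] | frozenset[int] = frozenset(),
    grid: GridDefinition | None = None,
) -> OccurrenceSet:
    """Deduplicate per grid cell and drop out-of-extent / bad-landcover points.

    The result is order independent: records are pre-sorted
    lexicographically on (lon, lat) and the first record in a cell wins.
    Idempotent by construction. Returns a possibly empty set (with a
    warning) rather than raising, so the caller decides how to proceed.
    """
    if grid is None and landcover is not None:
        grid = landcover.grid
    pts = raw.points
    if len(pts) == 0:
        return OccurrenceSet(raw.species, pts)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    keep = np.ones(len(pts), dtype=bool)
    if extent is not None:
        keep &= shapely.intersects_xy(extent, pts[:, 0], pts[:, 1])
    if grid is not None:
        inside = (
            (pts[:, 0] >= grid.x_min)
            & (pts[:, 0] < grid.x_max)
            & (pts[:, 1] > grid.y_min)
            & (pts[:, 1] <= grid.y_max)
        )
        keep &= inside
    pts = pts[keep]

    if landcover is not None and excluded_classes:
        cells = grid.cells_of(pts)
        classes = landcover.values[cells[:, 0], cells[:, 1]]
        bad = np.isin(classes, list(excluded_classes))
        n_bad = int(bad.sum())
        if n_bad:
            logger.info("dropped %d record(s) on excluded land-cover classes", n_bad)
        pts = pts[~bad]

    if grid is not None and len(pts):
        cells = grid.cells_of(pts)
        _, first = np.unique(cells, axis=0, return_index=True)
        pts = pts[np.sort(first)]
    else:
        pts = np.unique(pts, axis=0)

    if len(pts) == 0:
        warnings.warn(
            f"all occurrence records for {raw.species!r} were removed by cleaning",
            stacklevel=2,
        )
    return OccurrenceSet(raw.species, pts)


def extract_at_points(stack: PredictorStack, points: np.ndarray) -> pd.DataFrame:
    """Predictor values at each point's containing cell.

    One row per point, columns ``lon, lat`` plus one per layer. Points on
    a nodata cell in any layer are excluded with a log entry; points off
    the raster raise ``ValueError``.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    cells = stack.grid.cells_of(points)
    data = {"lon": points[:, 0], "lat": points[:, 1]}
    for name, layer in stack.items():
        data[name] = layer.values[cells[:, 0], cells[:, 1]]
    df = pd.DataFrame(data)
    bad = df[stack.names].isna().any(axis=1)
    if bad.any():
        logger.warning("excluded %d point(s) falling on nodata cells", int(bad.sum()))
        df = df[~bad].reset_index(drop=True)
    return df


def build_sample_table(
    stack: PredictorStack,
    presences: np.ndarray,
    pseudo_absences: np.ndarray,
) -> pd.DataFrame:
    """Presence/pseudo-absence training table with a binary ``label`` column."""
    pres = extract_at_points(stack, presences)
    pres["label"] = 1
    absn = extract_at_points(stack, pseudo_absences)
    absn["label"] = 0
    return pd.concat([pres, absn], ignore_index=True)
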