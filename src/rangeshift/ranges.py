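"""Range geometry and occupancy: alpha-hull EOO, AOO cell counts, change maps.

The extent of occurrence (EOO) is an alpha hull around the cleaned
occurrence points — a Delaunay triangulation with triangles whose
circumradius exceeds ``alpha`` discarded, so disjunct ranges yield
multipart hulls — buffered outward by 0.1 decimal degrees. The area of
occupancy (AOO) is the count of suitable grid cells (nominally 2 km,
4 km² each) inside the buffered EOO after land-cover masking; both
current and future binary maps are cropped by the same EOO, so gains
outside the EOO do not rescue a shrinking AOO.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import shapely
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, Polygon, mapping
from shapely.ops import unary_union

from .exceptions import DegenerateGeometryError, GridAlignmentError
from .grids import RasterGrid

__all__ = [
    "EOOPolygon",
    "AOOEstimate",
    "ChangeMap",
    "CHANGE_CLASSES",
    "default_alpha",
    "alpha_hull",
    "buffer_eoo",
    "mask_by_polygon",
    "mask_by_landcover",
    "compute_aoo",
    "make_change_map",
    "apply_dispersal",
    "aoo_change_percent",
]

# change-map class table
NEVER, LOSS, STABLE, GAIN = 0, 1, 2, 3
CHANGE_CLASSES = {NEVER: "never", LOSS: "loss", STABLE: "stable", GAIN: "gain"}


@dataclasses.dataclass
class EOOPolygon:
    """Buffered alpha-hull extent of occurrence (decimal degrees)."""

    geometry: shapely.Geometry
    alpha: float
    buffer_deg: float

    @property
    def area(self) -> float:
        return self.geometry.area

    def write_geojson(self, path: str | Path) -> Path:
        path = Path(path)
        feature = {
            "type": "Feature",
            "geometry": mapping(self.geometry),
            "properties": {"alpha": self.alpha, "buffer_deg": self.buffer_deg},
        }
        path.write_text(json.dumps({"type": "FeatureCollection", "features": [feature]}))
        return path


@dataclasses.dataclass(frozen=True)
class AOOEstimate:
    """Occupied-cell count under one threshold rule / scenario combination."""

    cell_count: int
    cell_area_km2: float = 4.0
    threshold_rule: str = ""
    scenario: str = ""

    @property
    def area_km2(self) -> float:
        return self.cell_count * self.cell_area_km2


@dataclasses.dataclass
class ChangeMap:
    """Categorical loss/stable/gain/never raster plus its provenance."""

    raster: RasterGrid
    dispersal: str = "full"

    def counts(self) -> dict[str, int]:
        v = self.raster.values
        return {
            name: int(np.nansum(v == code)) for code, name in CHANGE_CLASSES.items()
        }

    def future_binary(self) -> RasterGrid:
        """Binary future suitability implied by the (post-dispersal) classes."""
        v = self.raster.values
        out = np.where(np.isfinite(v), np.isin(v, (STABLE, GAIN)).astype(float), np.nan)
        return self.raster.with_values(out)

    def current_binary(self) -> RasterGrid:
        v = self.raster.values
        out = np.where(np.isfinite(v), np.isin(v, (STABLE, LOSS)).astype(float), np.nan)
        return self.raster.with_values(out)


def default_alpha(points: np.ndarray) -> float:
    """Default hull alpha: 2 x median nearest-neighbour distance (degrees)."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(points) < 2:
        raise DegenerateGeometryError("need at least 2 points for a default alpha")
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    a = 2.0 * float(np.median(nn))
    return a if a > 0 else 1e-6


def _circumradius(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    la, lb, lc = (
        np.linalg.norm(b - c),
        np.linalg.norm(a - c),
        np.linalg.norm(a - b),
    )
    area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
    if area2 == 0:
        return np.inf
    return float(la * lb * lc / (2.0 * area2))


def alpha_hull(points: np.ndarray, alpha: float) -> shapely.Geometry:
    """Alpha shape: union of Delaunay triangles with circumradius <= alpha.

    May be a MultiPolygon for disjunct point clusters. Fewer than 3 or
    collinear points cannot be triangulated; the fall-back is the union
    of the points buffered by ``alpha``, emitted with a warning.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    pts_unique = np.unique(points, axis=0)

    def _fallback() -> shapely.Geometry:
        warnings.warn(
            "degenerate point set for alpha hull; falling back to buffered points",
            stacklevel=3,
        )
        return MultiPoint(pts_unique).buffer(alpha)

    if len(pts_unique) < 3:
        return _fallback()
    try:
        tri = Delaunay(pts_unique)
    except QhullError:
        return _fallback()
    keep = []
    for simplex in tri.simplices:
        a, b, c = pts_unique[simplex]
        if _circumradius(a, b, c) <= alpha:
            keep.append(Polygon([a, b, c]))
    if not keep:
        return _fallback()
    hull = unary_union(keep)
    # occurrences in no kept triangle stay in the EOO as isolated (zero-area)
    # parts: buffering then yields small discs, i.e. disjunct range fragments
    covered = shapely.intersects_xy(hull, pts_unique[:, 0], pts_unique[:, 1])
    if not covered.all():
        hull = unary_union([hull, MultiPoint(pts_unique[~covered])])
    return hull


def buffer_eoo(
    geometry: shapely.Geometry, buffer_deg: float = 0.1, alpha: float = np.nan
) -> EOOPolygon:
    """Outward Euclidean buffer in degree units (default 0.1° ≈ 12 km)."""
    if buffer_deg < 0:
        raise ValueError("buffer must be non-negative")
    return EOOPolygon(
        geometry=geometry.buffer(buffer_deg) if buffer_deg > 0 else geometry,
        alpha=float(alpha),
        buffer_deg=buffer_deg,
    )


def mask_by_polygon(binary: RasterGrid, eoo: EOOPolygon | shapely.Geometry) -> RasterGrid:
    """Zero out suitable cells whose centers fall outside the polygon."""
    geom = eoo.geometry if isinstance(eoo, EOOPolygon) else eoo
    X, Y = binary.grid.center_mesh()
    inside = shapely.intersects_xy(geom, X.ravel(), Y.ravel()).reshape(binary.grid.shape)
    if not inside.any():
        warnings.warn("polygon does not cover any cell center; result is all zero",
                      stacklevel=2)
    out = np.where(inside, binary.values, 0.0)
    out = np.where(np.isfinite(binary.values), out, np.nan)
    return binary.with_values(out)


def mask_by_landcover(
    binary: RasterGrid, landcover: RasterGrid, allowed_classes
) -> RasterGrid:
    """Suitable only where the land-cover class is in ``allowed_classes``."""
    if not landcover.grid.same_geometry(binary.grid):
        raise GridAlignmentError("land-cover raster is not aligned with the binary map")
    allowed = np.isin(landcover.values, list(allowed_classes))
    out = np.where(allowed, binary.values, 0.0)
    out = np.where(np.isfinite(binary.values), out, np.nan)
    return binary.with_values(out)


def compute_aoo(
    binary_masked: RasterGrid,
    cell_area_km2: float = 4.0,
    threshold_rule: str = "",
    scenario: str = "",
) -> AOOEstimate:
    """Count suitable (==1) cells; area = count x nominal cell area."""
    count = int(np.nansum(binary_masked.values == 1))
    return AOOEstimate(
        cell_count=count,
        cell_area_km2=cell_area_km2,
        threshold_rule=threshold_rule,
        scenario=scenario,
    )


def make_change_map(current_bin: RasterGrid, future_bin: RasterGrid) -> ChangeMap:
    """Per-cell transition classes: loss / stable / gain / never."""
    if not current_bin.grid.same_geometry(future_bin.grid):
        raise GridAlignmentError("current and future binaries are on different grids")
    cur, fut = current_bin.values, future_bin.values
    out = np.full(cur.shape, np.nan)
    valid = np.isfinite(cur) & np.isfinite(fut)
    out[valid & (cur == 1) & (fut == 1)] = STABLE
    out[valid & (cur == 1) & (fut == 0)] = LOSS
    out[valid & (cur == 0) & (fut == 1)] = GAIN
    out[valid & (cur == 0) & (fut == 0)] = NEVER
    return ChangeMap(raster=current_bin.with_values(out))


def apply_dispersal(change: ChangeMap, scenario: str) -> ChangeMap:
    """Dispersal assumption: 'full' keeps gains; 'none' discards them.

    Under no dispersal, cells that become suitable only in the future are
    unreachable and are reclassified as never-suitable.
    """
    if scenario not in {"full", "none"}:
        raise ValueError(f"unknown dispersal scenario: {scenario!r}")
    values = change.raster.values.copy()
    if scenario == "none":
        values[values == GAIN] = NEVER
    return ChangeMap(raster=change.raster.with_values(values), dispersal=scenario)


def aoo_change_percent(current: AOOEstimate, future: AOOEstimate) -> float:
    """Percent change in AOO: negative = loss, positive = gain.

    The risk classifier consumes ``loss_pct = max(0, -change)``.
    """
    if current.cell_count <= 0:
        raise ValueError("current AOO is zero; change percentage undefined")
    return 100.0 * (future.cell_count - current.cell_count) / current.cell_count
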