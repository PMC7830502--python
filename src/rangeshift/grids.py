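"""Georeferenced raster grids and multi-layer predictor stacks.

Rasters are plain 2-D numpy arrays of float64 with ``nan`` as the nodata
sentinel, tied to a :class:`GridDefinition` (origin, cell size, CRS).
Categorical layers (land cover, binary suitability, change maps) store
integer class codes in the same float representation so nodata propagates
uniformly.

On-disk format is the ESRI ASCII grid (``.asc``) — a plain-text raster
dialect readable by GDAL and the R ``raster`` package — with a ``.prj``
sidecar holding the CRS string. Non-square cells use the DX/DY header
extension.

Cell membership follows a single half-open convention shared with the
occupancy counting: a cell covers ``[x0, x0 + w)`` horizontally and
``(y0 - h, y0]`` vertically (top edge inclusive), so a point on a shared
edge belongs to exactly one cell.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .exceptions import GridAlignmentError, MissingLayerError

__all__ = [
    "GridDefinition",
    "RasterGrid",
    "PredictorStack",
    "read_raster",
    "write_raster",
    "resample_to_grid",
]

_NODATA_OUT = -9999.0


@dataclasses.dataclass(frozen=True)
class GridDefinition:
    """Affine definition of a north-up raster grid.

    ``x_min``/``y_max`` locate the outer corner of the top-left cell;
    rows increase southward, columns eastward.
    """

    n_rows: int
    n_cols: int
    x_min: float
    y_max: float
    cell_width: float
    cell_height: float
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_width <= 0 or self.cell_height <= 0:
            raise ValueError("cell sizes must be positive")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_width

    @property
    def y_min(self) -> float:
        return self.y_max - self.n_rows * self.cell_height

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_width

    def y_centers(self) -> np.ndarray:
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_height

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-center coordinates, shape ``(n_rows, n_cols)``."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x_min + (col + 0.5) * self.cell_width,
            self.y_max - (row + 0.5) * self.cell_height,
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing (x, y) under the half-open rule.

        Raises ``ValueError`` for points outside the grid extent.
        """
        col = int(np.floor((x - self.x_min) / self.cell_width))
        # (y0-h, y0] vertically: a point exactly on an interior horizontal
        # boundary belongs to the cell below it in row index terms.
        row = int(np.floor((self.y_max - y) / self.cell_height))
        if y == self.y_max:
            row = 0
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) is outside the grid extent")
        return row, col

    def cells_of(self, xy: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`cell_of` for an (n, 2) array; returns (n, 2) int."""
        xy = np.asarray(xy, dtype=float)
        col = np.floor((xy[:, 0] - self.x_min) / self.cell_width).astype(int)
        row = np.floor((self.y_max - xy[:, 1]) / self.cell_height).astype(int)
        row[xy[:, 1] == self.y_max] = 0
        bad = (row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)
        if bad.any():
            raise ValueError(f"{int(bad.sum())} point(s) outside the grid extent")
        return np.column_stack([row, col])

    def same_geometry(self, other: "GridDefinition", rtol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x_min, other.x_min, rtol=rtol)
            and np.isclose(self.y_max, other.y_max, rtol=rtol)
            and np.isclose(self.cell_width, other.cell_width, rtol=rtol)
            and np.isclose(self.cell_height, other.cell_height, rtol=rtol)
        )


@dataclasses.dataclass
class RasterGrid:
    """A single georeferenced layer: values + grid definition.

    ``values`` is float64 with ``nan`` marking nodata, even for
    categorical layers.
    """

    values: np.ndarray
    grid: GridDefinition

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(values=np.asarray(values, dtype=float), grid=self.grid)

    def min(self) -> float:
        return float(np.nanmin(self.values))

    def max(self) -> float:
        return float(np.nanmax(self.values))

    def mean(self) -> float:
        return float(np.nanmean(self.values))

    def value_at(self, x: float, y: float) -> float:
        row, col = self.grid.cell_of(x, y)
        return float(self.values[row, col])


class PredictorStack:
    """Ordered collection of aligned layers keyed by name (Bio1, Bio7, ...)."""

    def __init__(self, layers: dict[str, RasterGrid] | None = None):
        self._layers: dict[str, RasterGrid] = {}
        if layers:
            for name, layer in layers.items():
                self.add(name, layer)

    def add(self, name: str, layer: RasterGrid) -> None:
        if name in self._layers:
            raise ValueError(f"duplicate layer name: {name!r}")
        if self._layers:
            first = next(iter(self._layers.values()))
            if not layer.grid.same_geometry(first.grid):
                raise GridAlignmentError(
                    f"layer {name!r} is not aligned with the stack grid"
                )
        self._layers[name] = layer

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def grid(self) -> GridDefinition:
        if not self._layers:
            raise ValueError("empty stack has no grid")
        return next(iter(self._layers.values())).grid

    def __len__(self) -> int:
        return len(self._layers)

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __getitem__(self, name: str) -> RasterGrid:
        try:
            return self._layers[name]
        except KeyError:
            raise MissingLayerError(name) from None

    def items(self):
        return self._layers.items()

    def require(self, names) -> None:
        missing = [n for n in names if n not in self._layers]
        if missing:
            raise MissingLayerError(", ".join(missing))

    def valid_mask(self) -> np.ndarray:
        """Cells valid (non-nodata) in every layer."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for layer in self._layers.values():
            mask &= layer.valid_mask
        return mask

    def to_table(self, mask: np.ndarray | None = None) -> dict[str, np.ndarray]:
        """Flattened per-layer values at cells selected by ``mask``."""
        if mask is None:
            mask = self.valid_mask()
        return {name: layer.values[mask] for name, layer in self._layers.items()}

    def map(self, fn) -> "PredictorStack":
        return PredictorStack(
            {name: layer.with_values(fn(layer.values)) for name, layer in self.items()}
        )

    def write_dir(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, layer in self._layers.items():
            write_raster(layer, path / f"{name}.asc")
        (path / "layers.json").write_text(
            json.dumps({"layers": self.names, "crs": self.grid.crs}, indent=2)
        )
        return path

    @classmethod
    def read_dir(cls, path: str | Path) -> "PredictorStack":
        path = Path(path)
        meta = json.loads((path / "layers.json").read_text())
        stack = cls()
        for name in meta["layers"]:
            stack.add(name, read_raster(path / f"{name}.asc"))
        return stack


def write_raster(raster: RasterGrid, path: str | Path) -> Path:
    """Write a layer as an ESRI ASCII grid with a ``.prj`` CRS sidecar."""
    path = Path(path)
    g = raster.grid
    lines = [f"ncols {g.n_cols}", f"nrows {g.n_rows}"]
    lines.append(f"xllcorner {g.x_min:.17g}")
    lines.append(f"yllcorner {g.y_min:.17g}")
    if np.isclose(g.cell_width, g.cell_height):
        lines.append(f"cellsize {g.cell_width:.17g}")
    else:  # GDAL AAIGrid extension for rectangular cells
        lines.append(f"dx {g.cell_width:.17g}")
        lines.append(f"dy {g.cell_height:.17g}")
    lines.append(f"NODATA_value {_NODATA_OUT:.17g}")
    out = np.where(np.isfinite(raster.values), raster.values, _NODATA_OUT)
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in out)
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    path.with_suffix(".prj").write_text(g.crs + "\n")
    return path


def read_raster(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_raster` (or GDAL)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"raster file not found: {path}")
    text = path.read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(text):
        parts = text[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner",
            "cellsize", "dx", "dy", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    values = np.loadtxt(text[i:], dtype=float, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        values = values.reshape(n_rows, n_cols)
    cw = header.get("dx", header.get("cellsize"))
    ch = header.get("dy", header.get("cellsize"))
    if cw is None or ch is None:
        raise IOError(f"missing cell size in header of {path}")
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    prj = path.with_suffix(".prj")
    crs = prj.read_text().strip() if prj.exists() else "EPSG:4326"
    grid = GridDefinition(
        n_rows=n_rows,
        n_cols=n_cols,
        x_min=header["xllcorner"],
        y_max=header["yllcorner"] + n_rows * ch,
        cell_width=cw,
        cell_height=ch,
        crs=crs,
    )
    return RasterGrid(values=values, grid=grid)


def resample_to_grid(
    raster: RasterGrid,
    target: GridDefinition,
    method: str = "bilinear",
    categorical: bool = False,
) -> RasterGrid:
    """Resample onto ``target`` by nearest-neighbour or bilinear interpolation.

    Bilinear treats any nodata among the four neighbours as nodata in the
    output. Categorical layers must use ``nearest`` (bilinear would invent
    class values).
    """
    if method not in {"bilinear", "nearest"}:
        raise ValueError(f"unknown resampling method: {method!r}")
    if categorical and method != "nearest":
        raise ValueError("categorical layers must be resampled with method='nearest'")
    src = raster.grid
    if target.x_min >= src.x_max or target.x_max <= src.x_min or \
            target.y_min >= src.y_max or target.y_max <= src.y_min:
        raise ValueError("target grid does not overlap the source raster")

    tx = target.x_centers()
    ty = target.y_centers()
    # fractional source pixel coordinates of target cell centers
    fx = (tx - src.x_min) / src.cell_width - 0.5
    fy = (src.y_max - ty) / src.cell_height - 0.5
    FX, FY = np.meshgrid(fx, fy)

    if method == "nearest":
        ci = np.clip(np.rint(FX).astype(int), 0, src.n_cols - 1)
        ri = np.clip(np.rint(FY).astype(int), 0, src.n_rows - 1)
        out = raster.values[ri, ci]
    else:
        x0 = np.clip(np.floor(FX).astype(int), 0, src.n_cols - 1)
        y0 = np.clip(np.floor(FY).astype(int), 0, src.n_rows - 1)
        x1 = np.clip(x0 + 1, 0, src.n_cols - 1)
        y1 = np.clip(y0 + 1, 0, src.n_rows - 1)
        wx = np.clip(FX - x0, 0.0, 1.0)
        wy = np.clip(FY - y0, 0.0, 1.0)
        v = raster.values
        out = (
            v[y0, x0] * (1 - wx) * (1 - wy)
            + v[y0, x1] * wx * (1 - wy)
            + v[y1, x0] * (1 - wx) * wy
            + v[y1, x1] * wx * wy
        )
    # target centers outside the source extent have no data
    outside = (
        (FX < -0.5) | (FX > src.n_cols - 0.5) | (FY < -0.5) | (FY > src.n_rows - 0.5)
    )
    out = np.where(outside, np.nan, out)
    return RasterGrid(values=out, grid=target)
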