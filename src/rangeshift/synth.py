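"""Virtual-species simulation: climate surfaces, niches, presences, futures.

A virtual species has a known parametric niche over simulated climate
layers, so every downstream stage of the assessment (model fitting,
thresholding, range metrics, risk categorisation) can be validated
against ground truth without any external data.

The simulated world:

* climate layers are spatially autocorrelated continuous surfaces
  (Gaussian-smoothed white noise, min-max rescaled to realistic ranges,
  e.g. a temperature annual range layer spanning 21.75-33.65 °C);
* the species' suitability is a product of per-driver response functions
  (Gaussian bell around an optimum, or logistic in a driver);
* presences are sampled from suitability without replacement at the
  cell level, matching the deduplication applied to real records;
* a warmer future is an additive/multiplicative per-layer delta, standing
  in for GCM projections;
* land cover is an iid categorical map with a controllable forest
  fraction.

Default grid: 100 x 100 cells, nominally 2 km squares expressed as
0.0166667-degree (60 arc-second) cells, matching the analysis resolution
used for AOO counting.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import EmptySupportError, MissingLayerError
from .grids import GridDefinition, PredictorStack, RasterGrid
from .occurrences import OccurrenceSet

__all__ = [
    "GaussianResponse",
    "LogisticResponse",
    "VirtualNicheConfig",
    "ClimateDelta",
    "LANDCOVER_CLASSES",
    "FOREST",
    "default_grid",
    "make_random_field",
    "make_predictor_stack",
    "true_suitability",
    "sample_presences",
    "apply_climate_delta",
    "make_landcover",
    "write_virtual_dataset",
]

# Land-cover class dialect used throughout the synthetic world.
FOREST, GRASSLAND, WATER, URBAN = 1, 2, 3, 4
LANDCOVER_CLASSES = {FOREST: "forest", GRASSLAND: "grassland", WATER: "water", URBAN: "urban"}

#: 60 arc-seconds, the nominal-2-km analysis resolution.
CELL_DEG = 1.0 / 60.0


def default_grid(n_rows: int = 100, n_cols: int = 100) -> GridDefinition:
    """The default synthetic analysis grid (100x100 cells of 60 arc-sec)."""
    return GridDefinition(
        n_rows=n_rows,
        n_cols=n_cols,
        x_min=100.0,
        y_max=30.0,
        cell_width=CELL_DEG,
        cell_height=CELL_DEG,
        crs="EPSG:4326",
    )


@dataclasses.dataclass(frozen=True)
class GaussianResponse:
    """Bell-shaped response: suitability peaks at ``optimum``, s.d. ``breadth``."""

    optimum: float
    breadth: float

    def __post_init__(self) -> None:
        if self.breadth <= 0:
            raise ValueError("breadth must be positive")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((x - self.optimum) / self.breadth) ** 2)


@dataclasses.dataclass(frozen=True)
class LogisticResponse:
    """Monotone response: 1 / (1 + exp(-slope * (x - inflection)))."""

    inflection: float
    slope: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.slope * (x - self.inflection)))


@dataclasses.dataclass(frozen=True)
class VirtualNicheConfig:
    """Known species-climate relationship: driver name -> response function.

    Per-driver responses are combined by product, so suitability is in
    [0, 1] and equals 1 only where every driver sits at its optimum.
    """

    drivers: dict[str, GaussianResponse | LogisticResponse]
    combine: str = "product"

    def __post_init__(self) -> None:
        if not self.drivers:
            raise ValueError("niche needs at least one driver")
        if self.combine != "product":
            raise ValueError(f"unsupported combine rule: {self.combine!r}")

    def to_json(self) -> dict:
        out = {}
        for name, resp in self.drivers.items():
            d = dataclasses.asdict(resp)
            d["kind"] = "gaussian" if isinstance(resp, GaussianResponse) else "logistic"
            out[name] = d
        return {"drivers": out, "combine": self.combine}


@dataclasses.dataclass(frozen=True)
class ClimateDelta:
    """Per-layer change: ``new = old * factor + offset`` (layer units)."""

    offsets: dict[str, float] = dataclasses.field(default_factory=dict)
    factors: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, f in self.factors.items():
            if f <= 0:
                raise ValueError(f"factor for {name!r} must be > 0")

    @property
    def layer_names(self) -> set[str]:
        return set(self.offsets) | set(self.factors)


def make_random_field(
    n_rows: int,
    n_cols: int,
    correlation_range: float,
    seed: int,
    vmin: float = 0.0,
    vmax: float = 1.0,
    grid: GridDefinition | None = None,
) -> RasterGrid:
    """Spatially autocorrelated surface: smoothed white noise, rescaled.

    ``correlation_range`` is the Gaussian smoothing kernel s.d. in cells;
    larger values yield smoother fields (higher lag-1 autocorrelation).
    Deterministic for a fixed seed.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("grid must be at least 8 x 8")
    if correlation_range <= 0:
        raise ValueError("correlation_range must be positive")
    if vmax <= vmin:
        raise ValueError("vmax must exceed vmin")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_rows, n_cols))
    field = ndimage.gaussian_filter(noise, sigma=correlation_range, mode="reflect")
    lo, hi = field.min(), field.max()
    if hi == lo:  # pathological: flat field; place at midpoint
        field = np.full_like(field, (vmin + vmax) / 2.0)
    else:
        field = vmin + (field - lo) * (vmax - vmin) / (hi - lo)
    if grid is None:
        grid = default_grid(n_rows, n_cols)
    return RasterGrid(values=field, grid=grid)


def make_predictor_stack(
    layer_specs: list[tuple[str, float, float, float]],
    grid: GridDefinition | None = None,
    seed: int = 0,
) -> PredictorStack:
    """Stack of independent random fields, one per (name, min, max, range) spec."""
    names = [s[0] for s in layer_specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate layer names in specs")
    if grid is None:
        grid = default_grid()
    child_seeds = np.random.SeedSequence(seed).spawn(len(layer_specs))
    stack = PredictorStack()
    for (name, vmin, vmax, corr_range), ss in zip(layer_specs, child_seeds):
        stack.add(
            name,
            make_random_field(
                grid.n_rows, grid.n_cols, corr_range,
                seed=ss.generate_state(1)[0], vmin=vmin, vmax=vmax, grid=grid,
            ),
        )
    return stack


def true_suitability(stack: PredictorStack, niche: VirtualNicheConfig) -> RasterGrid:
    """Ground-truth suitability in [0, 1] from the known niche."""
    stack.require(niche.drivers)
    suit = np.ones(stack.grid.shape)
    for name, response in niche.drivers.items():
        suit = suit * response(stack[name].values)
    # nodata in any driver propagates
    for name in niche.drivers:
        suit = np.where(stack[name].valid_mask, suit, np.nan)
    return RasterGrid(values=suit, grid=stack.grid)


def sample_presences(
    suitability: RasterGrid,
    n_target: int,
    seed: int,
    contamination: float = 0.0,
) -> OccurrenceSet:
    """Sample presence cells with probability proportional to suitability.

    Sampling is without replacement at the cell level (one record per
    cell, like deduplicated herbarium records); returned points are cell
    centers. ``contamination`` optionally replaces that fraction of
    records with uniform random cells, emulating georeferencing error;
    the default claims no error model.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    if not 0.0 <= contamination <= 1.0:
        raise ValueError("contamination must be in [0, 1]")
    vals = suitability.values
    flat = np.where(np.isfinite(vals), vals, 0.0).ravel()
    if flat.min() < -1e-12 or flat.max() > 1 + 1e-12:
        raise ValueError("suitability values must lie in [0, 1]")
    support = np.flatnonzero(flat > 0)
    if support.size == 0:
        raise EmptySupportError("suitability is zero everywhere")
    n = min(n_target, support.size)
    rng = np.random.default_rng(seed)
    p = flat[support] / flat[support].sum()
    chosen = rng.choice(support, size=n, replace=False, p=p)
    if contamination > 0:
        n_bad = int(round(contamination * n))
        if n_bad:
            valid = np.flatnonzero(np.isfinite(vals).ravel())
            chosen[:n_bad] = rng.choice(valid, size=n_bad, replace=False)
            chosen = np.unique(chosen)
    grid = suitability.grid
    rows, cols = np.unravel_index(chosen, grid.shape)
    xs = grid.x_min + (cols + 0.5) * grid.cell_width
    ys = grid.y_max - (rows + 0.5) * grid.cell_height
    return OccurrenceSet("virtual", np.column_stack([xs, ys]))


def apply_climate_delta(current: PredictorStack, delta: ClimateDelta) -> PredictorStack:
    """Future stack: per-layer ``value * factor + offset``; grid unchanged."""
    unknown = delta.layer_names - set(current.names)
    if unknown:
        raise MissingLayerError(", ".join(sorted(unknown)))
    out = PredictorStack()
    for name, layer in current.items():
        factor = delta.factors.get(name, 1.0)
        offset = delta.offsets.get(name, 0.0)
        out.add(name, layer.with_values(layer.values * factor + offset))
    return out


def make_landcover(
    grid: GridDefinition,
    forest_fraction: float,
    seed: int,
) -> RasterGrid:
    """Categorical land-cover map; non-forest cells split among the other classes."""
    if not 0.0 < forest_fraction <= 1.0:
        raise ValueError("forest_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.random(grid.shape)
    classes = np.full(grid.shape, float(FOREST))
    nonforest = u >= forest_fraction
    others = np.array([GRASSLAND, WATER, URBAN], dtype=float)
    classes[nonforest] = rng.choice(others, size=int(nonforest.sum()))
    return RasterGrid(values=classes, grid=grid)


def calibrate_offset_for_area_loss(
    stack: PredictorStack,
    niche: VirtualNicheConfig,
    layer: str,
    target_loss_fraction: float,
    region_mask: np.ndarray | None = None,
    suitable_threshold: float = 0.5,
    max_offset: float | None = None,
) -> float:
    """Additive offset on ``layer`` that shrinks the true suitable area by a
    known fraction — the ground truth for contraction-recovery checks.

    The suitable area is the count of cells with true suitability >=
    ``suitable_threshold`` inside ``region_mask`` (e.g. the buffered EOO).
    Solved by bisection on the offset; raises if no bracketing offset up
    to ``max_offset`` (default: twice the layer's value range) achieves
    the target.
    """
    if not 0.0 < target_loss_fraction <= 1.0:
        raise ValueError("target_loss_fraction must be in (0, 1]")
    if layer not in stack:
        raise MissingLayerError(layer)
    if region_mask is None:
        region_mask = np.ones(stack.grid.shape, dtype=bool)

    def area(offset: float) -> int:
        shifted = apply_climate_delta(stack, ClimateDelta(offsets={layer: offset}))
        suit = true_suitability(shifted, niche).values
        return int(np.nansum((suit >= suitable_threshold) & region_mask))

    current = area(0.0)
    if current == 0:
        raise EmptySupportError("no suitable cells in the region at offset 0")
    target = (1.0 - target_loss_fraction) * current
    if max_offset is None:
        vals = stack[layer].values
        max_offset = 2.0 * float(np.nanmax(vals) - np.nanmin(vals))
    lo, hi = 0.0, max_offset
    if area(hi) > target:
        raise ValueError(
            f"offset {hi} does not reach the target loss; increase max_offset"
        )
    # bisection on a step function: find smallest offset with area <= target
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if area(mid) > target:
            lo = mid
        else:
            hi = mid
    return hi


#: Default simulation world. Layer ranges follow observed bioclim ranges for
#: high-montane conifer habitat (temperature annual range 21.75-33.65 deg C,
#: isothermality ~34-46, annual / wettest-quarter precipitation in mm); the
#: virtual species has a Gaussian niche on the temperature annual range
#: (optimum 23.5 deg C, breadth 0.6 deg C, confining it to roughly a tenth
#: of the region, as befits a narrow-range endemic) and 41 presence records — a
#: study-scale sample size for a narrow-range montane endemic. Futures are
#: additive warming deltas on the niche driver (moderate +3, high +5 deg C).
DEFAULT_SIM_CONFIG: dict = {
    "species": "virtual",
    "grid": {"n_rows": 100, "n_cols": 100},
    "layers": [
        {"name": "Bio7", "min": 21.75, "max": 33.65, "correlation_range": 8.0},
        {"name": "Bio3", "min": 34.44, "max": 45.62, "correlation_range": 8.0},
        {"name": "Bio12", "min": 573.5, "max": 987.0, "correlation_range": 8.0},
        {"name": "Bio16", "min": 295.0, "max": 419.2, "correlation_range": 8.0},
    ],
    "niche": {"Bio7": {"kind": "gaussian", "optimum": 23.5, "breadth": 0.6}},
    "n_presences": 41,
    "contamination": 0.0,
    "forest_fraction": 0.7,
    "deltas": {
        "rcp45": {"offsets": {"Bio7": 3.0}},
        "rcp85": {"offsets": {"Bio7": 5.0}},
    },
}


def niche_from_dict(spec: dict) -> VirtualNicheConfig:
    """Build a niche from config entries ``{layer: {kind, ...params}}``."""
    drivers: dict[str, GaussianResponse | LogisticResponse] = {}
    for name, d in spec.items():
        kind = d.get("kind", "gaussian")
        if kind == "gaussian":
            drivers[name] = GaussianResponse(optimum=d["optimum"], breadth=d["breadth"])
        elif kind == "logistic":
            drivers[name] = LogisticResponse(inflection=d["inflection"], slope=d["slope"])
        else:
            raise ValueError(f"unknown response kind {kind!r} for driver {name!r}")
    return VirtualNicheConfig(drivers=drivers)


def simulate_dataset(config: dict | None = None, out_dir: str | Path | None = None,
                     seed: int = 0):
    """Generate a full virtual-species dataset from a simulation config.

    Returns ``(stack, future_stacks, suitability, occurrences, landcover,
    niche)``; if ``out_dir`` is given the dataset is also written to disk
    in the pipeline's input layout.
    """
    cfg = dict(DEFAULT_SIM_CONFIG)
    cfg.update(config or {})
    grid = default_grid(cfg["grid"]["n_rows"], cfg["grid"]["n_cols"])
    specs = [
        (l["name"], l["min"], l["max"], l["correlation_range"]) for l in cfg["layers"]
    ]
    ss = np.random.SeedSequence(seed).spawn(3)
    stack = make_predictor_stack(specs, grid=grid, seed=int(ss[0].generate_state(1)[0]) % 2**31)
    niche = niche_from_dict(cfg["niche"])
    suitability = true_suitability(stack, niche)
    occurrences = sample_presences(
        suitability,
        n_target=cfg["n_presences"],
        seed=int(ss[1].generate_state(1)[0]) % 2**31,
        contamination=cfg.get("contamination", 0.0),
    )
    occurrences = OccurrenceSet(cfg.get("species", "virtual"), occurrences.points)
    landcover = make_landcover(
        grid, cfg["forest_fraction"], seed=int(ss[2].generate_state(1)[0]) % 2**31
    )
    future_stacks = {
        name: apply_climate_delta(
            stack,
            ClimateDelta(offsets=d.get("offsets", {}), factors=d.get("factors", {})),
        )
        for name, d in cfg.get("deltas", {}).items()
    }
    if out_dir is not None:
        write_virtual_dataset(
            out_dir, stack, suitability, occurrences, landcover, niche, seed,
            future_stacks=future_stacks,
        )
    return stack, future_stacks, suitability, occurrences, landcover, niche


def write_virtual_dataset(
    out_dir: str | Path,
    stack: PredictorStack,
    suitability: RasterGrid,
    occurrences: OccurrenceSet,
    landcover: RasterGrid,
    niche: VirtualNicheConfig,
    seed: int,
    future_stacks: dict[str, PredictorStack] | None = None,
) -> Path:
    """Write a complete simulated dataset plus a ground-truth JSON sidecar."""
    from .grids import write_raster
    from .occurrences import write_occurrences

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack.write_dir(out_dir / "current")
    for name, fstack in (future_stacks or {}).items():
        fstack.write_dir(out_dir / f"future_{name}")
    write_raster(suitability, out_dir / "true_suitability.asc")
    write_raster(landcover, out_dir / "landcover.asc")
    write_occurrences(occurrences, out_dir / "occurrences.csv")
    (out_dir / "truth.json").write_text(
        json.dumps({"niche": niche.to_json(), "seed": seed,
                    "species": occurrences.species}, indent=2)
    )
    return out_dir
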