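"""End-to-end assessment pipeline: config, orchestration, artifact manifest.

Stages (per species, per climate scenario):

1. clean occurrences (dedupe per cell, extent + land-cover filters);
2. sample pseudo-absences and build the training table;
3. collinearity filtering (|r| <= 0.75, VIF <= 5);
4. 70/30 split, fit GLM/GAM/RF/BRT, TSS-weighted ensemble;
5. thresholds from the training split (MTP, MTSS) plus the fixed 0.5 rule;
6. alpha-hull EOO with 0.1-degree buffer; binarize, mask by land cover
   and EOO, change maps under full/no dispersal, AOO counts;
7. AOO change percentage -> risk category -> listing change vs the
   current Red List status.

Stages communicate via declared file artifacts under one run directory,
and a manifest (config hash, seeds, outputs, warnings) is written at its
root even on partial failure. The master seed deterministically spawns a
seed per (stage, species) so adding a stage does not reshuffle others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth
from .collinearity import select_predictors, variable_importance
from .ensemble import (
    ModelSpec,
    average_stacks,
    build_ensemble,
    evaluate_ensemble,
    evaluate_member,
    fit_member,
    marginal_response,
    predict_surface,
    sample_pseudo_absences,
    split_train_test,
)
from .grids import PredictorStack, read_raster, write_raster
from .metrics import binarize, find_mtp, find_mtss
from .occurrences import build_sample_table, clean_occurrences, read_occurrences
from .ranges import (
    alpha_hull,
    aoo_change_percent,
    apply_dispersal,
    buffer_eoo,
    compute_aoo,
    default_alpha,
    make_change_map,
    mask_by_landcover,
    mask_by_polygon,
)
from .risk import RiskCategory, ScenarioOutcome, assess

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)

THRESHOLD_RULES = ("mtp", "mtss", "fixed_05")
DISPERSAL_SCENARIOS = ("full", "none")

# Paper-constant defaults; every application is logged by validate_config.
DEFAULTS = {
    "vif_max": 5.0,
    "r_max": 0.75,
    "pa_ratio": 10,
    "train_fraction": 0.7,
    "buffer_deg": 0.1,
    "cell_area_km2": 4.0,
}


@dataclasses.dataclass
class PipelineConfig:
    occurrences: str
    current_stack: str
    future_stacks: dict[str, list[str]]
    landcover: str | None = None
    output_dir: str = "run"
    vif_max: float = DEFAULTS["vif_max"]
    r_max: float = DEFAULTS["r_max"]
    pa_ratio: int = DEFAULTS["pa_ratio"]
    train_fraction: float = DEFAULTS["train_fraction"]
    exclusion_buffer_cells: int = 0
    models: list[dict] = dataclasses.field(
        default_factory=lambda: [{"family": f} for f in ("GLM", "GAM", "RF", "BRT")]
    )
    replicates: int = 1
    threshold_rules: list[str] = dataclasses.field(
        default_factory=lambda: list(THRESHOLD_RULES)
    )
    dispersal_scenarios: list[str] = dataclasses.field(
        default_factory=lambda: list(DISPERSAL_SCENARIOS)
    )
    alpha: float | None = None  # None -> 2 x median NN distance, logged per species
    buffer_deg: float = DEFAULTS["buffer_deg"]
    cell_area_km2: float = DEFAULTS["cell_area_km2"]
    allowed_landcover: list[int] = dataclasses.field(
        default_factory=lambda: [synth.FOREST, synth.GRASSLAND]
    )
    excluded_landcover: list[int] = dataclasses.field(
        default_factory=lambda: [synth.WATER, synth.URBAN]
    )
    species_status: dict[str, str] = dataclasses.field(default_factory=dict)
    population_trend: dict[str, str] = dataclasses.field(default_factory=dict)
    n_permutations: int = 10
    response_grid_points: int = 50
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if self.vif_max <= 0 or self.r_max <= 0:
            raise ValueError("selection thresholds (vif_max, r_max) must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.pa_ratio < 1:
            raise ValueError("pa_ratio must be >= 1")
        if self.buffer_deg < 0:
            raise ValueError("buffer_deg must be non-negative")
        unknown = set(self.threshold_rules) - set(THRESHOLD_RULES)
        if unknown:
            raise ValueError(f"unknown threshold rule(s): {sorted(unknown)}")
        unknown = set(self.dispersal_scenarios) - set(DISPERSAL_SCENARIOS)
        if unknown:
            raise ValueError(f"unknown dispersal scenario(s): {sorted(unknown)}")
        for m in self.models:
            ModelSpec(family=m["family"], hyperparameters=m.get("hyperparameters", {}))
        return self


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    stage_seeds: dict[str, int] = dataclasses.field(default_factory=dict)
    outputs: list[str] = dataclasses.field(default_factory=list)
    warnings: list[str] = dataclasses.field(default_factory=list)
    completed_species: list[str] = dataclasses.field(default_factory=list)
    failed_species: dict[str, str] = dataclasses.field(default_factory=dict)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def validate_config(path_or_dict) -> PipelineConfig:
    """Parse a YAML config, apply paper-constant defaults, and validate."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict or {})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    for key, default in DEFAULTS.items():
        if key not in raw:
            logger.info("config: %s omitted; using default %r", key, default)
    try:
        config = PipelineConfig(**raw)
    except TypeError as exc:
        raise ValueError(f"config schema violation: {exc}") from exc
    return config.validate()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _load_stacks(config: PipelineConfig) -> tuple[PredictorStack, dict[str, PredictorStack]]:
    current = PredictorStack.read_dir(config.current_stack)
    futures = {}
    for scenario, dirs in config.future_stacks.items():
        if isinstance(dirs, str):
            dirs = [dirs]
        stacks = [PredictorStack.read_dir(d) for d in dirs]
        futures[scenario] = stacks[0] if len(stacks) == 1 else average_stacks(stacks)
    return current, futures


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage for every species x scenario x rule x dispersal."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=_config_hash(config), master_seed=config.seed)
    manifest_path = out_dir / "manifest.json"

    def _record(path: Path) -> Path:
        manifest.outputs.append(str(path))
        return path

    try:
        current_stack, future_stacks = _load_stacks(config)
        landcover = read_raster(config.landcover) if config.landcover else None
        occurrences = read_occurrences(config.occurrences)
    except Exception:
        manifest.write(manifest_path)
        raise

    assessment_rows: list[dict] = []
    metric_rows: list[dict] = []
    aoo_rows: list[dict] = []

    for species, occ in occurrences.items():
        try:
            rows = _run_species(
                species, occ, current_stack, future_stacks, landcover,
                config, out_dir, manifest, _record,
            )
            assessment_rows.extend(rows["assessment"])
            metric_rows.extend(rows["metrics"])
            aoo_rows.extend(rows["aoo"])
            manifest.completed_species.append(species)
        except Exception as exc:  # per-species isolation
            logger.exception("species %s failed", species)
            manifest.failed_species[species] = f"{type(exc).__name__}: {exc}"
            manifest.warnings.append(f"{species}: {type(exc).__name__}: {exc}")

    if metric_rows:
        pd.DataFrame(metric_rows).to_csv(_record(out_dir / "model_metrics.csv"), index=False)
    if aoo_rows:
        pd.DataFrame(aoo_rows).to_csv(_record(out_dir / "aoo.csv"), index=False)
    if assessment_rows:
        pd.DataFrame(assessment_rows).to_csv(
            _record(out_dir / "assessment.csv"), index=False
        )
    manifest.write(manifest_path)
    if manifest.failed_species and not manifest.completed_species:
        raise RuntimeError(f"all species failed: {manifest.failed_species}")
    return manifest


def _run_species(
    species, occ, current_stack, future_stacks, landcover, config, out_dir,
    manifest, record,
) -> dict[str, list[dict]]:
    sdir = out_dir / species.replace(" ", "_")
    sdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        stage: stage_seed(config.seed, f"{stage}:{species}")
        for stage in ("background", "split", "models", "importance")
    }
    manifest.stage_seeds.update({f"{species}:{k}": v for k, v in seeds.items()})

    # -- clean occurrences ------------------------------------------------
    cleaned = clean_occurrences(
        occ,
        landcover=landcover,
        excluded_classes=set(config.excluded_landcover),
        grid=current_stack.grid,
    )
    if len(cleaned) < 3:
        raise ValueError(f"too few occurrence records after cleaning ({len(cleaned)})")

    # -- training table ----------------------------------------------------
    background = sample_pseudo_absences(
        current_stack, cleaned, ratio=config.pa_ratio,
        seed=seeds["background"],
        exclusion_buffer_cells=config.exclusion_buffer_cells,
    )
    table = build_sample_table(current_stack, cleaned.points, background)

    # -- collinearity filtering ---------------------------------------------
    report = select_predictors(
        table, vif_max=config.vif_max, r_max=config.r_max
    )
    report.to_frame().to_csv(record(sdir / "collinearity.csv"), index=False)
    variables = report.retained

    # -- fit members + ensemble ---------------------------------------------
    train, test = split_train_test(
        table, train_fraction=config.train_fraction, seed=seeds["split"]
    )
    members = []
    for rep in range(config.replicates):
        for i, m in enumerate(config.models):
            spec = ModelSpec(
                family=m["family"],
                hyperparameters=m.get("hyperparameters", {}),
                replicate_id=rep,
                seed=stage_seed(seeds["models"], f"{m['family']}:{rep}"),
            )
            member = fit_member(spec, train, variables=variables)
            members.append(evaluate_member(member, test))
    model = evaluate_ensemble(build_ensemble(members), test)

    train_scores = model.predict_table(train)
    train_labels = train["label"].to_numpy(dtype=int)
    t_mtss, _ = find_mtss(train_scores, train_labels)
    t_mtp = find_mtp(train_scores[train_labels == 1])
    thresholds = {"mtp": t_mtp, "mtss": t_mtss, "fixed_05": 0.5}

    metric_rows = []
    for member, w in zip(model.members, model.weights):
        ev = member.evaluation
        metric_rows.append({
            "species": species, "model": member.spec.family, "weight": float(w),
            "AUC": ev.auc, "TSS": ev.tss, "MTSS": ev.threshold_mtss,
            "MTP": ev.threshold_mtp,
        })
    metric_rows.append({
        "species": species, "model": "ensemble", "weight": 1.0,
        "AUC": model.evaluation.auc, "TSS": model.evaluation.tss,
        "MTSS": t_mtss, "MTP": t_mtp,
    })

    # -- variable importance + response curves -------------------------------
    importance = variable_importance(
        model, table, n_permutations=config.n_permutations, seed=seeds["importance"]
    )
    pd.DataFrame(
        [{"variable": k, "importance_pct": v} for k, v in importance.items()]
    ).to_csv(record(sdir / "importance.csv"), index=False)
    curves = []
    for name in variables:
        for value, prob in marginal_response(
            model, name, config.response_grid_points, train
        ):
            curves.append({"variable": name, "value": value, "probability": prob})
    pd.DataFrame(curves).to_csv(record(sdir / "response_curves.csv"), index=False)

    # -- suitability surfaces -------------------------------------------------
    current_surface = predict_surface(model, current_stack)
    record(write_raster(current_surface, sdir / "suitability_current.asc"))
    future_surfaces = {}
    for scenario, stack in future_stacks.items():
        surf = predict_surface(model, stack)
        future_surfaces[scenario] = surf
        record(write_raster(surf, sdir / f"suitability_{scenario}.asc"))

    # -- EOO ---------------------------------------------------------------
    alpha = config.alpha if config.alpha is not None else default_alpha(cleaned.points)
    logger.info("species %s: alpha-hull alpha = %.4f deg", species, alpha)
    hull = alpha_hull(cleaned.points, alpha)
    eoo = buffer_eoo(hull, buffer_deg=config.buffer_deg, alpha=alpha)
    record(eoo.write_geojson(sdir / "eoo.geojson"))

    # -- range metrics + risk -------------------------------------------------
    def _mask(binary):
        if landcover is not None:
            binary = mask_by_landcover(binary, landcover, config.allowed_landcover)
        return mask_by_polygon(binary, eoo)

    aoo_rows, outcomes = [], []
    for rule in config.threshold_rules:
        t = thresholds[rule]
        cur_bin = _mask(binarize(current_surface, t))
        aoo_cur = compute_aoo(cur_bin, config.cell_area_km2, rule, "current")
        aoo_rows.append({
            "species": species, "scenario": "current", "threshold_rule": rule,
            "dispersal": "", "threshold": t, "cells": aoo_cur.cell_count,
            "area_km2": aoo_cur.area_km2, "change_pct": 0.0,
        })
        if aoo_cur.cell_count == 0:
            manifest.warnings.append(
                f"{species}: zero current AOO under rule {rule}; scenarios skipped"
            )
            continue
        for scenario, surf in future_surfaces.items():
            fut_bin = _mask(binarize(surf, t))
            change = make_change_map(cur_bin, fut_bin)
            for dispersal in config.dispersal_scenarios:
                adjusted = apply_dispersal(change, dispersal)
                record(write_raster(
                    adjusted.raster,
                    sdir / f"change_{scenario}_{rule}_{dispersal}.asc",
                ))
                aoo_fut = compute_aoo(
                    adjusted.future_binary(), config.cell_area_km2, rule, scenario
                )
                change_pct = aoo_change_percent(aoo_cur, aoo_fut)
                aoo_rows.append({
                    "species": species, "scenario": scenario, "threshold_rule": rule,
                    "dispersal": dispersal, "threshold": t,
                    "cells": aoo_fut.cell_count, "area_km2": aoo_fut.area_km2,
                    "change_pct": change_pct,
                })
                outcomes.append(ScenarioOutcome(
                    climate_scenario=scenario, threshold_rule=rule,
                    dispersal=dispersal, aoo_change_pct=change_pct,
                ))

    status = config.species_status.get(species)
    result = assess(
        species,
        RiskCategory[status] if status else None,
        outcomes,
        n_records=len(cleaned),
        population_trend=config.population_trend.get(species, ""),
    )
    (sdir / "summary.txt").write_text(result.summary() + "\n")
    record(sdir / "summary.txt")
    return {"assessment": result.outcomes, "metrics": metric_rows, "aoo": aoo_rows}
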