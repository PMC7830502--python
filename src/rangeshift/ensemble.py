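"""Four-learner ensemble habitat-suitability modelling, TSS-weighted.

Pipeline: sample pseudo-absences (10x presences, random background),
split 70/30 stratified, fit GLM / GAM / RF / BRT members returning
presence probabilities, evaluate each on the held-out split, and combine
them into an ensemble whose per-cell prediction is the TSS-weighted mean
of member probabilities (members with non-positive held-out TSS get zero
weight).

Member families (scikit-learn under the hood):

* GLM — logistic regression on linear + quadratic terms of each predictor;
* GAM — logistic model on a per-predictor cubic B-spline basis
  (~8 basis functions per variable);
* RF  — random forest, 500 trees;
* BRT — stochastic gradient-boosted trees, logistic loss,
  1000 trees, learning rate 0.01, depth 3.

All members are seeded and deterministic for a fixed spec + seed.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import FunctionTransformer, SplineTransformer, StandardScaler

from .exceptions import GridAlignmentError, MissingLayerError
from .grids import PredictorStack, RasterGrid
from .metrics import EvaluationResult, auc, confusion_at, find_mtp, find_mtss
from .occurrences import OccurrenceSet

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "FittedModel",
    "EnsembleModel",
    "sample_pseudo_absences",
    "split_train_test",
    "fit_member",
    "evaluate_member",
    "evaluate_ensemble",
    "build_ensemble",
    "predict_surface",
    "marginal_response",
    "average_stacks",
]

logger = logging.getLogger(__name__)

FAMILIES = ("GLM", "GAM", "RF", "BRT")


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: dict = dataclasses.field(default_factory=dict)
    replicate_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family: {self.family!r}")


@dataclasses.dataclass
class FittedModel:
    spec: ModelSpec
    variables: list[str]
    pipeline: Pipeline | None
    evaluation: EvaluationResult | None = None
    failed: bool = False

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Presence probability in [0, 1] for each row."""
        if self.failed or self.pipeline is None:
            raise RuntimeError(f"member {self.spec.family} failed to fit")
        X = table[self.variables].to_numpy(dtype=float)
        proba = self.pipeline.predict_proba(X)
        classes = list(self.pipeline.classes_)
        return np.clip(proba[:, classes.index(1)], 0.0, 1.0)


@dataclasses.dataclass
class EnsembleModel:
    members: list[FittedModel]
    weights: np.ndarray
    retained_variables: list[str]
    evaluation: EvaluationResult | None = None

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        preds = np.stack([m.predict(table) for m in self.members])
        return np.asarray(self.weights) @ preds


def _quadratic_expand(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, X**2])


def _make_pipeline(spec: ModelSpec, fallback: bool = False) -> Pipeline:
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.family == "GLM":
        C = hp.get("C", 1.0 if fallback else 1e4)
        return Pipeline([
            ("quad", FunctionTransformer(_quadratic_expand)),
            ("scale", StandardScaler()),
            ("logit", LogisticRegression(C=C, max_iter=int(hp.get("max_iter", 2000)))),
        ])
    if spec.family == "GAM":
        n_knots = int(hp.get("n_knots", 6))  # ~8 cubic B-spline basis fns/variable
        C = hp.get("C", 0.5 if fallback else 1.0)
        return Pipeline([
            ("scale", StandardScaler()),
            ("spline", SplineTransformer(n_knots=n_knots, degree=3)),
            ("logit", LogisticRegression(C=C, max_iter=int(hp.get("max_iter", 2000)))),
        ])
    if spec.family == "RF":
        return Pipeline([
            ("rf", RandomForestClassifier(
                n_estimators=int(hp.get("n_trees", 500)),
                min_samples_leaf=int(hp.get("min_samples_leaf", 1)),
                random_state=seed,
                n_jobs=1,
            )),
        ])
    # BRT
    return Pipeline([
        ("brt", GradientBoostingClassifier(
            n_estimators=int(hp.get("n_trees", 1000)),
            learning_rate=float(hp.get("learning_rate", 0.01)),
            max_depth=int(hp.get("max_depth", 3)),
            subsample=float(hp.get("subsample", 0.75)),
            random_state=seed,
        )),
    ])


def sample_pseudo_absences(
    stack: PredictorStack,
    presences: OccurrenceSet | np.ndarray,
    ratio: int = 10,
    seed: int = 0,
    exclusion_buffer_cells: int = 0,
) -> np.ndarray:
    """Random background points: ``ratio`` x n_presences cell centers.

    Eligible cells are non-nodata cells not occupied by a presence (and
    outside an optional buffer of ``exclusion_buffer_cells`` around
    presence cells). If fewer eligible cells exist than requested, all of
    them are returned with a warning.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    points = presences.points if isinstance(presences, OccurrenceSet) else np.asarray(presences)
    grid = stack.grid
    eligible = stack.valid_mask()
    occupied = np.zeros(grid.shape, dtype=bool)
    cells = grid.cells_of(points)
    occupied[cells[:, 0], cells[:, 1]] = True
    if exclusion_buffer_cells > 0:
        from scipy import ndimage

        occupied = ndimage.binary_dilation(occupied, iterations=exclusion_buffer_cells)
    eligible &= ~occupied
    idx = np.flatnonzero(eligible.ravel())
    n_request = ratio * len(points)
    if idx.size < n_request:
        warnings.warn(
            f"only {idx.size} eligible background cells for {n_request} requested",
            stacklevel=2,
        )
        chosen = idx
    else:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(idx, size=n_request, replace=False)
    rows, cols = np.unravel_index(chosen, grid.shape)
    xs = grid.x_min + (cols + 0.5) * grid.cell_width
    ys = grid.y_max - (rows + 0.5) * grid.cell_height
    return np.column_stack([xs, ys])


def split_train_test(
    table: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split, stratified on the label."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = table["label"].to_numpy()
    for cls in (0, 1):
        if np.sum(labels == cls) < 2:
            raise ValueError(f"class {cls} has fewer than 2 rows")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    if stratified:
        groups = [np.flatnonzero(labels == cls) for cls in (0, 1)]
    else:
        groups = [np.arange(len(table))]
    for idx in groups:
        perm = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both sides non-empty
        train_idx.append(perm[:n_train])
    train_mask = np.zeros(len(table), dtype=bool)
    train_mask[np.concatenate(train_idx)] = True
    return (
        table.iloc[train_mask].reset_index(drop=True),
        table.iloc[~train_mask].reset_index(drop=True),
    )


def fit_member(
    spec: ModelSpec,
    train: pd.DataFrame,
    variables: list[str] | None = None,
) -> FittedModel:
    """Fit one member family on the training table.

    Non-convergence triggers one retry with fallback (stronger shrinkage)
    hyperparameters; a second failure flags the member failed so
    :func:`build_ensemble` can exclude it.
    """
    if variables is None:
        variables = [c for c in train.columns if c not in ("lon", "lat", "label")]
    y = train["label"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = train[variables].to_numpy(dtype=float)
    for attempt, fallback in enumerate((False, True)):
        pipeline = _make_pipeline(spec, fallback=fallback)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pipeline.fit(X, y)
            return FittedModel(spec=spec, variables=list(variables), pipeline=pipeline)
        except Exception as exc:  # noqa: BLE001 - fallback contract
            logger.warning("member %s fit attempt %d failed: %s", spec.family, attempt, exc)
    warnings.warn(f"member {spec.family} failed to fit; excluded", stacklevel=2)
    return FittedModel(spec=spec, variables=list(variables), pipeline=None, failed=True)


def _evaluate_scores(scores: np.ndarray, labels: np.ndarray) -> EvaluationResult:
    t_mtss, tss_val = find_mtss(scores, labels)
    counts = confusion_at(scores, labels, t_mtss)
    return EvaluationResult(
        auc=auc(scores, labels),
        tss=tss_val,
        sensitivity=counts.sensitivity,
        specificity=counts.specificity,
        threshold_mtss=t_mtss,
        threshold_mtp=find_mtp(scores[labels == 1]),
    )


def evaluate_member(member: FittedModel, test: pd.DataFrame) -> FittedModel:
    """Attach held-out AUC/TSS/threshold metrics to a fitted member."""
    if member.failed:
        return member
    scores = member.predict(test)
    labels = test["label"].to_numpy(dtype=int)
    member.evaluation = _evaluate_scores(scores, labels)
    return member


def build_ensemble(members: list[FittedModel]) -> EnsembleModel:
    """TSS-weighted ensemble: weight_i = max(TSS_i, 0) / sum max(TSS_j, 0).

    If every member has non-positive TSS the weights fall back to equal,
    with a warning. Failed members are excluded.
    """
    live = [m for m in members if not m.failed]
    if not live:
        raise ValueError("no successfully fitted members")
    for m in live:
        if m.evaluation is None:
            raise ValueError(f"member {m.spec.family} has no evaluation; "
                             "call evaluate_member first")
    raw = np.array([max(m.evaluation.tss, 0.0) for m in live])
    if raw.sum() == 0:
        warnings.warn("all member TSS <= 0; using equal weights", stacklevel=2)
        weights = np.full(len(live), 1.0 / len(live))
    else:
        weights = raw / raw.sum()
    return EnsembleModel(
        members=live, weights=weights, retained_variables=list(live[0].variables)
    )


def evaluate_ensemble(model: EnsembleModel, test: pd.DataFrame) -> EnsembleModel:
    """Attach the held-out evaluation of the weighted ensemble predictions."""
    scores = model.predict_table(test)
    labels = test["label"].to_numpy(dtype=int)
    model.evaluation = _evaluate_scores(scores, labels)
    return model


def predict_surface(model: EnsembleModel, stack: PredictorStack) -> RasterGrid:
    """Project the ensemble across the grid: weighted mean member probability.

    Nodata in any retained layer propagates to the output.
    """
    missing = [v for v in model.retained_variables if v not in stack]
    if missing:
        raise MissingLayerError(", ".join(missing))
    grid = stack.grid
    mask = np.ones(grid.shape, dtype=bool)
    for name in model.retained_variables:
        mask &= stack[name].valid_mask
    table = pd.DataFrame(
        {name: stack[name].values[mask] for name in model.retained_variables}
    )
    out = np.full(grid.shape, np.nan)
    if len(table):
        out[mask] = model.predict_table(table)
    return RasterGrid(values=out, grid=grid)


def marginal_response(
    model: EnsembleModel,
    variable: str,
    grid_points: int,
    table: pd.DataFrame,
) -> list[tuple[float, float]]:
    """Response curve: ensemble probability over the variable's observed
    range with all other predictors fixed at their training-set mean."""
    if variable not in model.retained_variables:
        raise ValueError(f"variable {variable!r} not retained by the model")
    values = np.linspace(
        table[variable].min(), table[variable].max(), grid_points
    )
    probe = pd.DataFrame(
        {name: np.full(grid_points, table[name].mean())
         for name in model.retained_variables}
    )
    probe[variable] = values
    probs = model.predict_table(probe)
    return list(zip(values.tolist(), probs.tolist()))


def average_stacks(stacks: list[PredictorStack]) -> PredictorStack:
    """Per-cell, per-layer arithmetic mean (e.g. the multi-GCM ensemble mean)."""
    if not stacks:
        raise ValueError("no stacks to average")
    first = stacks[0]
    for s in stacks[1:]:
        if s.names != first.names:
            raise ValueError("stacks have different layer names")
        if not s.grid.same_geometry(first.grid):
            raise GridAlignmentError("stacks are on different grids")
    out = PredictorStack()
    for name in first.names:
        mean = np.mean([s[name].values for s in stacks], axis=0)
        out.add(name, first[name].with_values(mean))
    return out
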