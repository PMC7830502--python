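"""Multicollinearity filtering: VIF and pairwise-correlation rules.

Highly correlated bioclim predictors inflate model variance and harm
transferability to future climates. The standard remedy is iterative:
first resolve the most correlated pair (drop the member with the larger
variance inflation factor) until all |r| <= r_max, then drop the
largest-VIF variable until all VIF <= vif_max, recomputing after each
removal. Defaults vif_max=5 and r_max=0.75 are the conventional cut-offs.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

__all__ = ["CollinearityReport", "compute_vif", "select_predictors", "variable_importance"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CollinearityReport:
    vif: dict[str, float]
    removed: list[tuple[str, str, float]]  # (name, reason in {vif, correlation}, value)
    retained: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        removed_names = {name for name, _, _ in self.removed}
        for name, vif in self.vif.items():
            if name in removed_names:
                reason, value = next(
                    (r, v) for n, r, v in self.removed if n == name
                )
                rows.append({"variable": name, "vif": vif, "status": "removed",
                             "reason": reason, "value": value})
            else:
                rows.append({"variable": name, "vif": vif, "status": "retained",
                             "reason": "", "value": np.nan})
        return pd.DataFrame(rows)


def compute_vif(table: pd.DataFrame, variables: list[str]) -> dict[str, float]:
    """VIF_j = 1 / (1 - R²_j), R²_j from regressing variable j on the others.

    A perfectly collinear variable yields +inf rather than an exception.
    Requires at least two variables and more rows than variables.
    """
    if len(variables) < 2:
        raise ValueError("VIF needs at least two variables")
    X = table[list(variables)].to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than variables")
    out: dict[str, float] = {}
    n = X.shape[1]
    for j, name in enumerate(variables):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:  # constant column: undefined, treat as fully explained
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        denom = 1.0 - r2
        # numerical floor: residual variance indistinguishable from zero
        if denom <= max(1e-12, 1e-10 * n):
            out[name] = np.inf
        else:
            out[name] = float(max(1.0, 1.0 / denom))
    return out


def select_predictors(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    vif_max: float = 5.0,
    r_max: float = 0.75,
) -> CollinearityReport:
    """Iteratively drop collinear variables (correlation rule, then VIF rule).

    Step (a): while any pair has |Pearson r| > r_max, remove the member of
    the most-correlated pair with the larger VIF. Step (b): while any VIF
    exceeds vif_max, remove the largest-VIF variable. VIFs are recomputed
    after every removal; ties remove the lexicographically later name, so
    the result is deterministic.
    """
    if vif_max <= 0 or r_max <= 0:
        raise ValueError("thresholds must be positive")
    if variables is None:
        variables = [c for c in table.columns if c not in ("lon", "lat", "label")]
    current = list(variables)
    initial_vif = compute_vif(table, current) if len(current) >= 2 else {
        v: 1.0 for v in current
    }
    removed: list[tuple[str, str, float]] = []

    def _vifs(names: list[str]) -> dict[str, float]:
        if len(names) < 2:
            return {n: 1.0 for n in names}
        return compute_vif(table, names)

    # (a) correlation rule
    while len(current) >= 2:
        corr = table[current].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        r = corr[i, j]
        if r <= r_max:
            break
        a, b = current[i], current[j]
        vifs = _vifs(current)
        if np.isclose(vifs[a], vifs[b]) or (np.isinf(vifs[a]) and np.isinf(vifs[b])):
            drop = max(a, b)  # lexicographically later
        else:
            drop = a if vifs[a] > vifs[b] else b
        removed.append((drop, "correlation", float(r)))
        current.remove(drop)

    # (b) VIF rule
    while len(current) >= 2:
        vifs = _vifs(current)
        worst = max(vifs.values())
        if worst <= vif_max:
            break
        ties = sorted(n for n, v in vifs.items() if v == worst or
                      (np.isinf(v) and np.isinf(worst)))
        drop = ties[-1]
        removed.append((drop, "vif", float(worst)))
        current.remove(drop)

    if len(current) < 2:
        warnings.warn(
            f"collinearity filtering left {len(current)} predictor(s)", stacklevel=2
        )
    return CollinearityReport(vif=initial_vif, removed=removed, retained=current)


def variable_importance(
    model,
    table: pd.DataFrame,
    n_permutations: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance as percent contribution per retained variable.

    Raw importance of a variable = 1 - Pearson correlation between model
    predictions on the original table and on the table with that column
    permuted, averaged over permutations; raw values are then normalized
    to percentages summing to 100. Constant predictions make the
    correlation undefined; such variables are flagged zero with a warning.
    """
    variables = list(model.retained_variables)
    rng = np.random.default_rng(seed)
    base = np.asarray(model.predict_table(table), dtype=float)
    raw: dict[str, float] = {}
    for name in variables:
        drops = []
        for _ in range(n_permutations):
            shuffled = table.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            pred = np.asarray(model.predict_table(shuffled), dtype=float)
            if np.std(base) == 0 or np.std(pred) == 0:
                warnings.warn(
                    f"constant predictions while permuting {name!r}; importance set to 0",
                    stacklevel=2,
                )
                drops.append(0.0)
            else:
                r = float(np.corrcoef(base, pred)[0, 1])
                drops.append(1.0 - r)
        raw[name] = max(0.0, float(np.mean(drops)))
    total = sum(raw.values())
    if total == 0:
        warnings.warn("all importances zero; returning zeros", stacklevel=2)
        return {name: 0.0 for name in variables}
    return {name: 100.0 * v / total for name, v in raw.items()}
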