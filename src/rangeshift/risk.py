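"""IUCN criterion A3(C)-style risk categorisation from projected AOO loss.

Projected AOO decline proxies the future population reduction of IUCN
criterion A3. The category cut-offs implemented here are the assessment
scheme's printed constants — LC below 15% loss, NT from 15%, VU above
30%, EN above 50%, CR above 80%, EX at exactly 100% — which differ from
the canonical IUCN A3 thresholds (30/50/80); see docs/methods.md.

Boundary semantics are precautionary: a loss exactly on a boundary takes
the more threatened category where the scheme's strict inequalities leave
it ambiguous (so 15 -> NT), and gains are clamped to LC. "EX" is a
projected-status label under A3(C), not a formal extinction declaration.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd

__all__ = [
    "RiskCategory",
    "ListingChange",
    "ScenarioOutcome",
    "AssessmentResult",
    "classify_risk",
    "compare_status",
    "assess",
    "EX_CAVEAT",
]

EX_CAVEAT = (
    "'EX' denotes a projected status under criterion A3(C), "
    "not a formal IUCN extinction declaration."
)


class RiskCategory(enum.IntEnum):
    """Red List categories, ordered from least to most threatened."""

    LC = 0
    NT = 1
    VU = 2
    EN = 3
    CR = 4
    EX = 5


class ListingChange(str, enum.Enum):
    UP_LISTED = "up-listed"
    DOWN_LISTED = "down-listed"
    UNCHANGED = "unchanged"
    UNKNOWN = "unknown"


#: (lower bound on loss %, category, bound-inclusive) — default boundaries.
DEFAULT_BOUNDARIES: tuple[tuple[float, RiskCategory, bool], ...] = (
    (100.0, RiskCategory.EX, True),
    (80.0, RiskCategory.CR, False),
    (50.0, RiskCategory.EN, False),
    (30.0, RiskCategory.VU, False),
    (15.0, RiskCategory.NT, True),
)


def classify_risk(loss_pct: float, boundaries=DEFAULT_BOUNDARIES) -> RiskCategory:
    """Category for a projected AOO loss percentage (gains enter as <= 0).

    EX iff loss == 100; CR for loss > 80; EN for loss > 50; VU for
    loss > 30; NT for loss >= 15; LC below that, including all gains.
    """
    if not np.isfinite(loss_pct):
        raise ValueError("loss percentage must be finite")
    if loss_pct > 100.0:
        raise ValueError("loss percentage cannot exceed 100")
    for bound, category, inclusive in boundaries:
        if loss_pct >= bound if inclusive else loss_pct > bound:
            return category
    return RiskCategory.LC


def compare_status(current: RiskCategory, proposed: RiskCategory) -> ListingChange:
    """Up-listed if the proposed category is more threatened, etc."""
    if proposed > current:
        return ListingChange.UP_LISTED
    if proposed < current:
        return ListingChange.DOWN_LISTED
    return ListingChange.UNCHANGED


@dataclasses.dataclass(frozen=True)
class ScenarioOutcome:
    """One threshold-rule x dispersal x climate-scenario projection."""

    climate_scenario: str
    threshold_rule: str
    dispersal: str
    aoo_change_pct: float

    @property
    def loss_pct(self) -> float:
        return max(0.0, -self.aoo_change_pct)


@dataclasses.dataclass
class AssessmentResult:
    species: str
    current_status: RiskCategory | None
    n_records: int
    outcomes: list[dict]
    caveat: str = EX_CAVEAT

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.outcomes)

    def summary(self) -> str:
        lines = [f"Species: {self.species}  (n = {self.n_records} records)"]
        status = self.current_status.name if self.current_status is not None else "unknown"
        lines.append(f"Current Red List status: {status}")
        for o in self.outcomes:
            change = (
                f"{-o['aoo_change_pct']:.0f}% loss"
                if o["aoo_change_pct"] <= 0
                else f"{o['aoo_change_pct']:.0f}% gain"
            )
            lines.append(
                f"  [{o['climate_scenario']} | {o['threshold_rule']} | "
                f"dispersal={o['dispersal']}] AOO {change} -> "
                f"{o['proposed_status']} ({o['listing_change']})"
            )
        lines.append(self.caveat)
        return "\n".join(lines)


def assess(
    species: str,
    current_status: RiskCategory | str | None,
    scenario_outcomes: list[ScenarioOutcome],
    n_records: int = 0,
    population_trend: str = "",
) -> AssessmentResult:
    """Classify every scenario outcome and compare against the current status.

    Outcomes under different threshold rules are reported side by side,
    never merged. A missing current status still yields proposed
    categories, with the listing change marked unknown.
    """
    if not scenario_outcomes:
        raise ValueError("no scenario outcomes to assess")
    if isinstance(current_status, str):
        current_status = RiskCategory[current_status]
    rows = []
    for outcome in scenario_outcomes:
        proposed = classify_risk(outcome.loss_pct)
        if current_status is None:
            change = ListingChange.UNKNOWN
        else:
            change = compare_status(current_status, proposed)
        rows.append(
            {
                "species": species,
                "n_records": n_records,
                "current_status": current_status.name if current_status else "",
                "trend": population_trend,
                "scenario": outcome.climate_scenario,
                "climate_scenario": outcome.climate_scenario,
                "threshold_rule": outcome.threshold_rule,
                "dispersal": outcome.dispersal,
                "aoo_change_pct": outcome.aoo_change_pct,
                "proposed_status": proposed.name,
                "listing_change": change.value,
            }
        )
    return AssessmentResult(
        species=species,
        current_status=current_status,
        n_records=n_records,
        outcomes=rows,
    )
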