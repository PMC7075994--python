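"""Bycatch compilation and mortality-reduction targets.

Interaction records are compiled by gear; where observed mortality is
missing, gear-specific mortality rates convert interactions to deaths
(5% for longlines, 33% for net gear).  Two complementary calculations give
the number of late-stage turtles a 20% cut in bycatch mortality would
save each year: one scales fleet-wide lethal-take estimates, the other
compares annual deaths in the modelled late-stage population at current
versus target survivorship.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "BycatchRecord",
    "DEFAULT_MORTALITY_RATES",
    "load_bycatch_records",
    "read_bycatch_csv",
    "compile_totals",
    "lethal_interactions",
    "saved_per_year_fleet",
    "saved_per_year_model",
]

GEARS = ("longline", "gillnet", "driftnet", "other")
DEFAULT_MORTALITY_RATES = {"longline": 0.05, "gillnet": 0.33, "driftnet": 0.33, "other": 0.33}


@dataclass(frozen=True)
class BycatchRecord:
    source: str
    gear: str
    interactions: float
    mortality: Optional[float] = None
    period_years: Optional[float] = None

    def __post_init__(self):
        if self.gear not in GEARS:
            raise ValueError(f"unknown gear {self.gear!r}")
        if self.interactions < 0:
            raise ValueError("interactions must be >= 0")
        if self.mortality is not None and not 0 <= self.mortality <= self.interactions:
            raise ValueError("mortality must lie between 0 and interactions")


def read_bycatch_csv(path: str | Path) -> list[BycatchRecord]:
    df = pd.read_csv(path, comment="#")
    out = []
    for r in df.to_dict("records"):
        mort = r.get("mortality")
        per = r.get("period_years")
        out.append(
            BycatchRecord(
                source=str(r["source"]),
                gear=str(r["gear"]),
                interactions=float(r["interactions"]),
                mortality=None if pd.isna(mort) else float(mort),
                period_years=None if pd.isna(per) else float(per),
            )
        )
    return out


def load_bycatch_records() -> list[BycatchRecord]:
    """The packaged regional compilation (2012 onward)."""
    with resources.files("leatherback_pva.data").joinpath("bycatch_records.csv").open() as fh:
        return read_bycatch_csv(fh)


def compile_totals(records: Sequence[BycatchRecord]) -> dict:
    """Interactions by gear, overall, and per-year mean over the record span."""
    by_gear = {g: 0.0 for g in GEARS}
    labels = [(r.source, r.gear) for r in records]
    if len(set(labels)) < len(labels):
        warnings.warn("duplicate source/gear labels: totals may double-count", stacklevel=2)
    for r in records:
        by_gear[r.gear] += r.interactions
    overall = sum(by_gear.values())
    spans = [r.period_years for r in records if r.period_years is not None]
    per_year = overall / max(spans) if spans else None
    return {"by_gear": by_gear, "overall": overall, "per_year": per_year}


def lethal_interactions(
    records: Sequence[BycatchRecord], default_rates: Optional[dict] = None
) -> dict:
    """Deaths by gear: observed mortality where recorded, otherwise
    interactions times the gear's default mortality rate."""
    rates = dict(DEFAULT_MORTALITY_RATES, **(default_rates or {}))
    if any(not 0 <= v <= 1 for v in rates.values()):
        raise ValueError("mortality rates must be proportions")
    deaths = {g: 0.0 for g in GEARS}
    for r in records:
        deaths[r.gear] += r.mortality if r.mortality is not None else r.interactions * rates[r.gear]
    deaths["overall"] = sum(deaths[g] for g in GEARS)
    return deaths


def saved_per_year_fleet(
    lethal_total: float, wp_fraction: float, reduction: float
) -> float:
    """Turtles saved per year from fleet-wide lethal-take estimates.

    ``wp_fraction`` removes the share attributable to the West Pacific
    subpopulation before applying the relative ``reduction``.
    """
    if lethal_total < 0 or not 0 <= wp_fraction <= 1 or not 0 <= reduction <= 1:
        raise ValueError("inputs outside valid ranges")
    return lethal_total * (1.0 - wp_fraction) * reduction


def saved_per_year_model(
    late_stage_total: float,
    s_current: float,
    s_target: float,
    sex_ratio: float = 0.84,
    late_stage_females: Optional[float] = None,
) -> dict:
    """Annual late-stage deaths now vs at a target survivorship.

    ``deaths_now = N (1 - s_current)``, ``deaths_target = N (1 - s_target)``;
    the difference is the number surviving each year under the recovery
    scenario that die today.  Female counts use ``late_stage_females`` when
    the female total is known directly (the model reports female abundance
    natively); otherwise they scale the both-sex total by the operational
    sex ratio.
    """
    if s_target < s_current:
        raise ValueError("target survivorship must not be below current")
    if not (0 <= s_current <= 1 and 0 <= s_target <= 1):
        raise ValueError("survivorships must be probabilities")
    n_f = late_stage_total * sex_ratio if late_stage_females is None else late_stage_females
    deaths_now = late_stage_total * (1.0 - s_current)
    deaths_target = late_stage_total * (1.0 - s_target)
    saved = deaths_now - deaths_target
    return {
        "deaths_now": deaths_now,
        "deaths_target": deaths_target,
        "saved": saved,
        "deaths_now_females": n_f * (1.0 - s_current),
        "deaths_target_females": n_f * (1.0 - s_target),
        "females_saved": n_f * (s_target - s_current),
    }
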