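"""Demographic parameters and per-female reproductive output.

The unit of parameterization is one nesting subpopulation (Costa Rica or
México; Nicaragua shares Costa Rica's rates).  Hatchling production per
nesting female follows one of two pathways, reflecting different beach
protocols:

* Costa Rica / Nicaragua:  ``H = f * es * w * fem`` — eggs per season times
  emergence success times the proportion of emerged hatchlings reaching the
  water, times the primary sex ratio.
* México (all clutches relocated, so egg-to-water survival is known
  directly): ``H = f * hw * fem``.

Under a pre-breeding census the first-year survival ``S1`` is folded into
the fertility coefficient, ``F = H * S1``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "VitalRates",
    "SubpopulationSet",
    "eggs_per_female",
    "hatchlings_to_water",
    "effective_fertility",
    "load_table1",
    "load_parameters",
]

_PROB_FIELDS = (
    "s1", "s2", "s3", "b1", "b2", "b3", "b4", "transient",
    "emergence_success", "water_success", "survival_to_water",
    "harvest_rate", "sex_ratio",
)


def eggs_per_female(clutch_size: float, ecf: float, rounding: str = "exact") -> float:
    """Eggs produced per female per season: mean clutch size x clutch frequency.

    ``rounding="half_up"`` applies the presentation rule (round half away
    from zero to an integer); ``"exact"`` returns the float product.
    """
    if clutch_size < 0 or ecf < 0:
        raise ValueError("clutch_size and ecf must be non-negative")
    f = clutch_size * ecf
    if rounding == "exact":
        return f
    if rounding == "half_up":
        return float(math.floor(f + 0.5))
    raise ValueError(f"unknown rounding policy: {rounding!r}")


@dataclass
class VitalRates:
    """Mean demographic rates for one nesting subpopulation.

    Probabilities and proportions are annual and dimensionless; fecundity
    fields are eggs per female per season.  ``survival_to_water`` is the
    combined egg-to-water proportion (``hw``); when both it and the
    ``emergence_success * water_success`` decomposition are supplied the
    combined value is canonical.  ``hatchling_multiplier`` is a scenario
    adjustment on hatchling output (1.0 = current conditions).
    """

    s1: float
    s2: float
    s3: float
    b1: float
    b2: float
    b3: float
    b4: float
    transient: float
    sex_ratio: float
    clutch_size: Optional[float] = None
    ecf: Optional[float] = None
    eggs_per_season: Optional[float] = None
    emergence_success: Optional[float] = None
    water_success: Optional[float] = None
    survival_to_water: Optional[float] = None
    harvest_rate: float = 0.0
    hatchling_multiplier: float = 1.0
    # printed dispersion/uncertainty used by the stochastic variance model
    clutch_size_sd: Optional[float] = None
    ecf_sd: Optional[float] = None
    s3_ci: Optional[tuple[float, float]] = None
    transient_ci: Optional[tuple[float, float]] = None
    name: str = ""

    def __post_init__(self) -> None:
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("clutch_size", "ecf", "eggs_per_season"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.eggs_per_season is None and self.clutch_size is not None and self.ecf is not None:
            self.eggs_per_season = eggs_per_female(self.clutch_size, self.ecf)
        if (
            self.eggs_per_season is not None
            and self.clutch_size is not None
            and self.ecf is not None
            and abs(self.clutch_size * self.ecf - self.eggs_per_season) > 1.0
        ):
            raise ValueError(
                "eggs_per_season inconsistent with clutch_size * ecf "
                f"({self.clutch_size * self.ecf:.1f} vs {self.eggs_per_season})"
            )

    @property
    def egg_to_water(self) -> float:
        """Egg-to-water survival; the combined estimate wins when present."""
        if self.survival_to_water is not None:
            return self.survival_to_water
        if self.emergence_success is not None and self.water_success is not None:
            return self.emergence_success * self.water_success
        raise ValueError(
            f"{self.name or 'VitalRates'}: neither survival_to_water nor "
            "emergence_success*water_success is available"
        )

    def with_(self, **kw) -> "VitalRates":
        return replace(self, **kw)


def hatchlings_to_water(
    rates: VitalRates, female_only: bool = True, apply_harvest: bool = False
) -> float:
    """Hatchlings reaching the water per nesting female per season (H).

    ``apply_harvest`` multiplies by ``1 - harvest_rate`` for contexts in
    which egg take is not already reflected in the measured success rates.
    The scenario ``hatchling_multiplier`` is always applied.
    """
    if rates.eggs_per_season is None:
        raise ValueError("eggs_per_season is not set")
    h = rates.eggs_per_season * rates.egg_to_water * rates.hatchling_multiplier
    if female_only:
        h *= rates.sex_ratio
    if apply_harvest:
        h *= 1.0 - rates.harvest_rate
    return h


def effective_fertility(hatchlings: float, s1: float) -> float:
    """Pre-breeding-census fertility coefficient F = H * S1."""
    if hatchlings < 0:
        raise ValueError("hatchlings must be non-negative")
    if not 0.0 <= s1 <= 1.0:
        raise ValueError("s1 must be a probability")
    return hatchlings * s1


@dataclass
class SubpopulationSet:
    """The two modelled subpopulations plus Nicaragua's alias.

    Nicaragua shares Costa Rica's demographic rates; ``nicaragua`` always
    resolves to the *same* :class:`VitalRates` object as ``costa_rica`` so
    scenario edits propagate.  ``nesting_shares`` are proportions of
    region-wide nesting activity and must sum to one.
    """

    costa_rica: VitalRates
    mexico: VitalRates
    nesting_shares: dict[str, float] = field(
        default_factory=lambda: {"mexico": 0.754, "costa_rica": 0.222, "nicaragua": 0.024}
    )

    def __post_init__(self) -> None:
        total = sum(self.nesting_shares.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"nesting shares sum to {total}, expected 1")

    @property
    def nicaragua(self) -> VitalRates:
        return self.costa_rica

    @property
    def block_shares(self) -> dict[str, float]:
        """Shares per modelled block: Nicaragua folds into Costa Rica."""
        return {
            "costa_rica": self.nesting_shares["costa_rica"] + self.nesting_shares.get("nicaragua", 0.0),
            "mexico": self.nesting_shares["mexico"],
        }

    def map_blocks(self, fn) -> "SubpopulationSet":
        return SubpopulationSet(
            costa_rica=fn("costa_rica", self.costa_rica),
            mexico=fn("mexico", self.mexico),
            nesting_shares=dict(self.nesting_shares),
        )


def _rates_from_record(rec: dict, name: str) -> VitalRates:
    def get(k):
        v = rec.get(k)
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return float(v)

    ci = lambda lo, hi: (get(lo), get(hi)) if get(lo) is not None else None
    return VitalRates(
        s1=get("s1"), s2=get("s2"), s3=get("s3"),
        b1=get("b1"), b2=get("b2"), b3=get("b3"), b4=get("b4"),
        transient=get("transient"), sex_ratio=get("sex_ratio"),
        clutch_size=get("clutch_size"), ecf=get("ecf"),
        eggs_per_season=get("eggs_per_season"),
        emergence_success=get("emergence_success"),
        water_success=get("water_success"),
        survival_to_water=get("survival_to_water"),
        harvest_rate=get("harvest_rate") or 0.0,
        clutch_size_sd=get("clutch_size_sd"), ecf_sd=get("ecf_sd"),
        s3_ci=ci("s3_ci_low", "s3_ci_high"),
        transient_ci=ci("transient_ci_low", "transient_ci_high"),
        name=name,
    )


def load_parameters(path: str | Path) -> SubpopulationSet:
    """Read a parameter file (CSV or JSON, one record per subpopulation)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        df = pd.DataFrame(records)
    else:
        df = pd.read_csv(path)
    return _from_frame(df)


def _from_frame(df: pd.DataFrame) -> SubpopulationSet:
    recs = {str(r["subpopulation"]): r for r in df.to_dict("records")}
    shares = {
        name: float(r["nesting_share"])
        for name, r in recs.items()
        if "nesting_share" in r and not pd.isna(r["nesting_share"])
    }
    cr = _rates_from_record(recs["costa_rica"], "costa_rica")
    mx = _rates_from_record(recs["mexico"], "mexico")
    kw = {"nesting_shares": shares} if shares else {}
    return SubpopulationSet(costa_rica=cr, mexico=mx, **kw)


def load_table1() -> SubpopulationSet:
    """Load the packaged mean-estimate table for current conditions."""
    with resources.files("leatherback_pva.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return _from_frame(df)
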