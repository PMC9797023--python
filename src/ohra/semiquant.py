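"""Semi-quantitative risk models: Risk = sqrt(HR x ER).

Four variants share the hazard rating HR (1-5, from carcinogenicity class
or acute lethality) and differ in how the exposure rating ER (1-5) is
obtained:

* ``ratio`` — the Chinese exposure-ratio method.  The weekly exposure
  E = F*D*M/W (F workdays/week, D hours/day, M measured C-TWA, W weekly
  hours) is compared to the OEL and the ratio banded to an integer ER.
  With W = F*D, E reduces to the C-TWA itself.
* ``singapore_ei`` — geometric mean of the exposure indices {hazard-control
  measures, weekly usage, vapour pressure, weekly working hours}.  (The
  particle-size index applies to dusts only and is omitted for vapours.)
* ``chinese_ei`` — geometric mean over a wider factor set {hazard-control
  measures, daily usage, daily hours, PPE, first aid, emergency rescue,
  occupational-health management}.
* ``synthesis`` — the Chinese factor set plus the banded E/OEL ratio as one
  more index, so measured exposure pulls the rating of well-controlled but
  clean workplaces down (and of dirty ones up).

The continuous score sqrt(HR*ER) is rounded half-up to the integer risk
level 1-5 (sqrt(5*1) = 2.236 -> level 2).
"""
from __future__ import annotations

import math
from typing import Literal, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .profiles import ChemicalProfile, ControlProfile, RubricConfig, SEGRecord, half_up

__all__ = [
    "HazardRating",
    "ExposureRating",
    "SemiQuantResult",
    "SEMIQUANT_METHODS",
    "determine_hr",
    "compute_weekly_exposure",
    "er_from_ratio",
    "score_ei",
    "er_geometric",
    "risk_from_hr_er",
    "run_model",
]

Method = Literal["ratio", "singapore_ei", "chinese_ei", "synthesis"]
SEMIQUANT_METHODS: tuple[str, ...] = ("ratio", "singapore_ei", "chinese_ei", "synthesis")


class HazardRating(BaseModel):
    model_config = ConfigDict(extra="forbid")

    hr: int = Field(ge=1, le=5)
    basis: Literal["iarc_acgih", "ld50", "lc50"]


class ExposureRating(BaseModel):
    model_config = ConfigDict(extra="forbid")

    er: float = Field(ge=1, le=5)
    indices: dict[str, int] = Field(default_factory=dict)
    method: Method


class SemiQuantResult(BaseModel):
    model_config = ConfigDict(extra="forbid")

    hr: HazardRating
    er: ExposureRating
    risk_score: float
    risk_level: int = Field(ge=1, le=5)
    label: str
    e_weekly: float | None = Field(default=None, description="mg/m^3")
    e_over_oel: float | None = None


def determine_hr(profile: ChemicalProfile, rubric: RubricConfig) -> HazardRating:
    """Hazard rating with precedence IARC/ACGIH > oral LD50 > inhalation LC50.

    A confirmed human carcinogen (IARC group 1 / ACGIH A1) rates 5; when the
    substance is unclassified the acute-lethality bands apply.
    """
    candidates = []
    if profile.iarc_group != "none":
        candidates.append(rubric.hr_iarc[profile.iarc_group])
    if profile.acgih_class != "none":
        candidates.append(rubric.hr_acgih[profile.acgih_class])
    if candidates:
        return HazardRating(hr=max(candidates), basis="iarc_acgih")
    if profile.oral_ld50 is not None:
        return HazardRating(hr=rubric.hr_ld50_bands.score(profile.oral_ld50), basis="ld50")
    if profile.inhal_lc50 is not None:
        return HazardRating(hr=rubric.hr_lc50_bands.score(profile.inhal_lc50), basis="lc50")
    raise ValueError(f"{profile.name}: no classification from which to derive HR")


def compute_weekly_exposure(f: float, d: float, m: float, w: float) -> float:
    """Weekly exposure E = F*D*M/W (mg/m^3)."""
    if w <= 0:
        raise ValueError("weekly working hours W must be positive")
    return f * d * m / w


def er_from_ratio(e_over_oel: float, rubric: RubricConfig) -> int:
    """Band the exposure ratio E/OEL to an integer ER 1..5."""
    if e_over_oel < 0:
        raise ValueError("E/OEL must be non-negative")
    return rubric.er_ratio_bands.score(e_over_oel)


def score_ei(factor_name: str, raw_value, rubric: RubricConfig) -> int:
    """Score one exposure factor to its index EI 1..5 via the rubric tables."""
    if factor_name in rubric.ei_numeric:
        return rubric.ei_numeric[factor_name].score(float(raw_value))
    if factor_name in rubric.ei_categorical:
        table = rubric.ei_categorical[factor_name]
        try:
            return table[str(raw_value)]
        except KeyError:
            raise ValueError(
                f"unknown category {raw_value!r} for factor {factor_name!r}; "
                f"expected one of {sorted(table)}"
            ) from None
    known = sorted(rubric.ei_numeric) + sorted(rubric.ei_categorical)
    raise ValueError(f"unknown exposure factor {factor_name!r}; known factors: {known}")


def er_geometric(indices: Sequence[float]) -> float:
    """Geometric mean [EI1 x EI2 x ... x EIn]^(1/n)."""
    if not indices:
        raise ValueError("need at least one exposure index")
    if any(not 1 <= x <= 5 for x in indices):
        raise ValueError("exposure indices must lie in [1, 5]")
    return math.exp(sum(math.log(x) for x in indices) / len(indices))


def risk_from_hr_er(
    hr: HazardRating | int,
    er: ExposureRating | float,
    rubric: RubricConfig,
    *,
    e_weekly: float | None = None,
    e_over_oel: float | None = None,
) -> SemiQuantResult:
    """Combine ratings: score = sqrt(HR*ER), level = half-up rounding."""
    hr_obj = hr if isinstance(hr, HazardRating) else HazardRating(hr=hr, basis="iarc_acgih")
    er_obj = er if isinstance(er, ExposureRating) else ExposureRating(er=float(er), method="ratio")
    if not 1 <= hr_obj.hr <= 5 or not 1 <= er_obj.er <= 5:
        raise ValueError("HR and ER must lie in [1, 5]")
    score = math.sqrt(hr_obj.hr * er_obj.er)
    level = min(5, max(1, half_up(score)))
    return SemiQuantResult(
        hr=hr_obj,
        er=er_obj,
        risk_score=score,
        risk_level=level,
        label=rubric.risk_labels[level],
        e_weekly=e_weekly,
        e_over_oel=e_over_oel,
    )


def _control_ei(controls: ControlProfile, rubric: RubricConfig) -> int:
    # single hazard-control index: the weaker of engineering control and
    # automation dominates (conservative max)
    return max(
        score_ei("ventilation", controls.ventilation, rubric),
        score_ei("automation", controls.automation, rubric),
    )


def _ppe_category(controls: ControlProfile) -> str:
    if controls.ppe_worn:
        return "worn"
    if controls.ppe_equipped:
        return "equipped"
    return "none"


def _exposure_ratio(record: SEGRecord, profile: ChemicalProfile) -> tuple[float, float]:
    e_weekly = compute_weekly_exposure(
        record.days_per_week, record.hours_per_day, record.c_twa, record.weekly_hours
    )
    return e_weekly, e_weekly / profile.oel


def run_model(
    record: SEGRecord,
    profile: ChemicalProfile,
    rubric: RubricConfig,
    method: str,
) -> SemiQuantResult:
    """Run one semi-quantitative method on one SEG."""
    if method not in SEMIQUANT_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {SEMIQUANT_METHODS}")
    hr = determine_hr(profile, rubric)
    e_weekly = e_over_oel = None

    if method == "ratio":
        e_weekly, e_over_oel = _exposure_ratio(record, profile)
        er = ExposureRating(
            er=float(er_from_ratio(e_over_oel, rubric)),
            indices={"e_over_oel": er_from_ratio(e_over_oel, rubric)},
            method="ratio",
        )
    else:
        indices: dict[str, int] = {"control_measures": _control_ei(record.controls, rubric)}
        if method == "singapore_ei":
            indices["weekly_usage"] = score_ei("weekly_usage", record.weekly_usage, rubric)
            indices["vapor_pressure"] = score_ei(
                "vapor_pressure", profile.vapor_pressure_25c, rubric
            )
            indices["weekly_hours"] = score_ei("weekly_hours", record.weekly_hours, rubric)
        else:  # chinese_ei and synthesis share the Chinese factor set
            indices["daily_usage"] = score_ei("daily_usage", record.daily_usage, rubric)
            indices["daily_hours"] = score_ei("daily_hours", record.hours_per_day, rubric)
            indices["ppe"] = score_ei("ppe", _ppe_category(record.controls), rubric)
            indices["first_aid"] = score_ei(
                "first_aid", "yes" if record.controls.first_aid else "no", rubric
            )
            indices["emergency_measures"] = score_ei(
                "emergency_measures", record.controls.emergency_measures, rubric
            )
            indices["oh_management"] = score_ei(
                "oh_management", record.controls.oh_management, rubric
            )
            if method == "synthesis":
                e_weekly, e_over_oel = _exposure_ratio(record, profile)
                indices["e_over_oel"] = score_ei("e_over_oel", e_over_oel, rubric)
        er = ExposureRating(
            er=er_geometric(list(indices.values())), indices=indices, method=method
        )

    return risk_from_hr_er(hr, er, rubric, e_weekly=e_weekly, e_over_oel=e_over_oel)
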