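"""EPA inhalation risk models: hazard quotient and lifetime cancer risk.

Non-carcinogenic risk is the hazard quotient HQ = EC/RfC, unacceptable at
HQ >= 1.  Carcinogenic risk is IR = IUR * d * tE/tL where IUR is the
inhalation unit risk (per ug/m^3), d the airborne concentration in ug/m^3,
tE the lifetime-equivalent exposure time in years and tL the life
expectancy; IR above 1e-4 is unacceptable.

EC defaults to the workplace air concentration itself (``direct`` mode); the
``adjusted`` mode scales the occupational schedule to continuous-exposure
equivalents, EC = C * (h/24) * (days/365).
"""
from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field

from .profiles import ChemicalProfile, RubricConfig, SEGRecord

__all__ = [
    "EpaResult",
    "compute_ec",
    "compute_hq",
    "compute_te",
    "compute_ir",
    "assess_epa",
    "HQ_THRESHOLD",
    "IR_THRESHOLD",
]

HQ_THRESHOLD = 1.0
IR_THRESHOLD = 1e-4
_HOURS_PER_YEAR = 24.0 * 365.0


class EpaResult(BaseModel):
    model_config = ConfigDict(extra="forbid")

    ec: float = Field(ge=0, description="mg/m^3")
    hq: float = Field(ge=0)
    hq_acceptable: bool
    te_years: float = Field(ge=0)
    ir: float = Field(ge=0)
    ir_acceptable: bool


def compute_ec(
    c_twa: float,
    hours_per_day: float = 8.0,
    days_per_year: float = 250.0,
    mode: str = "direct",
) -> float:
    """Exposure concentration (mg/m^3) for the hazard quotient."""
    if c_twa < 0:
        raise ValueError("c_twa must be non-negative")
    if mode == "direct":
        return c_twa
    if mode == "adjusted":
        return c_twa * (hours_per_day / 24.0) * (days_per_year / 365.0)
    raise ValueError(f"unknown EC mode {mode!r}; expected 'direct' or 'adjusted'")


def compute_hq(ec: float, rfc: float) -> tuple[float, bool]:
    """Hazard quotient and its acceptability (acceptable iff HQ < 1)."""
    if rfc <= 0:
        raise ValueError("rfc must be positive")
    hq = ec / rfc
    return hq, hq < HQ_THRESHOLD


def compute_te(hours_per_day: float, days_per_year: float, duration_years: float) -> float:
    """Lifetime-equivalent exposure time in years.

    tE = (hours/workday * workdays/year * duration) / (24 h/day * 365 d/yr).
    """
    return hours_per_day * days_per_year * duration_years / _HOURS_PER_YEAR


def compute_ir(
    iur: float, d_conc: float, te_years: float, tl_years: float
) -> tuple[float, bool]:
    """Lifetime cancer risk IR = IUR * d * tE/tL; acceptable iff IR <= 1e-4.

    ``d_conc`` is the airborne concentration in ug/m^3 (note the unit: the
    unit risk is defined per ug/m^3 of continuous exposure).
    """
    if tl_years <= 0:
        raise ValueError("tl_years must be positive")
    if te_years > tl_years:
        raise ValueError("exposure time cannot exceed life expectancy")
    ir = iur * d_conc * te_years / tl_years
    return ir, ir <= IR_THRESHOLD


def assess_epa(
    record: SEGRecord,
    profile: ChemicalProfile,
    rubric: RubricConfig,
    ec_mode: str | None = None,
) -> EpaResult:
    """Run both EPA models on one SEG.

    Workdays per year follow the 52-week rule (days/week * 52); exposure
    duration is the surveyed months of service / 12.  The mg -> ug
    conversion of the C-TWA for the cancer model happens here and nowhere
    else.
    """
    mode = ec_mode if ec_mode is not None else rubric.epa_ec_mode
    days_per_year = record.days_per_week * 52.0
    ec = compute_ec(record.c_twa, record.hours_per_day, days_per_year, mode=mode)
    hq, hq_ok = compute_hq(ec, profile.rfc)
    te = compute_te(record.hours_per_day, days_per_year, record.duration_months / 12.0)
    ir, ir_ok = compute_ir(
        profile.iur, record.c_twa * 1000.0, te, rubric.life_expectancy_years
    )
    return EpaResult(
        ec=ec, hq=hq, hq_acceptable=hq_ok, te_years=te, ir=ir, ir_acceptable=ir_ok
    )
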