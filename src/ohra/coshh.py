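"""COSHH Essentials qualitative control banding.

The scheme maps a substance's hazard (via its R-phrase allocation) to a
hazard band A-E, predicts an exposure band 1-4 from the substance's
volatility and the quantity in use, and reads the required control approach
(interpreted as the risk level 1-4) from a matrix.  Band E — carcinogens,
mutagens and respiratory sensitisers — always demands specialist advice,
i.e. risk level 4 regardless of the predicted exposure.
"""
from __future__ import annotations

from typing import Literal, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .profiles import ChemicalProfile, HazardBand, RubricConfig, SEGRecord

__all__ = [
    "CoshhAssessment",
    "assign_hazard_band",
    "assign_volatility_band",
    "assign_quantity_band",
    "predict_exposure_band",
    "coshh_risk_level",
    "assess_coshh",
]

VolatilityBand = Literal["low", "medium", "high"]
QuantityBand = Literal["small", "medium", "large"]

_BAND_ORDER = "ABCDE"


class CoshhAssessment(BaseModel):
    model_config = ConfigDict(extra="forbid")

    hazard_band: HazardBand
    volatility_band: VolatilityBand
    quantity_band: QuantityBand
    exposure_band: int = Field(ge=1, le=4)
    risk_level: int = Field(ge=1, le=4)
    label: str


def assign_hazard_band(risk_phrases: Sequence[str], rubric: RubricConfig) -> HazardBand:
    """Most severe hazard band (A < B < C < D < E) among the phrases' bands."""
    bands = [rubric.hazard_band_map[p] for p in risk_phrases if p in rubric.hazard_band_map]
    if not bands:
        raise ValueError(
            f"no recognized R-phrase among {list(risk_phrases)}; "
            "band the substance manually or extend hazard_band_map"
        )
    return max(bands, key=_BAND_ORDER.index)


def assign_volatility_band(
    vapor_pressure_25c: float,
    boiling_point: float,
    rubric: RubricConfig,
    operating_temp: float | None = None,
) -> VolatilityBand:
    """Band a liquid's volatility.

    Default thresholds: vapour pressure at the operating temperature of at
    least 10 kPa -> high; boiling point above 150 degC -> low; otherwise
    medium.  The bundled rubric takes the 25 degC vapour pressure as the
    operating-temperature value (operating temperature defaults to 25 degC).
    """
    del operating_temp  # room-temperature use; VP given at 25 degC
    if vapor_pressure_25c >= rubric.volatility_vp_high_kpa:
        return "high"
    if boiling_point > rubric.volatility_bp_low_c:
        return "low"
    return "medium"


def assign_quantity_band(daily_usage: float, rubric: RubricConfig) -> QuantityBand:
    """Order-of-magnitude quantity band: grams, kilograms or tonnes scale."""
    if daily_usage <= 0:
        raise ValueError("daily_usage must be positive")
    if daily_usage < rubric.quantity_medium_min_kg:
        return "small"
    if daily_usage < rubric.quantity_large_min_kg:
        return "medium"
    return "large"


def predict_exposure_band(
    volatility: VolatilityBand, quantity: QuantityBand, rubric: RubricConfig
) -> int:
    """Predicted exposure band 1..4 from the volatility x quantity matrix."""
    return rubric.exposure_band_matrix[volatility][quantity]


def coshh_risk_level(
    hazard_band: HazardBand,
    exposure_band: int,
    rubric: RubricConfig,
    volatility: VolatilityBand = "high",
    quantity: QuantityBand = "medium",
) -> CoshhAssessment:
    """Read the control-approach matrix; band E dominates at level 4."""
    if not 1 <= exposure_band <= 4:
        raise ValueError("exposure_band must be in 1..4")
    level = rubric.coshh_risk_matrix[hazard_band][exposure_band - 1]
    return CoshhAssessment(
        hazard_band=hazard_band,
        volatility_band=volatility,
        quantity_band=quantity,
        exposure_band=exposure_band,
        risk_level=level,
        label=f"{rubric.coshh_labels[level].capitalize()} risk",
    )


def assess_coshh(
    record: SEGRecord, profile: ChemicalProfile, rubric: RubricConfig
) -> CoshhAssessment:
    """Full COSHH banding of one SEG handling one substance."""
    hazard = assign_hazard_band(profile.risk_phrases, rubric)
    vol = assign_volatility_band(profile.vapor_pressure_25c, profile.boiling_point, rubric)
    qty = assign_quantity_band(record.daily_usage, rubric)
    exposure = predict_exposure_band(vol, qty, rubric)
    return coshh_risk_level(hazard, exposure, rubric, volatility=vol, quantity=qty)
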