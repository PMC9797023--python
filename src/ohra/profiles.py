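"""Domain types and I/O shared by every risk model.

The unit of assessment throughout is the *similar exposure group* (SEG): a
set of workers who share a production process, schedule, and control
measures, and whose airborne exposure is summarised by one 8-h time-weighted
average concentration (C-TWA) and, where measured, one short-term
concentration (C-STEL).  Air concentrations are mg/m^3 everywhere in this
package; the single unit conversion (mg -> ug for the inhalation-unit-risk
model) lives in :mod:`ohra.epa`.

Concentrations below the laboratory limit of detection (LOD) are
*left-censored*: they are stored at the LOD with an explicit flag, mirroring
the "<LOD" notation of survey tables, and are substituted at the LOD (not
LOD/2) in summaries so that the exposure ratio of a fully censored group is
LOD/OEL.
"""
from __future__ import annotations

import json
import math
from bisect import bisect_left, bisect_right
from pathlib import Path
from typing import Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ChemicalProfile",
    "ControlProfile",
    "SEGRecord",
    "NumericBands",
    "RubricConfig",
    "GroupSummary",
    "load_chemical_profile",
    "load_rubric",
    "load_seg_table",
    "write_seg_table",
    "summarize_group",
    "benzene_profile",
    "default_rubric",
    "SEG_CSV_COLUMNS",
]

IarcGroup = Literal["1", "2A", "2B", "3", "none"]
AcgihClass = Literal["A1", "A2", "A3", "A4", "A5", "none"]
HazardBand = Literal["A", "B", "C", "D", "E"]
Automation = Literal["full", "semi", "manual"]
Ventilation = Literal["local_exhaust", "general", "none"]
Emergency = Literal["complete", "partial", "none"]
OhManagement = Literal["good", "poor", "lacking"]
GroupName = Literal["printing", "cleaning", "pasting", "packaging", "other"]


class ChemicalProfile(BaseModel):
    """Toxicology and physico-chemical constants for one substance.

    ``pc_twa`` doubles as the occupational exposure limit (OEL) used as the
    denominator of the exposure ratio E/OEL.  ``pc_stel_limit`` defaults to
    twice ``pc_twa`` (the GBZ 2.1-2019 rule for substances without an
    explicit short-term limit).  ``rfc`` is the inhalation reference
    concentration (mg/m^3) of the hazard-quotient model; ``iur`` the
    inhalation unit risk (per ug/m^3) of the cancer-risk model.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    cas: str = ""
    risk_phrases: list[str] = Field(default_factory=list)
    iarc_group: IarcGroup = "none"
    acgih_class: AcgihClass = "none"
    oral_ld50: Optional[float] = Field(default=None, gt=0, description="mg/kg")
    inhal_lc50: Optional[float] = Field(default=None, gt=0, description="mg/m^3 (4 h)")
    vapor_pressure_25c: float = Field(gt=0, description="kPa at 25 degC")
    boiling_point: float = Field(description="degC")
    pc_twa: float = Field(gt=0, description="mg/m^3")
    pc_stel_limit: Optional[float] = Field(default=None, gt=0, description="mg/m^3")
    rfc: float = Field(gt=0, description="mg/m^3")
    iur: float = Field(gt=0, description="per ug/m^3")

    @model_validator(mode="after")
    def _finish(self) -> "ChemicalProfile":
        if self.pc_stel_limit is None:
            object.__setattr__(self, "pc_stel_limit", 2.0 * self.pc_twa)
        if (
            self.iarc_group == "none"
            and self.acgih_class == "none"
            and self.oral_ld50 is None
            and self.inhal_lc50 is None
        ):
            raise ValueError(
                "no hazard classification: need at least one of iarc_group, "
                "acgih_class, oral_ld50, inhal_lc50 so a hazard rating can be derived"
            )
        return self

    @property
    def oel(self) -> float:
        """Occupational exposure limit (mg/m^3); the PC-TWA."""
        return self.pc_twa


class ControlProfile(BaseModel):
    """Hazard-control measures of one SEG, as surveyed."""

    model_config = ConfigDict(extra="forbid")

    automation: Automation = "manual"
    ventilation: Ventilation = "none"
    ppe_equipped: bool = False
    ppe_worn: bool = False
    first_aid: bool = False
    emergency_measures: Emergency = "none"
    oh_management: OhManagement = "lacking"

    @model_validator(mode="after")
    def _ppe_consistent(self) -> "ControlProfile":
        if self.ppe_worn and not self.ppe_equipped:
            raise ValueError("ppe_worn requires ppe_equipped")
        return self


class SEGRecord(BaseModel):
    """One similar-exposure-group survey row.

    ``c_twa_censored`` means the measurement was below the LOD and is stored
    at the LOD.  Schedule fields feed both the weekly-exposure formula
    E = F*D*M/W (F = days/week, D = hours/day, M = C-TWA, W = F*D) and the
    lifetime-equivalent exposure time of the cancer-risk model.
    """

    model_config = ConfigDict(extra="forbid")

    seg_id: str
    group: GroupName = "other"
    n_workers: int = Field(gt=0)
    duration_months: float = Field(gt=0)
    daily_usage: float = Field(gt=0, description="kg/day")
    weekly_usage: float = Field(gt=0, description="kg/week")
    hours_per_day: float = Field(gt=0, le=24)
    days_per_week: float = Field(gt=0, le=7)
    c_twa: float = Field(ge=0, description="mg/m^3")
    c_twa_censored: bool = False
    c_stel: Optional[float] = Field(default=None, ge=0, description="mg/m^3")
    c_stel_censored: bool = False
    controls: ControlProfile = Field(default_factory=ControlProfile)

    @model_validator(mode="after")
    def _usage_consistent(self) -> "SEGRecord":
        if self.weekly_usage < self.daily_usage:
            raise ValueError("weekly_usage must be >= daily_usage")
        return self

    @property
    def weekly_hours(self) -> float:
        """W, the average working hours per week (= F * D)."""
        return self.hours_per_day * self.days_per_week


class NumericBands(BaseModel):
    """An ordered banding of the real line into integer scores.

    ``edges`` are the k-1 cut points of a k-band table; ``closed`` says which
    side of each cut belongs to the lower band ("right": value equal to an
    edge stays in the band below, i.e. upper-inclusive intervals like
    (0.1, 1]; "left": an edge value moves up, i.e. lower-inclusive intervals
    like [1, 10)).  ``scores`` default to 1..k ascending; descending score
    lists express "larger is safer" tables such as LD50.
    """

    model_config = ConfigDict(extra="forbid")

    edges: list[float]
    closed: Literal["left", "right"] = "left"
    scores: Optional[list[int]] = None

    @model_validator(mode="after")
    def _check(self) -> "NumericBands":
        if not self.edges:
            raise ValueError("edges must be non-empty")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")
        if self.scores is not None and len(self.scores) != len(self.edges) + 1:
            raise ValueError("scores must have len(edges)+1 entries")
        return self

    def score(self, value: float) -> int:
        if self.closed == "left":
            i = bisect_right(self.edges, value)
        else:
            i = bisect_left(self.edges, value)
        scores = self.scores or list(range(1, len(self.edges) + 2))
        return scores[i]


def _default_hazard_band_map() -> dict[str, str]:
    # R-phrase -> COSHH hazard band allocation (published scheme, abridged to
    # the phrases relevant to volatile organic solvents).
    return {
        # band A: irritants / low-toxicity
        "R36": "A", "R38": "A", "R65": "A", "R66": "A", "R67": "A",
        # band B: harmful
        "R20": "B", "R21": "B", "R22": "B", "R11": "B",
        # band C: toxic / corrosive / sensitising (skin)
        "R23": "C", "R24": "C", "R25": "C", "R34": "C", "R35": "C",
        "R37": "C", "R41": "C", "R43": "C",
        # band D: very toxic, suspected CMR, severe repeated-dose effects
        "R26": "D", "R27": "D", "R28": "D", "R40": "D",
        "R48/23": "D", "R48/24": "D", "R48/25": "D",
        "R48/23/24/25": "D", "R60": "D", "R61": "D", "R62": "D", "R63": "D",
        # band E: carcinogens / mutagens / respiratory sensitisers
        "R45": "E", "R46": "E", "R49": "E", "R42": "E", "R42/43": "E",
    }


def _default_coshh_matrix() -> dict[str, list[int]]:
    # (hazard band) -> control approach per predicted exposure band 1..4.
    # Band E always demands specialist advice (level 4) whatever the exposure.
    return {
        "A": [1, 1, 1, 2],
        "B": [1, 1, 2, 2],
        "C": [1, 2, 3, 3],
        "D": [2, 3, 3, 4],
        "E": [4, 4, 4, 4],
    }


def _default_exposure_band_matrix() -> dict[str, dict[str, int]]:
    # volatility band x quantity band -> predicted exposure band 1..4
    return {
        "low": {"small": 1, "medium": 1, "large": 2},
        "medium": {"small": 1, "medium": 2, "large": 3},
        "high": {"small": 2, "medium": 3, "large": 4},
    }


def _default_ei_numeric() -> dict[str, NumericBands]:
    return {
        # kPa; upper-inclusive: <=0.1 -> 1, (0.1,1] -> 2, (1,5] -> 3, (5,25] -> 4, >25 -> 5
        "vapor_pressure": NumericBands(edges=[0.1, 1.0, 5.0, 25.0], closed="right"),
        # kg/week; lower-inclusive decades
        "weekly_usage": NumericBands(edges=[1.0, 10.0, 100.0, 1000.0], closed="left"),
        # kg/day; same decade scale as weekly usage
        "daily_usage": NumericBands(edges=[1.0, 10.0, 100.0, 1000.0], closed="left"),
        # h/week
        "weekly_hours": NumericBands(edges=[8.0, 16.0, 24.0, 40.0], closed="left"),
        # h/day; upper-inclusive: <=2 -> 1 ... >8 -> 5
        "daily_hours": NumericBands(edges=[2.0, 4.0, 6.0, 8.0], closed="right"),
        # dimensionless E/OEL ratio, shared by the ratio method and the
        # synthesis-index E/OEL factor
        "e_over_oel": NumericBands(edges=[0.1, 0.5, 1.0, 2.0], closed="left"),
    }


def _default_ei_categorical() -> dict[str, dict[str, int]]:
    return {
        "ventilation": {"local_exhaust": 2, "general": 4, "none": 5},
        "automation": {"full": 1, "semi": 3, "manual": 5},
        "ppe": {"worn": 1, "equipped": 3, "none": 5},
        "first_aid": {"yes": 1, "no": 5},
        "emergency_measures": {"complete": 1, "partial": 3, "none": 5},
        "oh_management": {"good": 1, "poor": 3, "lacking": 5},
    }


class RubricConfig(BaseModel):
    """Every banding table of the battery, as editable data.

    The default tables reproduce the published COSHH Essentials scheme and
    the exposure-index rubrics of the Singapore guideline / GBZ/T 298-2017
    to the extent those are public; where a table is not published the
    defaults are a calibration chosen so that a benzene printing-industry
    survey reproduces the canonical banding (hazard band E, exposure band 3,
    COSHH risk 4; fully censored groups at ratio-method level 2).
    """

    model_config = ConfigDict(extra="forbid")

    lod: float = Field(default=0.02, gt=0, description="mg/m^3")
    hazard_band_map: dict[str, HazardBand] = Field(default_factory=_default_hazard_band_map)
    coshh_risk_matrix: dict[HazardBand, list[int]] = Field(default_factory=_default_coshh_matrix)
    exposure_band_matrix: dict[str, dict[str, int]] = Field(
        default_factory=_default_exposure_band_matrix
    )
    volatility_vp_high_kpa: float = Field(default=10.0, gt=0)
    volatility_bp_low_c: float = 150.0
    operating_temp_c: float = 25.0
    quantity_medium_min_kg: float = Field(default=1.0, gt=0)
    quantity_large_min_kg: float = Field(default=1000.0, gt=0)
    er_ratio_bands: NumericBands = Field(
        default_factory=lambda: NumericBands(edges=[0.1, 0.5, 1.0, 2.0], closed="left")
    )
    ei_numeric: dict[str, NumericBands] = Field(default_factory=_default_ei_numeric)
    ei_categorical: dict[str, dict[str, int]] = Field(default_factory=_default_ei_categorical)
    hr_iarc: dict[str, int] = Field(
        default_factory=lambda: {"1": 5, "2A": 4, "2B": 3, "3": 2}
    )
    hr_acgih: dict[str, int] = Field(
        default_factory=lambda: {"A1": 5, "A2": 4, "A3": 3, "A4": 2, "A5": 1}
    )
    hr_ld50_bands: NumericBands = Field(
        default_factory=lambda: NumericBands(
            edges=[25.0, 200.0, 2000.0, 5000.0], closed="left", scores=[5, 4, 3, 2, 1]
        )
    )
    hr_lc50_bands: NumericBands = Field(
        default_factory=lambda: NumericBands(
            edges=[200.0, 2000.0, 20000.0, 50000.0], closed="left", scores=[5, 4, 3, 2, 1]
        )
    )
    rounding: Literal["half_up_nearest_int"] = "half_up_nearest_int"
    epa_ec_mode: Literal["direct", "adjusted"] = "direct"
    life_expectancy_years: float = Field(default=70.0, gt=0)
    days_per_year_rule: Literal["weeks52"] = "weeks52"
    coshh_labels: dict[int, str] = Field(
        default_factory=lambda: {1: "low", 2: "medium", 3: "high", 4: "very high"}
    )
    risk_labels: dict[int, str] = Field(
        default_factory=lambda: {
            1: "negligible", 2: "low", 3: "medium", 4: "high", 5: "very high"
        }
    )

    @model_validator(mode="after")
    def _check_tables(self) -> "RubricConfig":
        for band, row in self.coshh_risk_matrix.items():
            if len(row) != 4 or any(not 1 <= v <= 4 for v in row):
                raise ValueError(f"coshh_risk_matrix[{band}] must be 4 values in 1..4")
        for vol, row in self.exposure_band_matrix.items():
            if any(not 1 <= v <= 4 for v in row.values()):
                raise ValueError(f"exposure_band_matrix[{vol}] values must be in 1..4")
        for name, table in self.ei_categorical.items():
            if any(not 1 <= v <= 5 for v in table.values()):
                raise ValueError(f"ei_categorical[{name}] values must be in 1..5")
        if self.quantity_large_min_kg <= self.quantity_medium_min_kg:
            raise ValueError("quantity_large_min_kg must exceed quantity_medium_min_kg")
        return self


def half_up(x: float) -> int:
    """Round half-up to the nearest integer (2.5 -> 3, 2.49 -> 2)."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# I/O

_DATA_DIR = Path(__file__).parent / "data"

SEG_CSV_COLUMNS = [
    "seg_id", "group", "n_workers", "duration_months", "daily_usage_kg",
    "weekly_usage_kg", "hours_per_day", "days_per_week", "c_twa", "c_stel",
    "automation", "ventilation", "ppe_equipped", "ppe_worn", "first_aid",
    "emergency_measures", "oh_management",
]

_BOOL_TOKENS = {"true": True, "false": False, "1": True, "0": False,
                "yes": True, "no": False}


def load_chemical_profile(path: str | Path) -> ChemicalProfile:
    """Load and validate a chemical hazard profile from JSON."""
    with open(path) as fh:
        raw = json.load(fh)
    return ChemicalProfile.model_validate(raw)


def load_rubric(path: str | Path) -> RubricConfig:
    """Load a banding-rubric configuration; omitted tables take defaults."""
    with open(path) as fh:
        raw = json.load(fh)
    return RubricConfig.model_validate(raw)


def benzene_profile() -> ChemicalProfile:
    """The bundled benzene profile (GBZ 2.1-2019 limits, IRIS RfC/IUR)."""
    return load_chemical_profile(_DATA_DIR / "benzene.json")


def default_rubric() -> RubricConfig:
    """The bundled default rubric (identical to ``RubricConfig()``)."""
    return load_rubric(_DATA_DIR / "rubric_default.json")


def _parse_conc(cell: str, lod: float, row: int, col: str) -> tuple[Optional[float], bool]:
    cell = cell.strip()
    if cell == "" or cell.lower() in {"na", "nan", "none"}:
        return None, False
    if cell.startswith("<"):
        rest = cell[1:].strip()
        if rest.upper() == "LOD":
            return lod, True
        value = float(rest)
        if col == "c_twa":
            # censored TWA is stored at the configured LOD regardless of the
            # number printed after "<"
            return lod, True
        return value, True
    value = float(cell)
    if value < 0:
        raise ValueError(f"row {row}: negative concentration in {col}: {cell!r}")
    return value, False


def _parse_bool(cell: str, row: int, col: str) -> bool:
    try:
        return _BOOL_TOKENS[cell.strip().lower()]
    except KeyError:
        raise ValueError(f"row {row}: unknown boolean token {cell!r} in {col}") from None


def load_seg_table(path: str | Path, rubric: RubricConfig) -> list[SEGRecord]:
    """Read a SEG survey CSV into validated records.

    Censored concentration cells carry a leading ``<``; a censored C-TWA is
    stored at the rubric's LOD with ``c_twa_censored=True``.  Lines starting
    with ``#`` (the reproducibility header) are ignored.
    """
    df = pd.read_csv(path, dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in SEG_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SEG CSV missing columns: {missing}")
    records: list[SEGRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        c_twa, twa_cens = _parse_conc(row.c_twa, rubric.lod, i, "c_twa")
        if c_twa is None:
            raise ValueError(f"row {i}: c_twa is required")
        c_stel, stel_cens = _parse_conc(row.c_stel, rubric.lod, i, "c_stel")
        try:
            rec = SEGRecord(
                seg_id=row.seg_id,
                group=row.group,
                n_workers=int(row.n_workers),
                duration_months=float(row.duration_months),
                daily_usage=float(row.daily_usage_kg),
                weekly_usage=float(row.weekly_usage_kg),
                hours_per_day=float(row.hours_per_day),
                days_per_week=float(row.days_per_week),
                c_twa=c_twa,
                c_twa_censored=twa_cens,
                c_stel=c_stel,
                c_stel_censored=stel_cens,
                controls=ControlProfile(
                    automation=row.automation,
                    ventilation=row.ventilation,
                    ppe_equipped=_parse_bool(row.ppe_equipped, i, "ppe_equipped"),
                    ppe_worn=_parse_bool(row.ppe_worn, i, "ppe_worn"),
                    first_aid=_parse_bool(row.first_aid, i, "first_aid"),
                    emergency_measures=row.emergency_measures,
                    oh_management=row.oh_management,
                ),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def _fmt(value: float) -> str:
    s = format(value, "g")
    return s


def write_seg_table(
    records: Sequence[SEGRecord],
    path: str | Path,
    rubric: RubricConfig,
    header_comment: Optional[str] = None,
) -> None:
    """Write records back to the SEG CSV schema, restoring ``<`` markers."""
    rows = []
    for r in records:
        c_twa = f"<{_fmt(rubric.lod)}" if r.c_twa_censored else _fmt(r.c_twa)
        if r.c_stel is None:
            c_stel = ""
        elif r.c_stel_censored:
            c_stel = f"<{_fmt(r.c_stel)}"
        else:
            c_stel = _fmt(r.c_stel)
        rows.append({
            "seg_id": r.seg_id,
            "group": r.group,
            "n_workers": str(r.n_workers),
            "duration_months": _fmt(r.duration_months),
            "daily_usage_kg": _fmt(r.daily_usage),
            "weekly_usage_kg": _fmt(r.weekly_usage),
            "hours_per_day": _fmt(r.hours_per_day),
            "days_per_week": _fmt(r.days_per_week),
            "c_twa": c_twa,
            "c_stel": c_stel,
            "automation": r.controls.automation,
            "ventilation": r.controls.ventilation,
            "ppe_equipped": str(r.controls.ppe_equipped).lower(),
            "ppe_worn": str(r.controls.ppe_worn).lower(),
            "first_aid": str(r.controls.first_aid).lower(),
            "emergency_measures": r.controls.emergency_measures,
            "oh_management": r.controls.oh_management,
        })
    df = pd.DataFrame(rows, columns=SEG_CSV_COLUMNS)
    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


class GroupSummary(BaseModel):
    """Censoring-aware concentration summary of one work group."""

    n: int
    n_censored: int
    mean: float
    min: float
    min_censored: bool
    max: float
    max_censored: bool
    exceed_count: int
    exceed_fraction: float


def summarize_group(records: Sequence[SEGRecord], limit: float) -> GroupSummary:
    """Summarise a group's C-TWA values against a permissible limit.

    Censored values enter the mean at the LOD (at which they are stored).
    Exceedance is strict (> limit); a value exactly at the limit is
    compliant, and a censored value never exceeds.
    """
    if not records:
        raise ValueError("summarize_group requires a non-empty record list")
    values = [(r.c_twa, r.c_twa_censored) for r in records]
    n = len(values)
    mean = sum(v for v, _ in values) / n
    vmin, min_cens = min(values, key=lambda t: t[0])
    vmax, max_cens = max(values, key=lambda t: t[0])
    exceed = sum(1 for v, cens in values if not cens and v > limit)
    return GroupSummary(
        n=n,
        n_censored=sum(1 for _, c in values if c),
        mean=mean,
        min=vmin,
        min_censored=min_cens,
        max=vmax,
        max_censored=max_cens,
        exceed_count=exceed,
        exceed_fraction=exceed / n,
    )
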