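import pytest

from ohra.profiles import (
    ChemicalProfile,
    ControlProfile,
    RubricConfig,
    SEGRecord,
    benzene_profile,
    default_rubric,
)


@pytest.fixture(scope="session")
def benzene() -> ChemicalProfile:
    return benzene_profile()


@pytest.fixture(scope="session")
def rubric() -> RubricConfig:
    return default_rubric()


def make_seg(**overrides) -> SEGRecord:
    """A printing-group SEG with survey-typical defaults; fields overridable."""
    controls = overrides.pop("controls", None) or ControlProfile(
        automation="full",
        ventilation="local_exhaust",
        ppe_equipped=True,
        ppe_worn=True,
        first_aid=True,
        emergency_measures="complete",
        oh_management="good",
    )
    base = dict(
        seg_id="printing-01",
        group="printing",
        n_workers=10,
        duration_months=200,
        daily_usage=104.7,
        weekly_usage=596.8,
        hours_per_day=8.7,
        days_per_week=5.3,
        c_twa=4.67,
        c_twa_censored=False,
        controls=controls,
    )
    base.update(overrides)
    return SEGRecord(**base)


def make_cleaning_seg(i: int = 1) -> SEGRecord:
    """A fully censored cleaning-group SEG (C-TWA below the 0.02 LOD)."""
    return make_seg(
        seg_id=f"cleaning-{i:02d}",
        group="cleaning",
        n_workers=5,
        duration_months=184,
        daily_usage=68.0,
        weekly_usage=331.9,
        c_twa=0.02,
        c_twa_censored=True,
        controls=ControlProfile(
            automation="semi",
            ventilation="general",
            ppe_equipped=True,
            ppe_worn=False,
            first_aid=False,
            emergency_measures="partial",
            oh_management="good",
        ),
    )


@pytest.fixture()
def printing_seg() -> SEGRecord:
    return make_seg()


@pytest.fixture()
def cleaning_segs() -> list[SEGRecord]:
    return [make_cleaning_seg(i) for i in range(1, 4)]
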