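import json

import pytest
from hypothesis import given, settings, strategies as st
from pydantic import ValidationError

from ohra.profiles import (
    ChemicalProfile,
    NumericBands,
    RubricConfig,
    load_chemical_profile,
    load_seg_table,
    summarize_group,
    write_seg_table,
)
from conftest import make_seg

SEG_CSV = """seg_id,group,n_workers,duration_months,daily_usage_kg,weekly_usage_kg,hours_per_day,days_per_week,c_twa,c_stel,automation,ventilation,ppe_equipped,ppe_worn,first_aid,emergency_measures,oh_management
p1,printing,10,200,104.7,596.8,8.7,5.3,4.67,<0.07,full,local_exhaust,true,true,true,complete,good
c1,cleaning,5,184,68,331.9,8.7,5.3,<0.02,,semi,general,true,false,false,partial,good
"""


class TestChemicalProfile:
    def test_bundled_benzene_constants(self, benzene):
        assert benzene.pc_twa == 6.0
        assert benzene.vapor_pressure_25c == 12.66
        assert benzene.boiling_point == 80.1
        assert benzene.iarc_group == "1"

    def test_stel_limit_defaults_to_twice_twa(self):
        p = ChemicalProfile(
            name="x", iarc_group="1", vapor_pressure_25c=1.0, boiling_point=100.0,
            pc_twa=3.0, rfc=0.1, iur=1e-6,
        )
        assert p.pc_stel_limit == 6.0

    def test_profile_without_any_classification_rejected(self, tmp_path):
        raw = {
            "name": "x", "vapor_pressure_25c": 1.0, "boiling_point": 100.0,
            "pc_twa": 3.0, "rfc": 0.1, "iur": 1e-6,
        }
        path = tmp_path / "x.json"
        path.write_text(json.dumps(raw))
        with pytest.raises(ValidationError, match="classification"):
            load_chemical_profile(path)

    @pytest.mark.parametrize("field", ["pc_twa", "rfc", "iur", "vapor_pressure_25c"])
    def test_non_positive_constants_rejected(self, field):
        raw = dict(name="x", iarc_group="1", vapor_pressure_25c=1.0,
                   boiling_point=100.0, pc_twa=3.0, rfc=0.1, iur=1e-6)
        raw[field] = 0.0
        with pytest.raises(ValidationError):
            ChemicalProfile(**raw)


class TestSegTable:
    def test_censored_and_plain_cells(self, tmp_path, rubric):
        path = tmp_path / "segs.csv"
        path.write_text(SEG_CSV)
        records = load_seg_table(path, rubric)
        assert len(records) == 2
        p1, c1 = records
        assert (p1.c_twa, p1.c_twa_censored) == (4.67, False)
        assert (c1.c_twa, c1.c_twa_censored) == (rubric.lod, True)
        assert (p1.c_stel, p1.c_stel_censored) == (0.07, True)
        assert c1.c_stel is None

    def test_negative_concentration_rejected_with_row_number(self, tmp_path, rubric):
        path = tmp_path / "segs.csv"
        path.write_text(SEG_CSV.replace("4.67", "-1"))
        with pytest.raises(ValueError, match="row 1"):
            load_seg_table(path, rubric)

    def test_unknown_enumeration_token_rejected(self, tmp_path, rubric):
        path = tmp_path / "segs.csv"
        path.write_text(SEG_CSV.replace("local_exhaust", "windows"))
        with pytest.raises(ValueError, match="row 1"):
            load_seg_table(path, rubric)

    def test_excessive_hours_rejected(self, tmp_path, rubric):
        path = tmp_path / "segs.csv"
        path.write_text(SEG_CSV.replace(",8.7,5.3,4.67", ",25,5.3,4.67"))
        with pytest.raises(ValueError, match="row 1"):
            load_seg_table(path, rubric)

    def test_round_trip_is_byte_identical(self, tmp_path, rubric):
        first = tmp_path / "a.csv"
        second = tmp_path / "b.csv"
        records = [make_seg(), make_seg(seg_id="c1", group="cleaning",
                                        c_twa=0.02, c_twa_censored=True,
                                        c_stel=0.07, c_stel_censored=True)]
        write_seg_table(records, first, rubric)
        write_seg_table(load_seg_table(first, rubric), second, rubric)
        assert first.read_bytes() == second.read_bytes()
        assert "<0.02" in first.read_text() and "<0.07" in first.read_text()


class TestRecordValidation:
    def test_ppe_worn_requires_equipped(self):
        from ohra.profiles import ControlProfile
        with pytest.raises(ValidationError):
            ControlProfile(ppe_equipped=False, ppe_worn=True)

    def test_weekly_usage_below_daily_rejected(self):
        with pytest.raises(ValidationError):
            make_seg(daily_usage=10.0, weekly_usage=5.0)

    @given(
        hours=st.floats(-5, 40, allow_nan=False),
        days=st.floats(-2, 10, allow_nan=False),
        c_twa=st.floats(-1, 30, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_validation_matches_documented_legal_region(self, hours, days, c_twa):
        legal = 0 < hours <= 24 and 0 < days <= 7 and c_twa >= 0
        try:
            make_seg(hours_per_day=hours, days_per_week=days, c_twa=c_twa)
        except ValidationError:
            assert not legal
        else:
            assert legal


class TestGroupSummary:
    def test_printing_like_group(self):
        values = [24.08, 20.0, 2.5, 1.0, 0.2]
        records = [make_seg(seg_id=f"s{i}", c_twa=v) for i, v in enumerate(values)]
        records += [make_seg(seg_id=f"cens{i}", c_twa=0.02, c_twa_censored=True)
                    for i in range(2)]
        s = summarize_group(records, limit=6.0)
        assert s.mean == pytest.approx(6.83, abs=0.005)
        assert s.max == 24.08 and not s.max_censored
        assert s.min == 0.02 and s.min_censored
        assert (s.exceed_count, s.n_censored) == (2, 2)

    def test_all_censored(self):
        records = [make_seg(seg_id=f"s{i}", c_twa=0.02, c_twa_censored=True)
                   for i in range(3)]
        s = summarize_group(records, limit=6.0)
        assert s.mean == pytest.approx(0.02)
        assert s.exceed_count == 0

    def test_value_at_limit_is_compliant(self):
        s = summarize_group([make_seg(c_twa=6.0)], limit=6.0)
        assert s.exceed_count == 0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([], limit=6.0)

    @given(st.lists(st.floats(0, 50, allow_nan=False), min_size=1, max_size=8),
           st.integers(0, 7), st.floats(0.1, 20))
    @settings(max_examples=100, derandomize=True)
    def test_mean_monotone_in_each_member(self, values, idx, bump):
        records = [make_seg(seg_id=f"s{i}", c_twa=v) for i, v in enumerate(values)]
        base = summarize_group(records, limit=6.0).mean
        i = idx % len(values)
        records[i] = make_seg(seg_id=f"s{i}", c_twa=values[i] + bump)
        assert summarize_group(records, limit=6.0).mean >= base


class TestNumericBands:
    def test_closure_sides(self):
        right = NumericBands(edges=[0.1, 1, 5, 25], closed="right")
        assert [right.score(v) for v in (0.1, 0.2, 1.0, 12.66, 25.0, 26)] == [1, 2, 2, 4, 4, 5]
        left = NumericBands(edges=[1, 10, 100, 1000], closed="left")
        assert [left.score(v) for v in (0.5, 1.0, 9.99, 10, 1000)] == [1, 2, 2, 3, 5]

    def test_descending_scores(self):
        bands = NumericBands(edges=[25, 200, 2000, 5000], closed="left",
                             scores=[5, 4, 3, 2, 1])
        assert bands.score(6000) == 1 and bands.score(10) == 5

    def test_bad_tables_rejected(self):
        with pytest.raises(ValueError):
            NumericBands(edges=[5, 1])
        with pytest.raises(ValueError):
            NumericBands(edges=[1, 2], scores=[1, 2])
        with pytest.raises(ValueError):
            RubricConfig(coshh_risk_matrix={"A": [1, 2, 3]})
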