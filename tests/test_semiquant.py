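import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ohra.profiles import ChemicalProfile
from ohra.semiquant import (
    SEMIQUANT_METHODS,
    compute_weekly_exposure,
    determine_hr,
    er_from_ratio,
    er_geometric,
    risk_from_hr_er,
    run_model,
    score_ei,
)
from conftest import make_cleaning_seg, make_seg


def _profile(**overrides) -> ChemicalProfile:
    base = dict(name="x", vapor_pressure_25c=1.0, boiling_point=100.0,
                pc_twa=6.0, rfc=0.03, iur=1e-6)
    base.update(overrides)
    return ChemicalProfile(**base)


class TestHazardRating:
    def test_benzene_confirmed_carcinogen(self, benzene, rubric):
        hr = determine_hr(benzene, rubric)
        assert (hr.hr, hr.basis) == (5, "iarc_acgih")

    def test_ld50_fallback_least_toxic_band(self, rubric):
        hr = determine_hr(_profile(oral_ld50=6000.0), rubric)
        assert (hr.hr, hr.basis) == (1, "ld50")

    def test_classification_takes_precedence_over_ld50(self, rubric):
        hr = determine_hr(_profile(iarc_group="2B", oral_ld50=10.0), rubric)
        assert (hr.hr, hr.basis) == (3, "iarc_acgih")

    def test_lc50_is_last_resort(self, rubric):
        hr = determine_hr(_profile(inhal_lc50=150.0), rubric)
        assert (hr.hr, hr.basis) == (5, "lc50")


class TestWeeklyExposure:
    @pytest.mark.parametrize("f,d,m,w,expected", [
        (5, 8, 6, 40, 6.0),            # F*D = W: E reduces to the C-TWA
        (5.3, 8.7, 0.02, 46.11, 0.02),
        (2, 4, 10, 40, 2.0),
    ])
    def test_formula(self, f, d, m, w, expected):
        assert compute_weekly_exposure(f, d, m, w) == pytest.approx(expected, rel=1e-3)

    def test_zero_weekly_hours_rejected(self):
        with pytest.raises(ValueError):
            compute_weekly_exposure(5, 8, 6, 0)


class TestExposureBands:
    @pytest.mark.parametrize("ratio,er", [
        (0.003, 1), (0.09, 1), (0.1, 2), (0.49, 2), (0.5, 3), (0.78, 3),
        (0.99, 3), (1.0, 4), (1.99, 4), (2.0, 5), (4.01, 5),
    ])
    def test_ratio_banding(self, ratio, er, rubric):
        assert er_from_ratio(ratio, rubric) == er

    def test_negative_ratio_rejected(self, rubric):
        with pytest.raises(ValueError):
            er_from_ratio(-0.1, rubric)

    @pytest.mark.parametrize("factor,value,ei", [
        ("vapor_pressure", 12.66, 4),
        ("weekly_usage", 331.9, 4),
        ("weekly_hours", 46.1, 5),
        ("daily_hours", 8.7, 5),
        ("daily_usage", 68.0, 3),
        ("ventilation", "general", 4),
        ("ppe", "equipped", 3),
        ("oh_management", "good", 1),
    ])
    def test_ei_rubrics(self, factor, value, ei, rubric):
        assert score_ei(factor, value, rubric) == ei

    def test_unknown_factor_lists_known_ones(self, rubric):
        with pytest.raises(ValueError, match="vapor_pressure"):
            score_ei("particle_size", 1.0, rubric)

    def test_unknown_category_rejected(self, rubric):
        with pytest.raises(ValueError, match="ventilation|category"):
            score_ei("ventilation", "windows", rubric)


class TestGeometricMean:
    @pytest.mark.parametrize("indices,expected", [
        ([4, 4], 4.0), ([1, 4], 2.0), ([4, 4, 4, 5], 320 ** 0.25),
    ])
    def test_values(self, indices, expected):
        assert er_geometric(indices) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            er_geometric([])

    @given(st.lists(st.integers(1, 5), min_size=1, max_size=8), st.randoms())
    @settings(max_examples=200, derandomize=True)
    def test_bounded_by_extremes_and_permutation_invariant(self, indices, rnd):
        g = er_geometric(indices)
        assert min(indices) - 1e-12 <= g <= max(indices) + 1e-12
        shuffled = list(indices)
        rnd.shuffle(shuffled)
        assert er_geometric(shuffled) == pytest.approx(g, rel=1e-12)


class TestRiskCombination:
    def test_maximum(self, rubric):
        r = risk_from_hr_er(5, 5.0, rubric)
        assert (r.risk_score, r.risk_level) == (5.0, 5)

    def test_half_up_keeps_sqrt5_at_level_2(self, rubric):
        r = risk_from_hr_er(5, 1.0, rubric)
        assert r.risk_score == pytest.approx(math.sqrt(5), rel=1e-12)
        assert r.risk_level == 2  # 2.236 rounds down; never up to 3

    def test_cleaning_singapore_pattern(self, rubric):
        r = risk_from_hr_er(5, er_geometric([4, 4, 4, 5]), rubric)
        assert r.risk_score == pytest.approx(4.60, abs=0.005)
        assert r.risk_level == 5

    def test_out_of_range_rejected(self, rubric):
        with pytest.raises(ValueError):
            risk_from_hr_er(6, 1.0, rubric)
        with pytest.raises(ValueError):
            risk_from_hr_er(5, 0.5, rubric)

    def test_exact_half_rounds_up(self, rubric):
        # sqrt(2*3.125) = 2.5 exactly
        assert risk_from_hr_er(2, 3.125, rubric).risk_level == 3


class TestRunModel:
    def test_cleaning_ratio_level_2(self, benzene, rubric):
        r = run_model(make_cleaning_seg(), benzene, rubric, "ratio")
        assert r.e_over_oel == pytest.approx(0.02 / 6.0, rel=1e-3)
        assert (r.hr.hr, r.er.er, r.risk_level) == (5, 1.0, 2)

    def test_cleaning_singapore_level_5(self, benzene, rubric):
        r = run_model(make_cleaning_seg(), benzene, rubric, "singapore_ei")
        assert r.er.indices == {
            "control_measures": 4, "weekly_usage": 4, "vapor_pressure": 4,
            "weekly_hours": 5,
        }
        assert r.risk_level == 5

    def test_index_methods_floor_at_level_2_for_hr5(self, rubric, benzene):
        assert risk_from_hr_er(5, er_geometric([1] * 7), rubric).risk_level == 2

    def test_synthesis_adds_ratio_index(self, benzene, rubric):
        seg = make_cleaning_seg()
        cn = run_model(seg, benzene, rubric, "chinese_ei")
        syn = run_model(seg, benzene, rubric, "synthesis")
        assert set(syn.er.indices) == set(cn.er.indices) | {"e_over_oel"}
        # clean air (EI 1 below every other index) pulls the rating down
        assert syn.er.er <= cn.er.er

    def test_unknown_method_rejected(self, benzene, rubric):
        with pytest.raises(ValueError, match="unknown method"):
            run_model(make_seg(), benzene, rubric, "delphi")


class TestMonotonicity:
    def test_level_monotone_over_hr_er_lattice(self, rubric):
        er_grid = [1.0 + 0.25 * i for i in range(17)]
        for hr, (i, er) in itertools.product(range(1, 6), enumerate(er_grid)):
            level = risk_from_hr_er(hr, er, rubric).risk_level
            if hr < 5:
                assert risk_from_hr_er(hr + 1, er, rubric).risk_level >= level
            if i + 1 < len(er_grid):
                assert risk_from_hr_er(hr, er_grid[i + 1], rubric).risk_level >= level

    def test_ratio_level_is_step_function_of_concentration(self, benzene, rubric):
        # brute-force scan: level depends on C-TWA only through the E/OEL band
        concs = np.linspace(0.001, 30, 1500)
        levels = [run_model(make_seg(c_twa=c), benzene, rubric, "ratio").risk_level
                  for c in concs]
        expected = [risk_from_hr_er(5, er_from_ratio(c / 6.0, rubric), rubric).risk_level
                    for c in concs]
        assert levels == expected
        assert all(b >= a for a, b in zip(levels, levels[1:]))
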