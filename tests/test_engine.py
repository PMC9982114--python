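import math

import pytest
from hypothesis import given, settings, strategies as st

from haus.engine import (
    attributable_cases,
    attributable_deaths,
    attributable_yld,
    attributable_yll,
    mc_oracle,
    yld_per_case,
)
from haus.errors import EvaluationError, ValidationError
from haus.population import PopulationProfile, Stratum, split_exposure


def single_stratum(le, count=1.0):
    return PopulationProfile(
        strata=(Stratum(age=0, count=count, life_expectancy=le),), label="s"
    )


class TestAttributableDeaths:
    def test_null_effect_at_or_one(self):
        res = attributable_deaths(split_exposure(5_000, 0.4), 0.02, 1.0)
        assert res.Dattributed == 0

    def test_hand_arithmetic_harmful(self):
        # 10000 * 0.3 * 0.01 * (1.5 - 1) = 15
        res = attributable_deaths(split_exposure(10_000, 0.3), 0.01, 1.5)
        assert res.Dattributed == pytest.approx(15)
        assert res.Dexpected == pytest.approx(100)

    def test_hand_arithmetic_protective(self):
        # 1000 * 0.5 * 0.02 * (0.8 - 1) = -2
        res = attributable_deaths(split_exposure(1_000, 0.5), 0.02, 0.8)
        assert res.Dattributed == pytest.approx(-2)

    def test_rate_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="haus.engine"):
            res = attributable_deaths(split_exposure(100, 1.0), 0.6, 3.0)
        assert res.MRe == 1.0
        assert any("clamped" in r.message for r in caplog.records)

    def test_unexposed_rate_is_literature_rate(self):
        res = attributable_deaths(split_exposure(100, 0.5), 0.01, 2.0)
        assert res.MRu == 0.01
        assert res.MRe == 0.02

    def test_invalid_inputs_rejected(self):
        split = split_exposure(100, 0.5)
        with pytest.raises(ValidationError):
            attributable_deaths(split, 1.2, 1.0)
        with pytest.raises(ValidationError):
            attributable_deaths(split, 0.1, 0.0)


class TestAttributableYll:
    def test_null_effect(self):
        res = attributable_deaths(split_exposure(100, 0.5), 0.01, 1.0)
        assert attributable_yll(res, 40).YLLattributed == 0

    def test_hand_arithmetic(self):
        res = attributable_deaths(split_exposure(10_000, 0.3), 0.01, 1.5)
        out = attributable_yll(res, 40)
        assert out.YLLattributed == pytest.approx(600)

    def test_sign_preserved_for_protective(self):
        res = attributable_deaths(split_exposure(1_000, 0.5), 0.02, 0.8)
        assert attributable_yll(res, 35).YLLattributed == pytest.approx(-70)

    def test_transparency_fields(self):
        res = attributable_deaths(split_exposure(1_000, 0.5), 0.02, 0.8)
        out = attributable_yll(res, 35)
        assert out.YLLe == pytest.approx(35 * res.De)
        assert out.YLLu == pytest.approx(35 * res.Du)


class TestAttributableCases:
    def test_null_effect_at_or_one(self):
        assert attributable_cases(split_exposure(500, 0.5), 0.1, 1.0).Cattributed == 0

    def test_hand_arithmetic_full_result(self):
        res = attributable_cases(split_exposure(1_000, 0.5), 0.1, 1.2)
        assert res.Ce == pytest.approx(60)
        assert res.Cu == pytest.approx(50)
        assert res.Cexpected == pytest.approx(100)
        assert res.Cattributed == pytest.approx(10)

    def test_no_exposure_no_attribution(self):
        res = attributable_cases(split_exposure(1_000, 0.0), 0.1, 3.0)
        assert res.Cattributed == 0

    def test_decomposition_expected_equals_cu_plus_unscaled_exposed(self):
        split = split_exposure(1_234, 0.37)
        res = attributable_cases(split, 0.05, 1.4)
        assert res.Cexpected == pytest.approx(res.Cu + split.ne * 0.05)


class TestAttributableYld:
    def test_cap_not_binding(self):
        pop = single_stratum(le=30)
        assert yld_per_case(2.0, pop) == 2.0

    def test_cap_binding_forces_le(self):
        pop = single_stratum(le=30)
        assert yld_per_case(50.0, pop) == 30.0

    def test_cap_applied_per_stratum_before_averaging(self):
        pop = PopulationProfile(
            strata=(
                Stratum(age=0, count=1, life_expectancy=10),
                Stratum(age=1, count=1, life_expectancy=100),
            ),
            label="mix",
        )
        # per-stratum: min(50,10)=10, min(50,100)=50 -> mean 30 (not min(50,55)=50)
        assert yld_per_case(50.0, pop) == pytest.approx(30.0)

    def test_zero_attributed_gives_zero(self):
        assert attributable_yld(0.0, 5.0, single_stratum(40)) == 0

    def test_empty_profile_is_error(self):
        empty = PopulationProfile(strata=(), label="empty")
        with pytest.raises(EvaluationError):
            attributable_yld(1.0, 5.0, empty)


class TestMcOracle:
    def test_null_effect_within_three_se(self):
        mean, se = mc_oracle(split_exposure(2_000, 0.5), 0.05, 1.0, reps=500, seed=3)
        assert abs(mean) <= 3 * se

    def test_matches_closed_form_example(self):
        mean, se = mc_oracle(split_exposure(10_000, 0.3), 0.01, 1.5, reps=2_000, seed=11)
        assert abs(mean - 15) <= 3 * se

    def test_zero_rate_gives_exact_zero(self):
        mean, se = mc_oracle(split_exposure(1_000, 0.5), 0.0, 2.0, reps=50, seed=1)
        assert mean == 0 and se == 0

    def test_reproducible_under_seed(self):
        a = mc_oracle(split_exposure(1_000, 0.2), 0.03, 1.3, reps=200, seed=42)
        b = mc_oracle(split_exposure(1_000, 0.2), 0.03, 1.3, reps=200, seed=42)
        assert a == b

    def test_fractional_persons_rejected(self):
        with pytest.raises(ValidationError):
            mc_oracle(split_exposure(1_001, 0.5), 0.01, 1.2, reps=10, seed=0)


class TestProperties:
    @given(
        pe=st.floats(min_value=0, max_value=1),
        rate=st.floats(min_value=0, max_value=1),
        n=st.floats(min_value=1, max_value=1e7),
    )
    def test_null_calibration_or_one(self, pe, rate, n):
        split = split_exposure(n, pe)
        assert attributable_deaths(split, rate, 1.0).Dattributed == 0
        assert attributable_cases(split, rate, 1.0).Cattributed == 0

    @given(
        k=st.floats(min_value=0.001, max_value=1e4),
        pe=st.floats(min_value=0.01, max_value=1),
        rate=st.floats(min_value=1e-6, max_value=0.5),
        odds=st.floats(min_value=0.1, max_value=1.9),
    )
    def test_linearity_in_population_scale(self, k, pe, rate, odds):
        a = attributable_cases(split_exposure(1_000, pe), rate, odds)
        b = attributable_cases(split_exposure(1_000 * k, pe), rate, odds)
        assert b.Cattributed == pytest.approx(k * a.Cattributed, rel=1e-9, abs=1e-12)

    @given(
        or_lo=st.floats(min_value=0.2, max_value=5),
        delta=st.floats(min_value=1e-6, max_value=2),
    )
    def test_strict_monotonicity_in_odds_ratio(self, or_lo, delta):
        split = split_exposure(10_000, 0.5)
        rate = 0.01  # keeps rate*OR below the clamp
        lo = attributable_cases(split, rate, or_lo).Cattributed
        hi = attributable_cases(split, rate, or_lo + delta).Cattributed
        assert hi > lo

    @settings(deadline=None)
    @given(
        tsick=st.floats(min_value=0.1, max_value=120),
        les=st.lists(st.floats(min_value=0.5, max_value=100), min_size=1, max_size=8),
    )
    def test_yld_per_case_never_exceeds_tsick_or_max_le(self, tsick, les):
        pop = PopulationProfile(
            strata=tuple(
                Stratum(age=i, count=1.0, life_expectancy=le)
                for i, le in enumerate(les)
            ),
            label="h",
        )
        per_case = yld_per_case(tsick, pop)
        assert per_case <= tsick + 1e-12
        assert per_case <= max(les) + 1e-12

    def test_oracle_equivalence_on_small_grid(self):
        # acceptance runs the full 27-point grid; this is a fast 8-point slice
        for n in (1_000, 10_000):
            for pe in (0.2, 0.8):
                for odds in (0.7, 1.5):
                    split = split_exposure(n, pe)
                    closed = attributable_cases(split, 0.02, odds).Cattributed
                    mean, se = mc_oracle(split, 0.02, odds, reps=1_000, seed=n + int(10 * pe))
                    assert abs(mean - closed) <= 3 * se, (n, pe, odds)

    def test_attributed_is_finite_difference_of_totals(self):
        split = split_exposure(5_000, 0.3)
        res = attributable_cases(split, 0.04, 1.25)
        assert res.Cattributed == pytest.approx((res.Ce + res.Cu) - res.Cexpected)
        assert math.isfinite(res.Cattributed)
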