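import dataclasses
import math

import pytest

from haus.errors import AggregationError, ConfigurationError, ValidationError
from haus.runner import (
    compare_scenarios,
    percent_change,
    run_scenario,
    sensitivity_sweep,
)


def row_by(rows, environment_change, outcome):
    matches = [
        r
        for r in rows
        if r.environment_change == environment_change and r.outcome == outcome
    ]
    assert len(matches) == 1, (environment_change, outcome, len(matches))
    return matches[0]


class TestPercentChange:
    def test_park_use_diabetes_row(self):
        assert percent_change(-3, 20) == -15

    def test_proximity_mental_health_row(self):
        assert percent_change(125, 463) == 27

    def test_null_effect(self):
        assert percent_change(0, 100) == 0

    def test_zero_expected_is_dash(self):
        assert percent_change(5, 0) is None

    def test_half_away_from_zero(self):
        assert percent_change(5, 200) == 3  # 2.5 -> 3
        assert percent_change(-5, 200) == -3  # -2.5 -> -3

    def test_negative_expected_rejected(self):
        with pytest.raises(ValidationError):
            percent_change(1, -1)


class TestRunScenario:
    def test_baseline_table_structure(self, frome_baseline_rows):
        morbidity_outcomes = {"cancer_mouth_throat", "asthma", "weight_gain", "diabetes"}
        morbidity = [r for r in frome_baseline_rows if r.outcome in morbidity_outcomes]
        assert len(morbidity) == 7
        labels = {(r.population_label, round(r.N)) for r in frome_baseline_rows}
        assert ("Adults >18", 6_927) in labels
        assert ("Adults >35", 3_262) in labels
        assert ("Adults >65", 588) in labels
        assert ("Men >18", 3_616) in labels
        assert ("Children 9–12", 583) in labels
        assert ("Children <7", 1_223) in labels

    def test_baseline_expected_and_attributable_pairs(self, frome_baseline_rows):
        cases = {
            ("Park use", "diabetes"): (20, -3),
            ("Park use", "weight_gain"): (979, -127),
            ("Proximity to green space", "asthma"): (8, 5),
            ("Proximity to green space", "activity"): (4_295, 2_632),
            ("Proximity to green space", "mental_health"): (463, 125),
            ("Proximity to large, attractive, open space", "activity_large_space"): (3_671, 1_432),
        }
        for (change, outcome), (expected, attributed) in cases.items():
            row = row_by(frome_baseline_rows, change, outcome)
            assert row.cases_expected == pytest.approx(expected, rel=1e-9)
            assert row.attributable == pytest.approx(attributed, rel=1e-9)

    def test_inactive_pathways_render_dash(self, frome_baseline_rows):
        row = row_by(frome_baseline_rows, "Park improvements", "park_use")
        assert not row.active
        assert row.attributable is None
        assert row.pct_change is None
        assert row.value_total is None

    def test_all_pe_zero_gives_zero_attribution(self, frome):
        sc = frome.scenarios["baseline"]
        zeroed = dataclasses.replace(
            sc, pathway_exposure={k: 0.0 for k in sc.pathway_exposure}
        )
        rows = run_scenario(
            zeroed, frome.pathways, frome.population, frome.rates, frome.unit_values
        )
        assert all(r.attributable == 0 for r in rows if r.active)

    def test_missing_threshold_metric_fails_fast(self, frome):
        sc = frome.scenarios["baseline"]
        broken = dataclasses.replace(
            sc,
            metrics={
                k: v
                for k, v in sc.metrics.items()
                if k != "largest_contiguous_open_space_ha"
            },
        )
        with pytest.raises(ConfigurationError, match="largest_contiguous_open_space_ha"):
            run_scenario(
                broken, frome.pathways, frome.population, frome.rates, frome.unit_values
            )

    def test_missing_unit_value_fails_fast(self, frome):
        uvs = {k: v for k, v in frome.unit_values.items() if k != "diabetes"}
        with pytest.raises(ConfigurationError, match="diabetes"):
            run_scenario(
                frome.scenarios["baseline"],
                frome.pathways,
                frome.population,
                frome.rates,
                uvs,
            )

    def test_pct_change_consistent_with_operation(self, frome_scenario_rows):
        for rows in frome_scenario_rows.values():
            for r in rows:
                if r.active and r.cases_expected > 0:
                    assert r.pct_change == percent_change(r.attributable, r.cases_expected)

    def test_scenario_monotone_in_exposure(self, frome):
        sc = frome.scenarios["baseline"]
        target = "gs-prox-asthma-child"  # OR > 1

        def attributed(pe):
            exposure = dict(sc.pathway_exposure)
            exposure[target] = pe
            rows = run_scenario(
                dataclasses.replace(sc, pathway_exposure=exposure),
                frome.pathways,
                frome.population,
                frome.rates,
                frome.unit_values,
            )
            return row_by(rows, "Proximity to green space", "asthma").attributable

        values = [attributed(pe) for pe in (0.0, 0.25, 0.5, 1.0)]
        assert values == sorted(values)


class TestCompareScenarios:
    def test_open_space_diabetes_only_in_single_park_scenario(self, frome_scenario_rows):
        table = compare_scenarios(
            frome_scenario_rows["baseline"],
            [
                ("s2", frome_scenario_rows["s2_single_open_space"]),
                ("s3", frome_scenario_rows["s3_dispersed_open_space"]),
            ],
        )
        row = table[
            (table.environment_change == "Size of public open spaces")
            & (table.outcome == "diabetes")
        ].iloc[0]
        assert row["s2"] == pytest.approx(-10)
        assert math.isnan(row["s3"])
        assert math.isnan(row["Baseline"])

    def test_identical_scenarios_identical_columns(self, frome_baseline_rows):
        table = compare_scenarios(
            frome_baseline_rows, [("again", frome_baseline_rows)]
        )
        a, b = table["Baseline"], table["again"]
        assert ((a == b) | (a.isna() & b.isna())).all()

    def test_empty_scenario_list_gives_baseline_only(self, frome_baseline_rows):
        table = compare_scenarios(frome_baseline_rows, [])
        assert list(table.columns) == ["environment_change", "outcome", "Baseline"]

    def test_totals_row_flags_double_counting(self, frome_baseline_rows):
        table = compare_scenarios(frome_baseline_rows, [])
        assert "not adjusted for double counting" in table.iloc[-1].environment_change

    def test_duplicate_keys_rejected(self, frome_baseline_rows):
        doubled = list(frome_baseline_rows) + [frome_baseline_rows[0]]
        with pytest.raises(AggregationError):
            compare_scenarios(doubled, [])


class TestSensitivitySweep:
    def test_mortality_appears_only_above_threshold(self, frome):
        sc = frome.scenarios["baseline"]
        results = sensitivity_sweep(
            sc,
            "ndvi_increase",
            [0.15, 0.24],
            frome.pathways,
            frome.population,
            frome.rates,
            frome.unit_values,
        )
        below = row_by(results[0][1], "NDVI increase", "all_cause_mortality")
        above = row_by(results[1][1], "NDVI increase", "all_cause_mortality")
        assert below.attributable is None
        assert above.attributable == pytest.approx(-3.0, rel=1e-9)

    def test_identity_value_matches_plain_run(self, frome, frome_baseline_rows):
        sc = frome.scenarios["baseline"]
        results = sensitivity_sweep(
            sc,
            "ndvi_increase",
            [sc.metrics["ndvi_increase"]],
            frome.pathways,
            frome.population,
            frome.rates,
            frome.unit_values,
        )
        assert results[0][1] == frome_baseline_rows

    def test_three_values_three_reports_in_order(self, frome):
        sc = frome.scenarios["baseline"]
        results = sensitivity_sweep(
            sc,
            "ndvi_increase",
            [0.0, 0.1, 0.3],
            frome.pathways,
            frome.population,
            frome.rates,
            frome.unit_values,
        )
        assert [v for v, _ in results] == [0.0, 0.1, 0.3]

    def test_empty_values_rejected(self, frome):
        with pytest.raises(ValidationError):
            sensitivity_sweep(
                frome.scenarios["baseline"],
                "ndvi_increase",
                [],
                frome.pathways,
                frome.population,
                frome.rates,
                frome.unit_values,
            )

    def test_unknown_metric_rejected(self, frome):
        with pytest.raises(ConfigurationError, match="nope"):
            sensitivity_sweep(
                frome.scenarios["baseline"],
                "nope",
                [1.0],
                frome.pathways,
                frome.population,
                frome.rates,
                frome.unit_values,
            )
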