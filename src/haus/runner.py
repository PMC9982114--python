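"""Scenario evaluation, comparison tables and report rendering.

A scenario names a population, a set of environment metrics (which decide
threshold activation), per-pathway exposed proportions, and a project
timeline. Running it evaluates every pathway: active ones get the full
attributable-effect and valuation treatment, inactive ones emit dash rows.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__ as _pkg_version
from .engine import (
    attributable_cases,
    attributable_deaths,
    attributable_yll,
    yld_per_case,
)
from .errors import AggregationError, ConfigurationError, ValidationError
from .pathways import ImpactPathway, OutcomeKind, is_active
from .population import (
    PopulationProfile,
    RateTable,
    lookup_rate,
    mean_remaining_life,
    select_subpopulation,
    split_exposure,
)
from .valuation import (
    ProjectTimeline,
    UnitValue,
    ValueBreakdown,
    monetize,
    total_effect,
)

__all__ = [
    "Scenario",
    "ReportRow",
    "run_scenario",
    "percent_change",
    "compare_scenarios",
    "sensitivity_sweep",
    "render_report",
    "write_report_csv",
    "write_valuation_csv",
    "write_manifest",
    "DASH",
]

DASH = "-"

REPORT_COLUMNS = [
    "characteristic",
    "environment_change",
    "outcome",
    "population_label",
    "N",
    "cases_expected",
    "attributable",
    "pct_change",
    "value_total",
]


@dataclass(frozen=True)
class Scenario:
    name: str
    population_ref: str
    metrics: Mapping[str, float] = field(default_factory=dict)
    pathway_exposure: Mapping[str, float] = field(default_factory=dict)
    timeline: ProjectTimeline = field(default_factory=ProjectTimeline)

    def __post_init__(self) -> None:
        for metric, value in self.metrics.items():
            if not math.isfinite(value):
                raise ValidationError(
                    f"scenario {self.name!r}: metric {metric!r} is not finite"
                )
        for pid, pe in self.pathway_exposure.items():
            if not 0.0 <= pe <= 1.0:
                raise ValidationError(
                    f"scenario {self.name!r}: exposure for pathway {pid!r} "
                    f"must be in [0, 1], got {pe}"
                )


@dataclass(frozen=True)
class ReportRow:
    """One pathway evaluation in one scenario. None values render as a dash."""

    characteristic: str
    environment_change: str
    outcome: str
    population_label: str
    N: float
    cases_expected: Optional[float]
    attributable: Optional[float]
    pct_change: Optional[int]
    value_total: Optional[float]
    # not rendered in report.csv:
    pathway_id: str = ""
    active: bool = True
    lifetime_cases: Optional[float] = None
    breakdown: Optional[ValueBreakdown] = None


def percent_change(attributable: float, expected: float) -> Optional[int]:
    """Integer percent change, rounded half away from zero; None when expected = 0."""
    if expected < 0:
        raise ValidationError(f"expected cases must be >= 0, got {expected}")
    if expected == 0:
        return None
    x = 100.0 * attributable / expected
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def _band_label(pathway: ImpactPathway) -> str:
    f = pathway.population_filter
    if f.sex is not None:
        prefix = {"male": "Men", "female": "Women"}.get(f.sex, f.sex)
    else:
        prefix = "Adults" if f.age_min >= 13 else "Children"
    if f.age_max >= 200:
        if f.age_min <= 0:
            return "All ages"
        return f"{prefix} >{int(f.age_min)}"
    if f.age_min <= 0:
        return f"Children <{int(f.age_max)}"
    return f"Children {int(f.age_min)}–{int(f.age_max) - 1}"


def _validate_inputs(
    scenario: Scenario,
    pathways: Sequence[ImpactPathway],
    population: PopulationProfile,
    rates: RateTable,
    unit_values: Mapping[str, UnitValue],
) -> None:
    """Fail-fast pass: every referenced metric, rate and unit value must exist."""
    problems: list[str] = []
    for p in pathways:
        if p.threshold is not None and p.exposure_metric not in scenario.metrics:
            problems.append(
                f"pathway {p.id!r}: thresholded metric {p.exposure_metric!r} "
                "missing from scenario"
            )
        kind = "mortality" if p.outcome_kind is OutcomeKind.MORTALITY else "incidence"
        if not rates.rows_for(p.outcome_id, kind):
            problems.append(
                f"pathway {p.id!r}: no {kind} rate rows for outcome {p.outcome_id!r}"
            )
        if p.outcome_id not in unit_values:
            problems.append(
                f"pathway {p.id!r}: no unit value for outcome {p.outcome_id!r}"
            )
    if problems:
        raise ConfigurationError("; ".join(problems))


def _evaluate_pathway(
    pathway: ImpactPathway,
    scenario: Scenario,
    population: PopulationProfile,
    rates: RateTable,
    unit_values: Mapping[str, UnitValue],
) -> ReportRow:
    f = pathway.population_filter
    subpop = select_subpopulation(population, f.age_min, f.age_max, sex=f.sex)
    n = subpop.n
    label = _band_label(pathway)
    base = dict(
        characteristic=pathway.characteristic,
        environment_change=pathway.environment_change,
        outcome=pathway.outcome_id,
        population_label=label,
        N=n,
        pathway_id=pathway.id,
    )
    active = is_active(pathway, scenario.metrics)
    kind = (
        "mortality" if pathway.outcome_kind is OutcomeKind.MORTALITY else "incidence"
    )
    rate, duration = lookup_rate(
        rates, pathway.outcome_id, (f.age_min, f.age_max), kind, profile=subpop
    )
    expected = n * rate
    if not active:
        return ReportRow(
            **base,
            cases_expected=expected,
            attributable=None,
            pct_change=None,
            value_total=None,
            active=False,
        )

    Pe = float(scenario.pathway_exposure.get(pathway.id, 0.0))
    split = split_exposure(n, Pe)
    uv = unit_values[pathway.outcome_id]
    timeline = scenario.timeline

    if pathway.outcome_kind is OutcomeKind.MORTALITY:
        res = attributable_yll(
            attributable_deaths(split, rate, pathway.odds_ratio),
            mean_remaining_life(subpop),
        )
        annual_attr = res.Dattributed
        lifetime = total_effect(annual_attr, timeline)
        if uv.vsly is not None:
            lifetime_yll = total_effect(res.YLLattributed, timeline)
            breakdown = monetize(lifetime_yll, uv, "vsly", timeline)
        else:
            breakdown = monetize(lifetime, uv, "vsl", timeline)
        expected_out = res.Dexpected
    else:
        res = attributable_cases(split, rate, pathway.odds_ratio)
        annual_attr = res.Cattributed
        lifetime = total_effect(annual_attr, timeline)
        if uv.per_case is not None:
            breakdown = monetize(lifetime, uv, "per_case", timeline)
        else:
            per_case_years = yld_per_case(duration or 1.0, subpop)
            breakdown = monetize(lifetime * per_case_years, uv, "per_year", timeline)
        expected_out = res.Cexpected

    return ReportRow(
        **base,
        cases_expected=expected_out,
        attributable=annual_attr,
        pct_change=percent_change(annual_attr, expected_out),
        value_total=breakdown.total,
        lifetime_cases=lifetime,
        breakdown=breakdown,
    )


def run_scenario(
    scenario: Scenario,
    pathways: Sequence[ImpactPathway],
    population: PopulationProfile,
    rates: RateTable,
    unit_values: Mapping[str, UnitValue],
) -> list[ReportRow]:
    """Evaluate every pathway against one scenario; see module docstring."""
    _validate_inputs(scenario, pathways, population, rates, unit_values)
    return [
        _evaluate_pathway(p, scenario, population, rates, unit_values)
        for p in pathways
    ]


def compare_scenarios(
    baseline: Sequence[ReportRow],
    scenarios: Sequence[tuple[str, Sequence[ReportRow]]],
) -> pd.DataFrame:
    """One row per (environment_change, outcome) pair, one column per scenario.

    Cells hold the annual attributable count; pairs inactive in a scenario
    show NaN (rendered as a dash). The totals row sums active values and is
    explicitly flagged as not adjusted for double counting.
    """
    columns = [("Baseline", baseline)] + [(name, rows) for name, rows in scenarios]
    keys: list[tuple[str, str]] = []
    per_scenario: list[dict[tuple[str, str], Optional[float]]] = []
    for name, rows in columns:
        cells: dict[tuple[str, str], Optional[float]] = {}
        for row in rows:
            key = (row.environment_change, row.outcome)
            if key in cells:
                raise AggregationError(
                    f"scenario {name!r}: duplicate (environment_change, outcome) "
                    f"key {key}"
                )
            cells[key] = row.attributable
            if key not in keys:
                keys.append(key)
        per_scenario.append(cells)
    records = []
    for key in keys:
        rec = {"environment_change": key[0], "outcome": key[1]}
        for (name, _), cells in zip(columns, per_scenario):
            rec[name] = cells.get(key)
        records.append(rec)
    totals = {
        "environment_change": "Total (not adjusted for double counting)",
        "outcome": "",
    }
    for (name, _), cells in zip(columns, per_scenario):
        totals[name] = sum(v for v in cells.values() if v is not None)
    records.append(totals)
    return pd.DataFrame.from_records(records)


def sensitivity_sweep(
    scenario: Scenario,
    metric: str,
    values: Sequence[float],
    pathways: Sequence[ImpactPathway],
    population: PopulationProfile,
    rates: RateTable,
    unit_values: Mapping[str, UnitValue],
) -> list[tuple[float, list[ReportRow]]]:
    """Re-run the scenario with ``metric`` overridden per value, in input order.

    Threshold activations are recomputed for every value.
    """
    if metric not in scenario.metrics:
        raise ConfigurationError(
            f"scenario {scenario.name!r} does not define metric {metric!r}"
        )
    if not values:
        raise ValidationError("sensitivity sweep needs at least one value")
    out = []
    for v in values:
        metrics = dict(scenario.metrics)
        metrics[metric] = float(v)
        swept = replace(scenario, metrics=metrics)
        out.append((float(v), run_scenario(swept, pathways, population, rates, unit_values)))
    return out


# ---------------------------------------------------------------------------
# Rendering. Counts with |x| >= 1 render as integers, 0 < |x| < 1 to two
# decimals; internal precision is never rounded.
# ---------------------------------------------------------------------------


def format_count(x: Optional[float]) -> str:
    if x is None:
        return DASH
    if x == 0:
        return "0"
    if abs(x) >= 1:
        return format(int(math.copysign(math.floor(abs(x) + 0.5), x)), ",")
    return f"{x:.2f}"


def render_report(rows: Sequence[ReportRow]) -> pd.DataFrame:
    records = []
    for r in rows:
        records.append(
            {
                "characteristic": r.characteristic,
                "environment_change": r.environment_change,
                "outcome": r.outcome,
                "population_label": r.population_label,
                "N": format_count(r.N),
                "cases_expected": format_count(r.cases_expected),
                "attributable": format_count(r.attributable),
                "pct_change": DASH if r.pct_change is None else f"{r.pct_change}%",
                "value_total": DASH if r.value_total is None else f"{r.value_total:.2f}",
            }
        )
    return pd.DataFrame.from_records(records, columns=REPORT_COLUMNS)


def write_report_csv(rows: Sequence[ReportRow], path: str | Path) -> None:
    render_report(rows).to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def write_valuation_csv(rows: Sequence[ReportRow], path: str | Path) -> None:
    records = []
    for r in rows:
        b = r.breakdown
        if b is None:
            continue
        rec = {
            "pathway_id": r.pathway_id,
            "outcome": r.outcome,
            "total": b.total,
        }
        rec.update({f"component_{k}": v for k, v in sorted(b.by_component.items())})
        rec.update({f"bearer_{k}": v for k, v in sorted(b.by_bearer.items())})
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(
        path, index=False, encoding="utf-8", lineterminator="\n"
    )


def write_comparison_csv(table: pd.DataFrame, path: str | Path) -> None:
    rendered = table.copy()
    for col in rendered.columns:
        if col in ("environment_change", "outcome"):
            continue
        rendered[col] = [
            format_count(None if (isinstance(v, float) and math.isnan(v)) else v)
            for v in rendered[col]
        ]
    rendered.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def write_manifest(
    path: str | Path,
    input_files: Mapping[str, str | Path],
    config: Mapping[str, object],
    seed: Optional[int] = None,
) -> None:
    """Audit manifest: input digests, config echo, library versions, seed."""
    digests = {}
    for name, fp in sorted(input_files.items()):
        digests[name] = hashlib.sha256(Path(fp).read_bytes()).hexdigest()
    manifest = {
        "inputs_sha256": digests,
        "config": config,
        "seed": seed,
        "versions": {
            "haus": _pkg_version,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str), encoding="utf-8"
    )
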