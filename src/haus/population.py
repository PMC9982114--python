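"""Age-structured populations, baseline rate tables, and exposure splits.

Counts are statistical persons and may be fractional; full precision is kept
internally, rounding is a presentation concern. Age bands are half-open
``[age_min, age_max)`` in years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from ._io import write_csv
from .errors import EvaluationError, MissingRateError, SchemaError, ValidationError

__all__ = [
    "Stratum",
    "PopulationProfile",
    "RateRow",
    "RateTable",
    "ExposureSplit",
    "select_subpopulation",
    "mean_remaining_life",
    "split_exposure",
    "lookup_rate",
    "load_population",
    "save_population",
    "load_rates",
    "save_rates",
]


@dataclass(frozen=True)
class Stratum:
    """One age-year stratum: count of persons and their remaining life expectancy."""

    age: int
    count: float
    life_expectancy: float
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError(f"stratum age {self.age}: negative count {self.count}")
        if not self.life_expectancy > 0:
            raise ValidationError(
                f"stratum age {self.age}: life_expectancy must be > 0, "
                f"got {self.life_expectancy}"
            )


@dataclass(frozen=True)
class PopulationProfile:
    strata: tuple[Stratum, ...]
    label: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for s in self.strata:
            key = (s.age, s.sex)
            if key in seen:
                raise ValidationError(
                    f"profile {self.label!r}: duplicate stratum age={s.age} sex={s.sex}"
                )
            seen.add(key)

    @property
    def n(self) -> float:
        """Total persons (Σ counts)."""
        return float(sum(s.count for s in self.strata))


@dataclass(frozen=True)
class RateRow:
    outcome_id: str
    age_min: float
    age_max: float
    rate_kind: str  # "incidence" | "mortality"
    annual_rate: float
    duration_years: Optional[float] = None  # illness duration, morbidity rows only

    def __post_init__(self) -> None:
        if self.rate_kind not in ("incidence", "mortality"):
            raise ValidationError(
                f"rate row {self.outcome_id!r}: unknown rate_kind {self.rate_kind!r}"
            )
        if not 0.0 <= self.annual_rate <= 1.0:
            raise ValidationError(
                f"rate row {self.outcome_id!r}: annual_rate {self.annual_rate} "
                "outside [0, 1]"
            )
        if not self.age_min < self.age_max:
            raise ValidationError(
                f"rate row {self.outcome_id!r}: empty age band "
                f"[{self.age_min}, {self.age_max})"
            )
        if self.duration_years is not None and not self.duration_years > 0:
            raise ValidationError(
                f"rate row {self.outcome_id!r}: duration_years must be > 0"
            )

    def covers(self, age: float) -> bool:
        return self.age_min <= age < self.age_max


@dataclass(frozen=True)
class RateTable:
    rows: tuple[RateRow, ...]

    def __post_init__(self) -> None:
        # Bands for one (outcome, kind) must tile without overlap.
        groups: dict[tuple[str, str], list[RateRow]] = {}
        for r in self.rows:
            groups.setdefault((r.outcome_id, r.rate_kind), []).append(r)
        for (outcome, kind), rows in groups.items():
            rows = sorted(rows, key=lambda r: r.age_min)
            for a, b in zip(rows, rows[1:]):
                if b.age_min < a.age_max:
                    raise SchemaError(
                        f"overlapping age bands for outcome {outcome!r} ({kind}): "
                        f"[{a.age_min}, {a.age_max}) and [{b.age_min}, {b.age_max})"
                    )

    def rows_for(self, outcome_id: str, rate_kind: str) -> list[RateRow]:
        return [
            r
            for r in self.rows
            if r.outcome_id == outcome_id and r.rate_kind == rate_kind
        ]


@dataclass(frozen=True)
class ExposureSplit:
    """Partition of n persons into exposed (ne) and unexposed (nu)."""

    n: float
    ne: float
    nu: float
    Pe: float
    Pu: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.Pu is None:
            object.__setattr__(self, "Pu", 1.0 - self.Pe)


def select_subpopulation(
    profile: PopulationProfile,
    age_min: float,
    age_max: float,
    sex: Optional[str] = None,
) -> PopulationProfile:
    """Strata with ``age_min <= age < age_max`` (and matching sex, if given).

    An empty result is not an error; downstream evaluation against an empty
    profile is.
    """
    if not age_min < age_max:
        raise ValidationError(f"age_min must be < age_max, got [{age_min}, {age_max})")
    kept = tuple(
        s
        for s in profile.strata
        if age_min <= s.age < age_max and (sex is None or s.sex == sex)
    )
    label = f"{profile.label}[{age_min},{age_max})" + (f" {sex}" if sex else "")
    return PopulationProfile(strata=kept, label=label)


def mean_remaining_life(profile: PopulationProfile) -> float:
    """Count-weighted mean remaining life expectancy over the profile."""
    n = profile.n
    if n <= 0:
        raise EvaluationError(
            f"mean_remaining_life undefined for empty profile {profile.label!r}"
        )
    return sum(s.count * s.life_expectancy for s in profile.strata) / n


def split_exposure(n: float, Pe: float) -> ExposureSplit:
    """Split n persons into exposed/unexposed by proportion Pe.

    Fractional (statistical) persons are permitted.
    """
    if not 0.0 <= Pe <= 1.0:
        raise ValidationError(f"exposed proportion Pe must be in [0, 1], got {Pe}")
    if not n > 0:
        raise ValidationError(f"population size must be > 0, got {n}")
    ne = n * Pe
    nu = n - ne
    # store n as ne + nu so conservation holds bit-exactly (<= 1 ulp shift)
    return ExposureSplit(n=ne + nu, ne=ne, nu=nu, Pe=Pe)


def lookup_rate(
    rates: RateTable,
    outcome_id: str,
    age_band: tuple[float, float],
    rate_kind: str,
    profile: Optional[PopulationProfile] = None,
) -> tuple[float, Optional[float]]:
    """Return ``(annual_rate, duration_years)`` for an outcome over an age band.

    If one rate row fully covers the band it is returned directly. A band
    spanning several rows returns the count-weighted average (weights taken
    from ``profile`` counts within each row's overlap), which requires a
    profile to be supplied.
    """
    lo, hi = age_band
    candidates = [
        r
        for r in rates.rows_for(outcome_id, rate_kind)
        if r.age_min < hi and r.age_max > lo
    ]
    if not candidates:
        raise MissingRateError(
            f"no {rate_kind} rate for outcome {outcome_id!r} over band [{lo}, {hi})"
        )
    covering = [r for r in candidates if r.age_min <= lo and r.age_max >= hi]
    if covering:
        row = covering[0]
        return row.annual_rate, row.duration_years

    if profile is None:
        raise MissingRateError(
            f"band [{lo}, {hi}) for outcome {outcome_id!r} spans multiple rate rows "
            "and no population profile was supplied for weighting"
        )
    weights = []
    for r in candidates:
        w = sum(
            s.count for s in profile.strata if lo <= s.age < hi and r.covers(s.age)
        )
        weights.append(w)
    # Every person in the band must be covered by some candidate row.
    uncovered = sum(
        s.count
        for s in profile.strata
        if lo <= s.age < hi and not any(r.covers(s.age) for r in candidates)
    )
    if uncovered > 0:
        raise MissingRateError(
            f"rate rows for outcome {outcome_id!r} do not cover all of band "
            f"[{lo}, {hi}) ({uncovered:g} persons uncovered)"
        )
    total_w = sum(weights)
    if total_w <= 0:
        raise MissingRateError(
            f"no population weight in band [{lo}, {hi}) for outcome {outcome_id!r}"
        )
    rate = sum(w * r.annual_rate for w, r in zip(weights, candidates)) / total_w
    durations = [r.duration_years for r in candidates]
    if any(d is not None for d in durations):
        duration = (
            sum(w * (d if d is not None else 0.0) for w, d in zip(weights, durations))
            / total_w
        )
    else:
        duration = None
    return rate, duration


# ---------------------------------------------------------------------------
# File I/O — population CSV: age, count, life_expectancy[, sex];
#            rate CSV: outcome_id, age_min, age_max, rate_kind, annual_rate,
#            duration_years. UTF-8 with headers.
# ---------------------------------------------------------------------------

_POP_COLUMNS = ["age", "count", "life_expectancy"]
_RATE_COLUMNS = [
    "outcome_id",
    "age_min",
    "age_max",
    "rate_kind",
    "annual_rate",
    "duration_years",
]


def load_population(path: str | Path, label: Optional[str] = None) -> PopulationProfile:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _POP_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    has_sex = "sex" in frame.columns
    strata = tuple(
        Stratum(
            age=int(row["age"]),
            count=float(row["count"]),
            life_expectancy=float(row["life_expectancy"]),
            sex=(
                str(row["sex"])
                if has_sex and isinstance(row.get("sex"), str) and row["sex"].strip()
                else None
            ),
        )
        for row in frame.to_dict(orient="records")
    )
    return PopulationProfile(strata=strata, label=label or path.stem)


def save_population(profile: PopulationProfile, path: str | Path) -> None:
    has_sex = any(s.sex is not None for s in profile.strata)
    records = [
        {
            "age": s.age,
            "count": s.count,
            "life_expectancy": s.life_expectancy,
            **({"sex": s.sex or ""} if has_sex else {}),
        }
        for s in profile.strata
    ]
    cols = _POP_COLUMNS + (["sex"] if has_sex else [])
    write_csv(records, cols, path)


def load_rates(path: str | Path) -> RateTable:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _RATE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    rows = tuple(
        RateRow(
            outcome_id=str(rec["outcome_id"]),
            age_min=float(rec["age_min"]),
            age_max=float(rec["age_max"]),
            rate_kind=str(rec["rate_kind"]),
            annual_rate=float(rec["annual_rate"]),
            duration_years=(
                None
                if rec["duration_years"] is None
                or (isinstance(rec["duration_years"], float) and math.isnan(rec["duration_years"]))
                else float(rec["duration_years"])
            ),
        )
        for rec in frame.to_dict(orient="records")
    )
    return RateTable(rows=rows)


def save_rates(rates: RateTable, path: str | Path) -> None:
    records = [
        {
            "outcome_id": r.outcome_id,
            "age_min": r.age_min,
            "age_max": r.age_max,
            "rate_kind": r.rate_kind,
            "annual_rate": r.annual_rate,
            "duration_years": "" if r.duration_years is None else r.duration_years,
        }
        for r in rates.rows
    ]
    write_csv(records, _RATE_COLUMNS, path)
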