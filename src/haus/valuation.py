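"""Lag-ramped accumulation over the project lifetime and societal valuation.

Health effects phase in over a lag ramp (default 20% per year to full effect
at year five) and are accumulated only within the project lifetime, capped at
25 years by default. Monetization multiplies attributable quantities by
per-outcome societal unit values (GBP 2019), with component and bearer
disaggregation; an optional discount rate is available but off by default so
that the undiscounted arithmetic is reproduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._io import write_csv
from .errors import SchemaError, ValidationError, ValuationError

__all__ = [
    "DEFAULT_LAG_RAMP",
    "DEFAULT_CAP_YEARS",
    "ProjectTimeline",
    "UnitValue",
    "ValueBreakdown",
    "effective_exposure_years",
    "total_effect",
    "monetize",
    "discount_stream",
    "load_unit_values",
    "save_unit_values",
]

DEFAULT_LAG_RAMP: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
DEFAULT_CAP_YEARS = 25

COMPONENT_KEYS = ("medical", "productivity_informal_care", "disutility")
BEARER_KEYS = ("individual_family", "employer", "healthcare_provider", "state")


@dataclass(frozen=True)
class ProjectTimeline:
    years: int = DEFAULT_CAP_YEARS
    lag_ramp: tuple[float, ...] = DEFAULT_LAG_RAMP
    cap_years: int = DEFAULT_CAP_YEARS

    def __post_init__(self) -> None:
        if self.years < 1:
            raise ValidationError(f"project duration must be >= 1 year, got {self.years}")
        ramp = tuple(self.lag_ramp)
        object.__setattr__(self, "lag_ramp", ramp)
        if not ramp or any(not 0 < f <= 1 for f in ramp):
            raise ValidationError("lag ramp fractions must lie in (0, 1]")
        if any(b < a for a, b in zip(ramp, ramp[1:])) or ramp[-1] != 1.0:
            raise ValidationError("lag ramp must be non-decreasing and end at 1")

    @property
    def effective_years(self) -> int:
        """Number of project years counted: min(years, cap_years)."""
        return min(self.years, self.cap_years)

    def ramp_fractions(self) -> list[float]:
        """Per-year effect fraction over the effective duration."""
        return [
            self.lag_ramp[t] if t < len(self.lag_ramp) else 1.0
            for t in range(self.effective_years)
        ]


@dataclass(frozen=True)
class UnitValue:
    """Societal unit cost of one outcome in GBP 2019.

    ``per_case``/``per_year`` apply to morbidity, ``vsl``/``vsly`` to
    mortality; unpopulated bases are None. Components disaggregate the
    per-case total; bearer shares say where the burden falls.
    """

    outcome_id: str
    per_case: Optional[float] = None
    per_year: Optional[float] = None
    vsl: Optional[float] = None
    vsly: Optional[float] = None
    components: Mapping[str, float] = field(default_factory=dict)
    bearer_shares: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("per_case", "per_year", "vsl", "vsly"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(
                    f"unit value {self.outcome_id!r}: {name} must be >= 0, got {v}"
                )
        comp_total = sum(self.components.values())
        if self.components and self.per_case:
            if abs(comp_total - self.per_case) > 0.005 * self.per_case:
                raise ValidationError(
                    f"unit value {self.outcome_id!r}: components sum to "
                    f"{comp_total:.2f}, not within 0.5% of per_case {self.per_case:.2f}"
                )
        if self.bearer_shares:
            share_total = sum(self.bearer_shares.values())
            if abs(share_total - 1.0) > 1e-9:
                raise ValidationError(
                    f"unit value {self.outcome_id!r}: bearer shares sum to "
                    f"{share_total!r}, expected 1"
                )

    def rate_for(self, basis: str) -> float:
        v = getattr(self, basis, None)
        if v is None:
            raise ValuationError(
                f"unit value for outcome {self.outcome_id!r} has no {basis!r} basis"
            )
        return v


@dataclass(frozen=True)
class ValueBreakdown:
    outcome_id: str
    total: float
    by_component: dict[str, float]
    by_bearer: dict[str, float]
    by_year: tuple[float, ...]


def effective_exposure_years(timeline: ProjectTimeline) -> float:
    """Years-equivalent of full effect over the project: Σ ramp fractions."""
    return float(sum(timeline.ramp_fractions()))


def total_effect(annual_attributed: float, timeline: ProjectTimeline) -> float:
    """Lifetime attributable total: annual effect × lag-adjusted years."""
    if not math.isfinite(annual_attributed):
        raise ValidationError("annual attributable effect must be finite")
    return annual_attributed * effective_exposure_years(timeline)


def monetize(
    quantity: float,
    unit_value: UnitValue,
    basis: str,
    timeline: ProjectTimeline,
) -> ValueBreakdown:
    """Value an attributable quantity: total = quantity × unit rate.

    The total is spread across project years proportionally to the lag ramp;
    components and bearer shares scale linearly. ``quantity`` is the lifetime
    attributable amount in the units the basis expects (cases for per_case,
    illness-years for per_year, deaths for vsl, life-years for vsly).
    """
    rate = unit_value.rate_for(basis)
    total = quantity * rate
    fractions = timeline.ramp_fractions()
    weight = sum(fractions)
    by_year = tuple(total * f / weight for f in fractions)
    comp_total = sum(unit_value.components.values())
    if comp_total > 0:
        by_component = {
            k: total * v / comp_total for k, v in unit_value.components.items()
        }
    else:
        by_component = {k: 0.0 for k in COMPONENT_KEYS}
        by_component["disutility"] = total  # no split known: all disutility
    shares = unit_value.bearer_shares or {"individual_family": 1.0}
    by_bearer = {k: total * v for k, v in shares.items()}
    return ValueBreakdown(
        outcome_id=unit_value.outcome_id,
        total=total,
        by_component=by_component,
        by_bearer=by_bearer,
        by_year=by_year,
    )


def discount_stream(by_year: Sequence[float], rate: float) -> float:
    """Present value of an annual stream, discounting from year 1.

    ``rate = 0`` returns the undiscounted sum exactly.
    """
    if rate < 0:
        raise ValidationError(f"discount rate must be >= 0, got {rate}")
    if rate == 0:
        return float(sum(by_year))
    return float(sum(v / (1.0 + rate) ** (t + 1) for t, v in enumerate(by_year)))


# ---------------------------------------------------------------------------
# Unit-value CSV: outcome_id, per_case, per_year, vsl, vsly, comp_medical,
# comp_productivity_informal, comp_disutility, share_individual,
# share_employer, share_healthcare, share_state. GBP 2019 throughout.
# ---------------------------------------------------------------------------

_UV_COLUMNS = [
    "outcome_id",
    "per_case",
    "per_year",
    "vsl",
    "vsly",
    "comp_medical",
    "comp_productivity_informal",
    "comp_disutility",
    "share_individual",
    "share_employer",
    "share_healthcare",
    "share_state",
]


def _opt(v: object) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str) and not v.strip():
        return None
    return float(v)  # type: ignore[arg-type]


def load_unit_values(path: str | Path) -> dict[str, UnitValue]:
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _UV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    out: dict[str, UnitValue] = {}
    for rec in frame.to_dict(orient="records"):
        comps = {
            k: v
            for k, v in {
                "medical": _opt(rec["comp_medical"]),
                "productivity_informal_care": _opt(rec["comp_productivity_informal"]),
                "disutility": _opt(rec["comp_disutility"]),
            }.items()
            if v  # zero/absent components are dropped
        }
        shares = {
            k: v
            for k, v in {
                "individual_family": _opt(rec["share_individual"]),
                "employer": _opt(rec["share_employer"]),
                "healthcare_provider": _opt(rec["share_healthcare"]),
                "state": _opt(rec["share_state"]),
            }.items()
            if v
        }
        uv = UnitValue(
            outcome_id=str(rec["outcome_id"]),
            per_case=_opt(rec["per_case"]),
            per_year=_opt(rec["per_year"]),
            vsl=_opt(rec["vsl"]),
            vsly=_opt(rec["vsly"]),
            components=comps,
            bearer_shares=shares,
        )
        out[uv.outcome_id] = uv
    return out


def save_unit_values(unit_values: Mapping[str, UnitValue], path: str | Path) -> None:
    records = []
    for uv in unit_values.values():
        comps = dict(uv.components)
        shares = dict(uv.bearer_shares)
        records.append(
            {
                "outcome_id": uv.outcome_id,
                "per_case": "" if uv.per_case is None else uv.per_case,
                "per_year": "" if uv.per_year is None else uv.per_year,
                "vsl": "" if uv.vsl is None else uv.vsl,
                "vsly": "" if uv.vsly is None else uv.vsly,
                "comp_medical": comps.get("medical", ""),
                "comp_productivity_informal": comps.get(
                    "productivity_informal_care", ""
                ),
                "comp_disutility": comps.get("disutility", ""),
                "share_individual": shares.get("individual_family", ""),
                "share_employer": shares.get("employer", ""),
                "share_healthcare": shares.get("healthcare_provider", ""),
                "share_state": shares.get("state", ""),
            }
        )
    write_csv(records, _UV_COLUMNS, path)
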