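"""Impact-pathway registry: definition, validation, loading and activation.

An impact pathway links one change in the urban environment (e.g. an NDVI
increase, improved park provision) to one health outcome, carrying an odds
ratio, a target population filter, and an optional activation threshold on a
named scenario metric.
"""

from __future__ import annotations

import json
import logging
import math
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import pydantic
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from ._io import write_csv
from .errors import ConfigurationError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Typology",
    "OutcomeKind",
    "Threshold",
    "PopulationFilter",
    "ImpactPathway",
    "load_pathways",
    "save_pathways",
    "is_active",
    "select_pathways",
    "PATHWAY_CSV_COLUMNS",
]


class Typology(str, Enum):
    BUILDINGS = "Buildings"
    NATURAL_ENVIRONMENT = "Natural Environment"
    CLIMATE_CHANGE = "Climate Change"
    TRANSPORT = "Transport"
    COMMUNITY_INFRASTRUCTURE = "Community Infrastructure"
    SOCIO_ECONOMICS = "Socio-economics"


class OutcomeKind(str, Enum):
    MORTALITY = "mortality"
    MORBIDITY = "morbidity"
    BEHAVIOUR_WELLBEING = "behaviour_wellbeing"


class Threshold(BaseModel):
    """Activation condition on one scenario metric: ``metric cmp value``."""

    model_config = ConfigDict(frozen=True)

    comparator: str  # ">=" or "<="
    value: float

    @field_validator("comparator")
    @classmethod
    def _cmp_known(cls, v: str) -> str:
        if v not in (">=", "<="):
            raise ValueError(f"threshold comparator must be '>=' or '<=', got {v!r}")
        return v

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("threshold value must be finite")
        return v

    def satisfied_by(self, metric_value: float) -> bool:
        if self.comparator == ">=":
            return metric_value >= self.value
        return metric_value <= self.value


class PopulationFilter(BaseModel):
    """Half-open age band [age_min, age_max) with an optional sex restriction."""

    model_config = ConfigDict(frozen=True)

    age_min: float = 0.0
    age_max: float = 200.0
    sex: Optional[str] = None

    @model_validator(mode="after")
    def _band_ordered(self) -> "PopulationFilter":
        if not self.age_min < self.age_max:
            raise ValueError(
                f"age_min must be < age_max, got [{self.age_min}, {self.age_max})"
            )
        return self


class ImpactPathway(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: str
    typology: Typology
    characteristic: str
    environment_change: str
    outcome_id: str
    outcome_kind: OutcomeKind
    odds_ratio: float
    exposure_metric: str
    threshold: Optional[Threshold] = None
    population_filter: PopulationFilter = PopulationFilter()
    source_note: str = ""

    @field_validator("odds_ratio")
    @classmethod
    def _or_positive(cls, v: float) -> float:
        if not (math.isfinite(v) and v > 0):
            raise ValueError(f"odds_ratio must be a positive finite real, got {v}")
        return v


#: Exact ordered column set of the pathway CSV interchange format.
PATHWAY_CSV_COLUMNS = [
    "id",
    "typology",
    "characteristic",
    "environment_change",
    "outcome_id",
    "outcome_kind",
    "odds_ratio",
    "exposure_metric",
    "threshold_cmp",
    "threshold_value",
    "age_min",
    "age_max",
    "sex",
    "source_note",
]


def _row_to_pathway(row: Mapping[str, object]) -> ImpactPathway:
    def _blank(v: object) -> bool:
        if v is None:
            return True
        if isinstance(v, float) and math.isnan(v):
            return True
        return isinstance(v, str) and v.strip() == ""

    threshold = None
    if not _blank(row["threshold_cmp"]) or not _blank(row["threshold_value"]):
        if _blank(row["threshold_cmp"]) or _blank(row["threshold_value"]):
            raise ValidationError(
                f"pathway {row['id']!r}: threshold_cmp and threshold_value must "
                "both be present or both be empty"
            )
        threshold = Threshold(
            comparator=str(row["threshold_cmp"]).strip(),
            value=float(row["threshold_value"]),  # type: ignore[arg-type]
        )
    try:
        return ImpactPathway(
            id=str(row["id"]),
            typology=str(row["typology"]),  # type: ignore[arg-type]
            characteristic=str(row["characteristic"]),
            environment_change=str(row["environment_change"]),
            outcome_id=str(row["outcome_id"]),
            outcome_kind=str(row["outcome_kind"]),  # type: ignore[arg-type]
            odds_ratio=float(row["odds_ratio"]),  # type: ignore[arg-type]
            exposure_metric=str(row["exposure_metric"]),
            threshold=threshold,
            population_filter=PopulationFilter(
                age_min=0.0 if _blank(row["age_min"]) else float(row["age_min"]),  # type: ignore[arg-type]
                age_max=200.0 if _blank(row["age_max"]) else float(row["age_max"]),  # type: ignore[arg-type]
                sex=None if _blank(row["sex"]) else str(row["sex"]).strip(),
            ),
            source_note="" if _blank(row["source_note"]) else str(row["source_note"]),
        )
    except pydantic.ValidationError as exc:
        raise ValidationError(f"pathway {row['id']!r}: {exc}") from exc


def load_pathways(path: str | Path, format: str = "csv") -> list[ImpactPathway]:
    """Load a pathway library from ``path``.

    Row order is preserved. Raises :class:`SchemaError` for missing columns
    and :class:`ValidationError` (carrying the row id) for invalid records.
    """
    path = Path(path)
    if format == "csv":
        frame = pd.read_csv(
            path,
            dtype={"sex": "string", "source_note": "string"},
            float_precision="round_trip",
        )
        missing = [c for c in PATHWAY_CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        records = frame.to_dict(orient="records")
    elif format == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
        for rec in records:
            missing = [c for c in PATHWAY_CSV_COLUMNS if c not in rec]
            if missing:
                raise SchemaError(
                    f"{path}: record missing required field(s): {', '.join(missing)}"
                )
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")

    pathways = [_row_to_pathway(rec) for rec in records]
    if not pathways:
        logger.warning("loaded empty pathway library from %s", path)
    else:
        logger.info("loaded %d impact pathways from %s", len(pathways), path)
    return pathways


def save_pathways(
    pathways: Sequence[ImpactPathway], path: str | Path, format: str = "csv"
) -> None:
    """Write a pathway library in the documented interchange schema."""
    records = []
    for p in pathways:
        records.append(
            {
                "id": p.id,
                "typology": p.typology.value,
                "characteristic": p.characteristic,
                "environment_change": p.environment_change,
                "outcome_id": p.outcome_id,
                "outcome_kind": p.outcome_kind.value,
                "odds_ratio": p.odds_ratio,
                "exposure_metric": p.exposure_metric,
                "threshold_cmp": p.threshold.comparator if p.threshold else "",
                "threshold_value": p.threshold.value if p.threshold else "",
                "age_min": p.population_filter.age_min,
                "age_max": p.population_filter.age_max,
                "sex": p.population_filter.sex or "",
                "source_note": p.source_note,
            }
        )
    path = Path(path)
    if format == "csv":
        write_csv(records, PATHWAY_CSV_COLUMNS, path)
    elif format == "json":
        path.write_text(json.dumps(records, indent=1), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")


def is_active(pathway: ImpactPathway, metrics: Mapping[str, float]) -> bool:
    """Decide whether a scenario's metrics activate ``pathway``.

    A pathway without a threshold is always active. A thresholded pathway is
    active iff the scenario provides its exposure metric and the metric value
    satisfies the comparator. Inactive pathways contribute no attributable
    effect and render as a dash in reports.
    """
    if pathway.threshold is None:
        return True
    if pathway.exposure_metric not in metrics:
        raise ConfigurationError(
            f"pathway {pathway.id!r} has a threshold on metric "
            f"{pathway.exposure_metric!r} which the scenario does not provide"
        )
    return pathway.threshold.satisfied_by(metrics[pathway.exposure_metric])


def select_pathways(
    pathways: Sequence[ImpactPathway],
    characteristic: Optional[str] = None,
    typology: Optional[Typology | str] = None,
) -> list[ImpactPathway]:
    """Filter a pathway list; all provided filters must match. No filters → identity."""
    if typology is not None:
        typology = Typology(typology)
    out = []
    for p in pathways:
        if characteristic is not None and p.characteristic != characteristic:
            continue
        if typology is not None and p.typology != typology:
            continue
        out.append(p)
    return out
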