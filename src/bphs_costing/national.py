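"""Facility-type summaries and national extrapolation.

Sampled facilities are averaged within each facility type (plain arithmetic
means with min–max ranges); national totals are mean times the national count
of facilities of that type, summed over types.  Per-capita figures divide by
the single national population for every type, matching how such costings
present per-type columns.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .errors import MissingInputError
from .needs import utilization_per_capita
from .scenarios import ScenarioResult
from .types import (
    FacilityDataset,
    FacilityType,
    FacilityTypeCensus,
    ServiceDefinition,
    round_half_up,
)

__all__ = [
    "METRICS",
    "MetricSummary",
    "FacilityTypeSummary",
    "facility_metrics",
    "summarize_type",
    "NationalEstimate",
    "extrapolate_national",
]

#: Metric names summarized per facility type.  Cost metrics come from
#: scenario 1 (actual) and scenario 2 (required at actual volumes).
METRICS = (
    "catchment_population",
    "n_bphs_services",
    "n_non_bphs_services",
    "n_total_services",
    "actual_bphs_cost",
    "actual_total_cost",
    "required_bphs_cost",
    "required_total_cost",
)


class MetricSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    mean: float
    min: float
    max: float

    def __init__(self, **data):
        super().__init__(**data)
        if not (self.min <= self.mean + 1e-9 and self.mean <= self.max + 1e-9):
            raise ValueError(f"min <= mean <= max violated: {self}")


class FacilityTypeSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    facility_type: FacilityType
    n_sampled: int = Field(ge=1)
    metrics: dict[str, MetricSummary]

    @classmethod
    def from_means(
        cls, facility_type: FacilityType, n_sampled: int, means: Mapping[str, float]
    ) -> "FacilityTypeSummary":
        """Degenerate summary (mean = min = max), e.g. from a published table of means."""
        return cls(
            facility_type=facility_type,
            n_sampled=n_sampled,
            metrics={k: MetricSummary(mean=v, min=v, max=v) for k, v in means.items()},
        )


def facility_metrics(
    dataset: FacilityDataset,
    s1: ScenarioResult,
    s2: ScenarioResult,
    services: Iterable[ServiceDefinition] | Mapping[str, ServiceDefinition],
) -> dict[str, float]:
    """One facility's row of summarizable metrics."""
    pc = utilization_per_capita(dataset, services)
    p = dataset.catchment_population
    return {
        "catchment_population": p,
        "n_bphs_services": (pc.bphs or 0.0) * p,
        "n_non_bphs_services": (pc.non_bphs or 0.0) * p,
        "n_total_services": pc.total * p,
        "actual_bphs_cost": s1.bphs_cost,
        "actual_total_cost": s1.total_cost,
        "required_bphs_cost": s2.bphs_cost,
        "required_total_cost": s2.total_cost,
    }


def summarize_type(
    metric_rows: Sequence[Mapping[str, float]], facility_type: FacilityType
) -> FacilityTypeSummary:
    """Mean and min–max range over the sampled facilities of one type."""
    if not metric_rows:
        raise MissingInputError(f"no sampled facilities of type {facility_type.value}")
    keys = metric_rows[0].keys()
    metrics = {}
    for k in keys:
        vals = [row[k] for row in metric_rows]
        metrics[k] = MetricSummary(
            mean=sum(vals) / len(vals), min=min(vals), max=max(vals)
        )
    return FacilityTypeSummary(
        facility_type=facility_type, n_sampled=len(metric_rows), metrics=metrics
    )


class NationalEstimate(BaseModel):
    """National totals, per-capita figures, and funding percentages."""

    model_config = ConfigDict(frozen=True)

    national_population: float
    per_type_totals: dict[FacilityType, dict[str, float]]
    totals: dict[str, float]
    per_capita: dict[str, float]
    pct_bphs_funded: int
    pct_total_funded: int

    @property
    def bphs_utilization_per_capita(self) -> float:
        return self.per_capita["n_bphs_services"]

    @property
    def total_utilization_per_capita(self) -> float:
        return self.per_capita["n_total_services"]


def extrapolate_national(
    summaries: Iterable[FacilityTypeSummary], census: FacilityTypeCensus
) -> NationalEstimate:
    """Scale per-type means by national facility counts and sum.

    Every summarized facility type must appear in the census.  Population is
    intentionally excluded from the extrapolated totals: catchments overlap
    across facility levels, so per-capita figures use the census national
    population for every type.
    """
    per_type: dict[FacilityType, dict[str, float]] = {}
    for summary in summaries:
        ft = summary.facility_type
        if ft not in census.counts:
            raise MissingInputError(f"census has no facility count for type {ft.value}")
        count = census.counts[ft]
        per_type[ft] = {
            k: count * m.mean
            for k, m in summary.metrics.items()
            if k != "catchment_population"
        }
    keys = sorted({k for d in per_type.values() for k in d})
    totals = {k: sum(d.get(k, 0.0) for d in per_type.values()) for k in keys}
    per_capita = {k: v / census.national_population for k, v in totals.items()}
    pct_bphs = (
        round_half_up(100.0 * totals["actual_bphs_cost"] / totals["required_bphs_cost"])
        if totals.get("required_bphs_cost")
        else 0.0
    )
    pct_total = (
        round_half_up(100.0 * totals["actual_total_cost"] / totals["required_total_cost"])
        if totals.get("required_total_cost")
        else 0.0
    )
    return NationalEstimate(
        national_population=census.national_population,
        per_type_totals=per_type,
        totals=totals,
        per_capita=per_capita,
        pct_bphs_funded=int(pct_bphs),
        pct_total_funded=int(pct_total),
    )
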