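"""Need-based ("optimal") service volume estimation.

Gross need for a service is catchment population times its annual rate
(incidence, prevalence, or coverage target, all expressed per person of total
catchment population per year).  Gross need is then reduced by the share of
the population expected to use private or other public providers (facility-
type specific) and by the share without effective access:

    adjusted_need = P * r * (1 - q_other[type]) * (1 - q_access)

Needs are kept fractional internally; rounding happens only in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from pydantic import BaseModel, ConfigDict, Field

from .errors import MissingInputError, UnknownReferenceError
from .types import (
    AdjustmentFactors,
    EpidemiologyEntry,
    FacilityDataset,
    FacilityType,
    ServiceDefinition,
    by_id,
)

__all__ = [
    "NeededVolume",
    "PerCapitaUtilization",
    "needed_volume",
    "optimal_volume_table",
    "utilization_per_capita",
]


class NeededVolume(BaseModel):
    model_config = ConfigDict(frozen=True)

    service_id: str
    gross_need: float = Field(ge=0)
    adjusted_need: float = Field(ge=0)


@dataclass(frozen=True)
class PerCapitaUtilization:
    """Annual services per person; package/non-package splits when available."""

    total: float
    bphs: float | None = None
    non_bphs: float | None = None


def needed_volume(
    population: float,
    rate: EpidemiologyEntry,
    adj: AdjustmentFactors,
    facility_type: FacilityType,
) -> NeededVolume:
    """Needed annual volume of one service for one facility's catchment."""
    if population <= 0:
        raise ValueError("population must be > 0")
    if facility_type not in adj.other_provider_share:
        raise UnknownReferenceError(
            f"no other-provider share configured for facility type {facility_type.value}"
        )
    gross = population * rate.annual_rate
    adjusted = (
        gross
        * (1.0 - adj.other_provider_share[facility_type])
        * (1.0 - adj.non_access_share)
    )
    return NeededVolume(service_id=rate.service_id, gross_need=gross, adjusted_need=adjusted)


def optimal_volume_table(
    dataset: FacilityDataset,
    package: Iterable[ServiceDefinition] | Mapping[str, ServiceDefinition],
    epi: Iterable[EpidemiologyEntry] | Mapping[str, EpidemiologyEntry],
    adj: AdjustmentFactors,
) -> tuple[dict[str, NeededVolume], float]:
    """Needed volumes for every in-package service, plus the per-capita total.

    Includes package services the facility does not currently provide — that
    is the point of the optimal scenario.  Raises if any package service lacks
    an epidemiology entry, listing the missing ids.
    """
    pkg = by_id(package, "service_id")
    rates = by_id(epi, "service_id")
    missing = sorted(s for s in pkg if s not in rates)
    if missing:
        raise MissingInputError(
            f"no epidemiology entry for package services: {', '.join(missing)}"
        )
    table = {
        sid: needed_volume(
            dataset.catchment_population, rates[sid], adj, dataset.facility_type
        )
        for sid in pkg
    }
    per_capita = sum(v.adjusted_need for v in table.values()) / dataset.catchment_population
    return table, per_capita


def utilization_per_capita(
    dataset: FacilityDataset,
    services: Iterable[ServiceDefinition] | Mapping[str, ServiceDefinition] | None = None,
) -> PerCapitaUtilization:
    """Observed annual services per catchment person.

    With ``services`` supplied the figure is split into package (``in_bphs``)
    and non-package components; otherwise only the total is available.
    """
    if dataset.catchment_population <= 0:
        raise ValueError("catchment_population must be > 0")
    p = dataset.catchment_population
    total = sum(dataset.utilization.values()) / p
    if services is None:
        return PerCapitaUtilization(total=total)
    svc = by_id(services, "service_id")
    bphs = sum(
        n for s, n in dataset.utilization.items() if s in svc and svc[s].in_bphs
    ) / p
    non = sum(
        n for s, n in dataset.utilization.items() if s in svc and not svc[s].in_bphs
    ) / p
    return PerCapitaUtilization(total=total, bphs=bphs, non_bphs=non)
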