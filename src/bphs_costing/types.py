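"""Domain types and validation for activity-based health facility costing.

The vocabulary mirrors how essential-package costing exercises (CORE Plus,
OneHealth and relatives) describe a health system:

* a **cadre** is a category of health worker with a remuneration rate and an
  annual stock of available working minutes;
* a **resource item** is a medicine, supply, laboratory test, vaccine or
  nutrition commodity with a unit price (possibly donated in kind);
* a **service** is one intervention from the package (or outside it), and its
  **treatment protocol** is the per-case recipe of staff minutes and item
  quantities that the service *should* consume;
* a **facility dataset** is one facility-year of observed data: catchment
  population, staffing, annual utilization counts per service, and actual
  expenditure by line item.

Monetary amounts are US dollars throughout; no currency conversion or
discounting is performed.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, TypeVar

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "FacilityType",
    "CareType",
    "ItemCategory",
    "RateKind",
    "LINE_ITEMS",
    "DEFAULT_ANNUAL_AVAILABLE_MINUTES",
    "Cadre",
    "ResourceItem",
    "ServiceDefinition",
    "TreatmentProtocol",
    "EpidemiologyEntry",
    "AdjustmentFactors",
    "FacilityDataset",
    "FacilityTypeCensus",
    "Issue",
    "validate_dataset",
    "bphs_coverage_pct",
    "round_half_up",
    "by_id",
]


class FacilityType(str, Enum):
    """Levels of care, from mobile team to district hospital."""

    MHT = "MHT"  # mobile health team
    HSC = "HSC"  # health sub-center
    BHC = "BHC"  # basic health center
    CHC = "CHC"  # comprehensive health center
    DH = "DH"  # district hospital


class CareType(str, Enum):
    curative = "curative"
    preventive = "preventive"
    palliative = "palliative"
    rehabilitation = "rehabilitation"
    surgical = "surgical"
    inpatient = "inpatient"
    diagnostic = "diagnostic"


class ItemCategory(str, Enum):
    medicine = "medicine"
    supply = "supply"
    lab_test = "lab_test"
    vaccine = "vaccine"
    nutrition = "nutrition"


class RateKind(str, Enum):
    incidence = "incidence"
    prevalence = "prevalence"
    coverage_target = "coverage_target"


#: Expenditure line items recognised on a facility dataset.  Donated goods are
#: kept on a separate line so that donation-dependence shares stay computable.
LINE_ITEMS = (
    "technical_salaries",
    "support_salaries",
    "medicines_supplies",
    "donated_goods",
    "operating",
)

#: Default annual available minutes per staff-year:
#: 220 working days x 8 hours x 60 minutes x 0.75 productive-time factor.
DEFAULT_ANNUAL_AVAILABLE_MINUTES = 220 * 8 * 60 * 0.75  # = 79,200


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention used in the reports).

    Python's builtin ``round`` is banker's rounding; report tables here follow
    the half-up convention instead (e.g. 72.5 -> 73, 46.25 -> 46 at integers).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class Cadre(BaseModel):
    """A staff category with its pay and annual available working time."""

    model_config = ConfigDict(frozen=True)

    cadre_id: str
    name: str = ""
    annual_remuneration: float = Field(ge=0, description="USD per year, actual rate paid")
    annual_available_minutes: float = Field(
        default=DEFAULT_ANNUAL_AVAILABLE_MINUTES, gt=0
    )
    is_technical: bool = True


class ResourceItem(BaseModel):
    """A medicine, supply, test, vaccine or nutrition commodity."""

    model_config = ConfigDict(frozen=True)

    item_id: str
    name: str = ""
    category: ItemCategory = ItemCategory.medicine
    unit_price: float = Field(ge=0, description="Normative USD per unit (donated goods included)")
    donated: bool = False


class ServiceDefinition(BaseModel):
    model_config = ConfigDict(frozen=True)

    service_id: str
    name: str = ""
    program: str = Field(min_length=1)
    care_type: CareType
    in_bphs: bool = True


class TreatmentProtocol(BaseModel):
    """Per-case resource recipe: staff minutes by cadre and item quantities."""

    model_config = ConfigDict(frozen=True)

    service_id: str
    staff_minutes: dict[str, float] = Field(default_factory=dict)
    item_quantities: dict[str, float] = Field(default_factory=dict)


class EpidemiologyEntry(BaseModel):
    """Annual need rate for one service.

    ``annual_rate`` is expressed per person of *total* catchment population per
    year, whatever the epidemiological denominator of the source figure;
    subgroup-specific rates are folded into the rate before entry.
    ``rate_kind`` records the semantics (incidence, prevalence, or a national
    coverage target for preventive services) but does not change the formula.
    """

    model_config = ConfigDict(frozen=True)

    service_id: str
    annual_rate: float = Field(ge=0)
    rate_kind: RateKind = RateKind.incidence
    source_note: str = ""


class AdjustmentFactors(BaseModel):
    """Downward adjustments applied to gross epidemiological need.

    ``other_provider_share`` is the fraction of need met by the private sector
    or other public facilities (facility-type specific); ``non_access_share``
    is the fraction that cannot or will not access services (global).
    """

    model_config = ConfigDict(frozen=True)

    other_provider_share: dict[FacilityType, float] = Field(default_factory=dict)
    non_access_share: float = Field(default=0.0, ge=0, le=1)

    def __init__(self, **data):
        super().__init__(**data)
        for ft, v in self.other_provider_share.items():
            if not 0 <= v <= 1:
                raise ValueError(f"other_provider_share[{ft}]={v} outside [0, 1]")


class FacilityDataset(BaseModel):
    """One facility-year of observed data (annual aggregates, no patient records).

    Field-level invariants (positive population, non-negative counts and
    expenditures) are deliberately *not* enforced at construction so that
    :func:`validate_dataset` can report violations as issues rather than the
    model raising mid-load.
    """

    facility_id: str
    facility_type: FacilityType
    province: str = ""
    catchment_population: float
    staffing: dict[str, float] = Field(default_factory=dict)
    utilization: dict[str, float] = Field(default_factory=dict)
    expenditure: dict[str, float] = Field(default_factory=dict)

    @property
    def total_services(self) -> float:
        return float(sum(self.utilization.values()))

    @property
    def total_expenditure(self) -> float:
        return float(sum(self.expenditure.values()))


class FacilityTypeCensus(BaseModel):
    """National facility counts per type plus the national population."""

    model_config = ConfigDict(frozen=True)

    counts: dict[FacilityType, float]
    national_population: float = Field(gt=0)

    def __init__(self, **data):
        super().__init__(**data)
        for ft, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative facility count for {ft}")


class Issue(BaseModel):
    """A single validation finding."""

    severity: str  # "error" | "warning"
    message: str
    context: str = ""

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.severity}] {self.message} ({self.context})"


T = TypeVar("T")


def by_id(objs: Iterable[T] | Mapping[str, T], attr: str) -> dict[str, T]:
    """Normalise an iterable of domain objects into an id-keyed mapping."""
    if isinstance(objs, Mapping):
        return dict(objs)
    return {getattr(o, attr): o for o in objs}


def validate_dataset(
    dataset: FacilityDataset,
    services: Iterable[ServiceDefinition] | Mapping[str, ServiceDefinition],
    protocols: Iterable[TreatmentProtocol] | Mapping[str, TreatmentProtocol],
    cadres: Iterable[Cadre] | Mapping[str, Cadre] | None = None,
) -> list[Issue]:
    """Cross-check a facility dataset against the service catalogue.

    Returns an empty list iff every utilized service has a definition and a
    protocol and all dataset invariants hold.  Findings are reported, never
    raised.  Validation is idempotent and side-effect free.

    When ``cadres`` is supplied, protocols of utilized non-diagnostic services
    are additionally checked for having at least one technical cadre with
    positive minutes (otherwise indirect allocation has no basis for them).
    """
    svc = by_id(services, "service_id")
    prot = by_id(protocols, "service_id")
    cad = by_id(cadres, "cadre_id") if cadres is not None else None
    issues: list[Issue] = []
    ctx = f"facility={dataset.facility_id}"

    if dataset.catchment_population <= 0:
        issues.append(
            Issue(severity="error", message="catchment_population must be > 0", context=ctx)
        )
    for cid, n in dataset.staffing.items():
        if n < 0:
            issues.append(
                Issue(severity="error", message=f"negative staffing for cadre {cid}", context=ctx)
            )
    for sid, count in dataset.utilization.items():
        if count < 0:
            issues.append(
                Issue(severity="error", message=f"negative utilization for service {sid}", context=ctx)
            )
        if sid not in svc:
            issues.append(
                Issue(severity="error", message=f"utilization references unknown service_id {sid}", context=ctx)
            )
        elif sid not in prot:
            issues.append(
                Issue(severity="error", message=f"no treatment protocol for utilized service {sid}", context=ctx)
            )
        elif cad is not None and count > 0:
            definition = svc[sid]
            if definition.care_type is not CareType.diagnostic:
                tech = sum(
                    m
                    for c, m in prot[sid].staff_minutes.items()
                    if c in cad and cad[c].is_technical
                )
                if tech <= 0:
                    issues.append(
                        Issue(
                            severity="warning",
                            message=f"service {sid} has no technical staff minutes in its protocol",
                            context=ctx,
                        )
                    )
    for line, amount in dataset.expenditure.items():
        if line not in LINE_ITEMS:
            issues.append(
                Issue(severity="warning", message=f"unknown expenditure line item {line!r}", context=ctx)
            )
        if amount < 0:
            issues.append(
                Issue(severity="error", message=f"negative expenditure on line {line}", context=ctx)
            )
    return issues


def bphs_coverage_pct(
    dataset: FacilityDataset,
    package: Iterable[ServiceDefinition] | Mapping[str, ServiceDefinition],
) -> int:
    """Percentage of in-package service types the facility actually provided.

    A package service counts as provided when its annual utilization is
    positive.  Result is rounded half-up to the nearest integer percent.
    """
    pkg = [s for s in by_id(package, "service_id").values() if s.in_bphs]
    if not pkg:
        raise ValueError("coverage undefined: package contains no in-package services")
    provided = sum(1 for s in pkg if dataset.utilization.get(s.service_id, 0) > 0)
    return int(round_half_up(100.0 * provided / len(pkg)))
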