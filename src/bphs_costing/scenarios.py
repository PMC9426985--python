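"""The three costing scenarios and the financing/staffing gap report.

Scenario 1 (*actual services, actual costs*) values the observed service mix
at observed expenditure; scenario 2 (*actual services, required costs*) values
the same mix at normative unit costs; scenario 3 (*needed services, required
costs*) values the need-based optimal volumes at normative unit costs with the
indirect pool re-allocated over those volumes.  The financing gap is actual
expenditure as a percentage of required.
"""

from __future__ import annotations

import math
from enum import Enum
from typing import Iterable, Mapping

from pydantic import BaseModel, ConfigDict

from .costing import (
    IndirectPool,
    ServiceUnitCost,
    allocate_indirect,
    direct_unit_cost,
)
from .errors import DegenerateInputError, MissingInputError
from .needs import NeededVolume
from .types import (
    Cadre,
    FacilityDataset,
    ResourceItem,
    ServiceDefinition,
    TreatmentProtocol,
    by_id,
    round_half_up,
)

__all__ = [
    "Scenario",
    "ScenarioResult",
    "GapReport",
    "scenario_actual_actual",
    "scenario_actual_required",
    "scenario_needed_required",
    "gap_report",
    "required_staffing",
]


class Scenario(str, Enum):
    actual_actual = "actual_actual"
    actual_required = "actual_required"
    needed_required = "needed_required"


class ScenarioResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    scenario: Scenario
    facility_id: str
    total_cost: float
    bphs_cost: float
    non_bphs_cost: float
    volumes: dict[str, float]
    cost_per_service: float | None  # None iff total volume is zero (flagged)
    cost_per_capita_bphs: float
    cost_per_capita_total: float
    flags: tuple[str, ...] = ()

    @property
    def total_volume(self) -> float:
        return float(sum(self.volumes.values()))


class GapReport(BaseModel):
    model_config = ConfigDict(frozen=True)

    facility_id: str
    actual_pct_of_required: int
    actual_pct_of_optimal_services: int
    actual_staff: dict[str, float]
    required_staff: dict[str, int]  # under current (actual) service volumes
    required_staff_fte: dict[str, float]
    required_staff_optimal: dict[str, int]  # under needed volumes
    required_staff_optimal_fte: dict[str, float]

    @property
    def actual_staff_total(self) -> float:
        return float(sum(self.actual_staff.values()))

    @property
    def required_staff_total(self) -> int:
        return int(sum(self.required_staff.values()))

    @property
    def required_staff_optimal_total(self) -> int:
        return int(sum(self.required_staff_optimal.values()))


def _bphs_flags(
    services: Iterable[ServiceDefinition] | Mapping[str, ServiceDefinition],
) -> dict[str, bool]:
    return {s.service_id: s.in_bphs for s in by_id(services, "service_id").values()}


def _split_normative(
    volumes: Mapping[str, float],
    unit_costs: Mapping[str, ServiceUnitCost],
    in_bphs: Mapping[str, bool],
) -> tuple[float, float]:
    """Normative cost mass of package vs non-package volumes."""
    w_bphs = w_non = 0.0
    for sid, n in volumes.items():
        if n <= 0:
            continue
        if sid not in unit_costs:
            raise MissingInputError(f"no unit cost for service {sid!r}")
        mass = n * unit_costs[sid].total_unit_cost
        if in_bphs.get(sid, True):
            w_bphs += mass
        else:
            w_non += mass
    return w_bphs, w_non


def _result(
    scenario: Scenario,
    dataset: FacilityDataset,
    volumes: Mapping[str, float],
    total_cost: float,
    bphs_cost: float,
    flags: tuple[str, ...] = (),
) -> ScenarioResult:
    total_volume = sum(volumes.values())
    cps = total_cost / total_volume if total_volume > 0 else None
    if cps is None:
        flags = flags + ("zero_volume",)
    p = dataset.catchment_population
    return ScenarioResult(
        scenario=scenario,
        facility_id=dataset.facility_id,
        total_cost=total_cost,
        bphs_cost=bphs_cost,
        non_bphs_cost=total_cost - bphs_cost,
        volumes=dict(volumes),
        cost_per_service=cps,
        cost_per_capita_bphs=bphs_cost / p,
        cost_per_capita_total=total_cost / p,
        flags=flags,
    )


def scenario_actual_actual(
    dataset: FacilityDataset,
    unit_costs: Mapping[str, ServiceUnitCost],
    services: Iterable[ServiceDefinition] | Mapping[str, ServiceDefinition],
) -> ScenarioResult:
    """Observed service mix at observed expenditure.

    Total cost is the sum of all expenditure lines (donated goods included).
    Actual spending is not recorded per service, so the package/non-package
    split allocates the total in proportion to the normative cost masses of
    the package and non-package volumes actually delivered — the same
    minutes-and-recipe logic used for indirect allocation.
    """
    total = dataset.total_expenditure
    volumes = {s: n for s, n in dataset.utilization.items() if n > 0}
    w_bphs, w_non = _split_normative(volumes, unit_costs, _bphs_flags(services))
    if w_bphs + w_non > 0:
        bphs_cost = total * w_bphs / (w_bphs + w_non)
    else:
        bphs_cost = total  # no volumes: attribute the (standing) cost to the package
    return _result(Scenario.actual_actual, dataset, volumes, total, bphs_cost)


def scenario_actual_required(
    dataset: FacilityDataset,
    unit_costs: Mapping[str, ServiceUnitCost],
    services: Iterable[ServiceDefinition] | Mapping[str, ServiceDefinition],
) -> ScenarioResult:
    """Observed service mix valued at normative unit costs.

    The indirect component inside ``unit_costs`` must have been allocated over
    these same actual volumes (as :func:`bphs_costing.costing.unit_cost_table`
    does), so summing ``n_s * total_unit_cost_s`` returns direct costs plus
    the full pool.
    """
    in_bphs = _bphs_flags(services)
    volumes = {s: n for s, n in dataset.utilization.items() if n > 0}
    total = bphs_cost = 0.0
    for sid, n in volumes.items():
        if sid not in unit_costs:
            raise MissingInputError(f"no unit cost for utilized service {sid!r}")
        cost = n * unit_costs[sid].total_unit_cost
        total += cost
        if in_bphs.get(sid, True):
            bphs_cost += cost
    return _result(Scenario.actual_required, dataset, volumes, total, bphs_cost)


def scenario_needed_required(
    dataset: FacilityDataset,
    protocols: Iterable[TreatmentProtocol] | Mapping[str, TreatmentProtocol],
    cadres: Iterable[Cadre] | Mapping[str, Cadre],
    items: Iterable[ResourceItem] | Mapping[str, ResourceItem],
    pool: IndirectPool,
    needed: Mapping[str, NeededVolume],
    services: Iterable[ServiceDefinition] | Mapping[str, ServiceDefinition],
) -> ScenarioResult:
    """Need-based optimal volumes valued at normative unit costs.

    Unit costs are recomputed for the needed volume profile: direct components
    are unchanged (they are per-case) but the indirect pool is re-allocated
    over needed volumes, so the scenario is not a simple rescaling of
    scenario 2.
    """
    prot = by_id(protocols, "service_id")
    in_bphs = _bphs_flags(services)
    volumes = {sid: nv.adjusted_need for sid, nv in needed.items() if nv.adjusted_need > 0}
    for sid in volumes:
        if sid not in prot:
            raise MissingInputError(f"no treatment protocol for needed service {sid!r}")
    if not volumes:  # nothing needed: no variable cost, nothing to allocate over
        return _result(Scenario.needed_required, dataset, {}, 0.0, 0.0)
    indirect = allocate_indirect(pool, volumes, prot, cadres)
    total = bphs_cost = 0.0
    for sid, n in volumes.items():
        staff, goods = direct_unit_cost(prot[sid], cadres, items)
        cost = n * (staff + goods + indirect[sid])
        total += cost
        if in_bphs.get(sid, True):
            bphs_cost += cost
    return _result(Scenario.needed_required, dataset, volumes, total, bphs_cost)


def required_staffing(
    volumes: Mapping[str, float],
    protocols: Iterable[TreatmentProtocol] | Mapping[str, TreatmentProtocol],
    cadres: Iterable[Cadre] | Mapping[str, Cadre],
) -> tuple[dict[str, float], dict[str, int]]:
    """Technical staff needed to deliver a volume profile.

    Returns ``(fractional_fte, headcount)`` per technical cadre, where FTE is
    total protocol minutes divided by the cadre's annual available minutes and
    headcount is its ceiling (staff are hired whole).
    """
    prot = by_id(protocols, "service_id")
    cad = by_id(cadres, "cadre_id")
    minutes: dict[str, float] = {c: 0.0 for c in cad if cad[c].is_technical}
    for sid, n in volumes.items():
        if n <= 0:
            continue
        if sid not in prot:
            raise MissingInputError(f"no treatment protocol for service {sid!r}")
        for cadre_id, m in prot[sid].staff_minutes.items():
            if cadre_id in minutes:
                minutes[cadre_id] += n * m
    fte = {c: minutes[c] / cad[c].annual_available_minutes for c in minutes}
    heads = {c: int(math.ceil(v - 1e-9)) for c, v in fte.items()}
    return fte, heads


def gap_report(
    s1: ScenarioResult,
    s2: ScenarioResult,
    s3: ScenarioResult,
    dataset: FacilityDataset,
    protocols: Iterable[TreatmentProtocol] | Mapping[str, TreatmentProtocol],
    cadres: Iterable[Cadre] | Mapping[str, Cadre],
) -> GapReport:
    """Financing and staffing gaps across the three scenarios of one facility."""
    if not (s1.facility_id == s2.facility_id == s3.facility_id == dataset.facility_id):
        raise ValueError("scenario results must all belong to the same facility")
    if s2.total_cost <= 0:
        raise DegenerateInputError("required cost is zero; funding percentage undefined")
    if s3.total_volume <= 0:
        raise DegenerateInputError("optimal volume is zero; service percentage undefined")
    cad = by_id(cadres, "cadre_id")
    fte_req, heads_req = required_staffing(s2.volumes, protocols, cadres)
    fte_opt, heads_opt = required_staffing(s3.volumes, protocols, cadres)
    actual_staff = {
        c: n for c, n in dataset.staffing.items() if c in cad and cad[c].is_technical
    }
    return GapReport(
        facility_id=dataset.facility_id,
        actual_pct_of_required=int(round_half_up(100.0 * s1.total_cost / s2.total_cost)),
        actual_pct_of_optimal_services=int(
            round_half_up(100.0 * s1.total_volume / s3.total_volume)
        ),
        actual_staff=actual_staff,
        required_staff=heads_req,
        required_staff_fte=fte_req,
        required_staff_optimal=heads_opt,
        required_staff_optimal_fte=fte_opt,
    )
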