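"""Normative unit costing: bottom-up direct costs plus allocated indirect costs.

The normative unit cost of a service has three components:

* **direct staff cost** — protocol minutes per cadre times the cadre's
  per-minute remuneration rate ``w_c = annual_remuneration / annual_available_minutes``;
* **direct items cost** — protocol quantities times item unit prices, donated
  goods priced at their normative price;
* **indirect cost** — a facility-level pool (support salaries + operating
  expenditure, taken from actual spending in lieu of norms) allocated across
  services in proportion to utilization-weighted technical staff minutes.

Allocation conserves the pool exactly: summing per-case indirect cost times
utilization over services returns the pool amount.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from pydantic import BaseModel, ConfigDict, Field

from .errors import AllocationError, MissingInputError, UnknownReferenceError
from .types import (
    Cadre,
    FacilityDataset,
    ResourceItem,
    TreatmentProtocol,
    by_id,
)

__all__ = [
    "ServiceUnitCost",
    "IndirectPool",
    "staff_minute_rate",
    "direct_unit_cost",
    "technical_minutes_demand",
    "allocate_indirect",
    "unit_cost_table",
    "pool_from_expenditure",
]


class ServiceUnitCost(BaseModel):
    """Normative cost per case of one service, by component."""

    model_config = ConfigDict(frozen=True)

    service_id: str
    direct_staff_cost: float = Field(ge=0)
    direct_items_cost: float = Field(ge=0)
    indirect_cost: float = Field(ge=0)

    @property
    def total_unit_cost(self) -> float:
        return self.direct_staff_cost + self.direct_items_cost + self.indirect_cost


class IndirectPool(BaseModel):
    """Facility-level annual pool of costs not attributable to one service."""

    model_config = ConfigDict(frozen=True)

    amount: float = Field(ge=0)
    composition_note: str = "support salaries + operating costs (actual spending as norm)"


def pool_from_expenditure(dataset: FacilityDataset) -> IndirectPool:
    """Build the indirect pool from a facility's support-salary and operating lines."""
    amount = dataset.expenditure.get("support_salaries", 0.0) + dataset.expenditure.get(
        "operating", 0.0
    )
    return IndirectPool(amount=float(amount))


def staff_minute_rate(cadre: Cadre) -> float:
    """Per-minute remuneration rate of a cadre (USD/minute)."""
    if cadre.annual_available_minutes <= 0:
        raise ValueError(f"cadre {cadre.cadre_id}: annual_available_minutes must be > 0")
    return cadre.annual_remuneration / cadre.annual_available_minutes


def direct_unit_cost(
    protocol: TreatmentProtocol,
    cadres: Iterable[Cadre] | Mapping[str, Cadre],
    items: Iterable[ResourceItem] | Mapping[str, ResourceItem],
) -> tuple[float, float]:
    """Direct (staff, items) cost per case from a standard treatment protocol."""
    cad = by_id(cadres, "cadre_id")
    itm = by_id(items, "item_id")
    staff = 0.0
    for cadre_id, minutes in protocol.staff_minutes.items():
        if cadre_id not in cad:
            raise UnknownReferenceError(
                f"protocol for {protocol.service_id} references unknown cadre {cadre_id!r}"
            )
        staff += minutes * staff_minute_rate(cad[cadre_id])
    goods = 0.0
    for item_id, qty in protocol.item_quantities.items():
        if item_id not in itm:
            raise UnknownReferenceError(
                f"protocol for {protocol.service_id} references unknown item {item_id!r}"
            )
        goods += qty * itm[item_id].unit_price
    return staff, goods


def technical_minutes_demand(
    utilization: Mapping[str, float],
    protocols: Iterable[TreatmentProtocol] | Mapping[str, TreatmentProtocol],
    cadres: Iterable[Cadre] | Mapping[str, Cadre],
) -> tuple[dict[str, float], float]:
    """Total annual staff minutes implied by a utilization profile.

    Returns ``(per_cadre_minutes, technical_grand_total)`` where the grand
    total sums only cadres flagged technical.
    """
    prot = by_id(protocols, "service_id")
    cad = by_id(cadres, "cadre_id")
    per_cadre: dict[str, float] = {c: 0.0 for c in cad}
    for sid, count in utilization.items():
        if sid not in prot:
            raise MissingInputError(f"no treatment protocol for utilized service {sid!r}")
        for cadre_id, minutes in prot[sid].staff_minutes.items():
            if cadre_id not in cad:
                raise UnknownReferenceError(
                    f"protocol for {sid} references unknown cadre {cadre_id!r}"
                )
            per_cadre[cadre_id] += count * minutes
    technical_total = sum(v for c, v in per_cadre.items() if cad[c].is_technical)
    return per_cadre, technical_total


def _technical_minutes_per_case(
    protocol: TreatmentProtocol, cad: Mapping[str, Cadre]
) -> float:
    return sum(
        m for c, m in protocol.staff_minutes.items() if c in cad and cad[c].is_technical
    )


def allocate_indirect(
    pool: IndirectPool,
    utilization: Mapping[str, float],
    protocols: Iterable[TreatmentProtocol] | Mapping[str, TreatmentProtocol],
    cadres: Iterable[Cadre] | Mapping[str, Cadre],
) -> dict[str, float]:
    """Allocate the indirect pool to services; returns indirect cost *per case*.

    Service ``s`` receives the pool share ``n_s * tech_minutes_s / sum_t n_t *
    tech_minutes_t``; dividing by ``n_s`` gives the per-case figure, so
    per-case indirect cost is ``pool * tech_minutes_s / sum_t n_t * tech_minutes_t``
    (services delivered in volume dilute the pool for everyone).  Services with
    zero technical minutes (pure commodity distribution) receive zero.
    """
    prot = by_id(protocols, "service_id")
    cad = by_id(cadres, "cadre_id")
    weights: dict[str, float] = {}
    for sid, count in utilization.items():
        if sid not in prot:
            raise MissingInputError(f"no treatment protocol for utilized service {sid!r}")
        weights[sid] = count * _technical_minutes_per_case(prot[sid], cad)
    total_weight = sum(weights.values())
    if pool.amount > 0 and total_weight <= 0:
        raise AllocationError(
            "indirect pool is positive but total technical minutes are zero; "
            "allocation basis undefined"
        )
    out: dict[str, float] = {}
    for sid, count in utilization.items():
        if pool.amount == 0 or weights[sid] == 0 or count == 0:
            out[sid] = 0.0
        else:
            out[sid] = pool.amount * (weights[sid] / total_weight) / count
    return out


def unit_cost_table(
    dataset: FacilityDataset,
    protocols: Iterable[TreatmentProtocol] | Mapping[str, TreatmentProtocol],
    cadres: Iterable[Cadre] | Mapping[str, Cadre],
    items: Iterable[ResourceItem] | Mapping[str, ResourceItem],
    pool: IndirectPool,
) -> dict[str, ServiceUnitCost]:
    """Normative unit costs for every utilized service of one facility."""
    prot = by_id(protocols, "service_id")
    utilized = {s: n for s, n in dataset.utilization.items() if n > 0}
    indirect = allocate_indirect(pool, utilized, prot, cadres)
    table: dict[str, ServiceUnitCost] = {}
    for sid in utilized:
        staff, goods = direct_unit_cost(prot[sid], cadres, items)
        table[sid] = ServiceUnitCost(
            service_id=sid,
            direct_staff_cost=staff,
            direct_items_cost=goods,
            indirect_cost=indirect[sid],
        )
    return table
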