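"""Rankings, cost breakdowns, donation dependence, and one-at-a-time sensitivity.

Sensitivity analyses here are deliberately *recomputations*: a perturbation is
applied to a copy of the inputs and the full costing pipeline is re-run, never
a share-times-delta shortcut.  Fixed components (the indirect pool) therefore
damp the response — e.g. a 10% cut in catchment population lowers an optimal-
scenario total by a little less than 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from pydantic import BaseModel, ConfigDict

from .costing import IndirectPool
from .errors import UnknownReferenceError
from .needs import optimal_volume_table
from .scenarios import scenario_needed_required
from .types import (
    AdjustmentFactors,
    Cadre,
    EpidemiologyEntry,
    FacilityDataset,
    ItemCategory,
    ResourceItem,
    ServiceDefinition,
    TreatmentProtocol,
    by_id,
)

__all__ = [
    "RankedService",
    "rank_services",
    "breakdowns",
    "DonationShares",
    "donation_dependence",
    "donation_dependence_items",
    "PerturbationResult",
    "sensitivity_oat",
    "ExpenditureState",
    "OptimalCostState",
]


class RankedService(BaseModel):
    model_config = ConfigDict(frozen=True)

    rank: int
    service_id: str
    volume: float
    volume_pct: float
    total_cost: float
    cost_pct: float
    avg_cost_per_service: float
    cost_per_capita: float


def rank_services(
    costed: Mapping[str, tuple[float, float]],
    population: float,
    top_n: int = 10,
) -> list[RankedService]:
    """Rank services by total cost, descending; ties broken by service id.

    ``costed`` maps service_id to ``(annual_count, total_cost)``.  Percentage
    columns are computed over the full, untruncated set; only the returned
    list is truncated to ``top_n``.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    total_volume = sum(v for v, _ in costed.values())
    total_cost = sum(c for _, c in costed.values())
    ordered = sorted(costed.items(), key=lambda kv: (-kv[1][1], kv[0]))
    out = []
    for i, (sid, (volume, cost)) in enumerate(ordered[:top_n], start=1):
        out.append(
            RankedService(
                rank=i,
                service_id=sid,
                volume=volume,
                volume_pct=100.0 * volume / total_volume if total_volume else 0.0,
                total_cost=cost,
                cost_pct=100.0 * cost / total_cost if total_cost else 0.0,
                avg_cost_per_service=cost / volume if volume else 0.0,
                cost_per_capita=cost / population,
            )
        )
    return out


def breakdowns(
    costed: Mapping[str, tuple[float, float]],
    services: Iterable[ServiceDefinition] | Mapping[str, ServiceDefinition],
) -> dict[str, dict[str, dict[str, float]]]:
    """Cost and volume shares (percent) by care type and by program.

    Returns ``{"care_type": {"cost_share": {...}, "volume_share": {...}},
    "program": {...}}``; each share set sums to 100 up to float rounding.
    """
    svc = by_id(services, "service_id")
    result: dict[str, dict[str, dict[str, float]]] = {}
    total_volume = sum(v for v, _ in costed.values())
    total_cost = sum(c for _, c in costed.values())
    for dim, keyf in (
        ("care_type", lambda s: svc[s].care_type.value),
        ("program", lambda s: svc[s].program),
    ):
        cost_share: dict[str, float] = {}
        volume_share: dict[str, float] = {}
        for sid, (volume, cost) in costed.items():
            if sid not in svc:
                raise UnknownReferenceError(f"no service definition for {sid!r}")
            k = keyf(sid)
            cost_share[k] = cost_share.get(k, 0.0) + cost
            volume_share[k] = volume_share.get(k, 0.0) + volume
        result[dim] = {
            "cost_share": {
                k: 100.0 * v / total_cost if total_cost else 0.0
                for k, v in cost_share.items()
            },
            "volume_share": {
                k: 100.0 * v / total_volume if total_volume else 0.0
                for k, v in volume_share.items()
            },
        }
    return result


@dataclass(frozen=True)
class DonationShares:
    pct_of_medicines_supplies: float
    pct_of_total: float


def donation_dependence(expenditure: Mapping[str, float]) -> DonationShares:
    """Donated-goods share of medicines-and-supplies spending and of total spending."""
    donated = expenditure.get("donated_goods", 0.0)
    items_total = donated + expenditure.get("medicines_supplies", 0.0)
    total = sum(expenditure.values())
    return DonationShares(
        pct_of_medicines_supplies=100.0 * donated / items_total if items_total else 0.0,
        pct_of_total=100.0 * donated / total if total else 0.0,
    )


def donation_dependence_items(
    item_costs: Mapping[str, float],
    items: Iterable[ResourceItem] | Mapping[str, ResourceItem],
    other_cost: float = 0.0,
) -> DonationShares:
    """Donation shares from per-item normative cost masses and donated flags.

    ``other_cost`` is the non-commodity remainder (staff, indirect) entering
    the total-cost denominator.
    """
    itm = by_id(items, "item_id")
    donated = sum(c for i, c in item_costs.items() if itm[i].donated)
    items_total = sum(item_costs.values())
    total = items_total + other_cost
    return DonationShares(
        pct_of_medicines_supplies=100.0 * donated / items_total if items_total else 0.0,
        pct_of_total=100.0 * donated / total if total else 0.0,
    )


# ---------------------------------------------------------------------------
# One-at-a-time sensitivity
# ---------------------------------------------------------------------------


class PerturbationResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    variable: str
    delta: float
    baseline_total: float
    new_total: float

    @property
    def absolute_change(self) -> float:
        return self.new_total - self.baseline_total

    @property
    def pct_change(self) -> float:
        return 100.0 * self.absolute_change / self.baseline_total


@dataclass(frozen=True)
class ExpenditureState:
    """Pipeline state whose total is a sum of expenditure lines.

    Selectors: ``line:<name>`` scales one line; ``group:<name>`` scales every
    line in a named group (default groups: ``medicines`` = medicines_supplies
    + donated_goods, ``technical_salaries``).
    """

    lines: Mapping[str, float]
    groups: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "medicines": ("medicines_supplies", "donated_goods"),
            "technical_salaries": ("technical_salaries",),
        }
    )

    def total(self) -> float:
        return float(sum(self.lines.values()))

    def perturbed(self, selector: str, delta: float) -> "ExpenditureState":
        kind, _, name = selector.partition(":")
        if kind == "line" and name in self.lines:
            targets = (name,)
        elif kind == "group" and name in self.groups:
            targets = self.groups[name]
        else:
            raise UnknownReferenceError(f"unresolvable selector {selector!r}")
        lines = {
            k: v * (1.0 + delta) if k in targets else v for k, v in self.lines.items()
        }
        return replace(self, lines=lines)


@dataclass(frozen=True)
class OptimalCostState:
    """Pipeline state whose total is the needed-services-at-required-costs cost.

    Selectors:

    * ``population`` — catchment population;
    * ``rate:<service_id>`` — one service's annual need rate;
    * ``price:all`` / ``price:<item_id>`` / ``price:category:<name>`` — item prices;
    * ``salary:all`` / ``salary:<cadre_id>`` — cadre remuneration;
    * ``adjustment:access`` — the utilization (access) rate ``1 - q_access``.
    """

    dataset: FacilityDataset
    services: Mapping[str, ServiceDefinition]
    protocols: Mapping[str, TreatmentProtocol]
    cadres: Mapping[str, Cadre]
    items: Mapping[str, ResourceItem]
    pool: IndirectPool
    epi: Mapping[str, EpidemiologyEntry]
    adjustment: AdjustmentFactors

    def total(self) -> float:
        needed, _ = optimal_volume_table(
            self.dataset, self.services, self.epi, self.adjustment
        )
        result = scenario_needed_required(
            self.dataset,
            self.protocols,
            self.cadres,
            self.items,
            self.pool,
            needed,
            self.services,
        )
        return result.total_cost

    def perturbed(self, selector: str, delta: float) -> "OptimalCostState":
        kind, _, name = selector.partition(":")
        scale = 1.0 + delta
        if selector == "population":
            dataset = self.dataset.model_copy(
                update={"catchment_population": self.dataset.catchment_population * scale}
            )
            return replace(self, dataset=dataset)
        if kind == "rate":
            if name not in self.epi:
                raise UnknownReferenceError(f"unresolvable selector {selector!r}")
            epi = dict(self.epi)
            epi[name] = epi[name].model_copy(
                update={"annual_rate": epi[name].annual_rate * scale}
            )
            return replace(self, epi=epi)
        if kind == "price":
            items = dict(self.items)
            if name == "all":
                targets = list(items)
            elif name.startswith("category:"):
                cat = ItemCategory(name.split(":", 1)[1])
                targets = [i for i, it in items.items() if it.category is cat]
            elif name in items:
                targets = [name]
            else:
                raise UnknownReferenceError(f"unresolvable selector {selector!r}")
            for i in targets:
                items[i] = items[i].model_copy(
                    update={"unit_price": items[i].unit_price * scale}
                )
            return replace(self, items=items)
        if kind == "salary":
            cadres = dict(self.cadres)
            targets = list(cadres) if name == "all" else [name]
            for c in targets:
                if c not in cadres:
                    raise UnknownReferenceError(f"unresolvable selector {selector!r}")
                cadres[c] = cadres[c].model_copy(
                    update={"annual_remuneration": cadres[c].annual_remuneration * scale}
                )
            return replace(self, cadres=cadres)
        if selector == "adjustment:access":
            # delta applies to the utilization rate (1 - q_access)
            new_access = 1.0 - (1.0 - self.adjustment.non_access_share) * scale
            adj = AdjustmentFactors(
                other_provider_share=dict(self.adjustment.other_provider_share),
                non_access_share=new_access,
            )
            return replace(self, adjustment=adj)
        raise UnknownReferenceError(f"unresolvable selector {selector!r}")


def sensitivity_oat(state, selector: str, delta: float) -> PerturbationResult:
    """One-at-a-time sensitivity: perturb one input, re-run the pipeline.

    ``state`` is any object exposing ``total()`` and ``perturbed(selector,
    delta)``; the perturbation acts on a copy, so the baseline state remains
    usable and two opposite sequential perturbations return to baseline.
    """
    baseline = state.total()
    new = state.perturbed(selector, delta).total()
    return PerturbationResult(
        variable=selector, delta=delta, baseline_total=baseline, new_total=new
    )
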