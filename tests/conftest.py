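import numpy as np
import pytest

from bphs_costing.costing import IndirectPool
from bphs_costing.types import (
    Cadre,
    CareType,
    FacilityDataset,
    FacilityType,
    ItemCategory,
    ResourceItem,
    ServiceDefinition,
    TreatmentProtocol,
)


def random_instance(seed: int, n_services: int = 8, n_cadres: int = 3, n_items: int = 5):
    """A small random facility costing instance for oracle comparisons."""
    rng = np.random.default_rng(seed)
    cadres = {
        f"c{i}": Cadre(
            cadre_id=f"c{i}",
            annual_remuneration=float(rng.uniform(2000, 15000)),
            is_technical=bool(i < n_cadres - 1),  # last cadre is support
        )
        for i in range(n_cadres)
    }
    items = {
        f"i{i}": ResourceItem(
            item_id=f"i{i}",
            category=list(ItemCategory)[i % len(ItemCategory)],
            unit_price=float(rng.uniform(0.1, 20)),
            donated=bool(rng.random() < 0.3),
        )
        for i in range(n_items)
    }
    services = {}
    protocols = {}
    utilization = {}
    for s in range(n_services):
        sid = f"s{s}"
        services[sid] = ServiceDefinition(
            service_id=sid,
            program="general curative care",
            care_type=CareType.curative if s % 2 else CareType.preventive,
            in_bphs=s % 3 != 0,
        )
        protocols[sid] = TreatmentProtocol(
            service_id=sid,
            staff_minutes={
                c: float(rng.uniform(0, 30)) for c in cadres if rng.random() < 0.8
            },
            item_quantities={
                i: float(rng.uniform(0, 3)) for i in items if rng.random() < 0.7
            },
        )
        utilization[sid] = float(rng.integers(1, 5000))
    dataset = FacilityDataset(
        facility_id=f"rand{seed}",
        facility_type=FacilityType.BHC,
        catchment_population=float(rng.uniform(5000, 40000)),
        utilization=utilization,
        expenditure={
            "technical_salaries": float(rng.uniform(1e4, 1e5)),
            "support_salaries": float(rng.uniform(1e3, 1e4)),
            "medicines_supplies": float(rng.uniform(1e4, 1e5)),
            "donated_goods": float(rng.uniform(0, 5e4)),
            "operating": float(rng.uniform(1e3, 1e4)),
        },
    )
    pool = IndirectPool(amount=float(rng.uniform(1e3, 5e4)))
    return dataset, services, cadres, items, protocols, pool


@pytest.fixture(scope="session")
def dykundi_chc():
    from bphs_costing.fixtures import build_dykundi_chc

    return build_dykundi_chc()


@pytest.fixture(scope="session")
def dykundi_chc_analysis(dykundi_chc):
    from bphs_costing.pipeline import analyze_facility

    return analyze_facility(dykundi_chc)
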