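"""Unit costing: direct costs, technical-minute demand, indirect allocation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bphs_costing.costing import (
    IndirectPool,
    allocate_indirect,
    direct_unit_cost,
    staff_minute_rate,
    technical_minutes_demand,
    unit_cost_table,
)
from bphs_costing.errors import AllocationError, UnknownReferenceError
from bphs_costing.types import Cadre, ResourceItem, TreatmentProtocol

from conftest import random_instance


def brute_force_direct(protocol, cadres, items):
    """Independent enumeration of the protocol rows."""
    staff = 0.0
    for cadre_id, minutes in protocol.staff_minutes.items():
        c = cadres[cadre_id]
        staff += minutes * c.annual_remuneration / c.annual_available_minutes
    goods = sum(
        qty * items[item_id].unit_price
        for item_id, qty in protocol.item_quantities.items()
    )
    return staff, goods


@pytest.mark.parametrize(
    "remuneration, minutes, expected",
    [(7_920.0, 79_200.0, 0.10), (0.0, 79_200.0, 0.0), (11_880.0, 79_200.0, 0.15)],
)
def test_staff_minute_rate(remuneration, minutes, expected):
    c = Cadre(cadre_id="c", annual_remuneration=remuneration, annual_available_minutes=minutes)
    assert staff_minute_rate(c) == pytest.approx(expected)


def test_staff_minute_rate_rejects_zero_minutes():
    c = Cadre.model_construct(
        cadre_id="c", annual_remuneration=100.0, annual_available_minutes=0.0
    )
    with pytest.raises(ValueError):
        staff_minute_rate(c)


class TestDirectUnitCost:
    def test_linear_combination(self):
        cadres = {"n": Cadre(cadre_id="n", annual_remuneration=7_920.0)}  # 0.10/min
        items = {
            "pill": ResourceItem(item_id="pill", unit_price=0.50),
            "test": ResourceItem(item_id="test", unit_price=1.00),
        }
        protocol = TreatmentProtocol(
            service_id="s",
            staff_minutes={"n": 15.0},
            item_quantities={"pill": 2.0, "test": 1.0},
        )
        assert direct_unit_cost(protocol, cadres, items) == pytest.approx((1.50, 2.00))

    def test_empty_protocol_is_free(self):
        assert direct_unit_cost(TreatmentProtocol(service_id="s"), {}, {}) == (0.0, 0.0)

    def test_unknown_reference_named(self):
        protocol = TreatmentProtocol(service_id="s", staff_minutes={"ghost": 5.0})
        with pytest.raises(UnknownReferenceError, match="ghost"):
            direct_unit_cost(protocol, {}, {})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        _, _, cadres, items, protocols, _ = random_instance(seed, n_cadres=3, n_items=5)
        for protocol in protocols.values():
            assert direct_unit_cost(protocol, cadres, items) == pytest.approx(
                brute_force_direct(protocol, cadres, items), rel=1e-12
            )


class TestTechnicalMinutes:
    def test_single_service(self):
        cadres = {"n": Cadre(cadre_id="n", annual_remuneration=1.0)}
        protocols = {"s": TreatmentProtocol(service_id="s", staff_minutes={"n": 12.0})}
        per_cadre, total = technical_minutes_demand({"s": 100}, protocols, cadres)
        assert per_cadre == {"n": 1_200.0} and total == 1_200.0

    def test_zero_utilization(self):
        cadres = {"n": Cadre(cadre_id="n", annual_remuneration=1.0)}
        protocols = {"s": TreatmentProtocol(service_id="s", staff_minutes={"n": 12.0})}
        per_cadre, total = technical_minutes_demand({"s": 0}, protocols, cadres)
        assert total == 0.0 and per_cadre["n"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_grand_total_excludes_support_minutes(self, seed):
        dataset, _, cadres, _, protocols, _ = random_instance(seed)
        per_cadre, total = technical_minutes_demand(dataset.utilization, protocols, cadres)
        expected = 0.0
        for sid, n in dataset.utilization.items():
            for cid, m in protocols[sid].staff_minutes.items():
                if cadres[cid].is_technical:
                    expected += n * m
        assert total == pytest.approx(expected, rel=1e-12)
        support = [c for c in cadres.values() if not c.is_technical]
        assert any(per_cadre[c.cadre_id] >= 0 for c in support)


class TestAllocateIndirect:
    def _two_service_setup(self):
        cadres = {"n": Cadre(cadre_id="n", annual_remuneration=1.0)}
        protocols = {
            "a": TreatmentProtocol(service_id="a", staff_minutes={"n": 3.0}),
            "b": TreatmentProtocol(service_id="b", staff_minutes={"n": 7.0}),
        }
        return cadres, protocols

    def test_proportional_split(self):
        cadres, protocols = self._two_service_setup()
        out = allocate_indirect(IndirectPool(amount=100.0), {"a": 100, "b": 100}, protocols, cadres)
        assert out["a"] * 100 == pytest.approx(30.0)
        assert out["b"] * 100 == pytest.approx(70.0)

    def test_zero_pool_all_zero(self):
        cadres, protocols = self._two_service_setup()
        out = allocate_indirect(IndirectPool(amount=0.0), {"a": 10, "b": 20}, protocols, cadres)
        assert out == {"a": 0.0, "b": 0.0}

    def test_positive_pool_needs_technical_minutes(self):
        cadres = {"s": Cadre(cadre_id="s", annual_remuneration=1.0, is_technical=False)}
        protocols = {"a": TreatmentProtocol(service_id="a", staff_minutes={"s": 10.0})}
        with pytest.raises(AllocationError):
            allocate_indirect(IndirectPool(amount=10.0), {"a": 5}, protocols, cadres)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_and_oracle(self, seed):
        dataset, _, cadres, _, protocols, pool = random_instance(seed, n_services=10)
        out = allocate_indirect(pool, dataset.utilization, protocols, cadres)
        allocated = sum(dataset.utilization[s] * out[s] for s in out)
        assert allocated == pytest.approx(pool.amount, rel=1e-6)
        # independent proportional split
        weights = {
            s: dataset.utilization[s]
            * sum(m for c, m in protocols[s].staff_minutes.items() if cadres[c].is_technical)
            for s in dataset.utilization
        }
        total_w = sum(weights.values())
        for s in out:
            expected = pool.amount * weights[s] / total_w / dataset.utilization[s]
            assert out[s] == pytest.approx(expected, rel=1e-9)

    def test_doubling_volumes_halves_per_case_indirect(self):
        dataset, _, cadres, _, protocols, pool = random_instance(11)
        base = allocate_indirect(pool, dataset.utilization, protocols, cadres)
        doubled = allocate_indirect(
            pool, {s: 2 * n for s, n in dataset.utilization.items()}, protocols, cadres
        )
        for s in base:
            assert doubled[s] == pytest.approx(base[s] / 2, rel=1e-9)


class TestUnitCostTable:
    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence_small_instances(self, seed):
        dataset, _, cadres, items, protocols, pool = random_instance(seed, n_services=10)
        table = unit_cost_table(dataset, protocols, cadres, items, pool)
        weights = {
            s: dataset.utilization[s]
            * sum(m for c, m in protocols[s].staff_minutes.items() if cadres[c].is_technical)
            for s in dataset.utilization
        }
        total_w = sum(weights.values())
        for sid, u in table.items():
            staff, goods = brute_force_direct(protocols[sid], cadres, items)
            indirect = pool.amount * weights[sid] / total_w / dataset.utilization[sid]
            assert u.total_unit_cost == pytest.approx(staff + goods + indirect, rel=1e-9)
            assert u.total_unit_cost == pytest.approx(
                u.direct_staff_cost + u.direct_items_cost + u.indirect_cost
            )

    def test_single_service_absorbs_full_pool(self):
        cadres = {"n": Cadre(cadre_id="n", annual_remuneration=7_920.0)}
        items = {"i": ResourceItem(item_id="i", unit_price=2.0)}
        protocols = {
            "s": TreatmentProtocol(service_id="s", staff_minutes={"n": 10.0}, item_quantities={"i": 1.0})
        }
        from bphs_costing.types import FacilityDataset, FacilityType

        dataset = FacilityDataset(
            facility_id="f", facility_type=FacilityType.HSC,
            catchment_population=1000, utilization={"s": 250},
        )
        pool = IndirectPool(amount=500.0)
        (u,) = unit_cost_table(dataset, protocols, cadres, items, pool).values()
        direct = 10 * 0.10 + 2.0
        assert u.total_unit_cost * 250 == pytest.approx(direct * 250 + 500.0)

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 100), bump=st.floats(0.01, 5.0))
    def test_price_increase_never_lowers_unit_costs(self, seed, bump):
        dataset, _, cadres, items, protocols, pool = random_instance(seed % 7)
        base = unit_cost_table(dataset, protocols, cadres, items, pool)
        rng = np.random.default_rng(seed)
        target = list(items)[int(rng.integers(len(items)))]
        items2 = dict(items)
        items2[target] = items2[target].model_copy(
            update={"unit_price": items2[target].unit_price + bump}
        )
        bumped = unit_cost_table(dataset, protocols, cadres, items2, pool)
        for sid in base:
            assert bumped[sid].total_unit_cost >= base[sid].total_unit_cost - 1e-12
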