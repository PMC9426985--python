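"""Scenario costing and gap reports."""

import pytest

from bphs_costing.costing import ServiceUnitCost, unit_cost_table
from bphs_costing.errors import DegenerateInputError
from bphs_costing.fixtures import build_dh_facility, build_dykundi_hsc, build_mht_facility
from bphs_costing.needs import NeededVolume
from bphs_costing.pipeline import analyze_facility
from bphs_costing.scenarios import (
    gap_report,
    required_staffing,
    scenario_actual_actual,
    scenario_actual_required,
    scenario_needed_required,
)
from bphs_costing.types import (
    CareType,
    FacilityDataset,
    FacilityType,
    ServiceDefinition,
    round_half_up,
)

from conftest import random_instance


class TestActualActual:
    def test_mht_cost_per_service(self):
        a = analyze_facility(build_mht_facility())
        assert round_half_up(a.actual.cost_per_service, 2) == 5.42

    def test_dykundi_chc_per_capita(self, dykundi_chc_analysis):
        assert round_half_up(dykundi_chc_analysis.actual.cost_per_capita_total, 2) == 8.35

    def test_zero_volume_facility_flagged(self):
        d = FacilityDataset(
            facility_id="f", facility_type=FacilityType.HSC,
            catchment_population=2_000, expenditure={"operating": 4_000.0},
        )
        res = scenario_actual_actual(d, {}, {})
        assert res.cost_per_service is None
        assert "zero_volume" in res.flags
        assert res.cost_per_capita_total == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_package_split_decomposes_exactly(self, seed):
        dataset, services, cadres, items, protocols, pool = random_instance(seed)
        table = unit_cost_table(dataset, protocols, cadres, items, pool)
        for fn in (scenario_actual_actual, scenario_actual_required):
            res = fn(dataset, table, services)
            assert res.bphs_cost + res.non_bphs_cost == pytest.approx(res.total_cost)


class TestActualRequired:
    def test_dykundi_chc_funding_gap(self, dykundi_chc_analysis):
        a = dykundi_chc_analysis
        assert a.required.total_cost == pytest.approx(396_115, rel=1e-9)
        assert a.gap.actual_pct_of_required == 46

    def test_realized_average_unit_costs_reproduce_actual(self):
        d = FacilityDataset(
            facility_id="f", facility_type=FacilityType.HSC,
            catchment_population=1_000, utilization={"s": 400},
            expenditure={"operating": 1_200.0},
        )
        services = [
            ServiceDefinition(service_id="s", program="g", care_type=CareType.curative)
        ]
        realized = {
            "s": ServiceUnitCost(
                service_id="s", direct_staff_cost=1.0, direct_items_cost=1.0,
                indirect_cost=1.0,
            )
        }
        s1 = scenario_actual_actual(d, realized, services)
        s2 = scenario_actual_required(d, realized, services)
        assert s1.total_cost == s2.total_cost == pytest.approx(1_200.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_doubling_prices_adds_exactly_the_items_share(self, seed):
        dataset, services, cadres, items, protocols, pool = random_instance(seed)
        table = unit_cost_table(dataset, protocols, cadres, items, pool)
        base = scenario_actual_required(dataset, table, services)
        items2 = {
            i: it.model_copy(update={"unit_price": 2 * it.unit_price})
            for i, it in items.items()
        }
        table2 = unit_cost_table(dataset, protocols, cadres, items2, pool)
        doubled = scenario_actual_required(dataset, table2, services)
        items_share = sum(
            dataset.utilization[s] * table[s].direct_items_cost for s in table
        )
        assert doubled.total_cost - base.total_cost == pytest.approx(items_share, rel=1e-9)


class TestNeededRequired:
    def test_dykundi_chc_optimal_cost(self, dykundi_chc_analysis):
        a = dykundi_chc_analysis
        assert a.optimal.total_cost == pytest.approx(610_434, rel=1e-9)
        assert round_half_up(a.optimal.cost_per_capita_total, 2) == 27.82

    @pytest.mark.parametrize("seed", range(3))
    def test_needs_equal_to_actual_reproduce_required(self, seed):
        dataset, services, cadres, items, protocols, pool = random_instance(seed)
        table = unit_cost_table(dataset, protocols, cadres, items, pool)
        s2 = scenario_actual_required(dataset, table, services)
        needed = {
            s: NeededVolume(service_id=s, gross_need=n, adjusted_need=n)
            for s, n in dataset.utilization.items()
        }
        s3 = scenario_needed_required(
            dataset, protocols, cadres, items, pool, needed, services
        )
        assert s3.total_cost == pytest.approx(s2.total_cost, rel=1e-9)

    def test_zero_needs_cost_nothing_variable(self):
        dataset, services, cadres, items, protocols, pool = random_instance(9)
        s3 = scenario_needed_required(dataset, protocols, cadres, items, pool, {}, services)
        assert s3.total_cost == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_scaling_up_needs_never_costs_less_than_required(self, seed):
        dataset, services, cadres, items, protocols, pool = random_instance(seed)
        table = unit_cost_table(dataset, protocols, cadres, items, pool)
        s2 = scenario_actual_required(dataset, table, services)
        needed = {
            s: NeededVolume(service_id=s, gross_need=2 * n, adjusted_need=1.5 * n)
            for s, n in dataset.utilization.items()
        }
        s3 = scenario_needed_required(
            dataset, protocols, cadres, items, pool, needed, services
        )
        assert s3.total_cost >= s2.total_cost - 1e-9


class TestGapReport:
    def test_dh_funding_percentage(self):
        a = analyze_facility(build_dh_facility())
        assert round_half_up(100 * a.actual.total_cost / a.required.total_cost) == 37

    def test_dykundi_hsc_volume_gap(self):
        a = analyze_facility(build_dykundi_hsc())
        assert a.gap.actual_pct_of_optimal_services == 41
        assert a.gap.actual_pct_of_required == 81
        assert a.gap.required_staff_total == 4
        assert a.gap.required_staff_optimal_total == 8

    def test_identical_scenarios_are_fully_funded(self, dykundi_chc):
        a = analyze_facility(dykundi_chc)
        g = gap_report(
            a.required, a.required, a.optimal, dykundi_chc.dataset,
            dykundi_chc.protocols, dykundi_chc.cadres,
        )
        assert g.actual_pct_of_required == 100

    def test_zero_required_cost_rejected(self, dykundi_chc):
        a = analyze_facility(dykundi_chc)
        zero = a.required.model_copy(update={"total_cost": 0.0})
        with pytest.raises(DegenerateInputError):
            gap_report(
                a.actual, zero, a.optimal, dykundi_chc.dataset,
                dykundi_chc.protocols, dykundi_chc.cadres,
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_required_staffing_monotone_in_volumes(self, seed):
        dataset, _, cadres, _, protocols, _ = random_instance(seed)
        fte1, heads1 = required_staffing(dataset.utilization, protocols, cadres)
        bigger = {s: 1.7 * n for s, n in dataset.utilization.items()}
        fte2, heads2 = required_staffing(bigger, protocols, cadres)
        for c in fte1:
            assert fte2[c] >= fte1[c] and heads2[c] >= heads1[c]
            assert heads1[c] >= fte1[c] - 1e-9  # ceiling covers the workload
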