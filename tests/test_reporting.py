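"""Rankings, breakdowns, donation shares, and one-at-a-time sensitivity."""

import pytest

from bphs_costing.errors import UnknownReferenceError
from bphs_costing.fixtures import (
    build_dh_facility,
    build_mht_facility,
    load_fixture,
    national_census,
    national_summary_means,
)
from bphs_costing.national import FacilityTypeSummary, extrapolate_national
from bphs_costing.reporting import (
    ExpenditureState,
    OptimalCostState,
    breakdowns,
    donation_dependence,
    donation_dependence_items,
    rank_services,
    sensitivity_oat,
)
from bphs_costing.types import CareType, ResourceItem, ServiceDefinition, round_half_up


def _dykundi_costed(analysis, dataset):
    return {
        sid: (n, n * analysis.unit_costs[sid].total_unit_cost)
        for sid, n in dataset.utilization.items()
    }


def _national_actual_lines():
    """National actual expenditure split into published input shares."""
    t1 = load_fixture("table1")
    summaries = [
        FacilityTypeSummary.from_means(ft, t1["n_sampled"][ft.value], means)
        for ft, means in national_summary_means().items()
    ]
    total = extrapolate_national(summaries, national_census()).totals["actual_total_cost"]
    return {
        "donated_goods": 0.47 * total,
        "medicines_supplies": 0.16 * total,
        "technical_salaries": 0.26 * total,
        "support_salaries": 0.06 * total,
        "operating": 0.05 * total,
    }


class TestRankServices:
    def test_dykundi_top_ranking(self, dykundi_chc, dykundi_chc_analysis):
        costed = _dykundi_costed(dykundi_chc_analysis, dykundi_chc.dataset)
        ranked = rank_services(costed, dykundi_chc.dataset.catchment_population, top_n=10)
        top = ranked[0]
        assert top.service_id == "asthma_copd"
        assert round_half_up(top.cost_pct) == 16
        assert round_half_up(top.avg_cost_per_service, 2) == 104.59
        assert round_half_up(top.cost_per_capita, 2) == 2.86
        assert round_half_up(top.volume_pct, 1) == 1.4
        # fourth-ranked: highest volume but a low unit cost
        assert ranked[3].service_id == "uti"
        assert round_half_up(ranked[3].avg_cost_per_service, 2) == 10.34
        published = [row["service_id"] for row in load_fixture("table5")]
        assert [r.service_id for r in ranked] == published

    def test_ties_break_on_service_id(self):
        costed = {"b": (10, 100.0), "a": (10, 100.0), "c": (5, 200.0)}
        ranked = rank_services(costed, 1_000, top_n=3)
        assert [r.service_id for r in ranked] == ["c", "a", "b"]

    def test_top_n_beyond_count_returns_all(self):
        costed = {"a": (1, 1.0), "b": (2, 2.0)}
        assert len(rank_services(costed, 100, top_n=10)) == 2

    def test_ranking_is_a_permutation_with_full_shares(self, dykundi_chc, dykundi_chc_analysis):
        costed = _dykundi_costed(dykundi_chc_analysis, dykundi_chc.dataset)
        ranked = rank_services(costed, 21_942, top_n=len(costed))
        assert sorted(r.service_id for r in ranked) == sorted(costed)
        assert sum(r.cost_pct for r in ranked) == pytest.approx(100, abs=0.5)
        assert sum(r.volume_pct for r in ranked) == pytest.approx(100, abs=0.5)
        for r in ranked:
            assert r.avg_cost_per_service * r.volume == pytest.approx(r.total_cost, rel=1e-9)


class TestBreakdowns:
    def test_national_required_care_type_shares(self):
        text = load_fixture("national_text")
        total = text["required_all_total"]
        costed = {
            "curative_mass": (1.0, 0.57 * total),
            "preventive_mass": (1.0, 0.41 * total),
            "other_mass": (1.0, 0.02 * total),
        }
        services = [
            ServiceDefinition(service_id="curative_mass", program="a", care_type=CareType.curative),
            ServiceDefinition(service_id="preventive_mass", program="b", care_type=CareType.preventive),
            ServiceDefinition(service_id="other_mass", program="c", care_type=CareType.inpatient),
        ]
        shares = breakdowns(costed, services)["care_type"]["cost_share"]
        assert round_half_up(shares["curative"]) == 57
        assert round_half_up(shares["preventive"]) == 41

    def test_mht_preventive_volume_share(self):
        inputs = build_mht_facility()
        costed = {sid: (n, 1.0) for sid, n in inputs.dataset.utilization.items()}
        shares = breakdowns(costed, inputs.services)["care_type"]["volume_share"]
        assert round_half_up(shares["preventive"], 1) == 64.6

    def test_single_category_is_everything(self):
        costed = {"s": (10, 50.0)}
        services = [ServiceDefinition(service_id="s", program="p", care_type=CareType.curative)]
        out = breakdowns(costed, services)
        assert out["care_type"]["cost_share"] == {"curative": 100.0}
        assert out["program"]["volume_share"] == {"p": 100.0}

    def test_each_dimension_sums_to_100(self, dykundi_chc, dykundi_chc_analysis):
        costed = _dykundi_costed(dykundi_chc_analysis, dykundi_chc.dataset)
        out = breakdowns(costed, dykundi_chc.services)
        for dim in out.values():
            for shares in dim.values():
                assert sum(shares.values()) == pytest.approx(100.0)


class TestDonationDependence:
    def test_national_actual_share(self):
        shares = donation_dependence(_national_actual_lines())
        assert round_half_up(shares.pct_of_total) == 47

    def test_mht_dependence_is_extreme(self):
        shares = donation_dependence(build_mht_facility().dataset.expenditure)
        assert round_half_up(shares.pct_of_medicines_supplies) == 93

    def test_dh_dependence_is_low(self):
        shares = donation_dependence(build_dh_facility().dataset.expenditure)
        assert round_half_up(shares.pct_of_medicines_supplies) == 28

    def test_no_donations(self):
        shares = donation_dependence({"medicines_supplies": 100.0, "operating": 10.0})
        assert shares.pct_of_total == 0.0

    def test_all_items_donated(self):
        items = [ResourceItem(item_id="v", unit_price=2.0, donated=True)]
        shares = donation_dependence_items({"v": 500.0}, items, other_cost=500.0)
        assert shares.pct_of_medicines_supplies == 100.0
        assert shares.pct_of_total == 50.0


class TestSensitivity:
    def test_national_medicines_cut(self):
        state = ExpenditureState(lines=_national_actual_lines())
        r = sensitivity_oat(state, "group:medicines", -0.10)
        assert round_half_up(r.pct_change) == -6
        assert r.absolute_change == pytest.approx(-20e6, rel=0.05)

    def test_national_salary_raise(self):
        state = ExpenditureState(lines=_national_actual_lines())
        r = sensitivity_oat(state, "group:technical_salaries", +0.10)
        assert r.pct_change == pytest.approx(2.5, abs=0.2)

    def test_zero_delta_changes_nothing(self):
        state = ExpenditureState(lines={"operating": 10.0, "donated_goods": 5.0})
        r = sensitivity_oat(state, "line:operating", 0.0)
        assert r.absolute_change == 0.0 and r.pct_change == 0.0

    def test_closed_form_share_times_delta(self):
        # purely variable model: a component with share f perturbed by d
        # moves the total by exactly f*d
        lines = {"a": 30.0, "b": 70.0}
        r = sensitivity_oat(ExpenditureState(lines=lines), "line:a", 0.2)
        assert r.pct_change == pytest.approx(0.3 * 0.2 * 100, rel=1e-12)

    def test_dykundi_population_cut_is_damped_by_fixed_pool(self, dykundi_chc):
        state = OptimalCostState(
            dataset=dykundi_chc.dataset, services=dykundi_chc.services,
            protocols=dykundi_chc.protocols, cadres=dykundi_chc.cadres,
            items=dykundi_chc.items, pool=dykundi_chc.pool,
            epi=dykundi_chc.epi, adjustment=dykundi_chc.adjustment,
        )
        r = sensitivity_oat(state, "population", -0.10)
        assert round_half_up(r.pct_change, 1) == -9.5

    def test_opposite_deltas_return_to_baseline(self, dykundi_chc):
        state = OptimalCostState(
            dataset=dykundi_chc.dataset, services=dykundi_chc.services,
            protocols=dykundi_chc.protocols, cadres=dykundi_chc.cadres,
            items=dykundi_chc.items, pool=dykundi_chc.pool,
            epi=dykundi_chc.epi, adjustment=dykundi_chc.adjustment,
        )
        base = state.total()
        up = state.perturbed("price:all", 0.25)
        back = up.perturbed("price:all", -0.2)  # (1.25)(0.8) = 1 exactly
        assert back.total() == pytest.approx(base, rel=1e-9)

    def test_unresolvable_selector_rejected(self):
        state = ExpenditureState(lines={"operating": 1.0})
        with pytest.raises(UnknownReferenceError):
            sensitivity_oat(state, "group:nonexistent", 0.1)
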