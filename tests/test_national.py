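"""Facility-type summaries and national extrapolation."""

import pytest

from bphs_costing.errors import MissingInputError
from bphs_costing.fixtures import load_fixture, national_census, national_summary_means
from bphs_costing.national import (
    FacilityTypeSummary,
    MetricSummary,
    extrapolate_national,
    summarize_type,
)
from bphs_costing.types import FacilityType, FacilityTypeCensus, round_half_up


def _published_summaries():
    t1 = load_fixture("table1")
    return [
        FacilityTypeSummary.from_means(ft, t1["n_sampled"][ft.value], means)
        for ft, means in national_summary_means().items()
    ]


class TestSummarizeType:
    def test_single_facility_degenerate(self):
        row = {"catchment_population": 8_000.0, "actual_total_cost": 50_000.0}
        s = summarize_type([row], FacilityType.HSC)
        m = s.metrics["actual_total_cost"]
        assert m.mean == m.min == m.max == 50_000.0

    def test_mean_matches_brute_force(self):
        import numpy as np

        rng = np.random.default_rng(5)
        rows = [
            {"actual_total_cost": float(rng.uniform(2e4, 2e5))} for _ in range(15)
        ]
        s = summarize_type(rows, FacilityType.BHC)
        vals = [r["actual_total_cost"] for r in rows]
        assert s.metrics["actual_total_cost"].mean == pytest.approx(sum(vals) / 15)
        assert s.metrics["actual_total_cost"].min == min(vals)
        assert s.metrics["actual_total_cost"].max == max(vals)

    def test_hsc_catchment_group(self):
        # 15 sub-centers calibrated to the published mean and range
        lo, hi, mean, n = 4_320.0, 11_662.0, 6_561.0, 15
        body = (mean * n - lo - hi) / (n - 2)
        rows = [{"catchment_population": p} for p in [lo, hi] + [body] * (n - 2)]
        s = summarize_type(rows, FacilityType.HSC)
        m = s.metrics["catchment_population"]
        assert (round_half_up(m.mean), m.min, m.max) == (6_561, 4_320, 11_662)

    def test_empty_group_rejected(self):
        with pytest.raises(MissingInputError):
            summarize_type([], FacilityType.MHT)

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            MetricSummary(mean=5.0, min=6.0, max=7.0)


class TestExtrapolateNational:
    def test_published_headline_figures(self):
        est = extrapolate_national(_published_summaries(), national_census())
        pc = est.per_capita
        assert round_half_up(pc["actual_bphs_cost"], 2) == 8.93
        assert round_half_up(pc["required_bphs_cost"], 2) == 14.34
        assert round_half_up(pc["actual_total_cost"], 2) == 10.14
        assert round_half_up(pc["required_total_cost"], 2) == 17.81
        assert est.pct_bphs_funded == 62
        assert est.pct_total_funded == 57
        assert round_half_up(est.bphs_utilization_per_capita, 2) == 2.74

    def test_totals_match_published_within_mean_rounding(self):
        # The published per-type means are rounded to whole dollars, so
        # recomposed totals agree only within a small relative tolerance.
        est = extrapolate_national(_published_summaries(), national_census())
        text = load_fixture("national_text")
        assert est.totals["actual_bphs_cost"] == pytest.approx(
            text["actual_bphs_total"], rel=5e-4
        )
        assert est.totals["required_total_cost"] == pytest.approx(
            text["required_all_total"], rel=5e-4
        )

    def test_per_type_totals_recompose(self):
        est = extrapolate_national(_published_summaries(), national_census())
        for metric, total in est.totals.items():
            parts = sum(d.get(metric, 0.0) for d in est.per_type_totals.values())
            assert parts == pytest.approx(total)
            assert est.per_capita[metric] * est.national_population == pytest.approx(total)

    def test_linear_in_census_counts(self):
        census = national_census()
        est = extrapolate_national(_published_summaries(), census)
        doubled = FacilityTypeCensus(
            counts={ft: 2 * c for ft, c in census.counts.items()},
            national_population=census.national_population,
        )
        est2 = extrapolate_national(_published_summaries(), doubled)
        for metric in est.totals:
            assert est2.totals[metric] == pytest.approx(2 * est.totals[metric])
            assert est2.per_capita[metric] == pytest.approx(2 * est.per_capita[metric])

    def test_single_type_identity(self):
        s = FacilityTypeSummary.from_means(
            FacilityType.CHC, 1, {"actual_total_cost": 100_000.0, "required_total_cost": 200_000.0}
        )
        census = FacilityTypeCensus(
            counts={FacilityType.CHC: 1}, national_population=1_000.0
        )
        est = extrapolate_national([s], census)
        assert est.totals["actual_total_cost"] == 100_000.0
        assert est.pct_total_funded == 50

    def test_missing_census_type_rejected(self):
        s = FacilityTypeSummary.from_means(FacilityType.MHT, 1, {"actual_total_cost": 1.0})
        census = FacilityTypeCensus(
            counts={FacilityType.CHC: 5}, national_population=1_000.0
        )
        with pytest.raises(MissingInputError):
            extrapolate_national([s], census)
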