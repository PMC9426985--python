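"""End-to-end orchestration over in-memory inputs.

The pipeline steps are the modules' public operations composed in the obvious
order: validate, unit-cost, scenarios, gap, then type summaries and national
extrapolation.  File-based runs (:mod:`bphs_costing.io`) and synthetic-bundle
analyses both come through here, so tests and the acceptance script exercise
exactly the code a command-line run uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .costing import ServiceUnitCost, pool_from_expenditure, unit_cost_table
from .errors import MissingInputError
from .fixtures import FacilityInputs
from .national import (
    FacilityTypeSummary,
    NationalEstimate,
    extrapolate_national,
    facility_metrics,
    summarize_type,
)
from .needs import NeededVolume, optimal_volume_table
from .scenarios import (
    GapReport,
    ScenarioResult,
    gap_report,
    scenario_actual_actual,
    scenario_actual_required,
    scenario_needed_required,
)
from .synthetic import SyntheticBundle
from .types import FacilityDataset, FacilityType, validate_dataset

__all__ = ["FacilityAnalysis", "BundleAnalysis", "analyze_facility", "analyze_bundle"]


@dataclass
class FacilityAnalysis:
    """All computed outputs for one facility."""

    dataset: FacilityDataset
    unit_costs: dict[str, ServiceUnitCost]
    actual: ScenarioResult
    required: ScenarioResult
    optimal: ScenarioResult | None = None
    needed: dict[str, NeededVolume] | None = None
    optimal_per_capita: float | None = None
    gap: GapReport | None = None

    @property
    def funding_pct(self) -> float:
        return 100.0 * self.actual.total_cost / self.required.total_cost


def analyze_facility(inputs: FacilityInputs) -> FacilityAnalysis:
    """Run validation, costing and all applicable scenarios for one facility.

    The optimal scenario and the gap report are produced only when the inputs
    carry epidemiology entries and adjustment factors.
    """
    issues = validate_dataset(
        inputs.dataset, inputs.services, inputs.protocols, inputs.cadres
    )
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise MissingInputError(
            "dataset failed validation: " + "; ".join(i.message for i in errors)
        )
    unit_costs = unit_cost_table(
        inputs.dataset, inputs.protocols, inputs.cadres, inputs.items, inputs.pool
    )
    s1 = scenario_actual_actual(inputs.dataset, unit_costs, inputs.services)
    s2 = scenario_actual_required(inputs.dataset, unit_costs, inputs.services)
    analysis = FacilityAnalysis(
        dataset=inputs.dataset, unit_costs=unit_costs, actual=s1, required=s2
    )
    if inputs.epi and inputs.adjustment is not None:
        package = {
            sid: svc for sid, svc in inputs.services.items() if sid in inputs.epi
        }
        needed, per_capita = optimal_volume_table(
            inputs.dataset, package, inputs.epi, inputs.adjustment
        )
        s3 = scenario_needed_required(
            inputs.dataset,
            inputs.protocols,
            inputs.cadres,
            inputs.items,
            inputs.pool,
            needed,
            inputs.services,
        )
        analysis.optimal = s3
        analysis.needed = needed
        analysis.optimal_per_capita = per_capita
        analysis.gap = gap_report(
            s1, s2, s3, inputs.dataset, inputs.protocols, inputs.cadres
        )
    return analysis


@dataclass
class BundleAnalysis:
    """Per-facility analyses plus type summaries and the national estimate."""

    facilities: list[FacilityAnalysis]
    summaries: dict[FacilityType, FacilityTypeSummary]
    national: NationalEstimate

    @property
    def funding_ratio(self) -> float:
        """Pooled actual / required cost over all facilities (recovery statistic)."""
        actual = sum(a.actual.total_cost for a in self.facilities)
        required = sum(a.required.total_cost for a in self.facilities)
        return actual / required

    def funding_pct(self) -> float:
        return 100.0 * self.funding_ratio


def analyze_bundle(bundle: SyntheticBundle) -> BundleAnalysis:
    """Analyze every facility of a bundle and extrapolate nationally."""
    analyses: list[FacilityAnalysis] = []
    rows_by_type: dict[FacilityType, list[Mapping[str, float]]] = {}
    for dataset in bundle.facilities:
        inputs = FacilityInputs(
            dataset=dataset,
            services=bundle.services,
            cadres=bundle.cadres,
            items=bundle.items,
            protocols=bundle.protocols,
            pool=pool_from_expenditure(dataset),
            epi=bundle.epi,
            adjustment=bundle.adjustment,
        )
        a = analyze_facility(inputs)
        analyses.append(a)
        rows_by_type.setdefault(dataset.facility_type, []).append(
            facility_metrics(dataset, a.actual, a.required, bundle.services)
        )
    summaries = {
        ft: summarize_type(rows, ft) for ft, rows in rows_by_type.items()
    }
    national = extrapolate_national(summaries.values(), bundle.census)
    return BundleAnalysis(facilities=analyses, summaries=summaries, national=national)
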