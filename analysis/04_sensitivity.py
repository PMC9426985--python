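#!/usr/bin/env python
"""One-at-a-time sensitivity of the national and Dykundi CHC totals.

Each row re-runs the relevant pipeline with one input perturbed; writes
results/sensitivity.csv.
"""

from pathlib import Path

import pandas as pd

from bphs_costing.fixtures import (
    build_dykundi_chc,
    load_fixture,
    national_census,
    national_summary_means,
)
from bphs_costing.national import FacilityTypeSummary, extrapolate_national
from bphs_costing.reporting import ExpenditureState, OptimalCostState, sensitivity_oat
from bphs_costing.types import round_half_up

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    t1 = load_fixture("table1")
    summaries = [
        FacilityTypeSummary.from_means(ft, t1["n_sampled"][ft.value], means)
        for ft, means in national_summary_means().items()
    ]
    total = extrapolate_national(summaries, national_census()).totals["actual_total_cost"]
    national = ExpenditureState(
        lines={
            "donated_goods": 0.47 * total,
            "medicines_supplies": 0.16 * total,
            "technical_salaries": 0.26 * total,
            "support_salaries": 0.06 * total,
            "operating": 0.05 * total,
        }
    )
    chc = build_dykundi_chc()
    optimal = OptimalCostState(
        dataset=chc.dataset, services=chc.services, protocols=chc.protocols,
        cadres=chc.cadres, items=chc.items, pool=chc.pool,
        epi=chc.epi, adjustment=chc.adjustment,
    )
    runs = [
        ("national actual", national, "group:medicines", -0.10),
        ("national actual", national, "group:technical_salaries", +0.10),
        ("dykundi CHC optimal", optimal, "population", -0.10),
        ("dykundi CHC optimal", optimal, "adjustment:access", -0.10),
        ("dykundi CHC optimal", optimal, "rate:asthma_copd", -0.50),
        ("dykundi CHC optimal", optimal, "price:all", +0.10),
    ]
    rows = []
    for label, state, selector, delta in runs:
        r = sensitivity_oat(state, selector, delta)
        rows.append(
            {
                "model": label,
                "variable": selector,
                "delta_pct": 100 * delta,
                "baseline_usd": round_half_up(r.baseline_total, 0),
                "new_usd": round_half_up(r.new_total, 0),
                "change_usd": round_half_up(r.absolute_change, 0),
                "change_pct": round_half_up(r.pct_change, 1),
            }
        )
        print(f"{label:>20} | {selector:<28} {100 * delta:+.0f}% -> {r.pct_change:+.1f}%")
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "sensitivity.csv", index=False)
    print(
        "finding: totals respond almost proportionally to volume drivers "
        "(population, access) but are damped by the fixed indirect pool; "
        "medicine prices dominate on the input side."
    )


if __name__ == "__main__":
    main()
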