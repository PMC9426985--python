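# bphs-costing

Activity-based costing and financing-gap analysis for a basic package of
primary health care (PHC) services, built around the 2018 costing of
Afghanistan's Basic Package of Health Services (BPHS). The package is aimed
at health economists and planners who need to answer three questions for a
network of facilities: what did the services actually cost, what *should*
they have cost given standard treatment protocols, and what would it cost to
serve the whole population that needs them?

## The model

For each service *s* at a facility, the **normative unit cost** is

```
u_s = Σ_c m_sc · w_c  +  Σ_i q_si · p_i  +  I · t_s / Σ_r n_r · t_r
      └─ staff ─┘        └─ items ─┘       └─── indirect ───┘
```

where `m_sc` are protocol minutes of cadre *c* per case, `w_c` is the cadre's
per-minute remuneration (annual pay / annual available minutes, default
79,200 min/yr), `q_si` and `p_i` are item quantities and unit prices (donated
goods priced at their normative price), and the facility-level indirect pool
`I` (support salaries + operating costs, actual spending used as the norm) is
allocated in proportion to utilization-weighted technical staff minutes
`n_s · t_s`. The allocation conserves the pool: `Σ_s n_s · indirect_s = I`.

**Need-based ("optimal") volumes** come from catchment population `P` and an
annual rate `r_s` (incidence, prevalence, or coverage target), reduced for
use of other providers and for non-access:

```
N_s = P · r_s · (1 − q_other[facility type]) · (1 − q_access)
```

Three **scenarios** are costed per facility — actual services at actual
expenditure, actual services at required (normative) cost, and needed
services at required cost with the indirect pool re-allocated over the needed
volumes. The financing gap is actual expenditure as a percentage of required.
Sampled facility-type means are extrapolated nationally by facility counts,
and one-at-a-time sensitivity re-runs the full pipeline with one input
perturbed.

## Worked example

```python
from bphs_costing.fixtures import build_dykundi_chc
from bphs_costing.pipeline import analyze_facility

chc = build_dykundi_chc()          # calibrated reconstruction of one CHC
a = analyze_facility(chc)
print(round(a.actual.cost_per_capita_total, 2))   # 8.35   USD actually spent per capita
print(round(a.required.total_cost))               # 396115 USD required for actual services
print(a.gap.actual_pct_of_required)               # 46     % of required cost funded
print(round(a.optimal.cost_per_capita_total, 2))  # 27.82  USD per capita at optimal volumes
print(round(a.unit_costs["asthma_copd"].total_unit_cost, 2))  # 104.59 USD per case
```

The facility spent US$8.35 per person but delivering its observed service mix
at protocol standards would have cost more than twice that (46% funded), and
covering the full estimated need would cost US$27.82 per capita — the cost of
closing the universal-coverage gap at this facility. The most expensive
single service by total normative cost is severe acute asthma/COPD management
at US$104.59 per case.

The numbered drivers under `analysis/` run the main analyses end to end and
write their tables under `results/`: `01_simulate.py` (synthetic bundle +
parameter recovery), `02_national_costing.py` (national extrapolation),
`03_dykundi_scenarios.py` (three-scenario comparison and service ranking),
`04_sensitivity.py` (one-at-a-time perturbations). A `bphs-cost` CLI exposes
the same pipeline over CSV inputs and a YAML manifest (`validate`,
`cost-facility`, `scenarios`, `national`, `rank`, `sensitivity`, `simulate`).

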