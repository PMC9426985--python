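# Methods

## Scope and data model

The package costs recurrent provider-level expenditure of primary health care
facilities for one year. Inputs are annual aggregates only: a facility roster
(type, province, catchment population, staffing), cadre remuneration, a
service catalogue with standard treatment protocols (staff minutes per cadre,
item quantities), a price list with donated flags, annual utilization counts,
expenditure by line item, an epidemiological rate table, and adjustment
factors. Capital expenditure, above-facility program management, community
health-post services, referral flows and discounting are out of scope, and
all money is nominal US dollars.

Five expenditure line items are recognised: technical salaries, support
salaries, medicines/supplies, donated goods, and operating costs. Donated
goods are a separate line (valued at normative prices, since their actual
cost is typically unknown) so that donation-dependence shares remain
computable from expenditure alone.

## Normative unit costs

Direct unit costs are bottom-up: protocol minutes times the cadre's
per-minute rate plus item quantities times unit prices. The per-minute rate
uses *actual* remuneration (providers cannot hire below market) divided by an
annual stock of available minutes. The default stock is 220 working days × 8
hours × 60 minutes × 0.75 productive-time factor = 79,200 minutes/year; no
published norm exists, so this is a configurable package default chosen to
make unit costs reproducible.

Indirect costs are a single facility-level pool — support salaries plus
operating expenditure, with actual spending standing in for absent norms —
allocated across services in proportion to utilization-weighted technical
staff minutes `n_s · t_s`. Per-case indirect cost is therefore
`I · t_s / Σ_r n_r t_r`; summing back over utilization returns the pool
exactly (asserted to 1e-6 relative in tests). Services whose protocols use no
technical staff time (pure commodity distribution) receive no indirect cost,
since the allocation basis is technical minutes by definition. No multi-tier
step-down cascades are attempted. A positive pool with zero technical minutes
across all services is an error, not a silent zero.

## Need estimation

Needed annual volume is `P · r · (1 − q_other) · (1 − q_access)`. All rates
are stored per person of *total* catchment population per year regardless of
their epidemiological denominator; subgroup-specific rates (e.g. per child
under five) must be folded into the stored rate. Coverage targets for
preventive services use the same formula — the `rate_kind` field carries the
semantics, not a different computation. `q_other` (care sought from private
or other public providers) is facility-type-specific; `q_access` (cannot or
will not access care) is global. The values used in the province-level
analyses are 20%/25%/15% for sub-center/basic/comprehensive health centers
plus a further 20% non-access; no shares were ever published for mobile teams
and district hospitals, so those remain required configuration with no
default. Needs are kept fractional until report time; rounding is half-up and
happens only in emitted tables, because rounding before aggregation distorts
per-capita figures.

## Scenarios and gaps

* **Actual/actual** — observed mix at observed expenditure (all lines,
  donated goods included). Cost per service uses all services (package and
  non-package) as the denominator. Actual spending is not recorded per
  service, so the package/non-package split allocates total expenditure in
  proportion to the normative cost masses of the delivered package and
  non-package volumes — the same recipe logic as indirect allocation. This is
  an estimate by construction and is documented as swappable.
* **Actual/required** — observed mix at normative unit costs, the indirect
  component allocated over those same observed volumes, so the total equals
  direct costs plus the full pool.
* **Needed/required** — need-based volumes at normative unit costs with the
  pool re-allocated over needed volumes. Because the pool is fixed, this
  scenario is not a rescaling of the previous one.

Indirect allocation happens over the complete service mix (package plus
non-package) before any package split, so non-package services bear their
share of overheads. The financing gap is actual as a percentage of required
(integer, half-up). Required staffing per technical cadre is total protocol
minutes under the scenario's volumes divided by the cadre's annual available
minutes; headcounts are ceilings (staff are hired whole) with fractional FTEs
also reported. Capacity constraints (rooms, beds, vehicle capacity) are
deliberately not modelled.

## National extrapolation

Sampled facilities are summarized per type by arithmetic mean and min–max
range; national totals are mean × national facility count, summed over types;
per-capita figures divide every type's total by the single national
population, since catchments overlap across facility levels. No survey
weights or variance estimates are attempted — the design is means × counts.
When summaries are built from published whole-dollar means rather than raw
facility data, recomposed totals are accepted within ±0.05% relative.

## Rankings, breakdowns, sensitivity

Rankings sort by total normative cost, descending, with ties broken by
service id (stable and reproducible); percentage columns are computed over
the untruncated set. Sensitivity is strictly one-at-a-time and strictly a
recomputation: the perturbed input is written into a copy of the state and
the full pipeline re-run. Share-scaling shortcuts would be wrong whenever a
fixed component (the indirect pool) is present — which is exactly why a 10%
population cut lowers the optimal total by 9.5%, not 10%, at the
comprehensive-health-center reconstruction. For purely variable models the
recomputation reduces to share × delta, which the tests use as a closed-form
check. No probabilistic sensitivity is performed.

## Published-table fixtures and calibrated reconstructions

`fixtures.load_fixture` exposes the published 2018 figures (facility-type
averages, the national census of 309/1,009/877/433/85 facilities and
31,526,403 population, the Dykundi comparison, the top-10 service ranking)
as structured data. The per-facility builders are **synthetic
reconstructions**: the publication prints aggregates, not protocols or
prices, so each builder solves a small calibration — protocol minutes
proportional to unit cost, one priced item per service, a pool consistent
with the stated population-sensitivity response — such that the engine's
ordinary arithmetic reproduces the printed aggregates. Residual volume at the
Dykundi CHC is spread over sixteen small synthetic lines so no artificial
aggregate outranks the published top ten. Calibration inputs are printed
values only; every reported number is computed by the engine at run time.

## Synthetic data generator

The generator emulates the study's sampling frame (7 mobile teams, 15 each of
four static types), with log-uniform catchment populations over the published
per-type ranges — a pragmatic stand-in for the wide, unmodelled within-type
heterogeneity of the real sample. Utilization is drawn around
`utilization_coverage × adjusted need` (default coverage 0.80): `noise = 0`
means deterministic half-up rounding, `noise = 1` Poisson, `noise > 1` a
gamma-Poisson mixture with variance `noise ×` mean. Actual expenditure is
constructed as `funding_ratio` (default 0.57) times the required cost of the
*expected* volumes — budgets are set on expectations, so sampling noise in
realized volumes propagates into the recovered funding ratio, which is what
makes parameter recovery a real test rather than an identity. Expenditure is
split across lines using the published input shares (medicines 63%, technical
salaries 26%, remainder support + operating). One seed drives a named,
ordered family of generators (per catalogue section, per facility slot), so
enlarging the bundle never reshuffles earlier draws.

What passing recovery tests show is that the pipeline arithmetic is
self-consistent under the generator's assumptions; they do not validate the
epidemiological rates, protocol content, or price levels against real
facilities, and real data are messier (missing indicators, misreported
catchments, within-year price changes) in ways the generator does not
emulate.

## Numerical conventions and limitations

Money is kept at full float precision internally; reports round half-up to
the printed precision (2 decimals for unit costs and per-capita figures,
integers for percentages). Zero-volume facilities get an undefined cost per
service (flagged) but per-capita figures are still computed. Degenerate
ratios (zero required cost, zero optimal volume, empty package) raise typed
errors rather than returning infinities.

Known limitations: the indirect pool is a single tier; the package split of
actual expenditure is a modelling assumption; inpatient services are costed
as per-admission recipes without bed-day structure; support staffing and
operating norms do not scale with service volumes in the optimal scenario
(their actuals are the norms); and the test-problem sizes (tens of services,
tens of facilities) are chosen for fast, deterministic suites rather than to
stress large national datasets.
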