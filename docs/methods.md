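# Methods

## Costing model

The package implements ingredient-based (bottom-up) incremental costing:
only expenditure introduced specifically for the program is counted, each
ingredient is costed at the lowest available level of detail, and the
pieces are aggregated into protocol- and program-level annual and
per-capita figures.

**Currency.** Ledgers are stored in their source currency (IRR expected)
and converted to US$ exactly once, immediately after reading, at one fixed
official rate (default 36 440 IRR/US$, the 2015–16 central-bank rate). A
currency tag on every item makes double conversion a hard error. No
inflation or PPP adjustment is applied; the analysis is a single-year
snapshot.

**Capital recovery.** Equipment prices are spread over the asset's useful
life with the annuity factor `a(L, r) = ((1+r)^L − 1)/(r (1+r)^L)`; the
annual charge is `price / a(L, r)`. `r` defaults to 0.10/yr. At `r = 0`
the analytic limit `a = L` (straight-line depreciation) is used, and
non-integer lives are accepted — the formula is defined for real `L`.
Useful lives are not published per equipment type; real runs must supply
them in the ledger, and the synthetic generator assigns them (default 5
years).

**Observation-window scaling.** Supply costs observed over `m` months are
scaled by `12/m`. The pilot window, February 2016–March 2017 inclusive, is
read as 13 months; `pilot_duration_months` is configurable because the
source material never states the figure it used. Demand is assumed
constant over the window — the estimator ignores seasonal variation.

**National apportionment.** Ministry-level (national) spending is divided
by 62, the number of Universities of Medical Sciences, attributing an
equal share to each university and hence to each pilot district's
implementation. Retraining and material revision are additionally divided
by their 5-year refresh cycle. District-level non-equipment capital items
(notably program introduction) are carried as one-off first-year amounts
rather than CRF-annualized; the per-capita report exposes them through the
with/without-introduction toggle.

**Personnel.** Per-visit task times come from direct observation (DOM) of
physicians, midwives and community health workers. Times are pooled per
role across districts and strata — the 2-urban + 2-rural, 10–20-patients
per-site design is too sparse to stratify the means. The fraction of the
working day spent on the program is `mean minutes × visits/day ÷ shift
length` (shift defaults to 480 min; never published, so configurable);
fractions above 1 are clamped to 1 with a logged warning because
over-allocation signals noisy timesheets rather than an invalid state.
Role attribution to protocols is proportional to the role's total observed
service-minutes per protocol; the source material states that service
times attribute staffing cost to protocols but gives no formula, and
minute-proportionality is the natural reading that conserves the role
total. Management time is representable as ledger `supervision` items
rather than folded into personnel.

**Allocation.** Supplies and personnel are variable (they scale with
coverage); all other categories are fixed. Shared supplies/equipment are
split equally over the protocols tagged on the item; non-specific overhead
is split equally over all five protocols. Equipment with no protocol tag
is treated as non-specific (the published rule is silent on this case) and
warned about. "Supervision" retains two report categories — recurrent
(annual workshops/supervision) and capital (initial setup) — keyed by the
ledger's capital/recurrent field, because both appear in the source
program's accounts.

**Per-capita.** Fixed cost ÷ eligible population, variable cost ÷ covered
population, per protocol. Two denominator modes exist:
`protocol_denominators` (default; each protocol has its own eligible and
covered counts, as protocols target different demographics) and
`program_denominators` (one pair for the whole program). Rounding to two
decimals happens only in report writers; all internal arithmetic is full
double precision, and comparisons against published two-decimal cells use
±0.01 because several published cells are truncations rather than
roundings (e.g. 1979.39/5 = 395.878 printed as 395.87).

## Coverage estimation

Each district's survey is a two-stage design: 25 clusters allocated to the
urban/rural strata proportionally to population with largest-remainder
(Hamilton) rounding, ties toward the larger stratum and at least one
cluster per stratum; then a seeded permutation selects blocks, and 10
eligible families are drawn per block; every eligible family member is
interviewed. The estimator is the plain unweighted ratio of users of ≥1
service to interviewed eligible individuals — the published definition
describes no design weights or finite-population correction. A block with
fewer than 10 eligible families aborts the draw with an error naming the
block, matching the field protocol of inviting until 10 families are
reached.

All randomness flows from one integer seed through counter-keyed
substreams (`default_rng([seed, tag])`): one stream per stratum for block
selection and one per block for family selection, so enlarging the design
adds clusters without perturbing existing ones.

Because usage is independent Bernoulli given eligibility, the unweighted
ratio is unbiased for the true usage probability under any such design;
the test suite verifies the mean over 2000 simulated surveys sits within
3 Monte-Carlo standard errors of the configured 40 % truth.

## Synthetic scenarios and what they do (not) show

A scenario states program-level annual US$ *targets* per protocol and
category plus survey-population shapes; the generator back-solves raw
ingredients so the pipeline reproduces the targets: supply rows carry
`target × window/12` in IRR, equipment rows carry `target × a(L, r)` as
the purchase price, national overhead rows carry `target × 62` (× 5 for
retraining), and salaries are solved from the role's cost share, task
times and roster. With the default zero time-noise (`time_cv = 0`) the DOM
log is balanced — one observation per (site, role, protocol), 15 per site,
within the 10–20 visits-per-site window — making the minute-proportional
attribution exact; with `time_cv > 0`, visit counts are uniform 10–20 per
site and times lognormal (positive, right-skewed service times; the mean
is the configured value).

`pilot_scenario()` sets every cost target to the published pilot figures.
The pilot did not publish per-protocol eligible/covered populations, and
its published per-protocol per-capita component cells are mutually
inconsistent with the printed protocol totals, so the scenario back-solves
denominators from the *internally consistent* published surface: the five
protocol totals without introduction (7.45, 1.05, 3.95, 7.13, 5.32 US$)
and the program total with introduction (25.32 US$). The with/without gap
is distributed over protocols proportionally to each protocol's
feasibility bound (covered ≤ eligible), which keeps every back-solved
denominator strictly feasible; the published per-protocol *with* column is
therefore matched in sum but not cell-by-cell. Eligible populations land
in the 30 000–80 000 range across the two districts — plausible for
districts of this size.

Limitations of the synthetic data relative to real program records: ledger
items are one row per category × protocol rather than hundreds of small
purchases; task times have a single configurable dispersion rather than
provider- and site-level heterogeneity; survey eligibility is independent
across household members and usage is independent Bernoulli, so passing
tests demonstrate the *estimators'* correctness under the stated design,
not robustness to intra-household correlation, non-response, or
misreported expenditure. The published overall coverage figure (40.74 %)
is not reproducible from its own headcounts (265/637 = 41.60 %) and is not
targeted; the package implements the stated definition.

## Numerical choices

- Equal splits are exact divisions; conservation (Σ cells = Σ inputs) holds
  to 1e-6 on arbitrary ledgers and is property-tested.
- Validation is two-tier: hard schema/enumeration errors are raised at
  read time; item-level invariant breaches are collected into a report and
  block the pipeline only if errors (not warnings) are present. Duplicate
  item ids warn; unit × unit-cost must match the amount within 0.5 currency
  units.
- Monte-Carlo sizes: 2000 replicate surveys in the test suite, 500 in the
  acceptance script — both give a standard error of the mean well under
  0.5 percentage points of coverage.
- Degenerate inputs: zero-cost items flow through as zeros; a positive
  variable cost with zero covered population is an error (undefined
  per-user cost); a zero grand total makes category shares undefined and
  errors.
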