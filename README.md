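# pencost

Bottom-up, ingredient-based incremental costing for primary-care
non-communicable-disease (NCD) prevention programs, modelled on the IraPEN
pilot — Iran's adaptation of the WHO Package of Essential NCD interventions
(PEN), piloted in the districts of Naqadeh and Shahreza with five service
protocols (MI & stroke prevention, respiratory disease screening,
colorectal-cancer prevention, female-cancer prevention, and an NCD
risk-factor survey).

The package is for health economists and program evaluators who need to
turn raw implementation records — item-level expenditure ledgers,
direct-observation task-time logs, staffing rosters, and household-survey
microdata — into auditable annual and per-capita incremental cost reports,
plus a design-based program-coverage estimate.

## The model

**Annualization.** Every expenditure item is converted to an equivalent
annual cost in US$ (one fixed official exchange rate, 36 440 IRR/US$):

- equipment is annualized by the capital recovery factor: the annual charge
  is the purchase price divided by the present-value-of-annuity factor

  `a(L, r) = ((1+r)^L − 1) / (r (1+r)^L)`

  for useful life `L` years at discount rate `r` (default 10 %/yr);
- supply spend observed over `m` months is scaled by `12/m`;
- retraining/material-revision cost is divided by its 5-year refresh cycle;
- national (ministry-level) spending of any kind is divided by 62, the
  number of Universities of Medical Sciences, to attribute an equal share
  to each district's university;
- personnel cost per role is `f × s × 12 × H`, where `f` is the fraction of
  the working day spent on program visits (mean observed minutes per visit
  × visits per day ÷ shift length), `s` the monthly salary and `H` the
  headcount; role costs are attributed to protocols in proportion to each
  role's observed service-minutes per protocol.

**Allocation.** Items tagged to one protocol are specific to it; items
shared by several protocols are split equally between them; non-specific
overhead (introduction, supervision, consultancy, customization,
retraining) is split equally across all five protocols. Supplies and
personnel are *variable* costs; everything else is *fixed*.

**Per-capita costs.** Fixed cost is divided by the protocol's *eligible*
population, variable cost by its *covered* population; protocol totals are
reported with and without the one-off program-introduction cost.

**Coverage.** A two-stage stratified cluster survey (25 clusters per
district allocated to urban/rural strata by largest-remainder proportional
allocation, 10 families per cluster, every eligible family member
interviewed) feeds the coverage estimator: the share of interviewed
eligible individuals who ever used at least one program service.

A synthetic-scenario module generates internally consistent inputs for
every stage from annual-cost targets with closed-form ground truth, so the
entire pipeline is testable without any external data; `pilot_scenario()`
is calibrated to the published IraPEN pilot figures.

## Worked example

```sh
pencost synth --seed 17 --out demo/data        # synthetic pilot inputs
pencost run --ledger demo/data/ledger.csv --dom demo/data/dom.csv \
    --staffing demo/data/staffing.csv \
    --denominators demo/data/denominators.csv --out demo/out
pencost coverage --survey demo/data/survey.csv --out demo/coverage.csv
```

prints

```
annual cost grand total: US$902,685.34
per-user total (without introduction): US$24.90
per-user total (with introduction): US$25.32
overall coverage: 40.11%
```

The grand total is the program's annual incremental cost across both
districts after annualization; the per-user totals divide fixed costs by
eligible and variable costs by covered populations and sum over the five
protocols, with and without the first-year introduction cost. The
coverage figure is the estimate from one realized synthetic survey of 250
families per district whose true usage probability is 0.40.
`demo/out/table1.csv` holds the protocol × category annual-cost matrix
with category shares (personnel 74.98 %, supplies 15.77 % of total cost),
`table2.csv` the per-capita report, and `summary.json` the totals plus
internal-consistency checks (per-capita cell × denominator must recover
the annual cost cell).

The same steps are available as library calls (`pencost.pilot_scenario`,
`pencost.write_scenario_files`, `pencost.run_pipeline`).

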