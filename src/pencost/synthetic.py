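"""Synthetic scenario generator with closed-form ground truth.

Builds complete, internally consistent inputs for every pipeline stage —
cost ledger, direct-observation task-time logs, staffing roster, survey
sampling frame, and population denominators — from a single scenario
configuration whose analytic ground truth (annual cost by protocol and
category, per-capita costs, true coverage) is known in closed form.  A
scenario states the *annual US$ targets* it should produce; the generator
back-solves the raw ingredients (IRR purchase prices, observation
windows, equipment prices at the stated useful life, salaries consistent
with the task times) so that running the full pipeline on the generated
files reproduces the targets.

:func:`pilot_scenario` is the calibration to the published two-district
IraPEN pilot (Naqadeh and Shahreza): its category and protocol cost
targets are the pilot's reported annual figures, and its per-protocol
eligible/covered denominators are back-solved from the reported
per-protocol and program per-user totals (the pilot did not publish the
denominators themselves).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allocate import CATEGORIES, CostBreakdown, empty_breakdown
from .coverage import (
    STRATA,
    SamplingFrame,
    SurveyDesign,
    allocate_clusters,
    draw_sample_frame,
    estimate_coverage,
)
from .ledger import (
    NONSPECIFIC,
    ConfigurationError,
    CostItem,
    Protocol,
    ProgramConstants,
)
from .annualize import annualization_factor
from .percapita import (
    PerCapitaReport,
    PopulationDenominators,
    build_report,
)
from .personnel import RoleStaffing, TaskObservation

#: Non-specific overhead categories emitted as national-level ledger items.
NONSPECIFIC_CATEGORIES = {
    "consultancy": ("consultancy", "capital"),
    "retraining": ("retraining", "recurrent"),
    "supervision_recurrent": ("supervision", "recurrent"),
    "introduction": ("introduction", "capital"),
    "customization": ("customization", "capital"),
    "supervision_capital": ("supervision", "capital"),
}


@dataclass(frozen=True)
class DistrictConfig:
    name: str
    urban_pop: int
    rural_pop: int


@dataclass(frozen=True)
class RoleConfig:
    """One provider role: roster size and a typical per-visit time."""

    role: str
    headcount: int
    visits_per_day: float
    base_minutes: float          # typical minutes per program visit
    weight: float                # share of total personnel cost
    workday_minutes: float = 480.0


@dataclass
class ScenarioConfig:
    """Targets and shapes of one synthetic scenario.

    Monetary targets are program-level annual US$; the generator emits
    raw IRR ledger rows that annualize back to them.  ``time_cv`` is the
    coefficient of variation of per-visit minutes: 0 gives a degenerate
    (noise-free) scenario whose pipeline output equals the ground truth
    exactly; > 0 draws lognormal times around the configured means.
    """

    districts: list[DistrictConfig]
    supply_annual_usd: dict[Protocol, float]
    equipment_annual_usd: dict[Protocol, float]
    personnel_annual_usd: dict[Protocol, float]
    nonspecific_annual_usd: dict[str, float]
    roles: list[RoleConfig]
    shared_supplies: list[tuple[float, frozenset[Protocol]]] = field(
        default_factory=list)
    equipment_life_years: float = 5.0
    time_cv: float = 0.0
    eligibility_fraction: float = 0.5
    usage_probability: float = 0.40
    denominators: pd.DataFrame | None = None   # explicit, else back-solved
    protocol_totals_without_usd: dict[Protocol, float] | None = None
    program_total_with_usd: float | None = None
    families_per_block: int = 14
    constants: ProgramConstants = field(default_factory=ProgramConstants)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.usage_probability <= 1.0:
            raise ConfigurationError("usage probability must be in [0, 1]")
        if not 0.0 < self.eligibility_fraction <= 1.0:
            raise ConfigurationError("eligibility fraction must be in (0, 1]")
        for mapping in (self.supply_annual_usd, self.equipment_annual_usd,
                        self.personnel_annual_usd,
                        self.nonspecific_annual_usd):
            for key, value in mapping.items():
                if value < 0:
                    raise ConfigurationError(f"negative target for {key}")
        if abs(sum(r.weight for r in self.roles) - 1.0) > 1e-9:
            raise ConfigurationError("role weights must sum to 1")

    @property
    def active_protocols(self) -> list[Protocol]:
        return [p for p in Protocol
                if (self.supply_annual_usd.get(p, 0)
                    + self.equipment_annual_usd.get(p, 0)
                    + self.personnel_annual_usd.get(p, 0)) > 0]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        def pmap(block):
            return {Protocol(k): float(v) for k, v in (block or {}).items()}
        constants = ProgramConstants(**(doc.get("constants") or {}))
        return cls(
            districts=[DistrictConfig(**d) for d in doc["districts"]],
            supply_annual_usd=pmap(doc.get("supply_annual_usd")),
            equipment_annual_usd=pmap(doc.get("equipment_annual_usd")),
            personnel_annual_usd=pmap(doc.get("personnel_annual_usd")),
            nonspecific_annual_usd={
                k: float(v) for k, v in
                (doc.get("nonspecific_annual_usd") or {}).items()},
            roles=[RoleConfig(**r) for r in doc["roles"]],
            shared_supplies=[
                (float(a), frozenset(Protocol(p) for p in ps))
                for a, ps in doc.get("shared_supplies", [])],
            equipment_life_years=float(doc.get("equipment_life_years", 5.0)),
            time_cv=float(doc.get("time_cv", 0.0)),
            eligibility_fraction=float(doc.get("eligibility_fraction", 0.5)),
            usage_probability=float(doc.get("usage_probability", 0.40)),
            protocol_totals_without_usd=(
                pmap(doc["protocol_totals_without_usd"])
                if "protocol_totals_without_usd" in doc else None),
            program_total_with_usd=doc.get("program_total_with_usd"),
            families_per_block=int(doc.get("families_per_block", 14)),
            constants=constants,
            seed=int(doc.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# ledger generation
# ---------------------------------------------------------------------------

def generate_ledger(config: ScenarioConfig, seed: int | None = None
                    ) -> list[CostItem]:
    """Emit the raw IRR cost ledger whose annualized USD totals equal the
    scenario targets.  Deterministic given (config, seed)."""
    c = config.constants
    rate = c.exchange_rate_irr_per_usd
    months = c.pilot_duration_months
    factor = annualization_factor(config.equipment_life_years,
                                  c.discount_rate)
    districts = itertools.cycle(d.name for d in config.districts)
    items: list[CostItem] = []

    for protocol, annual in sorted(config.supply_annual_usd.items()):
        if annual <= 0:
            continue
        raw = annual * months / c.months_per_year * rate
        items.append(CostItem(
            item_id=f"SUP-{protocol.value}",
            name=f"{protocol.value} supplies", district=next(districts),
            level="district", category="recurrent", kind="supply",
            protocols=frozenset({protocol}), amount=raw, currency="IRR",
            observed_over_months=months))
    for i, (annual, protocols) in enumerate(config.shared_supplies):
        raw = annual * months / c.months_per_year * rate
        items.append(CostItem(
            item_id=f"SUP-SHARED-{i}", name="shared consumables",
            district=next(districts), level="district",
            category="recurrent", kind="supply",
            protocols=frozenset(protocols), amount=raw, currency="IRR",
            observed_over_months=months))
    for protocol, annual in sorted(config.equipment_annual_usd.items()):
        if annual <= 0:
            continue
        unit_cost = annual * factor * rate
        items.append(CostItem(
            item_id=f"EQP-{protocol.value}",
            name=f"{protocol.value} equipment", district=next(districts),
            level="district", category="capital", kind="equipment",
            protocols=frozenset({protocol}), amount=unit_cost,
            currency="IRR", units_purchased=1, unit_cost=unit_cost,
            useful_life_years=config.equipment_life_years))
    for category, annual in sorted(config.nonspecific_annual_usd.items()):
        if annual <= 0:
            continue
        kind, cap_rec = NONSPECIFIC_CATEGORIES[category]
        raw = annual * c.n_universities * rate
        if category == "retraining":
            raw *= c.retraining_cycle_years
        items.append(CostItem(
            item_id=f"NSP-{category.upper()}",
            name=f"national {category}", district="NATIONAL",
            level="national", category=cap_rec, kind=kind,
            protocols=NONSPECIFIC, amount=raw, currency="IRR"))
    return items


# ---------------------------------------------------------------------------
# task-time and staffing generation
# ---------------------------------------------------------------------------

def _personnel_shares(config: ScenarioConfig) -> dict[Protocol, float]:
    total = sum(config.personnel_annual_usd.values())
    if total <= 0:
        raise ConfigurationError("total personnel target must be > 0")
    return {p: v / total for p, v in config.personnel_annual_usd.items()
            if v > 0}


def _role_minutes(config: ScenarioConfig, role: RoleConfig
                  ) -> dict[Protocol, float]:
    """Per-visit minutes per protocol, proportional to cost shares and
    averaging to the role's base_minutes over active protocols."""
    shares = _personnel_shares(config)
    n = len(shares)
    return {p: role.base_minutes * n * s for p, s in sorted(shares.items())}


def generate_dom_logs(config: ScenarioConfig, seed: int | None = None
                      ) -> tuple[list[TaskObservation], list[RoleStaffing]]:
    """Direct-observation log and staffing roster.

    Sites: 2 urban and 2 rural per district.  With ``time_cv == 0`` the
    log is balanced — one observation per (site, role, active protocol)
    at exactly the configured minutes — so the minute-proportional
    protocol attribution is exact.  With ``time_cv > 0`` each site logs a
    uniform 10-20 visits with lognormal per-visit times.

    Salaries are back-solved so each role's annual cost equals its weight
    times the total personnel target.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng([seed, 7])
    shares = _personnel_shares(config)
    observations: list[TaskObservation] = []
    sites = [(d.name, f"{d.name}-{stratum[0].upper()}{k}", stratum)
             for d in config.districts
             for stratum in STRATA for k in (1, 2)]
    pairs = [(role, protocol) for role in config.roles
             for protocol in sorted(shares)]
    for district, site, stratum in sites:
        if config.time_cv == 0:
            chosen = pairs
        else:
            n_visits = int(rng.integers(10, 21))
            start = int(rng.integers(0, len(pairs)))
            chosen = [pairs[(start + i) % len(pairs)]
                      for i in range(n_visits)]
        for role, protocol in chosen:
            mean = _role_minutes(config, role)[protocol]
            if config.time_cv == 0:
                minutes = mean
            else:
                sigma2 = np.log(1.0 + config.time_cv ** 2)
                mu = np.log(mean) - sigma2 / 2.0
                minutes = float(rng.lognormal(mu, np.sqrt(sigma2)))
            observations.append(TaskObservation(
                district=district, site=site, stratum=stratum,
                role=role.role, visit_date="2016-06-15",
                protocol=protocol, minutes_per_service=minutes))

    total_personnel = sum(config.personnel_annual_usd.values())
    staffing: list[RoleStaffing] = []
    rows = [(d.name, stratum) for d in config.districts for stratum in STRATA]
    for role in config.roles:
        fraction = (role.base_minutes * role.visits_per_day
                    / role.workday_minutes)
        if not 0 < fraction <= 1:
            raise ConfigurationError(
                f"role {role.role}: worktime fraction {fraction:.2f} "
                "outside (0, 1]; adjust visits or base minutes")
        salary = (role.weight * total_personnel
                  / (fraction * 12.0 * role.headcount))
        base, extra = divmod(role.headcount, len(rows))
        for i, (district, stratum) in enumerate(rows):
            headcount = base + (1 if i < extra else 0)
            if headcount == 0:
                continue
            staffing.append(RoleStaffing(
                district=district, stratum=stratum, role=role.role,
                headcount=headcount, monthly_salary_usd=salary,
                visits_per_day=role.visits_per_day,
                workday_minutes=role.workday_minutes))
    return observations, staffing


# ---------------------------------------------------------------------------
# population frame and survey outcomes
# ---------------------------------------------------------------------------

def generate_population_frame(config: ScenarioConfig,
                              seed: int | None = None) -> SamplingFrame:
    """Individual-level sampling frame with realized service usage.

    Block counts per stratum are sized to twice the cluster quota so the
    two-stage draw always has spare blocks; every frame family has 1-3
    eligible members; usage is Bernoulli with the configured true
    coverage probability, independent across individuals.
    """
    seed = config.seed if seed is None else seed
    c = config.constants
    protos = sorted(p.value for p in (config.active_protocols or Protocol))
    tag_universe = np.array(protos)
    parts: list[pd.DataFrame] = []
    for d_idx, d in enumerate(config.districts):
        quotas = dict(zip(STRATA, allocate_clusters(
            d.urban_pop, d.rural_pop, c.clusters_per_district)))
        for s_idx, stratum in enumerate(STRATA):
            n_blocks = 2 * quotas[stratum]
            rng = np.random.default_rng([seed, 31, d_idx, s_idx])
            n_families = n_blocks * config.families_per_block
            members = rng.integers(1, 4, size=n_families)
            n = int(members.sum())
            fam_idx = np.repeat(np.arange(n_families), members)
            block_idx = fam_idx // config.families_per_block
            member_idx = (np.arange(n)
                          - np.repeat(np.cumsum(members) - members, members))
            elig = rng.random((n, len(protos))) < config.eligibility_fraction
            none = ~elig.any(axis=1)
            if none.any():  # keep every frame member program-eligible
                forced = rng.integers(len(protos), size=int(none.sum()))
                elig[np.flatnonzero(none), forced] = True
            tags = [";".join(tag_universe[row]) for row in elig]
            used = rng.random(n) < config.usage_probability
            prefix = f"{d.name}-{stratum[0].upper()}B"
            block_ids = np.array([f"{prefix}{b:03d}"
                                  for b in range(n_blocks)])
            family_ids = np.char.add(
                np.char.add(block_ids[block_idx], "-F"),
                np.char.zfill((fam_idx % config.families_per_block)
                              .astype(str), 2))
            person_ids = np.char.add(
                np.char.add(family_ids, "-P"), member_idx.astype(str))
            parts.append(pd.DataFrame({
                "district": d.name, "block_id": block_ids[block_idx],
                "stratum": stratum, "family_id": family_ids,
                "person_id": person_ids, "eligible_protocols": tags,
                "used_service": used}))
    return SamplingFrame(individuals=pd.concat(parts, ignore_index=True))


def generate_population_and_survey(config: ScenarioConfig,
                                   seed: int | None = None
                                   ) -> tuple[SamplingFrame, pd.DataFrame]:
    """Frame plus one realized two-stage survey over all districts."""
    seed = config.seed if seed is None else seed
    frame = generate_population_frame(config, seed)
    samples = []
    for d in config.districts:
        design = SurveyDesign(
            district=d.name, urban_pop=d.urban_pop, rural_pop=d.rural_pop,
            n_clusters=config.constants.clusters_per_district,
            families_per_cluster=config.constants.families_per_cluster,
            seed=seed)
        samples.append(draw_sample_frame(frame, design))
    return frame, pd.concat(samples, ignore_index=True)


def simulate_coverage_mean(config: ScenarioConfig, n_reps: int,
                           seed: int) -> tuple[float, float]:
    """Mean and Monte-Carlo standard error of the coverage estimator over
    ``n_reps`` independently regenerated frames and surveys."""
    estimates = np.empty(n_reps)
    for r in range(n_reps):
        _, sample = generate_population_and_survey(config, seed=seed + r + 1)
        estimates[r] = estimate_coverage(sample)
    return float(estimates.mean()), float(estimates.std(ddof=1)
                                          / np.sqrt(n_reps))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _target_cells(config: ScenarioConfig) -> pd.DataFrame:
    cells = empty_breakdown()
    for p, v in config.supply_annual_usd.items():
        cells.loc[p, "supply"] += v
    for annual, protocols in config.shared_supplies:
        for p in protocols:
            cells.loc[p, "supply"] += annual / len(protocols)
    for p, v in config.equipment_annual_usd.items():
        cells.loc[p, "equipment"] += v
    for p, v in config.personnel_annual_usd.items():
        cells.loc[p, "personnel"] += v
    for category, v in config.nonspecific_annual_usd.items():
        for p in Protocol:
            cells.loc[p, category] += v / len(Protocol)
    return cells


def solve_denominators(cells: pd.DataFrame,
                       totals_without: dict[Protocol, float],
                       program_total_with: float,
                       districts: list[DistrictConfig]
                       ) -> PopulationDenominators:
    """Back-solve per-protocol eligible/covered populations from target
    per-user totals.

    For protocol p with fixed cost F_p (of which introduction I_p),
    variable cost V_p and target total-without t_p, an eligible count E_p
    and covered count C_p must satisfy (F_p - I_p)/E_p + V_p/C_p = t_p
    and sum_p I_p/E_p = (total with) - (total without).  The
    with/without gaps are distributed across protocols proportionally to
    their feasibility bounds (C_p <= E_p forces I_p/E_p <= I_p t_p /
    (total cost of p excl. introduction)), which keeps every protocol
    strictly feasible whenever the bounds sum to more than the required
    program gap.
    """
    fixed_cats = [c for c in CATEGORIES
                  if c not in ("supply", "personnel", "introduction")]
    gap_total = program_total_with - sum(totals_without.values())
    if gap_total <= 0:
        raise ConfigurationError("program gap (with - without) must be > 0")
    bounds, variable, fixed_ex, intro = {}, {}, {}, {}
    for p in Protocol:
        variable[p] = float(cells.loc[p, ["supply", "personnel"]].sum())
        fixed_ex[p] = float(cells.loc[p, fixed_cats].sum())
        intro[p] = float(cells.loc[p, "introduction"])
        cost_ex_intro = variable[p] + fixed_ex[p]
        bounds[p] = intro[p] * totals_without[p] / cost_ex_intro
    scale = gap_total / sum(bounds.values())
    if scale >= 1.0:
        raise ConfigurationError(
            "target totals infeasible: covered would exceed eligible")
    rows = []
    weights = np.array([d.urban_pop + d.rural_pop for d in districts],
                       dtype=float)
    weights /= weights.sum()
    for p in Protocol:
        gap = bounds[p] * scale
        eligible = intro[p] / gap
        variable_pc = totals_without[p] - fixed_ex[p] / eligible
        covered = variable[p] / variable_pc
        for d, w in zip(districts, weights):
            rows.append({
                "district": d.name, "protocol": p.value,
                "eligible_population": int(round(eligible * w)),
                "covered_population": int(round(covered * w))})
    return PopulationDenominators(pd.DataFrame(rows))


def scenario_denominators(config: ScenarioConfig) -> PopulationDenominators:
    if config.denominators is not None:
        return PopulationDenominators(config.denominators)
    if (config.protocol_totals_without_usd is None
            or config.program_total_with_usd is None):
        raise ConfigurationError(
            "scenario needs explicit denominators or target per-user totals")
    return solve_denominators(_target_cells(config),
                              config.protocol_totals_without_usd,
                              config.program_total_with_usd,
                              config.districts)


@dataclass
class GroundTruth:
    """Closed-form expectations of a scenario (no simulation)."""

    breakdown: CostBreakdown
    denominators: PopulationDenominators
    report: PerCapitaReport
    coverage: float


def expected_outputs(config: ScenarioConfig) -> GroundTruth:
    """Analytic ground truth: the annual cost matrix implied by the
    targets, the per-capita report under the scenario denominators, and
    the true coverage probability."""
    breakdown = CostBreakdown(cells=_target_cells(config))
    denominators = scenario_denominators(config)
    report = build_report(breakdown, denominators)
    return GroundTruth(breakdown=breakdown, denominators=denominators,
                       report=report, coverage=config.usage_probability)


# ---------------------------------------------------------------------------
# the calibrated pilot scenario
# ---------------------------------------------------------------------------

def pilot_scenario(seed: int = 0, time_cv: float = 0.0) -> ScenarioConfig:
    """Scenario calibrated to the published IraPEN two-district pilot.

    Annual cost targets per protocol and category are the pilot's
    reported figures (US$, 2015-16); per-protocol population denominators
    are back-solved from the reported per-user protocol totals and the
    program totals with/without introduction cost.  With the default
    ``time_cv = 0`` the generated inputs reproduce every reported cost
    cell exactly.
    """
    P = Protocol
    return ScenarioConfig(
        districts=[DistrictConfig("Naqadeh", urban_pop=50000,
                                  rural_pop=31000),
                   DistrictConfig("Shahreza", urban_pop=120000,
                                  rural_pop=40000)],
        # supply targets net of the shared-consumables item below
        supply_annual_usd={
            P.MI_STROKE: 102859.24 - 150.0, P.RESPIRATORY: 671.95,
            P.CRC: 7413.57, P.FEMALE_CANCER: 31270.27 - 150.0,
            P.NCD_RISK: 129.39},
        shared_supplies=[(300.0, frozenset({P.MI_STROKE,
                                            P.FEMALE_CANCER}))],
        equipment_annual_usd={
            P.MI_STROKE: 7389.52, P.RESPIRATORY: 1513.00,
            P.FEMALE_CANCER: 5.04},
        personnel_annual_usd={
            P.MI_STROKE: 186455.94, P.RESPIRATORY: 37361.09,
            P.CRC: 81284.81, P.FEMALE_CANCER: 163802.66,
            P.NCD_RISK: 207893.64},
        nonspecific_annual_usd={
            "consultancy": 21455.02, "retraining": 1979.39,
            "supervision_recurrent": 16741.34, "introduction": 18771.88,
            "customization": 7414.07, "supervision_capital": 8273.52},
        # 191 providers across the two districts, as in the pilot roster
        roles=[
            RoleConfig("physician", headcount=25, visits_per_day=16,
                       base_minutes=12.0, weight=0.40),
            RoleConfig("midwife", headcount=64, visits_per_day=14,
                       base_minutes=12.0, weight=0.30),
            RoleConfig("chw", headcount=102, visits_per_day=12,
                       base_minutes=12.0, weight=0.30),
        ],
        protocol_totals_without_usd={
            P.MI_STROKE: 7.45, P.RESPIRATORY: 1.05, P.CRC: 3.95,
            P.FEMALE_CANCER: 7.13, P.NCD_RISK: 5.32},
        program_total_with_usd=25.32,
        usage_probability=0.40,
        time_cv=time_cv,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_scenario_files(config: ScenarioConfig, outdir: str | Path,
                         seed: int | None = None) -> dict[str, Path]:
    """Generate and write every pipeline input CSV; returns the paths."""
    from .ledger import write_cost_ledger
    from .personnel import DOM_COLUMNS, STAFFING_COLUMNS

    seed = config.seed if seed is None else seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{k}.csv" for k in
             ("ledger", "dom", "staffing", "denominators", "survey")}

    write_cost_ledger(generate_ledger(config, seed), paths["ledger"])

    observations, staffing = generate_dom_logs(config, seed)
    pd.DataFrame([{
        "district": o.district, "site": o.site, "stratum": o.stratum,
        "role": o.role, "visit_date": o.visit_date,
        "protocol": o.protocol.value,
        "minutes_per_service": o.minutes_per_service}
        for o in observations])[DOM_COLUMNS].to_csv(
            paths["dom"], index=False)
    pd.DataFrame([{
        "district": s.district, "stratum": s.stratum, "role": s.role,
        "headcount": s.headcount, "monthly_salary": s.monthly_salary_usd,
        "currency": "USD", "visits_per_day": s.visits_per_day,
        "workday_minutes": s.workday_minutes}
        for s in staffing])[STAFFING_COLUMNS].to_csv(
            paths["staffing"], index=False)

    scenario_denominators(config).write_csv(paths["denominators"])

    _, sample = generate_population_and_survey(config, seed)
    sample = sample.rename(columns={"block_id": "cluster_id"})
    sample.to_csv(paths["survey"], index=False)
    return paths
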