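"""Per-capita incremental cost per protocol.

Fixed cost categories are divided by the protocol's *eligible*
population (they do not move with uptake); variable categories (supplies,
personnel) are divided by the *covered* population — the people the
program actually reached — giving a cost per user.  Program introduction
is a one-off first-year cost, so protocol and program totals are reported
both with and without it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .allocate import CATEGORIES, VARIABLE_CATEGORIES, CostBreakdown
from .ledger import (
    ConfigurationError,
    Protocol,
    PROTOCOL_LABELS,
    SchemaError,
)

DENOMINATOR_COLUMNS = ["district", "protocol", "eligible_population",
                       "covered_population"]


@dataclass
class PopulationDenominators:
    """Eligible and covered populations per (district, protocol)."""

    table: pd.DataFrame  # columns: DENOMINATOR_COLUMNS

    def __post_init__(self) -> None:
        missing = set(DENOMINATOR_COLUMNS) - set(self.table.columns)
        if missing:
            raise SchemaError(f"denominators missing: {sorted(missing)}")
        bad = self.table[
            (self.table["covered_population"] < 0)
            | (self.table["covered_population"]
               > self.table["eligible_population"])]
        if not bad.empty:
            raise ValueError(
                "covered population must satisfy 0 <= covered <= eligible")

    @classmethod
    def read_csv(cls, path: str | Path) -> "PopulationDenominators":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.table[DENOMINATOR_COLUMNS].to_csv(path, index=False)

    def by_protocol(self) -> pd.DataFrame:
        """Program-level denominators: sum over districts per protocol."""
        agg = (self.table.groupby("protocol")[
            ["eligible_population", "covered_population"]].sum())
        agg.index = [Protocol(p) for p in agg.index]
        return agg

    def program_pair(self) -> tuple[float, float]:
        """One (eligible, covered) pair for the whole program: the maximum
        over protocols, since protocol populations overlap."""
        per = self.by_protocol()
        return (float(per["eligible_population"].max()),
                float(per["covered_population"].max()))


def per_capita_fixed(annual_cost: float, eligible_population: float) -> float:
    """Fixed cost per eligible person."""
    if eligible_population <= 0:
        raise ValueError("eligible population must be > 0")
    return annual_cost / eligible_population


def per_capita_variable(annual_cost: float,
                        covered_population: float) -> float:
    """Variable cost per covered user."""
    if annual_cost > 0 and covered_population <= 0:
        raise ValueError(
            "positive variable cost with zero covered population")
    if annual_cost == 0:
        return 0.0
    return annual_cost / covered_population


def protocol_total(row: pd.Series | dict,
                   include_introduction: bool) -> float:
    """Sum a protocol's per-capita components, optionally with the
    one-off introduction component."""
    total = 0.0
    for cat in CATEGORIES:
        if cat == "introduction" and not include_introduction:
            continue
        total += float(row[cat])
    return total


@dataclass
class PerCapitaReport:
    """Per-capita US$ per protocol and category, plus totals."""

    cells: pd.DataFrame            # index Protocol, columns CATEGORIES
    totals_without_introduction: pd.Series
    totals_with_introduction: pd.Series

    @property
    def program_total_without_introduction(self) -> float:
        return float(self.totals_without_introduction.sum())

    @property
    def program_total_with_introduction(self) -> float:
        return float(self.totals_with_introduction.sum())


def build_report(breakdown: CostBreakdown,
                 denominators: PopulationDenominators,
                 mode: str = "protocol_denominators") -> PerCapitaReport:
    """Apply the fixed/eligible and variable/covered rules cell-wise.

    ``protocol_denominators`` (default) uses each protocol's own eligible
    and covered counts — protocols target different demographics (the
    female-cancer protocols, for instance, have a female-only eligible
    population).  ``program_denominators`` applies a single program-wide
    pair to every protocol.
    """
    per = denominators.by_protocol()
    if mode == "program_denominators":
        eligible, covered = denominators.program_pair()
        per = pd.DataFrame({"eligible_population": eligible,
                            "covered_population": covered},
                           index=list(Protocol))
    elif mode != "protocol_denominators":
        raise ValueError(f"unknown denominator mode {mode!r}")
    cells = pd.DataFrame(0.0, index=list(Protocol), columns=CATEGORIES)
    for protocol in Protocol:
        if breakdown.cells.loc[protocol].sum() > 0 and protocol not in per.index:
            raise ConfigurationError(
                f"no denominators for protocol {protocol.value}")
        if protocol not in per.index:
            continue
        eligible = float(per.loc[protocol, "eligible_population"])
        covered = float(per.loc[protocol, "covered_population"])
        for cat in CATEGORIES:
            cost = float(breakdown.cells.loc[protocol, cat])
            if cat in VARIABLE_CATEGORIES:
                cells.loc[protocol, cat] = per_capita_variable(cost, covered)
            else:
                cells.loc[protocol, cat] = per_capita_fixed(cost, eligible)
    without = cells.apply(
        lambda row: protocol_total(row, include_introduction=False), axis=1)
    with_intro = cells.apply(
        lambda row: protocol_total(row, include_introduction=True), axis=1)
    return PerCapitaReport(cells=cells,
                           totals_without_introduction=without,
                           totals_with_introduction=with_intro)


def consistency_checks(report: PerCapitaReport,
                       breakdown: CostBreakdown,
                       denominators: PopulationDenominators,
                       rel_tol: float = 0.005) -> list[dict]:
    """Internal-consistency audit of a finished report.

    Checks, per protocol: (a) the with/without-introduction gap equals
    the introduction component; (c) each per-capita cell times its
    denominator recovers the annual-cost cell to ``rel_tol``.  And at
    program level: (b) program totals equal the sum of protocol totals.
    Findings are returned, never raised.
    """
    checks: list[dict] = []
    per = denominators.by_protocol()
    for protocol in Protocol:
        gap = (report.totals_with_introduction[protocol]
               - report.totals_without_introduction[protocol])
        intro = float(report.cells.loc[protocol, "introduction"])
        checks.append({
            "check": "introduction_gap", "where": protocol.value,
            "passed": bool(abs(gap - intro) <= 0.01),
            "detail": f"gap {gap:.4f} vs introduction {intro:.4f}"})
        if protocol not in per.index:
            continue
        for cat in CATEGORIES:
            cost = float(breakdown.cells.loc[protocol, cat])
            if cost == 0:
                continue
            denom = float(per.loc[protocol,
                                  "covered_population"
                                  if cat in VARIABLE_CATEGORIES
                                  else "eligible_population"])
            recovered = float(report.cells.loc[protocol, cat]) * denom
            checks.append({
                "check": "cell_recovery",
                "where": f"{protocol.value}/{cat}",
                "passed": bool(abs(recovered - cost) <= rel_tol * cost),
                "detail": f"recovered {recovered:.2f} vs cost {cost:.2f}"})
    for label, series, total in (
            ("program_total_without_introduction",
             report.totals_without_introduction,
             report.program_total_without_introduction),
            ("program_total_with_introduction",
             report.totals_with_introduction,
             report.program_total_with_introduction)):
        checks.append({
            "check": "program_total", "where": label,
            "passed": bool(abs(float(series.sum()) - total) <= 1e-9),
            "detail": f"sum {series.sum():.4f} vs total {total:.4f}"})
    return checks


def report_table(report: PerCapitaReport) -> pd.DataFrame:
    """Display table (2-decimal, half-up style rounding via round())."""
    rows = []
    for protocol in Protocol:
        row = {"protocol": PROTOCOL_LABELS[protocol]}
        for cat in CATEGORIES:
            row[cat] = round(float(report.cells.loc[protocol, cat]), 2)
        row["total_without_introduction"] = round(
            float(report.totals_without_introduction[protocol]), 2)
        row["total_with_introduction"] = round(
            float(report.totals_with_introduction[protocol]), 2)
        rows.append(row)
    total_row = {"protocol": "Total"}
    for cat in CATEGORIES:
        total_row[cat] = round(float(report.cells[cat].sum()), 2)
    total_row["total_without_introduction"] = round(
        report.program_total_without_introduction, 2)
    total_row["total_with_introduction"] = round(
        report.program_total_with_introduction, 2)
    rows.append(total_row)
    return pd.DataFrame(rows)


def write_report_csv(report: PerCapitaReport, path: str | Path) -> None:
    report_table(report).to_csv(path, index=False)


def write_summary_json(report: PerCapitaReport, breakdown: CostBreakdown,
                       checks: list[dict], path: str | Path) -> None:
    from .allocate import category_shares
    overall, _ = category_shares(breakdown)
    payload = {
        "program_total_per_user_without_introduction_usd": round(
            report.program_total_without_introduction, 2),
        "program_total_per_user_with_introduction_usd": round(
            report.program_total_with_introduction, 2),
        "annual_cost_grand_total_usd": round(breakdown.grand_total, 2),
        "category_shares_pct": {c: round(float(overall[c]), 2)
                                for c in CATEGORIES},
        "checks": checks,
        "all_checks_passed": all(c["passed"] for c in checks),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
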