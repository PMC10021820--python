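"""End-to-end run: ledger + task times + denominators -> cost reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .allocate import (
    CostBreakdown,
    build_breakdown,
    category_shares,
    write_breakdown_csv,
)
from .annualize import annualize_ledger
from .ledger import (
    LedgerValidationError,
    ProgramConstants,
    ValidationReport,
    ledger_to_usd,
    read_cost_ledger,
    validate_ledger,
)
from .percapita import (
    PerCapitaReport,
    PopulationDenominators,
    build_report,
    consistency_checks,
    write_report_csv,
    write_summary_json,
)
from .personnel import personnel_cost_by_protocol, read_dom_log, read_staffing

logger = logging.getLogger("pencost")


@dataclass
class PipelineResult:
    validation: ValidationReport
    breakdown: CostBreakdown
    report: PerCapitaReport
    checks: list[dict]


def run_pipeline(ledger_path: str | Path, dom_path: str | Path,
                 staffing_path: str | Path, denominators_path: str | Path,
                 constants: ProgramConstants | None = None,
                 outdir: str | Path | None = None,
                 denominator_mode: str = "protocol_denominators"
                 ) -> PipelineResult:
    """Run the full costing pipeline from input CSVs.

    Reads and validates the ledger, converts it to US$, annualizes it,
    estimates personnel cost from the task-time log and roster, assembles
    the protocol x category matrix and the per-capita report, and (if
    ``outdir`` is given) writes ``table1.csv``, ``table2.csv`` and
    ``summary.json``.
    """
    constants = constants or ProgramConstants()
    items = read_cost_ledger(ledger_path, constants)
    validation = validate_ledger(items)
    for item_id, msg in validation.warnings:
        logger.warning("ledger %s: %s", item_id, msg)
    if not validation.ok:
        details = "; ".join(f"{i}: {m}" for i, m in validation.errors)
        raise LedgerValidationError(f"ledger validation failed: {details}")
    items = ledger_to_usd(items, constants)
    annualized = annualize_ledger(items, constants)
    personnel = personnel_cost_by_protocol(
        read_dom_log(dom_path), read_staffing(staffing_path, constants),
        constants)
    breakdown = build_breakdown(annualized, personnel, constants)
    denominators = PopulationDenominators.read_csv(denominators_path)
    report = build_report(breakdown, denominators, mode=denominator_mode)
    checks = consistency_checks(report, breakdown, denominators)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_breakdown_csv(breakdown, outdir / "table1.csv")
        write_report_csv(report, outdir / "table2.csv")
        write_summary_json(report, breakdown, checks,
                           outdir / "summary.json")
    return PipelineResult(validation=validation, breakdown=breakdown,
                          report=report, checks=checks)
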