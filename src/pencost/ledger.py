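"""Cost-ledger domain types, CSV I/O, validation, and currency handling.

The ledger is the item-level record of institutional expenditure on an
IraPEN-style NCD-prevention program: every row is one purchase or payment,
tagged with the administrative level it was incurred at (national ministry
vs. district), whether it is a capital (one-off) or recurrent item, the
kind of ingredient it buys, and the service protocol(s) it supports.
Everything downstream (annualization, allocation, per-capita reporting)
consumes the validated list of :class:`CostItem` produced here.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("pencost")

#: Sentinel protocol tag for overhead items not attributable to any protocol.
NONSPECIFIC = "NONSPECIFIC"

#: Marker for ledger rows incurred at the national (ministry) level.
NATIONAL = "NATIONAL"

LEDGER_COLUMNS = [
    "item_id", "name", "district", "level", "category", "kind",
    "protocols", "amount", "currency", "units_purchased", "unit_cost",
    "useful_life_years", "observed_over_months",
]


class PencostError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(PencostError):
    """An input file does not match its documented column schema."""


class LedgerValidationError(PencostError):
    """A ledger row violates a hard invariant."""


class CurrencyError(PencostError):
    """A currency conversion was applied to the wrong currency."""


class ConfigurationError(PencostError):
    """The run configuration or item routing is inconsistent."""


class InsufficientDataError(PencostError):
    """A requested estimate has no supporting observations."""


class SamplingError(PencostError):
    """The survey design cannot be satisfied by the sampling frame."""


class Protocol(str, Enum):
    """The five IraPEN service protocols."""

    MI_STROKE = "MI_STROKE"
    RESPIRATORY = "RESPIRATORY"
    CRC = "CRC"
    FEMALE_CANCER = "FEMALE_CANCER"
    NCD_RISK = "NCD_RISK"


PROTOCOL_LABELS = {
    Protocol.MI_STROKE: "MI & Stroke prevention",
    Protocol.RESPIRATORY: "Respiratory diseases screening",
    Protocol.CRC: "CRC prevention",
    Protocol.FEMALE_CANCER: "Female cancer prevention",
    Protocol.NCD_RISK: "NCD risk factors survey",
}

VALID_KINDS = {
    "equipment", "supply", "personnel", "consultancy", "retraining",
    "supervision", "introduction", "customization", "meeting",
}

VALID_LEVELS = {"national", "district"}
VALID_CATEGORIES = {"capital", "recurrent"}
VALID_CURRENCIES = {"IRR", "USD"}


@dataclass(frozen=True)
class ProgramConstants:
    """Program-wide constants of the costing exercise.

    Defaults are the values used in the IraPEN two-district pilot: a 10%
    annual discount rate for capital recovery, national costs shared
    equally across the 62 Universities of Medical Sciences, retraining
    material refreshed on a 5-year cycle, and the official 2015-16
    exchange rate of 36440 IRR per US$.
    """

    discount_rate: float = 0.10
    n_universities: int = 62
    retraining_cycle_years: int = 5
    months_per_year: int = 12
    pilot_duration_months: float = 13.0
    exchange_rate_irr_per_usd: float = 36440.0
    n_protocols: int = 5
    families_per_cluster: int = 10
    clusters_per_district: int = 25

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ConfigurationError("discount_rate must be >= 0")
        if self.exchange_rate_irr_per_usd <= 0:
            raise ConfigurationError("exchange rate must be > 0")
        if self.pilot_duration_months <= 0:
            raise ConfigurationError("pilot_duration_months must be > 0")
        for name in ("n_universities", "retraining_cycle_years",
                     "months_per_year", "n_protocols",
                     "families_per_cluster", "clusters_per_district"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")

    @property
    def families_per_district(self) -> int:
        return self.clusters_per_district * self.families_per_cluster

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProgramConstants":
        """Load constants from the ``constants:`` block of a YAML config."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        block = doc.get("constants", doc) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(block) - known
        if unknown:
            raise ConfigurationError(f"unknown constants: {sorted(unknown)}")
        return cls(**block)


@dataclass
class CostItem:
    """One ledger line: a single expenditure item.

    ``protocols`` is either a frozenset of :class:`Protocol` members or the
    string :data:`NONSPECIFIC` for shared overhead.  Equipment items carry
    ``units_purchased``, ``unit_cost`` and ``useful_life_years``; supply
    items carry the observation window ``observed_over_months``.
    """

    item_id: str
    name: str
    district: str
    level: str            # "national" | "district"
    category: str         # "capital" | "recurrent"
    kind: str
    protocols: frozenset[Protocol] | str
    amount: float
    currency: str = "IRR"
    units_purchased: float | None = None
    unit_cost: float | None = None
    useful_life_years: float | None = None
    observed_over_months: float | None = None


@dataclass
class ValidationReport:
    """Findings of :func:`validate_ledger`; the pipeline refuses to run
    while ``errors`` is non-empty."""

    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def parse_protocols(tag: str) -> frozenset[Protocol] | str:
    """Parse a semicolon-joined protocol tag (or NONSPECIFIC)."""
    tag = (tag or "").strip()
    if not tag:
        raise LedgerValidationError("empty protocol tag")
    if tag.upper() == NONSPECIFIC:
        return NONSPECIFIC
    members = []
    for part in tag.split(";"):
        part = part.strip()
        try:
            members.append(Protocol(part))
        except ValueError:
            raise LedgerValidationError(f"unknown protocol tag {part!r}")
    return frozenset(members)


def format_protocols(protocols: frozenset[Protocol] | str) -> str:
    if isinstance(protocols, str):
        return protocols
    return ";".join(sorted(p.value for p in protocols))


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_cost_ledger(path: str | Path,
                     constants: ProgramConstants | None = None
                     ) -> list[CostItem]:
    """Read a ledger CSV into a list of :class:`CostItem`.

    Raises :class:`SchemaError` on a missing mandatory column and
    :class:`LedgerValidationError` on a negative amount, an unknown item
    kind (e.g. excluded laboratory-analysis costs), or an unparseable
    protocol tag.  Currency tags are preserved; no conversion happens here.
    """
    df = pd.read_csv(path, dtype={"item_id": str, "district": str})
    missing = set(LEDGER_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"ledger {path} missing columns: {sorted(missing)}")
    items: list[CostItem] = []
    for row in df.itertuples(index=False):
        kind = str(row.kind).strip()
        if kind not in VALID_KINDS:
            raise LedgerValidationError(
                f"item {row.item_id}: unknown kind {kind!r}")
        level = str(row.level).strip()
        if level not in VALID_LEVELS:
            raise LedgerValidationError(
                f"item {row.item_id}: unknown level {level!r}")
        category = str(row.category).strip()
        if category not in VALID_CATEGORIES:
            raise LedgerValidationError(
                f"item {row.item_id}: unknown category {category!r}")
        currency = str(row.currency).strip().upper()
        if currency not in VALID_CURRENCIES:
            raise CurrencyError(
                f"item {row.item_id}: unknown currency {currency!r}")
        amount = float(row.amount)
        if amount < 0:
            raise LedgerValidationError(
                f"item {row.item_id}: negative amount {amount}")
        items.append(CostItem(
            item_id=str(row.item_id),
            name=str(row.name),
            district=str(row.district),
            level=level,
            category=category,
            kind=kind,
            protocols=parse_protocols(str(row.protocols)),
            amount=amount,
            currency=currency,
            units_purchased=_opt_float(row.units_purchased),
            unit_cost=_opt_float(row.unit_cost),
            useful_life_years=_opt_float(row.useful_life_years),
            observed_over_months=_opt_float(row.observed_over_months),
        ))
    return items


def write_cost_ledger(items: Iterable[CostItem], path: str | Path) -> None:
    """Write items back to the ledger CSV schema (round-trips with
    :func:`read_cost_ledger`)."""
    rows = []
    for it in items:
        rows.append({
            "item_id": it.item_id, "name": it.name, "district": it.district,
            "level": it.level, "category": it.category, "kind": it.kind,
            "protocols": format_protocols(it.protocols),
            "amount": it.amount, "currency": it.currency,
            "units_purchased": it.units_purchased,
            "unit_cost": it.unit_cost,
            "useful_life_years": it.useful_life_years,
            "observed_over_months": it.observed_over_months,
        })
    pd.DataFrame(rows, columns=LEDGER_COLUMNS).to_csv(path, index=False)


def validate_ledger(items: Sequence[CostItem]) -> ValidationReport:
    """Check every item invariant and return the findings.

    Errors: negative amounts, equipment without a positive useful life or
    with negative units, supply without a positive observation window,
    unit arithmetic off by more than 0.5 currency units.  Duplicated
    item_ids are warnings.
    """
    report = ValidationReport()
    for it in items:
        if it.amount < 0:
            report.errors.append((it.item_id, f"negative amount {it.amount}"))
        if it.kind == "equipment":
            if it.useful_life_years is None or it.useful_life_years <= 0:
                report.errors.append(
                    (it.item_id, "equipment requires useful_life_years > 0"))
            if it.units_purchased is not None and it.units_purchased < 0:
                report.errors.append(
                    (it.item_id, "units_purchased must be >= 0"))
        if it.kind == "supply":
            if it.observed_over_months is None or it.observed_over_months <= 0:
                report.errors.append(
                    (it.item_id, "supply requires observed_over_months > 0"))
        if it.units_purchased is not None and it.unit_cost is not None:
            expected = it.units_purchased * it.unit_cost
            if abs(expected - it.amount) > 0.5:
                report.errors.append((
                    it.item_id,
                    f"amount {it.amount} != units x unit_cost {expected}"))
        if not isinstance(it.protocols, str) and not it.protocols:
            report.errors.append((it.item_id, "empty protocol set"))
    counts = Counter(it.item_id for it in items)
    for item_id, n in counts.items():
        if n > 1:
            report.warnings.append((item_id, f"item_id appears {n} times"))
    return report


def convert_currency(amount_irr: float, rate: float) -> float:
    """Convert an IRR amount to US$ at ``rate`` IRR per US$."""
    if rate <= 0:
        raise CurrencyError(f"exchange rate must be > 0, got {rate}")
    return amount_irr / rate


def convert_item_to_usd(item: CostItem, rate: float) -> CostItem:
    """Return a copy of ``item`` with all money fields converted to US$.

    The currency tag guarantees conversion is applied exactly once;
    converting an already-USD item raises :class:`CurrencyError`.
    """
    if item.currency == "USD":
        raise CurrencyError(f"item {item.item_id} is already in USD")
    return dataclasses.replace(
        item,
        amount=convert_currency(item.amount, rate),
        unit_cost=(None if item.unit_cost is None
                   else convert_currency(item.unit_cost, rate)),
        currency="USD",
    )


def ledger_to_usd(items: Sequence[CostItem],
                  constants: ProgramConstants) -> list[CostItem]:
    """Convert every non-USD item once; USD items pass through unchanged."""
    out = []
    for it in items:
        if it.currency == "USD":
            out.append(it)
        else:
            out.append(convert_item_to_usd(
                it, constants.exchange_rate_irr_per_usd))
    return out
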