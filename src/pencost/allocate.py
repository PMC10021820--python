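"""Fixed/variable classification and protocol allocation of annual costs.

Annualized items are assembled into a protocol x cost-category matrix:

* *specific* items (tagged to one protocol) land in that protocol's cell;
* items shared by several protocols (e.g. disposable gloves used by more
  than one screening protocol) are divided equally between the tagged
  protocols;
* *non-specific* overhead (program introduction, supervision,
  customization, consultancy, retraining) is apportioned equally across
  all five protocols.

Supplies and personnel are classed *variable* (they scale with coverage);
every other category is *fixed*.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annualize import AnnualizedItem
from .ledger import (
    NONSPECIFIC,
    ConfigurationError,
    Protocol,
    PROTOCOL_LABELS,
    ProgramConstants,
)

#: Report columns, in display order.  "supervision" appears twice in the
#: source ledgers — as a recurrent (annual workshops/supervision) and a
#: capital (initial supervision setup) item — so it keeps two categories.
CATEGORIES = [
    "supply", "personnel", "equipment", "consultancy", "retraining",
    "supervision_recurrent", "introduction", "customization",
    "supervision_capital",
]

VARIABLE_CATEGORIES = {"supply", "personnel"}


def item_category(kind: str, category: str) -> str:
    """Map a ledger (kind, capital/recurrent) pair to a report category."""
    if kind == "supervision":
        return ("supervision_recurrent" if category == "recurrent"
                else "supervision_capital")
    if kind in {"meeting", "consultancy"}:
        # initial meetings / workshops / consultancies are one family
        return "consultancy"
    if kind in {"supply", "personnel", "equipment", "retraining",
                "introduction", "customization"}:
        return kind
    raise ConfigurationError(f"kind {kind!r} has no report category")


def classify_fixed_variable(item: AnnualizedItem) -> str:
    """Variable if the cost scales with coverage (supplies, personnel)."""
    cat = item_category(item.kind, item.category)
    return "variable" if cat in VARIABLE_CATEGORIES else "fixed"


def split_nonspecific(cost: float,
                      protocols: list[Protocol]) -> dict[Protocol, float]:
    """Equal apportionment of overhead across the given protocols."""
    if not protocols:
        raise ValueError("cannot apportion over an empty protocol list")
    share = cost / len(protocols)
    return {p: share for p in protocols}


def split_shared_item(item: AnnualizedItem,
                      using_protocols: frozenset[Protocol] | None = None
                      ) -> dict[Protocol, float]:
    """Equal split of a shared item over the protocols that use it."""
    protocols = using_protocols if using_protocols is not None else item.protocols
    if isinstance(protocols, str) or not protocols:
        raise ValueError("shared split needs a non-empty protocol set")
    if (not isinstance(item.protocols, str)
            and not protocols <= item.protocols):
        raise ValueError("using_protocols must be a subset of the item tags")
    return split_nonspecific(item.annual_cost_usd, sorted(protocols))


@dataclass
class CostBreakdown:
    """Protocol x category matrix of annual US$ costs."""

    cells: pd.DataFrame  # index: Protocol, columns: CATEGORIES

    @property
    def column_totals(self) -> pd.Series:
        return self.cells.sum(axis=0)

    @property
    def protocol_totals(self) -> pd.Series:
        return self.cells.sum(axis=1)

    @property
    def grand_total(self) -> float:
        return float(self.cells.to_numpy().sum())

    def fixed_variable(self) -> pd.Series:
        """Category -> 'fixed' | 'variable'."""
        return pd.Series({c: ("variable" if c in VARIABLE_CATEGORIES
                              else "fixed") for c in CATEGORIES})


def empty_breakdown() -> pd.DataFrame:
    return pd.DataFrame(0.0, index=list(Protocol), columns=CATEGORIES)


def build_breakdown(items: list[AnnualizedItem],
                    personnel_by_protocol: pd.Series,
                    constants: ProgramConstants | None = None
                    ) -> CostBreakdown:
    """Assemble the protocol x category cost matrix.

    ``personnel_by_protocol`` comes from the task-time module; ledger
    items of kind ``personnel`` are rejected here to avoid double counting.
    Equipment with no protocol tag is treated as non-specific overhead
    (split five ways) with a warning.
    """
    cells = empty_breakdown()
    for item in items:
        if item.kind == "personnel":
            raise ConfigurationError(
                f"item {item.item_id}: personnel cost must come from "
                "task-time observations, not the ledger")
        category = item_category(item.kind, item.category)
        if isinstance(item.protocols, str):
            if item.protocols != NONSPECIFIC:
                raise ConfigurationError(
                    f"item {item.item_id}: unknown protocol tag "
                    f"{item.protocols!r}")
            split = split_nonspecific(item.annual_cost_usd, list(Protocol))
        elif len(item.protocols) == 0:
            raise ConfigurationError(
                f"item {item.item_id}: no protocol tag and not NONSPECIFIC")
        elif len(item.protocols) > 1:
            split = split_shared_item(item)
        else:
            (protocol,) = item.protocols
            split = {protocol: item.annual_cost_usd}
        for protocol, amount in split.items():
            cells.loc[protocol, category] += amount
    for protocol in Protocol:
        cells.loc[protocol, "personnel"] = float(
            personnel_by_protocol.get(protocol, 0.0))
    return CostBreakdown(cells=cells)


def category_shares(breakdown: CostBreakdown
                    ) -> tuple[pd.Series, pd.DataFrame]:
    """Percentage shares of the grand total per category, and per-protocol
    shares within the supply, personnel and equipment columns."""
    grand = breakdown.grand_total
    if grand <= 0:
        raise ValueError("category shares undefined for a zero grand total")
    overall = 100.0 * breakdown.column_totals / grand
    within = pd.DataFrame(index=list(Protocol),
                          columns=["supply", "personnel", "equipment"],
                          dtype=float)
    for col in within.columns:
        total = breakdown.column_totals[col]
        within[col] = (100.0 * breakdown.cells[col] / total
                       if total > 0 else 0.0)
    return overall, within


def breakdown_table(breakdown: CostBreakdown) -> pd.DataFrame:
    """Display table: protocol rows, category columns with within-category
    share columns, a totals row and a category-share row (2 decimals)."""
    overall, within = category_shares(breakdown)
    rows = []
    for protocol in Protocol:
        row = {"protocol": PROTOCOL_LABELS[protocol]}
        for cat in CATEGORIES:
            row[cat] = round(breakdown.cells.loc[protocol, cat], 2)
            if cat in ("supply", "personnel", "equipment"):
                row[f"{cat}_share_pct"] = round(
                    float(within.loc[protocol, cat]), 2)
        rows.append(row)
    totals = {"protocol": "Total"}
    shares = {"protocol": "Share of category in total cost (%)"}
    for cat in CATEGORIES:
        totals[cat] = round(float(breakdown.column_totals[cat]), 2)
        shares[cat] = round(float(overall[cat]), 2)
    rows.extend([totals, shares])
    return pd.DataFrame(rows)


def write_breakdown_csv(breakdown: CostBreakdown, path) -> None:
    breakdown_table(breakdown).to_csv(path, index=False)
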