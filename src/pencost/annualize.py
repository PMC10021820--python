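"""Annualization of capital and recurrent expenditures.

Every ledger item is turned into an equivalent *annual* cost in US$:

* equipment — purchase price divided by the present-value-of-annuity
  factor ((1+r)^L - 1) / (r (1+r)^L) for useful life ``L`` years at
  discount rate ``r`` (capital recovery), so the asset price is spread
  into a constant annual charge over its life;
* supplies — observed spend scaled from the observation window to 12
  months (demand is assumed constant over the pilot);
* retraining material — total production cost divided by the refresh
  cycle length (5 years in the pilot);
* national-level spending of any kind — divided by the number of
  Universities of Medical Sciences (62) to attribute an equal share to
  each university, hence to each pilot district.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .ledger import (
    NONSPECIFIC,
    ConfigurationError,
    CostItem,
    Protocol,
    ProgramConstants,
)

__all__ = [
    "AnnualizedItem",
    "annualization_factor",
    "annual_equipment_cost",
    "annualize_supply",
    "apportion_national",
    "annualize_cyclic",
    "annualize_ledger",
]


@dataclass
class AnnualizedItem:
    """A ledger item reduced to its annual US$ cost."""

    item_id: str
    kind: str
    category: str          # capital | recurrent (carried from the ledger)
    protocols: frozenset[Protocol] | str
    annual_cost_usd: float

    def __post_init__(self) -> None:
        if self.annual_cost_usd < 0:
            raise ConfigurationError(
                f"item {self.item_id}: negative annual cost")


def annualization_factor(useful_life_years: float,
                         discount_rate: float) -> float:
    """Present-value-of-annuity factor ((1+r)^L - 1) / (r (1+r)^L).

    Dividing a purchase price by this factor gives the constant annual
    payment with the same present value over ``L`` years at rate ``r``
    (the capital-recovery annual charge).  At r = 0 the factor is the
    analytic limit L (straight-line depreciation).
    """
    if useful_life_years <= 0:
        raise ValueError(f"useful life must be > 0, got {useful_life_years}")
    if discount_rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {discount_rate}")
    if discount_rate == 0:
        return float(useful_life_years)
    growth = (1.0 + discount_rate) ** useful_life_years
    return (growth - 1.0) / (discount_rate * growth)


def annual_equipment_cost(units_purchased: float, unit_cost: float,
                          useful_life_years: float,
                          discount_rate: float) -> float:
    """Annual cost of an equipment purchase: price / annuity factor."""
    if units_purchased < 0 or unit_cost < 0:
        raise ValueError("units and unit cost must be >= 0")
    price = units_purchased * unit_cost
    return price / annualization_factor(useful_life_years, discount_rate)


def annualize_supply(total_cost: float, observed_over_months: float,
                     months_per_year: int = 12) -> float:
    """Scale supply spend from its observation window to a full year."""
    if observed_over_months <= 0:
        raise ValueError(
            f"observation window must be > 0 months, got {observed_over_months}")
    return total_cost / observed_over_months * months_per_year


def apportion_national(cost: float, n_universities: int) -> float:
    """Equal share of a national (ministry-level) cost per university."""
    if n_universities < 1:
        raise ValueError("n_universities must be >= 1")
    return cost / n_universities


def annualize_cyclic(cost: float, cycle_years: int) -> float:
    """Annual cost of spending repeated every ``cycle_years`` years."""
    if cycle_years < 1:
        raise ValueError(f"cycle must be >= 1 year, got {cycle_years}")
    return cost / cycle_years


def _annualize_one(item: CostItem, constants: ProgramConstants) -> float:
    """Dispatch one USD-denominated item to its annualization rule."""
    if item.kind == "equipment":
        if item.useful_life_years is None:
            raise ConfigurationError(
                f"item {item.item_id}: equipment without useful_life_years")
        if item.units_purchased is not None and item.unit_cost is not None:
            annual = annual_equipment_cost(
                item.units_purchased, item.unit_cost,
                item.useful_life_years, constants.discount_rate)
        else:
            annual = item.amount / annualization_factor(
                item.useful_life_years, constants.discount_rate)
    elif item.kind == "supply":
        if item.observed_over_months is None:
            raise ConfigurationError(
                f"item {item.item_id}: supply without observed_over_months")
        annual = annualize_supply(item.amount, item.observed_over_months,
                                  constants.months_per_year)
    elif item.kind == "retraining":
        annual = annualize_cyclic(item.amount,
                                  constants.retraining_cycle_years)
    elif item.kind in {"meeting", "consultancy", "supervision",
                       "introduction", "customization"}:
        # Reported as annual (or one-off first-year) amounts already.
        annual = item.amount
    else:
        raise ConfigurationError(
            f"item {item.item_id}: kind {item.kind!r} is not annualized "
            "here (personnel costs come from the task-time module)")
    if item.level == "national":
        annual = apportion_national(annual, constants.n_universities)
    return annual


def annualize_ledger(items: Sequence[CostItem],
                     constants: ProgramConstants) -> list[AnnualizedItem]:
    """Annualize a validated, USD-denominated ledger item by item.

    Personnel rows are rejected: staffing cost is estimated from
    task-time observations, not from the expenditure ledger.
    """
    out = []
    for item in items:
        if item.currency != "USD":
            raise ConfigurationError(
                f"item {item.item_id}: convert the ledger to USD first")
        out.append(AnnualizedItem(
            item_id=item.item_id,
            kind=item.kind,
            category=item.category,
            protocols=item.protocols,
            annual_cost_usd=_annualize_one(item, constants),
        ))
    return out
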