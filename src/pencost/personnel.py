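"""Personnel cost from direct-observation task times.

Per-visit service times for physicians, midwives and community health
workers (CHWs) are measured by an on-site observer (Direct Observation
Method).  The mean time per visit, the daily visit volume and the shift
length give the fraction of each provider's working day spent on program
services; that fraction of the monthly salary, times 12 and the
headcount, is the annual staffing cost per role.  Role costs are then
attributed to service protocols in proportion to the role's total
observed service-minutes per protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .ledger import (
    InsufficientDataError,
    Protocol,
    ProgramConstants,
    SchemaError,
    convert_currency,
)

logger = logging.getLogger("pencost")

ROLES = ("physician", "midwife", "chw")

#: Default shift length in minutes (8-hour working day); configurable per
#: roster row.
DEFAULT_WORKDAY_MINUTES = 480.0

DOM_COLUMNS = ["district", "site", "stratum", "role", "visit_date",
               "protocol", "minutes_per_service"]
STAFFING_COLUMNS = ["district", "stratum", "role", "headcount",
                    "monthly_salary", "currency", "visits_per_day",
                    "workday_minutes"]


@dataclass(frozen=True)
class TaskObservation:
    """One timed service delivery: role, protocol, and minutes taken."""

    district: str
    site: str
    stratum: str
    role: str
    visit_date: str
    protocol: Protocol
    minutes_per_service: float

    def __post_init__(self) -> None:
        if self.minutes_per_service <= 0:
            raise ValueError("minutes_per_service must be > 0")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class RoleStaffing:
    """One roster row: headcount and pay of a role in a district stratum."""

    district: str
    stratum: str
    role: str
    headcount: int
    monthly_salary_usd: float
    visits_per_day: float
    workday_minutes: float = DEFAULT_WORKDAY_MINUTES

    def __post_init__(self) -> None:
        if self.headcount < 0:
            raise ValueError("headcount must be >= 0")
        if self.workday_minutes <= 0:
            raise ValueError("workday_minutes must be > 0")


def read_dom_log(path: str | Path) -> list[TaskObservation]:
    """Read the direct-observation log CSV."""
    df = pd.read_csv(path)
    missing = set(DOM_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"DOM log {path} missing columns: {sorted(missing)}")
    return [
        TaskObservation(
            district=str(r.district), site=str(r.site),
            stratum=str(r.stratum), role=str(r.role),
            visit_date=str(r.visit_date),
            protocol=Protocol(str(r.protocol)),
            minutes_per_service=float(r.minutes_per_service),
        )
        for r in df.itertuples(index=False)
    ]


def read_staffing(path: str | Path,
                  constants: ProgramConstants) -> list[RoleStaffing]:
    """Read the staffing roster CSV, converting salaries to US$."""
    df = pd.read_csv(path)
    missing = set(STAFFING_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(
            f"staffing roster {path} missing columns: {sorted(missing)}")
    rows = []
    for r in df.itertuples(index=False):
        salary = float(r.monthly_salary)
        if str(r.currency).upper() == "IRR":
            salary = convert_currency(
                salary, constants.exchange_rate_irr_per_usd)
        rows.append(RoleStaffing(
            district=str(r.district), stratum=str(r.stratum),
            role=str(r.role), headcount=int(r.headcount),
            monthly_salary_usd=salary,
            visits_per_day=float(r.visits_per_day),
            workday_minutes=float(r.workday_minutes),
        ))
    return rows


def mean_task_time(observations: Sequence[TaskObservation], role: str,
                   protocol: Protocol | None = None) -> float:
    """Mean minutes per visit for a role (optionally one protocol)."""
    subset = [o.minutes_per_service for o in observations
              if o.role == role
              and (protocol is None or o.protocol == protocol)]
    if not subset:
        raise InsufficientDataError(
            f"no task-time observations for role={role}"
            + (f", protocol={protocol.value}" if protocol else ""))
    return sum(subset) / len(subset)


def worktime_fraction(mean_minutes_per_visit: float, visits_per_day: float,
                      workday_minutes: float) -> float:
    """Fraction of the working day spent delivering program services.

    Values above 1 indicate noisy timesheets (over-allocation) and are
    clamped to 1 with a warning rather than rejected.
    """
    if workday_minutes <= 0:
        raise ValueError("workday_minutes must be > 0")
    fraction = mean_minutes_per_visit * visits_per_day / workday_minutes
    if fraction > 1.0:
        logger.warning(
            "worktime fraction %.3f exceeds 1; clamping to 1.0", fraction)
        return 1.0
    return fraction


def annual_personnel_cost(fraction: float, monthly_salary_usd: float,
                          headcount: int) -> float:
    """Annual staffing cost: fraction x monthly salary x 12 x headcount."""
    if fraction < 0 or monthly_salary_usd < 0 or headcount < 0:
        raise ValueError("inputs must be >= 0")
    return fraction * monthly_salary_usd * 12.0 * headcount


def role_annual_costs(observations: Sequence[TaskObservation],
                      staffing: Sequence[RoleStaffing]) -> dict[str, float]:
    """Total annual cost per role, summed over roster rows.

    Task times are pooled per role across districts and strata (the
    observation design is too sparse to stratify the means).
    """
    totals: dict[str, float] = {}
    for role in ROLES:
        rows = [s for s in staffing if s.role == role and s.headcount > 0]
        if not rows:
            continue
        mean_minutes = mean_task_time(observations, role)  # raises if none
        total = 0.0
        for s in rows:
            fraction = worktime_fraction(mean_minutes, s.visits_per_day,
                                         s.workday_minutes)
            total += annual_personnel_cost(fraction, s.monthly_salary_usd,
                                           s.headcount)
        totals[role] = total
    return totals


def protocol_minute_shares(observations: Sequence[TaskObservation],
                           role: str) -> dict[Protocol, float]:
    """Share of a role's total observed service-minutes per protocol."""
    minutes: dict[Protocol, float] = {p: 0.0 for p in Protocol}
    total = 0.0
    for o in observations:
        if o.role == role:
            minutes[o.protocol] += o.minutes_per_service
            total += o.minutes_per_service
    if total == 0:
        raise InsufficientDataError(
            f"no observed minutes for role={role}")
    return {p: m / total for p, m in minutes.items()}


def personnel_cost_by_protocol(observations: Sequence[TaskObservation],
                               staffing: Sequence[RoleStaffing],
                               constants: ProgramConstants | None = None
                               ) -> pd.Series:
    """Annual personnel cost per protocol (US$/year).

    Each role's annual cost is split across protocols proportionally to
    that role's total observed service-minutes per protocol, so protocol
    totals conserve the all-role personnel total.
    """
    totals = role_annual_costs(observations, staffing)
    out = pd.Series(0.0, index=list(Protocol), name="personnel")
    for role, cost in totals.items():
        shares = protocol_minute_shares(observations, role)
        for protocol, share in shares.items():
            out[protocol] += cost * share
    return out
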