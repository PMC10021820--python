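"""Two-stage stratified cluster survey design and the coverage estimator.

The household survey behind the coverage figure samples, in each
district, 25 geographic blocks (clusters) split between the urban and
rural strata proportionally to population, then 10 families per block by
postal code; every program-eligible member of a sampled family is
interviewed.  Coverage is the plain ratio of interviewed eligible
individuals who ever used at least one program service — the survey
design is equal-take per cluster and the published definition applies no
design weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ledger import (
    InsufficientDataError,
    Protocol,
    SamplingError,
    SchemaError,
)

STRATA = ("urban", "rural")

SURVEY_COLUMNS = ["district", "cluster_id", "stratum", "family_id",
                  "person_id", "eligible_protocols", "used_service"]


@dataclass(frozen=True)
class SurveyDesign:
    """Two-stage design for one district."""

    district: str
    urban_pop: int
    rural_pop: int
    n_clusters: int = 25
    families_per_cluster: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.urban_pop <= 0 or self.rural_pop <= 0:
            raise ValueError("stratum populations must be > 0")
        if self.n_clusters < 2:
            raise ValueError("need at least one cluster per stratum")


@dataclass(frozen=True)
class SurveyRecord:
    """One interviewed eligible individual."""

    district: str
    cluster_id: str
    stratum: str
    family_id: str
    person_id: str
    eligible_protocols: frozenset[Protocol]
    used_service: bool

    def __post_init__(self) -> None:
        if self.used_service and not self.eligible_protocols:
            raise ValueError(
                "used_service implies eligibility for >= 1 protocol")


@dataclass
class SamplingFrame:
    """Individual-level frame for synthetic survey runs.

    ``individuals`` columns: district, block_id, stratum, family_id,
    person_id, eligible_protocols (semicolon-joined), used_service (bool).
    Only program-eligible individuals appear (ineligible household members
    are never interviewed, so the frame omits them).
    """

    individuals: pd.DataFrame

    def __post_init__(self) -> None:
        missing = ({"district", "block_id", "stratum", "family_id",
                    "person_id", "eligible_protocols", "used_service"}
                   - set(self.individuals.columns))
        if missing:
            raise SchemaError(f"frame missing columns: {sorted(missing)}")

    def blocks(self, stratum: str) -> list[str]:
        sub = self.individuals[self.individuals["stratum"] == stratum]
        return sorted(sub["block_id"].unique())


def allocate_clusters(urban_pop: int, rural_pop: int,
                      n_clusters: int) -> tuple[int, int]:
    """Proportional cluster allocation with largest-remainder rounding.

    Each stratum receives at least one cluster; remainder ties go to the
    larger stratum.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must cover both strata")
    if urban_pop <= 0 or rural_pop <= 0:
        raise ValueError("populations must be > 0")
    total = urban_pop + rural_pop
    raw = (n_clusters * urban_pop / total, n_clusters * rural_pop / total)
    base = [int(np.floor(x)) for x in raw]
    remainder = n_clusters - sum(base)
    fractions = [raw[i] - base[i] for i in range(2)]
    # order strata by (fractional part, population) descending: largest
    # remainder first, ties broken toward the larger stratum
    order = sorted(range(2), key=lambda i: (fractions[i],
                                            (urban_pop, rural_pop)[i]),
                   reverse=True)
    for i in range(remainder):
        base[order[i % 2]] += 1
    # guarantee >= 1 per stratum
    for i in range(2):
        if base[i] == 0:
            base[i] += 1
            base[1 - i] -= 1
    return base[0], base[1]


def _block_rng(seed: int, tag: int) -> np.random.Generator:
    """Independent substream keyed by (seed, tag): regenerating one
    cluster never perturbs the draws of another."""
    return np.random.default_rng([seed, tag])


def draw_sample_frame(frame: SamplingFrame,
                      design: SurveyDesign) -> pd.DataFrame:
    """Two-stage draw, returned as the sampled individuals DataFrame.

    Stage 1 selects blocks per stratum by a seeded permutation; stage 2
    selects ``families_per_cluster`` eligible families per block with a
    per-block substream.  Deterministic given ``design.seed``.
    """
    ind = frame.individuals
    ind = ind[ind["district"] == design.district]
    if ind.empty:
        raise SamplingError(f"no frame rows for district {design.district}")
    quotas = dict(zip(STRATA, allocate_clusters(
        design.urban_pop, design.rural_pop, design.n_clusters)))
    all_blocks = sorted(ind["block_id"].unique())
    block_pos = {b: i for i, b in enumerate(all_blocks)}
    by_block = dict(tuple(ind.groupby("block_id", sort=False)))
    picked: list[pd.DataFrame] = []
    for s_idx, stratum in enumerate(STRATA):
        sub = ind[ind["stratum"] == stratum]
        blocks = sorted(sub["block_id"].unique())
        quota = quotas[stratum]
        if len(blocks) < quota:
            raise SamplingError(
                f"stratum {stratum}: {len(blocks)} blocks < {quota} clusters")
        perm = _block_rng(design.seed, s_idx).permutation(len(blocks))
        selected = [blocks[i] for i in perm[:quota]]
        for block in selected:
            rows = by_block[block]
            families = np.sort(rows["family_id"].unique())
            if len(families) < design.families_per_cluster:
                raise SamplingError(
                    f"block {block} exhausted: {len(families)} eligible "
                    f"families < {design.families_per_cluster}")
            rng = _block_rng(design.seed, 1000 + block_pos[block])
            chosen = rng.choice(families, size=design.families_per_cluster,
                                replace=False)
            picked.append(rows[rows["family_id"].isin(chosen)])
    out = pd.concat(picked, ignore_index=True)
    return out.rename(columns={"block_id": "cluster_id"})


def draw_sample(frame: SamplingFrame,
                design: SurveyDesign) -> list[SurveyRecord]:
    """As :func:`draw_sample_frame`, materialized as records."""
    df = draw_sample_frame(frame, design)
    records = []
    for r in df.itertuples(index=False):
        tags = frozenset(Protocol(t) for t in
                         str(r.eligible_protocols).split(";") if t)
        records.append(SurveyRecord(
            district=str(r.district), cluster_id=str(r.cluster_id),
            stratum=str(r.stratum), family_id=str(r.family_id),
            person_id=str(r.person_id), eligible_protocols=tags,
            used_service=bool(r.used_service)))
    return records


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([{
        "district": r.district, "stratum": r.stratum,
        "used_service": r.used_service} for r in records])


def estimate_coverage(records: Sequence[SurveyRecord] | pd.DataFrame,
                      by: str = "overall") -> float | pd.Series:
    """Coverage: users of >= 1 service over interviewed eligible people.

    Returns a proportion in [0, 1] (overall) or a Series of proportions
    per district / per stratum.  The estimator is the unweighted ratio of
    the published definition; no design weights are applied.
    """
    df = _records_frame(records)
    if df.empty:
        raise InsufficientDataError("no eligible survey records")
    if by == "overall":
        return float(df["used_service"].mean())
    if by in ("district", "stratum"):
        return df.groupby(by)["used_service"].mean()
    raise ValueError(f"unknown grouping {by!r}")


def coverage_table(records) -> pd.DataFrame:
    """Overall / per-district / per-stratum coverage as percentages."""
    rows = [{"group": "overall", "level": "",
             "coverage_pct": round(100 * estimate_coverage(records), 2)}]
    for by in ("district", "stratum"):
        for level, value in estimate_coverage(records, by=by).items():
            rows.append({"group": by, "level": level,
                         "coverage_pct": round(100 * float(value), 2)})
    return pd.DataFrame(rows)


def read_survey(path: str | Path) -> pd.DataFrame:
    """Read a survey CSV in the documented schema."""
    df = pd.read_csv(path)
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"survey {path} missing columns: {sorted(missing)}")
    df["used_service"] = df["used_service"].astype(bool)
    return df


def write_survey(records, path: str | Path) -> None:
    if isinstance(records, pd.DataFrame):
        df = records[[c for c in SURVEY_COLUMNS if c in records.columns]]
    else:
        df = pd.DataFrame([{
            "district": r.district, "cluster_id": r.cluster_id,
            "stratum": r.stratum, "family_id": r.family_id,
            "person_id": r.person_id,
            "eligible_protocols": ";".join(
                sorted(p.value for p in r.eligible_protocols)),
            "used_service": r.used_service} for r in records])
    df.to_csv(path, index=False)
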