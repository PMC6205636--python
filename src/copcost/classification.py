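"""Partner classification, proportional NA allocation, and scope filtering.

Planned funding that cannot be tied to a signed agreement at COP time is
published as "NA" by country, year and budget code.  The model allocates
those amounts proportionately to the classified funding in the same
stratum, then restricts itself to international organizations (IO) and
universities; local and US-government partners are out of scope.

The allocation stratum is (country, year, budget_code), escalating to
(country, year) and then (year) when a stratum has no classified funding.
Because NA amounts are split pro-rata over the classified *rows* of the
stratum, the allocated funding inherits the stratum's class, agency and
partner mix simultaneously, and conservation holds to the cent via a
largest-remainder split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .cop_data import NA_PARTNER
from .money import largest_remainder_split

log = logging.getLogger("copcost")

IN_SCOPE_CLASSES = ("IO", "UNIVERSITY")
ALLOCATABLE_CLASSES = ("IO", "UNIVERSITY", "LOCAL", "USG")

_KEY = ["country", "year", "budget_code", "agency", "partner", "class"]


@dataclass
class AllocationAudit:
    """What happened to each NA pool during allocation."""

    allocated_cents: int = 0
    unallocatable_cents: int = 0
    fallback_strata: list[tuple] = field(default_factory=list)
    unallocatable_strata: list[tuple] = field(default_factory=list)


def classify_funding(funding: pd.DataFrame, class_table: dict[str, str]) -> pd.DataFrame:
    """Tag every funding record with its partner class and aggregate.

    Partners absent from the classification table become NA by contract.
    Returns totals keyed by (country, year, budget_code, agency, partner,
    class); the grand total equals the input ledger's grand total exactly.
    """
    df = funding.copy()
    df["class"] = df["partner"].map(lambda p: class_table.get(p, "NA"))
    out = (
        df.groupby(_KEY, as_index=False, sort=True)["amount_cents"]
        .sum()
        .astype({"amount_cents": "int64"})
    )
    return out


def allocate_na(classified: pd.DataFrame) -> tuple[pd.DataFrame, AllocationAudit]:
    """Redistribute NA funding pro-rata within its stratum.

    Each NA pool is split across the classified rows of its
    (country, year, budget_code) stratum in proportion to their totals;
    strata without classified funding escalate to (country, year), then
    (year).  Pools that no level can absorb are kept as NA rows and
    reported.  Conservation is exact.
    """
    audit = AllocationAudit()
    df = classified.copy().reset_index(drop=True)
    is_na = df["class"] == "NA"
    recipients = df.loc[~is_na]
    extra = pd.Series(0, index=df.index, dtype="int64")
    keep_na: list[int] = []

    levels = (
        ["country", "year", "budget_code"],
        ["country", "year"],
        ["year"],
    )
    for idx, row in df.loc[is_na].iterrows():
        pool = int(row["amount_cents"])
        if pool == 0:
            continue
        target_index = None
        for depth, level in enumerate(levels):
            mask = pd.Series(True, index=recipients.index)
            for col in level:
                mask &= recipients[col] == row[col]
            cand = recipients.index[mask]
            if len(cand) and int(recipients.loc[cand, "amount_cents"].sum()) > 0:
                target_index = cand
                if depth > 0:
                    audit.fallback_strata.append(tuple(row[c] for c in levels[0]))
                break
        if target_index is None:
            audit.unallocatable_cents += pool
            audit.unallocatable_strata.append(tuple(row[c] for c in levels[0]))
            keep_na.append(idx)
            continue
        weights = [int(w) for w in recipients.loc[target_index, "amount_cents"]]
        shares = largest_remainder_split(pool, weights)
        extra.loc[target_index] += pd.Series(shares, index=target_index)
        audit.allocated_cents += pool

    out = df.loc[(~is_na) | df.index.isin(keep_na)].copy()
    out["amount_cents"] = out["amount_cents"] + extra.reindex(out.index, fill_value=0)
    out = out.reset_index(drop=True)
    if audit.unallocatable_cents:
        log.warning(
            "NA funding of %d cents could not be allocated in %d strata",
            audit.unallocatable_cents,
            len(audit.unallocatable_strata),
        )
    return out, audit


def filter_in_scope(allocated: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep IO and university funding; report what was excluded.

    Returns funding at (partner, agency, year, budget_code, class) grain —
    the budget-code detail is needed later for the lab-equipment and ARV
    exclusions — plus per-class excluded totals for the audit log.
    """
    excluded = {
        klass: int(allocated.loc[allocated["class"] == klass, "amount_cents"].sum())
        for klass in ("LOCAL", "USG", "NA")
    }
    scoped = allocated.loc[allocated["class"].isin(IN_SCOPE_CLASSES)]
    scoped = (
        scoped.groupby(
            ["partner", "agency", "year", "budget_code", "class"], as_index=False,
            sort=True,
        )["amount_cents"]
        .sum()
        .astype({"amount_cents": "int64"})
    )
    if scoped.empty:
        log.warning("no in-scope (IO/university) funding after filtering")
    return scoped, excluded


def cell_totals(scoped: pd.DataFrame) -> pd.DataFrame:
    """Aggregate scoped funding to (partner, agency, year) cost cells."""
    cells = (
        scoped.groupby(["partner", "agency", "year"], as_index=False, sort=True)
        .agg(total_cents=("amount_cents", "sum"), klass=("class", "first"))
        .astype({"total_cents": "int64"})
    )
    return cells


def sentinel_partner() -> str:
    return NA_PARTNER
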