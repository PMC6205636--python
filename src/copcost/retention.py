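"""Retention-rate estimation and the applied-retention adjustment.

Sub-award amounts are excluded from the modified total direct cost (MTDC)
base, but sub-award data exist only for an early observation window.  The
model therefore estimates, per (prime partner, funding agency), the share
of an award the prime retains::

    R = (window funding - window sub-awards) / window funding

and adjusts it for the share ``p`` of sub-awarded dollars that flow to
other international organizations or universities (which charge their own
indirect rates), giving the *applied retention rate*::

    applied = R + (1 - R) * p

Partners without observed sub-award data fall back to a funding-weighted
agency average, then to a funding-weighted global average; each resolved
rate carries a provenance flag.  The first $25,000 of each sub-award (on
which indirect rates may be charged) is deliberately not credited back.

All rates are exact fractions; ``Ret = rate x Total`` is rounded half-even
to the cent, and ``Sub = Total - Ret`` so the cell identity is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction

import pandas as pd

from .money import round_cents

log = logging.getLogger("copcost")

DEFAULT_IO_SUB_THRESHOLD_CENTS = 100_000 * 100  # $100,000

INTERNATIONAL_CLASSES = ("IO", "UNIVERSITY")


class Provenance(str, Enum):
    PARTNER_OBSERVED = "PARTNER_OBSERVED"
    AGENCY_AVERAGE = "AGENCY_AVERAGE"
    GLOBAL_AVERAGE = "GLOBAL_AVERAGE"


class RetentionError(Exception):
    pass


@dataclass
class RetentionTable:
    """Resolved applied retention rates at every fallback level."""

    partner_applied: dict[tuple[str, str], Fraction]
    partner_raw: dict[tuple[str, str], Fraction]
    agency_applied: dict[str, Fraction]
    agency_avg_r: dict[str, Fraction]
    agency_io_proportion: dict[str, Fraction]
    global_applied: Fraction
    global_avg_r: Fraction
    global_io_proportion: Fraction
    clamped_pairs: list[tuple[str, str]] = field(default_factory=list)

    def lookup(self, partner: str, agency: str) -> tuple[Fraction, Provenance]:
        key = (partner, agency)
        if key in self.partner_applied:
            return self.partner_applied[key], Provenance.PARTNER_OBSERVED
        if agency in self.agency_applied:
            return self.agency_applied[agency], Provenance.AGENCY_AVERAGE
        return self.global_applied, Provenance.GLOBAL_AVERAGE

    def to_frame(self) -> pd.DataFrame:
        """Audit rendering: one row per resolved partner/agency rate plus
        the agency and global fallbacks."""
        rows = []
        for (partner, agency), rate in sorted(self.partner_applied.items()):
            rows.append(
                {
                    "partner": partner,
                    "agency": agency,
                    "retention_rate": float(self.partner_raw[(partner, agency)]),
                    "applied_rate": float(rate),
                    "provenance": Provenance.PARTNER_OBSERVED.value,
                }
            )
        for agency, rate in sorted(self.agency_applied.items()):
            rows.append(
                {
                    "partner": "*",
                    "agency": agency,
                    "retention_rate": float(self.agency_avg_r[agency]),
                    "applied_rate": float(rate),
                    "provenance": Provenance.AGENCY_AVERAGE.value,
                }
            )
        rows.append(
            {
                "partner": "*",
                "agency": "*",
                "retention_rate": float(self.global_avg_r),
                "applied_rate": float(self.global_applied),
                "provenance": Provenance.GLOBAL_AVERAGE.value,
            }
        )
        return pd.DataFrame(rows)


def applied_retention(r: Fraction | float, p: Fraction | float) -> Fraction:
    """Adjust a retention rate for internationally sub-awarded dollars.

    ``applied = R + (1 - R) * p``: the share of sub-awards flowing to other
    IOs or universities is treated as retained for rate-application
    purposes.  Monotone in both arguments and never below ``R``.
    """
    r, p = Fraction(r), Fraction(p)
    if not (0 <= r <= 1 and 0 <= p <= 1):
        raise RetentionError(f"rates must lie in [0, 1]: R={r}, p={p}")
    return r + (1 - r) * p


def partner_retention(
    subawards: pd.DataFrame,
    funding: pd.DataFrame,
    window_years: list[int],
) -> tuple[dict[tuple[str, str], Fraction], dict[tuple[str, str], int], list[tuple[str, str]]]:
    """Per-(partner, agency) retention over the observation window.

    ``funding`` is in-scope funding with partner/agency/year/amount_cents
    columns (any grain).  Returns (rates, window funding weights, clamped
    keys).  Keys with zero window funding are skipped; sub-awards exceeding
    funding clamp R to 0 and are reported as a data-quality signal.
    """
    window = set(int(y) for y in window_years)
    fund = (
        funding.loc[funding["year"].isin(window)]
        .groupby(["partner", "agency"])["amount_cents"]
        .sum()
    )
    sub = (
        subawards.loc[subawards["year"].isin(window)]
        .groupby(["prime_partner", "agency"])["amount_cents"]
        .sum()
    )
    rates: dict[tuple[str, str], Fraction] = {}
    weights: dict[tuple[str, str], int] = {}
    clamped: list[tuple[str, str]] = []
    for key, sub_cents in sub.items():
        fund_cents = int(fund.get(key, 0))
        if fund_cents <= 0:
            log.warning("sub-awards for %s with no window funding; skipped", (key,))
            continue
        if sub_cents > fund_cents:
            clamped.append(key)
            rates[key] = Fraction(0)
        else:
            rates[key] = Fraction(fund_cents - int(sub_cents), fund_cents)
        weights[key] = fund_cents
    return rates, weights, clamped


def io_subaward_proportion(
    subawards: pd.DataFrame,
    class_table: dict[str, str],
    year: int | None = None,
    threshold_cents: int = DEFAULT_IO_SUB_THRESHOLD_CENTS,
) -> tuple[dict[str, Fraction], Fraction]:
    """Share of sub-award dollars flowing to international sub-partners.

    Computed per agency from a single reference year (default: the first
    year with sub-award data).  A sub-partner whose within-agency total for
    that year is at or below the threshold is treated as local, as is any
    sub-partner of unknown class.  Returns (per-agency p, pooled global p).
    """
    if subawards.empty:
        raise RetentionError("no sub-award records; cannot estimate IO proportion")
    if year is None:
        year = int(subawards["year"].min())
    sl = subawards.loc[subawards["year"] == year]
    per_agency: dict[str, Fraction] = {}
    tot_io = tot_all = 0
    by_sub = sl.groupby(["agency", "sub_partner"])["amount_cents"].sum()
    for agency, grp in by_sub.groupby(level=0):
        io_cents = 0
        all_cents = int(grp.sum())
        for (_, sub_partner), cents in grp.items():
            klass = class_table.get(sub_partner, "NA")
            if klass in INTERNATIONAL_CLASSES and int(cents) > threshold_cents:
                io_cents += int(cents)
        if all_cents > 0:
            per_agency[str(agency)] = Fraction(io_cents, all_cents)
        tot_io += io_cents
        tot_all += all_cents
    if tot_all == 0:
        raise RetentionError(f"no sub-award dollars in reference year {year}")
    return per_agency, Fraction(tot_io, tot_all)


def fallback_rates(
    rates: dict[tuple[str, str], Fraction],
    weights: dict[tuple[str, str], int],
    agency_p: dict[str, Fraction],
    global_p: Fraction,
) -> tuple[dict[str, Fraction], dict[str, Fraction], Fraction, Fraction]:
    """Funding-weighted agency and global average retention rates.

    The agency average is taken over partners with observed sub-award data
    only, weighted by their window funding (equivalently, the pooled ratio
    of retained to total window dollars).  Agencies with no reference-year
    sub-awards borrow the pooled global IO proportion.  Raises if nothing
    was observed anywhere: the model cannot run.
    """
    if not rates:
        raise RetentionError("no partner has observed sub-award data; cannot proceed")
    agency_avg_r: dict[str, Fraction] = {}
    agency_applied: dict[str, Fraction] = {}
    num: dict[str, Fraction] = {}
    den: dict[str, int] = {}
    g_num = Fraction(0)
    g_den = 0
    for (partner, agency), r in rates.items():
        w = weights[(partner, agency)]
        num[agency] = num.get(agency, Fraction(0)) + r * w
        den[agency] = den.get(agency, 0) + w
        g_num += r * w
        g_den += w
    for agency in num:
        avg = num[agency] / den[agency]
        p = agency_p.get(agency, global_p)
        agency_avg_r[agency] = avg
        agency_applied[agency] = applied_retention(avg, p)
    global_avg = g_num / g_den
    global_applied = applied_retention(global_avg, global_p)
    return agency_avg_r, agency_applied, global_avg, global_applied


def build_retention_table(
    subawards: pd.DataFrame,
    funding: pd.DataFrame,
    class_table: dict[str, str],
    window_years: list[int] | None = None,
    io_reference_year: int | None = None,
    threshold_cents: int = DEFAULT_IO_SUB_THRESHOLD_CENTS,
) -> RetentionTable:
    """Assemble the full retention table from raw sub-award observations.

    The observation window defaults to the years present in the sub-award
    table.  Per the model's convention, the IO-proportion adjustment is an
    agency-level quantity and is applied to partner-level retention rates
    as well.
    """
    if window_years is None:
        window_years = sorted(subawards["year"].unique().tolist())
    rates, weights, clamped = partner_retention(subawards, funding, window_years)
    agency_p, global_p = io_subaward_proportion(
        subawards, class_table, io_reference_year, threshold_cents
    )
    agency_avg_r, agency_applied, global_avg, global_applied = fallback_rates(
        rates, weights, agency_p, global_p
    )
    partner_applied = {
        key: applied_retention(r, agency_p.get(key[1], global_p))
        for key, r in rates.items()
    }
    return RetentionTable(
        partner_applied=partner_applied,
        partner_raw=rates,
        agency_applied=agency_applied,
        agency_avg_r=agency_avg_r,
        agency_io_proportion=agency_p,
        global_applied=global_applied,
        global_avg_r=global_avg,
        global_io_proportion=global_p,
        clamped_pairs=clamped,
    )


def apply_retention(cells: pd.DataFrame, table: RetentionTable) -> pd.DataFrame:
    """Split every cell's total into retained and sub-awarded amounts.

    ``Ret = round(applied_rate x Total)`` (half-even, cents) and
    ``Sub = Total - Ret``, so ``Total = Sub + Ret`` holds exactly per cell.
    """
    out = cells.copy()
    applied = []
    prov = []
    for row in out.itertuples(index=False):
        rate, flag = table.lookup(row.partner, row.agency)
        applied.append(rate)
        prov.append(flag.value)
    out["applied_rate"] = applied
    out["rate_provenance"] = prov
    out["ret_cents"] = [
        round_cents(rate * int(tot))
        for rate, tot in zip(out["applied_rate"], out["total_cents"])
    ]
    out["ret_cents"] = out["ret_cents"].astype("int64")
    out["sub_cents"] = (out["total_cents"] - out["ret_cents"]).astype("int64")
    return out
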