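"""Rate scenarios and the NEC -> indirect-cost inversion.

Non-excludable costs combine the MTDC base and the indirect costs charged
on it, ``NEC = MTDC + Ind`` with ``Ind = r * MTDC``, hence::

    Ind = NEC * r / (1 + r)

Universities carry their own published NICRA rates for other sponsored
activities (OSA), on-campus or off-campus depending on the scenario.
International organizations (IOs), whose negotiated rates are private, get
a scenario rule: the average of university rates, or a fixed assumed rate.
Six standard scenarios, least to most conservative:

=============  ==================  ================================
scenario       university basis    IO rate
=============  ==================  ================================
A              on-campus OSA       average university on-campus
B              off-campus OSA      average university on-campus
C              off-campus OSA      average university off-campus
ASSUMED_20     off-campus OSA      fixed 20%
ASSUMED_15     off-campus OSA      fixed 15%
ASSUMED_10     off-campus OSA      fixed 10% (the de minimis rate)
=============  ==================  ================================

Universities keep their own OSA rates even in the assumed scenarios; only
the IO rate is fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .cop_data import RateEntry
from .money import round_cents

ON_CAMPUS = "ON_CAMPUS"
OFF_CAMPUS = "OFF_CAMPUS"


class RateLookupError(Exception):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """One rate-assignment rule.

    ``io_rate_rule`` is UNIV_ON_AVG, UNIV_OFF_AVG or FIXED (with
    ``fixed_rate`` set).
    """

    id: str
    university_basis: str
    io_rate_rule: str
    fixed_rate: Fraction | None = None

    def __post_init__(self):
        if self.university_basis not in (ON_CAMPUS, OFF_CAMPUS):
            raise ValueError(f"unknown basis {self.university_basis!r}")
        if self.io_rate_rule not in ("UNIV_ON_AVG", "UNIV_OFF_AVG", "FIXED"):
            raise ValueError(f"unknown IO rate rule {self.io_rate_rule!r}")
        if (self.io_rate_rule == "FIXED") != (self.fixed_rate is not None):
            raise ValueError("fixed_rate must be set exactly for FIXED rule")
        if self.fixed_rate is not None and self.fixed_rate < 0:
            raise ValueError("fixed_rate must be non-negative")


DEFAULT_SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec("A", ON_CAMPUS, "UNIV_ON_AVG"),
    ScenarioSpec("B", OFF_CAMPUS, "UNIV_ON_AVG"),
    ScenarioSpec("C", OFF_CAMPUS, "UNIV_OFF_AVG"),
    ScenarioSpec("ASSUMED_20", OFF_CAMPUS, "FIXED", Fraction(20, 100)),
    ScenarioSpec("ASSUMED_15", OFF_CAMPUS, "FIXED", Fraction(15, 100)),
    ScenarioSpec("ASSUMED_10", OFF_CAMPUS, "FIXED", Fraction(10, 100)),
)

SCENARIO_ALIASES = {
    "a": "A",
    "b": "B",
    "c": "C",
    "a20": "ASSUMED_20",
    "a15": "ASSUMED_15",
    "a10": "ASSUMED_10",
    "assumed_20": "ASSUMED_20",
    "assumed_15": "ASSUMED_15",
    "assumed_10": "ASSUMED_10",
}


def _basis_rate(entry: RateEntry, basis: str) -> Fraction:
    return entry.on_campus_osa if basis == ON_CAMPUS else entry.off_campus_osa


def university_rate(
    partner: str,
    year: int,
    basis: str,
    rate_table: dict[str, list[RateEntry]],
) -> Fraction:
    """OSA rate for one university in one year.

    Uses the NICRA period covering the year; where no period covers it, the
    nearest period's rate is applied retrospectively (or prospectively),
    ties resolved toward the more recent period.
    """
    entries = rate_table.get(partner)
    if not entries:
        raise RateLookupError(f"no NICRA rate entry for university {partner!r}")
    covering = [e for e in entries if e.covers(year)]
    if covering:
        return _basis_rate(covering[0], basis)
    nearest = min(entries, key=lambda e: (e.distance(year), -e.period_end))
    return _basis_rate(nearest, basis)


def io_average_rate(
    rate_table: dict[str, list[RateEntry]],
    year: int,
    basis: str,
    weights: dict[str, int] | None = None,
) -> Fraction:
    """Average university rate for a year, used as the IO rate.

    Unweighted mean over distinct universities by default; pass per-partner
    funding ``weights`` for a funding-weighted variant.  May drift year to
    year as NICRA periods roll over.
    """
    if not rate_table:
        raise RateLookupError("empty NICRA rate table")
    rates = {p: university_rate(p, year, basis, rate_table) for p in rate_table}
    if weights is None:
        return Fraction(sum(rates.values(), Fraction(0)), len(rates))
    wsum = sum(weights.get(p, 0) for p in rates)
    if wsum <= 0:
        return Fraction(sum(rates.values(), Fraction(0)), len(rates))
    return sum(r * weights.get(p, 0) for p, r in rates.items()) / wsum


def indirect_from_nec(nec_cents: int, r: Fraction) -> tuple[int, int]:
    """Invert NEC into (indirect, MTDC) cents under rate ``r``.

    ``Ind = NEC * r / (1 + r)`` rounded half-even to the cent;
    ``MTDC = NEC - Ind`` so the additive identity is exact.
    """
    if r < 0:
        raise ValueError("indirect cost rate must be non-negative")
    if nec_cents < 0:
        raise ValueError("NEC must be non-negative")
    ind = round_cents(Fraction(nec_cents) * r / (1 + r))
    return ind, nec_cents - ind


def scenario_rate(
    spec: ScenarioSpec,
    klass: str,
    partner: str,
    year: int,
    rate_table: dict[str, list[RateEntry]],
    io_avg_cache: dict[tuple[int, str], Fraction],
) -> Fraction:
    if klass == "UNIVERSITY":
        return university_rate(partner, year, spec.university_basis, rate_table)
    if spec.io_rate_rule == "FIXED":
        return spec.fixed_rate
    basis = ON_CAMPUS if spec.io_rate_rule == "UNIV_ON_AVG" else OFF_CAMPUS
    key = (year, basis)
    if key not in io_avg_cache:
        io_avg_cache[key] = io_average_rate(rate_table, year, basis)
    return io_avg_cache[key]


def run_scenarios(
    cells: pd.DataFrame,
    specs: tuple[ScenarioSpec, ...],
    rate_table: dict[str, list[RateEntry]],
    io_override: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Populate per-scenario rate, indirect and MTDC columns on every cell.

    ``io_override`` forces named partners to be rated as IOs even if they
    are classed as universities (e.g. non-US universities without public
    NICRAs).  Adds columns ``r_<id>``, ``ind_<id>_cents``,
    ``mtdc_<id>_cents`` per scenario.
    """
    out = cells.copy()
    io_override = io_override or {}
    io_avg_cache: dict[tuple[int, str], Fraction] = {}
    for spec in specs:
        rates, inds, mtdcs = [], [], []
        for row in out.itertuples(index=False):
            klass = row.klass
            if io_override.get(row.partner):
                klass = "IO"
            r = scenario_rate(
                spec, klass, row.partner, int(row.year), rate_table, io_avg_cache
            )
            ind, mtdc = indirect_from_nec(int(row.nec_cents), r)
            rates.append(r)
            inds.append(ind)
            mtdcs.append(mtdc)
        out[f"r_{spec.id}"] = rates
        out[f"ind_{spec.id}_cents"] = pd.Series(inds, index=out.index, dtype="int64")
        out[f"mtdc_{spec.id}_cents"] = pd.Series(mtdcs, index=out.index, dtype="int64")
    return out
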