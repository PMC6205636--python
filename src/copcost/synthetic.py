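"""Synthetic COP-style ledger generator with known ground truth.

The generator composes funding in the reverse direction of the estimator:
it draws cell totals, applies known retention rates, exclusion fractions
and indirect-cost rates, and emits the five input tables together with a
per-cell ground-truth table that satisfies the full identity chain
(Total = Sub + Ret, Ret = EC + NEC, NEC = MTDC + Ind, Ind = r x MTDC)
exactly.

Two constructions make the round trip exact to the cent:

* cell totals are drawn as whole millions of dollars and every generating
  rate is a four-decimal fraction, so sub-award and exclusion amounts are
  exact integers with no rounding anywhere in the forward direction;
* ground-truth retained amounts use the *realized* rates — the exact
  rational ratios of the cents actually written to the tables — which are
  identical to what the estimator recovers when every observation is
  available.

Observation masks then blank sub-award rows outside their window and
cross-cutting rows outside theirs, emulating the coverage gaps of the real
ledgers (sub-awards in the first three years only, capital cross-cutting
from year four, vehicles from year seven); the ground truth keeps the
unmasked values, so masked runs have measurable, bounded recovery error.

Only the accounting structure is emulated — no country-level epidemiology.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .money import cents_to_dollars_str, largest_remainder_split, round_cents
from .retention import applied_retention
from .scenarios import (
    DEFAULT_SCENARIOS,
    ON_CAMPUS,
    ScenarioSpec,
    indirect_from_nec,
)

MILLION_CENTS = 100_000_000  # $1,000,000 in cents
_4DP = 10_000


class InfeasibleConfigError(Exception):
    pass


class KeyMismatchError(Exception):
    pass


def _f4(x: str | float | Fraction) -> Fraction:
    """Coerce to a four-decimal fraction (validates the generator's grid)."""
    fr = x if isinstance(x, Fraction) else Fraction(str(x))
    if _4DP % fr.denominator != 0:
        raise InfeasibleConfigError(f"rate {x!r} is not a four-decimal fraction")
    return fr


@dataclass(frozen=True)
class AgencySpec:
    """Generating parameters for one funding agency."""

    name: str
    retention: Fraction  # target partner retention R_j
    io_proportion: Fraction  # share of sub-award dollars to IOs/universities


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters for the ledger generator.

    Defaults mimic the real study's shape: ten fiscal years, sub-awards
    observed in the first three, capital cross-cutting from year four,
    vehicles from year seven, roughly 60% of funding in scope, about a
    third of partner-agency pairs reporting sub-award data, and exclusion
    fractions near the published aggregate shares (capital 0.85%, vehicles
    0.53%, ARV 14%, lab code 4% with 40% excluded).
    """

    seed: int = 0
    start_year: int = 2007
    n_years: int = 10
    countries: tuple[str, ...] = ("kenya", "uganda", "mozambique", "vietnam")
    n_io: int = 10
    n_univ: int = 6
    n_local: int = 8
    n_usg: int = 2
    agencies: tuple[AgencySpec, ...] = (
        AgencySpec("hhs/cdc", Fraction("0.8633"), Fraction("0.2675")),
        AgencySpec("usaid", Fraction("0.8906"), Fraction("0.2829")),
        AgencySpec("dept of defense", Fraction("0.9397"), Fraction("0.7636")),
        AgencySpec("hhs/hrsa", Fraction("0.6851"), Fraction("0.4090")),
    )
    retention_jitter: Fraction = Fraction("0.03")
    subaward_reporting: float = 0.35
    capital_fraction: Fraction = Fraction("0.0085")
    vehicle_fraction: Fraction = Fraction("0.0053")
    hlab_share: Fraction = Fraction("0.04")
    htxd_share: Fraction = Fraction("0.14")
    na_share: Fraction = Fraction("0.14")
    io_true_rate: Fraction = Fraction("0.25")
    subaward_year_count: int = 3
    capital_start_index: int = 3
    vehicle_start_index: int = 6
    io_sub_threshold_cents: int = 100_000 * 100

    def __post_init__(self):
        for name in (
            "capital_fraction",
            "vehicle_fraction",
            "hlab_share",
            "htxd_share",
        ):
            object.__setattr__(self, name, _f4(getattr(self, name)))
        budget = self.hlab_share + self.htxd_share
        if budget >= 1:
            raise InfeasibleConfigError("budget-code shares must sum below 1")
        for ag in self.agencies:
            ec = (
                self.capital_fraction
                + self.vehicle_fraction
                + Fraction(2, 5) * self.hlab_share
                + self.htxd_share
            )
            if ec >= ag.retention - self.retention_jitter:
                raise InfeasibleConfigError(
                    f"exclusion fractions leave no NEC under agency {ag.name!r}"
                )
        if not 0 <= self.na_share < 1:
            raise InfeasibleConfigError("na_share must lie in [0, 1)")
        if self.subaward_year_count < 1 or self.subaward_year_count > self.n_years:
            raise InfeasibleConfigError("sub-award window outside study years")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.start_year, self.start_year + self.n_years))

    @property
    def subaward_years(self) -> tuple[int, ...]:
        return self.years[: self.subaward_year_count]

    @property
    def capital_years(self) -> tuple[int, ...]:
        return self.years[self.capital_start_index :]

    @property
    def vehicle_years(self) -> tuple[int, ...]:
        return self.years[self.vehicle_start_index :]

    def fully_observed(self) -> "SyntheticConfig":
        """The same ledger shape with every observation gap removed:
        all years observed for every table, every pair reporting
        sub-awards, and no unclassified (NA) funding."""
        return replace(
            self,
            subaward_reporting=1.0,
            na_share=Fraction(0),
            subaward_year_count=self.n_years,
            capital_start_index=0,
            vehicle_start_index=0,
        )


@dataclass
class SyntheticLedger:
    """Generated tables (internal representation) plus ground truth."""

    config: SyntheticConfig
    funding: pd.DataFrame
    subawards: pd.DataFrame
    crosscutting: pd.DataFrame
    classes: pd.DataFrame
    rates: pd.DataFrame
    ground_truth: pd.DataFrame
    true_class_shares: dict[str, Fraction] = field(default_factory=dict)


def _mech_id(*parts: str) -> str:
    """Stable mechanism id from its identifying fields (process-independent)."""
    return f"M{zlib.crc32('|'.join(parts).encode()) % 9000 + 1000}"


_CAPITAL_CYCLE = ("CONSTRUCTION", "RENOVATION", "CONSTRUCTION_RENOVATION")
_GENERIC_CODES = ("HBHC", "OHSS")
_ORG_TYPE = {
    "IO": "International NGO",
    "UNIVERSITY": "University",
    "LOCAL": "Local NGO",
    "USG": "USG Agency",
}


def _draw_rate_periods(rng: np.random.Generator, cfg: SyntheticConfig, univ: str):
    """1-2 NICRA periods per university, four-decimal rates, full coverage."""
    on4 = int(rng.integers(2800, 5200))
    gap4 = int(rng.integers(400, 1200))
    entries = []
    if len(cfg.years) >= 6 and rng.random() < 0.5:
        split = int(rng.choice(cfg.years[2:-2]))
        on4b = on4 + int(rng.integers(-200, 201))
        entries.append((cfg.start_year - 3, split - 1, on4, on4 - gap4))
        entries.append((split, cfg.years[-1] + 3, on4b, on4b - gap4))
    else:
        entries.append((cfg.start_year - 3, cfg.years[-1] + 3, on4, on4 - gap4))
    rows = [
        {
            "partner": univ,
            "period_start": s,
            "period_end": e,
            "on_campus_osa": Fraction(on, _4DP),
            "off_campus_osa": Fraction(off, _4DP),
        }
        for s, e, on, off in entries
    ]
    year_map = {}
    for y in cfg.years:
        for s, e, on, off in entries:
            if s <= y <= e:
                year_map[y] = (Fraction(on, _4DP), Fraction(off, _4DP))
                break
    return rows, year_map


def generate(config: SyntheticConfig) -> SyntheticLedger:
    """Generate the five input tables and the matching ground truth.

    Deterministic for a fixed config (same seed, byte-identical tables).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    agencies = cfg.agencies

    partners = (
        [("international health org %02d" % i, "IO") for i in range(1, cfg.n_io + 1)]
        + [("university of region %02d" % i, "UNIVERSITY") for i in range(1, cfg.n_univ + 1)]
        + [("national aids council %02d" % i, "LOCAL") for i in range(1, cfg.n_local + 1)]
        + [("us government agency %02d" % i, "USG") for i in range(1, cfg.n_usg + 1)]
    )

    rate_rows: list[dict] = []
    univ_year_rates: dict[str, dict[int, tuple[Fraction, Fraction]]] = {}
    for name, klass in partners:
        if klass == "UNIVERSITY":
            rows, year_map = _draw_rate_periods(rng, cfg, name)
            rate_rows.extend(rows)
            univ_year_rates[name] = year_map

    # partner -> agencies, countries, size factor, partner-level retention
    assignments = []
    retention_of: dict[tuple[str, str], Fraction] = {}
    jitter4 = int(cfg.retention_jitter * _4DP)
    for name, klass in partners:
        n_ag = 1 + int(rng.random() < 0.4)
        ag_idx = rng.choice(len(agencies), size=n_ag, replace=False)
        pair_agencies = [agencies[i] for i in sorted(ag_idx)]
        n_co = 1 + int(rng.random() < 0.5)
        co_idx = rng.choice(len(cfg.countries), size=n_co, replace=False)
        pcountries = [cfg.countries[i] for i in sorted(co_idx)]
        size = int(rng.integers(2, 9))
        reports = {}
        for ag in pair_agencies:
            r4 = int(ag.retention * _4DP) + int(rng.integers(-jitter4, jitter4 + 1))
            r4 = min(max(r4, 5000), 9950)
            retention_of[(name, ag.name)] = Fraction(r4, _4DP)
            reports[ag.name] = bool(rng.random() < cfg.subaward_reporting)
        assignments.append((name, klass, pair_agencies, pcountries, size, reports))

    # force at least one reporting in-scope pair per agency (the fallback
    # chain needs an anchor; real agencies all had some reporting partners)
    for ag in agencies:
        if not any(
            rep.get(ag.name)
            for _, klass, pags, _, _, rep in assignments
            if klass in ("IO", "UNIVERSITY") and any(a.name == ag.name for a in pags)
        ):
            for entry in assignments:
                name, klass, pags, _, _, rep = entry
                if klass in ("IO", "UNIVERSITY") and any(
                    a.name == ag.name for a in pags
                ):
                    rep[ag.name] = True
                    break

    funding_rows: list[dict] = []
    sub_rows: list[dict] = []
    cc_rows: list[dict] = []
    truth_rows: list[dict] = []
    cap_i = 0

    # window accumulators for realized fallback rates
    win_fund: dict[tuple[str, str], int] = {}
    win_sub: dict[tuple[str, str], int] = {}
    y1_io: dict[str, int] = {}
    y1_all: dict[str, int] = {}

    for name, klass, pair_agencies, pcountries, size, reports in assignments:
        in_scope = klass in ("IO", "UNIVERSITY")
        for ag in pair_agencies:
            for year in cfg.years:
                # per-country totals in whole millions; cell total is their sum
                parts = [
                    int(rng.integers(size, 4 * size + 1)) * MILLION_CENTS
                    for _ in pcountries
                ]
                total = sum(parts)
                for country, part in zip(pcountries, parts):
                    mech = _mech_id(name, ag.name, country)
                    hlab = int(cfg.hlab_share * part)
                    htxd = int(cfg.htxd_share * part)
                    rest = part - hlab - htxd
                    gen = largest_remainder_split(rest, [3, 2])
                    for code, cents in (
                        ("HLAB", hlab),
                        ("HTXD", htxd),
                        (_GENERIC_CODES[0], gen[0]),
                        (_GENERIC_CODES[1], gen[1]),
                    ):
                        if cents:
                            funding_rows.append(
                                {
                                    "country": country,
                                    "year": year,
                                    "mechanism_id": mech,
                                    "partner": name,
                                    "org_type": _ORG_TYPE[klass],
                                    "agency": ag.name,
                                    "budget_code": code,
                                    "amount_cents": cents,
                                }
                            )
                if not in_scope:
                    continue

                r_i = retention_of[(name, ag.name)]
                sub_total = int((1 - r_i) * total)  # exact: total is $1M-grid
                io_part = int(ag.io_proportion * sub_total)  # exact: 4dp grid
                local_part = sub_total - io_part
                reporting = reports[ag.name]
                if reporting and year in cfg.subaward_years:
                    win_fund[(name, ag.name)] = win_fund.get((name, ag.name), 0) + total
                    win_sub[(name, ag.name)] = win_sub.get((name, ag.name), 0) + sub_total
                    if year == cfg.subaward_years[0]:
                        y1_io[ag.name] = y1_io.get(ag.name, 0) + io_part
                        y1_all[ag.name] = y1_all.get(ag.name, 0) + sub_total
                    if io_part:
                        sub_rows.append(
                            {
                                "prime_partner": name,
                                "agency": ag.name,
                                "year": year,
                                "sub_partner": f"global relief partners {ag.name}",
                                "amount_cents": io_part,
                            }
                        )
                    if local_part:
                        sub_rows.append(
                            {
                                "prime_partner": name,
                                "agency": ag.name,
                                "year": year,
                                "sub_partner": f"community services {ag.name}",
                                "amount_cents": local_part,
                            }
                        )

                cap_amt = int(cfg.capital_fraction * total)
                veh_amt = int(cfg.vehicle_fraction * total)
                mech0 = _mech_id(name, ag.name, pcountries[0])
                if cap_amt and year in cfg.capital_years:
                    cc_rows.append(
                        {
                            "mechanism_id": mech0,
                            "partner": name,
                            "agency": ag.name,
                            "year": year,
                            "category": _CAPITAL_CYCLE[cap_i % 3],
                            "amount_cents": cap_amt,
                        }
                    )
                    cap_i += 1
                if veh_amt and year in cfg.vehicle_years:
                    cc_rows.append(
                        {
                            "mechanism_id": mech0,
                            "partner": name,
                            "agency": ag.name,
                            "year": year,
                            "category": "MOTOR_VEHICLES_PURCHASED",
                            "amount_cents": veh_amt,
                        }
                    )

                truth_rows.append(
                    {
                        "partner": name,
                        "agency": ag.name,
                        "year": year,
                        "klass": klass,
                        "reporting": reporting,
                        "total_cents": total,
                        "ec_capital_cents": cap_amt,
                        "ec_vehicles_cents": veh_amt,
                        "ec_lab_cents": int(Fraction(2, 5) * cfg.hlab_share * total),
                        "ec_arv_cents": int(cfg.htxd_share * total),
                    }
                )

    # ---- realized retention rates (exact ratios of written cents) ----
    if not win_fund:
        raise InfeasibleConfigError("no reporting partner-agency pair was generated")
    agency_p: dict[str, Fraction] = {
        a: Fraction(y1_io[a], y1_all[a]) for a in y1_all if y1_all[a] > 0
    }
    global_p = Fraction(sum(y1_io.values()), sum(y1_all.values()))
    for a, io_cents in y1_io.items():
        if 0 < io_cents <= cfg.io_sub_threshold_cents:
            raise InfeasibleConfigError(
                f"IO sub-partner total for agency {a!r} is below the "
                "classification threshold; raise cell sizes"
            )
    def cell_applied(name: str, aname: str, reporting: bool) -> Fraction:
        # Reporting pairs: the realized window ratio (identical to the
        # generating rate by exact construction).  Non-reporting pairs
        # still sub-award at their own drawn rate — the estimator can only
        # see the agency average for them, which is exactly the bounded
        # error the recovery report measures under masked observation.
        key = (name, aname)
        if reporting and key in win_fund:
            r_real = Fraction(win_fund[key] - win_sub[key], win_fund[key])
        else:
            r_real = retention_of[key]
        return applied_retention(r_real, agency_p.get(aname, global_p))

    # ---- complete the ground-truth identity chain ----
    specs: tuple[ScenarioSpec, ...] = DEFAULT_SCENARIOS
    univ_list = sorted(univ_year_rates)
    io_avg: dict[tuple[int, str], Fraction] = {}
    for y in cfg.years:
        ons = [univ_year_rates[u][y][0] for u in univ_list]
        offs = [univ_year_rates[u][y][1] for u in univ_list]
        if ons:
            io_avg[(y, "ON")] = Fraction(sum(ons), len(ons))
            io_avg[(y, "OFF")] = Fraction(sum(offs), len(offs))

    for row in truth_rows:
        a = cell_applied(row["partner"], row["agency"], row["reporting"])
        ret = round_cents(a * row["total_cents"])
        row["applied_rate"] = a
        row["ret_cents"] = ret
        row["sub_cents"] = row["total_cents"] - ret
        ec = (
            row["ec_capital_cents"]
            + row["ec_vehicles_cents"]
            + row["ec_lab_cents"]
            + row["ec_arv_cents"]
        )
        row["nec_cents"] = ret - ec
        if row["nec_cents"] < 0:
            raise InfeasibleConfigError("exclusions exceed retained funding")
        year = row["year"]
        for spec in specs:
            if row["klass"] == "UNIVERSITY":
                on, off = univ_year_rates[row["partner"]][year]
                r = on if spec.university_basis == ON_CAMPUS else off
            elif spec.io_rate_rule == "FIXED":
                r = spec.fixed_rate
            else:
                r = io_avg[(year, "ON" if spec.io_rate_rule == "UNIV_ON_AVG" else "OFF")]
            ind, mtdc = indirect_from_nec(row["nec_cents"], r)
            row[f"r_{spec.id}"] = r
            row[f"ind_{spec.id}_cents"] = ind
            row[f"mtdc_{spec.id}_cents"] = mtdc
        r_true = (
            univ_year_rates[row["partner"]][year][0]
            if row["klass"] == "UNIVERSITY"
            else cfg.io_true_rate
        )
        ind, mtdc = indirect_from_nec(row["nec_cents"], r_true)
        row["r_TRUE"] = r_true
        row["ind_TRUE_cents"] = ind
        row["mtdc_TRUE_cents"] = mtdc

    funding = pd.DataFrame(funding_rows)

    # ---- unclassified (NA) funding by country/year/budget-code stratum ----
    true_shares: dict[str, Fraction] = {}
    if cfg.na_share > 0:
        strata = funding.groupby(["country", "year", "budget_code"])["amount_cents"].sum()
        na_rows = []
        for (country, year, code), cents in strata.items():
            na_amt = round_cents(cfg.na_share / (1 - cfg.na_share) * int(cents))
            if na_amt:
                na_rows.append(
                    {
                        "country": country,
                        "year": year,
                        "mechanism_id": "NA",
                        "partner": "NA",
                        "org_type": "NA",
                        "agency": "NA",
                        "budget_code": code,
                        "amount_cents": na_amt,
                    }
                )
        funding = pd.concat([funding, pd.DataFrame(na_rows)], ignore_index=True)
    class_of = {name: klass for name, klass in partners}
    classified_total = sum(
        r["amount_cents"] for r in funding_rows
    )
    for klass in ("IO", "UNIVERSITY", "LOCAL", "USG"):
        cents = sum(
            r["amount_cents"] for r in funding_rows if class_of[r["partner"]] == klass
        )
        true_shares[klass] = Fraction(cents, classified_total)

    class_rows = [{"partner": n, "class": k} for n, k in partners]
    for ag in agencies:
        class_rows.append(
            {"partner": f"global relief partners {ag.name}", "class": "IO"}
        )
        class_rows.append(
            {"partner": f"community services {ag.name}", "class": "LOCAL"}
        )

    return SyntheticLedger(
        config=cfg,
        funding=funding,
        subawards=pd.DataFrame(
            sub_rows,
            columns=["prime_partner", "agency", "year", "sub_partner", "amount_cents"],
        ),
        crosscutting=pd.DataFrame(
            cc_rows,
            columns=[
                "mechanism_id",
                "partner",
                "agency",
                "year",
                "category",
                "amount_cents",
            ],
        ),
        classes=pd.DataFrame(class_rows),
        rates=pd.DataFrame(
            rate_rows,
            columns=[
                "partner",
                "period_start",
                "period_end",
                "on_campus_osa",
                "off_campus_osa",
            ],
        ),
        ground_truth=pd.DataFrame(truth_rows),
        true_class_shares=true_shares,
    )


def write_tables(ledger: SyntheticLedger, out_dir: str | Path) -> dict[str, Path]:
    """Write the five input CSVs (external schema, dollar amounts) plus
    ground_truth.csv.  Byte-identical for identical ledgers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _dollars(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df["amount"] = df["amount_cents"].map(cents_to_dollars_str)
        return df.drop(columns=["amount_cents"])

    paths["funding"] = out_dir / "funding.csv"
    _dollars(ledger.funding).to_csv(paths["funding"], index=False, lineterminator="\n")
    paths["subawards"] = out_dir / "subawards.csv"
    _dollars(ledger.subawards).to_csv(paths["subawards"], index=False, lineterminator="\n")
    paths["crosscutting"] = out_dir / "crosscutting.csv"
    _dollars(ledger.crosscutting).to_csv(
        paths["crosscutting"], index=False, lineterminator="\n"
    )
    paths["classes"] = out_dir / "partner_classes.csv"
    ledger.classes.to_csv(paths["classes"], index=False, lineterminator="\n")
    rates = ledger.rates.copy()
    for col in ("on_campus_osa", "off_campus_osa"):
        rates[col] = rates[col].map(lambda f: f"{float(f):.4f}")
    paths["rates"] = out_dir / "nicra_rates.csv"
    rates.to_csv(paths["rates"], index=False, lineterminator="\n")

    truth = ledger.ground_truth.copy()
    for col in truth.columns:
        if col.startswith("r_") or col == "applied_rate":
            truth[col] = truth[col].map(lambda f: f"{f.numerator}/{f.denominator}")
    paths["ground_truth"] = out_dir / "ground_truth.csv"
    truth.to_csv(paths["ground_truth"], index=False, lineterminator="\n")
    return paths


#: Quantities compared by the recovery report.
RECOVERY_QUANTITIES = (
    "sub_cents",
    "ret_cents",
    "ec_capital_cents",
    "ec_vehicles_cents",
    "ec_lab_cents",
    "ec_arv_cents",
    "nec_cents",
) + tuple(f"ind_{s.id}_cents" for s in DEFAULT_SCENARIOS)


def recovery_report(
    pipeline_cells: pd.DataFrame, ground_truth: pd.DataFrame
) -> pd.DataFrame:
    """Per-quantity estimation error of a pipeline run against ground truth.

    Cells are matched on (partner, agency, year); orphans on either side
    raise :class:`KeyMismatchError` listing them.  Returns one row per
    quantity with maximum and total absolute error (cents) and the
    aggregate relative error.
    """
    key = ["partner", "agency", "year"]
    merged = pipeline_cells.merge(
        ground_truth, on=key, how="outer", suffixes=("_est", "_true"), indicator=True
    )
    orphans = merged.loc[merged["_merge"] != "both", key]
    if len(orphans):
        raise KeyMismatchError(
            f"unmatched cells between pipeline and truth: "
            f"{orphans.to_records(index=False).tolist()[:10]}"
        )
    rows = []
    for q in RECOVERY_QUANTITIES:
        est = merged[f"{q}_est"].astype("int64")
        true = merged[f"{q}_true"].astype("int64")
        err = (est - true).abs()
        denom = int(true.abs().sum())
        rows.append(
            {
                "quantity": q,
                "max_abs_err_cents": int(err.max()) if len(err) else 0,
                "total_abs_err_cents": int(err.sum()),
                "aggregate_rel_err": (float(err.sum()) / denom) if denom else 0.0,
            }
        )
    return pd.DataFrame(rows)
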