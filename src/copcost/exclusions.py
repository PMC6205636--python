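"""Excluded costs: capital, vehicles, lab equipment, ARV drugs, and NEC.

Beyond sub-awards, four cost groups are excluded from the indirect-rate
base per cell (partner i, agency j, year t):

* capital — cross-cutting construction/renovation amounts;
* vehicles — the purchased-motor-vehicles cross-cutting category;
* lab equipment — a fixed fraction (default 40%) of funding under the
  laboratory-infrastructure budget code (HLAB);
* ARV drugs — all funding under the ARV budget code (HTXD).

Cross-cutting data exist only for part of the study window (capital from
2010, vehicles from 2013 in the real ledgers).  For earlier years the model
back-fills by applying pooled proportional rates — partner-level where the
partner has observed-window funding, else agency-level, else global — to
the cell's total funding.  Non-excludable costs are then
``NEC = Ret - (capital + vehicles + lab + ARV)``, clamped at zero with the
offending cells reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction

import pandas as pd

from .cop_data import CAPITAL_CATEGORIES, VEHICLE_CATEGORIES
from .money import largest_remainder_split, round_cents

log = logging.getLogger("copcost")

EC_COLUMNS = ("ec_capital_cents", "ec_vehicles_cents", "ec_lab_cents", "ec_arv_cents")


@dataclass(frozen=True)
class ExclusionPolicy:
    """Which costs are excluded, and over which years they are observed.

    ``None`` observed-year ranges mean "infer from the cross-cutting data":
    every year that carries at least one record of the category counts as
    observed.  ``backfill_level`` picks the first pooling level tried for
    imputation; coarser levels remain as fallbacks.
    """

    capital_categories: frozenset[str] = CAPITAL_CATEGORIES
    vehicle_categories: frozenset[str] = VEHICLE_CATEGORIES
    lab_budget_code: str = "HLAB"
    lab_fraction: Fraction = Fraction(2, 5)
    arv_budget_code: str = "HTXD"
    capital_observed_years: tuple[int, ...] | None = None
    vehicle_observed_years: tuple[int, ...] | None = None
    backfill_level: str = "partner"  # partner | agency | global

    def __post_init__(self):
        if not 0 <= self.lab_fraction <= 1:
            raise ValueError("lab_fraction must lie in [0, 1]")
        if self.backfill_level not in ("partner", "agency", "global"):
            raise ValueError(f"unknown backfill_level {self.backfill_level!r}")


def resolve_observed_years(
    policy: ExclusionPolicy, crosscutting: pd.DataFrame
) -> ExclusionPolicy:
    """Fill in observed-year ranges from the data where the policy left
    them unset."""
    updates = {}
    if policy.capital_observed_years is None:
        years = crosscutting.loc[
            crosscutting["category"].isin(policy.capital_categories), "year"
        ]
        updates["capital_observed_years"] = tuple(sorted(years.unique().tolist()))
    if policy.vehicle_observed_years is None:
        years = crosscutting.loc[
            crosscutting["category"].isin(policy.vehicle_categories), "year"
        ]
        updates["vehicle_observed_years"] = tuple(sorted(years.unique().tolist()))
    return replace(policy, **updates) if updates else policy


@dataclass
class ExclusionAudit:
    clamped_components: list[tuple[str, str, int, str]] = field(default_factory=list)
    negative_nec_cells: list[tuple[str, str, int]] = field(default_factory=list)
    backfill_provenance: dict[str, dict] = field(default_factory=dict)


def _crosscutting_by_cell(
    crosscutting: pd.DataFrame, categories: frozenset[str], years: tuple[int, ...]
) -> pd.Series:
    sel = crosscutting.loc[
        crosscutting["category"].isin(categories)
        & crosscutting["year"].isin(set(years))
    ]
    return sel.groupby(["partner", "agency", "year"])["amount_cents"].sum()


def direct_exclusions(
    cells: pd.DataFrame,
    scoped_funding: pd.DataFrame,
    crosscutting: pd.DataFrame,
    policy: ExclusionPolicy,
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Attach observed-year exclusion components to every cell.

    Lab and ARV exclusions come from the cell's own budget-code composition
    (available for all years); capital and vehicle exclusions from matching
    cross-cutting records within their observed windows.  Components
    exceeding the retained amount are clamped and reported.
    """
    policy = resolve_observed_years(policy, crosscutting)
    audit = ExclusionAudit()
    out = cells.copy()
    key = ["partner", "agency", "year"]

    cap = _crosscutting_by_cell(
        crosscutting, policy.capital_categories, policy.capital_observed_years
    )
    veh = _crosscutting_by_cell(
        crosscutting, policy.vehicle_categories, policy.vehicle_observed_years
    )
    lab = scoped_funding.loc[
        scoped_funding["budget_code"] == policy.lab_budget_code
    ].groupby(key)["amount_cents"].sum()
    arv = scoped_funding.loc[
        scoped_funding["budget_code"] == policy.arv_budget_code
    ].groupby(key)["amount_cents"].sum()

    idx = pd.MultiIndex.from_frame(out[key])
    out["ec_capital_cents"] = cap.reindex(idx, fill_value=0).to_numpy("int64")
    out["ec_vehicles_cents"] = veh.reindex(idx, fill_value=0).to_numpy("int64")
    hlab = lab.reindex(idx, fill_value=0).to_numpy("int64")
    out["ec_lab_cents"] = [round_cents(policy.lab_fraction * int(v)) for v in hlab]
    out["ec_lab_cents"] = out["ec_lab_cents"].astype("int64")
    out["ec_arv_cents"] = arv.reindex(idx, fill_value=0).to_numpy("int64")

    for col in EC_COLUMNS:
        over = out[col] > out["ret_cents"]
        for row in out.loc[over].itertuples(index=True):
            audit.clamped_components.append(
                (row.partner, row.agency, row.year, col)
            )
        out.loc[over, col] = out.loc[over, "ret_cents"]
    return out, audit


def pooled_proportion(
    category_cents_by_year: dict[int, int],
    funding_cents_by_year: dict[int, int],
    observed_years: tuple[int, ...],
) -> Fraction:
    """Pooled category share of funding over the observed years.

    Σ category / Σ funding; zero funding in the window yields 0 with a
    warning rather than an error, so sparse strata degrade gracefully.
    """
    num = sum(int(category_cents_by_year.get(y, 0)) for y in observed_years)
    den = sum(int(funding_cents_by_year.get(y, 0)) for y in observed_years)
    if den <= 0:
        log.warning("pooled proportion over %s has zero funding; using 0", observed_years)
        return Fraction(0)
    return Fraction(num, den)


def _pooled_fractions(
    cells: pd.DataFrame,
    ec_col: str,
    observed_years: tuple[int, ...],
    level_cols: list[str],
) -> dict:
    """Pooled EC/total ratios at one grouping level over observed years."""
    obs = cells.loc[cells["year"].isin(set(observed_years))]
    if obs.empty:
        return {}
    grouped = obs.groupby(level_cols)[[ec_col, "total_cents"]].sum()
    out = {}
    for lvl, row in grouped.iterrows():
        if int(row["total_cents"]) > 0:
            out[lvl] = Fraction(int(row[ec_col]), int(row["total_cents"]))
    return out


_LEVELS = {"partner": 0, "agency": 1, "global": 2}


def backfill_exclusions(
    cells: pd.DataFrame,
    crosscutting_policy: ExclusionPolicy,
    audit: ExclusionAudit | None = None,
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Impute capital and vehicle exclusions for unobserved years.

    For each cell outside the observed window, the imputed component is
    ``fraction x total``, where the fraction is the pooled observed-window
    ratio at the configured level: partner first (requires the partner to
    have observed-window funding), then agency, then global.  Imputation is
    scale-equivariant in the cell total by construction.
    """
    audit = audit or ExclusionAudit()
    out = cells.copy()
    start = _LEVELS[crosscutting_policy.backfill_level]
    for ec_col, years in (
        ("ec_capital_cents", crosscutting_policy.capital_observed_years),
        ("ec_vehicles_cents", crosscutting_policy.vehicle_observed_years),
    ):
        years = years or ()
        if not years:
            log.warning("no observed years for %s; back-fill skipped", ec_col)
            continue
        levels = [
            _pooled_fractions(out, ec_col, years, ["partner"]),
            _pooled_fractions(out, ec_col, years, ["agency"]),
        ]
        obs = out.loc[out["year"].isin(set(years))]
        glob = (
            Fraction(int(obs[ec_col].sum()), int(obs["total_cents"].sum()))
            if int(obs["total_cents"].sum()) > 0
            else Fraction(0)
        )
        prov: dict[str, int] = {"partner": 0, "agency": 0, "global": 0}
        unobserved = ~out["year"].isin(set(years))
        values = out[ec_col].to_numpy().copy()
        for i, row in zip(out.index[unobserved], out.loc[unobserved].itertuples()):
            frac, level = glob, "global"
            for li in range(start, 2):
                table = levels[li]
                lkey = row.partner if li == 0 else row.agency
                if lkey in table:
                    frac, level = table[lkey], ("partner", "agency")[li]
                    break
            values[out.index.get_loc(i)] = round_cents(frac * int(row.total_cents))
            prov[level] += 1
        out[ec_col] = pd.Series(values, index=out.index, dtype="int64")
        audit.backfill_provenance[ec_col] = prov
    return out, audit


def compute_nec(
    cells: pd.DataFrame, audit: ExclusionAudit | None = None
) -> tuple[pd.DataFrame, ExclusionAudit]:
    """Derive non-excludable costs: ``NEC = Ret - ΣEC``.

    Cells whose combined exclusions exceed the retained amount are reported
    and their components scaled down (largest-remainder) so that
    ``Ret = EC + NEC`` holds exactly on every cell with ``NEC = 0``.
    """
    audit = audit or ExclusionAudit()
    out = cells.copy()
    ec_sum = sum(out[c] for c in EC_COLUMNS)
    out["nec_cents"] = (out["ret_cents"] - ec_sum).astype("int64")
    neg = out["nec_cents"] < 0
    for i in out.index[neg]:
        row = out.loc[i]
        audit.negative_nec_cells.append(
            (row["partner"], row["agency"], int(row["year"]))
        )
        weights = [int(row[c]) for c in EC_COLUMNS]
        scaled = largest_remainder_split(int(row["ret_cents"]), weights)
        for c, v in zip(EC_COLUMNS, scaled):
            out.loc[i, c] = v
        out.loc[i, "nec_cents"] = 0
    if neg.any():
        log.warning("%d cells had exclusions exceeding retained funding", int(neg.sum()))
    return out, audit
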