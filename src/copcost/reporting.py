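"""Presentation surfaces: annual report, scenario ranges, shares of total.

Aggregation happens in exact integer cents; rounding to thousands of
dollars (half-even) occurs only at the presentation edge, and shares of
total funding are reported to two decimals.  Rendering is deterministic:
identical inputs produce byte-identical CSV output.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN
from pathlib import Path

import pandas as pd

from .exclusions import EC_COLUMNS
from .money import cents_to_thousands

#: Report rows, in presentation order (before the per-scenario block).
BASE_ROWS = (
    ("total_funding", "total_cents"),
    ("sub_awards", "sub_cents"),
    ("ec_capital", "ec_capital_cents"),
    ("ec_vehicles", "ec_vehicles_cents"),
    ("ec_lab", "ec_lab_cents"),
    ("ec_arv", "ec_arv_cents"),
    ("total_nec", "nec_cents"),
)


class ReportingError(Exception):
    pass


@dataclass
class AnnualReport:
    """Exact per-year totals (cents) with presentation helpers.

    ``cents`` is indexed by measure name with one column per year plus
    ``Total``; ``scenario_ids`` lists the indirect-estimate rows present as
    ``ind_<id>``.
    """

    cents: pd.DataFrame
    scenario_ids: tuple[str, ...]

    def to_thousands(self) -> pd.DataFrame:
        return self.cents.map(cents_to_thousands)

    def total_funding(self) -> int:
        return int(self.cents.loc["total_funding", "Total"])

    def scenario_totals(self) -> dict[str, int]:
        return {
            s: int(self.cents.loc[f"ind_{s}", "Total"]) for s in self.scenario_ids
        }


def share_of_total(component_total: int | float, funding_total: int | float) -> float:
    """Component share of total funding, in percent to two decimals."""
    if funding_total == 0:
        raise ReportingError("share of a zero funding total is undefined")
    share = Decimal(100 * Decimal(str(component_total)) / Decimal(str(funding_total)))
    return float(share.quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


def build_report(cells: pd.DataFrame, scenario_ids: tuple[str, ...]) -> AnnualReport:
    """Aggregate cost cells into the annual report matrix.

    Every measure is summed exactly per year and overall; the yearly
    columns therefore sum to the Total column by construction.
    """
    years = sorted(int(y) for y in cells["year"].unique()) if len(cells) else []
    measures = list(BASE_ROWS) + [(f"ind_{s}", f"ind_{s}_cents") for s in scenario_ids]
    data = {}
    for year in years:
        sel = cells.loc[cells["year"] == year]
        data[year] = [int(sel[col].sum()) for _, col in measures]
    data["Total"] = [int(cells[col].sum()) if len(cells) else 0 for _, col in measures]
    frame = pd.DataFrame(data, index=[name for name, _ in measures])
    return AnnualReport(cents=frame, scenario_ids=tuple(scenario_ids))


def range_summary(report: AnnualReport) -> pd.DataFrame:
    """Max-minus-min spread of the scenario estimates, per column.

    Returns the spread in cents and as a share of total funding; a report
    carrying a single scenario yields zero spread (warned upstream).
    """
    rows = [f"ind_{s}" for s in report.scenario_ids]
    if not rows:
        raise ReportingError("no scenarios in report")
    est = report.cents.loc[rows]
    spread = est.max(axis=0) - est.min(axis=0)
    out = pd.DataFrame(
        {
            "range_cents": spread.astype("int64"),
            "range_thousands": spread.map(cents_to_thousands).astype("int64"),
        }
    )
    out["share_of_funding_pct"] = [
        share_of_total(int(spread[c]), int(report.cents.loc["total_funding", c]))
        if int(report.cents.loc["total_funding", c])
        else 0.0
        for c in est.columns
    ]
    out.index.name = "column"
    return out


def shares_table(report: AnnualReport) -> pd.DataFrame:
    """Cumulative shares of total funding for every report measure."""
    total = report.total_funding()
    rows = []
    for name in report.cents.index:
        if name == "total_funding":
            continue
        rows.append(
            {
                "measure": name,
                "total_thousands": cents_to_thousands(int(report.cents.loc[name, "Total"])),
                "share_of_funding_pct": share_of_total(
                    int(report.cents.loc[name, "Total"]), total
                )
                if total
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


def write_outputs(
    out_dir: str | Path,
    report: AnnualReport,
    retention_frame: pd.DataFrame,
    audit_lines: list[str],
) -> dict[str, Path]:
    """Emit the machine-readable CSVs and the audit log.

    Writes report_annual.csv (thousands of USD), report_range.csv,
    report_shares.csv, retention_table.csv and audit_log.txt, plus a plain
    text rendering of the annual report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    annual = report.to_thousands()
    annual.index.name = "measure_thousands_usd"
    paths["report_annual"] = out_dir / "report_annual.csv"
    annual.to_csv(paths["report_annual"], lineterminator="\n")

    paths["report_range"] = out_dir / "report_range.csv"
    range_summary(report).to_csv(paths["report_range"], lineterminator="\n")

    paths["report_shares"] = out_dir / "report_shares.csv"
    shares_table(report).to_csv(paths["report_shares"], index=False, lineterminator="\n")

    paths["retention_table"] = out_dir / "retention_table.csv"
    retention_frame.to_csv(paths["retention_table"], index=False, lineterminator="\n")

    paths["audit_log"] = out_dir / "audit_log.txt"
    paths["audit_log"].write_text("\n".join(audit_lines) + "\n", encoding="utf-8")

    paths["report_text"] = out_dir / "report_annual.txt"
    paths["report_text"].write_text(annual.to_string() + "\n", encoding="utf-8")
    return paths
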