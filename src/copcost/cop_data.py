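"""Reading, validation and canonicalization of COP-style input tables.

Five CSV tables drive the model (all UTF-8, comma separated, header row
required; amounts are dollars with at most two decimals):

``funding.csv``
    country, year, mechanism_id, partner, org_type, agency, budget_code, amount
``subawards.csv``
    prime_partner, agency, year, sub_partner, amount
``crosscutting.csv``
    mechanism_id, partner, agency, year, category, amount
``partner_classes.csv``
    partner, class          (class in IO / UNIVERSITY / LOCAL / USG / NA)
``nicra_rates.csv``
    partner, period_start, period_end, on_campus_osa, off_campus_osa

Amounts become integer cents, rates become exact fractions, and partner
names are canonicalized with :func:`normalize_name` on the way in, so the
rest of the pipeline never sees raw spellings.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import pandas as pd

from .money import parse_amount_cents, parse_rate

log = logging.getLogger("copcost")

NA_PARTNER = "NA"

#: Partner classes used by the model.
CLASSES = ("IO", "UNIVERSITY", "LOCAL", "USG", "NA")

#: Accepted spellings in partner_classes.csv.
_CLASS_ALIASES = {
    "io": "IO",
    "international": "IO",
    "university": "UNIVERSITY",
    "univ": "UNIVERSITY",
    "local": "LOCAL",
    "usg": "USG",
    "na": "NA",
}

#: Closed set of cross-cutting categories the model recognises.
CAPITAL_CATEGORIES = frozenset(
    {"CONSTRUCTION", "RENOVATION", "CONSTRUCTION_RENOVATION"}
)
VEHICLE_CATEGORIES = frozenset({"MOTOR_VEHICLES_PURCHASED"})
CROSSCUTTING_CATEGORIES = CAPITAL_CATEGORIES | VEHICLE_CATEGORIES

#: Organisation-name suffixes stripped during canonicalization (editable).
DEFAULT_SUFFIXES = (
    "inc",
    "incorporated",
    "ltd",
    "limited",
    "llc",
    "corp",
    "corporation",
    "intl",
)

TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "funding": (
        "country",
        "year",
        "mechanism_id",
        "partner",
        "org_type",
        "agency",
        "budget_code",
        "amount",
    ),
    "subawards": ("prime_partner", "agency", "year", "sub_partner", "amount"),
    "crosscutting": ("mechanism_id", "partner", "agency", "year", "category", "amount"),
    "classes": ("partner", "class"),
    "rates": ("partner", "period_start", "period_end", "on_campus_osa", "off_campus_osa"),
}


class CopDataError(Exception):
    """Base class for input-validation failures."""


class MissingTableError(CopDataError):
    pass


class MissingColumnError(CopDataError):
    pass


class AmountError(CopDataError):
    """Non-numeric or sub-cent amount, with row context."""


class NegativeAmountError(CopDataError):
    pass


class InvalidCategoryError(CopDataError):
    pass


class InvalidClassError(CopDataError):
    pass


class InvalidRateError(CopDataError):
    pass


def normalize_name(raw: object, suffixes: tuple[str, ...] = DEFAULT_SUFFIXES) -> str:
    """Canonicalize a partner name.

    Case-folds, trims, collapses internal whitespace and strips a trailing
    run of legal-form suffixes ("Inc.", "Ltd." ...).  Total on strings and
    idempotent.  Empty or not-available spellings map to the sentinel
    ``"NA"``.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return NA_PARTNER
    text = re.sub(r"\s+", " ", str(raw)).strip().casefold()
    if text in ("", "na", "n/a", "n.a.", "not available", "none"):
        return NA_PARTNER
    tokens = text.split(" ")
    sufset = {s.casefold() for s in suffixes}
    while tokens and tokens[-1].strip(".,") in sufset:
        tokens.pop()
    tokens = [t.strip(",") for t in tokens]
    out = " ".join(t for t in tokens if t)
    return out if out else NA_PARTNER


@dataclass(frozen=True)
class RateEntry:
    """One university NICRA period: on/off-campus OSA rates, inclusive years."""

    partner: str
    period_start: int
    period_end: int
    on_campus_osa: Fraction
    off_campus_osa: Fraction

    def covers(self, year: int) -> bool:
        return self.period_start <= year <= self.period_end

    def distance(self, year: int) -> int:
        if self.covers(year):
            return 0
        return min(abs(year - self.period_start), abs(year - self.period_end))


def _require_columns(df: pd.DataFrame, kind: str, path: Path) -> None:
    expected = TABLE_SCHEMAS[kind]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise MissingColumnError(
            f"{path}: missing required column(s) {missing} for table kind {kind!r}"
        )


def _parse_amounts(df: pd.DataFrame, path: Path) -> pd.Series:
    cents = []
    for idx, raw in df["amount"].items():
        try:
            value = parse_amount_cents(raw)
        except ValueError as exc:
            raise AmountError(f"{path}: row {idx + 2}: {exc}") from exc
        if value < 0:
            raise NegativeAmountError(
                f"{path}: row {idx + 2}: negative amount {raw!r}"
            )
        cents.append(value)
    return pd.Series(cents, index=df.index, dtype="int64")


def _parse_year(df: pd.DataFrame, column: str, path: Path) -> pd.Series:
    try:
        return df[column].astype("int64")
    except (ValueError, TypeError) as exc:
        raise CopDataError(f"{path}: non-integer {column}: {exc}") from exc


def read_table(path: str | Path, table_kind: str, *,
               suffixes: tuple[str, ...] = DEFAULT_SUFFIXES) -> pd.DataFrame:
    """Read one input table, validate it, and canonicalize it.

    Returns a DataFrame in the internal representation: integer-cent
    ``amount_cents`` columns, integer years, normalized partner names.  Each
    failure mode raises a distinct :class:`CopDataError` subclass naming the
    offending row.
    """
    if table_kind not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {table_kind!r}")
    path = Path(path)
    if not path.exists():
        raise MissingTableError(f"input table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, table_kind, path)
    df = df.loc[:, list(TABLE_SCHEMAS[table_kind])].copy()

    if table_kind == "funding":
        df["amount_cents"] = _parse_amounts(df, path)
        df["year"] = _parse_year(df, "year", path)
        df["partner"] = df["partner"].map(lambda s: normalize_name(s, suffixes))
        df["budget_code"] = df["budget_code"].str.strip().str.upper()
        if (df["budget_code"] == "").any():
            bad = df.index[df["budget_code"] == ""][0]
            raise CopDataError(f"{path}: row {bad + 2}: empty budget_code")
        return df.drop(columns=["amount"])

    if table_kind == "subawards":
        df["amount_cents"] = _parse_amounts(df, path)
        df["year"] = _parse_year(df, "year", path)
        df["prime_partner"] = df["prime_partner"].map(
            lambda s: normalize_name(s, suffixes)
        )
        df["sub_partner"] = df["sub_partner"].map(lambda s: normalize_name(s, suffixes))
        self_award = df["prime_partner"] == df["sub_partner"]
        if self_award.any():
            bad = df.index[self_award][0]
            raise CopDataError(
                f"{path}: row {bad + 2}: prime_partner equals sub_partner"
            )
        return df.drop(columns=["amount"])

    if table_kind == "crosscutting":
        df["amount_cents"] = _parse_amounts(df, path)
        df["year"] = _parse_year(df, "year", path)
        df["partner"] = df["partner"].map(lambda s: normalize_name(s, suffixes))
        df["category"] = (
            df["category"].str.strip().str.upper().str.replace(r"[ /:-]+", "_", regex=True)
        )
        bad = ~df["category"].isin(CROSSCUTTING_CATEGORIES)
        if bad.any():
            row = df.index[bad][0]
            raise InvalidCategoryError(
                f"{path}: row {row + 2}: unknown cross-cutting category "
                f"{df.loc[row, 'category']!r}"
            )
        return df.drop(columns=["amount"])

    if table_kind == "classes":
        df["partner"] = df["partner"].map(lambda s: normalize_name(s, suffixes))
        mapped = df["class"].str.strip().str.casefold().map(_CLASS_ALIASES)
        if mapped.isna().any():
            row = df.index[mapped.isna()][0]
            raise InvalidClassError(
                f"{path}: row {row + 2}: unknown partner class "
                f"{df.loc[row, 'class']!r}"
            )
        df["class"] = mapped
        return df

    # rates
    df["partner"] = df["partner"].map(lambda s: normalize_name(s, suffixes))
    df["period_start"] = _parse_year(df, "period_start", path)
    df["period_end"] = _parse_year(df, "period_end", path)
    for col in ("on_campus_osa", "off_campus_osa"):
        try:
            df[col] = df[col].map(parse_rate)
        except ValueError as exc:
            raise InvalidRateError(f"{path}: {exc}") from exc
    bad = (
        (df["period_start"] > df["period_end"])
        | df["on_campus_osa"].map(lambda r: not 0 <= r <= 1)
        | df["off_campus_osa"].map(lambda r: not 0 <= r <= 1)
    )
    if bad.any():
        row = df.index[bad][0]
        raise InvalidRateError(f"{path}: row {row + 2}: invalid rate entry")
    return df


def class_lookup(classes: pd.DataFrame) -> dict[str, str]:
    """Partner -> class mapping; later rows win on duplicates."""
    table = dict(zip(classes["partner"], classes["class"]))
    table[NA_PARTNER] = "NA"
    return table


def rate_table(rates: pd.DataFrame) -> dict[str, list[RateEntry]]:
    """Group the NICRA table into per-university period lists.

    Overlapping periods for one partner are rejected (the model needs a
    unique covering rate per year).
    """
    out: dict[str, list[RateEntry]] = {}
    for row in rates.itertuples(index=False):
        out.setdefault(row.partner, []).append(
            RateEntry(
                partner=row.partner,
                period_start=int(row.period_start),
                period_end=int(row.period_end),
                on_campus_osa=row.on_campus_osa,
                off_campus_osa=row.off_campus_osa,
            )
        )
    for partner, entries in out.items():
        entries.sort(key=lambda e: e.period_start)
        for a, b in zip(entries, entries[1:]):
            if b.period_start <= a.period_end:
                raise InvalidRateError(
                    f"overlapping NICRA periods for {partner!r}: "
                    f"{a.period_start}-{a.period_end} and "
                    f"{b.period_start}-{b.period_end}"
                )
    return out
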