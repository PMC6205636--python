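"""Exact money and rate arithmetic.

All monetary amounts are carried internally as integer US cents; all rates
(retention rates, exclusion fractions, indirect-cost rates) as
:class:`fractions.Fraction`.  Every rounding step in the pipeline goes
through :func:`round_cents` (banker's rounding), so conservation identities
hold to the cent on any input.
"""

from __future__ import annotations

from decimal import Decimal, InvalidOperation, ROUND_HALF_EVEN
from fractions import Fraction
from typing import Sequence

CENTS_PER_DOLLAR = 100


def parse_amount_cents(raw: object) -> int:
    """Parse a ledger amount (dollars, possibly with decimals) into cents.

    Raises ``ValueError`` on non-numeric input or amounts with sub-cent
    precision; the caller attaches row context.
    """
    text = str(raw).strip().replace(",", "")
    if text == "":
        raise ValueError("empty amount")
    try:
        dollars = Decimal(text)
    except InvalidOperation as exc:
        raise ValueError(f"non-numeric amount {raw!r}") from exc
    cents = dollars * CENTS_PER_DOLLAR
    if cents != cents.to_integral_value():
        raise ValueError(f"amount {raw!r} has sub-cent precision")
    return int(cents)


def cents_to_dollars_str(cents: int) -> str:
    """Render integer cents as a plain dollars string with two decimals."""
    sign = "-" if cents < 0 else ""
    q, r = divmod(abs(int(cents)), CENTS_PER_DOLLAR)
    return f"{sign}{q}.{r:02d}"


def parse_rate(raw: object) -> Fraction:
    """Parse a rate given as a decimal string (e.g. ``0.2675``) exactly."""
    text = str(raw).strip()
    if text.endswith("%"):
        return parse_rate(text[:-1]) / 100
    if "/" in text:
        return Fraction(text)
    try:
        return Fraction(Decimal(text))
    except InvalidOperation as exc:
        raise ValueError(f"non-numeric rate {raw!r}") from exc


def round_half_even(value: Fraction) -> int:
    """Round an exact rational to the nearest integer, ties to even."""
    num, den = value.numerator, value.denominator
    q, r = divmod(num, den)  # floor division; r >= 0 since den > 0
    twice = 2 * r
    if twice > den or (twice == den and q % 2 == 1):
        q += 1
    return q


def round_cents(value: Fraction | int) -> int:
    """Round an exact rational amount of cents to integer cents."""
    if isinstance(value, int):
        return value
    return round_half_even(value)


def cents_to_thousands(cents: int) -> int:
    """Display rounding: cents -> thousands of dollars, half-even."""
    return int(
        (Decimal(int(cents)).scaleb(-5)).quantize(Decimal(1), rounding=ROUND_HALF_EVEN)
    )


def largest_remainder_split(total: int, weights: Sequence[int]) -> list[int]:
    """Split integer ``total`` across ``weights`` proportionally and exactly.

    Uses the largest-remainder (Hamilton) method so the parts sum to
    ``total`` to the cent.  Ties go to the earliest index, which keeps the
    split deterministic for a fixed row order.
    """
    if total < 0:
        raise ValueError("cannot split a negative total")
    wsum = sum(weights)
    if wsum <= 0:
        raise ValueError("weights must have a positive sum")
    if any(w < 0 for w in weights):
        raise ValueError("weights must be non-negative")
    base = [total * w // wsum for w in weights]
    remainders = [(total * w) % wsum for w in weights]
    short = total - sum(base)
    # hand out the shortfall to the largest remainders, stable on ties
    order = sorted(range(len(weights)), key=lambda i: (-remainders[i], i))
    for i in order[:short]:
        base[i] += 1
    return base
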