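"""Shared fixtures: tiny hand-built ledgers and seeded synthetic ledgers."""

from __future__ import annotations

from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import settings

from copcost import SyntheticConfig, generate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def funding_frame(rows):
    """rows: (country, year, partner, agency, budget_code, amount_cents)."""
    return pd.DataFrame(
        rows,
        columns=["country", "year", "partner", "agency", "budget_code", "amount_cents"],
    ).assign(mechanism_id="M1", org_type="x")


def subaward_frame(rows):
    """rows: (prime_partner, agency, year, sub_partner, amount_cents)."""
    return pd.DataFrame(
        rows,
        columns=["prime_partner", "agency", "year", "sub_partner", "amount_cents"],
    )


@pytest.fixture(scope="session")
def small_config():
    """A compact synthetic configuration for fast end-to-end tests."""
    return SyntheticConfig(seed=7, n_io=6, n_univ=4, n_local=5, n_usg=1, n_years=8)


@pytest.fixture(scope="session")
def full_ledger(small_config):
    """Fully observed ledger: no masks, no NA funding, all pairs reporting."""
    return generate(small_config.fully_observed())


@pytest.fixture(scope="session")
def masked_ledger(small_config):
    """Realistic observation gaps, but no NA funding (cell-comparable)."""
    from dataclasses import replace

    return generate(replace(small_config, na_share=Fraction(0)))


@pytest.fixture(scope="session")
def default_ledger(small_config):
    """The default shape including NA funding."""
    return generate(small_config)
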