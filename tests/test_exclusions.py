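"""Excluded costs: direct components, pooled back-fill, and NEC."""

from __future__ import annotations

from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from copcost import ExclusionPolicy, compute_nec, direct_exclusions, pooled_proportion
from copcost.exclusions import EC_COLUMNS, backfill_exclusions


def cells_frame(rows):
    """rows: (partner, agency, year, total_cents, ret_cents)."""
    df = pd.DataFrame(
        rows, columns=["partner", "agency", "year", "total_cents", "ret_cents"]
    )
    df["klass"] = "IO"
    df["sub_cents"] = df["total_cents"] - df["ret_cents"]
    return df


def scoped_frame(rows):
    """rows: (partner, agency, year, budget_code, amount_cents)."""
    return pd.DataFrame(
        rows, columns=["partner", "agency", "year", "budget_code", "amount_cents"]
    )


def crosscutting_frame(rows):
    """rows: (partner, agency, year, category, amount_cents)."""
    return pd.DataFrame(
        rows, columns=["partner", "agency", "year", "category", "amount_cents"]
    ).assign(mechanism_id="M1")


class TestDirectExclusions:
    def test_lab_is_forty_percent_of_hlab(self):
        cells = cells_frame([("p", "a", 2010, 1000_00, 1000_00)])
        scoped = scoped_frame(
            [("p", "a", 2010, "HLAB", 100_00), ("p", "a", 2010, "HBHC", 900_00)]
        )
        out, _ = direct_exclusions(cells, scoped, crosscutting_frame([]), ExclusionPolicy())
        assert out.loc[0, "ec_lab_cents"] == 40_00

    def test_arv_budget_code_fully_excluded(self):
        cells = cells_frame([("p", "a", 2010, 1000_00, 1000_00)])
        scoped = scoped_frame([("p", "a", 2010, "HTXD", 250_00)])
        out, _ = direct_exclusions(cells, scoped, crosscutting_frame([]), ExclusionPolicy())
        assert out.loc[0, "ec_arv_cents"] == 250_00

    def test_no_crosscutting_records_give_zero_capital_and_vehicles(self):
        cells = cells_frame([("p", "a", 2010, 1000_00, 1000_00)])
        out, _ = direct_exclusions(
            cells, scoped_frame([]), crosscutting_frame([]), ExclusionPolicy()
        )
        assert out.loc[0, "ec_capital_cents"] == 0
        assert out.loc[0, "ec_vehicles_cents"] == 0

    def test_capital_and_vehicle_categories_summed_within_observed_years(self):
        cells = cells_frame(
            [("p", "a", 2010, 1000_00, 1000_00), ("p", "a", 2009, 1000_00, 1000_00)]
        )
        cc = crosscutting_frame(
            [
                ("p", "a", 2010, "CONSTRUCTION", 30_00),
                ("p", "a", 2010, "RENOVATION", 20_00),
                ("p", "a", 2010, "MOTOR_VEHICLES_PURCHASED", 5_00),
                ("p", "a", 2009, "CONSTRUCTION", 99_00),  # outside observed window
            ]
        )
        policy = ExclusionPolicy(
            capital_observed_years=(2010,), vehicle_observed_years=(2010,)
        )
        out, _ = direct_exclusions(cells, scoped_frame([]), cc, policy)
        by_year = out.set_index("year")
        assert by_year.loc[2010, "ec_capital_cents"] == 50_00
        assert by_year.loc[2010, "ec_vehicles_cents"] == 5_00
        assert by_year.loc[2009, "ec_capital_cents"] == 0

    def test_component_exceeding_ret_clamped_and_reported(self):
        cells = cells_frame([("p", "a", 2010, 1000_00, 100_00)])
        scoped = scoped_frame([("p", "a", 2010, "HTXD", 900_00)])
        out, audit = direct_exclusions(
            cells, scoped, crosscutting_frame([]), ExclusionPolicy()
        )
        assert out.loc[0, "ec_arv_cents"] == 100_00
        assert audit.clamped_components == [("p", "a", 2010, "ec_arv_cents")]


class TestPooledProportion:
    def test_direct_ratio_over_two_years(self):
        frac = pooled_proportion(
            {2010: 10, 2011: 20}, {2010: 1000, 2011: 1000}, (2010, 2011)
        )
        assert frac == Fraction(30, 2000) == Fraction("0.015")

    def test_zero_category_amounts(self):
        assert pooled_proportion({}, {2010: 1000}, (2010,)) == 0

    def test_zero_funding_in_window_warns_and_returns_zero(self):
        assert pooled_proportion({2010: 5}, {}, (2010,)) == 0

    def test_single_year_published_scale_ratio(self):
        # one observed year with a capital-to-funding ratio near 0.85%,
        # the aggregate scale the real ledgers show
        frac = pooled_proportion({2010: 130_070}, {2010: 15_338_981}, (2010,))
        assert float(frac) == pytest.approx(0.00848, abs=5e-5)


class TestBackfill:
    def _cells(self):
        cells = cells_frame(
            [
                ("p", "a", 2010, 1000_00, 1000_00),  # observed year
                ("p", "a", 2007, 500_00, 500_00),  # unobserved
                ("q", "a", 2007, 500_00, 500_00),  # partner absent from window
            ]
        )
        for col in EC_COLUMNS:
            cells[col] = 0
        cells.loc[0, "ec_capital_cents"] = 10_00  # observed fraction 0.01
        return cells

    def test_partner_fraction_applied_to_unobserved_year(self):
        policy = ExclusionPolicy(
            capital_observed_years=(2010,), vehicle_observed_years=(2010,)
        )
        out, audit = backfill_exclusions(self._cells(), policy)
        got = out.set_index(["partner", "year"])
        assert got.loc[("p", 2007), "ec_capital_cents"] == 5_00  # 0.01 x 500
        assert audit.backfill_provenance["ec_capital_cents"]["partner"] == 1

    def test_partner_absent_from_window_falls_back_to_agency(self):
        policy = ExclusionPolicy(
            capital_observed_years=(2010,), vehicle_observed_years=(2010,)
        )
        out, audit = backfill_exclusions(self._cells(), policy)
        got = out.set_index(["partner", "year"])
        assert got.loc[("q", 2007), "ec_capital_cents"] == 5_00  # agency ratio 0.01
        assert audit.backfill_provenance["ec_capital_cents"]["agency"] == 1

    def test_all_fractions_zero_imputes_zero(self):
        cells = self._cells()
        cells["ec_capital_cents"] = 0
        policy = ExclusionPolicy(
            capital_observed_years=(2010,), vehicle_observed_years=(2010,)
        )
        out, _ = backfill_exclusions(cells, policy)
        assert (out["ec_capital_cents"] == 0).all()

    def test_backfill_is_scale_equivariant(self):
        policy = ExclusionPolicy(
            capital_observed_years=(2010,), vehicle_observed_years=(2010,)
        )
        base = self._cells()
        doubled = base.copy()
        unobs = doubled["year"] != 2010
        doubled.loc[unobs, "total_cents"] *= 2
        out1, _ = backfill_exclusions(base, policy)
        out2, _ = backfill_exclusions(doubled, policy)
        unobs1 = out1.loc[out1["year"] != 2010, "ec_capital_cents"].to_numpy()
        unobs2 = out2.loc[out2["year"] != 2010, "ec_capital_cents"].to_numpy()
        assert (unobs2 == 2 * unobs1).all()


class TestComputeNEC:
    def test_subtraction(self):
        cells = cells_frame([("p", "a", 2010, 1100_00, 1000_00)])
        cells["ec_capital_cents"] = 50_00
        cells["ec_vehicles_cents"] = 10_00
        cells["ec_lab_cents"] = 40_00
        cells["ec_arv_cents"] = 250_00
        out, _ = compute_nec(cells)
        assert out.loc[0, "nec_cents"] == 650_00

    def test_all_zero_exclusions_leave_nec_equal_ret(self):
        cells = cells_frame([("p", "a", 2010, 1100_00, 1000_00)])
        for col in EC_COLUMNS:
            cells[col] = 0
        out, _ = compute_nec(cells)
        assert out.loc[0, "nec_cents"] == 1000_00

    def test_negative_nec_reported_and_identity_restored(self):
        cells = cells_frame([("p", "a", 2010, 1000_00, 100_00)])
        cells["ec_capital_cents"] = 80_00
        cells["ec_vehicles_cents"] = 80_00
        cells["ec_lab_cents"] = 0
        cells["ec_arv_cents"] = 0
        out, audit = compute_nec(cells)
        assert audit.negative_nec_cells == [("p", "a", 2010)]
        assert out.loc[0, "nec_cents"] == 0
        assert sum(out.loc[0, c] for c in EC_COLUMNS) == 100_00

    @given(
        st.integers(min_value=0, max_value=10**10),
        st.lists(st.integers(min_value=0, max_value=10**9), min_size=4, max_size=4),
    )
    def test_conservation_ret_equals_ec_plus_nec(self, ret, ecs):
        cells = cells_frame([("p", "a", 2010, ret + 1, ret)])
        for col, v in zip(EC_COLUMNS, ecs):
            cells[col] = v
        out, _ = compute_nec(cells)
        total_ec = sum(int(out.loc[0, c]) for c in EC_COLUMNS)
        assert total_ec + int(out.loc[0, "nec_cents"]) == ret
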