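"""Retention rates, the IO sub-award adjustment, and fallbacks."""

from __future__ import annotations

from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from copcost import (
    applied_retention,
    apply_retention,
    build_retention_table,
    io_subaward_proportion,
    partner_retention,
)
from copcost.retention import Provenance, RetentionError, fallback_rates
from conftest import funding_frame, subaward_frame

CLASSES = {"big io": "IO", "sub io": "IO", "sub univ": "UNIVERSITY",
           "sub loc": "LOCAL"}


def _fund(partner, agency, year, cents):
    return ("k", year, partner, agency, "HBHC", cents)


class TestPartnerRetention:
    def test_average_retention_arithmetic(self):
        # single partner: funding 1000, sub-awards 165 -> R = 0.835, the
        # published average for partners with disclosed sub-awards
        f = funding_frame([_fund("big io", "usaid", 2007, 1000_00)])
        s = subaward_frame([("big io", "usaid", 2007, "sub loc", 165_00)])
        rates, weights, clamped = partner_retention(s, f, [2007])
        assert rates[("big io", "usaid")] == Fraction("0.835")
        assert weights[("big io", "usaid")] == 1000_00
        assert clamped == []

    def test_no_subawards_gives_full_retention(self):
        f = funding_frame([_fund("big io", "usaid", 2007, 1000_00)])
        s = subaward_frame([("big io", "usaid", 2007, "sub loc", 0)])
        rates, _, _ = partner_retention(s, f, [2007])
        assert rates[("big io", "usaid")] == 1

    def test_subawards_equal_funding_boundary(self):
        f = funding_frame([_fund("big io", "usaid", 2007, 500)])
        s = subaward_frame([("big io", "usaid", 2007, "sub loc", 500)])
        rates, _, _ = partner_retention(s, f, [2007])
        assert rates[("big io", "usaid")] == 0

    def test_subawards_exceeding_funding_clamped_and_reported(self):
        f = funding_frame([_fund("big io", "usaid", 2007, 100)])
        s = subaward_frame([("big io", "usaid", 2007, "sub loc", 150)])
        rates, _, clamped = partner_retention(s, f, [2007])
        assert rates[("big io", "usaid")] == 0
        assert clamped == [("big io", "usaid")]

    def test_window_restricts_both_sides(self):
        f = funding_frame(
            [_fund("big io", "usaid", 2007, 1000), _fund("big io", "usaid", 2012, 9999)]
        )
        s = subaward_frame(
            [
                ("big io", "usaid", 2007, "sub loc", 100),
                ("big io", "usaid", 2012, "sub loc", 9999),
            ]
        )
        rates, _, _ = partner_retention(s, f, [2007])
        assert rates[("big io", "usaid")] == Fraction(900, 1000)


class TestIOSubawardProportion:
    def test_direct_ratio(self):
        s = subaward_frame(
            [
                ("big io", "usaid", 2007, "sub io", 30_000_000_00),
                ("big io", "usaid", 2007, "sub loc", 70_000_000_00),
            ]
        )
        per_agency, global_p = io_subaward_proportion(s, CLASSES)
        assert per_agency["usaid"] == Fraction(30, 100)
        assert global_p == Fraction(30, 100)

    def test_small_io_subpartner_treated_as_local(self):
        # within-agency total of $50,000 is below the $100,000 threshold
        s = subaward_frame(
            [
                ("big io", "usaid", 2007, "sub io", 50_000_00),
                ("big io", "usaid", 2007, "sub loc", 50_000_00),
            ]
        )
        per_agency, _ = io_subaward_proportion(s, CLASSES)
        assert per_agency["usaid"] == 0

    def test_unknown_class_subpartner_treated_as_local(self):
        s = subaward_frame(
            [("big io", "usaid", 2007, "mystery sub", 500_000_00)]
        )
        per_agency, _ = io_subaward_proportion(s, CLASSES)
        assert per_agency["usaid"] == 0

    def test_all_university_subawards_give_p_of_one(self):
        s = subaward_frame(
            [("big io", "usaid", 2007, "sub univ", 500_000_00)]
        )
        per_agency, _ = io_subaward_proportion(s, CLASSES)
        assert per_agency["usaid"] == 1

    def test_reference_year_defaults_to_first_observed(self):
        s = subaward_frame(
            [
                ("big io", "usaid", 2008, "sub io", 500_000_00),
                ("big io", "usaid", 2009, "sub loc", 500_000_00),
            ]
        )
        per_agency, _ = io_subaward_proportion(s, CLASSES)
        assert per_agency["usaid"] == 1  # only 2008 counts


class TestAppliedRetention:
    @pytest.mark.parametrize(
        "r,p,expected",
        [
            ("0.8633", "0.2675", "89.99"),  # HHS/CDC
            ("0.9397", "0.7636", "98.57"),  # Dept of Defense
            ("0.6851", "0.4090", "81.39"),  # HHS/HRSA
            ("0.9917", "0", "99.17"),       # Dept of Labor
            ("0.9365", "0.0000", "93.65"),  # Bur. PRM
        ],
    )
    def test_published_agency_rows_reproduced(self, r, p, expected):
        got = applied_retention(Fraction(r), Fraction(p))
        assert round(float(got) * 100, 2) == float(expected)

    def test_no_international_subawardees_is_identity(self):
        assert applied_retention(Fraction("0.75"), 0) == Fraction("0.75")

    @pytest.mark.parametrize("r,p", [(-0.1, 0.5), (0.5, 1.2), (1.5, 0)])
    def test_out_of_range_inputs_rejected(self, r, p):
        with pytest.raises(RetentionError):
            applied_retention(r, p)

    @given(
        st.fractions(min_value=0, max_value=1),
        st.fractions(min_value=0, max_value=1),
        st.fractions(min_value=0, max_value=1),
    )
    def test_monotone_and_never_below_r(self, r, p, q):
        a = applied_retention(r, p)
        assert a >= r
        assert 0 <= a <= 1
        if q >= p:
            assert applied_retention(r, q) >= a


class TestFallbacks:
    def test_equal_weight_agency_average(self):
        # two partners, R = 0.8 and 0.9, equal window funding, p = 0
        rates = {("a", "ag"): Fraction("0.8"), ("b", "ag"): Fraction("0.9")}
        weights = {("a", "ag"): 100, ("b", "ag"): 100}
        avg_r, applied, g_r, g_applied = fallback_rates(rates, weights, {}, Fraction(0))
        assert avg_r["ag"] == Fraction("0.85")
        assert applied["ag"] == Fraction("0.85")

    def test_funding_weighted_average(self):
        rates = {("a", "ag"): Fraction("0.8"), ("b", "ag"): Fraction("0.9")}
        weights = {("a", "ag"): 300, ("b", "ag"): 100}
        avg_r, _, _, _ = fallback_rates(rates, weights, {}, Fraction(0))
        assert avg_r["ag"] == Fraction("0.825")

    def test_single_agency_global_equals_agency(self):
        rates = {("a", "ag"): Fraction("0.8")}
        weights = {("a", "ag"): 100}
        _, applied, _, g_applied = fallback_rates(
            rates, weights, {"ag": Fraction("0.5")}, Fraction("0.5")
        )
        assert g_applied == applied["ag"]

    def test_no_observed_partners_is_a_hard_error(self):
        with pytest.raises(RetentionError):
            fallback_rates({}, {}, {}, Fraction(0))


class TestRetentionTableAndApply:
    def _table(self):
        f = funding_frame(
            [
                _fund("big io", "usaid", 2007, 10_000_000_00),
                _fund("other io", "usaid", 2007, 5_000_000_00),
                _fund("lone io", "cdc", 2007, 2_000_000_00),
            ]
        )
        s = subaward_frame(
            [
                ("big io", "usaid", 2007, "sub io", 1_000_000_00),
                ("big io", "usaid", 2007, "sub loc", 1_000_000_00),
            ]
        )
        return build_retention_table(s, f, CLASSES)

    def test_provenance_precedence_partner_agency_global(self):
        t = self._table()
        rate, prov = t.lookup("big io", "usaid")
        assert prov is Provenance.PARTNER_OBSERVED
        _, prov = t.lookup("other io", "usaid")
        assert prov is Provenance.AGENCY_AVERAGE
        _, prov = t.lookup("lone io", "cdc")
        assert prov is Provenance.GLOBAL_AVERAGE

    def test_applied_rate_composition(self):
        t = self._table()
        # R = 0.8 over the window, p = 0.5 -> applied = 0.8 + 0.2*0.5 = 0.9
        rate, _ = t.lookup("big io", "usaid")
        assert rate == Fraction("0.9")

    def test_apply_retention_identity_total_sub_ret(self):
        t = self._table()
        cells = pd.DataFrame(
            {
                "partner": ["big io", "other io", "lone io"],
                "agency": ["usaid", "usaid", "cdc"],
                "year": [2010, 2010, 2010],
                "klass": ["IO", "IO", "IO"],
                "total_cents": [999_99, 1_000_01, 123_45],
            }
        )
        out = apply_retention(cells, t)
        assert (out["sub_cents"] + out["ret_cents"] == out["total_cents"]).all()
        assert (out["sub_cents"] >= 0).all() and (out["ret_cents"] >= 0).all()

    def test_full_retention_means_zero_sub(self):
        f = funding_frame(
            [_fund("a", "ag", 2007, 1000), _fund("b", "ag2", 2007, 1000)]
        )
        s = subaward_frame(
            [
                ("a", "ag", 2007, "sub loc", 0),
                ("b", "ag2", 2007, "sub loc", 100),
            ]
        )
        t = build_retention_table(s, f, CLASSES)
        cells = pd.DataFrame(
            {
                "partner": ["a"],
                "agency": ["ag"],
                "year": [2010],
                "klass": ["IO"],
                "total_cents": [777_77],
            }
        )
        out = apply_retention(cells, t)
        assert out.loc[0, "sub_cents"] == 0
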