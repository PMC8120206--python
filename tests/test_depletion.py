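"""Contingency machinery: odds ratios, depletion calls, immunogenicity bias."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from neoscape import (
    DepletionStatus,
    TwoByTwoTable,
    build_table,
    cohort_depletion_summary,
    depletion_call,
    immunogenicity_bias_or,
    odds_ratio,
)
from neoscape.synthetic import simulate_depletion_sample


def fisher_p_enumeration(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    n1, k, N = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, N, n1, k)
    lo, hi = max(0, k - (c + d)), min(k, n1)
    return sum(
        hypergeom.pmf(x, N, n1, k)
        for x in range(lo, hi + 1)
        if hypergeom.pmf(x, N, n1, k) <= p_obs * (1 + 1e-9)
    )


class TestOddsRatio:
    def test_hand_value(self):
        res = odds_ratio(TwoByTwoTable(5, 15, 2, 38))
        assert res.odds_ratio == pytest.approx(190 / 30)
        assert not res.continuity_corrected
        assert res.ci95[0] < res.odds_ratio < res.ci95[1]

    def test_independence(self):
        res = odds_ratio(TwoByTwoTable(10, 30, 20, 60))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_fisher == pytest.approx(1.0)

    def test_zero_cell_correction(self):
        res = odds_ratio(TwoByTwoTable(0, 10, 5, 35))
        assert res.continuity_corrected
        assert res.odds_ratio == pytest.approx((0.5 * 35.5) / (10.5 * 5.5))

    def test_row_column_swap_invariances(self):
        t = TwoByTwoTable(7, 13, 4, 26)
        base = odds_ratio(t).odds_ratio
        both = odds_ratio(TwoByTwoTable(26, 4, 13, 7)).odds_ratio  # both swapped
        rows = odds_ratio(TwoByTwoTable(4, 26, 7, 13)).odds_ratio  # rows swapped
        assert both == pytest.approx(base)
        assert rows == pytest.approx(1 / base)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwoTable(-1, 2, 3, 4)

    @given(
        a=st.integers(1, 25), b=st.integers(1, 25),
        c=st.integers(1, 25), d=st.integers(1, 25),
    )
    @settings(derandomize=True, max_examples=60)
    def test_fisher_matches_enumeration(self, a, b, c, d):
        res = odds_ratio(TwoByTwoTable(a, b, c, d))
        assert res.p_fisher == pytest.approx(
            fisher_p_enumeration(a, b, c, d), rel=1e-9, abs=1e-12
        )


class TestBuildTable:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "neoantigenic": rng.random(60) < 0.4,
                "in_copy_loss": rng.random(60) < 0.3,
            }
        )
        t = build_table(df, "neoantigenic", "in_copy_loss")
        assert t.a == int((df.neoantigenic & df.in_copy_loss).sum())
        assert t.b == int((df.neoantigenic & ~df.in_copy_loss).sum())
        assert t.c == int((~df.neoantigenic & df.in_copy_loss).sum())
        assert t.d == int((~df.neoantigenic & ~df.in_copy_loss).sum())
        assert t.total == 60

    def test_degenerate_margins(self):
        df = pd.DataFrame({"neo": [True] * 5, "attr": [True, False] * 2 + [True]})
        t = build_table(df, "neo", "attr")
        assert t.c == 0 and t.d == 0
        t2 = build_table(df.assign(attr=False), "neo", "attr")
        assert t2.a == 0 and t2.c == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_table(pd.DataFrame(columns=["neo", "attr"]), "neo", "attr")


class TestDepletionCall:
    def test_forced_direction(self):
        # every neoantigenic mutation expressed, every other one silent at RNA
        df = pd.DataFrame(
            {
                "variant_class": "MISSENSE",
                "neoantigenic": [True] * 10 + [False] * 10,
                "expressed": [True] * 10 + [False] * 10,
                "in_copy_loss": [False] * 20,
            }
        )
        call = depletion_call(df, "s")
        assert call.txn_or.odds_ratio > 1
        assert not call.txn_depleted

    def test_undetermined_when_one_row_empty(self):
        df = pd.DataFrame(
            {
                "variant_class": "MISSENSE",
                "neoantigenic": True,
                "expressed": [True, False] * 3,
                "in_copy_loss": False,
            }
        )
        call = depletion_call(df, "s")
        assert call.cnv_status is DepletionStatus.UNDETERMINED
        assert call.txn_status is DepletionStatus.UNDETERMINED

    def test_silent_variants_ignored(self):
        df = pd.DataFrame(
            {
                "variant_class": ["SILENT"] * 50
                + ["MISSENSE"] * 4,
                "neoantigenic": [True] * 50 + [True, True, False, False],
                "expressed": [False] * 50 + [False, False, True, True],
                "in_copy_loss": False,
            }
        )
        call = depletion_call(df, "s")
        # only the 4 nonsynonymous rows count: OR < 1 -> depleted
        assert call.txn_or.odds_ratio < 1
        assert call.txn_depleted


class TestImmunogenicityBias:
    def test_hand_value(self):
        res = immunogenicity_bias_or(
            [True] * 8 + [False] * 2, [True] * 3 + [False] * 7
        )
        assert res.odds_ratio == pytest.approx((8 * 7) / (2 * 3))

    def test_equal_proportions(self):
        res = immunogenicity_bias_or([True, False], [True, False])
        assert res.odds_ratio == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            immunogenicity_bias_or([], [True])


class TestCohortSummary:
    def _call(self, sid, depleted):
        df = pd.DataFrame(
            {
                "variant_class": "MISSENSE",
                "neoantigenic": [True] * 20 + [False] * 20,
                "expressed": ([False] * 15 + [True] * 5 + [True] * 15 + [False] * 5)
                if depleted
                else ([True] * 10 + [False] * 10) * 2,
                "in_copy_loss": False,
            }
        )
        return depletion_call(df, sid)

    def test_fraction(self):
        calls = [self._call(f"s{i}", i == 0) for i in range(4)]
        sites = {f"s{i}": "PRIMARY" for i in range(4)}
        summary = cohort_depletion_summary(calls, sites)
        txn = summary[(summary.site == "PRIMARY") & (summary.depletion_kind == "txn")]
        assert txn["fraction_depleted"].iloc[0] == pytest.approx(0.25)

    def test_empty_site_reported_missing(self):
        calls = [self._call("s0", True)]
        summary = cohort_depletion_summary(calls, {"s0": "PRIMARY"})
        distant = summary[summary.site == "DISTANT"]
        assert distant["fraction_depleted"].isna().all()

    def test_unknown_site_rejected(self):
        with pytest.raises(ValueError, match="unknown site"):
            cohort_depletion_summary([self._call("s0", True)], {"s0": "BRAIN"})


class TestPlantedRecovery:
    def test_direction_under_strong_planting(self):
        # theta_txn = 0.5 on big samples: depletion direction recovered mostly
        rng = np.random.default_rng(7)
        flags = []
        for _ in range(20):
            df = simulate_depletion_sample(400, theta_txn=0.5, rng=rng)
            flags.append(depletion_call(df, "s").txn_depleted)
        assert np.mean(flags) >= 0.8

    def test_null_is_symmetric(self):
        rng = np.random.default_rng(8)
        ors = [
            depletion_call(
                simulate_depletion_sample(200, theta_txn=1.0, theta_cnv=1.0, rng=rng),
                "s",
            ).cnv_loss_or.odds_ratio
            for _ in range(40)
        ]
        assert 0.75 < float(np.median(ors)) < 1.30
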