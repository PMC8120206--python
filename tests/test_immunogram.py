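"""Enrichment engine, cohort z, IGS formula, TMIT quadrants, cell ratios."""

import numpy as np
import pandas as pd
import pytest

from neoscape import (
    Orientation,
    antigenicity_axis,
    cell_ratios,
    cohort_z,
    default_axis_catalog,
    igs,
    immunogram,
    ssgsea_score,
    tmit_classify,
)


def toy_matrix():
    # 5 genes x 2 samples; sample B reverses the ranking of sample A
    return pd.DataFrame(
        {
            "A": [5.0, 4.0, 3.0, 2.0, 1.0],
            "B": [1.0, 2.0, 3.0, 4.0, 5.0],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )


def oracle_ssgsea(expr_col, index, gene_set, weight=0.25):
    """Independent step-by-step running-sum for one sample."""
    n = len(index)
    order = sorted(range(n), key=lambda i: (-expr_col[i], i))
    in_set = [index[i] in gene_set for i in order]
    m = sum(in_set)
    weights = [((n - pos) / n) ** weight if hit else 0.0
               for pos, hit in enumerate(in_set)]
    wsum = sum(weights)
    es, p_hit, p_miss = 0.0, 0.0, 0.0
    for pos in range(n):
        p_hit += weights[pos] / wsum
        p_miss += (0 if in_set[pos] else 1) / (n - m)
        es += p_hit - p_miss
    return es


class TestSsgsea:
    def test_matches_hand_traced_oracle(self):
        expr = toy_matrix()
        gs = ["g1", "g3"]
        scores = ssgsea_score(expr, gs)
        for col in expr.columns:
            expected = oracle_ssgsea(list(expr[col]), list(expr.index), set(gs))
            assert scores[col] == pytest.approx(expected, rel=1e-12)

    def test_top_set_beats_bottom_set(self):
        expr = toy_matrix()
        top = ssgsea_score(expr, ["g1", "g2"])
        bottom = ssgsea_score(expr, ["g4", "g5"])
        assert top["A"] > bottom["A"]
        assert top["B"] < bottom["B"]  # rankings reversed in sample B

    def test_row_permutation_invariance(self):
        expr = toy_matrix()
        shuffled = expr.sample(frac=1, random_state=1)
        gs = ["g2", "g5"]
        pd.testing.assert_series_equal(
            ssgsea_score(expr, gs), ssgsea_score(shuffled, gs)
        )

    def test_raising_a_set_gene_increases_score(self):
        expr = toy_matrix()
        gs = ["g4", "g5"]
        base = ssgsea_score(expr, gs)["A"]
        boosted = expr.copy()
        boosted.loc["g5", "A"] = 100.0
        assert ssgsea_score(boosted, gs)["A"] > base

    def test_too_few_genes_error_names_missing(self):
        with pytest.raises(ValueError, match="missing.*gX"):
            ssgsea_score(toy_matrix(), ["g1", "gX"])


class TestCohortZ:
    def test_hand_value(self):
        z = cohort_z([1.0, 2.0, 3.0])
        assert z == pytest.approx([-1.2247448, 0.0, 1.2247448], abs=1e-6)

    def test_moments(self):
        rng = np.random.default_rng(0)
        z = cohort_z(rng.normal(10, 3, size=50))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        z = cohort_z([4.0, 8.0, 15.0, 16.0])
        assert cohort_z(z) == pytest.approx(z)

    def test_constant_scores_warn(self):
        with pytest.warns(UserWarning, match="zero dispersion"):
            z = cohort_z([2.0, 2.0, 2.0])
        assert (z == 0).all()


class TestIgs:
    @pytest.mark.parametrize(
        "z,orientation,raw,display",
        [
            (0.0, Orientation.STIMULATORY, 3.0, 3.0),
            (0.0, Orientation.INHIBITORY, 3.0, 3.0),
            (1.0, Orientation.STIMULATORY, 4.5, 4.5),
            (1.0, Orientation.INHIBITORY, 1.5, 1.5),
            (2.0, Orientation.STIMULATORY, 6.0, 5.0),   # clamped display
            (-2.0, Orientation.STIMULATORY, 0.0, 1.0),  # clamped display
        ],
    )
    def test_formula_and_clamp(self, z, orientation, raw, display):
        got_raw, got_disp = igs(z, orientation)
        assert got_raw == pytest.approx(raw)
        assert got_disp == pytest.approx(display)

    def test_orientation_reflects_about_3(self):
        for z in (-1.3, -0.2, 0.9):
            s, _ = igs(z, Orientation.STIMULATORY)
            i, _ = igs(z, Orientation.INHIBITORY)
            assert s + i == pytest.approx(6.0)


class TestAntigenicityAxis:
    def test_equal_loads_give_3(self):
        with pytest.warns(UserWarning):
            ax = antigenicity_axis(pd.Series([50, 50, 50], index=list("abc")))
        assert (ax["igs_raw"] == 3.0).all()

    def test_monotone(self):
        ax = antigenicity_axis(pd.Series([10, 100, 1000], index=list("abc")))
        assert ax["igs_raw"].idxmax() == "c"
        # z on log10(x+1) matches hand computation
        logs = np.log10(np.array([10, 100, 1000]) + 1)
        expected = (logs - logs.mean()) / logs.std(ddof=0)
        assert ax["z"].to_numpy() == pytest.approx(expected)


class TestImmunogram:
    def test_eight_axes_and_orientations(self):
        rng = np.random.default_rng(4)
        genes = sorted({g for gs in default_axis_catalog().values() for g in gs.genes})
        expr = pd.DataFrame(
            rng.normal(5, 1, size=(len(genes), 6)),
            index=genes,
            columns=[f"s{i}" for i in range(6)],
        )
        loads = pd.Series(rng.poisson(200, 6), index=expr.columns)
        radar = immunogram(expr, loads)
        assert set(radar) == set(expr.columns)
        for axes in radar.values():
            assert len(axes) == 8
            assert [a.orientation for a in axes[:5]] == [Orientation.STIMULATORY] * 5
            assert [a.orientation for a in axes[5:]] == [Orientation.INHIBITORY] * 3
            assert all(1.0 <= a.igs_display <= 5.0 for a in axes)

    def test_inflamed_sample_polarity(self):
        rng = np.random.default_rng(9)
        catalog = default_axis_catalog()
        genes = sorted({g for gs in catalog.values() for g in gs.genes})
        expr = pd.DataFrame(
            rng.normal(5, 0.3, size=(len(genes), 8)),
            index=genes,
            columns=[f"s{i}" for i in range(8)],
        )
        # sample s0: T-cell and trafficking signatures up, Treg signature down
        expr.loc[list(catalog[1].genes), "s0"] += 4
        expr.loc[list(catalog[4].genes), "s0"] += 4
        expr.loc[list(catalog[6].genes), "s0"] -= 4
        loads = pd.Series(100.0, index=expr.columns)
        axes = {a.axis_index: a for a in immunogram(expr, loads)["s0"]}
        assert axes[1].igs_raw > 3
        assert axes[4].igs_raw > 3
        assert axes[6].igs_raw > 3  # inhibitory axis: fewer Tregs -> higher IGS

    def test_missing_axis_errors(self):
        rng = np.random.default_rng(0)
        catalog = default_axis_catalog()
        del catalog[7]
        genes = sorted({g for gs in catalog.values() for g in gs.genes})
        expr = pd.DataFrame(
            rng.normal(5, 1, size=(len(genes), 4)),
            index=genes, columns=[f"s{i}" for i in range(4)],
        )
        with pytest.raises(ValueError, match="axis 7"):
            immunogram(expr, pd.Series(1.0, index=expr.columns), catalog)


class TestTmit:
    def test_quadrants(self):
        cd8 = pd.Series([10, 1, 1, 10], index=list("abcd"))
        pdl1 = pd.Series([10, 1, 10, 1], index=list("abcd"))
        labels = tmit_classify(cd8, pdl1)
        assert list(labels) == ["I", "II", "III", "IV"]

    def test_partition(self):
        rng = np.random.default_rng(1)
        idx = [f"s{i}" for i in range(20)]
        labels = tmit_classify(
            pd.Series(rng.normal(size=20), index=idx),
            pd.Series(rng.normal(size=20), index=idx),
        )
        assert labels.isin(["I", "II", "III", "IV"]).all()

    def test_missing_marker_rejected(self):
        cd8 = pd.Series([1.0, np.nan], index=list("ab"))
        with pytest.raises(ValueError):
            tmit_classify(cd8, pd.Series([1.0, 2.0], index=list("ab")))


class TestCellRatios:
    def test_pseudocount_values(self):
        df = pd.DataFrame(
            {
                "Tregs": [0.10], "T_cells_CD8": [0.05],
                "Macrophages_M1": [0.0], "Macrophages_M2": [0.2],
            }
        )
        out = cell_ratios(df)
        assert out["treg_cd8_ratio"].iloc[0] == pytest.approx(0.101 / 0.051)
        assert out["m2_m1_ratio"].iloc[0] == pytest.approx(0.201 / 0.001)

    def test_missing_column(self):
        with pytest.raises(ValueError, match="missing columns"):
            cell_ratios(pd.DataFrame({"Tregs": [0.1]}))
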