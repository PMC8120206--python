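"""Neoantigen calling cascade, classes, yield, sharing and ITH statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoscape import (
    AffinityClass,
    Neoepitope,
    StabilityClass,
    branch_proportion,
    call_neoantigens,
    classify_affinity,
    classify_stability,
    neoantigen_yield,
    sharing_stats,
    tcr_clonal_proportion,
)


def epi(affinities, fpkm, peptide="ACDEFGHIK", stability=None, vid="v1", **kw):
    return Neoepitope(
        variant_id=vid,
        peptide=peptide,
        hla_allele="HLA-A*02:01",
        predictor_affinities={f"p{i}": a for i, a in enumerate(affinities)},
        stability_halflife=stability,
        fpkm=fpkm,
        **kw,
    )


class TestCalling:
    def test_min_of_predictors_and_gates(self):
        called = call_neoantigens([epi((620, 480, 700), 2.3)])
        assert len(called) == 1
        assert called[0].best_affinity == 480
        assert called[0].affinity_class is AffinityClass.WEAK

    def test_strong_class(self):
        called = call_neoantigens([epi((45, 60, 80), 5.0)])
        assert called[0].affinity_class is AffinityClass.STRONG

    def test_expression_gate(self):
        assert call_neoantigens([epi((300, 310, 320), 0.8)]) == []

    def test_affinity_gate(self):
        assert call_neoantigens([epi((510, 620, 900), 5.0)]) == []

    def test_output_subset_of_input(self):
        epis = [epi((a,), f, vid=f"v{i}")
                for i, (a, f) in enumerate([(100, 2), (600, 2), (100, 0.5)])]
        called = call_neoantigens(epis)
        assert {n.variant_id for n in called} <= {e.variant_id for e in epis}
        assert [n.variant_id for n in called] == ["v0"]

    def test_invalid_peptide_length(self):
        with pytest.raises(ValueError, match="9- and 10-mers"):
            epi((100,), 2.0, peptide="ACDEFGHIKLMN")

    def test_nonpositive_affinity_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            epi((0.0,), 2.0)

    @given(
        affs=st.lists(st.floats(1, 1000), min_size=1, max_size=3),
        fpkm=st.floats(0, 5),
    )
    @settings(derandomize=True, max_examples=150)
    def test_monotone_in_thresholds(self, affs, fpkm):
        e = [epi(tuple(affs), fpkm)]
        strict = call_neoantigens(e, affinity_gate=500, fpkm_gate=1)
        relaxed = call_neoantigens(e, affinity_gate=800, fpkm_gate=0.5)
        assert len(relaxed) >= len(strict)

    def test_every_called_gets_exactly_one_class(self):
        for a in (1, 49, 50, 149, 150, 499):
            called = call_neoantigens([epi((float(a),), 2.0)])
            assert len(called) == 1
            assert called[0].affinity_class in AffinityClass


class TestClassBoundaries:
    @pytest.mark.parametrize(
        "affinity,expected",
        [
            (45, AffinityClass.STRONG),
            (49.999, AffinityClass.STRONG),
            (50, AffinityClass.MEDIUM),     # boundary falls to the weaker class
            (149.999, AffinityClass.MEDIUM),
            (150, AffinityClass.WEAK),
            (499, AffinityClass.WEAK),
        ],
    )
    def test_affinity(self, affinity, expected):
        assert classify_affinity(affinity) is expected

    def test_affinity_out_of_gate(self):
        with pytest.raises(ValueError):
            classify_affinity(500)

    @pytest.mark.parametrize(
        "halflife,expected",
        [
            (3.5, StabilityClass.HIGH),
            (2.0, StabilityClass.LOW),    # strict > 2 h
            (0.0, StabilityClass.LOW),
            (None, StabilityClass.UNKNOWN),
            (float("nan"), StabilityClass.UNKNOWN),
        ],
    )
    def test_stability(self, halflife, expected):
        assert classify_stability(halflife) is expected


class TestYield:
    def test_direct_ratio(self):
        classes = {f"v{i}": "MISSENSE" for i in range(10)}
        neo_ids = [f"v{i % 5}" for i in range(45)]  # 45 neoantigens, 5 sources
        yld, frac = neoantigen_yield(classes, neo_ids, "MISSENSE")
        assert yld == pytest.approx(4.5)
        assert frac == pytest.approx(0.5)

    def test_no_yield(self):
        classes = {"v0": "MISSENSE", "v1": "SILENT"}
        yld, frac = neoantigen_yield(classes, [], "MISSENSE")
        assert yld == 0.0 and frac == 0.0

    def test_identity_case(self):
        classes = {f"v{i}": "FRAMESHIFT_INDEL" for i in range(4)}
        yld, frac = neoantigen_yield(
            classes, list(classes), "FRAMESHIFT_INDEL"
        )
        assert yld == 1.0 and frac == 1.0


class TestSharing:
    def test_within_patient(self):
        key = ("PEPTIDEAA", "HLA-A*02:01")
        recs = [("P1", "S1", key), ("P1", "S2", key)]
        frac, cross = sharing_stats(recs)
        assert frac == 1.0 and cross == set()

    def test_all_private(self):
        recs = [("P1", "S1", ("A" * 9, "x")), ("P2", "S2", ("C" * 9, "x"))]
        frac, cross = sharing_stats(recs)
        assert frac == 0.0 and cross == set()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        keys = [(f"PEP{i}", "hla") for i in range(6)]
        recs = [
            (f"P{rng.integers(3)}", f"S{rng.integers(4)}", keys[rng.integers(6)])
            for _ in range(40)
        ]
        recs = list(dict.fromkeys(recs))  # distinct instances
        frac, cross = sharing_stats(recs)
        # brute force over every record
        def shared(rec):
            p, s, k = rec
            return any(p2 == p and k2 == k and s2 != s for p2, s2, k2 in recs)
        expected_frac = sum(shared(r) for r in recs) / len(recs)
        expected_cross = {
            k for _, _, k in recs
            if len({p for p, _, k2 in recs if k2 == k}) >= 2
        }
        assert frac == pytest.approx(expected_frac)
        assert cross == expected_cross


class TestBranchProportion:
    def test_direct_value(self):
        # union 10 keys, intersection 4 -> branch proportion 0.6
        a, b = set(range(10)), set(range(4))
        assert branch_proportion([a, b]) == pytest.approx(0.6)

    def test_identical_and_disjoint(self):
        s = {1, 2, 3}
        assert branch_proportion([s, set(s)]) == 0.0
        assert branch_proportion([{1, 2}, {3, 4}]) == 1.0

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            branch_proportion([set(), set()])

    @given(
        sets=st.lists(
            st.sets(st.integers(0, 15), max_size=10), min_size=2, max_size=5
        )
    )
    @settings(derandomize=True, max_examples=100)
    def test_permutation_invariant_and_matches_brute_force(self, sets):
        union = set().union(*sets)
        if not union:
            return
        expected = 1 - len(set.intersection(*map(set, sets))) / len(union)
        for perm in itertools.islice(itertools.permutations(sets), 6):
            assert branch_proportion(list(perm)) == pytest.approx(expected)


class TestTcrClonalProportion:
    def _frame(self, counts, chain="beta"):
        return pd.DataFrame(
            {"chain": chain, "cdr3": [f"C{i}" for i in range(len(counts))],
             "count": counts}
        )

    def test_single_dominant_clone(self):
        assert tcr_clonal_proportion(self._frame([500]))["beta"] == 1.0

    def test_uniform_small_clones(self):
        props = tcr_clonal_proportion(self._frame([1] * 1000))
        assert props["beta"] == 0.0

    def test_all_above_threshold(self):
        props = tcr_clonal_proportion(self._frame([50, 30, 20]))
        assert props["beta"] == pytest.approx(1.0)

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            tcr_clonal_proportion(self._frame([0, 0]))
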