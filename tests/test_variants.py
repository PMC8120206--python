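"""Variant-level QC, clonality, tracking, MATH and wGII."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from neoscape import (
    ClonalityLabel,
    CopyNumberSegment,
    TrackedVariantGroup,
    classify_clonality,
    math_score,
    qc_filter_snv,
    reduction_ratio,
    track_variants,
    wgii,
)
from neoscape.variants import AUTOSOME_LENGTHS


class TestQCFilter:
    @pytest.mark.parametrize(
        "tumor_alt,tumor_ref,normal_alt,normal_ref,expected",
        [
            (4, 96, 0, 100, False),   # support below the 5-read floor
            (20, 80, 0, 100, True),   # clear somatic signal
            (5, 95, 5, 95, False),    # identical compositions, p = 1
        ],
    )
    def test_rule(self, tumor_alt, tumor_ref, normal_alt, normal_ref, expected):
        assert (
            qc_filter_snv(tumor_alt, tumor_ref, normal_alt, normal_ref) is expected
        )

    def test_agrees_with_direct_fisher(self):
        # independent check of the composition-test gate
        rng = np.random.default_rng(3)
        for _ in range(50):
            ta, tr, na, nr = rng.integers(0, 60, size=4)
            _, p = stats.fisher_exact([[ta, tr], [na, nr]])
            assert qc_filter_snv(ta, tr, na, nr) == (ta >= 5 and p < 0.05)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            qc_filter_snv(-1, 10, 0, 10)


class TestClonality:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (0.92, 1.04, ClonalityLabel.CLONAL),
            (0.40, 0.80, ClonalityLabel.SUBCLONAL),
            (1.00, 1.00, ClonalityLabel.CLONAL),   # boundary contact counts
            (1.01, 1.40, ClonalityLabel.SUBCLONAL),
        ],
    )
    def test_rule(self, lo, hi, expected):
        assert classify_clonality(lo, hi) is expected

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            classify_clonality(1.2, 0.8)

    @given(
        lo=st.floats(0, 1.5, allow_nan=False),
        width=st.floats(0, 1.5, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=200)
    def test_matches_interval_containment_oracle(self, lo, width):
        hi = lo + width
        expected = (
            ClonalityLabel.CLONAL if lo <= 1 <= hi else ClonalityLabel.SUBCLONAL
        )
        assert classify_clonality(lo, hi) is expected


CLON = st.sampled_from([ClonalityLabel.CLONAL, ClonalityLabel.SUBCLONAL])
VKEY = st.tuples(
    st.sampled_from(["1", "2", "17"]), st.integers(1, 30),
    st.sampled_from("ACGT"), st.sampled_from("ACGT"),
)


class TestTracking:
    def test_group_definitions(self):
        key = ("1", 100, "A", "T")
        clonal, sub = ClonalityLabel.CLONAL, ClonalityLabel.SUBCLONAL
        assert track_variants({key: clonal}, {})[key] is TrackedVariantGroup.REDUCED
        assert track_variants({}, {key: clonal})[key] is TrackedVariantGroup.INCREASED
        assert (
            track_variants({key: sub}, {key: sub})[key]
            is TrackedVariantGroup.PERSISTENT
        )
        assert (
            track_variants({key: clonal}, {key: sub})[key]
            is TrackedVariantGroup.REDUCED
        )
        assert (
            track_variants({key: sub}, {key: clonal})[key]
            is TrackedVariantGroup.INCREASED
        )

    @given(
        primary=st.dictionaries(VKEY, CLON, max_size=25),
        metastasis=st.dictionaries(VKEY, CLON, max_size=25),
    )
    @settings(derandomize=True, max_examples=100)
    def test_output_partitions_union(self, primary, metastasis):
        groups = track_variants(primary, metastasis)
        assert set(groups) == set(primary) | set(metastasis)


class TestReductionRatio:
    def test_printed_formula(self):
        groups = (
            [TrackedVariantGroup.INCREASED] * 10 + [TrackedVariantGroup.REDUCED] * 30
        )
        s = reduction_ratio(groups, 100)
        assert s.reduction_ratio == pytest.approx(-0.20)
        assert s.reduction_flag

    def test_symmetry_and_positive(self):
        balanced = [TrackedVariantGroup.INCREASED] * 5 + [TrackedVariantGroup.REDUCED] * 5
        assert reduction_ratio(balanced, 50).reduction_ratio == 0.0
        assert not reduction_ratio(balanced, 50).reduction_flag
        up = [TrackedVariantGroup.INCREASED] * 25 + [TrackedVariantGroup.REDUCED] * 5
        s = reduction_ratio(up, 100)
        assert s.reduction_ratio == pytest.approx(0.20)
        assert not s.reduction_flag

    def test_zero_load_rejected(self):
        with pytest.raises(ValueError):
            reduction_ratio([], 0)


class TestMath:
    def test_hand_value(self):
        # median 0.3, raw MAD 0.1 -> scaled 0.14826 -> 49.42
        assert math_score([0.1, 0.2, 0.3, 0.4, 0.5]) == pytest.approx(49.42, abs=0.01)

    def test_zero_dispersion(self):
        assert math_score([0.3, 0.3, 0.3, 0.3]) == 0.0

    @given(
        vafs=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=30),
        scale=st.floats(0.1, 10.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_scale_invariance(self, vafs, scale):
        base = math_score(vafs)
        scaled = math_score([v * scale for v in vafs])
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestWgii:
    def _full_cover(self, aberrant_chroms, cn_aberrant=3):
        segs = []
        for chrom, length in AUTOSOME_LENGTHS.items():
            cn = cn_aberrant if chrom in aberrant_chroms else 2
            segs.append(CopyNumberSegment(chrom, 0, length, cn))
        return segs

    def test_no_aberration(self):
        value, cin = wgii(self._full_cover(set()), 2.0)
        assert value == 0.0 and not cin

    def test_single_aberrant_autosome(self):
        value, cin = wgii(self._full_cover({"7"}), 2.0)
        assert value == pytest.approx(1 / 22)
        assert not cin

    def test_fully_aberrant_genome(self):
        value, cin = wgii(self._full_cover(set(AUTOSOME_LENGTHS)), 2.0)
        assert value == 1.0 and cin

    def test_monotone_in_aberrant_segments(self):
        chroms = list(AUTOSOME_LENGTHS)
        prev = -1.0
        for k in range(0, 23, 5):
            value, _ = wgii(self._full_cover(set(chroms[:k])), 2.0)
            assert value >= prev
            prev = value

    def test_out_of_bounds_segment(self):
        segs = [CopyNumberSegment("21", 0, AUTOSOME_LENGTHS["21"] + 5, 2)]
        with pytest.raises(ValueError):
            wgii(segs, 2.0)
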