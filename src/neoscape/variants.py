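"""Somatic-variant level operations.

Covers the post-calling QC filter (alt-read support + Fisher composition
test against the matched normal), CCF-based clonality classification,
paired primary/metastasis variant tracking into reduced / increased /
persistent groups, the neoantigen reduction ratio, and the per-sample
heterogeneity and instability indices (MATH, wGII).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantClass",
    "ClonalityLabel",
    "TrackedVariantGroup",
    "ReductionSummary",
    "CopyNumberSegment",
    "AUTOSOME_LENGTHS",
    "qc_filter_snv",
    "classify_clonality",
    "track_variants",
    "reduction_ratio",
    "math_score",
    "wgii",
]


class VariantClass(str, enum.Enum):
    MISSENSE = "MISSENSE"
    FRAMESHIFT_INDEL = "FRAMESHIFT_INDEL"
    OTHER_NONSILENT = "OTHER_NONSILENT"
    SILENT = "SILENT"

    @property
    def nonsilent(self) -> bool:
        return self is not VariantClass.SILENT


NONSILENT_CLASSES = (
    VariantClass.MISSENSE.value,
    VariantClass.FRAMESHIFT_INDEL.value,
    VariantClass.OTHER_NONSILENT.value,
)


class ClonalityLabel(str, enum.Enum):
    CLONAL = "CLONAL"
    SUBCLONAL = "SUBCLONAL"


class TrackedVariantGroup(str, enum.Enum):
    REDUCED = "REDUCED"
    INCREASED = "INCREASED"
    PERSISTENT = "PERSISTENT"


# GRCh38 autosome lengths rounded to megabases.
AUTOSOME_LENGTHS: dict[str, int] = {
    "1": 249_000_000, "2": 242_000_000, "3": 198_000_000, "4": 190_000_000,
    "5": 182_000_000, "6": 171_000_000, "7": 159_000_000, "8": 145_000_000,
    "9": 138_000_000, "10": 134_000_000, "11": 135_000_000, "12": 133_000_000,
    "13": 114_000_000, "14": 107_000_000, "15": 102_000_000, "16": 90_000_000,
    "17": 83_000_000, "18": 80_000_000, "19": 59_000_000, "20": 64_000_000,
    "21": 47_000_000, "22": 51_000_000,
}


def qc_filter_snv(
    tumor_alt: int,
    tumor_ref: int,
    normal_alt: int,
    normal_ref: int,
    *,
    min_alt_reads: int = 5,
    alpha: float = 0.05,
) -> bool:
    """True-positive QC for a called SNV.

    Keep the variant iff the tumor alt-read support is at least
    ``min_alt_reads`` (default 5) and the two-sided Fisher exact test on the
    mutant/wild-type read composition between tumor and matched normal is
    significant at ``alpha`` (default 0.05).
    """
    counts = (tumor_alt, tumor_ref, normal_alt, normal_ref)
    if any(c < 0 for c in counts):
        raise ValueError(f"read counts must be non-negative, got {counts}")
    if tumor_alt < min_alt_reads:
        return False
    _, p = stats.fisher_exact(
        [[tumor_alt, tumor_ref], [normal_alt, normal_ref]], alternative="two-sided"
    )
    return bool(p < alpha)


def qc_filter_table(
    variants: pd.DataFrame, *, min_alt_reads: int = 5, alpha: float = 0.05
) -> pd.Series:
    """Vectorised ``qc_filter_snv`` over a variant table; returns a keep mask."""
    keep = np.zeros(len(variants), dtype=bool)
    cols = ["tumor_alt_reads", "tumor_ref_reads", "normal_alt_reads", "normal_ref_reads"]
    arr = variants[cols].to_numpy()
    # cache Fisher p-values: tables repeat heavily at fixed depth
    cache: dict[tuple[int, int, int, int], bool] = {}
    for i, (ta, tr, na, nr) in enumerate(arr):
        key = (int(ta), int(tr), int(na), int(nr))
        if key not in cache:
            cache[key] = qc_filter_snv(
                *key, min_alt_reads=min_alt_reads, alpha=alpha
            )
        keep[i] = cache[key]
    return pd.Series(keep, index=variants.index, name="qc_keep")


def classify_clonality(ccf_lo: float, ccf_hi: float) -> ClonalityLabel:
    """Clonal iff the closed 95% CCF confidence interval contains 1."""
    if ccf_lo > ccf_hi:
        raise ValueError(f"interval lower bound {ccf_lo} exceeds upper bound {ccf_hi}")
    if ccf_lo <= 1.0 <= ccf_hi:
        return ClonalityLabel.CLONAL
    return ClonalityLabel.SUBCLONAL


def track_variants(
    primary: Mapping[tuple, ClonalityLabel],
    metastasis: Mapping[tuple, ClonalityLabel],
) -> dict[tuple, TrackedVariantGroup]:
    """Classify each variant of a primary/metastasis pair by its fate.

    A variant key maps to REDUCED when it is present only in the primary or
    goes clonal -> subclonal; INCREASED when present only in the metastasis or
    subclonal -> clonal; PERSISTENT when present in both with an unchanged
    clonality class. Keys are (chrom, pos, ref, alt) tuples; the result is a
    total map over the union of keys.
    """
    out: dict[tuple, TrackedVariantGroup] = {}
    for key in set(primary) | set(metastasis):
        in_p, in_m = key in primary, key in metastasis
        if in_p and not in_m:
            out[key] = TrackedVariantGroup.REDUCED
        elif in_m and not in_p:
            out[key] = TrackedVariantGroup.INCREASED
        else:
            p, m = ClonalityLabel(primary[key]), ClonalityLabel(metastasis[key])
            if p is ClonalityLabel.CLONAL and m is ClonalityLabel.SUBCLONAL:
                out[key] = TrackedVariantGroup.REDUCED
            elif p is ClonalityLabel.SUBCLONAL and m is ClonalityLabel.CLONAL:
                out[key] = TrackedVariantGroup.INCREASED
            else:
                out[key] = TrackedVariantGroup.PERSISTENT
    return out


@dataclass(frozen=True)
class ReductionSummary:
    """Per-pair neoantigen (or mutation) fate counts and reduction ratio.

    ``reduction_ratio = (n_increased - n_reduced) / primary_load``; a
    negative ratio flags net reduction during metastasis.
    """

    pair_id: str
    n_reduced: int
    n_increased: int
    n_persistent: int
    primary_load: int
    reduction_ratio: float
    reduction_flag: bool


def reduction_ratio(
    groups: Mapping[tuple, TrackedVariantGroup] | Iterable[TrackedVariantGroup],
    primary_load: int,
    pair_id: str = "",
) -> ReductionSummary:
    """Summarise tracked groups into the reduction ratio for one pair."""
    if primary_load <= 0:
        raise ValueError("primary_load must be > 0 for a defined reduction ratio")
    values = list(groups.values()) if isinstance(groups, Mapping) else list(groups)
    n_red = sum(1 for g in values if TrackedVariantGroup(g) is TrackedVariantGroup.REDUCED)
    n_inc = sum(1 for g in values if TrackedVariantGroup(g) is TrackedVariantGroup.INCREASED)
    n_per = len(values) - n_red - n_inc
    ratio = (n_inc - n_red) / primary_load
    return ReductionSummary(
        pair_id=pair_id,
        n_reduced=n_red,
        n_increased=n_inc,
        n_persistent=n_per,
        primary_load=primary_load,
        reduction_ratio=ratio,
        reduction_flag=ratio < 0,
    )


def math_score(vafs: Sequence[float]) -> float:
    """Mutant-allele tumor heterogeneity: 100 * 1.4826*MAD / median of VAFs.

    The MAD is scaled by 1.4826 (consistency with the normal sd), per the
    standard MATH convention. Requires at least 3 VAFs and a positive median.
    """
    v = np.asarray(vafs, dtype=float)
    if v.size < 3:
        raise ValueError(f"MATH needs >= 3 VAFs, got {v.size}")
    med = float(np.median(v))
    if med <= 0:
        raise ValueError("median VAF must be > 0")
    mad = stats.median_abs_deviation(v, scale="normal")  # = 1.4826 * raw MAD
    return 100.0 * float(mad) / med


@dataclass(frozen=True)
class CopyNumberSegment:
    """One absolute copy-number segment, half-open [start, end)."""

    chrom: str
    start: int
    end: int
    total_cn: int
    loh: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end {self.end} must exceed start {self.start}")
        if self.total_cn < 0:
            raise ValueError("total_cn must be non-negative")


def wgii(
    segments: Iterable[CopyNumberSegment],
    sample_ploidy: float,
    *,
    cin_cut: float = 0.2,
) -> tuple[float, bool]:
    """Weighted genome instability index and CIN status.

    Per autosome, the length fraction of covered genome whose total copy
    number deviates from round(ploidy); averaged over the 22 autosomes
    (chromosomes without segments contribute 0). CIN+ iff wGII > ``cin_cut``.
    """
    if sample_ploidy <= 0:
        raise ValueError("ploidy must be > 0")
    baseline = int(round(sample_ploidy))
    covered: dict[str, float] = {c: 0.0 for c in AUTOSOME_LENGTHS}
    aberrant: dict[str, float] = {c: 0.0 for c in AUTOSOME_LENGTHS}
    for seg in segments:
        chrom = str(seg.chrom).removeprefix("chr")
        if chrom not in AUTOSOME_LENGTHS:
            continue  # sex chromosomes are excluded by convention
        if seg.start < 0 or seg.end > AUTOSOME_LENGTHS[chrom]:
            raise ValueError(
                f"segment {chrom}:{seg.start}-{seg.end} outside chromosome bounds"
            )
        length = seg.end - seg.start
        covered[chrom] += length
        if seg.total_cn != baseline:
            aberrant[chrom] += length
    fracs = [
        aberrant[c] / covered[c] if covered[c] > 0 else 0.0 for c in AUTOSOME_LENGTHS
    ]
    value = float(np.mean(fracs))
    return value, value > cin_cut
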