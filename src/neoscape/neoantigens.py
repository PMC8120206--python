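"""Neoantigen calling and landscape statistics.

A neoepitope (9/10-mer peptide-HLA pair with per-predictor binding
affinities) is called a neoantigen when its best (minimum) predicted
affinity is below 500 nM and its source transcript is expressed (FPKM > 1).
Called neoantigens are classified by affinity (strong < 50 nM,
medium < 150 nM, weak otherwise) and binding stability (high > 2 h).

Also implements cohort-level landscape statistics: per-mutation neoantigen
yield, within/cross-patient sharing, multiregion intratumor-heterogeneity
branch proportions (for neoantigens and TCR clonotypes alike) and the
clonal-TCR proportion.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "AffinityClass",
    "StabilityClass",
    "Neoepitope",
    "Neoantigen",
    "classify_affinity",
    "classify_stability",
    "call_neoantigens",
    "neoantigen_yield",
    "sharing_stats",
    "branch_proportion",
    "tcr_clonal_proportion",
]

VALID_PEPTIDE_LENGTHS = (9, 10)


class AffinityClass(str, enum.Enum):
    STRONG = "STRONG"
    MEDIUM = "MEDIUM"
    WEAK = "WEAK"


class StabilityClass(str, enum.Enum):
    HIGH = "HIGH"
    LOW = "LOW"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class Neoepitope:
    """A candidate peptide-HLA presentation event before filtering."""

    variant_id: str
    peptide: str
    hla_allele: str
    predictor_affinities: dict[str, float] = field(default_factory=dict)
    stability_halflife: Optional[float] = None  # hours
    fpkm: float = 0.0
    sample_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        if len(self.peptide) not in VALID_PEPTIDE_LENGTHS:
            raise ValueError(
                f"peptide {self.peptide!r} has length {len(self.peptide)}; "
                f"only 9- and 10-mers are considered"
            )
        if not self.predictor_affinities:
            raise ValueError("at least one predictor affinity is required")
        for name, aff in self.predictor_affinities.items():
            if not (aff > 0):
                raise ValueError(f"predictor {name}: affinity must be > 0, got {aff}")
        if self.stability_halflife is not None and self.stability_halflife < 0:
            raise ValueError("stability half-life must be non-negative")
        if self.fpkm < 0:
            raise ValueError("fpkm must be non-negative")

    @property
    def best_affinity(self) -> float:
        """Lowest affinity across predictors = strongest predicted binding."""
        return min(self.predictor_affinities.values())

    @property
    def key(self) -> tuple[str, str]:
        """Identity of the presentation event: (peptide, HLA allele)."""
        return (self.peptide, self.hla_allele)


@dataclass(frozen=True)
class Neoantigen:
    """A neoepitope that passed the calling gates, with classes attached."""

    epitope: Neoepitope
    best_affinity: float
    affinity_class: AffinityClass
    stability_class: StabilityClass
    clonality: Optional[str] = None

    @property
    def key(self) -> tuple[str, str]:
        return self.epitope.key

    @property
    def variant_id(self) -> str:
        return self.epitope.variant_id


def classify_affinity(
    best_affinity: float,
    *,
    strong_cut: float = 50.0,
    medium_cut: float = 150.0,
    gate: float = 500.0,
) -> AffinityClass:
    """Strong if < 50 nM, medium if < 150 nM, weak otherwise (within the gate).

    Boundaries fall to the weaker class: exactly 50 nM is MEDIUM, exactly
    150 nM is WEAK, mirroring the strict "<" in the class definitions.
    """
    if not (0 < best_affinity < gate):
        raise ValueError(
            f"best affinity {best_affinity} nM outside the calling gate (0, {gate})"
        )
    if best_affinity < strong_cut:
        return AffinityClass.STRONG
    if best_affinity < medium_cut:
        return AffinityClass.MEDIUM
    return AffinityClass.WEAK


def classify_stability(
    halflife_h: Optional[float], *, cut_h: float = 2.0
) -> StabilityClass:
    """High stability iff the pMHC half-life exceeds 2 h (strict)."""
    if halflife_h is None or (isinstance(halflife_h, float) and math.isnan(halflife_h)):
        return StabilityClass.UNKNOWN
    if halflife_h < 0:
        raise ValueError("half-life must be non-negative")
    return StabilityClass.HIGH if halflife_h > cut_h else StabilityClass.LOW


def call_neoantigens(
    epitopes: Iterable[Neoepitope],
    *,
    affinity_gate: float = 500.0,
    fpkm_gate: float = 1.0,
    strong_cut: float = 50.0,
    medium_cut: float = 150.0,
    stability_cut: float = 2.0,
    clonality_by_variant: Optional[dict[str, str]] = None,
) -> list[Neoantigen]:
    """Apply the calling cascade: min-affinity < 500 nM AND FPKM > 1.

    Relaxing either gate can only grow the returned set (monotone in both
    thresholds). Clonality, if supplied per variant id, is inherited by the
    called neoantigen.
    """
    called: list[Neoantigen] = []
    for epi in epitopes:
        best = epi.best_affinity
        if best >= affinity_gate or epi.fpkm <= fpkm_gate:
            continue
        called.append(
            Neoantigen(
                epitope=epi,
                best_affinity=best,
                affinity_class=classify_affinity(
                    best, strong_cut=strong_cut, medium_cut=medium_cut, gate=affinity_gate
                ),
                stability_class=classify_stability(
                    epi.stability_halflife, cut_h=stability_cut
                ),
                clonality=(clonality_by_variant or {}).get(epi.variant_id),
            )
        )
    return called


def neoantigens_to_frame(neoantigens: Sequence[Neoantigen]) -> pd.DataFrame:
    """Tabular view of called neoantigens (one row per presentation event)."""
    rows = [
        {
            "patient_id": n.epitope.patient_id,
            "sample_id": n.epitope.sample_id,
            "variant_id": n.variant_id,
            "peptide": n.epitope.peptide,
            "hla_allele": n.epitope.hla_allele,
            "best_affinity": n.best_affinity,
            "affinity_class": n.affinity_class.value,
            "stability_halflife": n.epitope.stability_halflife,
            "stability_class": n.stability_class.value,
            "fpkm": n.epitope.fpkm,
            "clonality": n.clonality,
        }
        for n in neoantigens
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "sample_id", "variant_id", "peptide", "hla_allele",
            "best_affinity", "affinity_class", "stability_halflife",
            "stability_class", "fpkm", "clonality",
        ],
    )


def neoantigen_yield(
    variant_classes: dict[str, str],
    neoantigen_variant_ids: Sequence[str],
    by_class: str,
    *,
    nonsilent_classes: Sequence[str] = (
        "MISSENSE",
        "FRAMESHIFT_INDEL",
        "OTHER_NONSILENT",
    ),
) -> tuple[float, float]:
    """Neoantigens-per-mutation yield for one variant class.

    ``variant_classes`` maps variant id -> class for all mutations of the
    sample/cohort; ``neoantigen_variant_ids`` lists the source variant id of
    every called neoantigen (with multiplicity). Returns

    - yield: (# neoantigens from variants of ``by_class``) / (# variants of
      that class) — the denominator is *all* mutations of the class, whether
      or not they generated an epitope;
    - fraction_generating: proportion of nonsilent variants with >= 1
      called neoantigen.
    """
    class_variants = [v for v, c in variant_classes.items() if c == by_class]
    if not class_variants:
        raise ValueError(f"no variants of class {by_class}")
    class_set = set(class_variants)
    n_neo = sum(1 for vid in neoantigen_variant_ids if vid in class_set)
    yld = n_neo / len(class_variants)

    nonsilent = [v for v, c in variant_classes.items() if c in set(nonsilent_classes)]
    generating = set(neoantigen_variant_ids)
    frac = (
        sum(1 for v in nonsilent if v in generating) / len(nonsilent)
        if nonsilent
        else 0.0
    )
    return yld, frac


def sharing_stats(
    records: Iterable[tuple[str, str, tuple]],
) -> tuple[float, set]:
    """Within-patient sharing fraction and cross-patient shared identity keys.

    ``records`` are (patient_id, sample_id, identity_key) triples, one per
    neoantigen instance. An instance counts as within-patient shared iff its
    key occurs in >= 2 distinct samples of the same patient; the fraction is
    shared instances / total instances. The cross-patient set holds keys seen
    in >= 2 distinct patients.
    """
    records = list(records)
    samples_by_patient_key: dict[tuple, set] = {}
    patients_by_key: dict[tuple, set] = {}
    for patient, sample, key in records:
        samples_by_patient_key.setdefault((patient, key), set()).add(sample)
        patients_by_key.setdefault(key, set()).add(patient)
    if not records:
        return 0.0, set()
    shared = sum(
        1
        for patient, _, key in records
        if len(samples_by_patient_key[(patient, key)]) >= 2
    )
    cross = {key for key, pts in patients_by_key.items() if len(pts) >= 2}
    return shared / len(records), cross


def branch_proportion(region_sets: Sequence[set]) -> float:
    """ITH as the proportion of branch (non-ubiquitous) features.

    1 - |intersection over regions| / |union over regions|, for >= 2
    multiregion feature sets (neoantigen keys or TCR clonotypes). Order of
    regions is immaterial.
    """
    if len(region_sets) < 2:
        raise ValueError("branch proportion needs >= 2 region sets")
    sets = [set(s) for s in region_sets]
    union = set().union(*sets)
    if not union:
        raise ValueError("all region sets are empty")
    inter = set.intersection(*sets)
    return 1.0 - len(inter) / len(union)


def tcr_clonal_proportion(
    clonotypes: pd.DataFrame,
    *,
    frequency_threshold: float = 0.01,
) -> dict[str, float]:
    """Per-chain proportion of reads in clones above a clonal-size threshold.

    A clone is "clonal" when its read count exceeds ``frequency_threshold``
    (default 1%) of the chain's total reads; the returned value is the read
    fraction carried by such clones, per chain.
    """
    required = {"chain", "count"}
    missing = required - set(clonotypes.columns)
    if missing:
        raise ValueError(f"clonotype table missing columns: {sorted(missing)}")
    out: dict[str, float] = {}
    for chain, grp in clonotypes.groupby("chain"):
        total = grp["count"].sum()
        if total <= 0:
            raise ValueError(f"chain {chain}: zero total read count")
        clonal = grp.loc[grp["count"] / total > frequency_threshold, "count"].sum()
        out[str(chain)] = float(clonal / total)
    return out
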