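"""Single-sample enrichment, the 8-axis immunogram, TMIT and cell ratios.

The immunogram summarises the cancer-immunity cycle per sample on eight
axes. Seven axes are scored from expression with a single-sample gene-set
enrichment engine (a rank-weighted running sum), converted to cohort
z-scores Z, and mapped to an immunogram score (IGS):

    stimulatory axes: IGS = 3 + 1.5 * Z
    inhibitory axes:  IGS = 3 - 1.5 * Z

so that 3 is the cohort average and higher is always "more favourable".
The eighth axis, tumor antigenicity, is the z-score of the per-sample
neoantigen load (log10(x+1)-transformed by default). Radar displays clamp
IGS to [1, 5]; the raw value is always retained.

The enrichment engine is deliberately simple and pluggable: every
downstream use passes through cohort z-scores, so any deterministic
monotone single-sample score serves.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSet",
    "Orientation",
    "ImmunogramAxis",
    "TMITLabel",
    "DEFAULT_AXES",
    "default_axis_catalog",
    "ssgsea_score",
    "cohort_z",
    "igs",
    "antigenicity_axis",
    "immunogram",
    "tmit_classify",
    "cell_ratios",
]


class Orientation(str, enum.Enum):
    STIMULATORY = "STIMULATORY"
    INHIBITORY = "INHIBITORY"


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple[str, ...]
    orientation: Orientation
    axis_index: int  # 1..8

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError(f"gene set {self.name}: needs >= 2 member genes")
        if not (1 <= self.axis_index <= 8):
            raise ValueError("axis_index must be in 1..8")


@dataclass(frozen=True)
class ImmunogramAxis:
    axis_name: str
    axis_index: int
    orientation: Orientation
    nes: float
    z: float
    igs_raw: float
    igs_display: float


# Axis order of the cancer-immunity cycle; axis 2 (antigenicity) is scored
# from the neoantigen load, the others from expression gene sets.
DEFAULT_AXES: tuple[tuple[int, str, Orientation], ...] = (
    (1, "T_cell_immunity", Orientation.STIMULATORY),
    (2, "Tumor_antigenicity", Orientation.STIMULATORY),
    (3, "Priming_activation", Orientation.STIMULATORY),
    (4, "Trafficking_infiltration", Orientation.STIMULATORY),
    (5, "Recognition_of_tumor_cells", Orientation.STIMULATORY),
    (6, "Inhibitory_cells", Orientation.INHIBITORY),
    (7, "Checkpoint_expression", Orientation.INHIBITORY),
    (8, "Other_inhibitory_molecules", Orientation.INHIBITORY),
)


def default_axis_catalog() -> dict[int, GeneSet]:
    """Built-in placeholder signatures for the 7 expression axes.

    Small, curation-style marker panels per axis of the cancer-immunity
    cycle. They are a configurable stand-in, not a reproduction of any
    published signature collection; swap in a GMT catalog for real use.
    """
    members = {
        1: ("CD8A", "CD3E", "GZMB", "PRF1", "IFNG"),
        3: ("CD80", "CD86", "CD40", "BATF3", "IL12B"),
        4: ("CXCL9", "CXCL10", "CCL5", "ICAM1", "ITGB2"),
        5: ("HLA-A", "HLA-B", "HLA-C", "B2M", "TAP1", "TAP2"),
        6: ("FOXP3", "IL2RA", "CCR8", "ARG1", "NOS2"),
        7: ("PDCD1", "CD274", "CTLA4", "LAG3", "HAVCR2", "BTLA"),
        8: ("IDO1", "TGFB1", "IL10", "VEGFA", "ADORA2A"),
    }
    catalog: dict[int, GeneSet] = {}
    for idx, name, orientation in DEFAULT_AXES:
        if idx == 2:
            continue
        catalog[idx] = GeneSet(
            name=name, genes=members[idx], orientation=orientation, axis_index=idx
        )
    return catalog


def ssgsea_score(
    expr: pd.DataFrame, gene_set: Sequence[str], *, weight: float = 0.25
) -> pd.Series:
    """Single-sample enrichment score per sample (columns of ``expr``).

    For each sample, genes are ranked by expression (ties broken by gene
    order after sorting the index, making the score invariant to input row
    order). Walking the ranking from top to bottom, the running sum adds
    normalized-rank**weight steps (normalised to 1 overall) on set genes and
    subtracts uniform steps on non-set genes; the score is the sum of the
    running-sum deviations. Higher when set genes rank higher.
    """
    genes_present = [g for g in dict.fromkeys(gene_set) if g in expr.index]
    if len(genes_present) < 2:
        missing = [g for g in gene_set if g not in expr.index]
        raise ValueError(
            f"gene set has {len(genes_present)} member(s) in the matrix "
            f"(>= 2 required); missing: {missing}"
        )
    expr = expr.sort_index(kind="mergesort")
    n = len(expr.index)
    in_set = np.asarray(expr.index.isin(genes_present))
    m = int(in_set.sum())
    scores = {}
    values = expr.to_numpy(dtype=float)
    for j, sample in enumerate(expr.columns):
        # descending expression; mergesort keeps index-order for ties
        order = np.argsort(-values[:, j], kind="mergesort")
        hit = in_set[order]
        # normalized rank from the bottom: top gene has rank n/n = 1
        norm_rank = (n - np.arange(n)) / n
        w = np.where(hit, norm_rank**weight, 0.0)
        p_hit = np.cumsum(w) / w.sum()
        p_miss = np.cumsum(~hit) / (n - m)
        scores[sample] = float(np.sum(p_hit - p_miss))
    return pd.Series(scores, name="es")


def normalized_enrichment(
    expr: pd.DataFrame, gene_set: Sequence[str], *, weight: float = 0.25
) -> pd.Series:
    """Enrichment scores normalised by the cohort score range (NES)."""
    es = ssgsea_score(expr, gene_set, weight=weight)
    spread = es.max() - es.min()
    return es / spread if spread > 0 else es * 0.0


def cohort_z(scores: Sequence[float] | pd.Series, *, population_sd: bool = True) -> np.ndarray:
    """Z-scores across the cohort (population-sd convention by default).

    Constant input yields all-zero z with a warning rather than an error.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("cohort z-score needs >= 2 samples")
    sd = x.std(ddof=0 if population_sd else 1)
    # guard against floating-point noise on effectively constant input
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        warnings.warn("zero dispersion: z-scores set to 0", stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def igs(z: float, orientation: Orientation) -> tuple[float, float]:
    """(raw, display) immunogram score: 3 +/- 1.5*Z, display clamped to [1,5]."""
    orientation = Orientation(orientation)
    raw = 3 + 1.5 * z if orientation is Orientation.STIMULATORY else 3 - 1.5 * z
    return raw, float(np.clip(raw, 1.0, 5.0))


def antigenicity_axis(
    neoantigen_loads: pd.Series, *, log_transform: bool = True, population_sd: bool = True
) -> pd.DataFrame:
    """Tumor-antigenicity axis from per-sample neoantigen loads.

    Loads are log10(x+1)-transformed by default (heavy-tailed counts), then
    z-scored over the cohort and mapped as a stimulatory axis.
    """
    loads = neoantigen_loads.astype(float)
    if (loads < 0).any():
        raise ValueError("neoantigen loads must be non-negative")
    if len(loads) < 2:
        raise ValueError("antigenicity axis needs >= 2 samples")
    x = np.log10(loads + 1) if log_transform else loads
    z = cohort_z(x.to_numpy(), population_sd=population_sd)
    rows = []
    for sample, zi in zip(loads.index, z):
        raw, disp = igs(zi, Orientation.STIMULATORY)
        rows.append({"sample_id": sample, "z": zi, "igs_raw": raw, "igs_display": disp})
    return pd.DataFrame(rows).set_index("sample_id")


def immunogram(
    expr: pd.DataFrame,
    neoantigen_loads: pd.Series,
    catalog: Optional[dict[int, GeneSet]] = None,
    *,
    weight: float = 0.25,
    population_sd: bool = True,
    log_transform_loads: bool = True,
) -> dict[str, list[ImmunogramAxis]]:
    """Full 8-axis immunogram for every sample of the cohort.

    ``expr`` is genes x samples on the log2(TPM+1) scale; ``neoantigen_loads``
    is indexed by the same sample ids. Returns sample id -> 8 axes in axis
    order (1-5 stimulatory, 6-8 inhibitory).
    """
    catalog = default_axis_catalog() if catalog is None else catalog
    samples = list(expr.columns)
    if set(neoantigen_loads.index) < set(samples):
        missing = sorted(set(samples) - set(neoantigen_loads.index))
        raise ValueError(f"neoantigen loads missing for samples: {missing}")

    per_axis: dict[int, pd.DataFrame] = {}
    for idx, name, orientation in DEFAULT_AXES:
        if idx == 2:
            ax = antigenicity_axis(
                neoantigen_loads.loc[samples],
                log_transform=log_transform_loads,
                population_sd=population_sd,
            )
            ax["nes"] = np.log10(neoantigen_loads.loc[samples] + 1)
            per_axis[idx] = ax
            continue
        if idx not in catalog:
            raise ValueError(f"gene-set catalog is missing axis {idx} ({name})")
        nes = normalized_enrichment(expr, catalog[idx].genes, weight=weight)
        z = cohort_z(nes.loc[samples].to_numpy(), population_sd=population_sd)
        rows = []
        for sample, zi in zip(samples, z):
            raw, disp = igs(zi, orientation)
            rows.append(
                {"sample_id": sample, "z": zi, "igs_raw": raw, "igs_display": disp,
                 "nes": float(nes.loc[sample])}
            )
        per_axis[idx] = pd.DataFrame(rows).set_index("sample_id")

    out: dict[str, list[ImmunogramAxis]] = {}
    for sample in samples:
        axes = []
        for idx, name, orientation in DEFAULT_AXES:
            row = per_axis[idx].loc[sample]
            axes.append(
                ImmunogramAxis(
                    axis_name=name,
                    axis_index=idx,
                    orientation=orientation,
                    nes=float(row["nes"]),
                    z=float(row["z"]),
                    igs_raw=float(row["igs_raw"]),
                    igs_display=float(row["igs_display"]),
                )
            )
        out[str(sample)] = axes
    return out


class TMITLabel(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


def tmit_classify(cd8a: pd.Series, pdl1: pd.Series) -> pd.Series:
    """Tumor-microenvironment immune type from CD8A and PD-L1 expression.

    High/low is split at the cohort median per marker (ties -> low):
    I = high PD-L1 & high CD8A (inflamed), II = low/low,
    III = high PD-L1 & low CD8A, IV = low PD-L1 & high CD8A.
    """
    if cd8a.isna().any() or pdl1.isna().any():
        raise ValueError("CD8A/PD-L1 expression must be present for all samples")
    if not cd8a.index.equals(pdl1.index):
        raise ValueError("CD8A and PD-L1 series must share the same sample index")
    cd8_high = cd8a > cd8a.median()
    pd_high = pdl1 > pdl1.median()
    labels = np.where(
        pd_high & cd8_high, TMITLabel.I.value,
        np.where(
            ~pd_high & ~cd8_high, TMITLabel.II.value,
            np.where(pd_high & ~cd8_high, TMITLabel.III.value, TMITLabel.IV.value),
        ),
    )
    return pd.Series(labels, index=cd8a.index, name="tmit")


def cell_ratios(
    fractions: pd.DataFrame,
    *,
    treg_col: str = "Tregs",
    cd8_col: str = "T_cells_CD8",
    m1_col: str = "Macrophages_M1",
    m2_col: str = "Macrophages_M2",
    eps: float = 1e-3,
) -> pd.DataFrame:
    """Per-sample Treg/CD8 and M2/M1 ratios with a pseudocount.

    Deconvolved fractions contain exact zeros, so ``eps`` is added to both
    numerator and denominator to keep every ratio finite.
    """
    needed = [treg_col, cd8_col, m1_col, m2_col]
    missing = [c for c in needed if c not in fractions.columns]
    if missing:
        raise ValueError(f"cell-fraction table missing columns: {missing}")
    return pd.DataFrame(
        {
            "treg_cd8_ratio": (fractions[treg_col] + eps) / (fractions[cd8_col] + eps),
            "m2_m1_ratio": (fractions[m2_col] + eps) / (fractions[m1_col] + eps),
        },
        index=fractions.index,
    )
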