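"""Readers and writers for the pipeline's table dialects.

All user-facing tables are TSV with 1-based inclusive genomic coordinates
(SEG segments are written 1-based and converted to half-open 0-based
internally). Every reader validates its required columns and raises a
``SchemaError`` naming the file and the offending column or line; every
reader/writer pair round-trips through :func:`canonical_variants` (etc.)
identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .immunogram import GeneSet, Orientation
from .neoantigens import VALID_PEPTIDE_LENGTHS, Neoepitope

__all__ = [
    "SchemaError",
    "read_variants", "write_variants", "canonical_variants",
    "read_vcf_variants",
    "read_segments", "write_segments",
    "read_epitopes", "write_epitopes", "epitopes_to_objects",
    "read_expression", "write_expression",
    "read_gmt", "write_gmt",
    "read_cell_fractions", "write_cell_fractions",
    "read_clonotypes", "write_clonotypes",
    "write_radar_json",
]


class SchemaError(ValueError):
    """An input table violates its declared dialect."""


VARIANT_COLUMNS = [
    "sample_id", "patient_id", "site", "variant_id", "gene", "variant_class",
    "chrom", "pos", "ref", "alt",
    "tumor_alt_reads", "tumor_ref_reads", "normal_alt_reads", "normal_ref_reads",
    "vaf", "in_copy_loss", "expressed", "fpkm", "ccf_point", "ccf_lo", "ccf_hi",
]
VARIANT_BOOL_COLUMNS = ["in_copy_loss", "expressed"]
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "total_cn", "loh"]
EPITOPE_COLUMNS = [
    "patient_id", "sample_id", "variant_id", "peptide", "hla_allele",
    "netmhc", "netmhcpan", "pickpocket", "stability_halflife", "fpkm",
]
CLONOTYPE_COLUMNS = ["sample_id", "chain", "cdr3", "count"]


def _require(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


# -- somatic variants (MAF-like TSV) ----------------------------------------

def canonical_variants(df: pd.DataFrame) -> pd.DataFrame:
    """Canonical column order, row order and dtypes for comparison."""
    out = df.copy()
    extra = [c for c in out.columns if c not in VARIANT_COLUMNS]
    out = out[VARIANT_COLUMNS + extra]
    for col in VARIANT_BOOL_COLUMNS + [c for c in extra if out[c].dtype == bool]:
        out[col] = out[col].astype(bool)
    for col in ("pos", "tumor_alt_reads", "tumor_ref_reads",
                "normal_alt_reads", "normal_ref_reads"):
        out[col] = out[col].astype(np.int64)
    out["chrom"] = out["chrom"].astype(str)
    return out.sort_values(["sample_id", "variant_id"], kind="mergesort").reset_index(
        drop=True
    )


def write_variants(df: pd.DataFrame, path) -> None:
    canonical_variants(df).to_csv(path, sep="\t", index=False)


def read_variants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require(df, VARIANT_COLUMNS, path)
    for col in VARIANT_BOOL_COLUMNS:
        if df[col].dtype != bool:
            df[col] = df[col].map({"True": True, "False": False, True: True, False: False})
            if df[col].isna().any():
                raise SchemaError(f"{path}: column {col} is not boolean")
    bad = df["ccf_lo"] > df["ccf_hi"]
    if bad.any():
        raise SchemaError(
            f"{path}: line {int(df.index[bad][0]) + 2}: ccf_lo > ccf_hi"
        )
    return canonical_variants(df)


def read_vcf_variants(
    path,
    *,
    tumor_sample: str = "TUMOR",
    normal_sample: str = "NORMAL",
) -> pd.DataFrame:
    """Minimal VCF reader mapping CHROM/POS/REF/ALT + per-sample AD fields.

    AD follows the VCF convention: allelic depths for the REF allele first,
    then each ALT allele, so ``AD=20,80`` maps to 20 ref / 80 alt reads.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for name in (tumor_sample, normal_sample):
            if name not in vcf.header.samples:
                raise SchemaError(f"{path}: sample {name!r} absent from VCF header")
        for rec in vcf.fetch() if vcf.index else vcf:
            if rec.alts is None:
                continue
            t_ad = rec.samples[tumor_sample].get("AD")
            n_ad = rec.samples[normal_sample].get("AD")
            if t_ad is None or n_ad is None:
                raise SchemaError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks an AD field"
                )
            rows.append(
                {
                    "chrom": str(rec.chrom).removeprefix("chr"),
                    "pos": int(rec.pos),
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "tumor_ref_reads": int(t_ad[0]),
                    "tumor_alt_reads": int(t_ad[1]),
                    "normal_ref_reads": int(n_ad[0]),
                    "normal_alt_reads": int(n_ad[1]),
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        depth = df["tumor_alt_reads"] + df["tumor_ref_reads"]
        df["vaf"] = np.where(depth > 0, df["tumor_alt_reads"] / depth, 0.0)
    return df


# -- copy-number segments (SEG-like TSV) -------------------------------------

def write_segments(df: pd.DataFrame, path) -> None:
    out = df[SEGMENT_COLUMNS].copy()
    out["start"] = out["start"].astype(np.int64) + 1  # 1-based inclusive on disk
    out.to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require(df, SEGMENT_COLUMNS, path)
    df["start"] = df["start"].astype(np.int64) - 1  # back to half-open 0-based
    if (df["end"] <= df["start"]).any():
        raise SchemaError(f"{path}: segment with end <= start")
    if df["loh"].dtype != bool:
        df["loh"] = df["loh"].map({"True": True, "False": False, True: True, False: False})
    return df


# -- neoepitope tables (pVACseq-style TSV) -----------------------------------

def write_epitopes(df: pd.DataFrame, path) -> None:
    df[EPITOPE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_epitopes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, EPITOPE_COLUMNS, path)
    lengths = df["peptide"].astype(str).str.len()
    bad = ~lengths.isin(VALID_PEPTIDE_LENGTHS)
    if bad.any():
        i = int(df.index[bad][0])
        raise SchemaError(
            f"{path}: line {i + 2}, column 'peptide': "
            f"{df['peptide'].iloc[i]!r} is a {lengths.iloc[i]}-mer; "
            "only 9- and 10-mers are accepted"
        )
    for col in ("netmhc", "netmhcpan", "pickpocket"):
        if (df[col] <= 0).any():
            i = int(df.index[df[col] <= 0][0])
            raise SchemaError(
                f"{path}: line {i + 2}, column {col!r}: non-positive affinity"
            )
    return df


def epitopes_to_objects(df: pd.DataFrame) -> list[Neoepitope]:
    predictors = ["netmhc", "netmhcpan", "pickpocket"]
    out = []
    for rec in df.itertuples():
        stab = getattr(rec, "stability_halflife", None)
        out.append(
            Neoepitope(
                variant_id=str(rec.variant_id),
                peptide=str(rec.peptide),
                hla_allele=str(rec.hla_allele),
                predictor_affinities={p: float(getattr(rec, p)) for p in predictors},
                stability_halflife=None if stab is None or pd.isna(stab) else float(stab),
                fpkm=float(rec.fpkm),
                sample_id=str(getattr(rec, "sample_id", "")),
                patient_id=str(getattr(rec, "patient_id", "")),
            )
        )
    return out


# -- expression matrices ------------------------------------------------------

def write_expression(expr: pd.DataFrame, path) -> None:
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate gene identifier {dup!r}")
    # imputation policy: drop genes with any missing value
    df = df.dropna(axis=0, how="any")
    df.index.name = "gene"
    return df


# -- GMT gene sets ------------------------------------------------------------

def read_gmt(path, *, orientations: Optional[dict[str, str]] = None,
             axis_indices: Optional[dict[str, int]] = None) -> dict[str, GeneSet]:
    """GMT reader: name <tab> description <tab> gene1 <tab> gene2 ...

    ``orientations``/``axis_indices`` map set names to immunogram metadata;
    unmapped sets default to STIMULATORY / axis 1.
    """
    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:  # name + description + >= 2 genes
            raise SchemaError(
                f"{path}: line {lineno}: gene set {parts[0]!r} has "
                f"{max(len(parts) - 2, 0)} gene(s); >= 2 required"
            )
        name = parts[0]
        genes = tuple(dict.fromkeys(g for g in parts[2:] if g))
        if len(genes) < 2:
            raise SchemaError(
                f"{path}: line {lineno}: gene set {name!r} has < 2 distinct genes"
            )
        sets[name] = GeneSet(
            name=name,
            genes=genes,
            orientation=Orientation((orientations or {}).get(name, "STIMULATORY")),
            axis_index=(axis_indices or {}).get(name, 1),
        )
    return sets


def write_gmt(sets: dict[str, GeneSet], path) -> None:
    lines = [
        "\t".join([gs.name, gs.orientation.value, *gs.genes]) for gs in sets.values()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- immune-cell fractions ----------------------------------------------------

def write_cell_fractions(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_cell_fractions(path, *, tolerance: float = 1e-6) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    sums = df.sum(axis=1)
    bad = (sums - 1).abs() > tolerance
    if bad.any():
        sample = df.index[bad][0]
        raise SchemaError(
            f"{path}: cell fractions of sample {sample!r} sum to "
            f"{sums[bad].iloc[0]:.8f}, not 1"
        )
    return df


# -- TCR clonotypes -----------------------------------------------------------

def write_clonotypes(df: pd.DataFrame, path) -> None:
    df[CLONOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clonotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, CLONOTYPE_COLUMNS, path)
    if (df["count"] < 0).any():
        raise SchemaError(f"{path}: negative clonotype count")
    return df


# -- cohort directories -------------------------------------------------------

def load_cohort_dir(in_dir):
    """Load a cohort directory (as written by `neoscape simulate`) into a
    bundle plus the per-patient truth subtype labels, if present."""
    from .config import SyntheticCohortConfig
    from .synthetic import CohortBundle

    d = Path(in_dir)
    samples = pd.read_csv(d / "samples.tsv", sep="\t")
    bundle = CohortBundle(
        samples=samples,
        variants=read_variants(d / "variants.tsv"),
        epitopes=read_epitopes(d / "epitopes.tsv"),
        expression=read_expression(d / "expression.tsv"),
        segments=read_segments(d / "segments.tsv"),
        cell_fractions=read_cell_fractions(d / "cell_fractions.tsv"),
        clonotypes=read_clonotypes(d / "clonotypes.tsv"),
        config=SyntheticCohortConfig(),
    )
    labels = None
    if (d / "true_subtypes.tsv").exists():
        lab = pd.read_csv(d / "true_subtypes.tsv", sep="\t")
        labels = lab.set_index("patient_id")["subtype"]
    return bundle, labels


# -- radar export -------------------------------------------------------------

def write_radar_json(radar: dict[str, list], path) -> None:
    """sample id -> {axis name: display IGS} plus raw values, as JSON."""
    payload = {
        sample: {
            "igs": {ax.axis_name: round(ax.igs_display, 6) for ax in axes},
            "igs_raw": {ax.axis_name: round(ax.igs_raw, 6) for ax in axes},
            "z": {ax.axis_name: round(ax.z, 6) for ax in axes},
        }
        for sample, axes in radar.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
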