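"""End-to-end orchestration of the downstream neoantigen-landscape analysis.

Stages: variant QC -> clonality -> neoantigen calling -> variant-level
neoantigenic annotation -> per-sample depletion odds ratios -> paired
primary/metastasis fate tracking and reduction ratios -> immunogenicity
bias -> heterogeneity/instability indices (MATH, wGII, multiregion branch
proportions) -> immunogram -> TMIT and cell ratios -> subtype calls.

Outputs are written as TSV/JSON with a run manifest; identical inputs,
config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as nio
from .config import PipelineConfig
from .depletion import (
    cohort_depletion_summary,
    depletion_call,
    immunogenicity_bias_or,
)
from .immunogram import cell_ratios, immunogram, tmit_classify
from .neoantigens import (
    branch_proportion,
    call_neoantigens,
    neoantigens_to_frame,
    sharing_stats,
    tcr_clonal_proportion,
)
from .subtypes import predict_subtype, train_subtype_model
from .synthetic import CohortBundle
from .variants import (
    CopyNumberSegment,
    classify_clonality,
    math_score,
    qc_filter_table,
    reduction_ratio,
    track_variants,
    wgii,
)

__all__ = ["PipelineResult", "run_pipeline", "write_outputs"]

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]


@dataclass
class PipelineResult:
    variants_qc: pd.DataFrame
    neoantigens: pd.DataFrame
    depletion_calls: pd.DataFrame
    depletion_summary: pd.DataFrame
    tracking: pd.DataFrame
    reduction: pd.DataFrame
    bias: pd.DataFrame
    heterogeneity: pd.DataFrame
    ith: pd.DataFrame
    sharing: dict
    radar: dict
    tmit_ratios: pd.DataFrame
    subtype_calls: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _variant_keys(df: pd.DataFrame) -> pd.Series:
    return pd.Series(
        list(zip(df["chrom"], df["pos"], df["ref"], df["alt"])), index=df.index
    )


def _clonality_map(df: pd.DataFrame) -> dict:
    return dict(zip(_variant_keys(df), df["clonality"]))


def run_pipeline(
    bundle: CohortBundle,
    config: Optional[PipelineConfig] = None,
    subtype_labels: Optional[pd.Series] = None,
) -> PipelineResult:
    """Run every stage on an in-memory cohort bundle.

    ``subtype_labels`` (patient -> I/II/III) enables the subtype stage; the
    trained model then predicts each patient from their primary-region
    expression with the probability gate.
    """
    cfg = config or PipelineConfig()
    variants = bundle.variants.copy()
    sites = dict(zip(bundle.samples["sample_id"], bundle.samples["site"]))

    # 1. QC filter
    variants["qc_keep"] = qc_filter_table(
        variants, min_alt_reads=cfg.min_alt_reads, alpha=cfg.alpha
    )
    vq = variants[variants["qc_keep"]].copy()

    # 2. clonality from the CCF interval
    vq["clonality"] = [
        classify_clonality(lo, hi).value
        for lo, hi in zip(vq["ccf_lo"], vq["ccf_hi"])
    ]

    # 3. neoantigen calling per sample (epitopes of QC-passed variants only)
    neo_frames = []
    for sample_id, grp in bundle.epitopes.groupby("sample_id", sort=True):
        sample_variants = vq[vq["sample_id"] == sample_id]
        grp = grp[grp["variant_id"].isin(sample_variants["variant_id"])]
        if not len(grp):
            continue
        clonality = dict(
            zip(sample_variants["variant_id"], sample_variants["clonality"])
        )
        called = call_neoantigens(
            nio.epitopes_to_objects(grp),
            affinity_gate=cfg.affinity_gate_nm,
            fpkm_gate=cfg.fpkm_gate,
            strong_cut=cfg.strong_affinity_nm,
            medium_cut=cfg.medium_affinity_nm,
            stability_cut=cfg.stability_cut_h,
            clonality_by_variant=clonality,
        )
        neo_frames.append(neoantigens_to_frame(called))
    neoantigens = (
        pd.concat(neo_frames, ignore_index=True)
        if neo_frames
        else neoantigens_to_frame([])
    )

    # 4. observed variant-level neoantigenic flag
    neo_by_sample = neoantigens.groupby("sample_id")["variant_id"].agg(set)
    vq["neoantigenic"] = [
        vid in neo_by_sample.get(sid, set())
        for sid, vid in zip(vq["sample_id"], vq["variant_id"])
    ]

    # immunogenic flag per (sample, variant): any called neoantigen with
    # strong/medium affinity or high stability
    imm = neoantigens.assign(
        immunogenic=(neoantigens["best_affinity"] < cfg.medium_affinity_nm)
        | (neoantigens["stability_class"] == "HIGH")
    )
    imm_by_sample = imm.groupby("sample_id").apply(
        lambda g: set(g.loc[g["immunogenic"], "variant_id"]), include_groups=False
    ) if len(imm) else pd.Series(dtype=object)

    # 5. depletion odds ratios per sample
    dep_calls, dep_rows = [], []
    for sample_id, grp in vq.groupby("sample_id", sort=True):
        call = depletion_call(
            grp, sample_id,
            significance_gate=cfg.depletion_significance_gate,
            alpha=cfg.alpha,
        )
        dep_calls.append(call)
        dep_rows.append(
            {
                "sample_id": sample_id,
                "site": sites.get(sample_id, ""),
                "cnv_or": call.cnv_loss_or.odds_ratio if call.cnv_loss_or else np.nan,
                "cnv_ci_lo": call.cnv_loss_or.ci95[0] if call.cnv_loss_or else np.nan,
                "cnv_ci_hi": call.cnv_loss_or.ci95[1] if call.cnv_loss_or else np.nan,
                "cnv_p": call.cnv_loss_or.p_fisher if call.cnv_loss_or else np.nan,
                "cnv_status": call.cnv_status.value,
                "txn_or": call.txn_or.odds_ratio if call.txn_or else np.nan,
                "txn_ci_lo": call.txn_or.ci95[0] if call.txn_or else np.nan,
                "txn_ci_hi": call.txn_or.ci95[1] if call.txn_or else np.nan,
                "txn_p": call.txn_or.p_fisher if call.txn_or else np.nan,
                "txn_status": call.txn_status.value,
            }
        )
    depletion_calls = pd.DataFrame(dep_rows)
    depletion_summary = (
        cohort_depletion_summary(dep_calls, sites) if dep_calls else pd.DataFrame()
    )

    # 6. paired tracking, reduction ratio, immunogenicity bias
    track_rows, red_rows, bias_rows = [], [], []
    for patient, pgrp in vq.groupby("patient_id", sort=True):
        primaries = sorted(
            pgrp.loc[pgrp["site"] == "PRIMARY", "sample_id"].unique()
        )
        mets = sorted(pgrp.loc[pgrp["site"] != "PRIMARY", "sample_id"].unique())
        if not primaries or not mets:
            continue
        ref = primaries[0]
        pvar = pgrp[(pgrp["sample_id"] == ref) & pgrp["neoantigenic"]]
        pmap = _clonality_map(pvar)
        p_imm_vids = imm_by_sample.get(ref, set())
        imm_key_p = dict(zip(_variant_keys(pvar),
                             pvar["variant_id"].isin(p_imm_vids)))
        for met in mets:
            mvar = pgrp[(pgrp["sample_id"] == met) & pgrp["neoantigenic"]]
            mmap = _clonality_map(mvar)
            m_imm_vids = imm_by_sample.get(met, set())
            imm_key_m = dict(zip(_variant_keys(mvar),
                                 mvar["variant_id"].isin(m_imm_vids)))
            groups = track_variants(pmap, mmap)
            pair_id = f"{ref}|{met}"
            for key, grp_label in sorted(groups.items(), key=lambda kv: str(kv[0])):
                track_rows.append(
                    {
                        "pair_id": pair_id, "patient_id": patient,
                        "chrom": key[0], "pos": key[1], "ref": key[2],
                        "alt": key[3], "group": grp_label.value,
                    }
                )
            primary_load = len(pmap)
            if primary_load > 0:
                summary = reduction_ratio(groups, primary_load, pair_id)
                red_rows.append(
                    {
                        "pair_id": pair_id, "patient_id": patient,
                        "met_site": sites.get(met, ""),
                        "n_reduced": summary.n_reduced,
                        "n_increased": summary.n_increased,
                        "n_persistent": summary.n_persistent,
                        "primary_load": summary.primary_load,
                        "reduction_ratio": summary.reduction_ratio,
                        "reduction_flag": summary.reduction_flag,
                    }
                )
            reduced = [
                imm_key_p.get(k, imm_key_m.get(k, False))
                for k, g in groups.items() if g.value == "REDUCED"
            ]
            increased = [
                imm_key_m.get(k, imm_key_p.get(k, False))
                for k, g in groups.items() if g.value == "INCREASED"
            ]
            if reduced and increased:
                res = immunogenicity_bias_or(reduced, increased)
                bias_rows.append(
                    {
                        "pair_id": pair_id,
                        "bias_or": res.odds_ratio,
                        "ci_lo": res.ci95[0], "ci_hi": res.ci95[1],
                        "p": res.p_fisher,
                        "corrected": res.continuity_corrected,
                        "n_reduced": len(reduced), "n_increased": len(increased),
                    }
                )
    tracking = pd.DataFrame(track_rows)
    reduction = pd.DataFrame(red_rows)
    bias = pd.DataFrame(bias_rows)

    # 7. MATH + wGII per sample
    het_rows = []
    seg_by_sample = dict(tuple(bundle.segments.groupby("sample_id")))
    ploidies = dict(zip(bundle.samples["sample_id"], bundle.samples["ploidy"]))
    for sample_id, grp in vq.groupby("sample_id", sort=True):
        vafs = grp["vaf"].to_numpy()
        score = (
            math_score(vafs) if len(vafs) >= 3 and np.median(vafs) > 0 else np.nan
        )
        segs = seg_by_sample.get(sample_id)
        if segs is not None:
            objs = [
                CopyNumberSegment(str(r.chrom), int(r.start), int(r.end),
                                  int(r.total_cn), bool(r.loh))
                for r in segs.itertuples()
            ]
            w, cin = wgii(objs, ploidies.get(sample_id, 2.0), cin_cut=cfg.cin_wgii_cut)
        else:
            w, cin = np.nan, False
        het_rows.append(
            {
                "sample_id": sample_id, "site": sites.get(sample_id, ""),
                "math": score, "wgii": w, "cin_positive": cin,
                "n_variants": len(grp),
                "neoantigen_load": int(
                    (neoantigens["sample_id"] == sample_id).sum()
                ),
            }
        )
    heterogeneity = pd.DataFrame(het_rows)

    # 8. multiregion ITH (neoantigen keys and TCR clonotypes)
    ith_rows = []
    neo_keys_by_sample = {
        sid: set(zip(g["peptide"], g["hla_allele"]))
        for sid, g in neoantigens.groupby("sample_id")
    }
    tcr_by_sample = dict(tuple(bundle.clonotypes.groupby("sample_id")))
    for patient, pgrp in bundle.samples.groupby("patient_id", sort=True):
        regions = sorted(
            pgrp.loc[pgrp["site"] == "PRIMARY", "sample_id"].unique()
        )
        if len(regions) < 2:
            continue
        neo_sets = [neo_keys_by_sample.get(r, set()) for r in regions]
        row = {"patient_id": patient, "n_regions": len(regions)}
        try:
            row["neoantigen_ith"] = branch_proportion(neo_sets)
        except ValueError:
            row["neoantigen_ith"] = np.nan
        tcr_sets = [
            set(tcr_by_sample[r]["cdr3"]) if r in tcr_by_sample else set()
            for r in regions
        ]
        try:
            row["tcr_ith"] = branch_proportion(tcr_sets)
        except ValueError:
            row["tcr_ith"] = np.nan
        ith_rows.append(row)
    ith = pd.DataFrame(ith_rows)

    # cohort sharing statistics
    share_frac, cross = sharing_stats(
        (r.patient_id, r.sample_id, (r.peptide, r.hla_allele))
        for r in neoantigens.itertuples()
    )
    sharing = {
        "within_patient_shared_fraction": share_frac,
        "n_cross_patient_shared": len(cross),
        "total_neoantigen_instances": int(len(neoantigens)),
    }

    # 9. immunogram
    loads = heterogeneity.set_index("sample_id")["neoantigen_load"].astype(float)
    loads = loads.reindex(bundle.expression.columns).fillna(0.0)
    radar = immunogram(
        bundle.expression, loads,
        population_sd=cfg.zscore_population_sd,
        log_transform_loads=cfg.log_transform_neoantigen_load,
    )

    # 10. TMIT + cell ratios + clonal TCR proportions
    tmit = tmit_classify(
        bundle.expression.loc["CD8A"], bundle.expression.loc["CD274"]
    )
    ratios = cell_ratios(bundle.cell_fractions)
    tmit_ratios = ratios.join(tmit).reset_index().rename(columns={"index": "sample_id"})
    tcr_rows = []
    for sample_id, grp in bundle.clonotypes.groupby("sample_id", sort=True):
        props = tcr_clonal_proportion(
            grp, frequency_threshold=cfg.tcr_clonal_frequency
        )
        tcr_rows.append({"sample_id": sample_id, **{
            f"clonal_tcr_{chain}": p for chain, p in props.items()}})
    tmit_ratios = tmit_ratios.merge(
        pd.DataFrame(tcr_rows), on="sample_id", how="left"
    )

    # 11. subtype model (requires training labels)
    subtype_calls = pd.DataFrame(
        columns=["patient_id", "label", "p_I", "p_II", "p_III", "regions"]
    )
    if subtype_labels is not None:
        try:
            subtype_calls = _subtype_stage(bundle, cfg, subtype_labels)
        except ValueError as exc:
            # small or unbalanced cohorts can defeat signature extraction;
            # the rest of the report is still valid
            logging.getLogger(__name__).warning("subtype stage skipped: %s", exc)
    manifest = {
        "config": json.loads(cfg.model_dump_json()),
        "config_hash": hashlib.sha256(
            cfg.model_dump_json().encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "n_samples": int(len(bundle.samples)),
        "n_patients": int(bundle.samples["patient_id"].nunique()),
    }
    return PipelineResult(
        variants_qc=vq.reset_index(drop=True),
        neoantigens=neoantigens,
        depletion_calls=depletion_calls,
        depletion_summary=depletion_summary,
        tracking=tracking,
        reduction=reduction,
        bias=bias,
        heterogeneity=heterogeneity,
        ith=ith,
        sharing=sharing,
        radar=radar,
        tmit_ratios=tmit_ratios,
        subtype_calls=subtype_calls,
        manifest=manifest,
    )


def _subtype_stage(
    bundle: CohortBundle, cfg: PipelineConfig, subtype_labels: pd.Series
) -> pd.DataFrame:
    """Train on the per-patient reference primary sample, predict every
    patient from all their primary regions (multiregion mean probability)."""
    primary_samples = bundle.samples[bundle.samples["site"] == "PRIMARY"]
    ref_samples = primary_samples.groupby("patient_id")["sample_id"].min()
    expr_primary = bundle.expression[ref_samples.to_numpy()]
    labels = pd.Series(
        subtype_labels.loc[ref_samples.index].to_numpy(),
        index=ref_samples.to_numpy(),
    )
    model = train_subtype_model(
        expr_primary, labels,
        train_fraction=cfg.train_fraction,
        iterations=cfg.resampling_iterations,
        seed=cfg.seed,
        probability_gate=cfg.probability_gate,
    )
    rows = []
    for patient, grp in primary_samples.groupby("patient_id", sort=True):
        regions = bundle.expression[sorted(grp["sample_id"])]
        call = predict_subtype(model, regions, patient)
        rows.append(
            {
                "patient_id": patient, "label": call.label,
                "p_I": call.mean_probabilities.get("I", np.nan),
                "p_II": call.mean_probabilities.get("II", np.nan),
                "p_III": call.mean_probabilities.get("III", np.nan),
                "regions": ",".join(call.contributing_regions),
            }
        )
    calls = pd.DataFrame(rows)
    calls.attrs["validation_accuracy"] = model.validation_accuracy
    return calls


def write_outputs(result: PipelineResult, outdir) -> list[Path]:
    """Write every report table; on failure, partial outputs are removed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        tables = {
            "neoantigens.tsv": result.neoantigens,
            "depletion_calls.tsv": result.depletion_calls,
            "depletion_summary.tsv": result.depletion_summary,
            "tracking.tsv": result.tracking,
            "reduction.tsv": result.reduction,
            "immunogenicity_bias.tsv": result.bias,
            "heterogeneity.tsv": result.heterogeneity,
            "ith.tsv": result.ith,
            "tmit_ratios.tsv": result.tmit_ratios,
            "subtype_calls.tsv": result.subtype_calls,
        }
        for name, df in tables.items():
            path = outdir / name
            df.to_csv(path, sep="\t", index=False)
            written.append(path)
        radar_path = outdir / "immunogram_radar.json"
        nio.write_radar_json(result.radar, radar_path)
        written.append(radar_path)
        for name, payload in (
            ("sharing.json", result.sharing),
            ("manifest.json", result.manifest),
        ):
            path = outdir / name
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
            written.append(path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return written
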