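"""Seed-deterministic synthetic metastatic-tumor cohort generator.

Generates every input table the downstream analyses consume — somatic
variants with read counts and CCF intervals, neoepitope tables, an
expression matrix with planted 3-subtype structure, copy-number segments,
immune-cell fractions and TCR clonotypes — for a cohort of patients with
paired primary / regional-lymph-node / distant-metastasis samples, plus a
ground-truth record for parameter-recovery tests.

Planted effects:

- ``theta_cnv`` / ``theta_txn``: odds multipliers with which neoantigenic
  nonsynonymous mutations sit in copy-loss regions / remain expressed.
  They are exactly the population odds ratios the depletion statistics
  estimate (theta = 1 plants the null).
- ``beta_reduction``: in metastatic samples, the drop-out odds of
  immunogenic neoantigens (strong/medium affinity or high stability) are
  multiplied by ``1 + beta_reduction``; 0 makes fates exchangeable.
- ``subtype_effect``: mean shift (in residual-sd units) on each class's
  signature genes.

Identical config + seed reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import SyntheticCohortConfig
from .variants import AUTOSOME_LENGTHS

__all__ = [
    "CohortBundle",
    "GroundTruth",
    "simulate_cohort",
    "ground_truth_report",
    "simulate_depletion_sample",
    "simulate_tracking_pair",
    "simulate_expression_cohort",
    "default_site_layout",
]

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
HLA_POOL = [
    "HLA-A*02:01", "HLA-A*11:01", "HLA-A*24:02", "HLA-A*33:03",
    "HLA-B*13:01", "HLA-B*40:01", "HLA-B*46:01", "HLA-B*58:01",
    "HLA-C*01:02", "HLA-C*03:04", "HLA-C*07:02", "HLA-C*08:01",
]
PREDICTORS = ("netmhc", "netmhcpan", "pickpocket")
NORMAL_ERROR_RATE = 0.002
SUBTYPES = ("I", "II", "III")


def default_site_layout(n_patients: int) -> dict[str, list[str]]:
    """Built-in site map: every patient a primary, ~62% with a lymph-node
    and ~46% with a distant metastasis, three patients with a second
    primary region (multiregion). At 26 patients this yields the study-like
    29 primary / 16 lymph / 12 distant layout."""
    layout: dict[str, list[str]] = {}
    n_lymph = round(16 / 26 * n_patients)
    n_distant = round(12 / 26 * n_patients)
    multiregion = {i for i in (13, 14, 19) if i < n_patients}  # 0-based
    for i in range(n_patients):
        pid = f"P{i + 1:02d}"
        sites = ["PRIMARY:1"]
        if i in multiregion:
            sites.append("PRIMARY:2")
        if i < n_lymph:
            sites.append("LYMPH:1")
        if 4 <= i < 4 + n_distant:
            sites.append("DISTANT:1")
        layout[pid] = sites
    return layout


@dataclass
class CohortBundle:
    """All synthetic input tables of one cohort."""

    samples: pd.DataFrame        # sample_id, patient_id, site, region, purity, ploidy
    variants: pd.DataFrame       # per-sample somatic variant table
    epitopes: pd.DataFrame       # per-sample neoepitope predictions
    expression: pd.DataFrame     # genes x samples, log2(TPM+1)-like
    segments: pd.DataFrame       # SEG-like copy-number table
    cell_fractions: pd.DataFrame # samples x cell types
    clonotypes: pd.DataFrame     # sample_id, chain, cdr3, count
    config: SyntheticCohortConfig


@dataclass
class GroundTruth:
    """Planted values for recovery tests; one record per simulated entity."""

    theta_cnv: float
    theta_txn: float
    beta_reduction: float
    subtypes: pd.Series                     # patient -> I/II/III
    pair_truth: pd.DataFrame                # per-pair, per-variant true fate
    region_neoantigen_sets: dict[str, frozenset] = field(default_factory=dict)
    sample_true_or: pd.DataFrame = field(default_factory=pd.DataFrame)


def _random_peptides(rng: np.random.Generator, n: int) -> list[str]:
    lengths = rng.choice([9, 10], size=n)
    return ["".join(rng.choice(AA, size=int(l))) for l in lengths]


def _odds_prob(base_p: float, multiplier: float) -> float:
    odds = base_p / (1 - base_p) * multiplier
    return odds / (1 + odds)


def _lognormal_below(rng: np.random.Generator, mu: float, sigma: float,
                     bound: float, size: int) -> np.ndarray:
    """Lognormal draws conditioned below ``bound`` (rejection sampling)."""
    out = rng.lognormal(mu, sigma, size=size)
    bad = out >= bound
    while bad.any():
        out[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
        bad = out >= bound
    return out


def _lognormal_above(rng: np.random.Generator, mu: float, sigma: float,
                     bound: float, size: int) -> np.ndarray:
    out = rng.lognormal(mu, sigma, size=size)
    bad = out <= bound
    while bad.any():
        out[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
        bad = out <= bound
    return out


def _trunk_mutations(
    cfg: SyntheticCohortConfig, rng: np.random.Generator, patient: str,
    hla: list[str], start_index: int, n_mut: int,
) -> pd.DataFrame:
    """Patient-level mutation attributes shared by all of their samples."""
    chroms = list(AUTOSOME_LENGTHS)
    lengths = np.array([AUTOSOME_LENGTHS[c] for c in chroms], dtype=float)
    probs = [
        cfg.missense_fraction,
        cfg.frameshift_fraction,
        cfg.other_nonsilent_fraction,
    ]
    probs.append(max(0.0, 1 - sum(probs)))
    classes = rng.choice(
        ["MISSENSE", "FRAMESHIFT_INDEL", "OTHER_NONSILENT", "SILENT"],
        size=n_mut, p=np.array(probs) / np.sum(probs),
    )
    chrom_idx = rng.choice(len(chroms), size=n_mut, p=lengths / lengths.sum())
    pos = (rng.random(n_mut) * (lengths[chrom_idx] - 1)).astype(np.int64) + 1
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=n_mut)
    alt = rng.choice(bases, size=n_mut)
    same = alt == ref
    while same.any():
        alt[same] = rng.choice(bases, size=int(same.sum()))
        same = alt == ref
    nonsilent = classes != "SILENT"
    neo = nonsilent & (rng.random(n_mut) < cfg.neoantigenic_fraction)

    p_loss_neo = _odds_prob(cfg.p_copy_loss_base, cfg.theta_cnv)
    p_expr_neo = _odds_prob(cfg.p_expressed_base, cfg.theta_txn)
    in_loss = rng.random(n_mut) < np.where(neo, p_loss_neo, cfg.p_copy_loss_base)
    expressed = rng.random(n_mut) < np.where(neo, p_expr_neo, cfg.p_expressed_base)

    clonal = rng.random(n_mut) < cfg.p_clonal
    ccf = np.where(clonal, 1.0, rng.uniform(0.15, 0.85, size=n_mut))

    mu_f, sg_f = cfg.fpkm_lognorm_params
    fpkm = rng.lognormal(mu_f, sg_f, size=n_mut)
    fpkm[neo] = _lognormal_above(rng, mu_f, sg_f, 1.0, int(neo.sum()))

    return pd.DataFrame(
        {
            "variant_id": [f"{patient}_v{start_index + i:05d}" for i in range(n_mut)],
            "gene": [f"GENE_{rng.integers(0, 2000):04d}" for _ in range(n_mut)],
            "variant_class": classes,
            "chrom": [chroms[i] for i in chrom_idx],
            "pos": pos,
            "ref": ref,
            "alt": ["" .join([a, "A"]) if c == "FRAMESHIFT_INDEL" else a
                    for a, c in zip(alt, classes)],
            "neoantigenic": neo,
            "in_copy_loss": in_loss,
            "expressed": expressed,
            "clonal_true": clonal,
            "ccf_true": ccf,
            "fpkm": fpkm,
        }
    )


def _trunk_epitopes(
    cfg: SyntheticCohortConfig, rng: np.random.Generator,
    trunk: pd.DataFrame, hla: list[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Epitopes per trunk mutation; returns the table and a per-variant
    immunogenicity flag (best passing affinity < 150 nM or stability > 2 h)."""
    mu_a, sg_a = cfg.affinity_lognorm_params
    mu_s, sg_s = cfg.stability_lognorm_params
    rows = []
    immunogenic: dict[str, bool] = {}
    for rec in trunk.itertuples():
        if rec.variant_class == "SILENT":
            continue
        if rec.neoantigenic:
            mean = cfg.epitopes_per_mutation
            if rec.variant_class == "FRAMESHIFT_INDEL":
                mean *= cfg.frameshift_epitope_factor
            n_epi = 1 + rng.poisson(max(mean - 1, 0.0))
        else:
            if rng.random() >= 0.3:  # most non-neoantigenic mutations yield nothing
                immunogenic[rec.variant_id] = False
                continue
            n_epi = 1 + rng.poisson(1.0)
        peptides = _random_peptides(rng, n_epi)
        alleles = rng.choice(hla, size=n_epi)
        stab = rng.lognormal(mu_s, sg_s, size=n_epi)
        best_pass_aff, best_pass_stab = np.inf, -np.inf
        for k in range(n_epi):
            if rec.neoantigenic and k == 0:
                affs = _lognormal_below(rng, mu_a, sg_a, 500.0, 3)
            elif not rec.neoantigenic and rec.fpkm > 1.0:
                # decoy: shifted above the gate so it can never be called
                affs = 500.0 + rng.lognormal(mu_a, sg_a, size=3)
            else:
                affs = rng.lognormal(mu_a, sg_a, size=3)
            if min(affs) < 500.0 and rec.fpkm > 1.0:
                best_pass_aff = min(best_pass_aff, float(min(affs)))
                best_pass_stab = max(best_pass_stab, float(stab[k]))
            rows.append(
                {
                    "variant_id": rec.variant_id,
                    "peptide": peptides[k],
                    "hla_allele": str(alleles[k]),
                    PREDICTORS[0]: float(affs[0]),
                    PREDICTORS[1]: float(affs[1]),
                    PREDICTORS[2]: float(affs[2]),
                    "stability_halflife": float(stab[k]),
                    "fpkm": float(rec.fpkm),
                }
            )
        immunogenic[rec.variant_id] = (
            best_pass_aff < 150.0 or (np.isfinite(best_pass_stab) and best_pass_stab > 2.0)
        )
    cols = ["variant_id", "peptide", "hla_allele", *PREDICTORS,
            "stability_halflife", "fpkm"]
    return (
        pd.DataFrame(rows, columns=cols),
        pd.Series(immunogenic, dtype=bool),
    )


def _realize_sample(
    cfg: SyntheticCohortConfig, rng: np.random.Generator,
    trunk: pd.DataFrame, present_idx: np.ndarray, clonal_flags: np.ndarray,
    purity: float, sample_id: str, patient: str, site: str,
) -> pd.DataFrame:
    """Turn trunk attributes + presence/clonality into an observed table
    with binomial read counts and CCF intervals under a one-mutated-allele
    model (local CN 1 in copy-loss regions, else 2)."""
    sub = trunk.iloc[present_idx].reset_index(drop=True)
    n = len(sub)
    clonal = clonal_flags.astype(bool)
    # subclonal CCFs are re-drawn when a variant's clonality flipped down
    was_clonal = sub["clonal_true"].to_numpy()
    ccf = np.where(
        clonal, 1.0,
        np.where(was_clonal, rng.uniform(0.15, 0.85, size=n),
                 sub["ccf_true"].to_numpy()),
    )
    cn = np.where(sub["in_copy_loss"].to_numpy(), 1.0, 2.0)
    denom = purity * cn + (1 - purity) * 2.0
    vaf_true = np.clip(purity * ccf / denom, 0.0, 1.0)
    depth = cfg.depth
    alt = rng.binomial(depth, vaf_true)
    normal_alt = rng.binomial(depth, NORMAL_ERROR_RATE, size=n)
    vaf_hat = alt / depth
    scale = denom / purity
    ccf_hat = np.clip(vaf_hat * scale, 0.0, 1.5)
    half_width = 1.96 * np.sqrt(np.maximum(vaf_hat * (1 - vaf_hat), 1e-4) / depth) * scale
    out = sub.copy()
    out["sample_id"] = sample_id
    out["patient_id"] = patient
    out["site"] = site
    out["tumor_alt_reads"] = alt
    out["tumor_ref_reads"] = depth - alt
    out["normal_alt_reads"] = normal_alt
    out["normal_ref_reads"] = depth - normal_alt
    out["vaf"] = vaf_hat
    out["ccf_point"] = ccf_hat
    out["ccf_lo"] = np.clip(ccf_hat - half_width, 0.0, 1.5)
    out["ccf_hi"] = np.clip(ccf_hat + half_width, 0.0, 1.5)
    out["clonal_planted"] = clonal
    return out


def _met_presence(
    cfg: SyntheticCohortConfig, rng: np.random.Generator,
    trunk: pd.DataFrame, immunogenic: pd.Series, biased: bool,
) -> np.ndarray:
    """Drop-out mask for a metastatic (or extra-region) sample."""
    n = len(trunk)
    p_drop = cfg.p_drop_met if biased else 0.08
    if biased and cfg.beta_reduction > 0:
        imm_lookup = immunogenic.to_dict()
        imm = trunk["neoantigenic"].to_numpy() & np.array(
            [bool(imm_lookup.get(v, False)) for v in trunk["variant_id"]]
        )
        p = np.where(imm, _odds_prob(p_drop, 1 + cfg.beta_reduction), p_drop)
    else:
        p = np.full(n, p_drop)
    return rng.random(n) >= p  # True = kept


def simulate_cohort(
    config: Optional[SyntheticCohortConfig] = None, **overrides
) -> tuple[CohortBundle, GroundTruth]:
    """Simulate the full cohort; see the module docstring for the model."""
    cfg = config or SyntheticCohortConfig(**overrides)
    if overrides and config is not None:
        cfg = config.model_copy(update=overrides)
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.sites_per_patient or default_site_layout(cfg.n_patients)

    sample_rows, variant_frames, epitope_frames = [], [], []
    pair_rows = []
    region_sets: dict[str, frozenset] = {}
    subtype_labels = {}

    for patient in sorted(layout):
        sites = layout[patient]
        subtype_labels[patient] = str(
            rng.choice(SUBTYPES, p=np.array(cfg.subtype_proportions))
        )
        hla = list(rng.choice(HLA_POOL, size=6, replace=False))
        n_mut = max(5, rng.poisson(cfg.n_mutations_mean))
        trunk = _trunk_mutations(cfg, rng, patient, hla, 0, n_mut)
        epitopes, immunogenic = _trunk_epitopes(cfg, rng, trunk, hla)
        next_vid = n_mut

        # per-sample presence/clonality
        presence: dict[str, np.ndarray] = {}
        clonality: dict[str, np.ndarray] = {}
        tables: dict[str, pd.DataFrame] = {}
        epi_tables: dict[str, pd.DataFrame] = {}
        trunk_by_sample: dict[str, pd.DataFrame] = {}
        imm_by_sample: dict[str, dict[str, bool]] = {}
        for site_label in sites:
            site, region = site_label.split(":")
            sample_id = f"{patient}-{site[:3].title()}{region}"
            purity = float(rng.uniform(0.4, 0.9))
            is_primary_ref = site == "PRIMARY" and region == "1"
            cur_trunk, cur_epi, cur_imm = trunk, epitopes, immunogenic
            if is_primary_ref:
                kept = np.ones(n_mut, dtype=bool)
                clonal = trunk["clonal_true"].to_numpy().copy()
            else:
                kept = _met_presence(cfg, rng, trunk, immunogenic,
                                     biased=site != "PRIMARY")
                clonal = trunk["clonal_true"].to_numpy().copy()
                if site != "PRIMARY":
                    flip = rng.random(n_mut) < cfg.p_clonality_flip
                    clonal = np.where(flip, ~clonal, clonal)
                # private gains
                n_gain = rng.poisson(cfg.gain_fraction_met * n_mut)
                if n_gain > 0:
                    gains = _trunk_mutations(cfg, rng, patient, hla, next_vid, n_gain)
                    next_vid += n_gain
                    gain_epi, gain_imm = _trunk_epitopes(cfg, rng, gains, hla)
                    cur_trunk = pd.concat([trunk, gains], ignore_index=True)
                    cur_epi = pd.concat(
                        [f for f in (epitopes, gain_epi) if len(f)] or [epitopes],
                        ignore_index=True,
                    )
                    cur_imm = pd.concat([immunogenic, gain_imm])
                    kept = np.concatenate([kept, np.ones(n_gain, dtype=bool)])
                    clonal = np.concatenate(
                        [clonal, gains["clonal_true"].to_numpy()]
                    )
            present_idx = np.flatnonzero(kept)
            obs = _realize_sample(
                cfg, rng, cur_trunk, present_idx, clonal[present_idx],
                purity, sample_id, patient, site,
            )
            tables[sample_id] = obs
            epi_tables[sample_id] = cur_epi[
                cur_epi["variant_id"].isin(obs["variant_id"])
            ].assign(sample_id=sample_id, patient_id=patient)
            trunk_by_sample[sample_id] = cur_trunk
            imm_by_sample[sample_id] = cur_imm.to_dict()
            presence[sample_id] = kept
            clonality[sample_id] = clonal
            sample_rows.append(
                {
                    "sample_id": sample_id, "patient_id": patient, "site": site,
                    "region": int(region), "purity": purity, "ploidy": 2.0,
                    "subtype_true": subtype_labels[patient],
                }
            )
            variant_frames.append(obs)
            epitope_frames.append(epi_tables[sample_id])

            # true neoantigen identity keys present in the sample
            epi = epi_tables[sample_id]
            passing = epi[
                (epi[list(PREDICTORS)].min(axis=1) < 500.0) & (epi["fpkm"] > 1.0)
            ]
            region_sets[sample_id] = frozenset(
                zip(passing["peptide"], passing["hla_allele"])
            )

        # planted pair truth: reference primary vs every metastatic sample
        ref_id = f"{patient}-Pri1"
        met_ids = [s for s in tables if tables[s]["site"].iat[0] != "PRIMARY"]
        for met_id in met_ids:
            met_trunk = trunk_by_sample[met_id]
            for j in range(len(met_trunk)):
                vid = met_trunk["variant_id"].iat[j]
                in_p = j < n_mut  # trunk variants only exist in the primary
                in_m = bool(presence[met_id][j])
                if not in_p and not in_m:
                    continue
                if in_p and not in_m:
                    group = "REDUCED"
                elif in_m and not in_p:
                    group = "INCREASED"
                else:
                    cp = bool(trunk["clonal_true"].iloc[j])
                    cm = bool(clonality[met_id][j])
                    group = (
                        "REDUCED" if cp and not cm
                        else "INCREASED" if cm and not cp
                        else "PERSISTENT"
                    )
                pair_rows.append(
                    {
                        "pair_id": f"{ref_id}|{met_id}",
                        "patient_id": patient,
                        "primary_sample_id": ref_id,
                        "met_sample_id": met_id,
                        "variant_id": vid,
                        "neoantigenic": bool(met_trunk["neoantigenic"].iloc[j]),
                        "immunogenic": bool(
                            imm_by_sample[met_id].get(vid, False)
                        ),
                        "true_group": group,
                    }
                )

    samples = pd.DataFrame(sample_rows)
    variants = pd.concat(variant_frames, ignore_index=True)
    nonempty_epi = [f for f in epitope_frames if len(f)]
    epitopes_all = pd.concat(
        nonempty_epi or epitope_frames[:1], ignore_index=True
    )

    expression, _ = _expression_matrix(
        cfg, rng, samples, pd.Series(subtype_labels)
    )
    segments = _copy_segments(cfg, rng, samples)
    fractions = _cell_fractions(cfg, rng, samples)
    clonotypes = _tcr_clonotypes(cfg, rng, samples)

    bundle = CohortBundle(
        samples=samples,
        variants=variants,
        epitopes=epitopes_all,
        expression=expression,
        segments=segments,
        cell_fractions=fractions,
        clonotypes=clonotypes,
        config=cfg,
    )
    truth = GroundTruth(
        theta_cnv=cfg.theta_cnv,
        theta_txn=cfg.theta_txn,
        beta_reduction=cfg.beta_reduction,
        subtypes=pd.Series(subtype_labels, name="subtype"),
        pair_truth=pd.DataFrame(pair_rows),
        region_neoantigen_sets=region_sets,
        sample_true_or=pd.DataFrame(
            {
                "sample_id": samples["sample_id"],
                "true_cnv_or": cfg.theta_cnv,
                "true_txn_or": cfg.theta_txn,
            }
        ),
    )
    return bundle, truth


def _expression_matrix(
    cfg: SyntheticCohortConfig, rng: np.random.Generator,
    samples: pd.DataFrame, subtypes: pd.Series,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    from .immunogram import default_axis_catalog

    catalog_genes: list[str] = []
    for gs in default_axis_catalog().values():
        catalog_genes.extend(gs.genes)
    catalog_genes = list(dict.fromkeys(catalog_genes + ["CD8A", "CD274"]))
    sig = {
        k: [f"SIG{k}_{i:03d}" for i in range(cfg.n_signature_genes)]
        for k in SUBTYPES
    }
    filler = [f"GENE_{i:04d}" for i in range(cfg.n_background_genes)]
    genes = catalog_genes + sig["I"] + sig["II"] + sig["III"] + filler

    base = rng.normal(5.0, 0.5, size=len(genes))
    values = base[:, None] + rng.normal(0.0, 1.0, size=(len(genes), len(samples)))
    expr = pd.DataFrame(values, index=genes, columns=samples["sample_id"])
    for k in SUBTYPES:
        cols = samples.loc[
            samples["patient_id"].map(subtypes) == k, "sample_id"
        ]
        expr.loc[sig[k], cols] += cfg.subtype_effect
    expr = expr.clip(lower=0.0)
    expr.index.name = "gene"
    return expr, sig


def _copy_segments(
    cfg: SyntheticCohortConfig, rng: np.random.Generator, samples: pd.DataFrame
) -> pd.DataFrame:
    rows = []
    for sample_id in samples["sample_id"]:
        for chrom, length in AUTOSOME_LENGTHS.items():
            if rng.random() < 0.12:
                frac = float(rng.uniform(0.3, 1.0))
                cn = int(rng.choice([1, 3]))
                cut = int(frac * length)
                rows.append((sample_id, chrom, 0, cut, cn, cn == 1))
                if cut < length:
                    rows.append((sample_id, chrom, cut, length, 2, False))
            else:
                rows.append((sample_id, chrom, 0, length, 2, False))
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "total_cn", "loh"]
    )


def _cell_fractions(
    cfg: SyntheticCohortConfig, rng: np.random.Generator, samples: pd.DataFrame
) -> pd.DataFrame:
    cell_types = list(cfg.cell_fraction_dirichlet)
    conc = np.array([cfg.cell_fraction_dirichlet[c] for c in cell_types])
    values = rng.dirichlet(conc, size=len(samples))
    return pd.DataFrame(
        values, index=pd.Index(samples["sample_id"], name="sample_id"),
        columns=cell_types,
    )


def _tcr_clonotypes(
    cfg: SyntheticCohortConfig, rng: np.random.Generator, samples: pd.DataFrame
) -> pd.DataFrame:
    rows = []
    # samples of one patient draw from a shared repertoire pool, so
    # multiregion TCR branch proportions land strictly between 0 and 1
    for _, pgrp in samples.groupby("patient_id", sort=False):
        pool_size = int(cfg.n_tcr_clones * 1.5)
        pools = {
            chain: [
                "CASS" + "".join(rng.choice(AA, size=int(rng.integers(6, 11)))) + "F"
                for _ in range(pool_size)
            ]
            for chain in ("alpha", "beta")
        }
        for sample_id in pgrp["sample_id"]:
            for chain in ("alpha", "beta"):
                idx = rng.choice(pool_size, size=cfg.n_tcr_clones, replace=False)
                counts = rng.zipf(cfg.tcr_powerlaw_exponent, size=cfg.n_tcr_clones)
                for i, count in zip(idx, counts):
                    rows.append((sample_id, chain, pools[chain][i], int(count)))
    return pd.DataFrame(rows, columns=["sample_id", "chain", "cdr3", "count"])


def ground_truth_report(truth: GroundTruth) -> pd.DataFrame:
    """Per-pair summary of planted fates plus cohort-level planted values."""
    if len(truth.pair_truth) == 0:
        pair_summary = pd.DataFrame(
            columns=["pair_id", "n_reduced", "n_increased", "n_persistent"]
        )
    else:
        pair_summary = (
            truth.pair_truth.groupby("pair_id")["true_group"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=["REDUCED", "INCREASED", "PERSISTENT"], fill_value=0)
            .rename(
                columns={
                    "REDUCED": "n_reduced",
                    "INCREASED": "n_increased",
                    "PERSISTENT": "n_persistent",
                }
            )
            .reset_index()
        )
    pair_summary["theta_cnv"] = truth.theta_cnv
    pair_summary["theta_txn"] = truth.theta_txn
    pair_summary["beta_reduction"] = truth.beta_reduction
    return pair_summary


def simulate_depletion_sample(
    n_mutations: int = 200,
    *,
    theta_txn: float = 0.7,
    theta_cnv: float = 1.5,
    p_neoantigenic: float = 0.5,
    p_copy_loss_base: float = 0.15,
    p_expressed_base: float = 0.6,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Minimal nonsynonymous-mutation table with planted depletion odds.

    The population odds ratio of copy-loss (resp. expression) for
    neoantigenic vs non-neoantigenic mutations equals ``theta_cnv``
    (resp. ``theta_txn``) exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    neo = rng.random(n_mutations) < p_neoantigenic
    p_loss = np.where(
        neo, _odds_prob(p_copy_loss_base, theta_cnv), p_copy_loss_base
    )
    p_expr = np.where(
        neo, _odds_prob(p_expressed_base, theta_txn), p_expressed_base
    )
    return pd.DataFrame(
        {
            "variant_id": [f"v{i:05d}" for i in range(n_mutations)],
            "variant_class": "MISSENSE",
            "neoantigenic": neo,
            "in_copy_loss": rng.random(n_mutations) < p_loss,
            "expressed": rng.random(n_mutations) < p_expr,
        }
    )


def simulate_tracking_pair(
    n_variants: int = 400,
    *,
    p_immunogenic: float = 0.5,
    p_drop: float = 0.15,
    beta_reduction: float = 2.0,
    gain_fraction: float = 0.15,
    p_clonal: float = 0.65,
    p_flip: float = 0.15,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One primary/metastasis neoantigen pair for fate-tracking studies.

    Returns (primary, metastasis) tables with columns variant_id, clonality
    and immunogenic. Immunogenic variants drop out of the metastasis with
    odds multiplied by ``1 + beta_reduction``; clonality flips and private
    gains are immunogenicity-neutral.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    imm = rng.random(n_variants) < p_immunogenic
    clonal_p = rng.random(n_variants) < p_clonal
    drop_p = np.where(imm, _odds_prob(p_drop, 1 + beta_reduction), p_drop)
    kept = rng.random(n_variants) >= drop_p
    flip = rng.random(n_variants) < p_flip
    clonal_m = np.where(flip, ~clonal_p, clonal_p)

    primary = pd.DataFrame(
        {
            "variant_id": [f"v{i:05d}" for i in range(n_variants)],
            "clonality": np.where(clonal_p, "CLONAL", "SUBCLONAL"),
            "immunogenic": imm,
        }
    )
    met_rows = primary.loc[kept].copy()
    met_rows["clonality"] = np.where(clonal_m[kept], "CLONAL", "SUBCLONAL")
    n_gain = rng.poisson(gain_fraction * n_variants)
    gains = pd.DataFrame(
        {
            "variant_id": [f"g{i:05d}" for i in range(n_gain)],
            "clonality": np.where(
                rng.random(n_gain) < p_clonal, "CLONAL", "SUBCLONAL"
            ),
            "immunogenic": rng.random(n_gain) < p_immunogenic,
        }
    )
    met = pd.concat([met_rows, gains], ignore_index=True)
    return primary, met


def simulate_expression_cohort(
    n_samples: int = 120,
    *,
    effect: float = 1.5,
    n_signature_genes: int = 50,
    n_background_genes: int = 200,
    proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Expression matrix with planted 3-subtype structure, for classifier
    recovery studies. Each class has ``n_signature_genes`` genes shifted by
    ``effect`` residual sd in that class's samples."""
    rng = np.random.default_rng(seed)
    labels = rng.choice(SUBTYPES, size=n_samples, p=np.array(proportions))
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    sig = {
        k: [f"SIG{k}_{i:03d}" for i in range(n_signature_genes)] for k in SUBTYPES
    }
    filler = [f"GENE_{i:04d}" for i in range(n_background_genes)]
    genes = sig["I"] + sig["II"] + sig["III"] + filler
    base = rng.normal(5.0, 0.5, size=len(genes))
    values = base[:, None] + rng.normal(0.0, 1.0, size=(len(genes), n_samples))
    expr = pd.DataFrame(values, index=genes, columns=sample_ids)
    for k in SUBTYPES:
        expr.loc[sig[k], np.array(sample_ids)[labels == k]] += effect
    expr.index.name = "gene"
    return expr, pd.Series(labels, index=sample_ids, name="subtype")
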