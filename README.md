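# neoscape

Downstream neoantigen-landscape analysis for paired primary/metastasis
tumor cohorts (built around a nasopharyngeal-carcinoma-style study
design: primary tumors with matched regional-lymph-node and
distant-metastasis samples, some multiregion).

The package starts where the upstream callers stop. Given somatic variant
tables (read counts, CCF intervals), MHC-I epitope prediction tables,
expression matrices, copy-number segments, immune-cell fractions and TCR
clonotypes, it computes:

- **Neoantigen calling** — 9/10-mer epitopes with min-over-predictors
  binding affinity < 500 nM and FPKM > 1; affinity classes strong/medium/
  weak at 50/150 nM, stability high/low at a 2 h half-life; per-mutation
  yields, within/cross-patient sharing, multiregion branch proportions
  (ITH) for neoantigens and TCR.
- **Clonality tracking** — variants are clonal iff the CCF 95% CI contains
  1; between a primary and its metastasis every neoantigenic variant is
  reduced / increased / persistent, summarised by the reduction ratio
  `(increased − reduced) / primary load` and an immunogenicity-bias odds
  ratio (are high-affinity/high-stability neoantigens preferentially
  lost?).
- **Depletion statistics** — per-sample 2×2 odds ratios of neoantigenic
  vs non-neoantigenic nonsynonymous mutations against copy-number loss
  (depletion ⇔ OR > 1) and mutant-allele expression (depletion ⇔ OR < 1),
  with Haldane–Anscombe correction, Woolf CIs, Fisher exact p-values and
  per-site cohort fractions.
- **Immune scores** — MATH (100 × scaled MAD / median VAF), wGII with the
  0.2 CIN threshold, an 8-axis immunogram of the cancer-immunity cycle
  (single-sample enrichment → cohort z → IGS = 3 ± 1.5·Z, radar-clamped
  to [1, 5]), TMIT quadrants on CD8A × PD-L1, and Treg/CD8, M2/M1 ratios.
- **Subtype model** — pairwise rank-sum signature extraction, a random
  forest trained on a stratified 2/3 split with 100 resampling
  iterations, multiregion mean-probability prediction gated at 0.4.
- **Synthetic cohort generator** — seed-deterministic cohorts with
  planted depletion odds ratios, reduction bias and subtype structure, so
  every estimator is validated by parameter recovery.

## Worked example

```python
from neoscape import (PipelineConfig, SyntheticCohortConfig,
                      run_pipeline, simulate_cohort)

bundle, truth = simulate_cohort(SyntheticCohortConfig(seed=7))
result = run_pipeline(bundle, PipelineConfig(seed=7),
                      subtype_labels=truth.subtypes)

print(len(result.neoantigens))                       # 14021
print(result.sharing)
# {'within_patient_shared_fraction': 0.689..., 'n_cross_patient_shared': 0,
#  'total_neoantigen_instances': 14021}
print(result.reduction["reduction_flag"].mean())     # 0.928...
```

14,021 neoantigen presentation events are called across the 57 samples;
68.9% of instances recur in a second sample of the same patient and none
are shared between patients (peptide spaces are patient-private in the
generator). 92.9% of primary/metastasis pairs show net neoantigen
reduction — the generator plants biased loss of immunogenic neoantigens
in metastases (`beta_reduction=2.0`), and the tracking statistics recover
it. The same run yields per-site depletion fractions
(`result.depletion_summary`), MATH/wGII per sample
(`result.heterogeneity`), the immunogram radar (`result.radar`) and gated
subtype calls (`result.subtype_calls`).

The `analysis/` scripts run the same steps as a narrated sequence,
writing tables under `results/`:

```bash
python analysis/01_simulate_cohort.py   # cohort inputs -> results/cohort/
python analysis/02_run_pipeline.py      # full report  -> results/pipeline/
python analysis/03_depletion_recovery.py
python analysis/04_tracking_reduction.py
python analysis/05_immune_landscape.py
python analysis/06_subtype_model.py
```

There is also a CLI (`neoscape simulate|call|track|deplete|immunogram|
subtype|report`) over the same library; `neoscape report` runs the whole
pipeline on a cohort directory and is byte-reproducible under a fixed
seed.

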