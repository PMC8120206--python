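# Methods

`neoscape` implements the downstream analysis layer of a paired
primary/metastasis tumor-sequencing study: it consumes the outputs of
upstream callers (somatic variant tables with read counts and cancer-cell
fractions, MHC-I epitope prediction tables, expression matrices,
copy-number segments, immune-cell fractions, TCR clonotypes) and computes
the neoantigen landscape, its evolution during metastasis, and
immune-context summaries. Everything upstream — alignment, variant calling,
purity/ploidy/CCF estimation, HLA typing, binding prediction,
deconvolution — is out of scope and consumed as input.

## Variant QC and clonality

A called SNV is retained when (i) its tumor alt-read support is ≥ 5 and
(ii) the two-sided Fisher exact test comparing mutant/wild-type read
composition between tumor and matched normal gives p < 0.05 (both
thresholds configurable in `PipelineConfig`). "Presence" of a variant in a
sample always means it passed this filter there; there is no cross-sample
rescue or force-calling, so a variant that drops below the filter in a
metastasis counts as disappeared.

Clonality comes from the CCF 95% confidence interval: a mutation is
**clonal** when the closed interval contains 1 and **subclonal**
otherwise. The closed-interval convention means boundary contact
(`[1.00, 1.00]` or `[0.80, 1.00]`) is clonal; the defining rule does not
exclude endpoint contact and the closed form is the conservative reading.

## Neoantigen calling and classes

Candidate epitopes are 9- and 10-mer peptide–HLA pairs with per-predictor
binding affinities in nM. The **best affinity** is the minimum over the
predictors (strongest predicted binding). An epitope is called a
neoantigen iff best affinity < 500 nM **and** the source transcript's
FPKM > 1. Called neoantigens are classed by affinity — strong < 50 nM,
medium < 150 nM, weak otherwise — with boundaries falling to the weaker
class (exactly 50 ⇒ medium, exactly 150 ⇒ weak), because the class
definitions are strict inequalities. Binding stability is high when the
pMHC half-life exceeds 2 h (strict), low otherwise, unknown when missing.
"Immunogenic" below means strong/medium affinity (< 150 nM) or high
stability.

Neoantigen identity is the (peptide, HLA allele) pair: the same peptide
presented on a different allele is a different presentation event.
The per-mutation yield uses *all* mutations of a class as denominator
(not only epitope-generating ones); the alternative denominator is
computable from the same inputs.

## Fate tracking and reduction ratio

For a primary/metastasis pair, every neoantigenic variant in the union is
assigned one of three fates:

- **reduced** — present only in the primary, or clonal → subclonal;
- **increased** — present only in the metastasis, or subclonal → clonal;
- **persistent** — present in both with an unchanged clonality class.

The **reduction ratio** of a pair is
`(n_increased − n_reduced) / primary_load`, with the primary neoantigen
load as denominator; a negative ratio flags net reduction. The
immunogenicity-bias odds ratio cross-tabulates fate group (reduced vs
increased) against the immunogenicity property; OR > 1 means immunogenic
neoantigens preferentially disappear.

## Depletion odds ratios

Per sample, all nonsynonymous mutations are cross-tabulated as
neoantigenic vs not against (a) lying in a copy-number-loss region and
(b) mutant-allele expression in RNA-seq. Copy-loss depletion is OR > 1
(neoantigens enriched on lost segments); transcriptional depletion is
OR < 1 (neoantigen transcripts preferentially silenced). The `expressed`
flag is RNA-level support of the *mutant allele* and is deliberately
distinct from the gene-level FPKM in the epitope table: if the two were
identified, every called neoantigen would be expressed by construction
and the transcriptional table would be degenerate.

Numerics: OR = (a·d)/(b·c); when any cell is zero all four cells get the
Haldane–Anscombe +0.5 (flagged in the result); the 95% CI is the Woolf
logit interval on the (possibly corrected) table; the p-value is the
two-sided Fisher exact test on the uncorrected integer counts. The default
depletion call is direction-only (OR vs 1), matching per-site cohort
fractions that are not described as significance-gated; a p < α gate is a
config switch. Samples with an empty neoantigenic or non-neoantigenic row
are reported UNDETERMINED and excluded from cohort denominators rather
than counted as 0.

## Heterogeneity and instability

- **MATH** = 100 × (1.4826 × MAD) / median over a sample's VAFs (the
  1.4826 factor is the normal-consistency scaling of the cited MATH
  convention). Scale-invariant; requires ≥ 3 VAFs and positive median.
- **wGII** = mean over the 22 autosomes of the length fraction of covered
  genome whose total copy number differs from round(ploidy); CIN+ iff
  wGII > 0.2. Sex chromosomes are excluded; chromosome bounds use GRCh38
  autosome lengths rounded to Mb.
- **Branch proportion (ITH)** for multiregion tumors =
  1 − |∩ regions| / |∪ regions| over neoantigen identity keys or TCR
  clonotypes; the union denominator makes it the fraction of observed
  features that are not ubiquitous.
- **Clonal TCR proportion**: reads in clones whose frequency exceeds 1% of
  the chain total (the threshold is a configurable stand-in; no published
  cut exists for this quantity).

## Immunogram

Eight axes of the cancer-immunity cycle per sample. Seven are scored from
expression gene sets with a single-sample enrichment engine: genes are
ranked per sample (descending; ties broken by gene order for
determinism), and a running sum adds normalized-rank^0.25 steps on set
genes and uniform steps off-set; the score is the summed deviation, then
normalized by the cohort score range. The engine is intentionally simple
and pluggable — every downstream use passes through cohort z-scores, so
any deterministic monotone single-sample score yields the same IGS
ordering; it is not a reproduction of the GSVA package. The eighth axis
(tumor antigenicity) is the z-score of the per-sample neoantigen load,
log10(x+1)-transformed by default because loads are heavy-tailed.

z-scores use the population-sd convention (config-switchable); IGS is
3 + 1.5·Z for stimulatory axes (1–5) and 3 − 1.5·Z for inhibitory axes
(6–8), so 3 is always the cohort average and higher is more favourable.
Radar displays clamp IGS to [1, 5]; raw values are retained. The shipped
axis gene sets are small curated marker panels and are explicitly a
configurable placeholder catalog (swap in a GMT file), not a claimed
reproduction of any published signature collection.

TMIT quadrants split CD8A and PD-L1 (CD274) at the cohort median per
marker, ties to "low": I = high/high, II = low/low, III = high PD-L1/low
CD8A, IV = low PD-L1/high CD8A. Cell-type ratios (Treg/CD8, M2/M1) add a
pseudocount ε = 1e-3 to numerator and denominator because deconvolved
fractions contain exact zeros.

## Subtype model

Signature genes per class come from pairwise between-class comparisons:
gene g belongs to class k's signature iff the Mann–Whitney rank-sum test
against *each* other class has BH-adjusted p < 0.05 (adjustment across
genes within each comparison) and the median is higher in k both times.
The groups are independent samples, so the rank-sum form is used even
though the protocol names the signed-rank variant, which requires pairing
that does not exist here. No fold-change gate is applied by default.

Training follows the split-and-resample protocol: a stratified 2/3 split
(stratification keeps small classes in training), 100 bootstrap
resampling iterations to tune the random forest's `max_features`
(candidates `sqrt`, 0.25, 0.5; each resample scores every candidate on
its out-of-bootstrap samples), a 300-tree final forest, and held-out
accuracy on the remaining 1/3. Prediction averages class probabilities
over a patient's regions, then assigns the argmax class iff its mean
probability reaches the 0.4 gate; ties break deterministically by class
order I < II < III with a warning; below-gate patients stay UNCLASSIFIED.
All randomness derives from one seed.

## Synthetic cohort generator

The generator emulates the study conditions: 26 patients with 29 primary,
16 regional-lymph-node and 12 distant-metastasis samples (three patients
carry a second primary region for multiregion ITH), ~100 mutations per
sample of which ~65% are nonsilent (missense 0.55, frameshift 0.04, other
nonsilent 0.06, silent 0.35), 57% of nonsilent mutations neoantigenic,
and epitope yields tuned to ≈ 4.5 per missense mutation with a ×2 factor
for frameshift indels. Read counts are binomial at fixed 100× depth with
VAF derived from CCF, purity (uniform 0.4–0.9) and local copy number
under a one-mutated-allele model (local CN 1 in copy-loss regions, else
2); the CCF point estimate back-transforms the observed VAF and its CI is
±1.96 binomial SE on the same scale, so the clonality rule exercises both
outcomes. CCF CIs of the upstream caller are not publicly specified; this
CI model is a stand-in, not a reproduction.

Planted effects are exact population odds ratios: neoantigenic mutations
fall into copy-loss regions with odds multiplied by `theta_cnv` (default
1.5) and carry RNA support with odds multiplied by `theta_txn` (default
0.7); metastatic samples drop primary variants (base probability 0.12)
with drop odds ×(1 + `beta_reduction`) for immunogenic neoantigens
(default beta 2.0), flip clonality with probability 0.15 and gain private
variants (Poisson, 15% of the trunk size). Expression carries three
planted subtypes (50 signature genes per class shifted 1.5 residual sd);
cell fractions are Dirichlet draws; TCR clone sizes are Zipf (exponent
2.5) drawn from a shared patient-level repertoire pool so multiregion
branch proportions are informative.

What the generator does **not** emulate: mutational signatures and
realistic positional clustering, germline variation, linkage between
copy-number segments and the per-variant copy-loss flags (segments feed
wGII only), realistic epitope sequence similarity (peptides are random,
hence patient-private by construction — the empty cross-patient sharing
set is structural), viral load, and any coupling between the immune axes
and the planted subtypes. Passing recovery tests therefore demonstrate
estimator correctness under the stated model, not robustness to real-data
artifacts such as mapping bias, subclonal copy number or purity
estimation error.

## Problem sizes and runtime choices

Recovery studies use 50 samples × 200 nonsynonymous mutations for
depletion, 30 replicate pairs of 400 variants for the reduction bias, and
a 120-sample cohort for the classifier protocol; the label-permuted null
is averaged over several independent permutations because a single fixed
permutation retains per-cluster plurality structure that inflates
accuracy above 1/3. The shared test cohort is scaled to 15 patients with
~50 mutations per sample; the end-to-end check runs the full 26-patient
layout. All analyses are single-threaded (`n_jobs=1`) to keep outputs
byte-reproducible.

## Known limitations

- Per-sample depletion ORs at realistic mutation counts (~65 nonsilent)
  are noisy; direction-only calls at that scale have wide error bars, which
  is why the recovery studies use 200-mutation samples.
- The enrichment engine is rank-based and cohort-normalized; absolute NES
  values are not comparable across cohorts, only within.
- The placeholder axis catalogs and the 1% clonal-TCR cut are stand-ins
  where no public definition exists; both are configuration, not claims.
- `UNCLASSIFIED` subtype patients are excluded from downstream per-subtype
  comparisons rather than imputed.
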