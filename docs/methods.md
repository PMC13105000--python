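# Methods

This note documents the statistical models implemented in `karyotme`, the
design choices made where the procedure was genuinely open, what the
synthetic-data generator does and does not emulate, and the package's known
limitations.

## Overview

`karyotme` links somatic copy-number alterations (SCNAs) — at chromosome-arm,
cytoband, or gene resolution — to tumor immune-microenvironment phenotypes
and to survival under immune-checkpoint blockade. The pipeline runs in five
stages: immune scoring, SCNA calling, direction-stratified association
models, gene-level driver calling (TUSON-Immune), and survival analysis.

## Copy-number representation and preprocessing

Copy number is carried as log2(CN / ploidy) (0 = copy-neutral). Segment
files (SEG) are mapped onto arm or cytoband features by the
overlap-length-weighted mean of segment values over the feature interval
(weighted median available); features covered below a minimum fraction of
their length (default 0.5) are set to missing. Both SEG coordinate dialects
are supported; the default is 0-based half-open and 1-based-inclusive input
must be declared explicitly, because the two dialects cannot be
distinguished from the data.

Bulk profiles can be corrected for tumor purity `α` and ploidy `ψ` using the
standard two-component mixture model: the observed bulk copy number
`CN_obs = 2·2^log2raw` is decomposed as tumor plus diploid normal,

    CN_t = (CN_obs − 2(1 − α)) / α,   adjusted log2 = log2(CN_t / ψ),

with `CN_t` floored at 0.01 copies before the log. The formula sits behind a
single function so an alternative correction can be swapped in. Samples
lacking estimates are skipped with a warning (or rejected, configurable).

Discrete calls use strict thresholds: gain iff log2(CN) > 0.2, loss iff
log2(CN) < −0.2; values exactly at a threshold are neutral, and missing
values propagate. The aneuploidy score (AS) of a sample is the sum of
|log2(CN)| over its non-missing features at the analysis level, without
rescaling by feature count; it quantifies global chromosomal-instability
burden and is the key confounder covariate downstream. Whether AS should be
computed on raw or purity-adjusted values is not uniquely determined; the
pipeline computes it on whatever profile it is given, and the orchestrated
run adjusts first.

## Cytotoxic Immune Score (IS)

The IS is a rank-sum statistic over seven cytotoxic-lymphocyte genes
(CD247, CD2, CD3E, GZMH, NKG7, PRF1, GZMK). Within a cohort, each gene is
ranked across samples (ascending, average ties), per-sample ranks are
summed, and the sums are re-ranked to give the final score in [1, n].
Because only ranks enter, the score is invariant to any per-gene strictly
increasing transform of expression (TPM vs log-TPM vs RSEM is immaterial),
and it must never be compared across cohorts — "within a dataset" means
within one tumor type.

Classes: with the default 30/30 split, the bottom `ceil(0.3·n)` ranks are
immune-cold and the top `ceil(0.3·n)` immune-hot (ceil boundary rule,
recorded in the output metadata). Tie-averaged ranks falling between the
cutoffs stay intermediate, so a fully tied cohort is entirely intermediate.
Higher expression → higher rank → hotter is the fixed sign convention.

## Association models

For each feature and cohort, four logistic models are fit: {gain, loss} ×
{cold, hot}. The outcome is the indicator of the phenotype class against
all other samples (intermediates count as controls by default;
`drop_intermediate` restricts to cold-vs-hot). Predictors are the feature's
*continuous* log2 copy number plus the AS. The discrete call is used only
for exclusion: samples called loss at a feature are removed from that
feature's gain models and vice versa, which prevents the two directions of
dosage change from confounding each other. Models with fewer than 20 usable
samples (configurable), a constant outcome, or a constant predictor are kept
in the output as rows with machine-readable skip-reason codes.

Cell-type abundances (ingested from xCell-style score tables; deconvolution
itself is consumed, not reimplemented) get the same covariates and exclusion
rules with linear models. Scores are rank-transformed to normal scores by
default because xCell enrichment scores are strongly skewed and
zero-inflated; the raw scale is retained behind a flag. A negative
coefficient means less of the cell type with higher copy number.

P-values are Benjamini–Hochberg adjusted within (tumor type, level,
direction, phenotype) groups, i.e. per tumor type and SCNA type
independently. The landscape view collapses the cold and hot models of each
(feature, direction) to the smaller adjusted p: signed score
`±(−log10 q)`, positive when hot wins, negative when cold wins, exact ties
breaking toward cold. Cell-type associations are additionally filtered:
p > 0.2 is dropped, and gain/loss pairs whose effects share a sign
(directionally incoherent: both directions of dosage change moving the cell
type the same way) are dropped as pairs.

Per-patient single-cell proportion tables are compared between SCNA status
groups with two-sided Welch t-tests (≥ 2 patients per group); two
zero-variance identical groups return t = 0, p = 1 by convention.

## TUSON-Immune gene calling

Each gene is scored by three Spearman correlations (Pearson behind a flag):
DNA:IS, RNA:IS, and DNA:RNA, with the IS entering as its rank value and BH
adjustment per parameter within a tumor type. These three parameters are
the ones an L1-penalized logistic classifier retains when trained to
separate known drivers from background (`lasso_select_parameters`
implements that selection: standardized features, penalty chosen by seeded
cross-validation on log-loss with the one-standard-error rule, the glmnet
convention, which keeps the selected set sparse on null inputs).

Eligibility: a gene is in an *amplified region* when gain-called in ≥ 10%
of samples, *deleted* at the analogous loss frequency, the more frequent
direction winning when both qualify (threshold configurable; peak-membership
from an external caller can be substituted by passing precomputed calls).

Calls, all three parameters at adjusted p < 0.05 (strict):

* **iOG** (immune Oncogene): amplified region, all three rho > 0.
* **TiSG** (Tumor immune Suppressor Gene): deleted region, DNA:RNA rho > 0,
  DNA:IS and RNA:IS rho < 0.

The TiSG sign convention is implemented exactly as stated above. A
`flip_is_sign` option inverts the required sign of the two IS correlations
for users who prefer the opposite biological reading (a deleted immune
suppressor whose dosage tracks positively with immunity); the default makes
no such guess.

A seeded Random-Forest classifier over user-supplied per-gene features,
trained against a gold-standard gene list (negatives sampled from non-gold
genes at 5:1 by default), complements the rule-based TiSG calls and reports
stratified cross-validated and held-out AUROC. Cross-tumor recurrence
summaries count, per gene, the tumor types carrying each call and tally
per-arm counts for genes recurrent in ≥ 3 types (configurable).

## Survival analysis

For survival, SCNAs are categorized with strict ±0.3 thresholds (Gain /
Loss / Neutral). Per arm, two univariate Cox proportional-hazards contrasts
are fit with lifelines (Efron ties): Gain vs Neutral with Loss samples
excluded, and Loss vs Neutral with Gain excluded — the same exclusion logic
as the association models, applied here as a package decision since the
survival procedure itself does not force it. Contrasts need ≥ 10 events
(configurable); the landscape reports `±(−log10 p)` signed by whether
HR > 1 (worse survival positive), with BH FDR across arms per direction.
Kaplan–Meier curves and two-sided log-rank tests handle two-group
stratification.

For transcriptome-only cohorts, chromosome-1q gain is inferred from
expression. Panel selection: among candidate 1q genes shared between a
reference cohort's DNA and RNA, the top 50 by Spearman DNA–RNA concordance,
exact ties broken lexicographically for determinism. Scoring: per panel
gene, z-score of log1p expression across samples; per sample, the mean z
over the panel (up to 20% absent panel genes contribute zero; constant
genes are dropped with a warning); the top `ceil(n/4)` samples by score are
classified 1q-gain. The z-of-log1p / mean / ceil-quartile details are
package choices — none is forced by the procedure being emulated.

The multivariate Cox model takes binary-coded covariates: 1q gain,
CD8 T-cell high, B-cell high (both split at the cohort median by default —
the "high vs low" cutoff is not otherwise specified), TMB ≥ 10 mut/Mb
(inclusive, deliberately unlike the strict SCNA thresholds), and PD-L1
positivity. Complete cases only, with the count reported; constant or
duplicated covariates are rejected by name; per-term FDR is reported.

## Synthetic cohorts

The generator (`synthetic_data`) emulates the *statistical* structure the
models assume, so every stage is testable without patient data:

* Arm log2 CN: mixture of copy-neutral (Gaussian, sd 0.05) and altered
  states (uniform magnitude 0.2–0.8 with the arm's dominant sign; 30% of
  samples altered per arm by default). Gene CN inherits the arm value plus
  focal noise (sd 0.05).
* Expression: linear dosage response on the log scale
  (baseline + slope·CN + Gaussian noise, slope 1 by default).
* Immune activity: a latent variable with standard-logistic noise carries
  the planted effects. A planted arm effect enters as
  −(β / 0.4)·sign·CN, so β is the log-odds of the cold class per *typical
  alteration* (a 0.4 log2 excursion) and the induced cold model is exactly
  logistic. The seven signature genes are the latent activity plus small
  Gaussian noise, so the computed IS tracks it with minimal attenuation.
* Planted driver genes couple their (standardized) expression into the
  latent activity with a signed slope and carry their own focal
  copy-number variability (sd 0.3). The focal component is essential:
  without it a driver's copy number is nearly identical to every neighbor
  on its arm and driver-versus-passenger recovery is ill-posed by
  construction, not hard.
* Cell-type scores: linear in arm CN with planted slopes plus Gaussian
  noise, clipped at zero.
* Survival: exponential proportional hazards (Weibull available), baseline
  median 24 months, hazard multiplied by exp(log-HR) for carriers of a
  planted alteration; censoring marks a random fraction (default 0.3) of
  samples and truncates their time uniformly.

Everything is reproducible bitwise from the mandatory seed.

What the generator does **not** emulate: genome-wide segment/linkage
structure, correlated co-occurrence of alterations, realistic expression
covariance beyond dosage, compositionality of cell-type scores, or
cohort-level batch effects. Passing recovery tests therefore demonstrate
that the estimators are correct and calibrated under their assumed model,
not that the biological findings replicate on real cohorts.

## Problem sizes and tolerances in the test suite

Parameter-recovery suites use cohorts of n = 300 (immune and gene-calling
effects; 20 replicates each), n = 500 (single planted hazard ratio 2.0,
recovery window [1.6, 2.5]), n = 1000 × 50 replicates (log-HR bias < 0.1),
and 40 null cohorts of n = 200 × 12 arms for type-I-error calibration
(binomial confidence band around the nominal 5%). These sizes give each
check comfortable power while keeping the full suite to a few minutes on a
single core. Statistical agreement oracles (BH step-up, log-rank O−E,
Spearman-on-ranks, the iOG/TiSG truth table) are exact to numerical
tolerance (1e-9 … 1e-12).

## Known limitations

* Pan-cancer pooling, mixed-effects models, competing risks, and
  time-varying covariates are out of scope; all models are per tumor type.
* The purity/ploidy correction assumes a single clonal tumor population.
* Frequency-based region eligibility is a proxy for peak-based definitions
  from dedicated significance callers.
* Logistic p-values are asymptotic (Wald); very small strata are skipped
  rather than switched to exact tests.
* The landscape's min-q reduction across the cold/hot pair is one
  defensible summary; others (e.g. signed best-signed-q) would differ at
  features significant in both directions.
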