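# karyotme

Somatic copy-number alterations (SCNAs) — gains and losses of chromosome
arms, cytobands, or single genes — reshape the tumor immune
microenvironment and can blunt the response to immune checkpoint blockade.
`karyotme` is a Python toolkit for quantifying those links in bulk genomic
cohorts: it scores cytotoxic immune infiltration from RNA-seq, calls
discrete copy-number states, fits direction-stratified association models
between each locus and immune phenotype while controlling for global
aneuploidy burden, nominates candidate immune-driver genes, and tests
whether specific arm-level events (such as chromosome 1q gain in melanoma)
stratify survival under anti-PD-1/PD-L1 therapy.

It is aimed at computational oncologists working with GISTIC2-style
copy-number tables or SEG files, bulk expression matrices, xCell-style
deconvolution output, and clinical survival tables. A seeded simulator of
linked copy-number / expression / immune / survival cohorts with planted
effects makes every stage testable without patient data.

## The models in brief

**Immune Score (IS).** A rank-sum over seven cytotoxic genes (CD247, CD2,
CD3E, GZMH, NKG7, PRF1, GZMK): each gene is ranked across samples, ranks
are summed per sample and re-ranked. Bottom/top 30% of the score define
immune-cold and immune-hot classes.

**Association scan.** Per feature *j* and cohort, four logistic models

    logit P(class_i) = β₀ + β₁ · log2CN_ij + β₂ · AS_i

for class ∈ {cold, hot} × direction ∈ {gain, loss}, where AS_i = Σ_j
|log2CN_ij| is the aneuploidy score. Samples carrying the opposite
alteration at *j* are excluded from each direction's models. Benjamini–
Hochberg FDR is applied within (tumor type, level, direction, phenotype);
the landscape reports ±(−log10 q), positive for hot, negative for cold.
Cell-type abundances get the same treatment with linear models.

**TUSON-Immune.** Each gene is scored by Spearman correlations DNA:IS,
RNA:IS, and DNA:RNA. Genes in amplified regions with all three rho > 0 at
FDR < 0.05 are called immune Oncogenes (iOG); genes in deleted regions with
DNA:RNA > 0 and both IS correlations < 0 at FDR < 0.05 are called Tumor
immune Suppressor Genes (TiSG). A seeded Random-Forest classifier trained
on a user-supplied gold standard complements the rule-based calls.

**Survival.** Arms are categorized Gain (> 0.3) / Loss (< −0.3) / Neutral;
per arm, Gain-vs-Neutral and Loss-vs-Neutral Cox models give a signed
−log10 p survival landscape. Kaplan–Meier/log-rank stratification, an
expression-inferred 1q-gain score (50-gene DNA–RNA concordance panel, top
quartile = gain), and a multivariate Cox model over 1q gain, CD8/B-cell
infiltration, TMB ≥ 10 mut/Mb, and PD-L1 status complete the stage.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Simulate a melanoma-like cohort of 300 samples in which chromosome 1p gain
both chills the microenvironment (cold log-odds effect 1.0) and doubles the
death hazard, then recover both effects:

```python
import numpy as np
import karyotme as k

config = k.SimulationConfig(
    seed=7, n_samples=300,
    planted_is_effects=[("1p", "gain", 1.0)],
    planted_survival_effects=[("1p", "gain", np.log(2.0))],
)
cohort = k.simulate_cohort(config)

is_table = k.binarize_immune_score(k.cytotoxic_immune_score(cohort.expression))
calls = k.call_scna(cohort.arm_profile)          # gain > 0.2, loss < -0.2
as_table = k.aneuploidy_score(cohort.arm_profile)

cold = k.bh_adjust(k.fit_is_logistic(
    cohort.arm_profile, calls, is_table, as_table, "gain", "cold"))
hot = k.bh_adjust(k.fit_is_logistic(
    cohort.arm_profile, calls, is_table, as_table, "gain", "hot"))
landscape = k.build_signed_landscape(cold, hot)
print(landscape.sort_values("signed_score").head(3).to_string(index=False))

cats = k.categorize_for_survival(cohort.arm_profile)  # Gain > 0.3 / Loss < -0.3
cox = k.cox_landscape(cohort.clinical, cats)
row = cox[(cox["term"] == "1p") & (cox["direction"] == "gain")].iloc[0]
print(f"1p gain: HR={row.hazard_ratio:.2f} "
      f"[{row.ci_low:.2f}, {row.ci_high:.2f}], p={row.p:.2e}")
```

Output:

```
feature_id direction winner            q  signed_score
        1p      gain   cold 9.286341e-07     -6.032155
        1q      gain   cold 2.484504e-01     -0.604760
        4p      gain   cold 2.484504e-01     -0.604760
1p gain: HR=2.51 [1.78, 3.54], p=1.55e-07
```

The planted arm dominates the landscape with a strongly negative
(immune-cold) signed score of −6.0 while every unplanted arm stays far from
significance, and the Cox contrast recovers the planted hazard ratio of 2
with a confidence interval excluding 1.

The same pipeline runs from the shell:

```sh
karyotme simulate --seed 7 --out-dir sim/
karyotme run --config pipeline.yaml --out-dir results/
```

where `pipeline.yaml` points at the simulated (or your own) TSVs; every
output directory carries a `manifest.json` with input digests, seeds, and
effective parameters sufficient to re-run the command.

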