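# methrisk

DNA-methylation-guided risk stratification for high-risk prostate cancer.

After radical prostatectomy, patients classified as high-risk by
clinico-pathological criteria (stage ≥ T3a, Gleason 8–10 or PSA > 20 ng/ml)
still have very heterogeneous outcomes. Promoter hypermethylation of a small
panel of genes (*GSTP1*, *APC*, *RARB*, *PTGS2*, *CCND2*), measured by
quantitative multiplex methylation-specific PCR (QM-MSP), is almost absent in
benign prostate tissue and nearly ubiquitous in tumors — and, more
interestingly, the *level* of *GSTP1* methylation carries prognostic
information that is **non-linear**: patients with either low (< 15%) or high
(> 50%) methylation fail clinically more often than those with moderate
levels. `methrisk` implements the full analysis pipeline behind that kind of
finding, for biostatisticians and translational researchers who want to apply
or stress-test it:

1. **QM-MSP quantification** (`methrisk.qmmsp`) — percent methylation
   100·M/(M+U) from methylated/unmethylated copy counts, with the
   \>3000-copy per-well quality filter.
2. **Diagnostic accuracy** (`methrisk.diagnostics`) — benign-vs-tumor
   ROC/AUC, sensitivity/specificity/PPV/NPV at percent cutoffs, and the
   standard nonparametric association tests; Allred immunohistochemistry
   scoring.
3. **Survival engine** (`methrisk.survival`) — Kaplan–Meier, k-sample
   log-rank, and Newton–Raphson Cox partial-likelihood fitting (Breslow ties
   by default, Efron optional) with Wald hazard ratios, likelihood-ratio
   tests and explicit monotone-likelihood divergence detection.
4. **Risk modeling** (`methrisk.stratify`) — functional-form exploration
   (linear vs quadratic vs restricted cubic spline, by LRT), exhaustive
   two-stage optimal cutpoint search maximizing the Cox partial
   log-likelihood (all dichotomizations, then all trichotomizations with the
   first cut fixed), LM/MM/HM classification, and univariate + multivariate
   prognostic tables.
5. **Concordance validation** (`methrisk.cpe`) — the concordance
   probability estimate K = 2/(n(n−1)) Σ_{i<j} 1/(1+exp(−|η_i−η_j|)) for
   fitted Cox models, and repeated random sub-sampling cross-validation
   (default 200 × 80/20 splits, cutpoints re-tuned per training subset)
   comparing models with and without the methylation term via paired
   t-tests.
6. **Synthetic cohorts** (`methrisk.cohort`) — benign and tumor cohort
   generators (Gaussian-copula-coupled zero-inflated scaled-Beta methylation
   marginals, realistic clinical covariates, exponential survival with a
   U-shaped methylation effect and calibrated event fraction), so the whole
   pipeline is testable without patient data.

## Worked example

```python
import methrisk as mr

# a 147-patient high-risk tumor cohort and a 42-sample benign cohort
tumor  = mr.generate_cohort(mr.pca1_config(147, seed=1))
benign = mr.generate_cohort(mr.bph_config(42, seed=2))

# diagnostic accuracy of GSTP1 methylation, benign vs tumor
print(round(mr.roc_auc(tumor["GSTP1"], benign["GSTP1"]), 3))
# 0.99

# two-stage optimal cutpoint search on the tumor cohort
first  = mr.dichotomize_search(tumor, "GSTP1")
second = mr.trichotomize_search(tumor, "GSTP1", first.cut1)
print(round(second.cut1, 2), round(second.cut2, 2))
# 49.95 76.6

# prognostic models over the low/moderate/high trichotomy at (15, 50)
table, log = mr.build_table4_models(tumor, mr.TrichotomyRule(15.0, 50.0))
row = table[table.variable == "lm_hm"].iloc[0]
print(round(row.hr_multivariate, 2),
      (round(row.ci_low_multivariate, 2), round(row.ci_high_multivariate, 2)))
# 3.66 (1.53, 8.73)
```

The AUC near 1 reflects the near-total absence of methylation in benign
tissue. The multivariate hazard ratio ≈ 3.7 for the low+high vs moderate
methylation contrast at the generating cuts (15, 50) recovers the simulated
effect (HR 3) within its confidence interval. Note that the *discovered*
cuts on this single 147-patient draw sit far from (15, 50): a
one-cut-at-a-time likelihood search on a U-shaped hazard with a small
low-methylation arm is only weakly identified at this size, which is why
each `CutpointResult` carries the full likelihood profile for audit rather
than just the argmax.

A command-line interface mirrors the library:

```bash
methrisk run --seed 11 --out results/ --stages simulate,diagnose,cutpoints,models,validate
```

## Documentation

See `docs/methods.md` for the statistical methods, the synthetic-data
model and its limitations, and the numerical choices (tie handling,
convergence tolerances, boundary conventions).
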