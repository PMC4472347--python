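# Statistical methods

This note documents the models, numerical choices and known limitations of
`methrisk`. Nothing here reports an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## QM-MSP quantification

Percent methylation of one gene in one sample is 100·M/(M+U), where M and U
are the absolute methylated and unmethylated template copy numbers from the
second (quantitative) PCR step. Copy numbers are accepted as non-negative
reals because qPCR standard-curve interpolation yields fractional copies.
Wells are rejected unless M+U strictly exceeds a quality threshold (default
3000 copies after pre-amplification); the rule is applied per sample×gene
well rather than summed over the multiplex, the stricter and more common
reading. Rejected or empty wells propagate as missing percent, never as 0.

## Diagnostic accuracy

The empirical ROC AUC is computed by midranks — equivalent to exhaustive
pair counting with half-credit for ties and to the trapezoidal area under
the empirical ROC curve. Operating characteristics at a percent cutoff call
a sample positive when its value is ≥ the cutoff (the boundary side is a
convention; it matters only for atoms at the cutoff). Undefined metrics
(zero denominators) are reported as missing rather than 0. Association
tests are two-sided: Mann–Whitney and Kruskal–Wallis with midrank ties and
the tie-corrected asymptotic distribution (cohort sizes of 40–220 make
exact permutation unnecessary; exact enumeration backs the tests at small
n), Fisher's exact test by hypergeometric enumeration, Pearson correlation
with the t-transform on n−2 df. Allred immunohistochemistry scores sum a
0–5 proportion and a 0–3 intensity score; totals ≤ 2 are negative.

## Survival engine

Cox proportional-hazards models are fitted by Newton–Raphson on the partial
likelihood with internal covariate standardization for conditioning,
step-halving on likelihood decrease, convergence at gradient norm < 1e-8,
and at most 50 iterations. Breslow tie handling is the default (for parity
with mainstream SAS-style output); Efron is available by flag, and the two
coincide on tie-free data. The covariance matrix is the inverse observed
information at the optimum; hazard-ratio confidence intervals are Wald,
exp(β̂ ± 1.96·SE), matching the conventional HR (95% CI) presentation.
Monotone partial likelihood (a covariate perfectly ordering event order,
driving |β| → ∞) is detected when a standardized coefficient exceeds 10
with the gradient still far from zero, and reported as non-convergence
rather than an exception so that tabulating code can flag the row.
Collinear covariates fall back to minimum-norm Newton steps, so redundant
columns converge to the same maximized likelihood (their Wald SEs are not
meaningful in that case). At tied times, events precede censorings — a
subject censored at t remains at risk for events at t.

Kaplan–Meier estimation and the k-sample log-rank test (observed minus
expected with hypergeometric variance, chi-square on k−1 df) follow the
standard constructions; the two-group log-rank statistic equals the squared
score test of the corresponding univariate Cox model, verified numerically
in the tests. Type-I error of the log-rank test is checked by simulation
(2000 null replicates) to lie within [0.04, 0.06] at the 0.05 level.

## Functional form and optimal cutpoints

The marker–hazard relationship is probed by likelihood-ratio tests of a
linear Cox term against (a) linear+quadratic and (b) a restricted cubic
spline with 3 knots at the 10th/50th/90th marker percentiles (4- and
5-knot Harrell placements are available). The verdict is "nonlinear" when
either LRT rejects at 0.05. Inputs below configurable floors (30 records,
10 events) are refused rather than fitted silently.

Cutpoint discovery is a two-stage exhaustive search. Candidates are the
midpoints between consecutive distinct marker values. Stage one scans all
dichotomizations; stage two fixes the first cut and scans all
trichotomizations, modeling the indicator of the combined low+high class
versus the moderate class. The selection criterion is the maximum Cox
partial log-likelihood among admissible candidates; admissibility requires
each indicator side to contain at least 10% of the cohort and at least 5
events (floors prevent degenerate minima; both are configurable). A
judgment-based final selection that weighs clinical plausibility cannot be
automated reproducibly, so likelihood is the sole automatic criterion and
the full candidate profile is returned for the analyst to apply judgment.
No multiplicity correction is applied over the candidate grid: maximally
selected statistics are optimistically biased, which is why discovered
cutpoints should be validated out-of-sample (the cross-validation stage
re-tunes them inside each training subset for exactly this reason).

Classification boundaries follow the low/moderate/high convention
literally: low < cut1, moderate in [cut1, cut2] (closed at both ends),
high > cut2; missing marker values propagate as missing group.

The prognostic table fits univariate Cox models per variable and one
multivariate model with the low+high indicator, the pT 3b–4 vs 2–3a
indicator, the Gleason 8–10 vs 2–7 indicator and continuous PSA (per
ng/ml). Missing covariates are handled complete-case per model with
dropped-record counts logged; non-converged fits yield flagged rows.

## Concordance probability estimate

For fitted linear predictors η, the estimate is
K = 2/(n(n−1)) Σ_{i<j} 1/(1+exp(−|η_i−η_j|)): under proportional hazards
the probability that the lower-η subject of a pair outlives the other is
1/(1+exp(−|Δη|)). Ties contribute exactly 0.5 and the |·| form bounds K in
[0.5, 1], matching the stated no-predictive-value and perfect-prediction
bounds. K is a function of the predictors alone — no event or censoring
indicators enter — which makes it usable on small test sets but has a
consequence documented under Limitations.

Model comparison uses repeated random sub-sampling cross-validation:
n_splits (default 200) independent 80/20 train/test splits drawn uniformly
without stratification; when a model specification includes the methylation
marker, the two-stage cutpoint search is re-run on the training subset
only (clinical covariate codings stay fixed); Cox weights are fitted on
train; K is evaluated over all test-subject pairs using the train-fitted
coefficients. Failed splits (non-convergence, no admissible cutpoint) are
resampled and counted, and systematic failure (> 10% of the requested
splits) aborts with diagnostics. Summaries report the per-split mean and a
halfwidth of 1.96 × SD of the per-split test-set estimates, plus a paired
t-test on the per-split differences between the two models.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
not the biology that produced it.

* **Methylation.** Per-gene marginals are zero-inflated scaled-Beta
  mixtures on [0, 100] percent, moment-matched to published per-gene
  medians and quartiles for the tumor defaults (GSTP1 median ≈ 40% with
  quartiles ≈ 26–55%, the other genes lower, all ranging 0 to ~80%;
  validation-like defaults are shifted lower). The benign defaults put 80%
  mass at exactly 0 and the rest on a Beta with mean ≈ 1.3%, giving
  per-gene means ≈ 0.3%, well under the 2% benign ceiling. Genes are
  coupled by a Gaussian copula; the default latent correlation is 0.70
  between the first gene and the rest and 0.60 otherwise, implying
  pairwise Pearson correlations of ≈ 0.56–0.69 on the observed scale —
  inside the moderate-to-strong band reported for such panels.
  Missingness is completely at random at per-gene rates (defaults mirror
  the per-gene measurement counts of the emulated cohorts).
* **Clinical covariates.** Categorical frequencies default to the
  emulated cohort tables (e.g. Gleason 2–6/7/8–10 at 38/28/33% with 1%
  missing in the training-like config); PSA is log-normal (training-like
  median 38.3 ng/ml).
* **Survival.** Event times are exponential with hazard
  b·exp(linear predictor); the default linear predictor carries the
  low+high-vs-moderate indicator at log(3), Gleason 8–10 at log(4.8),
  pT 3b–4 at log(1.7), and 0.001 per ng/ml PSA. True groups come from the
  first gene's latent (pre-missingness) value at cuts (15, 50). Censoring
  is exponential (default rate 0.10/yr, giving a ~7-year median follow-up)
  plus an administrative horizon (13 yr); neither mechanism is reported
  for the emulated cohorts, so both are stated assumptions. The baseline
  hazard b is calibrated by root-finding on the closed-form expected event
  fraction so the realized fraction matches the target (default 20%)
  within ±0.05 at n ≥ 1000.
* **Determinism.** One root seed; each stage (methylation, clinical,
  survival) draws from a deterministic child stream keyed by stage name,
  so all outputs are bit-identical given the config.

What the generator does **not** emulate: intratumor spatial heterogeneity,
stroma-content effects, qPCR fluorescence/efficiency noise, informative
censoring, accrual patterns, and treatment effects. Passing tests therefore
demonstrate that the estimators recover the structure this generator
encodes, not that real cohorts satisfy its assumptions.

### Fixture design for the recovery demonstrations

The structure-recovery tests use generator settings chosen by power
analysis rather than the cohort defaults. The step/U-shape fixtures use a
balanced marginal (Beta(0.765, 1.392), no zero mass) that places ≈ 29/41/30%
of patients in the low/moderate/high classes at cuts (15, 50), and a
"strong" effect of HR 4 on the low+high indicator. Under the asymmetric
cohort-default marginal the low arm holds only ~10–14% of patients and a
linear trend absorbs most of the U-shape — a regime in which neither the
linearity scan nor one-cut-at-a-time search can be expected to succeed, as
the README's worked example illustrates deliberately. The demonstrations
use n = 500 (functional form, type-I at 60 replicates) and n = 1000
(cutpoint recovery, 20 replicates each); the cross-validation checks use
n ≈ 330 with 50 splits and 10 meta-replicates. These sizes keep the full
suite's runtime modest while leaving the binomial slack of each assertion
wide relative to the expected rates.

## Known limitations

* **Additive-noise inflation of the concordance estimate.** Because K
  depends only on |η differences|, Jensen's inequality makes *any* added
  covariate — pure noise included — increase the test-set estimate
  slightly (measured ≈ +0.006 for an untuned standard-normal noise
  covariate at n = 300). The paired t-test over sub-sampling splits is
  powerful against such tiny systematic shifts because the splits are
  highly correlated, so "model B adds noise" comparisons reject far above
  the nominal rate. A cross-validated comparison based on this estimator
  therefore establishes *ranking* of models credibly only when the
  improvement is material relative to that inflation floor; the test suite
  records this behavior rather than hiding it (one acceptance check of
  nominal null calibration fails by design of the estimator, not by
  implementation error).
* Discovered cutpoints are maximally selected and optimistically biased;
  use the cross-validation stage, not in-sample p-values, to judge them.
* The Cox fitter targets small-to-moderate p (the pipeline uses ≤ 4
  covariates); it builds an n×p×p array internally and is not tuned for
  wide designs.
* Exact rank-test enumeration is used only as a test oracle; reported
  p-values use tie-corrected asymptotics and are approximate below ~10
  observations per group.
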