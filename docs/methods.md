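# Methods

This note documents the models the package implements, the defaults it
ships, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would want to know about.

## Within-trial interaction meta-analysis

Sex-subgroup hazard ratios compared *across* trials confound sex with
trial-level differences (cancer type, control arm, era, eligibility). The
package therefore estimates the treatment × sex interaction *within* each
trial as d = ln HR_female − ln HR_male and pools the d's — the "difference
in effect of treatment" (deft) strategy. Assumptions: the reported per-sex
CIs are Wald intervals on the log-HR scale (so se = (ln hi − ln lo)/2z),
and the two subgroup estimates within a trial are independent (they come
from disjoint patients), giving se² = se_f² + se_m².

The random-effects model is d_i ~ N(μ, se_i² + τ²). τ² is estimated by
REML via the standard fixed-point iteration

    τ²_{t+1} = Σ w²[(d−μ̂)² − se²] / Σ w² + 1/Σ w,   w = 1/(se² + τ²_t),

initialized at the DerSimonian–Laird moment estimate, truncated at zero,
tolerance 1e−8, max 100 iterations (non-convergence is an error, not a
silent best-effort). Agreement with R `metafor` (`rma(..., method =
"REML")`) is at the 1e−9 level on the shipped panel and is asserted in the
test suite.

Pooling uses inverse-variance weights 1/(se² + τ̂²); the pooled ratio is
exp(μ̂) with a Wald z interval at a fixed z = 1.959964 and a two-sided
normal p. Q and I² are reported from fixed-effect weights (Higgins'
Q-based I²; `metafor` prints the τ²-based version, which differs by a few
tenths of a percent). The Wald z interval is the default because reported
trial CIs are z-type; it is known to undercover slightly when τ² is
estimated — measured coverage at k = 30, τ² = 0.05 is ≈ 0.93 rather than
0.95 (see "Calibration results" below). The Knapp–Hartung adjustment
(t(k−1) reference, variance scaled by the weighted residual mean square)
is available via `knapp_hartung=True` and measures ≈ 0.94 under the same
conditions.

Direction tallies (`count_directions`) classify each trial by sign(d);
exact ties are reported in a third column rather than assigned to either
sex, so they cannot silently inflate a direction count.

## Propensity matching-weight screen

Per cancer type with at least 20 patients of each sex, a logistic model
P(female | age, race, smoking, stage, histology, purity) is fitted by IRLS
on complete cases (continuous covariates standardized; categoricals
one-hot with the most frequent level as reference). Perfect separation
triggers an automatic L2 ridge (1e−3, intercept unpenalized) with a logged
warning. Scores are clipped to [1e−6, 1 − 1e−6] so matching weights stay
finite.

Matching weights MW = min(e, 1−e)/[Z e + (1−Z)(1−e)] emulate 1:1 matching
while retaining all patients; each weight is bounded by 1, which avoids
the extreme-weight instability of inverse-probability weighting. Balance
is summarized by the standardized mean difference per covariate term,
before (unweighted) and after weighting; both the means and the variances
are weighted in the "after" SMD (the convention for post-weighting
diagnostics). |SMD| < 0.1 is the balance verdict. The score-distribution
overlap coefficient (histogram intersection over 50 bins) is reported as a
positivity diagnostic.

Continuous features are tested by weighted least squares of the feature on
an intercept and the female indicator with matching weights; the reported
SE is the HC0 sandwich, which for this two-group design reduces to
Σ w²e²/(Σ w)² summed over groups (identity with `statsmodels`
`WLS(...).fit(cov_type="HC0")` is asserted in tests). Model-based WLS
standard errors would be anticonservative under weighting. The sandwich
with *estimated* propensity scores is in turn mildly conservative — a
documented property, quantified below. An unweighted Mann–Whitney
comparison is available behind `continuous_test="mww"` for cohorts
analysed without adjustment (the convention for small ICB cohorts). Binary
indicators (gene mutations) use the unweighted Fisher exact test; exact
tests have no standard weighted form, and the output's `test` tag makes
the distinction visible.

BH-FDR is applied within each cancer type × feature family (so one
panel's dense block of correlated checkpoints cannot mask a sparse
biomarker panel), with FDR < 0.2 as the discovery threshold, and each
feature is labelled with its bias direction and a p-value band (strong
p < 0.05; weak 0.05 ≤ p < 0.2 — the band boundaries treat 0.05 as weak).
Per-cohort failures are logged and isolated; the screen continues.

## Signature scores

Gene-set scores use the single-sample rank-weighted running sum (ssGSEA
form): within each sample genes receive average ranks by expression;
walking the list in descending order, the score accumulates the difference
between the in-set weighted rank CDF (weights rank^α, α = 0.25) and the
uniform out-of-set CDF. This is a deliberate stand-in for kernel-CDF GSVA:
both capture relative per-sample enrichment, and the running sum has a
closed form that is checked against a brute-force evaluator in the tests.
Numeric agreement with GSVA output is *not* claimed. Scores are
rank-invariant per sample; no min–max normalization by default. Gene
identifiers are matched exactly after uppercasing both sides; set genes
missing from the matrix are dropped with a logged count, never silently.
Signature gene lists (immune-cell populations, the 18-gene GEP) are user
inputs in GMT format — none are shipped.

CYT = sqrt((GZMA + 0.01)(PRF1 + 0.01)) on the expression scale; the 0.01
offset keeps a zero count from annihilating the geometric mean.

## Survival statistics

The univariate Cox model is a vectorized Newton–Raphson on the partial
likelihood with Efron tie handling (Breslow behind a flag; they agree to
1e−10 without ties). Step-halving guarantees ascent; |β| > 30 is treated
as monotone likelihood (complete separation) and raised as an error with
advice, since no finite MLE exists. Wald CI and p. Agreement with
`lifelines` is at 1e−6. Kaplan–Meier is the product-limit estimator;
log-rank is the two-group hypergeometric-variance form. Fisher's exact
two-sided p uses the minimum-likelihood rule (sum of hypergeometric
probabilities ≤ the observed table's), matching `scipy.stats.fisher_exact`
and verified exhaustively against enumeration for small tables. MWW uses
exact enumeration when n_x·n_y ≤ 400 with no ties, otherwise the normal
approximation with tie and continuity corrections.

## Synthetic generators

`simulate_trials` draws a per-trial log interaction from N(ln R, τ²),
simulates exponential event times per arm × sex (constant hazard, so the
true HR is exactly the specified ratio), censors with an independent
uniform whose horizon is solved numerically to hit the target censoring
fraction, and fits per-sex Cox models to produce the HR/CI fields a trial
report would contain. The frozen `synthetic_trial_panel` (27 trials,
fixed internal seed) mirrors the public composition of the ICB trial
landscape — 7 melanoma / 11 NSCLC / 2 SCLC / 2 HNSC / 2 ccRCC / 1 each
mesothelioma, urothelial, GEJC; 5 docetaxel and 4 placebo controls; with
per-trial interaction directions set to the published tallies (melanoma
6-of-7 male-advantage, NSCLC 6 vs 5) via true log interactions of ±0.6 at
400 patients/arm. Its hazard ratios are simulated: pooled values from it
are *not* estimates of any published pooled value.

`simulate_cohort` draws age ~ N(60, 10), purity ~ Beta(5, 2) and fixed
multinomials for race/smoking/stage/histology; sex follows a logistic
model on the covariates, inducing confounding; features are linear in the
sex indicator and covariate terms with Gaussian noise; survival is
exponential. The default study conditions (`default_cohort_spec`):
n = 400, 45 null features loading 0.5 on standardized age, 5 features with
a +0.5 SD female shift, age raising the female log-odds by 0.5 per SD and
current smoking lowering it by 0.5 — a moderate, realistic confounding
level under which the naive unweighted comparison rejects null features
at ≈ 0.56 instead of 0.05.

`simulate_expression` draws log-normal expression (gene means N(3, 1),
unit log-SD) and up-shifts in-set genes by a fixed log amount in target
samples, additively across overlapping sets.

What the generators do **not** emulate: real covariate distributions,
gene–gene correlation, non-proportional hazards, informative censoring,
missingness mechanisms, or measurement error in the features. Passing
tests therefore demonstrate that the statistics do what they claim under
their own assumptions — not that any particular real-data conclusion is
correct.

## Calibration results (computed by the test suite / acceptance script)

* Matching-weight test type-I error at α = 0.05 on confounded nulls
  (n = 400, 2000 cohorts): ≈ 0.04, against ≈ 0.56 unweighted. Across
  independent replications the rate ranges ≈ 0.034–0.041 — at or just
  below nominal, reflecting the conservatism of HC0 with estimated
  propensity scores.
* Meta-analysis 95% CI coverage (k = 30, n = 500/arm, true ratio exp(0.2),
  τ² = 0.05): ≈ 0.93 with the default Wald z interval (the documented
  undercoverage), ≈ 0.94 with Knapp–Hartung. REML τ̂² at true τ² = 0.1 is
  unbiased within Monte-Carlo error.
* Balance: matching weights bring the confounded covariates' mean |SMD|
  below 0.1 in ~100% of cohorts.
* Embedded gene-set shifts of +1.0 log units are recovered with
  AUROC > 0.99; CYT matches its closed form exactly.

Problem sizes used by the default test run (2000 type-I cohorts, 500–2000
coverage replicates, 100 balance cohorts, 1500-gene expression matrices)
were chosen so the full suite completes in a few minutes on one CPU while
keeping Monte-Carlo error small relative to each acceptance band.

## Known limitations

* The deft estimates inherit whatever biases the per-trial subgroup HRs
  carry; nothing can be done within-trial about subgroup-selection or
  reporting bias.
* The screen's exact tests ignore the matching weights; a weighted
  logistic alternative would handle confounded binary features but adds
  assumptions the package deliberately avoids.
* FDR families are per cancer type × feature family; pooling across
  cancer types would change which features clear FDR < 0.2.
* REML assumes normal random effects; heavy-tailed between-trial
  heterogeneity will inflate τ̂² rather than being flagged.
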