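# Methods

This note documents the statistical procedures `ratioscreen` implements,
the synthetic-data model used to exercise them, the numerical choices, and
the limitations a user should know before trusting results on real data.

## Quality control

**LOD rule.** A metabolite is removed when the fraction of samples below
its limit of detection *or missing* is strictly greater than the threshold
(default 0.10). "Below LOD" and "missing" are pooled deliberately: targeted
assays usually report sub-LOD measurements as missing or as unreliable
numbers, and pooling is the conservative reading. The rule is strict — a
metabolite at exactly the threshold is retained — and idempotent. The mask,
not the stored value, drives the rule, so files that report numeric sub-LOD
values are handled identically to files with blanks.

**Imputation.** Remaining masked/missing cells are replaced by the
metabolite's mean over observed cells. Observed cells are never modified,
so each column's observed mean is preserved exactly. Imputation happens
before Z-scoring and ratio construction (ratios need complete columns);
mean imputation shrinks column variance, which slightly inflates the
Z-scores of observed values — acceptable at the low missingness the LOD
rule leaves behind (≤ 10% per metabolite).

**Batch check.** PCA on the column-standardized matrix; the batch statistic
is the one-way ANOVA p-value of batch label on PC1 scores, flagged at
p < 0.05. This operationalizes the usual visual "no batch clustering"
inspection as a reproducible test; it detects location shifts along the
dominant variance axis, not arbitrary batch artefacts. No batch
*correction* is provided: the intended use is to verify absence of batch
structure before an uncorrected analysis.

**Replicate CVs.** Assay precision from repeated measurements: CV per
(metabolite, sample) = sample SD (n−1) / mean, averaged across samples per
metabolite. With very few replicates the sample-SD estimator is biased low
(factor c₄(n), e.g. 0.80 at n = 2), which is the behaviour of the plain
estimator practitioners report; no small-sample correction is applied.

## Outcome

Percent cartilage-volume change at 24 months per knee compartment. Two sign
conventions exist: the loss formula (baseline − follow-up)/baseline·100
(loss positive) and the signed change (follow-up − baseline)/baseline·100
(loss negative). Cohort descriptive tables in this literature print
negative changes for loss, so `signed_change` is the default; the two are
exact negatives and both are available. Units cancel, so the measure is
invariant to rescaling both volumes.

## The ratio screen

**Standardization.** z = (x − mean)/SD with the sample SD (n−1). Columns of
the result have mean 0 and SD 1 to 1e−10.

**Ratios.** Every ordered pair of distinct metabolites (a, b) yields
r = z_a / z_b; a/b and b/a are kept as distinct reaction directions
(m(m−1) ratios; unordered mode m(m−1)/2 is available). The ratio of
Z-scores is implemented literally. It is heavy tailed — essentially
Cauchy-like, because the denominator Z-score can be arbitrarily close to
zero — which has real consequences: the ratio has no finite population
variance, single subjects can dominate a regression, and sample moments of
ratio columns are unstable across cohorts. A configurable guard ε flags
cells with |z_den| < ε as degenerate and excludes them from that pair's
fit; the default is ε = 0 (only exact zeros are excluded), reproducing the
literal definition. An alternative scheme (`ratio_then_zscore`: raw ratio
first, Z-score per pair afterwards) is provided for sensitivity analysis
but is not the default.

**Regression.** Per ratio, OLS of percent volume change on the ratio,
unadjusted and adjusted for the seven clinical covariates (age, sex, BMI,
diabetes, hypertension, dyslipidemia, treatment arm; binary codings
female = 1, licofelone = 1, flags 0/1). Inference is t-based with n−p−1
residual degrees of freedom: two-sided p, 95% CI at t quantiles. The hot
path residualizes the outcome and all ratio columns against the base
design with a single QR decomposition (Frisch–Waugh–Lovell), which is
algebraically identical to fitting each full model separately; tests
verify agreement with explicit normal-equations inference and with
statsmodels OLS to 1e−8. Pairs with degenerate cells fall back to
per-pair complete-case fits with `n_used` recorded. Subjects without an
outcome row for the requested compartment drop out as incomplete cases.

**Multiple testing.** Family-wise control by Bonferroni: significance at
p ≤ α/n_tests with n_tests the number of pairs actually fitted in the run
(an override is available to reproduce an externally fixed divisor, e.g. a
published 21,952 — note that for m = 152 the ordered count is
152·151 = 22,952 and the unordered count 11,476; neither equals 21,952, so
the pair mode is configurable and the count is always reported rather than
silently reconciled). Results are ranked by unadjusted p ascending, ties
broken by |β| descending then pair id — output order is deterministic.

**Post-hoc power.** Monte-Carlo: replicate the generative model (ratio of
standardized correlated normals, or a plain normal regressor), fit, count
p ≤ α. A closed-form normal approximation Φ(|β|/SE − z₁₋α/₂) is provided;
at metabolome-wide α (~1e−6) and n in the low hundreds it overstates power
because the t critical value exceeds the normal one — the simulation is
the authoritative number.

## Biomarker analyses

Pearson r with two-sided t p-values (n−2 df). Covariate adjustment is the
partial correlation by double residualization: regress both variables on
the covariates (with intercept) and correlate the residuals; p uses
n−p−2 df. This equals the inverse-correlation-matrix definition (tested)
and reduces exactly to the unadjusted correlation for an empty covariate
set. The extreme-decile comparison ranks subjects by the ratio (stable
sort, ties by subject id), takes the bottom and top fraction (default
10%), intersects each with marker availability — so group sizes may be
unequal — and applies Student's equal-variance t test (Welch behind a
flag). The comparison is invariant to monotone transforms of the ranking
variable.

## qPCR quantification

Livak 2^−ΔΔCt: triplicate Cts are averaged; ΔCt = Ct(target) −
Ct(reference, default GAPDH) per sample; ΔΔCt subtracts the calibrator's
ΔCt (the calibrator must be flagged explicitly — exactly one sample); RQ =
2^−ΔΔCt, so the calibrator's RQ is identically 1 and plate-wide Ct shifts
cancel. Triplicates with range > 0.5 cycles are flagged in the log (a
common lab QC heuristic) but kept. Group comparisons use Student's t on
natural-log RQ; the reported percent increase is the geometric-mean ratio
minus one, consistent with the log-scale analysis (arithmetic scale behind
a flag). Cytokine correlations are Pearson on log RQ with t-based p by
default and a seeded permutation option (10,000 shuffles). Primer
efficiency comes from the dilution-series standard curve: OLS of Ct on
log10 input; efficiency = (10^(−1/slope) − 1)·100, 100% at slope
−1/log₁₀2 ≈ −3.3219. Efficiency-corrected (Pfaffl) quantification and
multi-reference normalization are out of scope.

## Synthetic-data model

The generator emulates a two-arm 24-month knee-OA progression study so the
pipeline's operating characteristics can be measured. All generators are
pure functions of (parameters, seed); a master seed fans out to
per-component streams by hashing the component name into the seed
sequence, so outputs are byte-stable and adding a component never perturbs
the others.

**Panel.** 186 metabolites named after a p180-style kit: 40
acylcarnitines, 22 amino acids, 18 biogenic amines, 1 hexose sum, 105
phospho- and sphingolipids. LODs are drawn log-uniformly per class over
typical assay ranges.

**Concentrations.** Log-normal per metabolite: log x = μ_j + σ(√ρ·U_class
+ √(1−ρ)·E), with per-metabolite levels μ_j drawn around class means
(amino acids ~100 μM, hexose ~4.5 mM, lipids ~20 μM, acylcarnitines and
amines sub-μM), subject-level log-SD σ = 0.4, and exchangeable
within-class correlation ρ = 0.3. Log-normality is the standard model for
concentration data and guarantees positivity; the block-exchangeable
correlation reproduces the strong within-class co-regulation of lipid
panels without fitting a full covariance.

**Censoring.** The default plan censors the round(f·n) lowest values of
each selected metabolite (the LOD mechanism): 34 metabolites get fractions
in [0.12, 0.35] (above the 10% rule at n = 139), 30 get light censoring in
[0.005, 0.09] (retained), and the rest — including the analysis-critical
named analytes — are untouched. The counts are deterministic for any seed,
so the QC stage always retains exactly 152 of 186 metabolites under the
default conditions. Censored cells are stored as missing and flagged
below-LOD (a censored value is, by definition, not reliably quantified);
round-trips through CSV therefore carry an explicit mask file, and reading
a concentrations file without a mask falls back to the value < LOD rule.

**Cohort.** Arm sizes 69 (licofelone) and 70 (naproxen); ages
N(61, 9²)/N(61, 8²), BMI N(32.3, 5.8²)/N(31.2, 5.7²), female fractions
0.74/0.61, comorbidity flags Bernoulli(0.2).

**Outcomes.** Baseline volumes are normal per compartment and arm (lateral
6095.5 ± 1594.7 / 6364.1 ± 1822.0 mm³; medial 5523.0 ± 1503.3 /
5690.0 ± 1640.0). Percent change is linear: compartment intercept
(naproxen lateral −6.40%, medial −8.25%), treatment effect (+1.70% /
+0.67% for licofelone), small covariate effects (so adjusted and
unadjusted fits differ detectably), plus β·(ratio of Z-scores) for the
planted pair (default lysoPC a C18:2 / PC ae C44:3, β = −0.21 on the
lateral compartment) and N(0, residual_sd²) noise. The default residual SD
of 3.6% is calibrated so the total lateral-change SD — residual plus the
planted ratio term (≈0.21·sd(ratio) ≈ 1.8 in a typical cohort) plus
covariate contributions — lands near the target arm SD of ≈4.16%. The
follow-up volume is derived as V₀(1 + Δ%/100), so the progression formula
recovers the linear predictor *exactly*. Because the ratio regressor is
heavy tailed, the linear predictor can rarely (≲0.1% of cells) fall at or
below −100%, which no positive volume can represent; such rows are
omitted (a lost follow-up) rather than truncated — truncating them would
bend the model precisely at its highest-leverage points and visibly
degrade confidence-interval coverage. Consequently the planted ratio term
has no finite mean or variance: arm means of the *lateral* change are only
interpretable conditionally, and the generator's moment fidelity is
checked on the medial compartment (no planted term) and with the effect
switched off.

**Biomarkers.** Marker = mean + sd·(r·ratio_Z + √(1−r²)·noise) with the
ratio standardized in sample, so sample correlations concentrate near the
targets (COMP 0.32 at both timepoints, MMP-1 0.26 at follow-up, LCAT
−0.10) despite the ratio's heavy tails.

**qPCR.** A latent log2-RQ vector per sample for (PLA2G5, IL-6, TNF-α,
IL-1β) is multivariate normal with SD 0.9 cycles and a target correlation
matrix (PLA2G5–IL6 0.63, –TNFa 0.57, –IL1b 0.27; IL6–TNFa 0.78; remaining
cytokine pairs 0.45), nearest-positive-definite corrected if needed. The
target gene's latent mean shifts by log₂(fold) in the OA group (default
fold 1.85, i.e. +85%); cytokines shift mildly (log₂ 1.3). Ct = reference
Ct (N(18, 0.7)) + ΔCt + N(0, 0.15) replicate noise; triplicates per gene;
group sizes default to 32 OA vs 16 control; the first control sample is
the calibrator.

**What the generator does not emulate.** Real panels have non-exchangeable
correlation, batch effects, non-log-normal analytes, LODs coupled to
concentration scale, missingness not caused by LOD, and measurement error
in the outcome (MRI segmentation noise); treatment here affects only the
outcome mean, not the metabolome. Passing tests therefore demonstrate that
the *estimators and decision rules* behave as designed under their own
model — unbiasedness, CI coverage, FWER control, deterministic QC counts —
not that real cohorts will yield any particular discovery.

## Numerical and design choices

- OLS via QR; rank checked before fitting, collinear columns named in the
  error. p-values floored at the smallest positive double so reported
  p ∈ (0, 1].
- Exact-fit designs (zero residual) report SE = 0 and a point CI.
- CSV serialization uses 12 significant digits — lossless round trips at
  1e−11 relative for every table.
- Degenerate ratio cells (denominator Z within the guard of 0) are NaN in
  the ratio matrix and excluded per pair; `n_used` records the complete
  cases of each fit.
- Problem sizes used by the test suite: the full-scale screen runs once at
  m = 152 / n = 139 (22,952 ordered pairs, unadjusted + adjusted, a few
  seconds vectorized); error-rate and recovery suites use 200–400
  replicate seeds at n = 139 with reduced panels (m = 20) where the full
  panel adds nothing to the property under test.
- The t-approximation is used for correlation p-values; an exact
  permutation option exists where small samples warrant it.

## Known limitations

- The ratio-of-Z-scores screen inherits the heavy-tail pathology discussed
  above; with the guard off, a single subject with near-zero denominator
  Z-score can dominate a pair's fit. The guard ε and the
  `ratio_then_zscore` scheme exist for sensitivity analysis; results that
  survive neither should be treated cautiously.
- Mean imputation before standardization understates variance for censored
  metabolites; alternatives (half-LOD substitution, censored-likelihood
  estimation) are not implemented.
- The PCA batch statistic only screens PC1; subtler batch structure needs
  dedicated tooling.
- Bonferroni over tens of thousands of strongly correlated ratios is very
  conservative; no FDR or effective-number-of-tests alternative is
  provided, by design.
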