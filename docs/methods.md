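# Methods

This note documents the models, conventions and numerical choices behind
`acspredict`, in the spirit of the methods documentation of packages like
statsmodels or msprime: enough detail that a user can judge what the
pipeline assumes, what the synthetic test bed does and does not emulate,
and where genuinely open design choices were resolved.

## The analysis pipeline

The package implements a two-stage prognostic biomarker study on urinary
peptidome profiles measured by capillary electrophoresis coupled to mass
spectrometry (CE-MS). One urine sample yields a deconvoluted peak list of
detections (molecular mass in Da, CE migration time in minutes, signal
amplitude). The stages are:

1. **Peak-list processing** (`peptidome`). Migration times are mapped
   onto a reference time scale by locally weighted linear regression
   (lowess; tricube weights, one robustness iteration, span 0.3 of the
   anchors) fitted on anchor pairs matched by mass (<50 ppm) within a
   coarse 2-minute window. Lowess reproduces affine time distortions
   exactly, which is why a constant shift or a mild linear stretch
   calibrates to numerical precision. Before the fit, anchors whose
   residual from the median trend exceeds 3.5 robust standard deviations
   (MAD-based) are discarded: at catalogue densities of ~2000 peptides a
   detection occasionally sits within 50 ppm of a *different* peptide
   that is undetected in the sample, and such mis-pairs would otherwise
   contaminate both the fit and the reported maximum anchor residual.
   The maximum residual is recorded on the profile and flagged (not
   silently accepted) when it exceeds 0.35 min, the deviation a
   controlled CE run is expected to stay below.

   Amplitudes are then divided by a per-sample scale factor estimated
   from housekeeping peptides — peptides with stable excretion detected
   in essentially every sample — as the slope of the no-intercept
   regression of observed on reference amplitudes
   (`sum(ref*obs)/sum(ref*ref)`). This cancels urine dilution exactly:
   multiplying a profile by any constant multiplies the slope by the
   same constant, so the normalized profile is invariant (tested to
   1e-9 relative). A median-of-ratios estimator is available behind
   `method="median_ratio"`; the two agree exactly on noise-free scaling
   and differ only in their robustness trade-offs. At least 3 detected
   housekeeping peptides are required.

   Detections are clustered onto catalogue peptides when the mass
   deviation is strictly below 50 ppm and the time deviation is within
   the cluster window. The window is a *full relative width* that rises
   linearly from 2% of the migration time at 19 min to 5% at 45 min
   (clamped outside), i.e. a detection matches peptide *p* when
   `|t - t_p| <= width(t_p) * t_p / 2`; widening windows reflect analyte
   diffusion late in the electropherogram. Whether the quoted 2–5% is a
   full or half window is genuinely ambiguous; the full-window reading
   was fixed and is configurable in the matching tolerance. Ambiguity
   between multiple eligible peptides resolves by smallest ppm
   deviation, then smallest time deviation, then lexicographically
   smaller peptide id — fully deterministic and order-independent.
   Multiple detections of one peptide in one sample are summed,
   conserving total signal.

2. **Biomarker discovery** (`discovery`). A peptide is a candidate when
   detected (non-zero normalized amplitude) in at least 70% of cases or
   70% of controls; the boundary is inclusive. Candidates are screened
   with the two-sided Wilcoxon rank-sum test with undetected samples
   entering as amplitude 0 (ties at the bottom, mid-ranks). The exact
   permutation null is used for combined n ≤ 25 without ties — small
   enough to verify against full enumeration — and the
   continuity-corrected normal approximation with tie correction
   otherwise (worst observed exact-vs-approximate gap at n=8+8 is about
   0.011). Benjamini-Hochberg step-up correction is applied over the
   candidates actually tested, and peptides with adjusted p < 0.05 form
   the panel. Whether the significance level applies to raw or adjusted
   p is implicit in most study reports; adjusted p is the default here
   (raw-p mode via `use_adjusted=False`).

   The pipeline excludes housekeeping peptides from candidacy: their
   post-normalization amplitudes are anchored to the reference by
   construction, so offering them to the screen would be circular.

   Each panel record carries the differential excretion (DE): each
   group's product of (mean amplitude over *all* its samples, zeros
   included) × (its own detection frequency); DE is the case/control
   product ratio when cases excrete more, the negative reciprocal when
   controls do, +1.0 on exact equality, and flagged undefined when a
   product is zero. Swapping labels maps DE to −DE.

3. **Pattern scoring** (`classifier`). Samples are embedded as vectors
   of log2 amplitudes of the panel peptides. Undetected (0) is encoded
   as feature 0 — consistent with the zeros-included convention of the
   DE statistic, at the cost of colliding with a detected amplitude of
   exactly 1; a collision-free `log2(a+1)` encoding is available.
   Features are deliberately *not* standardized: the shipped kernel
   width is tied to the raw log2 scale. A soft-margin SVM with RBF
   kernel is fitted with cases as the positive class; the classification
   score is the signed decision-function value (distance to the
   separating hyperplane up to the weight-vector norm). Shipped defaults
   C = 1638.4 and γ = 0.000256 suit a ~75-peptide panel of log2
   intensities; `tune_hyperparameters` re-derives them by stratified
   k-fold (default 5) cross-validated lattice search, ties resolving to
   the smallest C then smallest γ. Models serialize to JSON carrying
   support vectors, dual coefficients and intercept, and a reloaded
   model scores bit-identically because scoring always evaluates the
   kernel expansion directly.

   The composite predictor is a linear combination of the pattern
   score, an externally supplied coronary-artery-disease pattern score,
   and age: default weights 0.2 / 2.6 / 0.15 with decision threshold
   10.256. Weights can be re-derived as the coefficients of a logistic
   regression of case status on the three covariates (Newton/IRLS);
   perfect separation triggers a flagged L2-penalized refit
   (ridge 1e-4) rather than a failure.

4. **Evaluation** (`evaluation`). Score thresholds are chosen by
   maximizing Youden's J = sensitivity + specificity − 1 over midpoints
   between consecutive distinct scores (ties: higher specificity, then
   lower threshold; test-positive means score strictly above the
   threshold). Sensitivity and specificity carry exact Clopper-Pearson
   95% intervals from Beta quantiles. Discrimination on censored
   outcomes uses Harrell's c: over pairs whose event ordering is known
   (the member with the shorter observed time had an event; equal-time
   pairs usable when exactly one member had an event), c = (concordant
   + 0.5·score-tied) / usable. The confidence interval derives from the
   asymptotic variance of Somers' D (c = (D+1)/2) by the per-subject
   cluster delta method; the exact variance options of the original
   somersd software are not recoverable, so this standard estimator is
   used and stated. Kaplan-Meier curves are reported as cumulative event
   percentage 100·(1 − S(t)). Cox regression uses the partial likelihood
   with Breslow tie handling (Newton iterations; Efron behind a switch)
   — under Breslow, duplicating every subject leaves the estimate
   unchanged and halves the squared standard error exactly, which the
   tests exploit as an oracle. Backwards step-down removes the
   least-significant removable covariate while its Wald p ≥ 0.05
   (configurable; biomarker terms can be forced to stay).

   Added predictive value over a base risk model (study centre as
   categorical indicators + the Framingham-type 10-year risk score,
   fitted by logistic regression; quasi-separation again falls back to
   flagged ridge) is quantified by IDI — the change in discrimination
   slope between events and non-events — and the categorical NRI over
   risk classes [0, 0.10), [0.10, 0.20), [0.20, 1]: (P(up) − P(down) |
   events) − (P(up) − P(down) | non-events). Standard errors treat
   events and non-events as independent samples; p-values are two-sided
   z-tests. Exchanging the two models flips the sign of both statistics.

5. **Orchestration** (`pipeline`, `cli`). All model selection — panel,
   SVM, thresholds, composite weights — happens on the discovery split;
   the validation split is scored and evaluated blinded with no
   re-fitting. The run manifest records config hash, per-stage timings,
   output checksums and warnings, and asserts zero sample-id overlap
   between the splits.

## The synthetic cohort generator

`synth` generates the full study: a peptide catalogue, a matched
case-control cohort with censored outcomes, and per-sample peak lists.
Defaults are the study conditions the pipeline is built for: 126 cases
and 126 controls (followed up to 5 years), 2042 catalogued peptides with
75 truly differential and 29 housekeeping, discovery/validation split
2:1 with age- (±5 y) and sex-matched controls.

Detected amplitudes are log-normal: log2 amplitude = peptide base level
(uniform 8–14) + N(0, σ) noise (σ = 1 by default; a quarter of that for
housekeeping, whose excretion is stable) + the planted effect in cases.
The log-normal choice is a modelling convenience — the amplitude law of
real urinary peptides is not established — selected because the pipeline
operates on log2 intensities. Planted effects have configurable mean
magnitude (default 1 log2 unit, sd 0.3) and random sign, mirroring
panels that contain both up- and down-excreted fragments. Detection is
independent Bernoulli per peptide and sample with per-peptide
frequencies uniform over `detect_freq_range` (biomarkers can be pinned
to `biomarker_freq`, housekeeping is always detected); this is the
simplest model matching the "detection frequency" notion of the
frequency filter. Every profile is multiplied by a per-sample dilution
factor, log-uniform in [0.5, 2], which the housekeeping normalization
must remove. Observed masses are jittered within ±15 ppm (strictly
inside the 50 ppm tolerance) and times within ±0.15 of the cluster
half-window (max ≈0.17 min, inside the 0.35-min calibration bound), so
profiles are matchable back to the catalogue by construction; configs
that violate matchability are rejected.

Clinical covariates are drawn per group with cases stochastically older
and higher-risk (blood pressures, BMI, smoking, diabetes, hypertension,
prior cardiac events, lower HDL and eGFR); controls' age and sex are
then resampled from the cases with a small downward age offset,
emulating the nested matched-control selection and guaranteeing that a
full pairing exists. A latent risk score (fixed linear predictor over
the covariates plus noise) drives three things: a synthetic
Framingham-type 10-year risk score in [0, 1] (inverse-logit of the risk
plus Gaussian noise — the pipeline consumes, never computes, this
score), a synthetic coronary-artery-disease pattern score, and the
event hazard. Case event times are drawn from the per-subject
exponential hazard conditioned on occurring before end of follow-up
(inverse-CDF of the truncated exponential; a zero baseline hazard is
rejected as infeasible); controls are censored at follow-up or at an
independent exponential censoring time (rate 0.02/y). The default
baseline hazard 0.1/y puts the conditional mean time-to-event near
2.3 years over a 5-year horizon.

All randomness derives from one configured seed through
stage-keyed `numpy` generator substreams (catalogue, cohort, matrix,
profiles) in documented order; identical configurations reproduce
byte-identical outputs.

**What the generator does not emulate.** Raw spectra, isotope envelopes
and charge states (the pipeline starts from deconvoluted peak lists);
multi-centre batch effects beyond the per-sample dilution factor;
correlated peptide co-regulation (detections and amplitudes are
independent across peptides given the group); non-proportional hazards;
informative censoring; and measurement drift that varies within one
run. Passing tests therefore demonstrate the correctness of the
statistical machinery and the pipeline's selection logic under the
stated generative model, not the clinical performance of any biomarker
panel on real cohorts.

## Problem sizes and runtime choices

The test suite and the acceptance script run the full pipeline at the
study scale (252 samples, 2042 peptides; roughly 15–20 s end-to-end)
and use reduced sizes where a property needs replication: planted-panel
recovery uses 50 seeds at 84+84 samples and 300 peptides with effect
2 log2 units at detection frequency 1.0 and background frequencies
0.1–0.5 (background peptides then essentially never pass the 70%
filter, which is what makes exact set recovery a fair expectation);
null false-discovery calibration uses 40 seeds at 30+30 samples and 400
peptides with no planted effects; Cox parameter recovery uses n = 500
two-group exponential data with true hazard ratio 3. Monte-Carlo
assertions use three-standard-error slack around the nominal value.

## Known limitations

- The SVM score is the decision-function value (functional margin), a
  monotone transform of the geometric distance; thresholds derived on
  one dataset transfer only to scores from the same fitted model.
- The feature encoding of undetected peptides (0 in log2 space)
  collides with amplitude exactly 1; use `log1p` encoding where that
  matters.
- The NRI/IDI standard errors are the classical independent-samples
  estimators; they ignore the sampling variability of the fitted risk
  models themselves.
- `stepwise_cox` inherits the known selection-inference caveats of any
  step-down procedure; it reports its removal trace so the path is
  auditable.
- Comparison of correlated c-statistics (paired DeLong-type tests) is
  out of scope.
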