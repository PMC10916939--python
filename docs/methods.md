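# Methods

## The cognitive age model

Chronological age at each neuropsychological visit is regressed on 20
predictors — 19 test scores (CVLT Trials 1–5, short/long delay free and cued
recall; TMT-A and TMT-B; Stroop in 60 s; FAS; animal and vegetable naming;
Digit Symbol; Logical Memory total; Visual Reproduction I, II and recognition;
Digit Span forward and backward; Boston Naming) plus the session number, which
absorbs practice effects of repeated testing. Predictors are z-scored with the
training-cohort mean and SD; those parameters are frozen and reused verbatim
at prediction time. The response (age, in years) is centered but not scaled.

The regression is partial least squares with a univariate response (PLS1),
computed by the NIPALS recursion. For a single response NIPALS and SIMPLS
give identical predictions, so any conforming cross-decomposition
implementation is a valid oracle; the test suite checks agreement with
scikit-learn's `PLSRegression` to 1e-6. Five components are the default.
Training R² is non-decreasing in the number of components (nested models);
per-component fractions of X-variance and y-variance are both emitted because
the two conventions are easy to conflate.

Every visit is treated as an independent row, both in fitting and in the
bootstrap. This ignores within-participant correlation of repeated sessions —
a deliberate simplification that matches the modelling protocol being
reproduced; standard errors derived from row counts are therefore optimistic,
which is one reason single-seed out-of-sample R² estimates are noisy.

**Bias correction.** Raw predictions over-estimate the age of young
participants and under-estimate the old (regression to the mean). The offset
`Offset = α·age + β` is an OLS fit of raw CAG on age, estimated **on the
training cohort only** and subtracted from every predicted age (training and
test alike). Fitting on training only avoids test-set leakage; on its own
fitting set the corrected CAG is orthogonal to age to machine precision, on
the test set only approximately. Accuracy metrics (Pearson r, R² = 1 −
SS_res/SS_tot, MAE) are reported before correction, since the correction
redistributes rather than reduces error.

**Bootstrap weight stability.** B resamples of session rows (participant-level
resampling available behind a flag), refitting the full model each time.
Because PLS component signs are arbitrary, each resampled component is aligned
to the reference fit by the sign of the dot product of weight vectors before
averaging; z = mean/SD per weight. Resamples in which a predictor loses all
variance cannot be fitted and are skipped and counted rather than imputed;
z is flagged undefined (NaN + mask) where the bootstrap SD is zero.

## Composites and classification

EM and NM composites are equally weighted means of z-scored constituents
(EM: CVLT SDFR and LDFR, Visual Reproduction I/II, Logical Memory total, and
Verbal Paired Associates when present; NM: Stroop, Digit Symbol, TMT-A,
Trails B−A, Digit Span backward, animal and vegetable naming), with timed
measures sign-flipped so higher is always better, re-standardized to unit
variance in the classification pool. An equally weighted z-composite is a
stand-in for confirmatory-factor-analysis composites whose loadings are not
available; an external weight vector can be supplied to emulate them. The
z-parameters come from the 70+ classification pool itself — the same pool
that defines the percentile cutoffs.

Classification uses one index session per participant (the session anchoring
the imaging visit; `first` by default, `latest` available) restricted to
participants aged 70+. The four rules:

| label    | rule                                                        |
|----------|-------------------------------------------------------------|
| SA-CAG   | corrected CAG ≤ 20th percentile of the pool                  |
| SA-EM    | age-regressed EM residual ≥ 80th percentile                  |
| SA-NM    | age-regressed NM residual ≥ 80th percentile                  |
| SA-CVLT  | CVLT long-delay free recall ≥ 14 (integer scale 0–16)        |

Percentiles are linear-interpolation quantiles (the numpy default). With n
distinct scores this selects exactly ⌈0.2·n⌉ members per tail (37 of 184);
ties at the cutoff are all included, so group sizes can exceed that under
ties. Cutoffs are computed once on the full pool and reused everywhere.
SA-ALL is the union of the four groups and TA its complement, so the two
partition the pool. The matched-size reanalysis shrinks each SA group to a
common n, by default keeping each definition's most extreme members
(deterministic rank mode); random subsampling behind a seed is also provided
because either reading of "same number of participants" is defensible.

## Agreement

Pairwise Cohen's κ = (p_o − p_e)/(1 − p_e) over the whole classification pool
(SA vs not-SA per definition), with strength bands poor (<0), slight (0–0.20),
fair (0.21–0.40), moderate (0.41–0.60), substantial (0.61–0.80) and almost
perfect (0.81–1). κ is flagged undefined when both raters are constant and
identical (p_e = 1). Overlap counts cover all 15 intersections of the four
sets plus exclusive ("only") counts.

## Group comparisons

Continuous demographics: Welch t with Satterthwaite df; Cohen's d uses the
pooled SD with (n1−1, n2−1) weights and no small-sample correction.
Categorical demographics: Pearson chi-square with Cramér's V
(V = √(χ²/(n·min(r−1, c−1)))). On 2×2 tables the Yates continuity correction
is applied by default — that convention, not the uncorrected statistic,
reproduces the reported demographic chi-squares — and can be disabled.

ROI outcomes use ANCOVA: OLS of the outcome on group plus covariates (age,
sex, years of education by default; each model re-run without education and
with the scan-to-cognition interval added). The group F uses Type-II sums of
squares, which for a single binary factor with continuous covariates equals
Type III, so the unstated choice is immaterial; partial η² =
SS_group/(SS_group + SS_residual), clamped non-negative against float
cancellation when the reduced model already fits perfectly. With no
covariates the F statistic equals the square of the pooled-variance t
exactly. Hippocampal volume is TIV-adjusted by residualization (OLS residual
of volume on TIV re-centered at the pool mean), not by ratio.

Amyloid utilities: Centiloids via the pipeline-specific affine conversion
CL = DVR × 142.73 − 141.99, reported rounded to the nearest integer;
positivity is strictly DVR > 1.065. BH-FDR is the standard step-up.

## The synthetic cohort generator

Each participant carries a latent general ability `a ~ N(0, ability_sd²)`
(latent unit: ability_sd = 1 by default). A fraction `sa_fraction` of
participants aged 70+ at baseline is drawn from an ability distribution
shifted by `sa_ability_shift`. At session s and age Ω the latent level is

    g = a − age_slope_g·(Ω − 70) + practice_effect·(s − 1)

and each test score is `intercept + loading·(g + ε)` with independent
ε ~ N(0, noise_sd²), sign-inverted for the timed tests (TMT-A/B, floored at
3 s) and discretized to integers 0–16 for CVLT LDFR so the normative rule is
exercisable. Baseline ages are uniform on `age_range`; visits are annual;
session counts are 1 + Poisson(λ) capped at 12, with separate λ for the
training (0.56) and test (3.8) cohorts so the mean sessions per participant
match the emulated cohorts (1.56 and 4.79). Because one latent factor drives
all 19 tests, the population R² of the best linear age prediction has the
closed form

    R² = S / (S + ability_sd² + noise_sd²/19),   S = age_slope_g²·Var(age)

implemented in `theoretical_r2` and inverted by `noise_sd_for_target_r2`.
Defaults (slope 0.076/y, noise 0.8) put R² near 0.45, bracketing the
train/test accuracies the generator emulates. Sex (56% F), education
(N(16.8, 2.2²) years), APOE group (9/66/25%) and family history (33%) are
drawn independently.

ROI outcomes (test cohort only) are Gaussian with a mild age trend plus a
planted standardized effect between the latent-truth SA and TA groups:
by default +0.45 SD hippocampal volume, −0.6 SD entorhinal FTP SUVR
(chosen because it implies partial η² ≈ 0.08 at the emulated tau-subsample
group sizes of 41 vs 73), −0.35 SD inferior-temporal SUVR and **zero**
amyloid (PiB DVR) effect. Hippocampal volume co-varies with TIV so the TIV
adjustment has something to remove; tau-PET values are missing for a random
38% to mirror a tau subsample. Latent truth (ability, SA membership) is
written only to a separate truth table, so no classification stage can read
it. `simulate_roi_groups` provides the same ROI draw at fixed group sizes for
calibration experiments.

What the generator does **not** emulate: test-specific floor/ceiling
psychometrics beyond the CVLT cap and the timed-test floor, dropout or
non-annual visit spacing, correlated residuals between tests beyond the
single factor, covariate-linked group imbalance (synthetic covariates are
independent of SA truth, so ANCOVA adjustment is exercised but never
decisive), or imaging itself. Passing tests therefore demonstrate that the
pipeline's logic and statistics behave correctly under a faithful but
simplified data-generating process — not that real cohorts satisfy the
single-factor model. Ages of late sessions can exceed the configured maximum
by the follow-up length; `age_range` constrains baselines.

## Numerical choices and degenerate inputs

- Quantiles: linear interpolation between order statistics; ≤/≥ boundary
  inclusion so cutoff ties are always selected.
- Zero-variance predictors, constant ages, empty pools, degenerate 2×2
  margins, and both-raters-constant κ all raise (or flag) rather than return
  silent zeros; error messages name the offending column.
- Scores are emitted rounded (3 decimals; ages 2), so "exact" noise-free
  identities hold to ~1e-2 in raw-score space and tests assert accordingly.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical tables and reports.

## Problem sizes

The test suite runs the full generator at its default sizes (293 + 238
participants) where cohort statistics are asserted, and reduced cohorts
(60–80 participants per arm) where only contracts are exercised. Simulation
suites use 10 seeds for R² recovery, 200 replicates for effect-size
calibration, 1,000 for type-I error, and 20 seeds × 200 bootstrap resamples
for weight stability — sizes chosen to keep Monte-Carlo error comfortably
inside the asserted tolerances.

## Known limitations

- Sessions are modelled as exchangeable rows; no mixed-effects modelling of
  within-participant correlation.
- The equally weighted z-composites approximate factor-score composites only
  up to their (unknown) loadings.
- The bias-correction convention (fit on training, applied everywhere) is one
  of several defensible readings; α and β are exposed so alternatives can be
  applied externally.
- Whether per-component variance explained refers to X or y is convention-
  dependent; both are reported.
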