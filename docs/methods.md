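# Methods

## The model

`longlme` models longitudinal trajectories of a standardized biomarker
(hippocampal volume, HV, in the motivating application) across five
clinical groups — stable healthy controls (sHC), controls who later
convert (cHC), stable MCI (sMCI), MCI-to-AD converters (cMCI), and AD at
baseline — with a Gaussian linear mixed-effects model.  For subject *i*
at visit time *t_ij* (years from baseline):

```
y_ij = β0 + β_t t_ij + Σ_g β_g 1[group_i = g] + Σ_g β_gt 1[group_i = g] t_ij
     + β_age age_i + β_sex sex_i + β_apoe apoe_i + β_at apoe_i t_ij + β_icv icv_i
     + b0_i + b1_i t_ij + ε_ij
```

with `(b0_i, b1_i) ~ N(0, G)` and `ε_ij ~ N(0, σ²)`.  Treatment coding
uses sHC as the reference, so each `β_gt` is the atrophy-rate difference
of group *g* relative to stable controls.  Two random structures are
supported: random intercept only ("Model 1", q = 1) and random intercept
plus slope ("Model 2", q = 2, the default).  The fixed-effect design for
five groups has p = 15 columns in a fixed, documented order (intercept,
time, four group dummies, four group-by-time dummies, age, sex, APOE,
APOE-by-time, ICV), so contrast matrices are stable positionally.

Outcome and ICV are z-scored — `(x − mean)/sd` with the sample (n−1) sd
pooled over all records — so that coefficients share a scale.  The
synthetic generator emits data directly on that standardized scale (its
effect sizes are defined there), which is why generated cohorts carry
`standardized=True`; `standardize_fisher_z` exists for raw imported data
and records its constants for back-transformation.

## Frequentist estimation

REML (default) or ML.  The scaled covariance Ψ = G/σ² is parameterized by
the log-Cholesky transform (logs of the diagonal, free off-diagonal), and
the criterion is profiled analytically over β (GLS) and σ².  Per-subject
Woodbury/Sylvester identities reduce each criterion evaluation to batched
closed-form 2×2 solves on per-subject cross-products, so a full-cohort
evaluation costs well under a millisecond and the removal simulations can
afford a fresh REML fit at every step.

Optimization: Nelder–Mead over the 1- or 3-dimensional θ (bounds ±10 on
log-scales), followed by a Powell polish, with criterion tolerance 1e-9.
Warm starts (used inside the removal loops) restart a tight simplex at the
previous optimum; a dedicated test confirms warm and cold starts agree to
1e-8 on the criterion.  Boundary fits (a random-effect variance driven to
zero) are returned flagged `singular=True` rather than raised: compromised
datasets near the estimability limit produce them routinely, and the
removal procedures treat them as valid fits.

AIC dialect: for a REML fit, `AIC = −2·ℓ_REML + 2(p + k_var)` with
`k_var` the number of variance parameters including σ² (4 for Model 2, 2
for Model 1), matching the convention of the standard R mixed-model stack;
the ML-based AIC is exposed alongside.  The random-structure comparison
uses the likelihood-ratio test with df = 2 and no boundary correction,
which is conservative (the test suite verifies rejection ≤ nominal under a
zero-slope-variance null).

## Satterthwaite F-tests

Seven named contrasts on the group-by-time slopes are tested with Wald F
statistics.  The denominator df uses the Satterthwaite moment-matching
construction: the covariance of the variance parameters is the inverse
observed information of the (restricted) criterion at the optimum
(central finite differences, relative step 5e-4 on the unconstrained
scale); for each single-df component of the contrast, the delta method
gives `Var(v_i)` and `df_i = 2 v_i²/Var(v_i)`; components combine through
`E = Σ_{df_i>2} df_i/(df_i−2)` and `df_den = 2E/(E−r)`, falling back to
`n − p` if `E ≤ r`.

One deliberate canonicalisation: the contrast matrix is first replaced by
an orthonormal basis of its row space (SVD).  The F statistic is invariant
to any invertible row mixing anyway; the canonicalisation makes the
*denominator df* exactly invariant to row scaling and orthogonal
re-mixing, which the raw eigen-procedure is not.  Single-df contrasts are
unaffected, and on such contrasts the df agrees with R's `lmerTest` to a
fraction of a percent (cross-checked in the suite via `Rscript`); joint
contrasts agree with `lmerTest::contest` to numerical precision on the
datasets tested.

Contrast scope: the default tests group-by-time slope terms only, so the
frequentist battery and the Bayesian credible-interval rules address the
same estimands (rate-of-change differences).  A joint level-plus-slope
scope is available via `scope="slope_and_level_terms"`.

Multiplicity: Bonferroni with n = 7 always, even when only one contrast is
testable (two-group datasets), so thresholds are comparable across dataset
variants.  The removal-loop stopping rule deliberately uses the single
named contrast *uncorrected* at α = 0.05.

Calibration caveat: the plug-in Wald F with Satterthwaite df is known to
be mildly liberal for joint contrasts in small samples.  At ~150 subjects
with the default generative conditions (where ~8% of null REML fits hit
the slope-variance boundary) the omnibus test's type-I error is near
0.05–0.07; it tightens toward 0.05 by ~300 subjects.  This matches the
reference implementation exactly and is a property of the method, not of
this implementation.

## Bayesian estimation

Blocked Gibbs sampling with conjugate full conditionals: normal prior on
β (sd 10 per coefficient on the standardized scale), inverse-gamma(2, 0.5)
on σ², inverse-Wishart(df 4, scale 0.1·I) on G.  The sampler draws
(β, b) as one block — β from its conditional with the random effects
integrated out (its moments come from the same per-subject Woodbury
identities as the REML engine), then b | β.  The naive `β | b` update is
exact but mixes pathologically slowly here, because per-subject effects
can absorb group-level fixed effects and the chain then random-walks in a
ridge; the collapsed draw removes that pathology while targeting the same
posterior.  With it, effective sample sizes are close to the number of
draws.

Defaults: 4 chains × 2000 iterations, 1000 warmup, thin 1, overdispersed
starts around the OLS solution.  Convergence is summarised by split-R-hat
and an FFT-based effective sample size with Geyer's initial-positive
truncation (cross-checked against `arviz` in the suite).  Posteriors are
returned with a non-convergence flag when any R-hat exceeds 1.05.

Inference uses central 95% credible intervals (2.5th–97.5th percentiles).
Decision rules: a vs-reference effect is "significant" when its CrI
excludes zero; two non-reference groups differ when their CrIs are
disjoint (with the CrI of the posterior difference reported alongside —
the overlap rule is strictly more conservative, a property the suite
checks); the omnibus five-group question is operationalised as "at least
one group-by-time CrI excludes zero", a composition of the two stated
rules that the agreement report records explicitly.

Prior influence: with the default priors the inverse-Wishart scale is a
noticeable fraction of the posterior scale for the (small) slope variance
below ~100 subjects, which widens CrIs and makes the contains-zero rule
conservative there.  Calibration experiments in the acceptance suite
therefore use cohorts of a few hundred subjects, where the data dominate.

## Removal simulations

*Minimum-N*: remove one uniformly random subject (all visits), refit by
REML (warm-started), re-test the named contrast; when p > 0.05 first
occurs, keep the previous dataset as the borderline-significant database.
*Missing timepoints*: remove one uniformly random subject-visit record;
before each refit check the estimability rule `n_obs > q·N` (N×2 for the
intercept-and-slope model) and stop on either p > α or an estimability
violation, returning the previous dataset.  By default a subject's last
remaining record is not removable, so visit deletion never silently drops
subjects; a flag (`allow_subject_loss`) enables the permissive variant.

Every trajectory is recorded as a trace of removal steps
(unit removed, resulting counts, p-value or estimability flag), and
`verify_borderline` re-checks the stopping property from the trace alone
with independent cold refits.  Refits that fail (non-convergence, or a
design made rank-deficient by an emptied group) resample the removal
target up to 10 times; an iteration whose candidates all fail is recorded
as an outlier, except that when *every remaining* candidate has been tried
the data are declared exhausted.  Batch runs use seed `base_seed + i` for
iteration i and aggregate final-N mean ± sd, per-group count
distributions, stop-reason tallies, and mean missing visits per subject.

## Synthetic cohorts

The generator draws five-group cohorts from the exact Model-2 process.
Defaults emulate a balanced four-visit cohort of 670 subjects
(172/53/187/186/72 across sHC/cHC/sMCI/cMCI/AD), with group demographics
(age means/sds, sex ratios, APOE-e4 carrier fractions) matching the
motivating cohort, visits at 0/0.51/1.01/2.02 years with per-visit timing
sd 0/0.05/0.06/0.08 (jitter truncated at ±3 sd; baseline exactly 0), and
group-by-time slopes anchored to the published posterior estimates
(0/−0.03/−0.02/−0.08/−0.11 per year).  Magnitudes not published anywhere
are fixed design choices: reference slope −0.01/yr, intercept offsets
(0, −0.1, −0.7, −0.9, −1.2), random intercept/slope sds 0.9/0.05 with
correlation 0.2, residual sd 0.15, covariate effects −0.02 per year of
age, +0.1 (female), −0.1 (APOE carrier), −0.02/yr (carrier × time), +0.3
per ICV sd.  These are sized so that group contrasts are clearly
significant at the full cohort and lose significance in the low hundreds
of subjects, which lets the removal simulations exercise both stopping
rules at desk scale.  Monotone dropout (baseline always observed, each
later visit retained with probability 1 − hazard given the previous one)
reproduces unbalanced variants; `derive_variants` produces the four
analysis datasets (all data; MCI-only; 4-visit-complete; both filters).

What the generator does *not* emulate: scanner/site effects, measurement
drift, non-linear trajectories, informative (outcome-dependent) dropout,
diagnostic misclassification, or heavy-tailed residuals.  Passing tests
therefore demonstrate correctness of the machinery under the stated
Gaussian linear model, not robustness of the scientific conclusions to
those real-data complications.

## Problem sizes in the test and acceptance runs

Simulation-based checks run at reduced scale, chosen once as the package's
own study conditions: null calibration of the omnibus F-test uses 1000
cohorts of ~150 subjects; parameter recovery uses 200 cohorts of ~300;
CrI calibration uses 500 two-group null cohorts of 600 (300 per arm) at
2 chains × 800 iterations; the missing-points experiment uses 25
iterations from a 0.7-scale balanced cohort (468 subjects, 1872 records —
large enough that the contrast outlives the estimability boundary, as in
the full-size cohort);
minimum-N power monotonicity uses 50 iterations at each of three effect
multipliers (1×, 1.5×, 2× the default slope offsets) from a ~175-subject
cohort.  Where a published-scale quantity depends on the starting size
(minimum N, stopping N), the scaled runs reproduce the qualitative
behaviour (positive-sd distributions, estimability-dominated stopping,
power monotonicity), not the printed magnitudes, which belong to the
original 1250-subject cohort.

## Numerical details and edge cases

- Rank checking of the fixed design uses pivoted QR and names the
  collinear columns; removal-loop refits skip the explicit check and let
  the Cholesky factorisation of X'V⁻¹X fail instead (handled as a
  resample).
- The information matrix for Satterthwaite is inverted directly when
  positive definite; near the variance boundary an eigenvalue-clipped
  pseudo-inverse is used.
- Contrast covariance matrices are rank-truncated at 1e-10 relative
  tolerance before the eigen-decomposition; degenerate components fall
  back to `df = n − p` with a flag.
- Inverse-gamma and inverse-Wishart draws go through `scipy.stats` with
  the chain's own `numpy` Generator, so all randomness flows from explicit
  seeds; per-stage seeds in the pipeline derive from the master seed by
  fixed offsets.
- Determinism: same seed → byte-identical cohorts, draws, and reports
  (verified by tests); record order and subject relabeling do not affect
  fits beyond 1e-7.

## Known limitations

- No Kenward–Roger correction; joint Wald tests are mildly liberal at
  small N (quantified above).
- No crossed random effects, autocorrelated residuals, or non-Gaussian
  outcomes.
- The Bayesian engine does not do model selection (no Bayes factors or
  information criteria); model choice is delegated to the frequentist
  LRT/AIC comparison.
- The borderline-evaluation omnibus rule is a documented convention; CrI
  overlap and contains-zero rules do not compose into a unique omnibus
  test.
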