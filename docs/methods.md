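# Methods

This note documents the models, algorithms and design choices behind
`sgapaf`, and what the synthetic-data experiments do and do not establish.

## Problem and outcome definition

Small-for-gestational-age (SGA) is birthweight strictly below the 10th
percentile of a gestational-age- and sex-specific reference distribution,
evaluated at completed weeks of gestation 24–44.  The outcome is a per-birth
binary label; births to the same mother are correlated, so all inference is
clustered by mother.  Analysis is stratified three ways — preterm births
(<37 completed weeks), term births to diabetic mothers, and term births to
non-diabetic mothers — with non-SGA births as the comparison group within
each stratum.  Diabetes acts as a stratifier only at term; in the preterm
stratum it is an ordinary covariate.

### Growth standard

The reference table maps (week, sex, percentile) to a cutoff in grams.  It
is a pure per-week lookup: gestational age is recorded in completed weeks,
so no interpolation across weeks is performed.  Ties at a cutoff are
classified non-SGA ("less than" is strict); the registry convention of how
a weight exactly on the published percentile is handled is not documented
anywhere we could anchor to, so the strict rule is a declared choice, not an
inferred one.  Birthweights are validated against the 5 g recording grid and
the range (0, 7000] g; out-of-range values are data errors, never silently
dropped.

The bundled synthetic standard is a normal location-scale family per
(week, sex): a Gompertz mean curve scaled to mean(39) = 3300 g (male) /
3230 g (female), with a week-constant coefficient of variation chosen per
sex so that the 10th percentile at 39 weeks is exactly 2500 g for both
sexes.  This is the simplest family that (a) reproduces the one anchor the
method is calibrated to, (b) satisfies all monotonicity invariants by
construction, and (c) admits closed-form quantiles so tests can check
cutoffs against independent numeric CDF inversion.  It is *not* a real
national percentile standard; real tables load from the same CSV format
(`week,sex,percentile,grams`).

## Cohort construction

Inclusion requires: singleton, livebirth, 24–44 completed weeks, and a
mother with a *complete obstetric history* — at every study-window birth
her self-reported count of previous pregnancies equals the number of linked
earlier birth records in the lookback window (1994 onwards by default).  A
mother failing the check has all her study births removed.  Exclusions are
tallied in a fixed order (plurality → vital status → gestation → history)
so counts are reproducible.  The completeness verdict is stored on the
output frame, which makes the filter idempotent even though the lookback
rows are dropped from the output.

History covariates are computed over strictly earlier linked births:
parity, previous caesareans, previous preterm (<37 weeks), previous
stillbirths, and previous SGA infants (classified with the same growth
standard as the study period — which standard was applied to pre-study
births in the original setting is unknowable, so one standard is used
throughout).  The inter-pregnancy interval runs from the previous birth to
the conception of the current pregnancy (birth date − gestation), binned as
6–41 months or nulliparous (reference) vs <6 or ≥42 months.

## Association models

The model-building protocol is:

1. **Screen**: Pearson chi-squared (no continuity correction) of each
   factor × SGA table; entry at P < 0.10.  Factors with a single observed
   level, or (at the pipeline level) with an empty outcome cell in the
   stratum, are excluded with a recorded note — an empty cell carries no
   finite odds ratio and would otherwise guarantee separation downstream.
2. **Collinearity**: variance inflation factors, 1/(1−R²) per design
   column; reported for review at threshold 10, never auto-dropped.
3. **Backward elimination** on independence logistic fits: the factor with
   the largest multi-degree-of-freedom Wald P over its design columns is
   removed while that P ≥ 0.01 — unless removing it changes any remaining
   factor level's adjusted odds ratio by ≥10 % (relative, on the OR scale),
   in which case it is retained as a confounder and frozen.  Ties in P are
   broken lexicographically so the trace is deterministic.  Selection uses
   independence fits because the clustering correction is applied "once the
   final model is determined"; a GEE selection mode is available by config.
4. **Re-entry**: each eliminated factor is added back independently and
   re-admitted if significant at 0.01.  **Interactions**: configured pairs
   are tested one at a time and kept at P < 0.01.
5. **Final fit**: logistic GEE with exchangeable working correlation over
   births sharing a mother, robust (sandwich) covariance, and 95 % CIs using
   the normal 1.96 multiplier.  Adjusted ORs are exp(β); reference levels
   print as 1.00 without a CI.

"Overall least significant" is operationalised as the largest multi-df Wald
P; Wald is used (rather than likelihood-ratio) so the same test applies
unchanged under GEE, where a likelihood does not exist.

### GEE solver

The solver performs Fisher scoring on the estimating equations
Σ D′V⁻¹(y−μ) = 0 with V = A^{1/2}R(α)A^{1/2}, re-estimating α each
iteration by the moment estimator on Pearson residuals (scale estimated
with n−p degrees of freedom).  For exchangeable R of cluster size m,
R⁻¹u = (u − c_m Σu·1)/(1−α) with c_m = α/(1+(m−1)α), so every step reduces
to per-cluster segment sums and the whole fit is vectorised over clusters.
Convergence is declared at sup-norm coefficient change < 1e−6 within 100
iterations; |β| > 40 or a singular system marks the fit non-convergent.
Separation (a 0/1 design column whose births all share one outcome) raises
a structured error naming the level; penalised fitting is deliberately not
offered because it would shift the reported odds ratios in undocumented
ways.  The solver agrees with statsmodels' GEE to ~1e−7 on coefficients,
robust SEs and α (test suite), and at α = 0 reduces exactly to independence
logistic regression.  It exists as first-party code because the bootstrap
and calibration studies need on the order of 10⁵ refits, which requires a
fit cost of well under a millisecond on a few thousand births.

## Population attributable fractions

For a converged final fit, the PAF of a set of factor levels is

PAF = 100 · (Σᵢ p̂ᵢ − Σᵢ p̂ᵢ⁰) / Σᵢ p̂ᵢ,

where p̂ᵢ⁰ recomputes each birth's probability with the named coefficients
set to zero and everything else (other coefficients, all covariate values)
unchanged.  This is a pure coefficient-zeroing counterfactual: the reduced
model is *not* refit, which would answer a different question.  Multi-level
factors get per-level PAFs by default (whole-factor zeroing is available).
Negative PAFs (protective factors) are computed and flagged rather than
suppressed; which factors are *reported* as prevention targets is a config
list of causative/modifiable factors, a reporting decision rather than a
computational one.  On a saturated one-factor model the definition
reproduces Miettinen's case-based attributable fraction pc·(RR−1)/RR
exactly, which the tests exploit as an independent oracle.

### Bootstrap confidence intervals

Mothers (not births) are resampled with replacement — all of a sampled
mother's births enter together, and a mother drawn twice contributes two
independent clusters — because all inference in the pipeline is clustered
by mother; resampling births would break the correlation structure the GEE
is there to respect.  Each replicate refits the final model (factor set
frozen; selection is never re-run inside the bootstrap) in the same
estimation mode as the reported fit and recomputes the PAF.  The 95 %
interval is bias-corrected (BC) percentile: z₀ = Φ⁻¹(fraction of replicate
PAFs below the point estimate), endpoints at percentiles Φ(2z₀ ± 1.96).
No acceleration constant is used (BC, not BCa).  Replicates that fail to
converge are dropped and counted; the estimate is invalid if more than 10 %
fail (a robustness guard).  The default is 10,000 replicates; the analysis
scripts use 2,000 and the calibration studies 300–500, which widens
Monte-Carlo noise on the interval endpoints slightly but leaves coverage
testable.  A single integer seed fully determines the resampling sequence.

## Synthetic cohort generator

The generator emulates the structure the pipeline assumes, with ground
truth retained for every birth:

* mothers with 1–3 study-window births (default split 80.8 / 18.5 / 0.7 %)
  plus 0–2 lookback births (default 55 / 30 / 15 %);
* birth dates built from inter-pregnancy intervals drawn from a mixture
  straddling the 6- and 42-month category bounds (25 % U(1,6), 60 %
  U(6,41), 15 % U(42,80) months); intervals are shrunk per mother when
  needed to fit the calendar windows, gestation lengths never are;
* gestational age: preterm with probability 0.052, with discrete week
  distributions rising towards 36 weeks (preterm) and peaking at 39–40
  weeks (term);
* risk factors per the configurable spec list; defaults echo the magnitudes
  of the motivating population study (smoking 12 % prevalence at
  conditional log-OR ln 2.31, overseas-born 30 % at ln 1.54, a five-level
  socio-economic gradient, diabetes 6 %, etc.);
* outcome: logit p = baseline + Σ effects + u, with mother intercept
  u ~ N(0, 0.5²) and the baseline solved by bisection so the realised
  marginal SGA prevalence hits its target (default 10 %);
* birthweight drawn *after* the outcome label, from the correct side of the
  standard's 10th-percentile cutoff (truncated normal, snapped to the 5 g
  grid without crossing the cutoff) — the analysis consumes the label, so
  exact prevalence control matters more than an unconditional weight draw;
* reported previous-pregnancy counts set truthfully, then inflated by one
  at the last birth of a configurable fraction of mothers (default 3 %) to
  exercise the completeness check.

Planted effects are conditional on the random intercept; the GEE estimates
marginal effects.  The truth ledger therefore stores realised per-birth
probabilities and their counterfactuals (factor effect removed), so the
true marginal PAF marginalises over the realised intercepts, and
`marginal_logodds` provides the attenuated marginal coefficient target by
Gauss–Hermite integration — recovery tests always compare like with like.

What the generator does **not** emulate: linkage error, hospital coding,
geography, the full 40-variable covariate set, history effects on the
current outcome (previous-SGA association arises only through the shared
intercept and mother-level covariates), or real percentile tables.  Passing
tests therefore demonstrate correctness of the *machinery* (classification,
derivation, estimation, calibration of intervals) under the stated
generating model — not that the pipeline would reproduce any particular
population's estimates.

## Numerical and reporting choices

* Reported percentages round half-up to one decimal.
* η is clipped at ±30 before the logistic transform; variances floored at
  1e−12.
* Working correlation α is clipped to (−1/(m_max−1), 0.995] to keep R
  positive definite.
* z₀ in the BC interval is computed with the replicate fraction clipped to
  (0.5/B, 1−0.5/B); an interval that fails to bracket the point estimate
  warns rather than silently passing.
* Empty denominators (e.g. percentages of an empty SGA set) raise; they are
  never reported as 0.

## Problem sizes in the test and acceptance studies

Effect recovery uses 50 cohorts of 50,000 mothers; bootstrap coverage uses
200 replications of 2,000 mothers at 500 bootstrap replicates; selection
behaviour uses 50 cohorts of 20,000 births; null-PAF calibration uses 100
replications at 300 replicates.  These sizes give Monte-Carlo bands tight
enough for the stated assertions (e.g. coverage inside [91 %, 99 %]) while
keeping the full suite a few minutes on one CPU.

## Known limitations

* The exchangeable-α moment estimator can go slightly negative in small
  strata; this is legitimate but means the "working correlation > 0"
  intuition only holds at scale.
* The confounder-retention rule compares coefficient positions by factor,
  which assumes a removed factor does not change the *meaning* of other
  columns (true for dummy coding).
* Backward elimination's re-entry pass re-admits factors in ascending-P
  order; other orders could, in principle, yield a different final set when
  re-admitted factors interact strongly.
* The generator's baseline calibration targets the realised study births of
  the drawn cohort, so the marginal prevalence is exact in expectation but
  inherits O(n^{-1/2}) sampling noise.
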