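# Methods

This note documents the statistical procedures implemented in
`telenorms`, the modelling choices made where the published description
leaves the design open, and what the synthetic-data generator does and
does not emulate.

## Demographic adjustment

Raw scores on five verbal-memory tests (DSF, DSB 0–9; RAVL-I 0–75;
RAVL-D 0–15; VPAL 0–22.5 in half-point steps) are corrected for age,
education (years of schooling), and gender (0 = male, 1 = female) by a
regression-based procedure:

1. **Transformation screening.** Per covariate, candidate functional
   forms are fit in one-predictor least-squares regressions of the raw
   score and ranked by R². The candidate sets are: age — identity, x³,
   √x, ln(c − x); education — identity, 1/x; gender — identity. These
   are exactly the forms that occur in the published equations plus the
   identity; the original search space is not documented, so the
   candidate set is kept minimal and configurable. The shifted-log
   offset defaults to max(observed age) + 4 (88 for an 18–84 cohort) and
   any candidate that is invalid on the observed range (offset not above
   the maximum, reciprocal of non-positive values) is skipped with a
   warning. Exact R² ties break toward the simpler (earlier-listed)
   form.
2. **Stepwise selection.** The best form per covariate enters a
   bidirectional p-value stepwise regression: forward steps admit the
   candidate with the smallest t-test p-value while it is below
   `alpha_enter`, backward steps drop the worst included covariate while
   its p-value exceeds `alpha_remove` (both default 0.05). The published
   account says only "stepwise"; a p-value criterion with symmetric
   thresholds is the most common reading and both thresholds are
   configurable.
3. **Mean-deviation refit.** Retained transformed covariates and the
   outcome are centered at their sample means and refit; coefficients
   are stored sign-reversed together with the centering constants. The
   resulting correction, `Σ β·(g(x) − mean(g(x)))`, is exactly zero at
   the sample means, so adjusted and raw cohort means coincide (this is
   asserted by a property test). R², adjusted R², and the root mean
   square error (√(SSE/(n − k − 1))) are recorded as fit diagnostics.

If no covariate enters, the equation has an empty term list and the
adjusted score equals the raw score; this is logged, not an error.

**Correction grid.** Corrections are tabulated on the fixed clinical
lattice (ages 18, 22, 27, …, 82, 84; educations 5, 8, 13, 16, 18, 21
when education is in the equation; stratified by gender when gender is).
Cells round half-away-from-zero to 2 decimals; all internal arithmetic
is unrounded. The shifted log uses the natural logarithm — verified by
recomputation: with ln, all 585 transcribed cells of the published grid
reproduce exactly at 2-decimal rounding (base-10 does not reproduce
them). Scoring outside the fitting range is computed but logged as
extrapolation.

The five published equations ship as fixtures (`telenorms.fixtures`)
together with the transcribed grid; `validate_fixtures()` recomputes
every cell and reports the maximum absolute deviation (0.0 as shipped,
tolerance 0.005). The package does not attempt to re-derive the
published coefficients — the underlying participant data are not
available.

## Tolerance limits and Equivalent Scores

Let B ~ Binomial(n, p) with p = 0.05 count observations below the
population 5th centile, and γ = 0.95 the confidence level.

* **Outer tolerance limit (OTL):** rank r = the largest integer with
  P(B ≤ r − 1) ≤ 1 − γ; the r-th order statistic is then a lower
  confidence bound on the 5th centile. A valid rank requires
  (1 − p)ⁿ ≤ 1 − γ, i.e. n ≥ 59 at these levels; smaller samples raise
  an error stating the minimum.
* **Inner tolerance limit (ITL):** rank s = the smallest integer with
  P(B ≤ s) ≥ γ. This is the convention that reproduces the rank pairs
  tabulated in the Equivalent-Score literature — at n = 204 it yields
  ranks (5, 16). (The alternative convention P(B ≤ s − 1) ≥ γ would
  give 17; the package deliberately follows the published rank tables.)

Both ranks use the exact binomial CDF — no normal approximation — and
are checked against a brute-force CDF-summation oracle for every
n ∈ [60, 500], plus a Monte-Carlo coverage check (the OTL undershoots
the true 5th centile in ≥ 95% of replicates).

**Equivalent Scores.** ES 0 is bounded above by the OTL and ES 4 below
by the sample median. Observations in (OTL, median] are split by rank
into three consecutive groups of as-equal-as-possible size, remainders
assigned to the lower groups first; the maxima of the first two groups
give the ES 1/ES 2 and ES 2/ES 3 cutoffs. The source method delegates
the intermediate bands to a rank-based procedure without printing
formulas, so this equal-frequency-tertile choice is isolated behind one
function (`es_thresholds`) and documented here. Bands use the
"≤ upper bound" convention visible in the published cutoff table: ES(x)
= 0 iff x ≤ c0, ES k iff c(k−1) < x ≤ ck, ES 4 iff x > c3. Tied or
too-sparse regions collapse with a warning and a `degenerate` flag.
The published VPAL cutoff row duplicates the DSF row verbatim (almost
certainly a typesetting error); it ships flagged `suspect` and is never
used as ground truth.

**Percentiles.** Empirical quantiles at levels 99, 95, 90, …, 5, 4, 3,
2, 1 use type-7 linear interpolation of order statistics (NumPy's
default); the convention is recorded in the output metadata. The
published percentile table derives from the unavailable raw data, so no
numeric equivalence is asserted — monotonicity and boundary behavior
are property-tested instead.

## Concordance of two normative systems

A normative system is an adjustment equation plus an impairment rule;
the default rule is adjusted score ≤ the system's OTL (Equivalent Score
0). Which ES level defines "impaired" is not stated in the source, so
the cutoff is configurable and recorded. Per test:

* **Accuracy** = (a + d)/n on the 2×2 cross-classification (reference
  system × predicting system).
* **Cohen's κ** = (p_o − p_e)/(1 − p_e) with p_e the product-of-marginals
  chance agreement; CI from the large-sample standard error
  √(p_o(1 − p_o)) / ((1 − p_e)√n). κ is undefined (NaN, with a warning)
  when both raters are single-class (p_e = 1).
* **Gwet's AC1** = (p_o − p_γ)/(1 − p_γ) with p_γ = 2π(1 − π), π the
  mean of the two systems' impaired proportions; CI from Gwet's
  linearized variance estimator, computable from the four cell counts.
  For binary ratings p_γ ≤ 0.5, so AC1 remains defined even on
  single-class tables — which is exactly its appeal under the heavy
  class imbalance of a clinical cohort.
* **AUC**: the Mann–Whitney rank statistic of the *continuous* adjusted
  score under the predicting system against the reference flag, oriented
  so lower scores predict impairment, ties counted half. The default CI
  is DeLong's; a seeded percentile bootstrap (2000 resamples) is
  available. ROC points are exported via scikit-learn.

κ and AC1 are verified against direct-formula oracles on every 2×2
table with n ≤ 40 (exhaustive at the count level), and the AUC against
exhaustive pair counting; AUC invariance under strictly monotone score
transforms is property-tested. The published comparison metrics
depend on external norms whose parameters are not printed in the
source, so they are treated as qualitative anchors (e.g. AC1 ≥ κ under
imbalance), not numeric targets.

## Sensitivity power analysis

The minimal detectable f² of a fixed-model regression coefficient test
solves power(f²) = 1 − β where power is the exact noncentral-F tail
beyond the central-F critical value, with df1 = number of tested
predictors (default 1, the single-coefficient reading), df2 = N − total
predictors − 1, and noncentrality λ = f²·N. The solver brackets and
bisects to |power − target| < 1e−10; `power_at` is its exact inverse
(f² = 0 returns α). With three predictors the solver gives f² = 0.03885
at N = 204 and f² = 0.04409 at N = 180. Note on display: the
conventional 3-decimal presentation of this pair (0.038 / 0.044) is
reproduced by *truncating* the third decimal, and `display_f2` follows
that convention; the solver itself always returns full precision. The
df1 = 1 reading is an inference from numerical consistency — the
omnibus df1 = 3 reading would give ≈ 0.054 at N = 204. A Monte-Carlo
check (10,000 simulated regressions at the solved f²) confirms the
rejection rate within ±0.02 of target.

## Synthetic cohorts

**Healthy normative cohort** (`simulate_healthy_cohort`). A Gaussian
copula over (gender, age, education, five test scores):

* Continuous marginals are truncated normals whose *realized* mean and
  SD match the published targets (age 44.33 ± 18.51 on [18, 84];
  education 14.98 ± 3.85 on [5, 26]; test scores at their published
  means/SDs on the catalog bounds), solved by bounded moment matching.
  The age target sits at the feasibility edge of the family (maximum
  attainable SD ≈ 18.34 at that mean); the fit prioritizes the mean and
  accepts the ~1% SD shortfall. Values are rounded to their granularity
  (integer years; integer scores, half points for VPAL) *after* the
  copula mapping, which preserves the correlation targets better than
  rounding before.
* Gender is a latent Gaussian thresholded on the upper tail at the
  female proportion (127/204), so the 0/1 code correlates positively
  with its latent variable.
* The latent correlation matrix de-attenuates the published targets by
  each variable's linear loading — corr(g(Z), Z) of the full marginal
  map, computed by quadrature; for gender this is the point-biserial
  factor φ(τ)/√(p(1−p)) — then clips to [−0.99, 0.99] and repairs to
  the nearest positive-semidefinite correlation matrix by eigenvalue
  clipping. If repair fails the offending eigenvalue is reported.

Calibration: averaged over 20 seeds at n = 204, the mean absolute
deviation between realized and target correlations is ≈ 0.008 (maximum
pairwise bias ≈ 0.03, on the heavily transformed age pairs). Any single
seed adds sampling noise of about 0.06 per pair on top of that bias.

What the generator does **not** emulate: the real sample's selection
effects (volunteers, cognitive screening), non-Gaussian dependence
(e.g. floor/ceiling clumping beyond truncation), item-level structure,
or test order effects. Passing tests therefore demonstrate the
*pipeline's* correctness on data with the published first- and
second-moment structure, not distributional fidelity to the original
cohort.

**Simulated clinical cohort** (`simulate_patient_cohort`). Per-test
scores are Normal(mean, SD), rounded to the test's granularity and
clipped to the catalog. The shipped clinical means/SDs are **synthetic
stand-ins** (the external face-to-face norms they emulate are not
redistributable): DSF 5.2 ± 1.0, DSB 3.3 ± 1.0, RAVL-I 28 ± 8,
RAVL-D 4.5 ± 2.8, VPAL 8.0 ± 3.5, with elderly demographics
(age 72 ± 6 on [55, 84], education 9 ± 3.5 on [5, 18]) — chosen to sit
roughly 2–3 healthy SDs below the healthy means, as expected for an
amnestic-MCI population; all are free configuration. Age and education
are drawn from their marginals and *paired* (education reordered along
a latent Gaussian correlated with the age ranks, latent level tuned by
bisection) until the realized Pearson correlation hits the target
(default −0.22) within ±0.02; an unattainable target raises after the
iteration budget. Warnings are emitted when catalog bounds are
inconsistent with a requested mean ± SD (clipping then shifts the
realized moments).

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds; the pipeline derives
per-stage substreams from one global seed via `SeedSequence` spawn keys,
and fixed-seed runs are bit-identical (checksummed in the manifest).
Simulation-based tests use 10,000 Monte-Carlo replicates for coverage
and power checks, 20 seeds for recovery-rate checks at n = 204 or
n = 2000, and exhaustive enumeration (all 2×2 tables with n ≤ 40; all
sample sizes 60–500 for tolerance ranks) where the domain is small
enough to enumerate; the acceptance script uses 5,000 replicates for
its seeded Monte-Carlo summaries.

## Known limitations

* The stepwise procedure inherits the usual post-selection caveats
  (biased coefficients near the inclusion boundary, optimistic R²); the
  package reproduces the published procedure rather than fixing it.
* The intermediate-ES tertile rule is one defensible reading of the
  rank-based construction; alternative readings shift c1/c2 by at most
  one order statistic.
* Copula calibration corrects first-order (linear-loading) attenuation
  only; strongly nonlinear marginal maps leave residual bias up to
  ~0.03 on individual pairs.
* Agreement CIs are asymptotic (κ) or linearized (AC1); for very small
  clinical cohorts a bootstrap would be preferable.
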