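# Methods

## The twin model

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared environmental (C) and unique environmental (E)
components from the contrast between monozygotic (MZ) and dizygotic (DZ)
co-twins.  The model's identifying assumptions, all standard, are:

- cross-twin correlation of A is 1 in MZ pairs and 0.5 in same-sex DZ
  pairs (random mating, purely additive gene action);
- C is perfectly correlated across co-twins in every zygosity group
  (equal-environment assumption);
- E (which absorbs measurement error) is uncorrelated across co-twins;
- total variances, and the proportions explained by A/C/E, are equal
  across zygosity groups — means, however, are zygosity-specific, since DZ
  twins run slightly taller and heavier than MZ twins.

In the bivariate case — one trait at two ages j < k — each component's 2×2
covariance is parameterised through a lower-triangular path matrix,
A = L_A·L_A′ etc. (Cholesky parameterisation), which makes positive
semidefiniteness structural rather than a constraint to enforce.
Standardising the off-diagonal of each component covariance gives the
component correlations r_A, r_C, r_E between ages, and the model-implied
phenotypic correlation satisfies the identity

    r_P = a1·r_A·a2 + c1·r_C·c2 + e1·r_E·e2,

with a, c, e the square roots of the standardized variance shares.  The
identity is verified to 1e-8 per fitted grid cell in the test suite.  Note
that per-variable c² is non-negative by construction, yet r_C can be
negative through the sign of the off-diagonal L_C entry — negative
shared-environment cross-age covariances are representable.

Two designs are implemented.  `single_sex` fits one path set to MZ and
same-sex-DZ pairs (opposite-sex pairs ignored).  `five_group` is a
sex-limitation model: separate male and female path matrices fitted jointly
to all five zygosity-by-sex groups (MZM, MZF, DZM, DZF, OSDZ), with the
opposite-sex-DZ cross-twin genetic correlation equal to 0.5·r_g(os), where
r_g(os) ∈ [0, 1] is estimated freely (logistic parameterisation) rather
than fixed at the same-sex value.  OSDZ families are ordered male-first;
their cross-twin block is k·L_A(M)·L_A(F)′ + L_C(M)·L_C(F)′.

`AE` (C fixed at zero) is the default/main model; `ACE` is the sensitivity
model.  Dominance, gene–environment interaction and zygosity-specific
variances are out of scope.

## Likelihood and estimation

Estimation is full-information maximum likelihood: each family contributes
the multivariate-normal log density of its *observed* sub-vector of
(twin1@j, twin1@k, twin2@j, twin2@k) under the zygosity-appropriate mean
and covariance sub-matrix.  Families whose co-twin is entirely unobserved
carry no cross-twin information (means are known to be ≈ 0 after
residualisation) and are dropped with a counter.  Implementation detail
that matters for speed: families are grouped by (zygosity, missingness
pattern) and the likelihood is evaluated from per-pattern sufficient
statistics (count, sum, sum of outer products) with batched small-matrix
linear algebra, making each evaluation independent of the number of
families.  A numerically singular observed sub-matrix gets a 1e-8 diagonal
jitter and is counted; a fit with > 1% jittered families is flagged
non-converged.

Free parameters are the unconstrained triangular path entries, the
zygosity-specific means per variable and sex, and logit r_g(os).
Optimisation is quasi-Newton (L-BFGS-B) on the average negative log
likelihood with finite-difference gradients — this mirrors what
off-the-shelf SEM engines do internally.  Starting values come from the
closed-form moment (Falconer) estimators computed on double-entered co-twin
correlations, floored at a 0.05 variance share and repaired to positive
definite; if the first attempt fails the convergence check (optimiser
success or max |grad| < 1e-4 on the average-likelihood scale), up to two
further deterministic perturbed restarts are tried, and the best point is
always returned with its flag.  Identical data and settings give identical
estimates to 1e-10.

**Sign conventions.** The likelihood is invariant under sign flips of
latent factors (columns of L).  Within one sex, columns of each L flip
freely, and diagonals are fixed non-negative.  In the five-group design the
OSDZ cross-sex block L(M)·L(F)′ ties the column signs of the two sexes
together for A and C: only joint flips are invariant.  Those flips are
keyed on the male diagonal; a residual negative female diagonal therefore
encodes a genuinely negative cross-sex loading, not an unfixed sign.  E
never crosses twins and is sign-fixed per sex.

## Confidence intervals

Default intervals for the component correlations r_A, r_C, r_E are profile
likelihood: the set of values whose profiled log likelihood lies within
χ²₁(0.95)/2 = 1.921 of the maximum.  The profile is computed exactly by
reparameterising the constrained component block as two standard deviations
plus the fixed correlation, leaving an unconstrained inner optimisation
that is warm-started from its neighbour; endpoints are located by outward
bracketing (seeded with the Wald half-width) plus Brent root finding, and
clipped to [−1, 1] with a one-sided flag when the drop never crosses the
threshold inside the unit interval.  Variance shares, r_P and r_g(os) get
delta-method Wald intervals from the inverse observed information
(numerical Hessian; pseudo-inverse to tolerate flat directions such as
c² = 0).  Coverage of the r_A profile interval is checked by simulation in
the test suite (200 replicates, binomial band 89–99% around nominal 95%).

Because profiling every grid cell would cost two orders of magnitude more
inner optimisations than the fits themselves, the grid runner defaults to
Wald intervals per cell (`ci_method="profile"` switches them); single fits
default to profile.

## Preprocessing

BMI = weight (kg) / height (m)², log-transformed with the natural log (the
base is irrelevant for correlations); height enters untransformed.  A
measurement at exact age x is assigned to the integer bin round(x) clipped
to [1, 19]; when a twin has several measures in one bin, the one closest to
the bin centre wins (ties: earliest record).  Within each 1-year-age × sex
stratum the phenotype is residualized by OLS on [1, exact age, birth year,
cohort indicators]; collinear columns are dropped deterministically
(cohort indicators first, last-entered first — residuals are invariant to
which collinear column goes), and a stratum without residual degrees of
freedom falls back to plain centering rather than a perfect fit.
Residualisation is idempotent and leaves every stratum with mean < 1e-8 in
absolute value.  Skewness (adjusted Fisher–Pearson) is reported before and
after the log transform; the skewness of a zero-variance sample is defined
as 0 to avoid NaN propagation in degenerate synthetic strata.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, so
every downstream stage is testable without any real cohort:

- zygosity mix 38% MZ / 33% same-sex DZ / 29% opposite-sex DZ, split
  equally between sexes within MZ and SSDZ;
- latent A/C/E per trait with per-age variance shares a²(t), c²(t), e²(t)
  summing to 1 and cross-age correlation matrices R_A, R_C, R_E (sampled
  through the spectral matrix square root, eigenvalues clipped at 0, so
  numerically semidefinite inputs are tolerated; anything below −1e-10 is
  rejected naming the offending matrix);
- cross-twin correlations 1 / 0.5 / 0.5·r_g(os) for A and 1 everywhere for
  C, exactly as the model assumes — MZ and DZ total variances are equal by
  construction;
- observed scale: the unit-variance latent phenotype is mapped through
  per-age, per-sex means and SDs.  The default calibration stores the
  descriptive mean/SD of BMI and height per age (1–19) and sex from a
  large pooled twin database; BMI is generated on the log scale (log-normal
  parameters matched to the printed arithmetic moments) and exponentiated,
  and weight is then derived as BMI·height², so the log-transformation step
  in preprocessing is exactly right for the generated data;
- nuisance structure for the residualisation stage to remove: a DZ−MZ mean
  offset (default +0.005 log-BMI, +0.4 cm), additive study-cohort offsets
  (three cohorts, ±0.01 log-BMI / ±0.5 cm), a linear birth-year trend
  (0.002 log-BMI, 0.02 cm per year over birth years 1980–2005), and
  within-bin growth at 4 cm per year of exact age for height;
- missingness completely at random per (twin, age), default rate 0.25.

Default variance shares encode the consensus picture for body size: log-BMI
a² = 0.65 / c² = 0.15 / e² = 0.20 up to age 5 and 0.80 / 0 / 0.20
afterwards; height 0.55 / 0.30 / 0.15 up to age 4 and 0.75 / 0.12 / 0.13
afterwards.  Default cross-age correlations decay as base^|j−k| with bases
0.95 (A), 0.90 (C), 0.30 (E) for log-BMI and 0.98 / 0.95 / 0.40 for height
— genetic continuity strong, stronger for height; unique-environment
carry-over weak.  Default r_g(os) = 0.95.

What the generator does **not** emulate — so what passing tests do not
show: real attrition structure (missingness is MCAR, actual cohort
follow-up is anything but), assortative mating, chorionicity, secular
non-linear BMI trends, cross-trait coupling of BMI and height beyond the
algebraic weight = BMI·height² link (the two traits' latent components are
drawn independently), or age-varying skewness of the real BMI distribution
(log-BMI is exactly normal here).  Parameter-recovery results therefore
validate the estimation machinery under the model's own assumptions, not
the assumptions themselves.

## Correlation grids

Each unordered age pair is fitted independently as a bivariate model — a
joint 19-variate model would be unidentifiable at realistic per-age overlap
and is not attempted.  Cells with fewer than `min_pairs` (default 30)
informative families, or with a zygosity group entirely absent, are skipped
and *marked*, never silently dropped; non-converged cells keep their
estimates plus a flag.  No multiple-testing adjustment is applied across
cells; intervals are per cell.  Matrices serialise with males in the upper
and females in the lower triangle; the long-format grid CSV carries one row
per (sex, age_j < age_k).

## Problem sizes used in the checks

The full-grid checks run 800 complete pairs across ages 1–19 (about 24,000
measurement rows at the default missingness), which keeps every one of the
171 cells estimable while the 171 five-group fits complete in a few
minutes; parameter-recovery fits use 5,000 MZ + 5,000 DZ pairs at two ages;
the CI-calibration study uses 200 replicates of 700 + 700 pairs.  These
sizes are the package's own choices for routine verification — the
estimator itself has no size-dependent switches.

## Known limitations

- Five-group fits report sex-specific r_A informed jointly by same-sex
  groups and OSDZ; with OSDZ absent the design degenerates (an error asks
  for `single_sex` instead).
- Profile CIs are implemented for r_A / r_C / r_E only; other quantities
  use Wald intervals, which can misbehave near the c² = 0 boundary (the
  pseudo-inverse keeps them defined but coverage there is approximate).
- The optimiser can, like any quasi-Newton method on a boundary-kissing
  ACE likelihood, terminate at a slightly sub-optimal point; nesting
  (logL_ACE ≥ logL_AE) is exercised in the tests, and the conditional
  restarts exist precisely for these cases.
- Whether log-BMI or raw BMI was residualized first is genuinely ambiguous
  in the field's descriptions; this package residualizes log-BMI.  Any
  base of logarithm gives identical correlations.
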