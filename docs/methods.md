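# Methods

## The procedure

Power is estimated by direct simulation of the design:

1. build the population skeleton (clusters × units × timepoints);
2. randomize treatments at their declared levels;
3. draw cluster (and, where present, child) random effects and
   residual errors, and form outcomes from the data-generating model;
4. apply attrition;
5. analyze the replicate exactly as the trial would be analyzed —
   marginal regression with cluster-robust sandwich standard errors —
   and record the Wald p-value for each tested coefficient;
6. repeat; the empirical power is the fraction of p-values below
   alpha, with Monte-Carlo standard error sqrt(p(1-p)/R).

All randomness flows from a single master seed through spawned
per-replicate streams (`numpy.random.SeedSequence`), so a scenario is
bit-reproducible and independent of execution order.  Within a
replicate, draws are ordered deterministically: cluster effects in
cluster-id order, then child effects, then residuals.

## Data-generating models

Three outcome families, all with normal, zero-mean, mutually
uncorrelated random components whose scales are always standard
deviations (never variances):

* **Continuous two-level** — `y_ij = mu + beta1*A_i + b_i + eps_ij`,
  `b_i ~ N(0, sigma_g)`, `eps_ij ~ N(0, sigma_e)`.  The intraclass
  correlation is `rho = sigma_g^2/(sigma_g^2+sigma_e^2)`.
* **Binary two-level** — `logit(p_ij) = mu + beta1*A_i + b_i`;
  `y_ij ~ Bernoulli(p_ij)`.  `mu` is the log-odds of the control-arm
  probability, `beta1` a log odds ratio.
* **Factorial three-level** — `y_ijt = mu + beta1*A_ijt + beta2*X_ijt +
  beta3*A_ijt*X_ijt + b_i + b_ij + eps_ijt` with village effect `b_i`,
  child effect `b_ij` (shared across a child's two measurements) and a
  fresh residual per measurement.  Exposure indicators are time-indexed
  and zero at baseline, so the single formula covers both timepoints;
  the model carries no secular-trend term of its own, but the default
  analysis model includes a time indicator so a trend added later would
  not bias the treatment contrasts.

Dropout removes a child's follow-up record independently with the
configured probability — missing completely at random, never the
baseline row.

## Randomization

Cluster-level treatments use balanced complete randomization: exactly
half the clusters treated (an odd cluster total is an error), labels
permuted first so cluster ids carry no arm information.  Unit-level
treatments are exactly balanced within every cluster at the configured
fraction (which must give an integer count per cluster).  Exact
within-cluster balance is an interpretation — a Bernoulli coin-flip
per household would also be defensible — chosen because it reduces
Monte-Carlo noise and matches the "half the households" framing of the
motivating design.  By default a fresh assignment is drawn every
replicate, so design and assignment are simulated jointly;
`Scenario(fix_assignment=True)` freezes one assignment and redraws
only the random effects, which reproduces the classical step-by-step
recipe literally.  Both are valid power definitions and agree closely
for balanced designs.

## Analysis stage

Point estimates come from OLS (continuous) or maximum-likelihood
logistic regression; the covariance is the clustered sandwich (score
contributions summed within cluster) with small-sample factor
G/(G-1), G the number of clusters.  The Wald statistic is referred to
a standard normal by default.  Two consequences worth knowing:

* At moderate G the combination is mildly anti-conservative — in our
  own null calibration runs at G = 200 the two-sided size is ≈ 5.3%
  rather than 5.0%.  A Student-t reference with G-1 degrees of freedom
  (`AnalysisSpec(t_reference=True)`) shrinks this; it is off by
  default to match the large-G framing of the closed-form benchmark.
* The one-sided p-value is taken in the direction of the observed
  estimate (half the two-sided value).  Under the null it therefore
  rejects at twice the threshold — 10% at 0.05 — which is exactly what
  the calibration diagnostic expects of it.  A pre-specified
  directional test would instead reject at 5%; the observed-direction
  convention was chosen because it is what the halve-the-p-value
  practice common in applied work actually does.

The factorial analysis model is deliberately simple and marginal:
regress the outcome on a follow-up indicator, both treatments and
their interaction over both timepoints, clustering robust SEs at the
village.  It matches the data-generating model, uses the baseline
data, and is robust to a secular trend.  A follow-up-only variant
(`AnalysisSpec(followup_only=True)`) is available.  Logistic
replicates that fail to converge (e.g. perfect separation) are
flagged, excluded from the rejection-rate denominator and counted; a
run with more than 1% failures raises an error rather than reporting
a power number built on a shifting denominator.

## Training-stage estimation

Variance components are estimated from long-format training data by
intercept-only mixed models: REML for linear outcomes (less biased SD
estimates than ML at modest cluster counts), fit with statsmodels
MixedLM — a random intercept per cluster, plus a nested child
variance component for three-level data.  The logistic random-intercept
model is fit by maximum likelihood with 40-node Gauss-Hermite
quadrature over the cluster effect (the intercept-only model's
per-cluster likelihood depends only on cluster size and success
count, so the integral is cheap and stable for sigma_g up to ~3).
Components estimated at zero are reported as zero, not errors.  A
level with no replication (no cluster with two units; no child with
two measurements) is a hard error naming the level.

## Synthetic training data

`powersim.fixtures` generates stand-ins for training datasets that
cannot be shipped.  Two built-in profiles emulate the statistical
shape of two field datasets used throughout the examples and tests:

* `east-java` — two-level cross-sectional survey: 2,090 children in
  160 villages, mean HAZ -0.875, village SD 0.482, child SD 1.297
  (total SD 1.384, ICC 0.12);
* `india-longitudinal` — three-level cohort: 1,236 children in 25
  villages, up to two measurements per child, mean -1.98, SDs
  0.297 / 1.259 / 1.079 (total SD 1.68).  The second measurement is
  retained with probability 0.9 — the real cohorts' missingness
  pattern is unreported, so this value is a pinned convention.

Cluster sizes are multinomial around the mean (adjusted so every
cluster keeps at least one child) to emulate field imbalance; the real
cluster-size distributions are unreported, so multinomial is a
declared stand-in.  The generators reproduce the multi-level variance
structure only: no age structure, covariates, spatial pattern,
non-normal tails or informative missingness.  Tests that pass on these
fixtures therefore demonstrate that the estimation and power machinery
is correct under the assumed model, not that the model fits any
particular real population.

## Numerical and default choices

* alpha defaults to 0.05, two-sided; replication count defaults to
  10,000, with a warning below 1,000.
* The closed-form CRT benchmark is
  `Phi( sqrt( c*n*d^2 / (2*sigma^2*(1+(n-1)*rho)) ) - z_{alpha/2} )`
  — the standard normal-approximation formula with design effect
  `1+(n-1)*rho`; it is validated against simulation across a cluster
  grid in the test suite.
* MDE search brackets the effect in [0, upper] and bisects: to a
  fixed power tolerance against the closed form, or until the target
  power falls inside the simulation estimate's 95% Monte-Carlo
  interval.
* The KS uniformity check uses the exact sup-distance of the ECDF and
  a parametric bootstrap under Uniform(0,1) with size-matched samples
  (default 1,000 resamples); QQ plotting positions are (k-0.5)/R.
  P-values from logistic fits on small samples are discrete, so a
  binary-family calibration report annotates rather than auto-fails.
* Problem sizes in the test suite are chosen to keep the default run
  at a few minutes: 10,000 replicates for the null calibration, 1,000
  per grid point for the power-curve comparisons, 20 seeds for
  parameter-recovery averages.

## Known limitations

Random effects are normal and uncorrelated by construction; count,
survival and rank-based outcome families, covariate adjustment,
stratified randomization, informative dropout, more than two
timepoints and cost-based design optimization are out of scope.  Power
estimates inherit every assumption of the data-generating model —
in particular the variance components taken from training data — and
say nothing about threats to validity such as non-random attrition or
systematic measurement error.
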