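# powersim

Monte-Carlo power estimation for cluster-randomized and multi-level
factorial trials.

Closed-form power equations exist for simple parallel designs, but many
field trials do not fit them: treatments deployed at different levels
(a sanitation campaign randomized across villages, nutrient supplements
randomized across households within villages), correlation at several
levels (within-village and within-child), repeated measures and
attrition.  `powersim` estimates power for such designs the direct way:
simulate the trial many times from an assumed data-generating model,
analyze each replicate exactly as the real trial would be analyzed,
and report the fraction of replicates that reject the null.

It is aimed at epidemiologists and applied statisticians planning
cluster-randomized or factorial trials, and at anyone who wants a
transparent, auditable alternative to design-effect formulas.

## The model

Outcomes arise from mixed-effects data-generating models.  For a
two-level continuous outcome (e.g. height-for-age Z-score, HAZ):

    Y_ij = mu + beta1 * A_i + b_i + eps_ij,
    b_i ~ N(0, sigma_g),  eps_ij ~ N(0, sigma_e),  cov(b_i, eps_ij) = 0

where `A_i` is the cluster-level treatment indicator.  The intraclass
correlation is `rho = sigma_g^2 / (sigma_g^2 + sigma_e^2)`.  A binary
outcome replaces the linear model by a logistic one with a cluster
random intercept; the two-treatment factorial design adds a
household-level treatment `X`, an interaction, a child random effect
and a baseline measurement:

    Y_ijt = mu + beta1*A_ijt + beta2*X_ijt + beta3*A_ijt*X_ijt
            + b_i + b_ij + eps_ijt

Each simulated replicate is analyzed with marginal regression (OLS or
logistic ML) and cluster-robust sandwich standard errors at the highest
level of correlation, with small-sample factor G/(G-1); empirical power
is the fraction of Wald p-values below alpha.  The engine also provides
the standard closed-form benchmark for a two-arm parallel CRT,

    power = Phi( sqrt( c*n*d^2 / (2*sigma^2*(1+(n-1)*rho)) ) - z_{alpha/2} ),

null-calibration diagnostics (rejection rate, bootstrapped
Kolmogorov-Smirnov uniformity test, QQ table), minimum-detectable-effect
search, variance-component estimation from training data (REML mixed
models; Gauss-Hermite ML for the binary family), and synthetic
training-data generators.

## Worked example

```python
import powersim as ps

design = ps.DesignSpec(clusters_per_arm=100, units_per_cluster=20)
params = ps.ContinuousParams(mu=-0.875, beta1=0.2, sigma_g=0.482, sigma_e=1.297)
analysis = ps.AnalysisSpec(family="linear", terms=("A",))
scenario = ps.Scenario(design=design, params=params, analysis=analysis,
                       n_reps=2000, seed=42)

est = ps.empirical_power(scenario)
ana = ps.analytic_power(ps.AnalyticPowerSpec(c=100, n=20, d=0.2,
                                             sigma2=1.384**2, rho=0.12))
print(est.primary, ana)
```

prints

```
empirical power : 0.722 (MC SE 0.010, 2000 replicates)
analytic power  : 0.713
```

i.e. with 100 villages per arm and 20 children per village, a +0.2 HAZ
effect is detected in about 72% of trials at alpha = 0.05, and the
simulation agrees with the closed form within Monte-Carlo error — the
agreement is expected, since both derive from the same model, and is
itself a useful check of a simulation setup.  The `examples/` directory
holds one short script per capability (simple CRT power, null
calibration, variance components, factorial power, MDE search); each
prints its numbers with a line on what they mean.

A thin CLI wraps the same functions:

```sh
powersim analytic --c 100 --n 20 --d 0.2 --sd 1.384 --icc 0.12
powersim run --config scenario.yaml --seed 42 --reps 10000
powersim nullcheck --config scenario.yaml --reps 10000
powersim fixture --profile east-java --seed 7 --out train.csv
powersim estimate-params --train train.csv
powersim mde --target 0.8 --c 100 --n 20 --sd 1.384 --icc 0.12
```

## Documentation

`docs/methods.md` describes the data-generating models, the analysis
stage, parameter defaults, numerical choices and known limitations.
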