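"""Monte-Carlo power loop, analytic CRT benchmark and MDE search.

The empirical power of a design is the fraction of simulated
replicates — each freshly randomized, simulated from the assumed
data-generating model, analyzed with cluster-robust regression — whose
Wald p-value falls below the Type-I error rate alpha.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignSpec, build_frame, randomize
from .dgm import (
    BinaryParams,
    ContinuousParams,
    FactorialParams,
    apply_dropout,
    simulate_binary,
    simulate_continuous,
    simulate_factorial,
)
from .inference import AnalysisSpec, fit_cluster_robust, wald_pvalue

__all__ = [
    "Scenario",
    "AnalyticPowerSpec",
    "PowerEstimate",
    "ConvergenceBudgetError",
    "empirical_power",
    "analytic_power",
    "mde_search",
]

logger = logging.getLogger(__name__)

#: fraction of replicates allowed to fail (e.g. logistic non-convergence)
#: before the whole run is considered unusable
MAX_FAILURE_FRACTION = 0.01


class ConvergenceBudgetError(RuntimeError):
    """More than the allowed fraction of replicates failed to converge."""


@dataclass(frozen=True)
class Scenario:
    """A fully specified simulation scenario.

    ``fix_assignment`` draws the randomization once and reuses it for
    every replicate (only the random effects and errors are redrawn, as
    in a fixed-assignment power definition); the default redraws the
    assignment every replicate.
    """

    design: DesignSpec
    params: ContinuousParams | BinaryParams | FactorialParams
    analysis: AnalysisSpec
    n_reps: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    fix_assignment: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.n_reps < 1000:
            logger.warning(
                "n_reps=%d is below 1,000; empirical power will be noisy",
                self.n_reps,
            )

    def effect_names(self) -> tuple[str, ...]:
        if isinstance(self.params, FactorialParams):
            return ("beta1", "beta2", "beta3")
        return ("beta1",)

    def with_effect(self, value: float) -> "Scenario":
        """Scenario with the (single) treatment effect replaced."""
        return replace(self, params=replace(self.params, beta1=value))

    def null(self) -> "Scenario":
        """Scenario with every treatment effect forced to zero."""
        zeros = {name: 0.0 for name in self.effect_names()}
        return replace(self, params=replace(self.params, **zeros))


@dataclass(frozen=True)
class AnalyticPowerSpec:
    """Inputs of the closed-form two-arm parallel-CRT power formula.

    ``c`` clusters per arm, ``n`` individuals per cluster, mean
    difference ``d``, total outcome variance ``sigma2``, intraclass
    correlation ``rho`` and two-sided Type-I error ``alpha``.
    """

    c: int
    n: int
    d: float
    sigma2: float
    rho: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.c < 1 or self.n < 1:
            raise ValueError("c and n must be >= 1")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class PowerEstimate:
    """Empirical power with its Monte-Carlo uncertainty.

    ``power``/``mc_se`` are keyed by tested term.  ``pvalues`` holds
    the per-replicate p-values (at the scenario's sidedness) so that
    calibration diagnostics and alternative thresholds can be derived
    without re-running.
    """

    power: dict[str, float]
    mc_se: dict[str, float]
    alpha: float
    sidedness: str
    n_reps_requested: int
    n_reps_used: int
    n_failed: int
    pvalues: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def primary(self) -> float:
        """Power for the first tested term."""
        return next(iter(self.power.values()))

    def rejection_rate(self, alpha: float | None = None) -> dict[str, float]:
        alpha = self.alpha if alpha is None else alpha
        return {
            term: float(np.mean(p < alpha)) for term, p in self.pvalues.items()
        }


def _simulate_table(
    frame: pd.DataFrame, scenario: Scenario, rng: np.random.Generator
) -> pd.DataFrame:
    params = scenario.params
    if isinstance(params, ContinuousParams):
        table = simulate_continuous(frame, params, rng)
    elif isinstance(params, BinaryParams):
        table = simulate_binary(frame, params, rng)
    elif isinstance(params, FactorialParams):
        table = simulate_factorial(frame, params, rng)
    else:  # pragma: no cover - guarded by Scenario typing
        raise TypeError(f"unsupported params type {type(params)!r}")
    if scenario.design.dropout_rate > 0:
        table = apply_dropout(table, scenario.design.dropout_rate, rng)
    return table


def empirical_power(scenario: Scenario) -> PowerEstimate:
    """Estimate power by Monte-Carlo simulation.

    Each replicate randomizes the design (unless ``fix_assignment``),
    simulates outcomes from the data-generating model, applies
    attrition, fits the cluster-robust analysis model and records the
    Wald p-value for every tested term.  Per-replicate random streams
    are spawned from the master seed, so the result is deterministic
    given the scenario and independent of execution order.
    """
    design, analysis = scenario.design, scenario.analysis
    frame = build_frame(design)
    master = np.random.SeedSequence(scenario.seed)
    streams = master.spawn(scenario.n_reps + 1)
    assigned = None
    if scenario.fix_assignment:
        assigned = randomize(frame, design, np.random.default_rng(streams[0]))

    terms = analysis.test_terms
    pvals: dict[str, list[float]] = {t: [] for t in terms}
    n_failed = 0
    for rep in range(scenario.n_reps):
        rng = np.random.default_rng(streams[rep + 1])
        f = assigned if assigned is not None else randomize(frame, design, rng)
        table = _simulate_table(f, scenario, rng)
        fit = fit_cluster_robust(table, analysis)
        if not fit.converged:
            n_failed += 1
            continue
        df = fit.n_clusters - 1 if analysis.t_reference else None
        for t in terms:
            pvals[t].append(wald_pvalue(fit, t, analysis.sidedness, df=df))

    n_used = scenario.n_reps - n_failed
    if n_failed > MAX_FAILURE_FRACTION * scenario.n_reps:
        raise ConvergenceBudgetError(
            f"{n_failed}/{scenario.n_reps} replicates failed to converge "
            f"(> {MAX_FAILURE_FRACTION:.0%} budget); family={analysis.family}, "
            f"n_obs/replicate≈{len(frame)}, clusters={design.n_clusters}"
        )
    arrays = {t: np.asarray(v) for t, v in pvals.items()}
    power = {t: float(np.mean(a < scenario.alpha)) for t, a in arrays.items()}
    mc_se = {
        t: float(np.sqrt(p * (1.0 - p) / n_used)) for t, p in power.items()
    }
    return PowerEstimate(
        power=power,
        mc_se=mc_se,
        alpha=scenario.alpha,
        sidedness=analysis.sidedness,
        n_reps_requested=scenario.n_reps,
        n_reps_used=n_used,
        n_failed=n_failed,
        pvalues=arrays,
    )


def analytic_power(spec: AnalyticPowerSpec) -> float:
    """Closed-form power of a two-arm parallel CRT with a continuous outcome.

    ``power = Phi( sqrt( c*n*d^2 / (2*sigma2*(1+(n-1)*rho)) ) - z_{alpha/2} )``

    The denominator is twice the total variance inflated by the design
    effect ``1+(n-1)*rho``; the normal approximation matches the
    large-cluster-count regime the simulation engine targets.
    """
    ncp = np.sqrt(
        spec.c * spec.n * spec.d**2 / (2.0 * spec.sigma2 * (1.0 + (spec.n - 1) * spec.rho))
    )
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(ncp - z_alpha))


def mde_search(
    base,
    target_power: float,
    tolerance: float = 1e-4,
    backend: str = "analytic",
    effect_bounds: tuple[float, float] = (0.0, 10.0),
    max_iter: int = 100,
) -> float:
    """Smallest effect size reaching ``target_power`` for a fixed design.

    ``base`` is an :class:`AnalyticPowerSpec` (its ``d`` is ignored)
    for the analytic backend, or a :class:`Scenario` for the
    simulation backend.  Bisection stops when the analytic power is
    within ``tolerance`` of the target, or — for the simulation
    backend — when the target lies inside the estimate's 95%
    Monte-Carlo interval.
    """
    if backend not in ("analytic", "simulation"):
        raise ValueError("backend must be 'analytic' or 'simulation'")
    lo, hi = effect_bounds
    if backend == "analytic":
        if not isinstance(base, AnalyticPowerSpec):
            raise TypeError("analytic backend requires an AnalyticPowerSpec")
        alpha = base.alpha
    else:
        if not isinstance(base, Scenario):
            raise TypeError("simulation backend requires a Scenario")
        alpha = base.alpha
    if not alpha < target_power < 1.0:
        raise ValueError("target_power must lie in (alpha, 1)")

    def power_at(d: float):
        if backend == "analytic":
            return analytic_power(replace(base, d=d)), 0.0
        est = empirical_power(base.with_effect(d))
        return est.primary, next(iter(est.mc_se.values()))

    p_hi, _ = power_at(hi)
    if p_hi < target_power:
        raise ValueError(
            f"target power {target_power} not reachable within effect bound {hi}"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p, se = power_at(mid)
        if backend == "analytic":
            if abs(p - target_power) <= tolerance:
                return mid
        else:
            if abs(p - target_power) <= 1.96 * se:
                return mid
        if p < target_power:
            lo = mid
        else:
            hi = mid
    if backend == "analytic" and hi - lo < tolerance:
        return 0.5 * (lo + hi)
    raise RuntimeError(
        f"MDE bisection did not converge in {max_iter} iterations "
        f"(bracket [{lo:.6g}, {hi:.6g}])"
    )
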