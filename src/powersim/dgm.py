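"""Mixed-effects data-generating models for simulated trial outcomes.

Three outcome families are supported, all built from normal random
effects with zero mean and uncorrelated components:

* continuous two-level: ``y_ij = mu + beta1*A_i + b_i + eps_ij`` with
  ``b_i ~ N(0, sigma_g)`` and ``eps_ij ~ N(0, sigma_e)``;
* binary two-level: ``logit(p_ij) = mu + beta1*A_i + b_i``,
  ``y_ij ~ Bernoulli(p_ij)``;
* continuous three-level factorial with repeated measures:
  ``y_ijt = mu + beta1*A_ijt + beta2*X_ijt + beta3*A_ijt*X_ijt
  + b_i + b_ij + eps_ijt``.

All scale parameters are standard deviations, never variances.

Draws are ordered deterministically — cluster effects first (in
cluster-id order), then child effects, then residuals — so a seeded
generator fully determines the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import KEY_COLUMNS

__all__ = [
    "ContinuousParams",
    "BinaryParams",
    "FactorialParams",
    "simulate_continuous",
    "simulate_binary",
    "simulate_factorial",
    "apply_dropout",
    "treatment_columns",
]


def treatment_columns(frame: pd.DataFrame) -> list[str]:
    """Names of the treatment indicator columns of a population frame."""
    return [c for c in frame.columns if c not in KEY_COLUMNS and c != "y"]


def _check_sd(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} is a standard deviation and must be >= 0")


@dataclass(frozen=True)
class ContinuousParams:
    """Two-level continuous model: control mean, treatment effect, SDs.

    ``beta1`` is the mean difference d on the outcome scale (HAZ units
    in the motivating examples); ``sigma_g`` the cluster random-effect
    SD; ``sigma_e`` the individual residual SD.
    """

    mu: float
    beta1: float
    sigma_g: float
    sigma_e: float

    def __post_init__(self) -> None:
        _check_sd("sigma_g", self.sigma_g)
        _check_sd("sigma_e", self.sigma_e)

    @property
    def total_variance(self) -> float:
        return self.sigma_g**2 + self.sigma_e**2


@dataclass(frozen=True)
class BinaryParams:
    """Two-level logistic model on the log-odds scale.

    ``mu`` is the log-odds of the control-arm outcome probability,
    ``beta1`` the log odds ratio, ``sigma_g`` the cluster
    random-effect SD on the log-odds scale.
    """

    mu: float
    beta1: float
    sigma_g: float

    def __post_init__(self) -> None:
        _check_sd("sigma_g", self.sigma_g)


@dataclass(frozen=True)
class FactorialParams:
    """Three-level factorial model with two treatments and repeat measures.

    ``beta1``/``beta2`` are the main effects of the cluster-level and
    unit-level treatments, ``beta3`` their interaction (synergy).
    ``sigma_v``, ``sigma_c``, ``sigma_e`` are the village, child and
    residual SDs.
    """

    mu: float
    beta1: float
    beta2: float
    beta3: float
    sigma_v: float
    sigma_c: float
    sigma_e: float

    def __post_init__(self) -> None:
        for name in ("sigma_v", "sigma_c", "sigma_e"):
            _check_sd(name, getattr(self, name))


def _sorted_frame(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.sort_values(list(KEY_COLUMNS), kind="mergesort", ignore_index=True)


def simulate_continuous(
    frame: pd.DataFrame,
    params: ContinuousParams,
    rng: np.random.Generator,
    treatment: str | None = None,
) -> pd.DataFrame:
    """Draw continuous outcomes for a single-timepoint two-level frame.

    One cluster effect is drawn per cluster (shared by all its units)
    and one residual per unit.
    """
    cols = treatment_columns(frame)
    if treatment is None:
        if len(cols) != 1:
            raise ValueError(
                f"frame has treatment columns {cols}; pass `treatment` explicitly"
            )
        treatment = cols[0]
    out = _sorted_frame(frame)
    cluster_idx, clusters = pd.factorize(out["cluster_id"], sort=True)
    b = rng.normal(0.0, params.sigma_g, size=len(clusters))
    eps = rng.normal(0.0, params.sigma_e, size=len(out))
    a = out[treatment].to_numpy(dtype=float)
    out["y"] = params.mu + params.beta1 * a + b[cluster_idx] + eps
    return out


def simulate_binary(
    frame: pd.DataFrame,
    params: BinaryParams,
    rng: np.random.Generator,
    treatment: str | None = None,
) -> pd.DataFrame:
    """Draw Bernoulli outcomes through the logistic two-level model."""
    cols = treatment_columns(frame)
    if treatment is None:
        if len(cols) != 1:
            raise ValueError(
                f"frame has treatment columns {cols}; pass `treatment` explicitly"
            )
        treatment = cols[0]
    out = _sorted_frame(frame)
    cluster_idx, clusters = pd.factorize(out["cluster_id"], sort=True)
    b = rng.normal(0.0, params.sigma_g, size=len(clusters))
    a = out[treatment].to_numpy(dtype=float)
    p = expit(params.mu + params.beta1 * a + b[cluster_idx])
    out["y"] = (rng.random(len(out)) < p).astype(np.int64)
    return out


def simulate_factorial(
    frame: pd.DataFrame,
    params: FactorialParams,
    rng: np.random.Generator,
    treatments: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Draw outcomes for the two-treatment factorial repeated-measures model.

    The village effect is drawn once per cluster, the child effect once
    per (cluster, unit) — shared across that child's baseline and
    follow-up rows — and the residual fresh for every row.  Exposure
    indicators are expected to be 0 on baseline rows, so a single
    formula covers both timepoints.
    """
    cols = treatment_columns(frame)
    if treatments is None:
        if len(cols) != 2:
            raise ValueError(
                f"frame has treatment columns {cols}; pass `treatments` explicitly"
            )
        treatments = (cols[0], cols[1])
    a_col, x_col = treatments
    out = _sorted_frame(frame)
    cluster_idx, clusters = pd.factorize(out["cluster_id"], sort=True)
    child_key = out["cluster_id"].astype(np.int64) * (out["unit_id"].max() + 1) + out[
        "unit_id"
    ].astype(np.int64)
    child_idx, children = pd.factorize(child_key, sort=True)
    b_v = rng.normal(0.0, params.sigma_v, size=len(clusters))
    b_c = rng.normal(0.0, params.sigma_c, size=len(children))
    eps = rng.normal(0.0, params.sigma_e, size=len(out))
    a = out[a_col].to_numpy(dtype=float)
    x = out[x_col].to_numpy(dtype=float)
    out["y"] = (
        params.mu
        + params.beta1 * a
        + params.beta2 * x
        + params.beta3 * a * x
        + b_v[cluster_idx]
        + b_c[child_idx]
        + eps
    )
    return out


def apply_dropout(
    table: pd.DataFrame, rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Remove each child's follow-up row independently with probability ``rate``.

    Dropout is completely at random: independent of treatment and
    outcome.  Baseline (t = 0) rows are never removed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("dropout rate must lie in [0, 1]")
    if rate == 0.0:
        return table
    if table["time"].max() < 1:
        raise ValueError("dropout requires a follow-up timepoint (time = 1)")
    key = table["cluster_id"].to_numpy(np.int64) * (
        table["unit_id"].max() + 1
    ) + table["unit_id"].to_numpy(np.int64)
    codes, children = pd.factorize(key, sort=True)
    lost = rng.random(len(children)) < rate
    drop = (table["time"].to_numpy() == 1) & lost[codes]
    return table[~drop].reset_index(drop=True)
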