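"""Synthetic training datasets for variance-component estimation.

Real training datasets (existing cohorts with the outcome measured on
children nested in clusters) are often not shareable.  This module
generates synthetic stand-ins with a declared multi-level variance
structure so the estimation workflow — fit an intercept-only mixed
model, read off the per-level SDs, feed them to the power engine —
can be exercised and tested end to end.

Two named profiles ship with the package, emulating the statistical
shape (not the covariates, age structure or geography) of two field
datasets:

* ``east-java`` — a two-level cross-sectional child-growth survey:
  2,090 children in 160 villages, mean HAZ -0.875, village SD 0.482,
  child SD 1.297 (implied ICC 0.12, total SD 1.384).
* ``india-longitudinal`` — a three-level cohort with up to two HAZ
  measurements per child: 1,236 children in 25 villages, mean -1.98,
  SDs 0.297 (village), 1.259 (child), 1.079 (residual).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FixtureProfile", "PROFILES", "generate_training_fixture"]


@dataclass(frozen=True)
class FixtureProfile:
    """Recipe for one synthetic training dataset.

    ``sds`` has two entries (cluster, residual) for a single-measurement
    profile or three (cluster, child, residual) for a repeated-measures
    profile.  ``second_measurement_retention`` is the probability that a
    child's second measurement is realized when
    ``measurements_per_child == 2``.  Cluster sizes are multinomial
    around the mean (then adjusted so every cluster keeps at least one
    child), emulating field-data imbalance.
    """

    name: str
    n_clusters: int
    total_children: int
    mu: float
    sds: tuple[float, ...]
    measurements_per_child: int = 1
    second_measurement_retention: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_children < self.n_clusters:
            raise ValueError(
                "infeasible profile: fewer children than clusters "
                f"({self.total_children} < {self.n_clusters})"
            )
        if len(self.sds) not in (2, 3):
            raise ValueError("sds must have 2 (two-level) or 3 (three-level) entries")
        if any(s < 0 for s in self.sds):
            raise ValueError("SDs must be >= 0")
        if self.measurements_per_child not in (1, 2):
            raise ValueError("measurements_per_child must be 1 or 2")
        if len(self.sds) == 3 and self.measurements_per_child != 2:
            raise ValueError("a three-level profile needs repeated measurements")
        if not 0.0 <= self.second_measurement_retention <= 1.0:
            raise ValueError("second_measurement_retention must lie in [0, 1]")
        object.__setattr__(self, "sds", tuple(float(s) for s in self.sds))


PROFILES: dict[str, FixtureProfile] = {
    "east-java": FixtureProfile(
        name="east-java",
        n_clusters=160,
        total_children=2090,
        mu=-0.875,
        sds=(0.482, 1.297),
    ),
    "india-longitudinal": FixtureProfile(
        name="india-longitudinal",
        n_clusters=25,
        total_children=1236,
        mu=-1.98,
        sds=(0.297, 1.259, 1.079),
        measurements_per_child=2,
        second_measurement_retention=0.9,
    ),
}


def _cluster_sizes(profile: FixtureProfile, rng: np.random.Generator) -> np.ndarray:
    sizes = rng.multinomial(
        profile.total_children, np.full(profile.n_clusters, 1.0 / profile.n_clusters)
    )
    # every cluster must keep at least one child: move one from the largest
    while (sizes == 0).any():
        sizes[np.argmax(sizes == 0)] += 1
        sizes[np.argmax(sizes)] -= 1
    return sizes


def generate_training_fixture(
    profile: FixtureProfile, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Generate one synthetic training dataset from a profile.

    Returns a long-format frame with columns ``cluster_id``,
    ``unit_id``, ``time`` and ``y`` (time is constant 0 for
    single-measurement profiles).  Outcomes come from the matching
    intercept-only mixed model with no treatment terms.
    """
    rng = np.random.default_rng(profile.seed) if rng is None else rng
    sizes = _cluster_sizes(profile, rng)
    n_children = int(sizes.sum())
    cluster_of_child = np.repeat(np.arange(profile.n_clusters), sizes)
    unit_of_child = np.concatenate([np.arange(s) for s in sizes])

    if len(profile.sds) == 2:
        sigma_g, sigma_e = profile.sds
        b = rng.normal(0.0, sigma_g, size=profile.n_clusters)
        eps = rng.normal(0.0, sigma_e, size=n_children)
        return pd.DataFrame(
            {
                "cluster_id": cluster_of_child,
                "unit_id": unit_of_child,
                "time": 0,
                "y": profile.mu + b[cluster_of_child] + eps,
            }
        )

    sigma_v, sigma_c, sigma_e = profile.sds
    b_v = rng.normal(0.0, sigma_v, size=profile.n_clusters)
    b_c = rng.normal(0.0, sigma_c, size=n_children)
    has_second = rng.random(n_children) < profile.second_measurement_retention
    n_meas = 1 + has_second.astype(np.int64)
    cluster_col = np.repeat(cluster_of_child, n_meas)
    unit_col = np.repeat(unit_of_child, n_meas)
    child_col = np.repeat(np.arange(n_children), n_meas)
    time_col = np.concatenate([np.arange(m) for m in n_meas])
    eps = rng.normal(0.0, sigma_e, size=int(n_meas.sum()))
    return pd.DataFrame(
        {
            "cluster_id": cluster_col,
            "unit_id": unit_col,
            "time": time_col,
            "y": profile.mu + b_v[cluster_col] + b_c[child_col] + eps,
        }
    )
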