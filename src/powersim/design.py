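"""Population skeletons and randomization for cluster/factorial trial designs.

A design is described by a :class:`DesignSpec` (geometry plus the
randomization plan); :func:`build_frame` expands it into one row per
(cluster, unit, time) and :func:`randomize` draws the treatment
assignment at the declared level(s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DesignSpec", "build_frame", "randomize", "DesignError"]

#: key columns of a population frame, in order
KEY_COLUMNS = ("cluster_id", "unit_id", "time")


class DesignError(ValueError):
    """A design violates one of its structural invariants."""


@dataclass(frozen=True)
class DesignSpec:
    """Geometry and randomization plan of a (possibly factorial) trial.

    Parameters
    ----------
    arms
        Number of treatment arms; 2 for a simple parallel CRT.
    clusters_per_arm
        Clusters (villages, communities) per arm, ``c``.
    units_per_cluster
        Units (children, households) enrolled per cluster, ``n``.
        One child per household is assumed, so no separate household
        level exists.
    timepoints
        1 for a single post-intervention measurement, 2 for a
        baseline + follow-up design.
    cluster_level_treatments
        Treatment labels randomized across whole clusters (balanced
        1:1, exactly half the clusters treated).
    unit_level_treatments
        Treatment labels randomized across units within every cluster.
    unit_allocation_fraction
        Fraction of units per cluster receiving each unit-level
        treatment; must yield an integer count per cluster.
    dropout_rate
        Probability that a unit's follow-up record is missing
        (requires ``timepoints == 2``).
    """

    clusters_per_arm: int
    units_per_cluster: int
    arms: int = 2
    timepoints: int = 1
    cluster_level_treatments: tuple[str, ...] = ("A",)
    unit_level_treatments: tuple[str, ...] = ()
    unit_allocation_fraction: float = 0.5
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.arms < 1:
            raise DesignError("arms must be >= 1")
        if self.clusters_per_arm < 1:
            raise DesignError("clusters_per_arm must be >= 1")
        if self.units_per_cluster < 1:
            raise DesignError("units_per_cluster must be >= 1")
        if self.timepoints not in (1, 2):
            raise DesignError("timepoints must be 1 or 2")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise DesignError("dropout_rate must lie in [0, 1]")
        if self.dropout_rate > 0 and self.timepoints != 2:
            raise DesignError(
                "dropout_rate > 0 requires timepoints = 2 (dropout removes "
                "the follow-up record)"
            )
        if self.unit_level_treatments:
            k = self.unit_allocation_fraction * self.units_per_cluster
            if abs(k - round(k)) > 1e-9 or round(k) < 1:
                raise DesignError(
                    "unit_allocation_fraction * units_per_cluster must be a "
                    f"positive integer, got {k!r}"
                )
        overlap = set(self.cluster_level_treatments) & set(self.unit_level_treatments)
        if overlap:
            raise DesignError(f"treatment labels used at both levels: {sorted(overlap)}")
        # normalize to tuples so specs are hashable even if lists were passed
        object.__setattr__(
            self, "cluster_level_treatments", tuple(self.cluster_level_treatments)
        )
        object.__setattr__(
            self, "unit_level_treatments", tuple(self.unit_level_treatments)
        )

    @property
    def n_clusters(self) -> int:
        return self.arms * self.clusters_per_arm

    @property
    def treatments(self) -> tuple[str, ...]:
        return self.cluster_level_treatments + self.unit_level_treatments


def build_frame(design: DesignSpec) -> pd.DataFrame:
    """Expand a design into its population frame.

    Returns one row per (cluster, unit, time) with globally unique
    cluster ids, unit ids unique within each cluster, and every
    treatment column initialized to 0.  Randomization has not happened
    yet; call :func:`randomize`.
    """
    C = design.n_clusters
    n = design.units_per_cluster
    T = design.timepoints
    cluster = np.repeat(np.arange(C), n * T)
    unit = np.tile(np.repeat(np.arange(n), T), C)
    time = np.tile(np.arange(T), C * n)
    frame = pd.DataFrame({"cluster_id": cluster, "unit_id": unit, "time": time})
    for label in design.treatments:
        frame[label] = 0
    return frame


def randomize(
    frame: pd.DataFrame, design: DesignSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw a treatment assignment for ``frame`` at the declared levels.

    Cluster-level treatments use balanced complete randomization:
    exactly half the clusters receive each treatment (the labels are
    permuted first, so cluster ids carry no arm information).
    Unit-level treatments are exactly balanced within every cluster at
    ``unit_allocation_fraction``.  With two timepoints the exposure
    indicators are set on follow-up rows only — at baseline (t = 0)
    nobody has been treated yet.
    """
    out = frame.copy()
    cluster_idx = out["cluster_id"].to_numpy()
    C = design.n_clusters
    # rows on which exposure indicators are switched on
    if design.timepoints == 2:
        exposed = out["time"].to_numpy() == 1
    else:
        exposed = np.ones(len(out), dtype=bool)

    for label in design.cluster_level_treatments:
        if C % 2:
            raise DesignError(
                f"cannot split {C} clusters 1:1 for cluster-level "
                f"treatment {label!r}; use an even cluster count"
            )
        treated = np.zeros(C, dtype=np.int64)
        treated[rng.permutation(C)[: C // 2]] = 1
        out[label] = np.where(exposed, treated[cluster_idx], 0)

    if design.unit_level_treatments:
        n = design.units_per_cluster
        k = round(design.unit_allocation_fraction * n)
        for label in design.unit_level_treatments:
            # one exact-balance draw per cluster: a (C, n) 0/1 matrix
            picks = np.zeros((C, n), dtype=np.int64)
            for c in range(C):
                picks[c, rng.permutation(n)[:k]] = 1
            unit_idx = out["unit_id"].to_numpy()
            out[label] = np.where(exposed, picks[cluster_idx, unit_idx], 0)
    return out
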