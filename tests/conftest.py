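from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import powersim as ps

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_linear() -> pd.DataFrame:
    """Six observations in three clusters with a cluster-level treatment."""
    return pd.read_csv(DATA_DIR / "toy_linear.csv")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def simple_crt_design() -> ps.DesignSpec:
    """2 arms x 100 clusters/arm x 10 children, one cluster-level treatment."""
    return ps.DesignSpec(clusters_per_arm=100, units_per_cluster=10)


@pytest.fixture
def east_java_params() -> ps.ContinuousParams:
    """Two-level continuous parameters estimated from the East Java survey."""
    return ps.ContinuousParams(mu=-0.875, beta1=0.0, sigma_g=0.482, sigma_e=1.297)


@pytest.fixture
def factorial_design() -> ps.DesignSpec:
    """Factorial geometry: sanitation at village level, LNS to half the
    households, baseline + follow-up, 10% dropout."""
    return ps.DesignSpec(
        clusters_per_arm=30,
        units_per_cluster=20,
        timepoints=2,
        cluster_level_treatments=("A",),
        unit_level_treatments=("X",),
        unit_allocation_fraction=0.5,
        dropout_rate=0.1,
    )


@pytest.fixture
def india_params() -> ps.FactorialParams:
    """Three-level parameters estimated from the India cohort."""
    return ps.FactorialParams(
        mu=-1.98,
        beta1=0.15,
        beta2=0.15,
        beta3=0.15,
        sigma_v=0.297,
        sigma_c=1.259,
        sigma_e=1.079,
    )
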