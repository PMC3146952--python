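import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import powersim as ps


def brute_force_cluster_sandwich(data, terms=("A",)):
    """Independent matrix-arithmetic oracle for the CR1 clustered sandwich."""
    y = data["y"].to_numpy(float)
    X = np.column_stack([np.ones(len(data))] + [data[t].to_numpy(float) for t in terms])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    bread = np.linalg.inv(X.T @ X)
    meat = np.zeros((X.shape[1], X.shape[1]))
    clusters = data["cluster_id"].unique()
    for g in clusters:
        rows = (data["cluster_id"] == g).to_numpy()
        s_g = X[rows].T @ resid[rows]
        meat += np.outer(s_g, s_g)
    G = len(clusters)
    V = G / (G - 1) * bread @ meat @ bread
    return beta, np.sqrt(np.diag(V))


class TestClusterRobustFit:
    def test_toy_matches_brute_force(self, toy_linear):
        spec = ps.AnalysisSpec(family="linear", terms=("A",))
        fit = ps.fit_cluster_robust(toy_linear, spec)
        beta, se = brute_force_cluster_sandwich(toy_linear)
        assert fit.coefficients["Intercept"] == pytest.approx(beta[0], rel=1e-10)
        assert fit.coefficients["A"] == pytest.approx(beta[1], rel=1e-10)
        assert fit.robust_se["Intercept"] == pytest.approx(se[0], rel=1e-10)
        assert fit.robust_se["A"] == pytest.approx(se[1], rel=1e-10)

    def test_singleton_clusters_reduce_to_observation_sandwich(self):
        """One unit per cluster: the clustered estimator equals the
        heteroskedasticity-robust per-observation sandwich (same factor)."""
        rng = np.random.default_rng(21)
        n = 60
        data = pd.DataFrame(
            {
                "cluster_id": np.arange(n),
                "unit_id": 0,
                "time": 0,
                "A": rng.integers(0, 2, n),
                "y": rng.normal(size=n),
            }
        )
        spec = ps.AnalysisSpec(terms=("A",))
        fit = ps.fit_cluster_robust(data, spec)
        y = data["y"].to_numpy()
        X = np.column_stack([np.ones(n), data["A"].to_numpy(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        e = y - X @ beta
        bread = np.linalg.inv(X.T @ X)
        meat = (X * (e**2)[:, None]).T @ X  # HC0 per-observation
        V = n / (n - 1) * bread @ meat @ bread
        se = np.sqrt(np.diag(V))
        assert fit.robust_se["A"] == pytest.approx(se[1], rel=1e-10)

    def test_row_shuffle_invariance(self, toy_linear):
        spec = ps.AnalysisSpec(terms=("A",))
        fit = ps.fit_cluster_robust(toy_linear, spec)
        shuffled = toy_linear.sample(frac=1, random_state=3).reset_index(drop=True)
        fit2 = ps.fit_cluster_robust(shuffled, spec)
        assert fit.coefficients["A"] == pytest.approx(fit2.coefficients["A"])
        assert fit.robust_se["A"] == pytest.approx(fit2.robust_se["A"])

    def test_perfect_separation_flagged(self):
        data = pd.DataFrame(
            {
                "cluster_id": [0, 0, 1, 1],
                "unit_id": [0, 1, 0, 1],
                "time": 0,
                "A": [0.0, 0.0, 1.0, 1.0],
                "y": [0.0, 0.0, 1.0, 1.0],
            }
        )
        spec = ps.AnalysisSpec(family="logistic", terms=("A",))
        fit = ps.fit_cluster_robust(data, spec)
        assert not fit.converged

    def test_logistic_fit_recovers_log_odds_ratio(self):
        rng = np.random.default_rng(22)
        design = ps.DesignSpec(clusters_per_arm=100, units_per_cluster=50)
        frame = ps.randomize(ps.build_frame(design), design, rng)
        params = ps.BinaryParams(mu=-1.0, beta1=0.6, sigma_g=0.0)
        table = ps.simulate_binary(frame, params, rng)
        fit = ps.fit_cluster_robust(
            table, ps.AnalysisSpec(family="logistic", terms=("A",))
        )
        assert fit.converged
        assert fit.coefficients["A"] == pytest.approx(0.6, abs=0.15)

    def test_too_few_clusters_rejected(self, toy_linear):
        one = toy_linear[toy_linear["cluster_id"] == 0]
        with pytest.raises(ValueError, match="2 clusters"):
            ps.fit_cluster_robust(one, ps.AnalysisSpec(terms=("A",)))


class TestWaldPvalue:
    def _fit(self, z):
        return ps.FitResult(
            terms=("Intercept", "A"),
            coefficients={"Intercept": 0.0, "A": float(z)},
            robust_se={"Intercept": 1.0, "A": 1.0},
            n_obs=10,
            n_clusters=5,
        )

    def test_zero_statistic_gives_p_one(self):
        assert ps.wald_pvalue(self._fit(0.0), "A", "two") == pytest.approx(1.0)

    def test_critical_value(self):
        assert ps.wald_pvalue(self._fit(1.959964), "A", "two") == pytest.approx(
            0.05, abs=1e-6
        )

    def test_one_sided_is_half_two_sided(self):
        for z in (0.7, -0.7, 2.3):
            two = ps.wald_pvalue(self._fit(z), "A", "two")
            one = ps.wald_pvalue(self._fit(z), "A", "one")
            assert one == pytest.approx(two / 2)

    def test_t_reference_is_more_conservative(self):
        fit = self._fit(2.0)
        p_norm = ps.wald_pvalue(fit, "A", "two")
        p_t = ps.wald_pvalue(fit, "A", "two", df=10)
        assert p_t > p_norm

    def test_non_converged_fit_rejected(self):
        bad = ps.FitResult(
            terms=("Intercept", "A"),
            coefficients={"Intercept": np.nan, "A": np.nan},
            robust_se={"Intercept": np.nan, "A": np.nan},
            n_obs=4,
            n_clusters=2,
            converged=False,
        )
        with pytest.raises(ValueError):
            ps.wald_pvalue(bad, "A")


class TestVarianceComponents:
    def test_two_level_recovery(self):
        profile = ps.PROFILES["east-java"]
        table = ps.generate_training_fixture(profile, np.random.default_rng(30))
        vc = ps.estimate_variance_components(table, "two_level")
        assert vc.sigma_g == pytest.approx(0.482, abs=0.05)
        assert vc.sigma_e == pytest.approx(1.297, abs=0.05)
        assert vc.mu == pytest.approx(-0.875, abs=0.15)

    def test_three_level_recovery(self):
        profile = ps.PROFILES["india-longitudinal"]
        table = ps.generate_training_fixture(profile, np.random.default_rng(31))
        vc = ps.estimate_variance_components(table, "three_level")
        assert vc.sigma_g == pytest.approx(0.297, rel=0.30)
        assert vc.sigma_c == pytest.approx(1.259, rel=0.15)
        assert vc.sigma_e == pytest.approx(1.079, rel=0.15)

    def test_no_between_cluster_variance_reported_as_zero(self):
        rng = np.random.default_rng(32)
        n_clusters, n_units = 40, 20
        table = pd.DataFrame(
            {
                "cluster_id": np.repeat(np.arange(n_clusters), n_units),
                "unit_id": np.tile(np.arange(n_units), n_clusters),
                "y": rng.normal(0.0, 1.0, n_clusters * n_units),
            }
        )
        vc = ps.estimate_variance_components(table, "two_level")
        assert vc.sigma_g == pytest.approx(0.0, abs=0.1)

    def test_unreplicated_level_rejected(self):
        table = pd.DataFrame(
            {"cluster_id": [0, 1, 2, 3], "unit_id": 0, "y": [0.1, 0.2, 0.3, 0.4]}
        )
        with pytest.raises(ValueError, match="cluster"):
            ps.estimate_variance_components(table, "two_level")

    def test_binary_quadrature_recovery(self):
        rng = np.random.default_rng(33)
        design = ps.DesignSpec(clusters_per_arm=150, units_per_cluster=30)
        frame = ps.randomize(ps.build_frame(design), design, rng)
        params = ps.BinaryParams(mu=-1.2, beta1=0.0, sigma_g=0.6)
        table = ps.simulate_binary(frame, params, rng)
        vc = ps.estimate_variance_components(table, "two_level", family="logistic")
        assert vc.family == "logistic"
        assert vc.mu == pytest.approx(-1.2, abs=0.15)
        assert vc.sigma_g == pytest.approx(0.6, abs=0.12)

    def test_mean_bias_below_five_percent(self):
        """Averaged over repeated training sets at the two-level survey
        geometry, REML SD estimates are nearly unbiased."""
        profile = ps.PROFILES["east-java"]
        g, e = [], []
        for seed in range(50):
            table = ps.generate_training_fixture(
                profile, np.random.default_rng(1000 + seed)
            )
            vc = ps.estimate_variance_components(table, "two_level")
            g.append(vc.sigma_g)
            e.append(vc.sigma_e)
        assert abs(np.mean(g) - 0.482) < 0.05 * 0.482
        assert abs(np.mean(e) - 1.297) < 0.05 * 1.297


class TestIcc:
    def test_east_java_value(self):
        assert round(ps.icc(0.482, 1.297), 2) == 0.12

    @given(s=st.floats(0.01, 10.0))
    @settings(deadline=None, max_examples=25)
    def test_degenerate_limits(self, s):
        assert ps.icc(s, 0.0) == pytest.approx(1.0)
        assert ps.icc(0.0, s) == pytest.approx(0.0)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            ps.icc(0.0, 0.0)

    @given(
        sg=st.floats(0.01, 5.0),
        se=st.floats(0.01, 5.0),
        delta=st.floats(0.01, 1.0),
    )
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_components(self, sg, se, delta):
        assert ps.icc(sg + delta, se) > ps.icc(sg, se)
        assert ps.icc(sg, se + delta) < ps.icc(sg, se)


def test_read_training_data_renames_and_validates(tmp_path):
    df = pd.DataFrame(
        {
            "village": [0, 0, 1, 1],
            "child": [0, 1, 0, 1],
            "haz": [-1.0, -0.5, -2.0, -1.5],
        }
    )
    path = tmp_path / "train.csv"
    df.to_csv(path, index=False)
    out = ps.read_training_data(
        path, cluster_col="village", unit_col="child", outcome_col="haz"
    )
    assert list(out.columns) == ["cluster_id", "unit_id", "y"]
    with pytest.raises(ValueError, match="not found"):
        ps.read_training_data(path, cluster_col="nope", unit_col="child", outcome_col="haz")
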