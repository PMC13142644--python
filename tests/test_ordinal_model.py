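"""Likelihood, inner Newton, Laplace approximation, and the outer fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, sparse

import washord as w
from washord.ordinal_model import (FitConfig, ModelParams, RandomEffects,
                                   _Workspace, thresholds_from_raw)
from washord.synthetic_data import SurveyDataset

from conftest import make_config


def cluster_only_dataset(n_clusters, households, beta, thresholds, sigma_b,
                         seed):
    """Tiny cluster-effect-only survey with hand-drawn covariates."""
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_clusters):
        b = rng.normal(0, sigma_b)
        for _ in range(households):
            x = rng.normal(size=len(beta))
            z = float(x @ beta + b)
            p = w.class_probabilities(z, thresholds)
            y = int(rng.choice(len(p), p=p))
            rows.append((c, *x, y))
    df = pd.DataFrame(rows, columns=["cluster_id",
                                     *[f"x{j}" for j in range(len(beta))],
                                     "y"])
    df["household_id"] = np.arange(len(df))
    df["lon"] = df["cluster_id"].astype(float)
    df["lat"] = 0.0
    clusters = pd.DataFrame({"cluster_id": np.arange(n_clusters),
                             "lon": np.arange(n_clusters, dtype=float),
                             "lat": 0.0})
    return SurveyDataset(households=df, clusters=clusters,
                         K=len(thresholds) + 1,
                         design_columns=[f"x{j}" for j in range(len(beta))],
                         standardization={}, covariate_spec=[])


def gauss_hermite_marginal_nll(data, beta, thresholds, sigma_b, n_pts=61):
    """Independent quadrature oracle: per-cluster 61-point Gauss–Hermite
    integration of the cluster random effect."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_pts)
    total = 0.0
    X = data.X
    y = data.households["y"].to_numpy()
    cl = data.households["cluster_id"].to_numpy()
    for c in np.unique(cl):
        sel = cl == c
        eta = X[sel] @ beta
        # ∫ Π p(y_i | η_i + b) φ(b; σ_b) db  via  b = √2 σ_b t
        lik = 0.0
        for t, wt in zip(nodes, weights):
            b = np.sqrt(2.0) * sigma_b * t
            lik += wt * np.exp(
                -w.ordinal_nll(y[sel], eta + b, thresholds).sum())
        total -= np.log(lik / np.sqrt(np.pi))
    return total


class TestThresholds:
    @pytest.mark.parametrize("theta1,log_deltas,expected", [
        (-1.0, [0.0], [-1.0, 0.0]),
        (0.0, [], [0.0]),
        (2.0, [np.log(0.5), np.log(2.0)], [2.0, 2.5, 4.5]),
    ])
    def test_known_values(self, theta1, log_deltas, expected):
        np.testing.assert_allclose(thresholds_from_raw(theta1, log_deltas),
                                   expected)

    @given(st.floats(-5, 5),
           st.lists(st.floats(-4, 4), min_size=0, max_size=3))
    def test_always_strictly_increasing(self, theta1, log_deltas):
        th = thresholds_from_raw(theta1, log_deltas)
        assert np.all(np.diff(th) > 0)


class TestClassProbabilities:
    def test_symmetric_binary(self):
        np.testing.assert_allclose(w.class_probabilities(0.0, [0.0]),
                                   [0.5, 0.5])

    def test_three_category_logistic_values(self):
        np.testing.assert_allclose(
            w.class_probabilities(0.0, [-1.0, 1.0]),
            [0.26894, 0.46212, 0.26894], atol=5e-6)

    @given(st.floats(-30, 30), st.floats(-3, 3),
           st.floats(0.1, 4), st.floats(0.1, 4))
    def test_rows_sum_to_one(self, z, t1, d1, d2):
        p = w.class_probabilities(z, [t1, t1 + d1, t1 + d1 + d2])
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= 0)

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError):
            w.class_probabilities(0.0, [1.0, -1.0])


class TestOrdinalNll:
    def test_symmetric_binary_is_log2(self):
        assert w.ordinal_nll(0, 0.0, [0.0]) == pytest.approx(np.log(2))

    @pytest.mark.parametrize("z", [-35.0, 35.0])
    def test_stable_in_far_tails(self, z):
        vals = [w.ordinal_nll(k, z, [-1.0, 1.0]) for k in range(3)]
        assert np.all(np.isfinite(vals))
        assert np.all(np.asarray(vals) >= 0)

    def test_interior_category_minimized_between_thresholds(self):
        # 1-D grid-search oracle for the minimizing latent value
        th = [-1.0, 1.0]
        zgrid = np.linspace(-6, 6, 4001)
        zmin = zgrid[np.argmin([w.ordinal_nll(1, z, th) for z in zgrid])]
        assert -1.0 < zmin < 1.0
        assert zmin == pytest.approx(0.0, abs=0.01)

    def test_matches_direct_probability(self):
        rng = np.random.default_rng(0)
        th = np.array([-1.0, 0.3, 1.7])
        z = rng.normal(0, 2, 50)
        y = rng.integers(0, 4, 50)
        direct = -np.log(
            w.class_probabilities(z, th)[np.arange(50), y])
        np.testing.assert_allclose(w.ordinal_nll(y, z, th), direct,
                                   rtol=1e-10)

    def test_invalid_category_rejected(self):
        with pytest.raises(ValueError):
            w.ordinal_nll(3, 0.0, [0.0, 1.0])

    def test_location_invariance_with_threshold_shift(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=20)
        y = rng.integers(0, 3, 20)
        th = np.array([-0.5, 0.8])
        base = w.ordinal_nll(y, z, th)
        shifted = w.ordinal_nll(y, z + 2.7, th + 2.7)
        np.testing.assert_allclose(shifted, base, rtol=1e-9)


class TestJointNll:
    def test_gaussian_constant_at_origin(self):
        # b = 0, σ_b = 1: cluster penalty reduces to (n_c/2)·log(2π)
        data = cluster_only_dataset(4, 5, np.array([0.5]),
                                    np.array([0.0]), 0.5, seed=2)
        params = ModelParams(beta=[0.5], theta1=0.0, log_deltas=[],
                             log_sigma_b=0.0)
        re = RandomEffects(b=np.zeros(4), w=[])
        total = w.joint_nll(params, re, data)
        data_term = w.ordinal_nll(
            data.households["y"].to_numpy(),
            data.X @ np.array([0.5]), [0.0]).sum()
        assert total == pytest.approx(data_term + 2 * np.log(2 * np.pi))

    def test_matches_dense_reimplementation(self, small_survey):
        """Sparse joint NLL equals an independent dense-matrix computation
        on a 30-household subset."""
        keep = small_survey.clusters["cluster_id"].iloc[:4]
        pool = small_survey.households[
            small_survey.households["cluster_id"].isin(keep)]
        sub_h = pool.groupby("cluster_id").head(8).reset_index(drop=True)
        sub_c = small_survey.clusters[
            small_survey.clusters["cluster_id"].isin(
                sub_h["cluster_id"].unique())].reset_index(drop=True)
        data = SurveyDataset(households=sub_h, clusters=sub_c,
                             K=small_survey.K,
                             design_columns=small_survey.design_columns,
                             standardization=small_survey.standardization,
                             covariate_spec=small_survey.covariate_spec)
        mesh = w.build_mesh(sub_c[["lon", "lat"]].to_numpy(),
                            buffer_fraction=0.3, max_edge=3.0)
        A = w.projection_matrix(mesh, sub_c[["lon", "lat"]].to_numpy())
        params = ModelParams(beta=[0.4, -0.3, 0.2], theta1=-0.8,
                             log_deltas=[0.3], log_sigma_b=np.log(0.6),
                             log_range=np.log(3.0), log_sigma_u=np.log(0.7))
        rng = np.random.default_rng(3)
        re = RandomEffects(b=rng.normal(0, 0.3, len(sub_c)),
                           w=rng.normal(0, 0.3, mesh.n_nodes))
        sparse_val = w.joint_nll(params, re, data, mesh, A)

        # dense oracle, written from the definitions
        codes = pd.factorize(sub_h["cluster_id"], sort=True)[0]
        z = (data.X @ params.beta
             + np.asarray((A @ re.w))[codes] + re.b[codes])
        term1 = w.ordinal_nll(sub_h["y"].to_numpy(), z,
                              params.thresholds).sum()
        sb = params.sigma_b
        term2 = (len(sub_c) / 2 * np.log(2 * np.pi)
                 + len(sub_c) * np.log(sb)
                 + 0.5 * np.sum(re.b**2) / sb**2)
        Q = w.precision_matrix(mesh, params.spatial).toarray()
        sign, logdet = np.linalg.slogdet(Q)
        term3 = (mesh.n_nodes / 2 * np.log(2 * np.pi) - 0.5 * logdet
                 + 0.5 * re.w @ Q @ re.w)
        assert sparse_val == pytest.approx(term1 + term2 + term3, abs=1e-8)


class TestInnerMode:
    def test_gradient_small_at_mode(self):
        data = cluster_only_dataset(6, 20, np.array([0.7]),
                                    np.array([-0.5, 0.5]), 0.6, seed=4)
        params = ModelParams(beta=[0.7], theta1=-0.5, log_deltas=[0.0],
                             log_sigma_b=np.log(0.6))
        re, H = w.inner_mode(params, data, tol=1e-9)
        # finite-difference gradient of the joint NLL at the mode
        f0 = w.joint_nll(params, re, data)
        for i in range(len(re.b)):
            bp = re.b.copy(); bp[i] += 1e-6
            g = (w.joint_nll(params, RandomEffects(bp, re.w), data) - f0) / 1e-6
            assert abs(g) < 1e-4

    def test_flat_prior_limit_matches_per_cluster_mle(self):
        # σ_b → ∞: the mode is each cluster's 1-D maximum-likelihood offset
        data = cluster_only_dataset(5, 40, np.array([0.5]),
                                    np.array([0.0]), 0.8, seed=5)
        params = ModelParams(beta=[0.5], theta1=0.0, log_deltas=[],
                             log_sigma_b=np.log(100.0))
        re, _ = w.inner_mode(params, data, tol=1e-10)
        X = data.X
        y = data.households["y"].to_numpy()
        cl = data.households["cluster_id"].to_numpy()
        for c in range(5):
            sel = cl == c
            eta = X[sel] @ np.array([0.5])

            def nll_c(b):
                return w.ordinal_nll(y[sel], eta + b, [0.0]).sum()

            oracle = optimize.minimize_scalar(nll_c, bounds=(-5, 5),
                                              method="bounded").x
            assert re.b[c] == pytest.approx(oracle, abs=5e-3)

    def test_mode_invariant_to_row_permutation(self):
        data = cluster_only_dataset(4, 15, np.array([0.6]),
                                    np.array([0.0]), 0.5, seed=6)
        params = ModelParams(beta=[0.6], theta1=0.0, log_deltas=[],
                             log_sigma_b=np.log(0.5))
        re1, _ = w.inner_mode(params, data)
        perm = np.random.default_rng(0).permutation(len(data.households))
        data2 = SurveyDataset(
            households=data.households.iloc[perm].reset_index(drop=True),
            clusters=data.clusters, K=data.K,
            design_columns=data.design_columns,
            standardization={}, covariate_spec=[])
        re2, _ = w.inner_mode(params, data2)
        np.testing.assert_allclose(re1.b, re2.b, atol=1e-7)

    def test_newton_trajectory_nonincreasing(self):
        data = cluster_only_dataset(8, 25, np.array([0.7]),
                                    np.array([-0.5, 0.5]), 0.6, seed=7)
        params = ModelParams(beta=[0.7], theta1=-0.5, log_deltas=[0.0],
                             log_sigma_b=np.log(0.6))
        ws = _Workspace(data, None, None)
        _, _, _, traj = ws.newton_mode(params, tol=1e-9)
        diffs = np.diff(traj)
        assert np.all(diffs <= 1e-9 * (1 + np.abs(traj[:-1])))


class TestLaplaceMarginal:
    def test_symmetric_single_household_near_exact(self):
        """One household, K = 2, θ = 0, β = 0, σ_b = 1: the exact marginal
        probability is 0.5 by symmetry of ∫σ(±b)φ(b)db."""
        data = cluster_only_dataset(1, 1, np.array([0.0]),
                                    np.array([0.0]), 1.0, seed=8)
        params = ModelParams(beta=[0.0], theta1=0.0, log_deltas=[],
                             log_sigma_b=0.0)
        nll = w.laplace_marginal_nll(params, data)
        assert nll == pytest.approx(np.log(2), rel=0.02)

    def test_matches_gauss_hermite_quadrature(self):
        data = cluster_only_dataset(5, 25, np.array([0.6, -0.4]),
                                    np.array([-0.8, 0.8]), 0.5, seed=9)
        params = ModelParams(beta=[0.6, -0.4], theta1=-0.8, log_deltas=[0.47],
                             log_sigma_b=np.log(0.5))
        laplace = w.laplace_marginal_nll(params, data)
        oracle = gauss_hermite_marginal_nll(
            data, np.array([0.6, -0.4]), params.thresholds, 0.5)
        assert laplace == pytest.approx(oracle, rel=1e-3)

    def test_vanishing_sigma_b_recovers_fixed_effects_nll(self):
        data = cluster_only_dataset(4, 20, np.array([0.5]),
                                    np.array([0.0]), 0.3, seed=10)
        params = ModelParams(beta=[0.5], theta1=0.0, log_deltas=[],
                             log_sigma_b=np.log(1e-6))
        marg = w.laplace_marginal_nll(params, data)
        fixed = w.ordinal_nll(data.households["y"].to_numpy(),
                              data.X @ np.array([0.5]), [0.0]).sum()
        assert marg == pytest.approx(fixed, rel=1e-6)


class TestFit:
    def test_recovers_beta_without_random_effects(self):
        # data generated with σ_u = σ_b = 0 at n ≈ 5000
        cfg = make_config(n_clusters=200, households_per_cluster=(25, 25),
                          sigma_b=0.0, sigma_u=0.0, seed=14)
        data = w.simulate_survey(cfg)
        model = w.fit(data, fit_config=FitConfig(use_spatial=False))
        assert np.all(np.abs(model.params.beta - cfg.beta)
                      < 3 * model.beta_se)

    def test_refit_is_deterministic(self, nospatial_fit):
        cfg, data, model = nospatial_fit
        again = w.fit(data, fit_config=FitConfig(use_spatial=False))
        np.testing.assert_allclose(again.params.beta, model.params.beta,
                                   atol=1e-8)
        np.testing.assert_allclose(again.params.theta1, model.params.theta1,
                                   atol=1e-8)

    def test_unobserved_category_rejected(self):
        cfg = make_config(n_clusters=10, seed=15)
        data = w.simulate_survey(cfg)
        data.households.loc[data.households["y"] == 2, "y"] = 1
        with pytest.raises(ValueError, match="merge"):
            w.fit(data, fit_config=FitConfig(use_spatial=False))

    def test_intercept_shift_absorbed_by_thresholds(self):
        """No intercept column: a location shift of the latent scale must
        appear in θ̂, not in β̂."""
        cfg_a = make_config(n_clusters=120, sigma_b=0.0, sigma_u=0.0,
                            thresholds=np.array([-1.0, 1.0]), seed=16)
        cfg_b = make_config(n_clusters=120, sigma_b=0.0, sigma_u=0.0,
                            thresholds=np.array([-1.0, 1.0]) + 1.5, seed=16)
        fit_cfg = FitConfig(use_spatial=False, compute_cov=False)
        m_a = w.fit(w.simulate_survey(cfg_a), fit_config=fit_cfg)
        m_b = w.fit(w.simulate_survey(cfg_b), fit_config=fit_cfg)
        shift = m_b.params.thresholds.mean() - m_a.params.thresholds.mean()
        assert shift == pytest.approx(1.5, abs=0.25)
        np.testing.assert_allclose(m_b.params.beta, m_a.params.beta,
                                   atol=0.15)

    def test_covariate_rescaling_rescales_coefficient(self, nospatial_fit):
        cfg, data, model = nospatial_fit
        scaled = SurveyDataset(
            households=data.households.assign(
                hdi=data.households["hdi"] * 4.0),
            clusters=data.clusters, K=data.K,
            design_columns=data.design_columns,
            standardization=data.standardization,
            covariate_spec=data.covariate_spec)
        m2 = w.fit(scaled, fit_config=FitConfig(use_spatial=False,
                                                compute_cov=False))
        j = data.design_columns.index("hdi")
        assert m2.params.beta[j] == pytest.approx(model.params.beta[j] / 4.0,
                                                  abs=2e-3)

    def test_save_load_round_trip(self, nospatial_fit, tmp_path):
        _, _, model = nospatial_fit
        model.save(tmp_path / "model")
        loaded = w.FittedModel.load(tmp_path / "model")
        np.testing.assert_array_equal(loaded.params.beta, model.params.beta)
        np.testing.assert_array_equal(loaded.param_cov, model.param_cov)
        assert loaded.K == model.K
        assert loaded.standardization == model.standardization
        assert abs(loaded.conditional_precision
                   - model.conditional_precision).max() == 0
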