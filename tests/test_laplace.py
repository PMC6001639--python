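"""Gaussian approximation, hyper exploration, marginals and DIC."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import nmala as nm
from nmala.data import build_layout, enumerate_designs
from nmala.laplace import LaplaceEngine, MarginalDensity, explore_hyper
from nmala.model import HyperParams, ModelSpec, build_assembly, latent_prior_precision


def _normal_net():
    arms = []
    outcomes = {
        ("A", 1): 0.2, ("A", 2): 0.9, ("B", 1): -0.1, ("B", 3): 0.6,
        ("C", 2): 0.8, ("C", 3): 1.1, ("D", 1): 0.0, ("D", 2): 0.7, ("D", 3): 0.9,
    }
    for (s, t), m in outcomes.items():
        arms.append(nm.ArmRecord(s, t, mean=m, sd=1.5, n=30))
    return nm.NetworkTable(arms, "normal")


class TestGaussianApproximation:
    def test_normal_family_laplace_is_exact(self):
        """Gaussian likelihood: the hyper posterior equals the closed-form
        linear-mixed-model marginal likelihood, and the latent conditionals
        equal the GLS moments."""
        net = _normal_net()
        spec = ModelSpec("consistency", "normal")
        eng = LaplaceEngine(spec, net)
        asm = eng.asm
        R = np.diag(asm.obs_var)
        y = asm.ybar
        for tau in (0.15, 0.4, 1.1):
            theta = (2.0 * math.log(tau),)
            Q, _ = latent_prior_precision(eng.layout, spec, HyperParams(tau=tau))
            V = asm.X @ np.linalg.inv(Q) @ asm.X.T + R
            direct = stats.multivariate_normal.logpdf(
                y, mean=np.zeros(len(y)), cov=V
            ) + eng._log_prior_theta(theta)
            assert eng.log_posterior_hyper(theta) == pytest.approx(direct, abs=1e-6)

            ap = eng.approx_at(theta)
            C = np.linalg.inv(asm.X.T @ np.linalg.inv(R) @ asm.X + Q)
            m = C @ asm.X.T @ np.linalg.inv(R) @ y
            np.testing.assert_allclose(ap.mode, m, atol=1e-7)
            np.testing.assert_allclose(ap.mean_shift, 0.0, atol=1e-12)
            np.testing.assert_allclose(np.sqrt(np.diag(C)),
                                       [ap.marginal_sd(i) for i in range(len(m))],
                                       atol=1e-7)

    def test_binomial_mode_matches_numeric_optimizer(self, toy_net):
        spec = ModelSpec("consistency", "binomial")
        eng = LaplaceEngine(spec, toy_net)
        hp = HyperParams(tau=0.3)
        ap = eng.gaussian_approximation(hp=hp)
        Q, _ = latent_prior_precision(eng.layout, spec, hp)
        X = eng.asm.X

        def neg(a):
            return -(eng.asm.loglik(X @ a) - 0.5 * a @ Q @ a)

        res = optimize.minimize(neg, np.zeros(eng.layout.dim), method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 500})
        np.testing.assert_allclose(ap.mode, res.x, atol=1e-6)

    def test_start_at_mode_converges_immediately(self, toy_net):
        spec = ModelSpec("consistency", "binomial")
        eng = LaplaceEngine(spec, toy_net)
        ap = eng.gaussian_approximation(hp=HyperParams(tau=0.3))
        ap2 = eng.gaussian_approximation(hp=HyperParams(tau=0.3), start=ap.mode)
        assert ap2.n_iter == 0
        np.testing.assert_allclose(ap2.mode, ap.mode)

    def test_out_of_support_hyperparameters_rejected(self, toy_net):
        spec = ModelSpec("consistency", "binomial", tau_prior=(0, 2))
        eng = LaplaceEngine(spec, toy_net)
        with pytest.raises(ValueError, match="support"):
            eng.gaussian_approximation(hp=HyperParams(tau=3.0))


class TestHyperExploration:
    P = np.array([[2.0, 0.5], [0.5, 1.0]])
    m = np.array([0.3, -0.2])

    def _quad(self, th):
        d = np.atleast_1d(th) - self.m
        return -0.5 * float(d @ self.P @ d)

    def test_grid_symmetric_about_mode_1d(self):
        grid = explore_hyper(lambda t: -0.5 * float(t[0] - 1.0) ** 2, np.array([1.0]),
                             np.array([[1.0]]), strategy="grid")
        offs = grid.thetas[:, 0] - 1.0
        np.testing.assert_allclose(np.sort(offs), -np.sort(offs)[::-1], atol=1e-12)
        assert grid.weights.sum() == pytest.approx(1.0)
        assert np.sum(grid.density * grid.volumes) == pytest.approx(1.0)

    def test_ccd_q2_has_nine_points(self):
        grid = explore_hyper(self._quad, self.m, self.P, strategy="ccd")
        assert grid.n_points == 9

    def test_ccd_matches_grid_on_quadratic_density(self):
        g = explore_hyper(self._quad, self.m, self.P, strategy="grid")
        c = explore_hyper(self._quad, self.m, self.P, strategy="ccd")
        true_cov = np.linalg.inv(self.P)
        for grid in (g, c):
            mean = grid.weights @ grid.thetas
            cov = (grid.weights[:, None] * (grid.thetas - mean)).T @ (
                grid.thetas - mean
            )
            np.testing.assert_allclose(mean, self.m, atol=0.01)
            np.testing.assert_allclose(cov, true_cov, rtol=0.01, atol=0.005)

    def test_flat_density_extent_is_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            grid = explore_hyper(lambda t: 0.0, np.array([0.0]), np.array([[1.0]]),
                                 strategy="grid", max_steps=8)
        assert grid.n_points == 17

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            explore_hyper(self._quad, self.m, self.P, strategy="sobol")


class TestMarginalDensity:
    def test_single_gaussian_recovered(self):
        md = MarginalDensity.from_mixture([1.2], [0.4], [1.0])
        assert md.integral() == pytest.approx(1.0, abs=1e-6)
        assert md.mean() == pytest.approx(1.2, abs=1e-6)
        assert md.sd() == pytest.approx(0.4, abs=1e-4)
        assert md.median() == pytest.approx(1.2, abs=1e-4)
        assert md.quantile(0.975) == pytest.approx(1.2 + 1.959964 * 0.4, abs=1e-3)

    def test_symmetric_two_component_mixture_centered(self):
        md = MarginalDensity.from_mixture([-1.0, 1.0], [1.0, 1.0], [0.5, 0.5])
        assert md.mean() == pytest.approx(0.0, abs=1e-8)
        assert md.median() == pytest.approx(0.0, abs=1e-6)

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            MarginalDensity(np.linspace(0, 1, 5), np.zeros(5))


class TestFit:
    def test_fixed_effect_single_trial_matches_log_odds_ratio(self):
        net = nm.NetworkTable(
            [nm.ArmRecord("A", 1, events=40, n=100),
             nm.ArmRecord("A", 2, events=60, n=100)],
            "binomial",
        )
        res = nm.fit(ModelSpec("fixed", "binomial"), net)
        logor = math.log(60 * 60 / (40 * 40))
        asym_sd = math.sqrt(1 / 40 + 1 / 60 + 1 / 60 + 1 / 40)
        md = res.marginals["d[1,2]"]
        assert md.median() == pytest.approx(logor, abs=0.02)
        assert md.sd() == pytest.approx(asym_sd, rel=0.05)

    def test_fit_is_deterministic(self, small_sim):
        net, _ = small_sim
        spec = ModelSpec("consistency", "binomial")
        a = nm.fit(spec, net)
        b = nm.fit(spec, net)
        pd.testing.assert_frame_equal(a.summaries, b.summaries, check_exact=True)
        assert a.dic.dic == b.dic.dic

    def test_every_marginal_normalized(self, smoking_jackson_fit):
        for name, md in smoking_jackson_fit.marginals.items():
            assert md.integral() == pytest.approx(1.0, abs=1e-6), name

    def test_functional_contrast_consistent_with_basic_parameters(
        self, smoking_consistency_fit
    ):
        res = smoking_consistency_fit
        d23 = res.contrast(2, 3)
        expect = res.marginals["d[1,3]"].mean() - res.marginals["d[1,2]"].mean()
        assert d23.mean() == pytest.approx(expect, abs=2e-3)

    def test_fixed_effect_pd_counts_parameters(self, smoking):
        res = nm.fit(ModelSpec("fixed", "binomial"), smoking)
        n_params = 24 + 3
        assert res.dic.pd == pytest.approx(n_params, rel=0.1)
        assert res.dic.dic == pytest.approx(
            res.dic.mean_deviance + res.dic.pd, abs=1e-9
        )

    def test_optimize_hyper_rejects_fixed_kind(self, smoking):
        with pytest.raises(ValueError, match="hyperparameter"):
            nm.optimize_hyper(ModelSpec("fixed", "binomial"), smoking)

    def test_kappa_mode_near_zero_when_data_consistent(self):
        from nmala.simulate import TopologySpec, simulate_network

        ts = TopologySpec(
            designs=[((1, 2), 2), ((1, 3), 2), ((1, 4), 2),
                     ((2, 3), 2), ((2, 4), 2), ((3, 4), 2)],
            family="binomial", d={2: 0.5, 3: -0.3, 4: 0.2},
            tau=0.1, kappa=0.0, arm_size=500, seed=99,
        )
        net, _ = simulate_network(ts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = nm.fit(ModelSpec("jackson", "binomial"), net)
        assert res.marginals["kappa"].median() < 0.25
        assert res.marginals["kappa"].quantile(0.025) < 0.05

    def test_ccd_strategy_close_to_grid(self, smoking):
        spec = ModelSpec("jackson", "binomial")
        g = nm.fit(spec, smoking)
        c = nm.fit(spec, smoking, strategy="ccd")
        assert c.manifest["n_integration_points"] == 9  # q=2 central composite
        for p in ("d[1,2]", "d[1,3]", "d[1,4]"):
            assert c.marginals[p].median() == pytest.approx(
                g.marginals[p].median(), abs=0.02
            )
        assert c.marginals["tau"].median() == pytest.approx(
            g.marginals["tau"].median(), abs=0.02
        )

    def test_nested_laplace_marginal_option(self, smoking):
        spec = ModelSpec("consistency", "binomial")
        plain = nm.fit(spec, smoking)
        prof = nm.fit(spec, smoking, laplace_marginals=True)
        for p in ("d[1,2]", "d[1,3]", "d[1,4]"):
            assert prof.marginals[p].integral() == pytest.approx(1.0, abs=1e-6)
            assert prof.marginals[p].median() == pytest.approx(
                plain.marginals[p].median(), abs=0.05
            )

    def test_saturated_deviance_convention(self, smoking):
        spec = ModelSpec("consistency", "binomial")
        full = nm.fit(spec, smoking)
        sat = nm.fit(spec, smoking, deviance="saturated")
        # conventions differ by twice the saturated log likelihood; pD invariant
        assert sat.dic.pd == pytest.approx(full.dic.pd, abs=1e-9)
        assert sat.dic.dic < full.dic.dic
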