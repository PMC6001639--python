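"""Covariance structures, linear predictor, likelihood families and priors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

import nmala as nm
from nmala.data import build_layout, enumerate_designs
from nmala.model import (
    HyperParams,
    ModelSpec,
    build_assembly,
    cs_covariance,
    cs_decompose,
    cs_precision,
    latent_prior_precision,
    linear_predictor,
    log_likelihood,
    log_prior_hyper,
    log_prior_latent,
)
from nmala.simulate import TopologySpec, simulate_network


class TestCompoundSymmetry:
    def test_direct_substitution(self):
        np.testing.assert_allclose(cs_covariance(2.0, 2), [[4, 2], [2, 4]])
        np.testing.assert_allclose(cs_covariance(0.7, 1), [[0.49]])

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.05, 5.0), st.integers(1, 6))
    def test_positive_definite(self, sd, dim):
        vals = np.linalg.eigvalsh(cs_covariance(sd, dim))
        assert np.all(vals > 0)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.05, 5.0), st.integers(1, 6))
    def test_precision_matches_inverse(self, sd, dim):
        cov = cs_covariance(sd, dim)
        q, logdet = cs_precision(sd**2, dim)
        np.testing.assert_allclose(q @ cov, np.eye(dim), atol=1e-10)
        assert logdet == pytest.approx(np.linalg.slogdet(cov)[1])

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.05, 5.0), st.integers(1, 6))
    def test_decomposition_reproduces_covariance(self, sd, dim):
        dec = cs_decompose(sd, dim)
        np.testing.assert_allclose(
            dec.implied_covariance(), cs_covariance(sd, dim), rtol=0, atol=1e-12
        )

    def test_decomposition_shapes(self):
        one = cs_decompose(0.5, 1)
        assert one.single and one.shared_var == pytest.approx(0.25)
        three = cs_decompose(2.0, 3)
        assert three.shared_var == three.idio_var == pytest.approx(2.0)
        np.testing.assert_allclose(three.expand(1.0, [0.1, -0.2, 0.0]), [1.1, 0.8, 1.0])


class TestLinearPredictor:
    def _assembly(self, net, kind):
        cat = enumerate_designs(net)
        lay = build_layout(net, cat, kind)
        return lay, build_assembly(net, cat, lay)

    def test_zero_alpha_gives_zero_eta(self, smoking):
        lay, asm = self._assembly(smoking, "jackson")
        np.testing.assert_array_equal(
            linear_predictor(np.zeros(lay.dim), asm), np.zeros(asm.n_arms)
        )

    def test_baseline_arm_is_mu_only(self, smoking):
        lay, asm = self._assembly(smoking, "fixed")
        rng = np.random.default_rng(0)
        alpha = rng.standard_normal(lay.dim)
        eta = linear_predictor(alpha, asm)
        for i, (arm, base) in enumerate(zip(smoking.arms, asm.is_baseline)):
            if base:
                assert eta[i] == pytest.approx(alpha[lay.mu_index[arm.study]])

    def test_dimension_mismatch(self, smoking):
        _, asm = self._assembly(smoking, "fixed")
        with pytest.raises(ValueError, match="dimension"):
            linear_predictor(np.zeros(3), asm)

    def test_metareg_interaction_cancels_between_nonreference_arms(self):
        ts = TopologySpec(
            designs=[((1, 2, 3), 2), ((2, 3), 2)],
            family="binomial",
            d={2: 0.4, 3: -0.2},
            beta=0.5,
            covariate=(50.0, 5.0),
            tau=0.2,
            seed=11,
        )
        net, _ = simulate_network(ts)
        lay, asm = self._assembly(net, "metareg-consistency")
        rng = np.random.default_rng(1)
        a1 = rng.standard_normal(lay.dim)
        a2 = a1.copy()
        a2[lay.beta_index] += 2.7  # only beta differs
        e1, e2 = linear_predictor(a1, asm), linear_predictor(a2, asm)
        for study, arms in net.trials():
            rows = [i for i, s in enumerate(asm.studies) if s == study]
            nonbase = [i for i in rows if not asm.is_baseline[i]]
            if len(nonbase) == 2:
                # the contrast between two non-reference arms is free of beta
                assert (e1[nonbase[1]] - e1[nonbase[0]]) == pytest.approx(
                    e2[nonbase[1]] - e2[nonbase[0]]
                )
                # while each arm's own predictor does involve beta
                assert e1[nonbase[0]] != pytest.approx(e2[nonbase[0]])


class TestLikelihood:
    def test_binomial_closed_form(self):
        net = nm.NetworkTable(
            [
                nm.ArmRecord("A", 1, events=5, n=10),
                nm.ArmRecord("A", 2, events=5, n=10),
            ],
            "binomial",
        )
        val = log_likelihood(net, np.zeros(2))
        expect = 2 * (math.log(math.comb(10, 5)) + 10 * math.log(0.5))
        assert val == pytest.approx(expect)

    def test_normal_density_at_mode(self):
        net = nm.NetworkTable(
            [
                nm.ArmRecord("A", 1, mean=1.2, sd=2.0, n=25),
                nm.ArmRecord("A", 2, mean=-0.3, sd=2.0, n=25),
            ],
            "normal",
        )
        se = 2.0 / 5.0
        val = log_likelihood(net, np.array([1.2, -0.3]))
        assert val == pytest.approx(2 * (-math.log(se * math.sqrt(2 * math.pi))))

    def test_poisson_zero_count(self):
        net = nm.NetworkTable(
            [
                nm.ArmRecord("A", 1, events=0, exposure=50.0),
                nm.ArmRecord("A", 2, events=0, exposure=80.0),
            ],
            "poisson",
        )
        eta = np.array([0.3, -0.1])
        val = log_likelihood(net, eta)
        assert val == pytest.approx(-50 * math.exp(0.3) - 80 * math.exp(-0.1))

    def test_nonfinite_eta_rejected(self, smoking):
        with pytest.raises(ValueError, match="non-finite"):
            log_likelihood(smoking, np.full(len(smoking.arms), np.nan))

    def test_invariant_to_trial_and_arm_order(self, smoking):
        df = smoking.to_frame().sample(frac=1.0, random_state=5)
        net2 = nm.network_from_frame(
            df, "binomial", column_map={"events": "events", "n": "n"}
        )
        rng = np.random.default_rng(2)
        # evaluate at matched etas: use per-arm eta keyed by (study, treatment)
        key = {(a.study, a.treatment): rng.standard_normal() for a in smoking.arms}
        eta1 = np.array([key[(a.study, a.treatment)] for a in smoking.arms])
        eta2 = np.array([key[(a.study, a.treatment)] for a in net2.arms])
        assert log_likelihood(smoking, eta1) == pytest.approx(
            log_likelihood(net2, eta2)
        )


class TestPriors:
    def test_hyper_prior_support(self):
        spec = ModelSpec("jackson", "binomial")
        assert log_prior_hyper(HyperParams(tau=6.0, kappa=1.0), spec) == -math.inf
        assert math.isfinite(log_prior_hyper(HyperParams(tau=0.5, kappa=0.5), spec))
        narrow = ModelSpec(
            "jackson", "binomial", tau_prior=(0, 2), kappa_prior=(0, 2)
        )
        assert log_prior_hyper(HyperParams(tau=1.9, kappa=1.9), narrow) == pytest.approx(
            2 * -math.log(2.0)
        )
        assert log_prior_hyper(HyperParams(tau=2.1, kappa=0.5), narrow) == -math.inf

    def test_gamma_block_matches_cs_structure(self, smoking):
        cat = enumerate_designs(smoking)
        lay = build_layout(smoking, cat, "jackson")
        spec = ModelSpec("jackson", "binomial")
        hp = HyperParams(tau=0.7, kappa=0.3)
        Q, logdet = latent_prior_precision(lay, spec, hp)
        for group in lay.gamma_groups:
            block = np.linalg.inv(Q[np.ix_(group, group)])
            np.testing.assert_allclose(
                block, cs_covariance(0.7, len(group)), atol=1e-10
            )
        for group in lay.omega_groups:
            block = np.linalg.inv(Q[np.ix_(group, group)])
            np.testing.assert_allclose(
                block, cs_covariance(0.3, len(group)), atol=1e-10
            )
        # log-determinant consistent with the dense covariance
        sign, full_logdet = np.linalg.slogdet(np.linalg.inv(Q))
        assert sign > 0 and full_logdet == pytest.approx(logdet)

    def test_latent_log_prior_at_zero(self, toy_net):
        cat = enumerate_designs(toy_net)
        lay = build_layout(toy_net, cat, "consistency")
        spec = ModelSpec("consistency", "binomial")
        val = log_prior_latent(np.zeros(lay.dim), HyperParams(tau=0.4), spec, lay)
        _, logdet = latent_prior_precision(lay, spec, HyperParams(tau=0.4))
        assert val == pytest.approx(-0.5 * (lay.dim * math.log(2 * math.pi) + logdet))


class TestModelSpec:
    def test_rejects_bad_priors(self):
        with pytest.raises(Exception):
            ModelSpec("jackson", "binomial", tau_prior=(2, 1))
        with pytest.raises(Exception):
            ModelSpec("jackson", "binomial", prior_fixed_sd=0.0)

    def test_roundtrip_serialization(self):
        spec = ModelSpec("metareg-jackson", "binomial", reference=2,
                         tau_prior=(0, 2), kappa_prior=(0, 2))
        again = ModelSpec.from_dict(spec.to_dict())
        assert again == spec

    def test_unknown_keys_rejected(self):
        with pytest.raises(Exception, match="unknown"):
            ModelSpec.from_dict(
                {"model_kind": "fixed", "family": "binomial", "banana": 1}
            )
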