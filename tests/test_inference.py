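"""Inference tests: MAP vs grid oracles, marginals vs Monte-Carlo oracles,
model probabilities, family probabilities, model averaging."""

import numpy as np
import pytest
from scipy.special import logsumexp

import heurfit as hf
from heurfit.inference import beta_quadrature
from heurfit.models import ChoiceModelSpec, PriorConfig, log_likelihood, log_sigmoid
from heurfit.simulate import SelfReport

from conftest import make_dataset


def brute_force_log_marginal(spec, data, prior, n_draws, seed):
    """Simple Monte-Carlo evidence: parameters drawn from the prior.

    Independent of the quadrature / importance-sampling code paths. Returns
    (log Z, standard error of log Z).
    """
    rng = np.random.default_rng(seed)
    if spec.is_discrete:
        configs = hf.enumerate_weight_configs(spec, data.k)
        w = configs[rng.integers(len(configs), size=n_draws)]
    else:
        w = rng.uniform(-1, 1, (n_draws, data.k))
    beta = rng.gamma(prior.beta_shape, 1.0 / prior.beta_rate, n_draws)
    d = data.signed_diffs(spec.binary_values)
    ll = log_sigmoid(beta[:, None] * (w @ d.T)).sum(axis=1)
    log_z = logsumexp(ll) - np.log(n_draws)
    lik = np.exp(ll - ll.max())
    se = lik.std(ddof=1) / (np.sqrt(n_draws) * lik.mean())
    return float(log_z), float(se)


class TestBetaQuadrature:
    def test_integrates_prior_moments(self):
        prior = PriorConfig()
        betas, logw = beta_quadrature(prior, 64)
        w = np.exp(logw)
        assert w.sum() == pytest.approx(1.0, abs=1e-8)
        assert (betas * w).sum() == pytest.approx(4.0, rel=1e-6)  # Gamma(4,1) mean
        assert (betas**2 * w).sum() == pytest.approx(20.0, rel=1e-6)  # E[b^2]=a(a+1)

    def test_discrete_marginal_quadrature_converged(self):
        # doubling the node count moves the log marginal by < 1e-6
        data = make_dataset(3, [1.0, 0.0, -1.0], beta=3.0, n_trials=20, seed=31)
        spec = ChoiceModelSpec.from_id(3)
        z64, _, _ = hf.log_marginal_likelihood(spec, data, config=hf.FitConfig(n_quad=64))
        z128, _, _ = hf.log_marginal_likelihood(spec, data, config=hf.FitConfig(n_quad=128))
        assert abs(z64 - z128) < 1e-6


class TestDiscreteMAP:
    def test_matches_exhaustive_grid_search(self, fast_fit_config):
        # oracle: every config x a dense beta grid
        data = make_dataset(3, [1.0, -1.0], beta=2.0, n_trials=40, seed=32)
        spec = ChoiceModelSpec.from_id(3)
        prior = PriorConfig()
        map_w, map_beta, log_post = hf.fit_map(spec, data, prior, fast_fit_config)

        configs = hf.enumerate_weight_configs(spec, 2)
        betas = np.linspace(1e-6, 50, 2000)
        best = -np.inf
        for c in configs:
            lp = np.array(
                [log_likelihood(spec, c, b, data) for b in betas]
            ) + prior.log_beta_pdf(betas)
            if lp.max() > best:
                best, best_c, best_b = lp.max(), c, betas[np.argmax(lp)]
        assert log_post >= best - 1e-9
        assert np.array_equal(map_w, best_c)
        assert map_beta == pytest.approx(best_b, abs=0.05)

    def test_recovers_planted_single_attribute(self, spec5_dataset, fast_fit_config):
        map_w, map_beta, _ = hf.fit_map(
            ChoiceModelSpec.from_id(5), spec5_dataset, config=fast_fit_config
        )
        expected = np.zeros(9)
        expected[2] = 1.0
        assert np.array_equal(map_w, expected)


class TestContinuousMAP:
    def test_beats_dense_grid_oracle(self, fast_fit_config):
        data = make_dataset(1, [0.8, -0.5], beta=3.0, n_trials=20, seed=33)
        spec = ChoiceModelSpec.from_id(1)
        prior = PriorConfig()
        map_w, map_beta, log_post = hf.fit_map(spec, data, prior, fast_fit_config)

        # dense (w1, w2, beta) grid oracle, fully vectorized
        g = np.linspace(-1, 1, 200)
        bg = np.linspace(0.01, 50, 200)
        w_grid = np.stack(np.meshgrid(g, g, indexing="ij"), axis=-1).reshape(-1, 2)
        d = data.signed_diffs(False)
        z = w_grid @ d.T  # (G, T)
        grid_best = -np.inf
        for b in bg:
            lp = log_sigmoid(b * z).sum(axis=1) + float(prior.log_beta_pdf(b))
            m = lp.max()
            if m > grid_best:
                grid_best = m
                grid_arg = np.concatenate([w_grid[np.argmax(lp)], [b]])
        assert log_post >= grid_best - 1e-9
        # optimizer and grid argmax agree up to grid resolution
        assert np.abs(np.concatenate([map_w, [map_beta]]) - grid_arg).max() < 0.5
        assert log_post - grid_best < 0.1


class TestMarginalOracles:
    @pytest.mark.parametrize("spec_id", [3, 4, 5, 6])
    def test_discrete_marginal_within_mc_error(self, spec_id):
        w = {3: [1.0, 0.0, -1.0], 4: [1.0, 1.0, 0.0], 5: [0.0, 1.0, 0.0], 6: [-1.0, 0.0, 0.0]}
        data = make_dataset(spec_id, w[spec_id], beta=3.0, n_trials=20, seed=40 + spec_id)
        spec = ChoiceModelSpec.from_id(spec_id)
        prior = PriorConfig()
        log_z, _, _ = hf.log_marginal_likelihood(spec, data, prior)
        mc, se = brute_force_log_marginal(spec, data, prior, n_draws=100_000, seed=1)
        assert abs(log_z - mc) < 3 * se

    def test_continuous_marginal_within_mc_error(self):
        data = make_dataset(1, [0.7, -0.4], beta=3.0, n_trials=10, seed=50)
        spec = ChoiceModelSpec.from_id(1)
        prior = PriorConfig()
        log_z, se_is, _ = hf.log_marginal_likelihood(
            spec, data, prior, config=hf.FitConfig(seed=3)
        )
        mc, se_mc = brute_force_log_marginal(spec, data, prior, n_draws=1_000_000, seed=2)
        assert abs(log_z - mc) < 3 * np.hypot(se_is, se_mc)

    def test_empty_data_has_marginal_one(self):
        empty = hf.ChoiceDataset("e", np.empty((0, 2)), np.empty((0, 2)), np.empty(0, int))
        log_z, _, _ = hf.log_marginal_likelihood(ChoiceModelSpec.from_id(1), empty)
        assert log_z == 0.0


class TestModelProbabilities:
    def test_uniform_when_equal(self):
        p = hf.posterior_model_probabilities(np.zeros(6))
        assert np.allclose(p, 1 / 6)

    def test_closed_form_normalization(self):
        p = hf.posterior_model_probabilities(np.array([np.log(2), 0, 0, 0, 0, 0]))
        assert np.allclose(p, [2 / 7, 1 / 7, 1 / 7, 1 / 7, 1 / 7, 1 / 7])

    def test_simplex_and_overflow_safety(self):
        p = hf.posterior_model_probabilities(np.array([-1e4, 0, 1e4, 5, -3, 2.0]))
        assert p.sum() == pytest.approx(1.0) and (p >= 0).all() and (p <= 1).all()


class TestFamilyProbabilities:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            ([1, 0, 0, 0, 0, 0], [0, 0, 0]),
            ([0, 0, 0, 0, 0, 1], [1, 0, 1]),
            ([1 / 6] * 6, [1 / 3, 1 / 3, 1 / 2]),
        ],
    )
    def test_family_sums(self, probs, expected):
        assert np.allclose(
            hf.heuristic_family_probabilities(np.array(probs, dtype=float)), expected
        )


class TestModelAveraging:
    def _fits(self, k=2):
        fits = []
        for spec in hf.ALL_SPECS:
            w = np.zeros(k)
            w[0] = 1.0 if spec.is_discrete else 0.5
            fits.append(
                hf.inference.ModelFit(
                    spec=spec, map_w=w, map_beta=1.0, log_posterior=0.0,
                    log_marginal=0.0, diagnostics={},
                )
            )
        return fits

    def test_one_hot_returns_that_models_weights(self):
        fits = self._fits()
        p = np.eye(6)[3]
        assert np.array_equal(hf.model_averaged_weights(fits, p), fits[3].map_w)

    def test_fifty_fifty_is_elementwise_mean(self):
        fits = self._fits()
        p = np.array([0.5, 0, 0, 0, 0.5, 0])
        expected = (fits[0].map_w + fits[4].map_w) / 2
        assert np.allclose(hf.model_averaged_weights(fits, p), expected)

    def test_reported_average_two_term(self):
        rep = SelfReport(
            participant_id="x",
            graded=np.array([0.8, 0.2]),
            binary=np.array([1.0, 0.0]),
            single=np.array([1.0, 0.0]),
            extents=np.array([0.0, 0.0, 0.0]),
        )
        p = np.array([0.5, 0.0, 0.5, 0.0, 0.0, 0.0])
        assert np.allclose(
            hf.model_averaged_reported_weights(rep, p), [0.9, 0.1]
        )

    def test_single_mass_returns_single_slot(self):
        rep = SelfReport(
            participant_id="x",
            graded=np.array([0.8, 0.2]),
            binary=np.array([1.0, 0.0]),
            single=np.array([0.0, -1.0]),
            extents=np.array([1.0, 0.0, 0.0]),
        )
        p = np.array([0.0, 0.0, 0.0, 0.0, 0.7, 0.3])
        assert np.allclose(hf.model_averaged_reported_weights(rep, p), rep.single)


class TestFitParticipant:
    def test_recovery_and_determinism(self, spec5_dataset, fast_fit_config):
        pf1 = hf.fit_participant(spec5_dataset, config=fast_fit_config)
        assert pf1.model_probs.sum() == pytest.approx(1.0)
        # data came from a take-the-best decider: single-attribute family wins
        assert pf1.family_probs[0] > 0.5
        assert pf1.argmax_model_id in (5, 6)
        pf2 = hf.fit_participant(spec5_dataset, config=fast_fit_config)
        for f1, f2 in zip(pf1.fits, pf2.fits):
            assert f1.log_marginal == f2.log_marginal  # exact reproducibility
        # Occam's razor: flexible rational model penalized vs the true one
        assert pf1.model_probs[4] > pf1.model_probs[0]

    def test_report_averaging_attached(self, spec5_dataset, fast_fit_config):
        w = np.zeros(9)
        w[2] = 1.0
        rep = SelfReport(
            participant_id="p", graded=w.copy(), binary=w.copy(), single=w.copy(),
            extents=np.array([1.0, 0.0, 0.0]),
        )
        pf = hf.fit_participant(spec5_dataset, report=rep, config=fast_fit_config)
        assert pf.averaged_reported_w is not None
        assert np.allclose(pf.averaged_reported_w, w)
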