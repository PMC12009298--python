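"""Tests for the introspective-accuracy metrics and their chance levels."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import heurfit as hf
from heurfit.inference import ModelFit, ParticipantFit
from heurfit.metrics import CORRECT_METHOD_CHANCE, chance_levels, compute_metrics
from heurfit.simulate import SelfReport


def one_hot_fit(pid, model_id, w, p_top=1.0):
    """A ParticipantFit with posterior mass p_top on one model (rest uniform)."""
    k = len(w)
    probs = np.full(6, (1 - p_top) / 5)
    probs[model_id - 1] = p_top
    fits = [
        ModelFit(
            spec=s, map_w=np.asarray(w, dtype=float), map_beta=1.0,
            log_posterior=0.0, log_marginal=0.0, diagnostics={},
        )
        for s in hf.ALL_SPECS
    ]
    return ParticipantFit(
        participant_id=pid,
        fits=fits,
        model_probs=probs,
        family_probs=hf.heuristic_family_probabilities(probs),
        averaged_w=hf.model_averaged_weights(fits, probs),
    )


def make_report(pid, graded, extents):
    graded = np.asarray(graded, dtype=float)
    binary = np.where(np.abs(graded) > 0.5, np.sign(graded), 0.0)
    single = np.zeros_like(graded)
    i = int(np.argmax(np.abs(graded)))
    single[i] = 1.0 if graded[i] >= 0 else -1.0
    return SelfReport(
        participant_id=pid, graded=graded, binary=binary, single=single,
        extents=np.asarray(extents, dtype=float),
    )


class TestWeightCorrelation:
    def test_identity_and_reflection(self):
        v = np.array([0.9, 0.1, -0.4])
        assert hf.weight_correlation(v, v) == pytest.approx(1.0)
        assert hf.weight_correlation(v, -v) == pytest.approx(-1.0)

    def test_textbook_pearson(self):
        fitted = np.array([1.0, 0.0, 0.0])
        reported = np.array([0.8, 0.1, 0.1])
        # hand computation: cov / (sd_x * sd_y)
        x, y = fitted - fitted.mean(), reported - reported.mean()
        expected = (x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum())
        assert hf.weight_correlation(fitted, reported) == pytest.approx(expected)
        assert expected == pytest.approx(1.0)  # collinear here

    def test_constant_vector_is_undefined(self):
        assert hf.weight_correlation(np.ones(3), np.array([0.1, 0.5, 0.2])) is None

    def test_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(-1, 1, 5), rng.uniform(-1, 1, 5)
        r0 = hf.weight_correlation(a, b)
        assert hf.weight_correlation(0.3 * a + 0.2, b) == pytest.approx(r0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            hf.weight_correlation(np.ones(3), np.ones(4))


class TestAbsoluteWeightError:
    def test_hand_computed_cases(self):
        assert hf.absolute_weight_error(np.ones(4), np.ones(4)) == 0.0
        fitted = np.zeros(9)
        fitted[0] = 1.0
        reported = np.zeros(9)
        reported[0], reported[1] = 0.8, 0.1
        assert hf.absolute_weight_error(fitted, reported) == pytest.approx(0.3 / 9)
        assert hf.absolute_weight_error(np.ones(5), -np.ones(5)) == 2.0


class TestHeuristicError:
    def test_hand_computed_cases(self):
        assert hf.heuristic_error(np.array([0.2, 0.6, 0.9]), np.array([0.2, 0.6, 0.9])) == 0.0
        assert hf.heuristic_error(
            np.array([1.0, 0.0, 0.0]), np.array([0.5, 0.5, 0.5])
        ) == pytest.approx(0.5)

    @given(
        fp=arrays(float, 3, elements=st.floats(0, 1)),
        ex=arrays(float, 3, elements=st.floats(0, 1)),
    )
    @settings(deadline=None, max_examples=300)
    def test_range_property(self, fp, ex):
        assert 0.0 <= hf.heuristic_error(fp, ex) <= 1.0

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            hf.heuristic_error(np.array([1.2, 0, 0]), np.array([0, 0, 0.5]))


class TestReportedModel:
    @pytest.mark.parametrize(
        "extents,expected_id",
        [
            ((0.9, 0.1, 0.8), 6),
            ((0.9, 0.9, 0.1), 5),   # single-attribute wins the conflict
            ((0.1, 0.1, 0.1), 1),
            ((0.1, 0.8, 0.1), 3),
            ((0.5, 0.5, 0.5), 1),   # exactly 0.5 -> "not used"
        ],
    )
    def test_thresholding(self, extents, expected_id):
        rep = make_report("p", [0.9, 0.1, 0.1], extents)
        assert hf.reported_model(rep).model_id == expected_id


class TestBayesFactorAndCorrectMethod:
    def test_reported_equals_argmax_gives_one(self):
        p = np.array([0.1, 0.4, 0.2, 0.1, 0.1, 0.1])
        spec2 = hf.ChoiceModelSpec.from_id(2)
        assert hf.reported_model_bayes_factor(p, spec2) == 1.0
        assert hf.correct_method(p, spec2) is True

    def test_ratio_case(self):
        p = np.array([0.2, 0.4, 0.1, 0.1, 0.1, 0.1])
        assert hf.reported_model_bayes_factor(p, hf.ChoiceModelSpec.from_id(1)) == 0.5
        assert hf.correct_method(p, hf.ChoiceModelSpec.from_id(1)) is False

    def test_uniform_simplex_gives_one_for_any_report(self):
        p = np.full(6, 1 / 6)
        for mid in range(1, 7):
            assert hf.reported_model_bayes_factor(p, hf.ChoiceModelSpec.from_id(mid)) == \
                pytest.approx(1.0)

    def test_uniform_guessing_hits_one_sixth(self):
        # any posterior with a unique argmax: exactly one of six reports is correct
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.dirichlet(np.ones(6))
            hits = sum(
                hf.correct_method(p, hf.ChoiceModelSpec.from_id(m)) for m in range(1, 7)
            )
            assert hits == 1
        assert CORRECT_METHOD_CHANCE == pytest.approx(1 / 6)


class TestComputeMetrics:
    def test_perfect_report_identities(self):
        w = np.array([0.8, -0.3, 0.5, 0.1])
        fit = one_hot_fit("p", 1, w)
        rep = make_report("p", w, [0.0, 0.0, 0.0])
        m = compute_metrics(fit, rep)
        assert m.weight_correlation == pytest.approx(1.0)
        assert m.absolute_weight_error == pytest.approx(0.0)
        assert m.heuristic_error == pytest.approx(0.0)
        assert m.reported_model_bayes_factor == pytest.approx(1.0)
        assert m.correct_method is True


class TestChanceLevels:
    def _cohort(self, n=3):
        rng = np.random.default_rng(9)
        fits, reports = [], []
        for i in range(n):
            w = rng.uniform(-1, 1, 4)
            mid = int(rng.integers(1, 7))
            fits.append(one_hot_fit(f"p{i}", mid, w, p_top=0.8))
            spec = hf.ChoiceModelSpec.from_id(mid)
            reports.append(make_report(f"p{i}", rng.uniform(-1, 1, 4), spec.flags))
        return fits, reports

    def test_identical_participants_chance_equals_observed(self):
        fits, reports = self._cohort(1)
        fits, reports = fits * 3, reports * 3
        ch = chance_levels(fits, reports, n_boot=50, seed=1)
        m = compute_metrics(fits[0], reports[0])
        assert ch.heuristic_error == pytest.approx(m.heuristic_error)
        assert ch.correct_method == pytest.approx(float(m.correct_method))

    def test_matches_exhaustive_permutation_oracle(self):
        fits, reports = self._cohort(3)
        # oracle: all 3! = 6 pairings, uniformly weighted
        perms = list(itertools.permutations(range(3)))
        he = np.mean(
            [
                np.mean(
                    [
                        compute_metrics(f, reports[j]).heuristic_error
                        for f, j in zip(fits, perm)
                    ]
                )
                for perm in perms
            ]
        )
        ch = chance_levels(fits, reports, n_boot=4000, seed=2)
        assert ch.heuristic_error == pytest.approx(he, abs=0.01)
        assert ch.correct_method_analytic == pytest.approx(1 / 6)

    def test_too_few_participants_raise(self):
        fits, reports = self._cohort(1)
        with pytest.raises(ValueError):
            chance_levels(fits, reports, n_boot=10, seed=0)


class TestMetricRangesProperty:
    def test_ranges_on_randomized_inputs(self):
        rng = np.random.default_rng(12)
        for _ in range(10_000):
            fitted = rng.uniform(-1, 1, 5)
            reported = rng.uniform(-1, 1, 5)
            c = hf.weight_correlation(fitted, reported)
            assert c is None or -1.0 <= c <= 1.0
            assert 0.0 <= hf.absolute_weight_error(fitted, reported) <= 2.0
            p = rng.dirichlet(np.ones(6))
            fam = hf.heuristic_family_probabilities(p)
            ex = rng.uniform(0, 1, 3)
            assert 0.0 <= hf.heuristic_error(fam, ex) <= 1.0
            spec = hf.ChoiceModelSpec.from_id(int(rng.integers(1, 7)))
            assert 0.0 <= hf.reported_model_bayes_factor(p, spec) <= 1.0
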