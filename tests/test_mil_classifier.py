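import math

import numpy as np
import pytest

import tcrmotif as tm
from tcrmotif.mil_classifier import loss_and_grad


class TestScoring:
    def test_zero_features_zero_bias_score_half(self):
        params = tm.ModelParams(bias=0.0, weights=np.zeros(16))
        assert tm.score_motif(np.zeros(16), params) == 0.5

    def test_logit_ln3_gives_three_quarters(self):
        params = tm.ModelParams(bias=math.log(3), weights=np.zeros(16))
        assert np.isclose(tm.score_motif(np.zeros(16), params), 0.75, atol=1e-12)

    def test_matches_direct_evaluation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            f = rng.normal(size=16)
            params = tm.ModelParams(bias=rng.normal(), weights=rng.normal(size=16))
            direct = 1.0 / (1.0 + math.exp(-(params.bias + float(f @ params.weights))))
            assert abs(tm.score_motif(f, params) - direct) <= 1e-12

    def test_stable_at_extreme_logits(self):
        params = tm.ModelParams(bias=700.0, weights=np.zeros(16))
        assert tm.score_motif(np.zeros(16), params) == pytest.approx(1.0, abs=1e-15)
        params = tm.ModelParams(bias=-700.0, weights=np.zeros(16))
        low = tm.score_motif(np.zeros(16), params)
        assert np.isfinite(low) and 0.0 <= low <= 1e-300

    def test_non_finite_features_rejected(self):
        params = tm.ModelParams(bias=0.0, weights=np.zeros(2))
        with pytest.raises(ValueError):
            tm.score_motif([np.nan, 0.0], params)


class TestAggregation:
    def test_max_and_singleton(self):
        assert tm.score_repertoire([0.1, 0.9, 0.3]) == 0.9
        assert tm.score_repertoire([0.42]) == 0.42

    def test_empty_scores_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert tm.score_repertoire([]) == 0.0

    def test_adding_elements_never_decreases(self):
        rng = np.random.default_rng(0)
        probs = list(rng.uniform(size=5))
        base = tm.score_repertoire(probs)
        assert tm.score_repertoire(probs + [0.0]) >= base

    def test_classify_threshold_ties_positive(self):
        assert tm.classify(0.5) == 1
        assert tm.classify(0.4999) == 0
        assert tm.classify(1.0) == 1


class TestLikelihood:
    def test_perfect_predictions_near_zero(self):
        assert tm.negative_log_likelihood([1.0, 0.0], [1, 0]) <= 1e-11

    def test_all_half_is_ln_two(self):
        assert tm.negative_log_likelihood([0.5, 0.5, 0.5], [1, 0, 1]) == pytest.approx(
            math.log(2), abs=1e-15
        )

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(0.01, 0.99, size=11)
        y = rng.integers(0, 2, size=11)
        direct = -sum(
            yi * math.log(pi) + (1 - yi) * math.log(1 - pi) for pi, yi in zip(p, y)
        ) / len(y)
        assert abs(tm.negative_log_likelihood(p, y) - direct) <= 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tm.negative_log_likelihood([0.5], [1, 0])


class TestInitialization:
    def test_bias_always_zero(self):
        rng = np.random.default_rng(0)
        assert all(tm.init_params(rng, 16).bias == 0.0 for _ in range(10))

    def test_stated_weight_distributions(self):
        rng = np.random.default_rng(1)
        draws = np.array([tm.init_params(rng, 16).weights for _ in range(100_000)])
        atchley_var = draws[:, :15].var()
        abundance_var = draws[:, 15].var()
        assert atchley_var == pytest.approx(0.25 / 15, rel=0.05)
        assert abundance_var == pytest.approx(0.25, rel=0.05)
        # equal expected squared magnitude of the two blocks
        assert (draws[:, :15] ** 2).sum(axis=1).mean() == pytest.approx(
            (draws[:, 15] ** 2).mean(), rel=0.05
        )

    def test_alternative_variance_reading_flag(self):
        rng = np.random.default_rng(2)
        draws = np.array(
            [
                tm.init_params(rng, 16, init_variance_squared=True).weights
                for _ in range(50_000)
            ]
        )
        assert draws[:, :15].var() == pytest.approx((1 / 15) ** 2, rel=0.05)


def _toy_problem():
    rng = np.random.default_rng(5)
    features = [rng.normal(size=(4, 6)), rng.normal(size=(3, 6)), rng.normal(size=(5, 6))]
    labels = np.array([1, 0, 1])
    return features, labels


class TestGradient:
    def test_analytic_gradient_matches_finite_differences(self):
        features, labels = _toy_problem()
        rng = np.random.default_rng(6)
        params = tm.ModelParams(bias=0.1, weights=rng.normal(scale=0.3, size=6))
        loss, gb, gw = loss_and_grad(features, labels, params)
        eps = 1e-6

        def f(bias, weights):
            return loss_and_grad(features, labels, tm.ModelParams(bias, weights))[0]

        fd_b = (f(params.bias + eps, params.weights) - f(params.bias - eps, params.weights)) / (2 * eps)
        assert abs(gb - fd_b) / max(abs(fd_b), 1e-8) <= 1e-5
        for j in range(6):
            e = np.zeros(6)
            e[j] = eps
            fd = (f(params.bias, params.weights + e) - f(params.bias, params.weights - e)) / (2 * eps)
            assert abs(gw[j] - fd) / max(abs(fd), 1e-8) <= 1e-5

    def test_zero_parameters_give_half_scores_and_ln2_loss(self):
        features, labels = _toy_problem()
        params = tm.ModelParams(bias=0.0, weights=np.zeros(6))
        probs = tm.predict_repertoires(features, params)
        assert np.all(probs == 0.5)
        loss, _, _ = loss_and_grad(features, labels, params)
        assert loss == pytest.approx(math.log(2), abs=1e-15)


class TestFit:
    def test_best_loss_non_increasing_with_more_restarts(self):
        features, labels = _toy_problem()
        losses = {}
        for n in (8, 16):
            opt = tm.OptimizerConfig(n_restarts=n, n_steps=60, seed=11)
            losses[n] = tm.fit(features, labels, opt, n_atchley=5).training_loss
        assert losses[16] <= losses[8] + 1e-6

    def test_bit_reproducible_given_seed(self):
        features, labels = _toy_problem()
        opt = tm.OptimizerConfig(n_restarts=8, n_steps=40, seed=4)
        r1 = tm.fit(features, labels, opt, n_atchley=5)
        r2 = tm.fit(features, labels, opt, n_atchley=5)
        assert r1.restart_index == r2.restart_index
        assert np.array_equal(r1.params.weights, r2.params.weights)
        assert np.array_equal(r1.loss_by_step, r2.loss_by_step)

    def test_objective_invariant_to_sample_and_motif_order(self):
        features, labels = _toy_problem()
        opt = tm.OptimizerConfig(n_restarts=8, n_steps=40, seed=4)
        base = tm.fit(features, labels, opt, n_atchley=5)
        shuffled = tm.fit(features[::-1], labels[::-1], opt, n_atchley=5)
        assert shuffled.training_loss == pytest.approx(base.training_loss, abs=1e-6)

    def test_chunked_restarts_match_single_batch(self):
        features, labels = _toy_problem()
        opt = tm.OptimizerConfig(n_restarts=16, n_steps=40, seed=4)
        chunked = tm.OptimizerConfig(n_restarts=16, n_steps=40, seed=4, restart_chunk=4)
        a = tm.fit(features, labels, opt, n_atchley=5)
        b = tm.fit(features, labels, chunked, n_atchley=5)
        assert a.restart_index == b.restart_index
        assert a.training_loss == pytest.approx(b.training_loss, abs=1e-7)

    def test_separable_synthetic_cohort_reaches_perfect_training_accuracy(
        self, strong_cohort
    ):
        cohort, _ = strong_cohort
        config = tm.ModelConfig(3, 1)
        fc = tm.featurize_cohort(cohort, config)
        stats = tm.pooled_normalizer(fc.samples)
        X = [tm.apply_normalizer(s.raw, stats) for s in fc.samples]
        fr = tm.fit(X, fc.labels, tm.OptimizerConfig(n_restarts=128, n_steps=300, seed=0))
        probs = tm.predict_repertoires(X, fr.params)
        assert np.all((probs >= 0.5).astype(int) == fc.labels)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="no motifs"):
            tm.fit(
                [np.zeros((0, 6)), np.ones((2, 6))],
                [0, 1],
                tm.OptimizerConfig(n_restarts=2, n_steps=5, seed=0),
                n_atchley=5,
            )
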