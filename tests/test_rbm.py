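"""RBM core: CD updates against exact enumeration oracles, and the
discriminative RBM classifier."""

import copy

import numpy as np
import pytest

from gliadbn import (TrainConfig, cd_update, exact_grad_log_likelihood,
                     exact_log_likelihood, exact_visible_distribution,
                     gibbs_sample, hidden_preactivation, hidden_probability,
                     init_rbm, predict, train_discriminative_rbm, train_rbm)
from gliadbn.rbm import RBM, init_discriminative_rbm


def _random_rbm(nv, nh, seed, scale=1.0, bias_scale=0.3):
    rng = np.random.default_rng(seed)
    return RBM(W=scale * rng.standard_normal((nv, nh)),
               b=bias_scale * rng.standard_normal(nv),
               c=bias_scale * rng.standard_normal(nh))


class TestForward:
    def test_preactivation_direct_arithmetic(self):
        rbm = RBM(W=np.array([[0.5], [-0.5]]), b=np.zeros(2), c=np.array([0.25]))
        assert hidden_preactivation(rbm, [1.0, 0.0])[0] == pytest.approx(0.75)

    def test_zero_params_and_linearity(self):
        rbm = RBM(W=np.zeros((3, 2)), b=np.zeros(3), c=np.zeros(2))
        assert np.all(hidden_preactivation(rbm, np.ones(3)) == 0)
        rbm2 = _random_rbm(3, 2, 0, bias_scale=0.0)
        v = np.array([1.0, -2.0, 0.5])
        assert np.allclose(hidden_preactivation(rbm2, 3 * v),
                           3 * hidden_preactivation(rbm2, v))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            hidden_preactivation(_random_rbm(3, 2, 0), np.ones(4))

    def test_sigmoid_values(self):
        assert hidden_probability(np.array([0.0]))[0] == pytest.approx(0.5)
        assert hidden_probability(np.array([1.0]))[0] == pytest.approx(
            0.7310585786, abs=1e-9)
        big = hidden_probability(np.array([5.0, 20.0, 50.0]))
        assert np.all(np.diff(big) > 0) or np.allclose(big[-2:], 1.0)


class TestExactOracles:
    def test_uniform_model_log_quarter(self):
        rbm = init_rbm(2, 2, seed=0, weight_scale=0.0)
        for v in ([0, 0], [0, 1], [1, 0], [1, 1]):
            assert exact_log_likelihood(rbm, v) == pytest.approx(-np.log(4))

    def test_distribution_normalizes(self):
        _, p = exact_visible_distribution(_random_rbm(3, 2, 7))
        assert abs(p.sum() - 1.0) < 1e-10

    def test_too_large_model_errors(self):
        with pytest.raises(ValueError):
            exact_log_likelihood(init_rbm(15, 10), np.zeros(15))

    def test_analytic_gradient_matches_finite_differences(self):
        rbm = _random_rbm(4, 3, 2, scale=0.5)
        data = np.array([[1, 0, 1, 0], [0, 1, 1, 1]], dtype=float)
        dW, db, dc = exact_grad_log_likelihood(rbm, data)

        def mean_ll(r):
            return np.mean([exact_log_likelihood(r, v) for v in data])

        eps = 1e-6
        for arr, grad in ((rbm.W, dW), (rbm.b, db), (rbm.c, dc)):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                arr[i] += eps
                up = mean_ll(rbm)
                arr[i] -= 2 * eps
                dn = mean_ll(rbm)
                arr[i] += eps
                num = (up - dn) / (2 * eps)
                assert abs(num - grad[i]) <= 1e-5 * max(1.0, abs(grad[i]))


class TestCDUpdate:
    def test_zero_learning_rate_zero_deltas(self):
        rbm = _random_rbm(4, 3, 1)
        cfg = TrainConfig(learning_rate=0.0, visible_type="binary")
        deltas = cd_update(rbm, np.ones((2, 4)), cfg)
        assert all(np.all(d == 0) for d in deltas)

    def test_duplicated_row_matches_single_row_mean_gradient(self):
        # with the mean-gradient convention a batch of two identical rows
        # yields the same delta as the single row (equivalently, the sum
        # convention would double it); deterministic CD isolates this
        rbm = _random_rbm(4, 3, 5)
        cfg = TrainConfig(sample_hidden=False, visible_type="binary")
        row = np.array([[1.0, 0.0, 1.0, 1.0]])
        d1 = cd_update(rbm, row, cfg)
        d2 = cd_update(rbm, np.vstack([row, row]), cfg)
        for a, b in zip(d1, d2):
            assert np.allclose(a, b)

    def test_empty_batch_errors(self):
        with pytest.raises(ValueError):
            cd_update(_random_rbm(4, 3, 1), np.empty((0, 4)), TrainConfig())

    def test_training_raises_pattern_likelihood(self):
        pattern = np.array([1.0, 0.0, 1.0])
        data = np.tile(pattern, (20, 1))
        cfg = TrainConfig(learning_rate=0.1, epochs=200, seed=0,
                          visible_type="binary", weight_decay=0.0)
        before = exact_log_likelihood(
            init_rbm(3, 2, seed=cfg.seed), pattern)
        after = exact_log_likelihood(train_rbm(data, 2, cfg), pattern)
        assert after > before

    @pytest.mark.parametrize("init_seed", range(5))
    def test_cd_learning_decreases_kl(self, init_seed):
        # two-pattern empirical distribution on 3 visible units
        patterns = np.array([[1, 0, 1], [0, 1, 0]], dtype=float)
        data = np.tile(patterns, (10, 1))
        emp = {tuple(p): 0.5 for p in patterns}

        def kl(rbm):
            V, p = exact_visible_distribution(rbm)
            tot = 0.0
            for cfg_v, prob in zip(V, p):
                q = emp.get(tuple(cfg_v), 0.0)
                if q > 0:
                    tot += q * np.log(q / prob)
            return tot

        cfg = TrainConfig(learning_rate=0.05, epochs=150, seed=init_seed,
                          visible_type="binary", weight_decay=0.0,
                          sample_hidden=False)
        before = kl(init_rbm(3, 2, seed=init_seed))
        after = kl(train_rbm(data, 2, cfg))
        assert after < before


class TestGibbsSampling:
    def test_chain_approaches_enumerated_distribution(self):
        rbm = _random_rbm(3, 2, 9)
        samples = gibbs_sample(rbm, 20000, seed=1)
        codes = (samples @ (2 ** np.arange(3))).astype(int)
        emp = np.bincount(codes, minlength=8) / len(samples)
        V, p = exact_visible_distribution(rbm)
        exact = np.zeros(8)
        for v, prob in zip(V, p):
            exact[int(v @ (2 ** np.arange(3)))] = prob
        tv = 0.5 * np.abs(emp - exact).sum()
        assert tv < 0.05


class TestDiscriminativeRBM:
    def test_untrained_symmetric_posterior(self):
        model = init_discriminative_rbm(4, 3, seed=0, weight_scale=0.0)
        p = predict(model, np.random.default_rng(0).standard_normal((5, 4)))
        assert np.allclose(p, 0.5)

    def test_probabilities_normalize(self):
        model = init_discriminative_rbm(4, 3, seed=1, weight_scale=0.5)
        p = predict(model, np.random.default_rng(1).standard_normal((10, 4)))
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_separable_set_high_accuracy(self):
        # oracle: the set is linearly separable by construction (margin 1)
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 2))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += (2 * y - 1) * 1.0
        model = train_discriminative_rbm(
            X, y, TrainConfig(learning_rate=0.1, epochs=60, seed=0),
            n_hidden=8)
        acc = (predict(model, X).argmax(axis=1) == y).mean()
        assert acc >= 0.95

    def test_zero_hidden_units_degenerate_to_prior(self):
        # with no hidden units the posterior ignores x: it equals the
        # label-bias softmax, exactly what intercept-only logistic
        # regression learns
        rng = np.random.default_rng(5)
        X = rng.standard_normal((60, 3))
        y = (rng.random(60) < 0.7).astype(int)
        model = train_discriminative_rbm(
            X, y, TrainConfig(learning_rate=0.2, epochs=200, seed=0),
            n_hidden=0)
        p = predict(model, X)
        assert np.allclose(p, p[0])  # independent of x
        assert p[0, 1] == pytest.approx(y.mean(), abs=0.05)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            train_discriminative_rbm(np.ones((4, 2)), np.zeros(4))
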