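"""Likelihood primitives against brute-force oracles."""

import numpy as np
import pytest
from scipy.special import softmax

import screenpref as sp
from screenpref.params import MXLParams


class TestMnlProbabilities:
    def test_symmetry(self):
        assert np.allclose(sp.mnl_probabilities([0.0, 0.0, 0.0]), 1 / 3)

    def test_closed_form(self):
        p = sp.mnl_probabilities([np.log(2), 0.0])
        assert np.allclose(p, [2 / 3, 1 / 3])

    def test_overflow_safety(self):
        p = sp.mnl_probabilities([1000.0, 0.0])
        assert np.isfinite(p).all()
        assert p[0] > 1 - 1e-12

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(50, 4)) * 10
        assert np.allclose(sp.mnl_probabilities(u).sum(axis=1), 1.0)

    def test_too_few_alternatives_rejected(self):
        with pytest.raises(ValueError):
            sp.mnl_probabilities([1.0])


class TestPanelLoglik:
    def test_single_uniform_task(self):
        X = np.zeros((1, 3, 2))
        assert sp.panel_loglik_at_beta(X, [0], np.zeros(2)) == pytest.approx(
            np.log(1 / 3)
        )

    def test_additivity_over_tasks(self, tiny_panel):
        beta = np.array([0.7, -0.4, 0.2])
        X, chosen = tiny_panel.X[0], tiny_panel.chosen[0]
        both = sp.panel_loglik_at_beta(X, chosen, beta)
        t0 = sp.panel_loglik_at_beta(X[:1], chosen[:1], beta)
        t1 = sp.panel_loglik_at_beta(X[1:], chosen[1:], beta)
        assert both == pytest.approx(t0 + t1, abs=1e-12)

    def test_matches_bruteforce_product(self, tiny_panel):
        beta = np.array([1.2, -0.8, 0.3])
        for i in range(2):
            expected = 0.0
            for t in range(2):
                u = tiny_panel.X[i, t] @ beta
                expected += np.log(softmax(u)[tiny_panel.chosen[i, t]])
            got = sp.panel_loglik_at_beta(tiny_panel.X[i], tiny_panel.chosen[i], beta)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_task_list_rejected(self):
        with pytest.raises(ValueError):
            sp.panel_loglik_at_beta(np.zeros((0, 3, 2)), [], np.zeros(2))


class TestHaltonDraws:
    def test_marginal_moments(self):
        z = sp.halton_normal_draws(10_000, 1, seed=0)
        assert abs(z.mean()) < 0.02
        assert 0.98 < z.std() < 1.02

    def test_deterministic(self):
        a = sp.halton_normal_draws(100, 5, seed=3)
        b = sp.halton_normal_draws(100, 5, seed=3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, sp.halton_normal_draws(100, 5, seed=4))

    def test_all_finite(self):
        z = sp.halton_normal_draws(5000, 17, seed=1, n_units=3)
        assert z.shape == (3, 5000, 17)
        assert np.isfinite(z).all()

    def test_high_dimension_moments(self):
        # later Halton bases (larger primes) are the weak spot; scrambling
        # must keep every marginal close to standard normal
        z = sp.halton_normal_draws(4000, 17, seed=2)
        assert np.abs(z.mean(axis=0)).max() < 0.05
        assert np.abs(z.std(axis=0) - 1).max() < 0.05


class TestSimulatedLoglik:
    def test_zero_sds_equal_analytic_mnl(self, tiny_panel):
        params = MXLParams(["x", "optout"], [0.5, -1.0], [0.0, 0.0], left=0.3)
        z = sp.halton_normal_draws(7, 2, seed=0, n_units=2)
        got = sp.simulated_loglik(params, tiny_panel, z)
        beta = np.array([0.5, -1.0, 0.3])
        expected = sum(
            sp.panel_loglik_at_beta(tiny_panel.X[i], tiny_panel.chosen[i], beta)
            for i in range(2)
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_single_zero_draw_equals_mnl_at_means(self, tiny_panel):
        params = MXLParams(["x", "optout"], [0.5, -1.0], [0.8, 1.2], left=0.3)
        z = np.zeros((2, 1, 2))
        got = sp.simulated_loglik(params, tiny_panel, z)
        beta = np.array([0.5, -1.0, 0.3])
        expected = sum(
            sp.panel_loglik_at_beta(tiny_panel.X[i], tiny_panel.chosen[i], beta)
            for i in range(2)
        )
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_hand_computed_three_draw_mixture(self, tiny_panel):
        params = MXLParams(["x", "optout"], [0.4, -0.6], [0.9, 0.5], left=0.2)
        rng = np.random.default_rng(5)
        z = rng.normal(size=(2, 3, 2))
        got = sp.simulated_loglik(params, tiny_panel, z)
        expected = 0.0
        for i in range(2):
            probs = []
            for r in range(3):
                beta = np.concatenate(
                    [params.means + params.sds * z[i, r], [params.left]]
                )
                lp = sp.panel_loglik_at_beta(
                    tiny_panel.X[i], tiny_panel.chosen[i], beta
                )
                probs.append(np.exp(lp))
            expected += np.log(np.mean(probs))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_sd_sign_flips(self, tiny_panel):
        z = sp.halton_normal_draws(64, 2, seed=1, n_units=2)
        a = sp.simulated_loglik(
            MXLParams(["x", "optout"], [0.4, -0.6], [0.9, 0.5], left=0.2),
            tiny_panel, z,
        )
        # flipping the sign of one SD together with that coordinate of the
        # draws leaves every simulated beta unchanged: only |sd| is identified
        from screenpref.likelihood import _panel_mixture_stats

        z_flip = z.copy()
        z_flip[:, :, 0] *= -1
        flipped, _ = _panel_mixture_stats(
            np.array([0.4, -0.6]), np.array([-0.9, 0.5]), 0.2, tiny_panel,
            z_flip, False,
        )
        assert a == pytest.approx(flipped.sum(), abs=1e-10)

    def test_dimension_mismatch_rejected(self, tiny_panel):
        params = MXLParams(["x", "optout"], [0.4, -0.6], [0.9, 0.5], left=0.2)
        with pytest.raises(ValueError):
            sp.simulated_loglik(params, tiny_panel, np.zeros((2, 5, 3)))

    def test_analytic_gradient_matches_finite_differences(self, tiny_panel):
        from screenpref.likelihood import _panel_mixture_stats

        mu = np.array([0.4, -0.6])
        s = np.array([0.9, 0.5])
        delta = 0.2
        rng = np.random.default_rng(7)
        z = rng.normal(size=(2, 4, 2))
        _, G = _panel_mixture_stats(mu, s, delta, tiny_panel, z, True)
        g = G.sum(axis=0)
        theta0 = np.concatenate([mu, s, [delta]])

        def f(theta):
            a, _ = _panel_mixture_stats(
                theta[:2], theta[2:4], theta[4], tiny_panel, z, False
            )
            return a.sum()

        h = 1e-6
        for j in range(5):
            tp, tm = theta0.copy(), theta0.copy()
            tp[j] += h
            tm[j] -= h
            fd = (f(tp) - f(tm)) / (2 * h)
            assert g[j] == pytest.approx(fd, abs=1e-6)


class TestMMMLLoglik:
    @pytest.fixture()
    def two_class_params(self):
        cls1 = MXLParams(["x", "optout"], [0.4, -0.6], [0.9, 0.5], left=0.2)
        cls2 = MXLParams(["x", "optout"], [-0.3, 0.2], [0.1, 0.4], left=0.1)
        gamma = np.array([[0.3, -0.5]])
        return sp.MMMLParams([cls1, cls2], gamma, membership_names=["female"])

    def test_identical_classes_collapse_to_single_mixture(self, tiny_panel):
        cls = MXLParams(["x", "optout"], [0.4, -0.6], [0.9, 0.5], left=0.2)
        mm = sp.MMMLParams([cls, cls], np.zeros((1, 1)), membership_names=[])
        z = sp.halton_normal_draws(32, 2, seed=2, n_units=2)
        Z = np.ones((2, 1))
        assert sp.mmml_loglik(mm, tiny_panel, Z, z) == pytest.approx(
            sp.simulated_loglik(cls, tiny_panel, z), abs=1e-10
        )

    def test_matches_hand_enumerated_double_mixture(self, tiny_panel, two_class_params):
        rng = np.random.default_rng(9)
        z = [rng.normal(size=(2, 2, 2)), rng.normal(size=(2, 2, 2))]
        Z = np.array([[1.0, 1.0], [1.0, 0.0]])
        got = sp.mmml_loglik(two_class_params, tiny_panel, Z, z)
        expected = 0.0
        for i in range(2):
            eta = two_class_params.gamma @ Z[i]
            pi = softmax(np.concatenate([[0.0], eta]))
            total = 0.0
            for c, cls in enumerate(two_class_params.classes):
                probs = []
                for r in range(2):
                    beta = np.concatenate(
                        [cls.means + cls.sds * z[c][i, r], [cls.left]]
                    )
                    lp = sp.panel_loglik_at_beta(
                        tiny_panel.X[i], tiny_panel.chosen[i], beta
                    )
                    probs.append(np.exp(lp))
                total += pi[c] * np.mean(probs)
            expected += np.log(total)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_sds_equal_latent_class_plain_logit(self, tiny_panel, two_class_params):
        mm = two_class_params
        for cls in mm.classes:
            cls.sds = np.zeros(2)
        z = sp.halton_normal_draws(16, 2, seed=3, n_units=2)
        Z = np.array([[1.0, 1.0], [1.0, 0.0]])
        got = sp.mmml_loglik(mm, tiny_panel, Z, z)
        expected = 0.0
        for i in range(2):
            pi = softmax(np.concatenate([[0.0], mm.gamma @ Z[i]]))
            total = 0.0
            for c, cls in enumerate(mm.classes):
                beta = np.concatenate([cls.means, [cls.left]])
                total += pi[c] * np.exp(
                    sp.panel_loglik_at_beta(tiny_panel.X[i], tiny_panel.chosen[i], beta)
                )
            expected += np.log(total)
        assert got == pytest.approx(expected, abs=1e-12)


class TestClassPriorProbs:
    def test_zero_gamma_uniform(self):
        Z = np.column_stack([np.ones(5), np.random.default_rng(0).normal(size=(5, 3))])
        pi = sp.class_prior_probs(np.zeros((2, 4)), Z)
        assert np.allclose(pi, 1 / 3)

    def test_monotone_in_linear_predictor(self):
        Z = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]])
        pi = sp.class_prior_probs(np.array([[0.0, 0.8]]), Z)
        assert np.all(np.diff(pi[:, 1]) > 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sp.class_prior_probs(np.zeros((1, 3)), np.ones((2, 2)))
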