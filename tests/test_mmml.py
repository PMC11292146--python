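"""Latent-class mixed logit: membership model, posteriors, labeling, selection."""

import numpy as np
import pytest
from scipy.special import expit

import screenpref as sp
from screenpref.mmml import _relabel_by_optout
from screenpref.params import MXLParams


@pytest.fixture(scope="module")
def lc_fit(small_design):
    """A converged 2-class fit on a modest simulated latent-class sample."""
    mm = sp.reference_mmml_params()
    cohort = sp.simulate_respondents(250, seed=31, n_blocks=4)
    betas, lefts, classes = sp.draw_individual_coefficients(
        mm, 250, seed=31, covariates=cohort
    )
    ds = sp.simulate_choices(small_design, cohort, betas=betas, lefts=lefts, seed=31)
    flt, _ = sp.apply_sample_filters(ds)
    est = sp.LatentClassMixedLogit(
        n_classes=2, n_draws=30, seed=31, n_starts=4, compute_se=False
    ).fit(flt)
    return est


class TestMembershipModel:
    def test_female_coefficient_shifts_probability_up(self):
        mm = sp.reference_mmml_params()
        P = len(mm.membership_names) + 1
        z_male = np.zeros((1, P)); z_male[0, 0] = 1.0
        z_female = z_male.copy()
        z_female[0, 1 + mm.membership_names.index("female")] = 1.0
        p_male = sp.class_prior_probs(mm.gamma, z_male)[0, 1]
        p_female = sp.class_prior_probs(mm.gamma, z_female)[0, 1]
        intercept = mm.gamma[0, 0]
        assert p_female == pytest.approx(expit(intercept + 0.19), abs=1e-12)
        assert p_female > p_male

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        Z = np.column_stack([np.ones(20), rng.normal(size=(20, 3))])
        pi = sp.class_prior_probs(rng.normal(size=(2, 4)), Z)
        assert np.allclose(pi.sum(axis=1), 1.0)


class TestRelabeling:
    def _two_class(self, optout1, optout2):
        names = ["x", "optout"]
        c1 = MXLParams(names, [0.5, optout1], [0.1, 0.1], left=0.1)
        c2 = MXLParams(names, [-0.5, optout2], [0.1, 0.1], left=0.2)
        gamma = np.array([[0.4, 0.7]])
        return sp.MMMLParams([c1, c2], gamma, membership_names=["female"])

    def test_already_ordered_params_unchanged(self):
        mm = self._two_class(-5.0, -0.5)
        out, order = _relabel_by_optout(mm)
        assert order == [0, 1]
        assert np.allclose(out.gamma, mm.gamma)
        assert out.class_labels == ["strong_supporters", "weak_supporters"]

    def test_swapped_classes_reordered_and_gamma_reref(self):
        mm = self._two_class(-0.5, -5.0)
        out, order = _relabel_by_optout(mm)
        assert order == [1, 0]
        # class 2 becomes the reference: membership coefficients flip sign
        assert np.allclose(out.gamma, -mm.gamma)
        assert out.classes[0].means[1] == -5.0

    def test_prior_probabilities_invariant_under_relabeling(self):
        mm = self._two_class(-0.5, -5.0)
        out, order = _relabel_by_optout(mm)
        Z = np.array([[1.0, 0.0], [1.0, 1.0]])
        before = sp.class_prior_probs(mm.gamma, Z)
        after = sp.class_prior_probs(out.gamma, Z)
        assert np.allclose(after, before[:, order])


class TestPosterior:
    def test_impossible_class_gets_zero_posterior(self, tiny_panel):
        names = ["x", "optout"]
        # class 1 puts probability ~0 on the observed choices
        c1 = MXLParams(names, [-40.0, -40.0], [0.0, 0.0], left=-40.0)
        c2 = MXLParams(names, [0.0, 0.0], [0.0, 0.0], left=0.0)
        mm = sp.MMMLParams([c1, c2], np.zeros((1, 1)), membership_names=[])
        post = sp.posterior_class_probs(
            mm, tiny_panel, np.ones((2, 1)), np.zeros((2, 1, 2))
        )
        assert np.allclose(post.probabilities[:, 1], 1.0, atol=1e-8)

    def test_equal_class_likelihoods_return_prior(self, tiny_panel):
        names = ["x", "optout"]
        cls = MXLParams(names, [0.3, -0.2], [0.0, 0.0], left=0.1)
        gamma = np.array([[0.8]])
        mm = sp.MMMLParams([cls, cls], gamma, membership_names=[])
        Z = np.ones((2, 1))
        post = sp.posterior_class_probs(mm, tiny_panel, Z, np.zeros((2, 1, 2)))
        prior = sp.class_prior_probs(gamma, Z)
        assert np.allclose(post.probabilities, prior, atol=1e-12)

    def test_modal_counts_partition_sample(self, lc_fit):
        post = lc_fit.posterior_
        assert post.counts_modal.sum() == lc_fit.panel_.n_respondents
        assert np.allclose(post.probabilities.sum(axis=1), 1.0)
        assert post.shares_posterior.sum() == pytest.approx(1.0)
        assert post.shares_modal.sum() == pytest.approx(1.0)

    def test_posterior_shares_match_mean_prior_at_fit(self, lc_fit):
        # averaging posteriors over respondents reproduces the mean prior
        pi = sp.class_prior_probs(lc_fit.params_.gamma, lc_fit.Z_).mean(axis=0)
        assert np.abs(lc_fit.posterior_.shares_posterior - pi).max() < 0.05


class TestFit:
    def test_classes_labeled_strong_first(self, lc_fit):
        p = lc_fit.params_
        assert p.class_labels == ["strong_supporters", "weak_supporters"]
        o = [cls.means[cls.index("optout")] for cls in p.classes]
        assert o[0] < o[1]

    def test_two_class_loglik_beats_one_class(self, lc_fit, small_design):
        mm = sp.reference_mmml_params()
        cohort = sp.simulate_respondents(250, seed=31, n_blocks=4)
        betas, lefts, _ = sp.draw_individual_coefficients(
            mm, 250, seed=31, covariates=cohort
        )
        ds = sp.simulate_choices(small_design, cohort, betas=betas, lefts=lefts, seed=31)
        flt, _ = sp.apply_sample_filters(ds)
        one = sp.MixedLogit(n_draws=30, seed=31, compute_se=False).fit(flt)
        assert lc_fit.loglik_ >= one.loglik_ - 1e-3

    def test_single_class_requested_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            sp.LatentClassMixedLogit(n_classes=1).fit(small_dataset)

    def test_missing_covariates_rejected(self, small_design):
        ref = sp.reference_mxl_params()
        cohort = sp.simulate_respondents(60, seed=5, n_blocks=4)
        cohort_bad = sp.plant_missing_covariates(cohort, [1, 2, 3])
        ds = sp.simulate_choices(small_design, cohort_bad, params=ref, seed=5)
        ds = ds.drop_validity_tasks()
        with pytest.raises(ValueError, match="missing"):
            sp.LatentClassMixedLogit(n_classes=2, n_draws=5, n_starts=1).fit(ds)


class TestModelSelection:
    def test_bic_recomputation_and_table_shape(self, lc_fit, small_dataset):
        chosen, table = sp.select_n_classes(
            small_dataset, candidate_C=(2,), n_draws=10, seed=3, n_starts=2,
            start_iters=15,
        )
        assert len(table) == 2  # C=1 baseline + C=2
        for _, row in table.dropna(subset=["bic"]).iterrows():
            assert row["bic"] == pytest.approx(
                row["n_params"] * np.log(small_dataset.to_panel().n_choices)
                - 2 * row["loglik"]
            )
        assert chosen in (1, 2)
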