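"""Tests for the latent class core: likelihood, EM, fit statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import medpatterns as mp
from medpatterns import LCAParams, ValidationError
from medpatterns.errors import DegenerateClassError
from medpatterns.lta import match_classes

from . import _oracles
from .conftest import make_matrix


class TestCountParams:
    @pytest.mark.parametrize(
        "k, j, expected", [(4, 27, 111), (2, 27, 55), (3, 27, 83), (1, 9, 9)]
    )
    def test_values(self, k, j, expected):
        assert mp.count_params(k, j) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            mp.count_params(0, 5)


class TestLogLikelihood:
    def test_single_class_half_probabilities(self):
        data = make_matrix(np.random.default_rng(0).integers(0, 2, (7, 4)))
        params = LCAParams(np.array([1.0]), np.full((1, 4), 0.5))
        assert mp.log_likelihood(params, data) == pytest.approx(
            7 * 4 * np.log(0.5), abs=1e-10
        )

    def test_two_class_toy_frozen_value(self, toy_2class):
        # ln(.41) + ln(.09) + ln(.09) + ln(.41), by direct enumeration
        data, pi, rho = toy_2class
        ll = mp.log_likelihood(LCAParams(pi, rho), data)
        assert ll == pytest.approx(-6.599087455871311, abs=1e-9)
        assert ll == pytest.approx(
            _oracles.lca_loglik(pi, rho, data.values), abs=1e-10
        )

    def test_class_permutation_invariance(self, toy_2class):
        data, _, _ = toy_2class
        pi = np.array([0.3, 0.7])
        rho = np.array([[0.2, 0.8], [0.6, 0.4]])
        a = mp.log_likelihood(LCAParams(pi, rho), data)
        b = mp.log_likelihood(LCAParams(pi[::-1], rho[::-1]), data)
        assert a == pytest.approx(b, abs=1e-12)

    def test_dimension_mismatch_names_axis(self, toy_2class):
        data, pi, _ = toy_2class
        with pytest.raises(ValidationError, match="item axis"):
            mp.log_likelihood(LCAParams(pi, np.full((2, 5), 0.4)), data)


class TestESteps:
    def test_single_class_posterior_is_one(self, toy_2class):
        data, _, _ = toy_2class
        post = mp.e_step(LCAParams(np.array([1.0]), np.full((1, 2), 0.3)), data)
        assert np.array_equal(post, np.ones((4, 1)))

    def test_mirror_symmetry_gives_half(self):
        # for y = (0, 1), classes (p, q) and (1-q, 1-p) are equidistant:
        # f0 = (1-p) q and f1 = q (1-p)
        data = make_matrix([[0, 1]])
        params = LCAParams(
            np.array([0.5, 0.5]), np.array([[0.2, 0.7], [0.3, 0.8]])
        )
        post = mp.e_step(params, data)
        assert post[0] == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_matches_bayes_weights_from_enumeration(self, toy_2class):
        data, pi, rho = toy_2class
        post = mp.e_step(LCAParams(pi, rho), data)
        expected = _oracles.lca_posteriors(pi, rho, data.values)
        assert np.abs(post - expected).max() < 1e-10
        # frozen anchor for the all-zero row: 0.81 / 0.82
        assert post[0, 0] == pytest.approx(0.9878048780487805, abs=1e-12)


class TestMStep:
    def test_hard_posteriors_give_class_frequencies_and_means(self):
        data = make_matrix([[1, 0], [1, 1], [0, 0], [0, 1]])
        post = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
        params = mp.m_step(post, data)
        assert params.class_prevalence == pytest.approx([0.5, 0.5])
        assert params.item_response == pytest.approx(
            np.array([[1.0 - 1e-6, 0.5], [1e-6, 0.5]])
        )

    def test_uniform_posteriors_give_overall_means(self):
        data = make_matrix([[1, 0], [1, 1], [0, 0], [0, 1]])
        post = np.full((4, 2), 0.5)
        params = mp.m_step(post, data)
        assert params.item_response == pytest.approx(np.full((2, 2), 0.5))

    def test_one_em_iteration_hand_values(self, toy_2class):
        data, pi, rho = toy_2class
        post = mp.e_step(LCAParams(pi, rho), data)
        params = mp.m_step(post, data)
        assert params.class_prevalence == pytest.approx([0.5, 0.5], abs=1e-12)
        # weighted means computed by hand from the Bayes weights
        assert params.item_response[0] == pytest.approx(
            [0.2560975609756098, 0.2560975609756098], abs=1e-12
        )
        assert params.item_response[1] == pytest.approx(
            [0.7439024390243902, 0.7439024390243902], abs=1e-12
        )

    def test_degenerate_class_raises(self):
        data = make_matrix([[0, 1], [1, 0]])
        post = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(DegenerateClassError):
            mp.m_step(post, data)


class TestFitLCA:
    def test_one_class_closed_form(self):
        data = make_matrix([[1, 0], [1, 1], [0, 0], [1, 0]])
        fit = mp.fit_lca(data, 1, n_starts=3, seed=0)
        assert fit.params.class_prevalence == pytest.approx([1.0])
        assert fit.params.item_response[0] == pytest.approx([0.75, 0.25])
        assert fit.converged
        assert np.isnan(fit.entropy)  # relative entropy undefined for K=1

    def test_refit_same_seed_identical(self, toy_2class):
        rng = np.random.default_rng(1)
        data = make_matrix(rng.integers(0, 2, (60, 4)))
        a = mp.fit_lca(data, 2, n_starts=5, seed=7)
        b = mp.fit_lca(data, 2, n_starts=5, seed=7)
        assert a.log_likelihood == b.log_likelihood
        assert np.array_equal(a.posteriors, b.posteriors)
        assert np.array_equal(
            a.params.item_response, b.params.item_response
        )
        assert a.best_start_seed == b.best_start_seed

    def test_canonical_order_descending_prevalence(self):
        truth = mp.copdgene_like_truth(n_subjects=800, seed=2)
        data, _ = mp.generate_cross_sectional(truth)
        fit = mp.fit_lca(data, 3, n_starts=6, seed=3, tol=1e-7)
        pi = fit.params.class_prevalence
        assert (np.diff(pi) <= 1e-12).all()

    def test_posterior_rows_sum_to_one(self):
        truth = mp.copdgene_like_truth(n_subjects=400, seed=9)
        data, _ = mp.generate_cross_sectional(truth)
        fit = mp.fit_lca(data, 2, n_starts=4, seed=5, tol=1e-7)
        assert np.abs(fit.posteriors.sum(axis=1) - 1).max() < 1e-8

    def test_parameter_recovery_improves_with_n(self):
        # well-separated 2-class truth: errors shrink from N=500 to N=5000
        rho = np.array([[0.1] * 6, [0.9] * 6])
        errs = {}
        for n in (500, 5000):
            truth = mp.GenerativeTruth(
                n_subjects=n,
                class_prevalence=np.array([0.6, 0.4]),
                item_response_p1=rho,
                item_response_p2=rho,
                transition_matrix=np.eye(2),
                seed=21,
            )
            data, _ = mp.generate_cross_sectional(truth)
            fit = mp.fit_lca(data, 2, n_starts=5, seed=1, tol=1e-8)
            perm = match_classes(rho, fit.params.item_response)
            errs[n] = np.abs(
                fit.params.item_response[perm] - rho
            ).mean() + np.abs(
                fit.params.class_prevalence[perm]
                - truth.class_prevalence
            ).max()
        assert errs[5000] < errs[500]


class TestDevianceG2:
    def test_saturated_model_zero(self):
        # two observed patterns, two classes that reproduce them exactly
        data = make_matrix([[0, 0], [1, 1], [0, 0], [1, 1]])
        params = LCAParams(
            np.array([0.5, 0.5]), np.array([[0.0, 0.0], [1.0, 1.0]])
        )
        assert abs(mp.deviance_g2(params, data)) < 1e-3  # rho clamping only

    def test_one_class_hand_value(self):
        # rows 00,00,01,11: independence model with means (0.25, 0.5)
        data = make_matrix([[0, 0], [0, 0], [0, 1], [1, 1]])
        fit = mp.fit_lca(data, 1, n_starts=1, seed=0)
        assert fit.g_squared == pytest.approx(1.726092434710685, abs=1e-6)

    def test_row_order_invariance(self, toy_2class):
        data, pi, rho = toy_2class
        params = LCAParams(pi, rho)
        shuffled = make_matrix(data.values[::-1])
        assert mp.deviance_g2(params, data) == pytest.approx(
            mp.deviance_g2(params, shuffled), abs=1e-12
        )


class TestInformationCriteria:
    def test_published_fourclass_anchors(self):
        aic, bic, caic, sabic = mp.information_criteria(6694.69, 111, 5564)
        assert aic == pytest.approx(6916.69, abs=1e-9)
        assert caic - bic == pytest.approx(111.0, abs=1e-9)

    def test_caic_offset_from_bic(self):
        # published BIC 7651.86 implies CAIC 7762.86 for p=111
        assert 7651.86 + 111 == pytest.approx(7762.86)
        _, bic, caic, _ = mp.information_criteria(100.0, 111, 5564)
        assert caic == pytest.approx(bic + 111, abs=1e-10)

    def test_closed_form_exp_two(self):
        aic, bic, caic, _ = mp.information_criteria(0.0, 1, np.e**2)
        assert aic == pytest.approx(2.0, abs=1e-12)
        assert bic == pytest.approx(2.0, abs=1e-12)
        assert caic == pytest.approx(3.0, abs=1e-12)


class TestEntropyAndModal:
    def test_degenerate_posteriors_entropy_one(self):
        post = np.eye(3)[np.array([0, 1, 2, 0])]
        assert mp.relative_entropy(post) == pytest.approx(1.0)

    def test_uniform_posteriors_entropy_zero(self):
        assert mp.relative_entropy(np.full((5, 4), 0.25)) == pytest.approx(0.0)

    def test_matches_direct_evaluation(self):
        truth = mp.copdgene_like_truth(n_subjects=300, seed=13)
        data, _ = mp.generate_cross_sectional(truth)
        fit = mp.fit_lca(data, 2, n_starts=4, seed=2, tol=1e-7)
        direct = _oracles.relative_entropy_direct(fit.posteriors)
        assert fit.entropy == pytest.approx(direct, abs=1e-10)

    def test_modal_assignment_and_tie_break(self):
        post = np.array([[0.1, 0.9], [0.5, 0.5], [0.7, 0.3]])
        assert mp.modal_assign(post).tolist() == [1, 0, 0]


@st.composite
def small_problem(draw):
    k = draw(st.integers(1, 3))
    j = draw(st.integers(1, 4))
    n = draw(st.integers(2, 20))
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    pi = rng.dirichlet(np.ones(k))
    pi = pi / pi.sum()
    rho = rng.uniform(0.05, 0.95, (k, j))
    values = rng.integers(0, 2, (n, j))
    return pi, rho, values


@settings(max_examples=60, deadline=None, derandomize=True)
@given(small_problem())
def test_loglik_and_posteriors_match_enumeration(problem):
    """Vectorized log-space computation equals brute-force enumeration."""
    pi, rho, values = problem
    data = make_matrix(values)
    params = LCAParams(pi, rho)
    assert mp.log_likelihood(params, data) == pytest.approx(
        _oracles.lca_loglik(pi, rho, values), abs=1e-10
    )
    post = mp.e_step(params, data)
    assert np.abs(post - _oracles.lca_posteriors(pi, rho, values)).max() < 1e-10
    assert np.abs(post.sum(axis=1) - 1).max() < 1e-12
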