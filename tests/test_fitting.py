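"""Likelihood, MLE/MAP estimation, and the Laplace evidence approximation."""

import math

import numpy as np
import pytest
import scipy.stats

import rlcontext.fitting as ft
import rlcontext.models as m
import rlcontext.simulate as sim
import rlcontext.task as tk
from conftest import make_history


def brute_force_nll(params, history):
    """Independent likelihood replay, written directly from the update
    equations with plain Python floats (no shared code with the package
    kernels)."""
    n_ctx = history.n_contexts
    q = [[0.0, 0.0] for _ in range(n_ctx)]
    v = [0.0] * n_ctx
    total = 0.0
    for t in range(len(history)):
        s = int(history.context_idx[t])
        c = int(history.chosen[t])
        u = 1 - c
        p_chosen = 1.0 / (1.0 + math.exp(params.beta * (q[s][u] - q[s][c])))
        total -= math.log(p_chosen)
        r_c = float(history.r_c[t])
        if history.complete[t]:
            r_u = float(history.r_u[t])
            delta_u = r_u - v[s] - q[s][u]
            r_tot = (r_c + r_u) / 2.0
        else:
            delta_u = 0.0
            r_tot = (r_c + q[s][u]) / 2.0
        delta_c = r_c - v[s] - q[s][c]
        delta_v = r_tot - v[s]
        q[s][c] += params.alpha1 * delta_c
        q[s][u] += params.alpha2 * delta_u
        v[s] += params.alpha3 * delta_v
    return total


PARAM_SETS = [
    (m.Model.M1, m.Parameters(3.0, 0.5)),
    (m.Model.M2, m.Parameters(5.0, 0.3, 0.6)),
    (m.Model.M3, m.Parameters(2.0, 0.4, 0.2, 0.7)),
    (m.Model.M4, m.Parameters(7.0, 0.25, 0.0, 0.5)),
]


class TestNegativeLogLikelihood:
    @pytest.mark.parametrize("model,params", PARAM_SETS)
    def test_matches_brute_force_replay(self, contexts, model, params):
        """5-trial instances, mixed Partial/Complete contexts, to 1e-10."""
        history = make_history(
            contexts,
            context_idx=[0, 1, 3, 1, 2],
            chosen=[0, 1, 0, 0, 1],
            r_c=[1.0, 0.0, -1.0, 1.0, 0.0],
            r_u=[None, 1.0, 0.0, 0.0, None],
        )
        got = ft.negative_log_likelihood(params, model, history)
        expected = brute_force_nll(params.constrained_to(model), history)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_chance_model_closed_form(self, m3_session):
        history, _ = m3_session
        nll = ft.negative_log_likelihood(m.Parameters(0.0, 0.3), m.Model.M1, history)
        assert nll == pytest.approx(80 * math.log(2), rel=1e-12)

    def test_empty_history_scores_zero(self, contexts):
        empty = make_history(contexts, [], [], [], [])
        assert ft.negative_log_likelihood(m.Parameters(5.0, 0.3), m.Model.M1, empty) == 0.0


class TestPriors:
    def test_logpdf_matches_scipy(self):
        gamma = ft.Prior("gamma", (1.2, 5.0))
        beta = ft.Prior("beta", (1.1, 1.1))
        for x in (0.05, 0.4, 0.9):
            assert beta.logpdf(x) == pytest.approx(
                scipy.stats.beta.logpdf(x, 1.1, 1.1), rel=1e-12
            )
        for x in (0.5, 3.0, 20.0):
            assert gamma.logpdf(x) == pytest.approx(
                scipy.stats.gamma.logpdf(x, a=1.2, scale=5.0), rel=1e-12
            )

    def test_improper_prior_rejected(self):
        with pytest.raises(ValueError):
            ft.Prior("uniform", (0.0, np.inf))
        with pytest.raises(ValueError):
            ft.Prior("gamma", (-1.0, 5.0))


class TestFitMLE:
    def test_pinned_rates_stay_zero(self, m3_session):
        history, _ = m3_session
        fit = ft.fit_mle(m.Model.M1, history, n_restarts=4, seed=0)
        assert fit.params.alpha2 == 0.0 and fit.params.alpha3 == 0.0

    def test_duplicated_history_doubles_nll_same_argmax(self, m3_session):
        """Fitting the same session twice over (each replayed from the
        initial state) doubles the NLL and leaves the argmax unchanged."""
        history, _ = m3_session
        fit1 = ft.fit_mle(m.Model.M1, history, n_restarts=8, seed=1)
        fit2 = ft.fit_group_level(
            m.Model.M1, [history, history], objective="nll", n_restarts=8, seed=1
        )
        assert fit2.negll == pytest.approx(2 * fit1.negll, rel=1e-6)
        assert fit2.params.alpha1 == pytest.approx(fit1.params.alpha1, abs=5e-3)

    def test_restart_robustness(self, m3_session):
        """The likelihood surface at the study's scale is benign: nearly
        all restarts find the same optimum."""
        history, _ = m3_session
        fit = ft.fit_mle(m.Model.M1, history, n_restarts=20, seed=2)
        assert fit.n_restarts_converged >= 18

    def test_nested_nll_monotone(self, m3_session):
        history, _ = m3_session
        f1 = ft.fit_mle(m.Model.M1, history, n_restarts=8, seed=3)
        f2 = ft.fit_mle(
            m.Model.M2, history, n_restarts=8, seed=3,
            extra_starts=[np.array([f1.params.beta, f1.params.alpha1, 0.0])],
        )
        f3 = ft.fit_mle(
            m.Model.M3, history, n_restarts=8, seed=3,
            extra_starts=[
                np.array([f2.params.beta, f2.params.alpha1, f2.params.alpha2, 0.0])
            ],
        )
        assert f3.negll <= f2.negll + 1e-8 <= f1.negll + 2e-8


class TestFitMAP:
    def test_flat_priors_coincide_with_mle(self, m3_session):
        history, _ = m3_session
        mle = ft.fit_mle(m.Model.M1, history, n_restarts=8, seed=4)
        flat = ft.fit_map(
            m.Model.M1, history, priors=ft.PriorSpec.flat(), n_restarts=8, seed=4
        )
        assert flat.negll == pytest.approx(mle.negll, abs=1e-5)
        assert flat.params.alpha1 == pytest.approx(mle.params.alpha1, abs=1e-3)

    def test_tight_prior_dominates(self, m3_session):
        history, _ = m3_session
        target_beta, target_alpha = 4.0, 0.35
        priors = ft.PriorSpec(
            beta=ft.Prior("gamma", (1.6e5, target_beta / 1.6e5)),  # sd ~ 0.01
            alpha1=ft.Prior("beta", (target_alpha * 2e5, (1 - target_alpha) * 2e5)),
            alpha2=ft.Prior("beta", (1.1, 1.1)),
            alpha3=ft.Prior("beta", (1.1, 1.1)),
        )
        fit = ft.fit_map(m.Model.M1, history, priors=priors, n_restarts=6, seed=5)
        assert fit.params.beta == pytest.approx(target_beta, abs=0.1)
        assert fit.params.alpha1 == pytest.approx(target_alpha, abs=0.01)

    def test_evidence_penalises_complexity_on_m1_data(self, m1_cohort):
        """On data from basic Q-learning, the Laplace evidence of the
        generating model beats the full model's on average."""
        ev1 = ev3 = 0.0
        for history in m1_cohort[:6]:
            ev1 += ft.fit_map(m.Model.M1, history, n_restarts=6, seed=6).log_evidence
            ev3 += ft.fit_map(m.Model.M3, history, n_restarts=6, seed=6).log_evidence
        assert ev1 > ev3

    def test_recompute_matches_stored_evidence(self, m3_session):
        history, _ = m3_session
        fit = ft.fit_map(m.Model.M2, history, n_restarts=6, seed=7)
        again = ft.laplace_evidence(fit, m.Model.M2, history)
        assert again == pytest.approx(fit.log_evidence, abs=1e-6)

    def test_mle_fit_has_no_evidence(self, m3_session):
        history, _ = m3_session
        fit = ft.fit_mle(m.Model.M1, history, n_restarts=2, seed=0)
        with pytest.raises(ValueError):
            ft.laplace_evidence(fit, m.Model.M1, history)


class TestLaplaceApproximation:
    def test_exact_for_quadratic_log_posterior(self):
        A = np.array([[2.0, 0.3], [0.3, 1.5]])
        mu = np.array([0.4, -0.2])
        c = 3.7
        neg_logpost = lambda th: 0.5 * (th - mu) @ A @ (th - mu) + c
        analytic = -c + math.log(2 * math.pi) - 0.5 * np.linalg.slogdet(A)[1]
        got, logdet = ft.laplace_log_evidence(neg_logpost, mu)
        assert got == pytest.approx(analytic, abs=1e-6)
        assert logdet == pytest.approx(np.linalg.slogdet(A)[1], abs=1e-6)

    def test_beta_bernoulli_conjugate_oracle(self):
        """n=80 coin flips with a Beta(2,2) prior: Laplace within 0.02 nats
        of the closed-form marginal likelihood."""
        n, h, a, b = 80, 55, 2.0, 2.0
        from scipy.special import betaln

        def neg_logpost(th):
            x = th[0]
            return -(
                (h + a - 1) * math.log(x)
                + (n - h + b - 1) * math.log1p(-x)
                - betaln(a, b)
            )

        exact = betaln(a + h, b + n - h) - betaln(a, b)
        theta_map = np.array([(h + a - 1) / (n + a + b - 2)])
        got, _ = ft.laplace_log_evidence(neg_logpost, theta_map, bounds=[(1e-9, 1 - 1e-9)])
        assert got == pytest.approx(exact, abs=0.02)

    def test_zero_free_parameters_returns_negative_nll(self):
        got, logdet = ft.laplace_log_evidence(lambda th: 55.45, np.array([]))
        assert got == -55.45 and logdet == 0.0

    def test_non_positive_definite_hessian_raises(self):
        concave = lambda th: -float(th[0] ** 2)
        with pytest.raises(np.linalg.LinAlgError):
            ft.laplace_log_evidence(concave, np.array([0.0]))


class TestGroupLevel:
    def test_singleton_group_equals_subject_fit(self, m3_session):
        history, _ = m3_session
        solo = ft.fit_mle(m.Model.M1, history, n_restarts=6, seed=8)
        group = ft.fit_group_level(m.Model.M1, [history], objective="nll", n_restarts=6, seed=8)
        assert group.negll == pytest.approx(solo.negll, abs=1e-9)
        assert group.level == "group"

    def test_duplicated_subjects_same_argmax(self, m3_session):
        history, _ = m3_session
        one = ft.fit_group_level(m.Model.M1, [history], objective="nll", n_restarts=6, seed=9)
        three = ft.fit_group_level(
            m.Model.M1, [history] * 3, objective="nll", n_restarts=6, seed=9
        )
        assert three.params.alpha1 == pytest.approx(one.params.alpha1, abs=1e-4)
        assert three.negll == pytest.approx(3 * one.negll, rel=1e-6)

    def test_cohort_parameter_recovery(self, m1_cohort):
        group = ft.fit_group_level(m.Model.M1, m1_cohort, objective="nll", n_restarts=8, seed=10)
        assert group.params.alpha1 == pytest.approx(0.3, abs=0.12)
        assert group.params.beta == pytest.approx(5.0, rel=0.5)

    def test_lpp_objective_reports_posterior(self, m1_cohort):
        group = ft.fit_group_level(
            m.Model.M1, m1_cohort[:4], objective="lpp", n_restarts=6, seed=11
        )
        assert group.lpp is not None and group.log_evidence is not None

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            ft.fit_group_level(m.Model.M1, [], objective="nll")
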