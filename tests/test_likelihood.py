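"""Likelihood engine: closed forms, analytic score vs finite differences,
probability identities."""

import numpy as np
import pytest

from cshmpl import CompetingRisksMPL, simulate_dataset, study_preset
from cshmpl.likelihood import (
    LikelihoodWorkspace,
    ModelParameters,
    cif,
    cif_gradients,
    cumulative_hazard,
    hazard,
    survival,
)

from conftest import constant_hazard_basis, finite_difference_gradient, single_subject

# two constant-hazard risks h1=1, h2=0.5 realized with order-1 bases on [0,3]
TWO_RISK_CONST = ModelParameters(
    beta=np.zeros((2, 0)), theta=[np.array([3.0]), np.array([1.5])]
)
BASES_CONST = [constant_hazard_basis(3.0), constant_hazard_basis(3.0)]


class TestHazards:
    def test_constant_baseline(self):
        b = constant_hazard_basis(1.0)
        p = ModelParameters(np.zeros((1, 0)), [np.array([3.0])])
        np.testing.assert_allclose(hazard(p, [b], 0, [0.1, 0.9], np.zeros(0)), 3.0)

    def test_proportional_hazards_doubling(self):
        b = constant_hazard_basis(1.0)
        p = ModelParameters(np.array([[np.log(2.0)]]), [np.array([3.0])])
        h0 = hazard(p, [b], 0, [0.5], np.zeros(1))
        h1 = hazard(p, [b], 0, [0.5], np.ones(1))
        assert h1[0] == pytest.approx(2.0 * h0[0])

    def test_cumulative_hazard_closed_form_and_zero_at_origin(self):
        b = constant_hazard_basis(1.0)
        p = ModelParameters(np.zeros((1, 0)), [np.array([3.0])])
        H = cumulative_hazard(p, [b], 0, [0.0, 0.25], np.zeros(0))
        assert H[0] == 0.0
        assert H[1] == pytest.approx(0.75)

    def test_spline_fit_recovers_weibull_hazard_shape(self):
        """Least-squares projection of 3t^2 onto a cubic basis evaluates near
        3t^2 on an interior grid."""
        from cshmpl.splines import MSplineBasis

        basis = MSplineBasis(order=4, interior_knots=np.array([0.25, 0.5, 0.75]),
                             boundary=(0.0, 1.0))
        t = np.linspace(0, 1, 500)
        theta, *_ = np.linalg.lstsq(basis.eval_basis(t), 3 * t ** 2, rcond=None)
        interior = np.linspace(0.1, 0.9, 50)
        approx = basis.eval_basis(interior) @ theta
        np.testing.assert_allclose(approx, 3 * interior ** 2, atol=5e-3)


class TestCIF:
    def test_closed_form_two_constant_risks(self):
        # F1(t) = (2/3)(1 - exp(-1.5 t)); frozen value at t=1
        val = cif(TWO_RISK_CONST, BASES_CONST, 0, [1.0], np.zeros(0))
        assert val[0] == pytest.approx(0.5179132265677135, abs=1e-9)

    def test_symmetric_risks_have_identical_cifs(self):
        p = ModelParameters(np.zeros((2, 0)), [np.array([2.0]), np.array([2.0])])
        bases = [constant_hazard_basis(2.0)] * 2
        t = [0.3, 0.9, 1.5]
        np.testing.assert_allclose(
            cif(p, bases, 0, t, np.zeros(0)), cif(p, bases, 1, t, np.zeros(0))
        )

    def test_cif_zero_at_origin(self):
        assert cif(TWO_RISK_CONST, BASES_CONST, 0, [0.0], np.zeros(0))[0] == 0.0

    def test_survival_plus_cifs_is_one(self, small_workspace, random_params):
        ws = small_workspace
        X = ws.data.X[3]
        t = np.linspace(0.05, ws.bases[0].boundary[1], 20)
        total = survival(random_params, ws.bases, t, X)
        for r in range(ws.g):
            total = total + cif(random_params, ws.bases, r, t, X)
        np.testing.assert_allclose(total, 1.0, atol=1e-6)

    def test_cifs_monotone_nondecreasing(self, small_workspace, random_params):
        ws = small_workspace
        t = np.linspace(0, ws.bases[0].boundary[1], 50)
        for r in range(ws.g):
            f = cif(random_params, ws.bases, r, t, ws.data.X[0])
            assert np.all(np.diff(f) >= -1e-12)


class TestLogLikelihoodClosedForms:
    def test_single_event_exponential(self):
        ws = LikelihoodWorkspace(single_subject("event", 1.0, 1.0),
                                 [constant_hazard_basis(2.0)])
        p = ModelParameters(np.zeros((1, 1)), [np.array([2.0])])  # hazard 1
        assert ws.log_likelihood(p) == pytest.approx(-1.0)

    def test_single_right_censoring(self):
        ws = LikelihoodWorkspace(single_subject("right", 2.0, np.inf),
                                 [constant_hazard_basis(2.0)])
        p = ModelParameters(np.zeros((1, 1)), [np.array([1.0])])  # hazard 0.5
        assert ws.log_likelihood(p) == pytest.approx(-1.0)

    def test_single_interval_censoring(self):
        ws = LikelihoodWorkspace(single_subject("interval", 1.0, 2.0),
                                 [constant_hazard_basis(2.0)])
        p = ModelParameters(np.zeros((1, 1)), [np.array([2.0])])  # hazard 1
        expected = np.log(np.exp(-1.0) - np.exp(-2.0))
        assert ws.log_likelihood(p) == pytest.approx(expected, abs=1e-9)

    def test_single_left_censoring(self):
        ws = LikelihoodWorkspace(single_subject("left", 0.0, 1.0),
                                 [constant_hazard_basis(2.0)])
        p = ModelParameters(np.zeros((1, 1)), [np.array([2.0])])
        assert ws.log_likelihood(p) == pytest.approx(np.log(1 - np.exp(-1.0)), abs=1e-9)


class TestPenalizedObjective:
    def test_zero_lambda_equals_loglik(self, small_workspace, random_params):
        ws = small_workspace
        assert ws.penalized_objective(random_params, [0.0, 0.0]) == ws.log_likelihood(random_params)

    def test_penalty_gap_linear_in_lambda(self, small_workspace, random_params):
        ws = small_workspace
        ll = ws.log_likelihood(random_params)
        gap1 = ll - ws.penalized_objective(random_params, [1.0, 1.0])
        gap2 = ll - ws.penalized_objective(random_params, [2.0, 2.0])
        assert gap2 == pytest.approx(2.0 * gap1)

    def test_negative_lambda_rejected(self, small_workspace, random_params):
        with pytest.raises(ValueError):
            small_workspace.penalized_objective(random_params, [-1.0, 0.0])


class TestCIFGradients:
    @pytest.mark.parametrize("q", [0, 1])
    def test_derivatives_match_finite_differences(self, small_workspace, random_params, q):
        ws = small_workspace
        X = ws.data.X[5]
        t = np.array([0.6])
        A, B1, B2 = cif_gradients(random_params, ws.bases, q, t, X)
        eta0 = random_params.flatten()

        def f(eta):
            p = ModelParameters.unflatten(eta, ws.g, ws.p, ws.m)
            return cif(p, ws.bases, q, t, X)[0]

        fd = finite_difference_gradient(f, eta0)
        analytic = np.zeros_like(eta0)
        exb = np.exp(X @ random_params.beta.T)
        off = ws.theta_off
        for r in range(ws.g):
            analytic[off[r]:off[r + 1]] = ((q == r) * B1[r][0] - B2[r][0]) * exb[r]
            analytic[off[-1] + r * ws.p:off[-1] + (r + 1) * ws.p] = A[r][0] * X
        np.testing.assert_allclose(analytic, fd, atol=1e-6)

    def test_single_risk_constant_hazard_closed_form(self):
        """A_11(t) = int_0^t l e^{-l w}(1 - l w) dw = t l e^{-l t} for rate l."""
        lam = 0.8
        b = constant_hazard_basis(3.0)
        p = ModelParameters(np.zeros((1, 0)), [np.array([3.0 * lam])])
        for t in [0.5, 1.0, 2.0]:
            A, _, _ = cif_gradients(p, [b], 0, [t], np.zeros(0))
            assert A[0][0] == pytest.approx(t * lam * np.exp(-lam * t), abs=1e-10)


class TestScore:
    def test_matches_finite_differences_at_random_points(self, small_workspace, rng):
        ws = small_workspace
        lam = np.array([0.7, 0.3])
        for _ in range(3):
            params = ModelParameters(
                rng.normal(0, 0.3, (ws.g, ws.p)),
                [rng.uniform(0.2, 1.5, m) for m in ws.m],
            )
            analytic = ws.score(params, lam).flatten()
            fd = finite_difference_gradient(
                lambda eta: ws.penalized_objective(
                    ModelParameters.unflatten(eta, ws.g, ws.p, ws.m), lam),
                params.flatten(),
            )
            np.testing.assert_allclose(analytic, fd, rtol=1e-5, atol=1e-5)

    def test_per_subject_scores_sum_to_total(self, small_workspace, random_params):
        ws = small_workspace
        lam = np.array([0.4, 0.9])
        bundle = ws.score(random_params, lam, per_subject=True)
        np.testing.assert_allclose(
            bundle.per_subject.sum(axis=0), bundle.flatten(), atol=1e-10
        )

    def test_penalty_contribution_to_theta_block(self, small_workspace, random_params):
        ws = small_workspace
        g0 = ws.score(random_params, [0.0, 0.0])
        g1 = ws.score(random_params, [1.0, 0.0])
        diff = g0.grad_theta[0] - g1.grad_theta[0]
        np.testing.assert_allclose(diff, 2.0 * ws.penalties[0] @ random_params.theta[0])
        np.testing.assert_allclose(g0.grad_theta[1], g1.grad_theta[1])

    def test_beta_score_zero_at_exponential_mle(self):
        """All-event single-risk data: the analytic beta score vanishes at the
        MLE computed by an independent Newton iteration on the exponential
        regression likelihood."""
        rng = np.random.default_rng(8)
        n = 150
        x = rng.normal(size=n)
        beta_true = 0.7
        t = rng.exponential(1.0 / np.exp(beta_true * x))
        from cshmpl.data import CompetingRisksData

        data = CompetingRisksData(t, t, ["event"] * n, [1] * n, x[:, None], n_risks=1)
        b = constant_hazard_basis(float(t.max()))
        ws = LikelihoodWorkspace(data, [b])

        # oracle: Newton on (log rate a, beta) of the exponential model
        a, beta = 0.0, 0.0
        for _ in range(60):
            lam_i = np.exp(a + beta * x)
            ga = n - np.sum(lam_i * t)
            gb = np.sum(x) - np.sum(x * lam_i * t)
            Ha = -np.sum(lam_i * t)
            Hab = -np.sum(x * lam_i * t)
            Hb = -np.sum(x ** 2 * lam_i * t)
            step = np.linalg.solve([[Ha, Hab], [Hab, Hb]], [-ga, -gb])
            a, beta = a + step[0], beta + step[1]
        theta_hat = np.exp(a) * float(t.max())  # order-1 basis scale
        params = ModelParameters(np.array([[beta]]), [np.array([theta_hat])])
        bundle = ws.score(params, [0.0])
        assert abs(bundle.grad_beta[0, 0]) < 1e-6 * n
        assert abs(bundle.grad_theta[0][0]) < 1e-6 * n


class TestSeparability:
    def test_events_and_right_censoring_only_splits_by_risk(self):
        """With no left/interval censoring the log-likelihood is a sum of
        per-risk terms: zeroing the other risk's parameters changes the
        likelihood by a constant in this risk's parameters."""
        rng = np.random.default_rng(4)
        n = 80
        x = rng.normal(size=(n, 1))
        t = rng.exponential(0.5, size=n)
        risk = rng.integers(1, 3, size=n)
        status = np.where(rng.uniform(size=n) < 0.7, "event", "right")
        risk = np.where(status == "right", 0, risk)
        from cshmpl.data import CompetingRisksData

        data = CompetingRisksData(t, np.where(status == "right", np.inf, t),
                                  status, risk, x, n_risks=2, validate=False)
        b = constant_hazard_basis(float(t.max()))
        ws = LikelihoodWorkspace(data, [b, b])

        base = ModelParameters(np.array([[0.3], [-0.2]]),
                               [np.array([1.0]), np.array([0.8])])
        moved = base.copy()
        moved.theta[1] = np.array([1.7])
        moved.beta[1, 0] = 0.9
        # risk-1 block of the score is unchanged by risk-2 parameters
        s_base = ws.score(base, [0.0, 0.0])
        s_moved = ws.score(moved, [0.0, 0.0])
        np.testing.assert_allclose(s_base.grad_beta[0], s_moved.grad_beta[0], atol=1e-10)
        np.testing.assert_allclose(s_base.grad_theta[0], s_moved.grad_theta[0], atol=1e-10)
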