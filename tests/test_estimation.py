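"""Five-parameter Weibull-TVC likelihood, MLE and scenario diagnosis."""

import numpy as np
import pytest
from scipy import integrate

from survtvc import (
    SimulationConfig,
    SubjectRecord,
    diagnose_scenario,
    fit_weibull_tvc_mle,
    simulate_cohort,
    weibull_tvc_loglik,
)
from survtvc.estimate import EstimationError, WeibullTVCFit

TRUE = dict(alpha_E=1.5, lambda_E=0.005, alpha_TVC=0.5, lambda_TVC=0.05)


def quadrature_subject_loglik(params, s):
    """Independent oracle: integrate the piecewise hazard numerically."""
    a_e, l_e, a_t, l_t, beta = params
    t, d, tvc = s.followup_time, s.event_indicator, s.tvc_time

    def event_hazard(u):
        base = l_e * a_e * u ** (a_e - 1.0)
        if tvc is not None and u > tvc:
            base *= np.exp(beta)
        return base

    pts = [tvc] if tvc is not None and tvc < t else None
    cumhaz, _ = integrate.quad(event_hazard, 0.0, t, points=pts, limit=200)
    ll = -cumhaz + (np.log(event_hazard(t)) if d else 0.0)
    if tvc is not None:
        # density of the change time
        ll += (
            np.log(l_t) + np.log(a_t) + (a_t - 1.0) * np.log(tvc) - l_t * tvc**a_t
        )
    else:
        # survival of the change process past t, via its integrated hazard
        tvc_cumhaz, _ = integrate.quad(
            lambda u: l_t * a_t * u ** (a_t - 1.0), 0.0, t, limit=200
        )
        ll -= tvc_cumhaz
    return ll


class TestLoglik:
    def test_hand_nonchanger_censored(self):
        subj = [SubjectRecord("a", 10, 0)]
        assert weibull_tvc_loglik([1, 0.005, 1, 0.05, 0.3], subj) == pytest.approx(-0.55)

    def test_hand_nonchanger_event(self):
        subj = [SubjectRecord("a", 10, 1)]
        assert weibull_tvc_loglik([1, 0.005, 1, 0.05, 0.0], subj) == pytest.approx(
            -0.55 + np.log(0.005)
        )

    def test_beta_inert_without_changers(self):
        subj = [SubjectRecord("a", 10, 1), SubjectRecord("b", 4, 0)]
        base = weibull_tvc_loglik([1.2, 0.01, 0.8, 0.03, 0.0], subj)
        for beta in (-2.0, 1.0, 5.0):
            assert weibull_tvc_loglik([1.2, 0.01, 0.8, 0.03, beta], subj) == base

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(EstimationError, match="strictly positive"):
            weibull_tvc_loglik([0, 0.005, 1, 0.05, 0], [SubjectRecord("a", 1, 1)])

    def test_unnormalized_input_rejected(self):
        with pytest.raises(EstimationError, match="not normalized"):
            weibull_tvc_loglik([1, 0.01, 1, 0.01, 0], [SubjectRecord("a", 5, 1, 7.0)])

    def test_agrees_with_quadrature_oracle(self, rng):
        """The closed-form likelihood matches numerical integration of the
        hazard-based likelihood on random subjects."""
        params = [1.4, 0.01, 0.7, 0.04, 0.6]
        subjects = []
        for i in range(50):
            t = float(rng.uniform(0.5, 30))
            d = int(rng.random() < 0.6)
            tvc = float(rng.uniform(0.05, t * 0.95)) if rng.random() < 0.5 else None
            subjects.append(SubjectRecord(f"s{i}", t, d, tvc))
        closed = weibull_tvc_loglik(params, subjects)
        quad = sum(quadrature_subject_loglik(params, s) for s in subjects)
        assert closed == pytest.approx(quad, abs=1e-6)


class TestMLE:
    def cohort(self, n, seed, beta=np.log(2)):
        cfg = SimulationConfig(n=n, beta_TVC=float(beta), seed=seed, **TRUE)
        return simulate_cohort(cfg)

    def test_recovers_generating_parameters(self):
        fit = fit_weibull_tvc_mle(self.cohort(2000, seed=77), seed=0)
        assert fit.converged
        true = np.array([1.5, 0.005, 0.5, 0.05, np.log(2)])
        rel = np.abs(fit.params - true) / np.abs(true)
        assert np.all(rel < 0.25)

    def test_optimum_beats_truth_on_sample(self):
        cohort = self.cohort(800, seed=3)
        fit = fit_weibull_tvc_mle(cohort, seed=0)
        ll_true = weibull_tvc_loglik([1.5, 0.005, 0.5, 0.05, np.log(2)], cohort)
        assert fit.log_likelihood >= ll_true - 1e-6

    def test_no_changers_not_identifiable(self):
        subs = [SubjectRecord(f"s{i}", float(i + 1), 1) for i in range(10)]
        with pytest.raises(EstimationError, match="not identifiable"):
            fit_weibull_tvc_mle(subs)

    def test_no_events_errors(self):
        subs = [SubjectRecord("a", 3.0, 0, 1.0), SubjectRecord("b", 4.0, 0)]
        with pytest.raises(EstimationError, match="no events"):
            fit_weibull_tvc_mle(subs)

    def test_time_rescaling_equivariance(self):
        """t -> c*t leaves shapes and beta unchanged; rates scale by c^-alpha."""
        cohort = self.cohort(1500, seed=21)
        c = 30.0
        scaled = [
            SubjectRecord(
                s.subject_id,
                s.followup_time * c,
                s.event_indicator,
                None if s.tvc_time is None else s.tvc_time * c,
            )
            for s in cohort
        ]
        f1 = fit_weibull_tvc_mle(cohort, seed=0)
        f2 = fit_weibull_tvc_mle(scaled, seed=0)
        assert f2.alpha_E == pytest.approx(f1.alpha_E, rel=0.02)
        assert f2.alpha_TVC == pytest.approx(f1.alpha_TVC, rel=0.02)
        assert f2.beta == pytest.approx(f1.beta, abs=0.02)
        assert f2.lambda_E == pytest.approx(f1.lambda_E * c**-f1.alpha_E, rel=0.05)
        assert f2.lambda_TVC == pytest.approx(f1.lambda_TVC * c**-f1.alpha_TVC, rel=0.05)

    def test_errors_shrink_with_sample_size(self):
        """Mean absolute relative error at n=4000 does not exceed n=500."""
        true = np.array([1.5, 0.005, 0.5, 0.05, np.log(2)])

        def mean_err(n):
            errs = []
            for seed in range(5):
                fit = fit_weibull_tvc_mle(self.cohort(n, seed=500 + seed), seed=seed)
                errs.append(np.abs(fit.params - true) / np.abs(true))
            return np.mean(errs)

        assert mean_err(4000) <= mean_err(500)

    def test_event_profile_matches_censored_weibull_mle(self):
        """With no changers and beta inert, maximizing over the event-time
        parameters reproduces the standard censored-Weibull MLE (cross-checked
        against lifelines' independent parameterization)."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(123)
        n = 600
        t = (-np.log(rng.uniform(size=n)) / 0.02) ** (1 / 1.3)
        c = rng.uniform(2, 40, n)
        obs, ev = np.minimum(t, c), (t <= c).astype(int)
        subs = [SubjectRecord(f"s{i}", float(obs[i]), int(ev[i])) for i in range(n)]

        from scipy import optimize

        def negll(theta):
            a, l = np.exp(theta)
            return -weibull_tvc_loglik([a, l, 1.0, 1e-9, 0.0], subs)

        res = optimize.minimize(negll, [0.0, np.log(0.05)], method="Nelder-Mead")
        a_hat, l_hat = np.exp(res.x)
        wf = lifelines.WeibullFitter().fit(obs, ev)
        # lifelines: S(t) = exp(-(t/lambda)^rho)  ->  rate = scale^-shape
        assert a_hat == pytest.approx(wf.rho_, rel=1e-3)
        assert l_hat == pytest.approx(wf.lambda_ ** -wf.rho_, rel=1e-3)

    def test_tvc_time_zero_rejected(self):
        subs = [SubjectRecord("a", 5.0, 1, 0.0), SubjectRecord("b", 2.0, 1)]
        with pytest.raises(EstimationError, match="degenerate"):
            fit_weibull_tvc_mle(subs)


class TestDiagnose:
    def make_fit(self, a_tvc, a_e, converged=True):
        return WeibullTVCFit(
            alpha_E=a_e, lambda_E=0.005, alpha_TVC=a_tvc, lambda_TVC=0.05,
            beta=0.0, log_likelihood=-1.0, standard_errors=None,
            converged=converged, n_starts_used=5,
        )

    def test_early_tvc_late_events_minimal(self):
        assert "minimal naive bias" in diagnose_scenario(self.make_fit(0.4, 1.6))

    def test_late_tvc_early_events_large(self):
        verdict = diagnose_scenario(self.make_fit(1.6, 0.5))
        assert "large naive bias" in verdict
        assert "underestimates" in verdict

    def test_boundary_flagged_borderline(self):
        assert "borderline" in diagnose_scenario(self.make_fit(0.5, 1.5))

    def test_nonconverged_indeterminate(self):
        assert diagnose_scenario(self.make_fit(0.4, 1.6, converged=False)).startswith(
            "indeterminate"
        )
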