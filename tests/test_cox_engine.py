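"""Partial likelihood, Newton fit, Breslow hazard and the PH score test."""

import numpy as np
import pandas as pd
import pytest

from survtvc import (
    breslow_cumulative_hazard,
    cox_partial_loglik,
    fit_cox,
    make_naive_dataset,
    ph_score_test,
    SubjectRecord,
)
from survtvc.cox import CoxError

from conftest import tiny_cox_rows


def single_interval_rows(stop, event, x):
    return pd.DataFrame(
        {"id": np.arange(len(stop)), "start": 0.0, "stop": stop,
         "event": event, "x": x}
    )


def brute_force_loglik(rows: pd.DataFrame, betas: np.ndarray) -> np.ndarray:
    """Independent Breslow partial likelihood by risk-set enumeration."""
    betas = np.atleast_1d(betas).astype(float)
    ll = np.zeros_like(betas)
    for _, er in rows[rows["event"] == 1].iterrows():
        t = er["stop"]
        ll += betas * er["x"]
        at_risk = rows[(rows["start"] < t) & (t <= rows["stop"])]
        denom = np.exp(np.outer(betas, at_risk["x"].to_numpy())).sum(axis=1)
        ll -= np.log(denom)
    return ll


class TestPartialLoglik:
    def test_hand_breslow_tied_pair(self, toy_tied_rows):
        # both events at t=1, risk set of 2 each: ln(1/2 * 1/2)
        assert cox_partial_loglik(toy_tied_rows, 0.0, "breslow") == pytest.approx(
            np.log(0.25)
        )

    def test_beta_zero_reduces_to_risk_set_counts(self, rng):
        rows = single_interval_rows(
            stop=rng.uniform(1, 10, 12), event=np.ones(12, int),
            x=rng.integers(0, 2, 12),
        )
        order = np.sort(rows["stop"].to_numpy())[::-1]
        expected = -np.sum(np.log(np.arange(1, 13)))
        assert cox_partial_loglik(rows, 0.0) == pytest.approx(expected)

    def test_efron_equals_breslow_without_ties(self, rng):
        rows = single_interval_rows(
            stop=rng.uniform(1, 10, 20),
            event=rng.integers(0, 2, 20) | 1,
            x=rng.integers(0, 2, 20),
        )
        for beta in (-1.0, 0.3, 2.0):
            assert cox_partial_loglik(rows, beta, "efron") == pytest.approx(
                cox_partial_loglik(rows, beta, "breslow"), rel=1e-12
            )

    def test_matches_brute_force_on_tied_data(self, rng):
        for _ in range(10):
            rows = tiny_cox_rows(rng)
            if rows["event"].sum() == 0:
                continue
            for beta in (-0.8, 0.0, 1.2):
                assert cox_partial_loglik(rows, beta, "breslow") == pytest.approx(
                    float(brute_force_loglik(rows, np.array([beta]))[0]), abs=1e-10
                )

    def test_no_events_errors(self):
        rows = single_interval_rows(np.array([1.0, 2.0]), np.zeros(2, int), np.array([0, 1]))
        with pytest.raises(CoxError, match="no events"):
            cox_partial_loglik(rows, 0.0)


class TestFitCox:
    def test_symmetric_tied_toy_beta_zero(self, toy_tied_rows):
        fit = fit_cox(toy_tied_rows, tie_method="breslow")
        assert fit.beta == 0.0
        assert fit.converged

    def test_loglik_at_optimum_beats_null(self, rng):
        for _ in range(20):
            rows = tiny_cox_rows(rng)
            if rows["event"].sum() == 0 or rows["x"].nunique() < 2:
                continue
            try:
                with np.errstate(all="ignore"):
                    import warnings as _w

                    with _w.catch_warnings():
                        _w.simplefilter("ignore")
                        fit = fit_cox(rows, tie_method="breslow")
            except CoxError:
                continue
            assert fit.log_partial_likelihood >= cox_partial_loglik(
                rows, 0.0, "breslow"
            ) - 1e-12

    def test_matches_lifelines_beta_and_se(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 150
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / (0.1 * np.exp(0.6 * x)))
        c = rng.exponential(12, n)
        obs, ev = np.minimum(t, c), (t <= c).astype(int)
        fit = fit_cox(single_interval_rows(obs, ev, x))
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"T": obs, "E": ev, "x": x}), "T", "E"
        )
        assert fit.beta == pytest.approx(float(cph.params_.iloc[0]), abs=1e-5)
        assert fit.se == pytest.approx(float(cph.standard_errors_.iloc[0]), abs=1e-5)

    def test_monotone_likelihood_flagged(self):
        # all events in the exposed group while unexposed stay at risk
        rows = single_interval_rows(
            stop=np.array([1.0, 2.0, 3.0, 10.0, 10.0]),
            event=np.array([1, 1, 1, 0, 0]),
            x=np.array([1, 1, 1, 0, 0]),
        )
        with pytest.warns(UserWarning, match="converge"):
            fit = fit_cox(rows)
        assert not fit.converged

    def test_constant_covariate_errors(self):
        rows = single_interval_rows(np.array([1.0, 2.0]), np.array([1, 1]), np.array([1, 1]))
        with pytest.raises(CoxError, match="constant"):
            fit_cox(rows)

    def test_time_rescaling_leaves_beta_unchanged(self, rng):
        while True:
            rows = tiny_cox_rows(rng)
            if rows["event"].sum() < 2 or rows["x"].nunique() < 2:
                continue
            try:
                fit1 = fit_cox(rows, tie_method="breslow")
                break
            except CoxError:
                continue
        scaled = rows.assign(start=rows["start"] * 37.5, stop=rows["stop"] * 37.5)
        fit2 = fit_cox(scaled, tie_method="breslow")
        assert fit2.beta == pytest.approx(fit1.beta, abs=1e-8)

    def test_naive_fit_equals_split_interval_encoding(self, rng):
        """A time-fixed covariate gives the same beta whether each subject is
        one interval or is split at an arbitrary interior time."""
        subs = [
            SubjectRecord(f"s{i}", float(t), int(e), None if x == 0 else 0.0)
            for i, (t, e, x) in enumerate(
                zip(rng.uniform(1, 10, 40), rng.integers(0, 2, 40), rng.integers(0, 2, 40))
            )
        ]
        naive_rows = make_naive_dataset(subs).to_rows()
        fit1 = fit_cox(naive_rows)
        split = []
        for _, r in naive_rows.iterrows():
            mid = r["stop"] * 0.4
            split.append((r["id"], 0.0, mid, 0, r["x"]))
            split.append((r["id"], mid, r["stop"], r["event"], r["x"]))
        fit2 = fit_cox(pd.DataFrame(split, columns=["id", "start", "stop", "event", "x"]))
        assert fit2.beta == pytest.approx(fit1.beta, abs=1e-8)

    def test_ci_brackets_hr_and_p_in_unit_interval(self, rng):
        rows = single_interval_rows(
            rng.uniform(1, 10, 30), rng.integers(0, 2, 30) | 1, rng.integers(0, 2, 30)
        )
        fit = fit_cox(rows)
        lo, hi = fit.ci
        assert lo <= fit.hr <= hi
        assert 0 <= fit.p_value <= 1


class TestBreslowHazard:
    def test_hand_single_event(self):
        rows = single_interval_rows(np.array([1.0, 2.0]), np.array([1, 0]), np.array([0, 0]))
        # direct construction: beta = 0, both subjects at risk at t=1
        from survtvc.cox import CoxFit

        f0 = CoxFit(0.0, 1.0, 0.0, 2, 1, "breslow", True, 0)
        bh = breslow_cumulative_hazard(f0, rows)
        assert bh.at(1.0) == pytest.approx(0.5)
        assert bh.at(0.99) == 0.0

    def test_beta_zero_is_nelson_aalen(self, rng):
        from survtvc.cox import CoxFit

        n = 25
        rows = single_interval_rows(
            rng.uniform(1, 10, n), rng.integers(0, 2, n) | 1, rng.integers(0, 2, n)
        )
        f0 = CoxFit(0.0, 1.0, 0.0, n, int(rows["event"].sum()), "breslow", True, 0)
        bh = breslow_cumulative_hazard(f0, rows)
        # Nelson-Aalen by hand
        stops = rows["stop"].to_numpy()
        na = 0.0
        for t, h in zip(bh.event_times, bh.cumulative_hazard):
            d = int(((stops == t) & (rows["event"] == 1)).sum())
            na += d / int((stops >= t).sum())
            assert h == pytest.approx(na)

    def test_nondecreasing(self, rng):
        while True:
            rows = tiny_cox_rows(rng)
            if rows["event"].sum() == 0 or rows["x"].nunique() < 2:
                continue
            try:
                fit = fit_cox(rows, tie_method="breslow")
                break
            except CoxError:
                continue
        bh = breslow_cumulative_hazard(fit, rows)
        assert np.all(np.diff(bh.cumulative_hazard) >= 0)


class TestPHScoreTest:
    def test_statistic_nonnegative(self, rng):
        rows = single_interval_rows(
            rng.uniform(1, 10, 40), rng.integers(0, 2, 40) | 1, rng.integers(0, 2, 40)
        )
        fit = fit_cox(rows)
        stat, p = ph_score_test(fit, rows)
        assert stat >= 0
        assert 0 <= p <= 1

    def test_single_event_errors(self):
        rows = single_interval_rows(np.array([1.0, 2.0]), np.array([1, 0]), np.array([1, 0]))
        with pytest.warns(UserWarning):
            fit = fit_cox(rows)
        with pytest.raises(CoxError, match="2 events"):
            ph_score_test(fit, rows)

    def test_type_i_error_calibrated_under_ph(self):
        """Rejection rate at alpha=0.05 stays near nominal under proportional
        hazards (200 simulated cohorts of n=500)."""
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(200):
            n = 500
            x = rng.integers(0, 2, n)
            t = rng.exponential(1 / (0.08 * np.exp(0.5 * x)))
            c = rng.exponential(20, n)
            obs, ev = np.minimum(t, c), (t <= c).astype(int)
            rows = single_interval_rows(obs, ev, x)
            fit = fit_cox(rows)
            _, p = ph_score_test(fit, rows)
            rejections += p < 0.05
        assert 0.01 <= rejections / 200 <= 0.10
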