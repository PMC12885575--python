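"""Cox proportional hazards engine for counting-process data.

Fits the partial likelihood for a single covariate on ``(start, stop]``
interval data by Newton-Raphson, which subsumes the naive and landmark fits
(single-interval rows with a time-fixed covariate) and the time-dependent
(TD) Cox fit (multi-interval rows whose covariate switches 0 -> 1).

Risk-set membership at an event time ``t`` is ``start < t <= stop``,
consistent with the half-open interval convention of
:mod:`survtvc.data_model`.  Both the Efron and Breslow tie corrections are
available; Efron is the default (it is essentially exact for the light tie
patterns of continuous follow-up times), Breslow is simpler and is the one
used in hand-checked examples.

The Breslow baseline cumulative hazard and a score test of the proportional
hazards (PH) assumption against a linear-in-time interaction (scaled
Schoenfeld residuals, identity time transform) round out the engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoxFit",
    "BaselineHazard",
    "cox_partial_loglik",
    "fit_cox",
    "breslow_cumulative_hazard",
    "ph_score_test",
]


class CoxError(ValueError):
    """Raised when a Cox fit is not defined for the given data."""


@dataclass
class CoxFit:
    """Result of a single-covariate Cox partial-likelihood fit."""

    beta: float
    variance: float
    log_partial_likelihood: float
    n_subjects: int
    n_events: int
    tie_method: str
    converged: bool
    n_iter: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))

    @property
    def hr(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci(self) -> tuple[float, float]:
        """95% Wald confidence interval on the hazard-ratio scale."""
        if not np.isfinite(self.se):
            return float("nan"), float("nan")
        half = 1.959963984540054 * self.se
        with np.errstate(over="ignore"):
            return float(np.exp(self.beta - half)), float(np.exp(self.beta + half))

    @property
    def p_value(self) -> float:
        """Two-sided Wald p-value for beta = 0."""
        if self.se == 0 or not np.isfinite(self.se):
            return float("nan")
        z = self.beta / self.se
        return float(2.0 * stats.norm.sf(abs(z)))

    def summary(self) -> dict:
        lo, hi = self.ci
        return {
            "beta": self.beta,
            "se": self.se,
            "hr": self.hr,
            "ci_low": lo,
            "ci_high": hi,
            "p_value": self.p_value,
            "n_subjects": self.n_subjects,
            "n_events": self.n_events,
            "tie_method": self.tie_method,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


@dataclass
class BaselineHazard:
    """Step-function baseline cumulative hazard H0 at the event times.

    ``H0(t)`` is 0 before the first event time and constant between event
    times; :meth:`at` evaluates the step function.
    """

    event_times: np.ndarray
    cumulative_hazard: np.ndarray

    def at(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        padded = np.concatenate([[0.0], self.cumulative_hazard])
        out = padded[idx]
        return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# internal data preparation


def _as_arrays(rows, covariate: str | None = None):
    """Extract (start, stop, event, x, ids) arrays from a rows container.

    ``rows`` is a DataFrame with columns ``start, stop, event`` plus a
    covariate column (auto-detected among ``x``/``tvc`` unless named).
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    if covariate is None:
        for cand in ("x", "tvc", "x_fix", "x_landmark"):
            if cand in df.columns:
                covariate = cand
                break
        else:
            raise CoxError("no covariate column found (expected 'x' or 'tvc')")
    start = df["start"].to_numpy(float)
    stop = df["stop"].to_numpy(float)
    event = df["event"].to_numpy(float)
    x = df[covariate].to_numpy(float)
    if np.any(start >= stop):
        raise CoxError("invalid interval: start must be < stop for every row")
    ids = df["id"].to_numpy() if "id" in df.columns else np.arange(len(df))
    return start, stop, event, x, ids


class _PartialLikelihood:
    """Reusable structure for partial-likelihood evaluations.

    Risk-set sums at each death time are computed with suffix sums over
    stop- and start-sorted copies of the rows:
    ``sum over {start < t <= stop} = sum over {stop >= t} - sum over {start >= t}``.
    """

    def __init__(self, start, stop, event, x, tie_method: str):
        if tie_method not in ("efron", "breslow"):
            raise CoxError(f"unknown tie_method {tie_method!r}")
        self.tie_method = tie_method
        self.event_mask = event > 0
        self.n_events = int(self.event_mask.sum())
        if self.n_events == 0:
            raise CoxError("no events: partial likelihood undefined")
        self.x = x
        self.dtimes = stop[self.event_mask]  # one entry per death
        self.dx = x[self.event_mask]
        self.order_stop = np.argsort(stop, kind="stable")
        self.sorted_stop = stop[self.order_stop]
        self.order_start = np.argsort(start, kind="stable")
        self.sorted_start = start[self.order_start]
        # positions of each death time in the sorted arrays
        self.idx_stop = np.searchsorted(self.sorted_stop, self.dtimes, side="left")
        self.idx_start = np.searchsorted(self.sorted_start, self.dtimes, side="left")
        # tie groups (unique death times); only needed for Efron
        self.ut, self.inv, self.counts = np.unique(
            self.dtimes, return_inverse=True, return_counts=True
        )
        self.has_ties = bool(np.any(self.counts > 1))

    def _risk_sums(self, w):
        """S0, S1, S2 over the risk set at each death time (per death)."""
        xw = self.x * w
        x2w = self.x * xw

        def suffix(values, order, idx):
            s = np.concatenate([np.cumsum(values[order][::-1])[::-1], [0.0]])
            return s[idx]

        s0 = suffix(w, self.order_stop, self.idx_stop) - suffix(
            w, self.order_start, self.idx_start
        )
        s1 = suffix(xw, self.order_stop, self.idx_stop) - suffix(
            xw, self.order_start, self.idx_start
        )
        s2 = suffix(x2w, self.order_stop, self.idx_stop) - suffix(
            x2w, self.order_start, self.idx_start
        )
        return s0, s1, s2

    def loglik_score_info(self, beta: float):
        """Log partial likelihood, score and observed information at beta."""
        w = np.exp(beta * self.x)
        s0, s1, s2 = self._risk_sums(w)
        if self.tie_method == "breslow" or not self.has_ties:
            # per-death terms; exact Breslow, coincides with Efron when no ties
            m = s1 / s0
            ll = float(beta * self.dx.sum() - np.log(s0).sum())
            score = float(self.dx.sum() - m.sum())
            info = float((s2 / s0 - m * m).sum())
            return ll, score, info
        return self._efron_tied(beta, w, s0, s1, s2)

    def _efron_tied(self, beta, w, s0, s1, s2):
        dw = w[self.event_mask]
        dxw = self.dx * dw
        dx2w = self.dx * dxw
        # per-tie-group sums of risk and death quantities
        nbin = len(self.ut)
        g_s0 = np.zeros(nbin)
        g_s1 = np.zeros(nbin)
        g_s2 = np.zeros(nbin)
        # s0/s1/s2 are identical within a tie group; take first occurrence
        first = np.zeros(nbin, dtype=int)
        first[self.inv[::-1]] = np.arange(self.n_events - 1, -1, -1)
        g_s0, g_s1, g_s2 = s0[first], s1[first], s2[first]
        g_d0 = np.bincount(self.inv, weights=dw, minlength=nbin)
        g_d1 = np.bincount(self.inv, weights=dxw, minlength=nbin)
        g_d2 = np.bincount(self.inv, weights=dx2w, minlength=nbin)
        ll = float(beta * self.dx.sum())
        score = float(self.dx.sum())
        info = 0.0
        for k in range(nbin):
            d = int(self.counts[k])
            frac = np.arange(d) / d
            phi0 = g_s0[k] - frac * g_d0[k]
            phi1 = g_s1[k] - frac * g_d1[k]
            phi2 = g_s2[k] - frac * g_d2[k]
            ll -= float(np.log(phi0).sum())
            m = phi1 / phi0
            score -= float(m.sum())
            info += float((phi2 / phi0 - m * m).sum())
        return ll, score, info

    def schoenfeld(self, beta: float):
        """Per-death Schoenfeld residuals, risk-set variances and times."""
        w = np.exp(beta * self.x)
        s0, s1, s2 = self._risk_sums(w)
        m = s1 / s0
        v = s2 / s0 - m * m
        return self.dtimes, self.dx - m, v


def cox_partial_loglik(
    rows, beta: float, tie_method: str = "efron", covariate: str | None = None
) -> float:
    """Log partial likelihood of a single-covariate Cox model at ``beta``.

    Exposed as a pure function so the maximizer can be validated against
    brute-force evaluation.  The risk set at an event time ``t`` comprises
    the rows with ``start < t <= stop``.
    """
    start, stop, event, x, _ = _as_arrays(rows, covariate)
    pl = _PartialLikelihood(start, stop, event, x, tie_method)
    return pl.loglik_score_info(float(beta))[0]


def fit_cox(
    rows,
    tie_method: str = "efron",
    max_iter: int = 25,
    tol: float = 1e-9,
    covariate: str | None = None,
) -> CoxFit:
    """Newton-Raphson maximization of the Cox partial likelihood.

    Starts at ``beta = 0`` with step-halving whenever a step would decrease
    the likelihood.  The variance is the inverse observed information at the
    maximizer; Wald confidence limits and p-value derive from it.

    A monotone likelihood (e.g. all events in the exposed group while the
    unexposed group stays at risk) cannot converge: the fit is returned with
    ``converged=False`` and a warning rather than an exception, so the caller
    can surface the flag.

    Raises
    ------
    CoxError
        If there are no events or the covariate never varies.
    """
    start, stop, event, x, ids = _as_arrays(rows, covariate)
    if np.all(x == x[0]):
        raise CoxError("covariate is constant: log hazard ratio not identifiable")
    pl = _PartialLikelihood(start, stop, event, x, tie_method)

    beta = 0.0
    ll, score, info = pl.loglik_score_info(beta)
    if info <= 0.0:
        # within-risk-set variance of a binary covariate vanishes at beta=0
        # iff it vanishes everywhere: the partial likelihood is flat
        raise CoxError(
            "covariate is constant within every risk set: "
            "log hazard ratio not identifiable"
        )
    n_iter = 0
    converged = abs(score) <= tol
    for n_iter in range(1, max_iter + 1):
        if abs(score) <= tol:
            converged = True
            break
        step = score / info if info > 0 else np.sign(score)
        # step-halving: never accept a likelihood decrease
        for _ in range(30):
            cand = beta + step
            ll_new, score_new, info_new = pl.loglik_score_info(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if abs(score) <= tol:
            converged = True
            break
    # a maximizer walking beyond |beta| = 15 (HR beyond e^15) signals a
    # monotone or near-monotone likelihood: the data carry no finite MLE
    if abs(beta) > 15.0:
        converged = False
    if not converged:
        warnings.warn(
            "Cox fit did not converge (possible monotone likelihood); "
            "estimate reported with converged=False",
            stacklevel=2,
        )
    variance = 1.0 / info if info > 0 else float("inf")
    return CoxFit(
        beta=float(beta),
        variance=float(variance),
        log_partial_likelihood=float(ll),
        n_subjects=int(len(np.unique(ids))),
        n_events=pl.n_events,
        tie_method=tie_method,
        converged=bool(converged),
        n_iter=n_iter,
    )


def breslow_cumulative_hazard(fit: CoxFit, rows, covariate: str | None = None) -> BaselineHazard:
    """Breslow estimator of the baseline cumulative hazard.

    ``H0(t) = sum over event times t_k <= t of d_k / sum_{i at risk} exp(beta * x_i)``.
    At ``beta = 0`` this reduces to the Nelson-Aalen estimator of the pooled
    sample.
    """
    start, stop, event, x, _ = _as_arrays(rows, covariate)
    pl = _PartialLikelihood(start, stop, event, x, fit.tie_method)
    w = np.exp(fit.beta * x)
    s0, _, _ = pl._risk_sums(w)
    # one term per death; aggregate per unique time (d_k / S0 sums over ties)
    increments = np.bincount(pl.inv, weights=1.0 / s0, minlength=len(pl.ut))
    return BaselineHazard(
        event_times=pl.ut.copy(), cumulative_hazard=np.cumsum(increments)
    )


def ph_score_test(fit: CoxFit, rows, covariate: str | None = None) -> tuple[float, float]:
    """Score test of proportional hazards via scaled Schoenfeld residuals.

    Tests the coefficient of ``x * t`` (identity time transform) in the
    model augmented around the fitted ``beta``; the statistic is the
    1-degree-of-freedom chi-square score test evaluated at the restricted
    maximum, equivalent to a regression of the Schoenfeld residuals on time.

    Returns ``(statistic, p_value)``.  Requires at least two events.
    """
    start, stop, event, x, _ = _as_arrays(rows, covariate)
    pl = _PartialLikelihood(start, stop, event, x, fit.tie_method)
    if pl.n_events < 2:
        raise CoxError("proportional hazards test requires at least 2 events")
    g, resid, v = pl.schoenfeld(fit.beta)
    i_bb = float(v.sum())
    i_bt = float((g * v).sum())
    i_tt = float((g * g * v).sum())
    u = float((g * resid).sum())
    denom = i_tt - (i_bt * i_bt) / i_bb if i_bb > 0 else 0.0
    if denom <= 0:
        return 0.0, 1.0
    statistic = u * u / denom
    return float(statistic), float(stats.chi2.sf(statistic, df=1))
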