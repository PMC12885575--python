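"""Survival-curve constructions for a binary time-varying covariate.

Four curves are provided, matching the four analysis workflows:

* **naive KM** — product-limit curves by ever-changed status ``x_fix``
  (shown for comparison; biased, since changers are immortal before the
  change);
* **landmark KM** — product-limit curves on the residual-time scale after a
  landmark ``T*``, grouped by the TVC status at ``T*``;
* **Extended KM** — nonparametric curves whose group risk sets are updated
  dynamically as subjects' TVC status changes;
* **Smith-Zee** — model-based curves from the TD Cox fit for two
  hypothetical patients, one whose TVC never changes and one whose TVC
  changes at a prespecified ``t_change``; the curves coincide on
  ``[0, t_change]`` and split after.

All nonparametric curves carry Greenwood pointwise variance with a 95%
confidence interval on the log-survival scale, truncated to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cox import BaselineHazard, CoxFit
from .data_model import (
    SubjectRecord,
    default_landmark_times,
    make_landmark_dataset,
    make_naive_dataset,
)

__all__ = [
    "GroupCurve",
    "SurvivalCurve",
    "km_estimate",
    "extended_km",
    "smith_zee_curves",
    "naive_and_landmark_curves",
]

_Z = 1.959963984540054


@dataclass
class GroupCurve:
    """Step-function survival estimate for one group."""

    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_risk: np.ndarray | None = None
    variance: np.ndarray | None = None  # Greenwood pointwise variance of S


@dataclass
class SurvivalCurve:
    method: str  # naive_km | landmark_km | extended_km | smith_zee
    groups: dict[str, GroupCurve]
    origin_note: str = ""
    t_change: float | None = None

    def to_frame(self) -> pd.DataFrame:
        """One row per (group, time): method, group, time, survival, CI, n_risk."""
        frames = []
        for label, g in self.groups.items():
            n = len(g.times)
            frames.append(
                pd.DataFrame(
                    {
                        "method": self.method,
                        "group": label,
                        "time": g.times,
                        "survival": g.survival,
                        "ci_low": g.ci_low if g.ci_low is not None else np.nan,
                        "ci_high": g.ci_high if g.ci_high is not None else np.nan,
                        "n_risk": g.n_risk if g.n_risk is not None else np.nan,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _km_one_group(times: np.ndarray, events: np.ndarray) -> GroupCurve:
    """Product-limit estimate with Greenwood variance and log-scale CI."""
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    ut = np.unique(t)
    n_total = len(t)
    # at-risk and death counts at each unique observed time
    n_at = n_total - np.searchsorted(t, ut, side="left")
    d = np.array([int(e[t == u].sum()) for u in ut])
    keep = d > 0
    step_t, step_n, step_d = ut[keep], n_at[keep], d[keep]
    surv = np.cumprod(1.0 - step_d / step_n)
    # Greenwood variance of log S: cumulative d / (n (n - d)); the variance of
    # S itself is S^2 times this
    with np.errstate(divide="ignore", invalid="ignore"):
        varlog = np.cumsum(
            np.where(step_n > step_d, step_d / (step_n * (step_n - step_d)), np.inf)
        )
        selog = np.sqrt(varlog)
        logs = np.log(np.where(surv > 0, surv, np.nan))
        lo = np.exp(logs - _Z * selog)
        hi = np.exp(logs + _Z * selog)
    lo = np.clip(np.nan_to_num(lo, nan=0.0), 0.0, 1.0)
    hi = np.clip(np.nan_to_num(hi, nan=0.0), 0.0, 1.0)
    hi = np.where(surv > 0, hi, 0.0)
    with np.errstate(invalid="ignore"):
        var_s = np.nan_to_num(surv**2 * varlog, nan=0.0)  # 0 once S reaches 0
    times_out = np.concatenate([[0.0], step_t])
    return GroupCurve(
        times=times_out,
        survival=np.concatenate([[1.0], surv]),
        ci_low=np.concatenate([[1.0], lo]),
        ci_high=np.concatenate([[1.0], hi]),
        n_risk=np.concatenate([[n_total], step_n]),
        variance=np.concatenate([[0.0], var_s]),
    )


def km_estimate(
    times: Sequence[float],
    events: Sequence[int],
    group_labels: Sequence | None = None,
    method: str = "naive_km",
    origin_note: str = "",
) -> SurvivalCurve:
    """Kaplan-Meier curves, one per group.

    ``group_labels`` partitions the subjects; ``None`` fits a single pooled
    curve.  Empty groups are omitted with a warning.  Greenwood pointwise
    variance; 95% CI computed on the log-survival scale and truncated to
    [0, 1].
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times <= 0):
        raise ValueError("all times must be positive")
    if group_labels is None:
        group_labels = np.zeros(len(times), dtype=int)
        labels = {0: "all"}
    else:
        group_labels = np.asarray(group_labels)
        labels = {g: str(g) for g in np.unique(group_labels)}
        if len(labels) == 1:
            warnings.warn(
                f"only one group ({next(iter(labels.values()))!r}) present; "
                "the other group is empty and omitted",
                stacklevel=2,
            )
    groups: dict[str, GroupCurve] = {}
    for g, name in labels.items():
        mask = group_labels == g
        if not mask.any():
            warnings.warn(f"empty group {name!r} omitted from KM estimate", stacklevel=2)
            continue
        groups[name] = _km_one_group(times[mask], events[mask])
    return SurvivalCurve(method=method, groups=groups, origin_note=origin_note)


def extended_km(rows: pd.DataFrame) -> SurvivalCurve:
    """Extended Kaplan-Meier curves with dynamically updated risk sets.

    Operates on counting-process rows (columns ``start, stop, event, tvc``).
    At each event time ``t`` the group-``g`` risk set contains the subjects
    whose current interval ``(start, stop]`` covers ``t`` with
    ``tvc_value = g``; an event is attributed to the subject's group at the
    event time.  Each group's curve is the product over its own event times
    of ``1 - d_g/n_g``.

    The Greenwood-form variance uses the dynamic at-risk counts and is
    approximate, since group membership is time-varying.
    """
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    start = df["start"].to_numpy(float)
    stop = df["stop"].to_numpy(float)
    event = df["event"].to_numpy(int)
    tvc = df["tvc"].to_numpy(int)
    groups: dict[str, GroupCurve] = {}
    for g in (0, 1):
        gmask = tvc == g
        if not gmask.any():
            continue
        # this group's event times
        et = np.unique(stop[gmask & (event == 1)])
        n_at = np.array(
            [int(((start < t) & (t <= stop) & gmask).sum()) for t in et]
        )
        d = np.array(
            [int((gmask & (event == 1) & (stop == t)).sum()) for t in et]
        )
        surv = np.cumprod(1.0 - d / n_at) if len(et) else np.array([])
        with np.errstate(divide="ignore", invalid="ignore"):
            varlog = np.cumsum(
                np.where(n_at > d, d / (n_at * (n_at - d)), np.inf)
            )
            selog = np.sqrt(varlog)
            logs = np.log(np.where(surv > 0, surv, np.nan))
            lo = np.clip(np.nan_to_num(np.exp(logs - _Z * selog), nan=0.0), 0, 1)
            hi = np.clip(np.nan_to_num(np.exp(logs + _Z * selog), nan=0.0), 0, 1)
            var_s = np.nan_to_num(surv**2 * varlog, nan=0.0)
        n_risk0 = int(((start == 0) & gmask).sum())
        groups[str(g)] = GroupCurve(
            times=np.concatenate([[0.0], et]),
            survival=np.concatenate([[1.0], surv]),
            ci_low=np.concatenate([[1.0], lo]),
            ci_high=np.concatenate([[1.0], hi]),
            n_risk=np.concatenate([[n_risk0], n_at]),
            variance=np.concatenate([[0.0], var_s]),
        )
    return SurvivalCurve(method="extended_km", groups=groups)


def smith_zee_curves(
    fit: CoxFit, baseline: BaselineHazard, t_change: float
) -> SurvivalCurve:
    """Model-based curves for hypothetical patients from a TD Cox fit.

    The never-changer curve is ``S0(t) = exp(-H0(t))`` with ``H0`` the
    Breslow baseline cumulative hazard.  The curve of a patient whose TVC
    changes at ``t_change`` multiplies the hazard by ``exp(beta)`` from
    ``t_change`` on::

        S1(t) = exp(-[H0(min(t, t_change)) + exp(beta) * max(0, H0(t) - H0(t_change))])

    The two curves are identical on ``[0, t_change]`` and split after; with
    ``beta = 0`` they coincide everywhere.
    """
    if t_change <= 0:
        raise ValueError("t_change must be positive")
    last = baseline.event_times[-1] if len(baseline.event_times) else 0.0
    if t_change > last:
        warnings.warn(
            f"t_change={t_change} exceeds the last event time {last}; "
            "curves never split visibly",
            stacklevel=2,
        )
    times = np.unique(np.concatenate([[0.0], baseline.event_times, [t_change]]))
    h0 = baseline.at(times)
    h0c = float(baseline.at(t_change))
    s0 = np.exp(-h0)
    s1 = np.exp(-(np.minimum(h0, h0c) + np.exp(fit.beta) * np.maximum(0.0, h0 - h0c)))
    return SurvivalCurve(
        method="smith_zee",
        groups={
            "never": GroupCurve(times=times, survival=s0),
            "change_at_t": GroupCurve(times=times, survival=s1),
        },
        t_change=float(t_change),
        origin_note=f"hypothetical TVC change at t={t_change:g}",
    )


def naive_and_landmark_curves(
    subjects: Iterable[SubjectRecord],
    landmark_times: Sequence[float] | str = "auto",
) -> list[SurvivalCurve]:
    """Naive KM by ever-changed status plus landmark KM per landmark time.

    ``landmark_times="auto"`` uses the median and 0.95 quantile of the TVC
    change times.  The naive curve lives on the original time scale; each
    landmark curve lives on the residual-time scale with its origin recorded
    in ``origin_note``.
    """
    subjects = list(subjects)
    if landmark_times == "auto":
        landmark_times = default_landmark_times(subjects)
    naive = make_naive_dataset(subjects)
    curves = [
        km_estimate(
            naive.table["time"].to_numpy(float),
            naive.table["event"].to_numpy(int),
            naive.table["x_fix"].to_numpy(int),
            method="naive_km",
        )
    ]
    for t_star in landmark_times:
        lm = make_landmark_dataset(subjects, t_star)
        curves.append(
            km_estimate(
                lm.table["residual_time"].to_numpy(float),
                lm.table["event"].to_numpy(int),
                lm.table["x_landmark"].to_numpy(int),
                method="landmark_km",
                origin_note=f"time since landmark T*={t_star:g}",
            )
        )
    return curves
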