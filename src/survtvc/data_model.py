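"""Subject-level survival data with a single binary time-varying covariate.

A cohort is a collection of :class:`SubjectRecord` objects, one per subject,
holding the follow-up time, the event indicator and (optionally) the time at
which the binary time-varying covariate (TVC) switched from 0 to 1 — for
example the time a patient received a transplant after baseline.  From this
wide format the module derives the three datasets the analysis methods
require:

* the *naive* dataset, where ever-changed status ``x_fix`` is (incorrectly)
  treated as known at baseline;
* the *landmark* dataset at a chosen time ``T*``, restricted to subjects
  still at risk at ``T*`` and classified by their TVC status at ``T*``;
* the *counting-process* long format, one ``(start, stop]`` interval per
  constant covariate value, which feeds the time-dependent Cox model.

Conventions: intervals are half-open ``(start, stop]``; an event is
attributed to the interval containing it; exposure must strictly precede the
end of follow-up to count (a change recorded at or after the event/censoring
time is normalized to "never changed").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortValidationError",
    "SubjectRecord",
    "Cohort",
    "NaiveDataset",
    "LandmarkDataset",
    "normalize_subjects",
    "to_counting_process",
    "make_naive_dataset",
    "make_landmark_dataset",
    "default_landmark_times",
]


class CohortValidationError(ValueError):
    """Raised when subject-level input violates a cohort invariant."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject in wide format.

    Parameters
    ----------
    subject_id
        Unique identifier within the cohort.
    followup_time
        Time from origin to event or censoring (strictly positive; the unit
        is whatever the input uses — days, months — and is never converted).
    event_indicator
        1 if the event was observed at ``followup_time``, 0 if censored.
    tvc_time
        Time the TVC switched 0 -> 1, or ``None`` if it never switched during
        follow-up.  After normalization ``0 <= tvc_time < followup_time``.
    """

    subject_id: str
    followup_time: float
    event_indicator: int
    tvc_time: float | None = None

    @property
    def is_changer(self) -> bool:
        return self.tvc_time is not None


@dataclass
class Cohort:
    """A validated collection of subjects plus normalization bookkeeping."""

    subjects: list[SubjectRecord]
    n_tvc_normalized: int = 0  # tvc_time >= followup_time coerced to absent

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_events(self) -> int:
        return sum(s.event_indicator for s in self.subjects)

    @property
    def n_changers(self) -> int:
        return sum(s.is_changer for s in self.subjects)

    def summary(self) -> dict:
        n = len(self.subjects)
        tvc = [s.tvc_time for s in self.subjects if s.is_changer]
        return {
            "n": n,
            "n_events": self.n_events,
            "n_changers": self.n_changers,
            "pct_changers": 100.0 * self.n_changers / n if n else float("nan"),
            "median_tvc_time": float(np.median(tvc)) if tvc else None,
            "n_tvc_normalized": self.n_tvc_normalized,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.subject_id for s in self.subjects],
                "time": [s.followup_time for s in self.subjects],
                "status": [s.event_indicator for s in self.subjects],
                "tvc_time": [s.tvc_time for s in self.subjects],
            }
        )


@dataclass(frozen=True)
class NaiveDataset:
    """Ever-changed status treated as a baseline covariate (biased by design).

    ``table`` has one row per subject with columns
    ``subject_id, time, event, x_fix`` where ``x_fix = 1`` iff the TVC ever
    changed during follow-up.
    """

    table: pd.DataFrame

    def to_rows(self) -> pd.DataFrame:
        """Single-interval counting-process encoding (start = 0)."""
        return pd.DataFrame(
            {
                "id": self.table["subject_id"].to_numpy(),
                "start": 0.0,
                "stop": self.table["time"].to_numpy(float),
                "event": self.table["event"].to_numpy(int),
                "x": self.table["x_fix"].to_numpy(int),
            }
        )


@dataclass(frozen=True)
class LandmarkDataset:
    """Cohort re-based at a landmark time ``T*``.

    Subjects who fail or are censored at or before ``T*`` are excluded; the
    clock restarts at ``T*`` (``residual_time = followup_time - T*``) and the
    group ``x_landmark`` is the TVC status *at* ``T*``, frozen thereafter.
    """

    landmark_time: float
    table: pd.DataFrame  # subject_id, residual_time, event, x_landmark
    n_excluded: int

    def to_rows(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.table["subject_id"].to_numpy(),
                "start": 0.0,
                "stop": self.table["residual_time"].to_numpy(float),
                "event": self.table["event"].to_numpy(int),
                "x": self.table["x_landmark"].to_numpy(int),
            }
        )


DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "id": "id",
    "time": "time",
    "status": "status",
    "tvc": "tvc_time",
}


def normalize_subjects(
    raw_table: pd.DataFrame,
    column_map: Mapping[str, str] | None = None,
) -> Cohort:
    """Validate a raw subject table and return a normalized :class:`Cohort`.

    ``column_map`` maps the logical names ``id, time, status, tvc`` to the
    columns of ``raw_table`` (defaults: ``id, time, status, tvc_time``).
    An empty/NaN TVC entry means the covariate never changed.  A TVC change
    recorded at or after the end of follow-up cannot contribute exposed risk
    time and is normalized to absent, with a warning.

    Raises
    ------
    CohortValidationError
        On nonpositive follow-up time, event indicator outside {0, 1},
        negative TVC time, duplicate subject ids or a missing mapped column.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    for logical in ("id", "time", "status"):
        if cmap[logical] not in raw_table.columns:
            raise CohortValidationError(
                f"missing required column {cmap[logical]!r} (mapped from {logical!r})"
            )
    has_tvc = cmap["tvc"] in raw_table.columns

    ids = raw_table[cmap["id"]].astype(str).to_numpy()
    dup = pd.Series(ids).duplicated()
    if dup.any():
        raise CohortValidationError(
            f"duplicate subject_id: {ids[dup.to_numpy()][0]!r}"
        )

    subjects: list[SubjectRecord] = []
    n_normalized = 0
    for i, sid in enumerate(ids):
        row = raw_table.iloc[i]
        t = _as_float(row[cmap["time"]], sid, "followup time")
        if not np.isfinite(t) or t <= 0:
            raise CohortValidationError(
                f"subject {sid!r}: followup_time must be positive, got {t}"
            )
        status_raw = _as_float(row[cmap["status"]], sid, "event indicator")
        if status_raw not in (0.0, 1.0):
            raise CohortValidationError(
                f"subject {sid!r}: event_indicator must be 0 or 1, got {status_raw}"
            )
        tvc: float | None = None
        if has_tvc:
            raw = row[cmap["tvc"]]
            if raw is not None and not (isinstance(raw, str) and raw.strip() == "") and not pd.isna(raw):
                tvc = _as_float(raw, sid, "TVC change time")
                if tvc < 0:
                    raise CohortValidationError(
                        f"subject {sid!r}: tvc_time must be nonnegative, got {tvc}"
                    )
                if tvc >= t:
                    # change at/after end of follow-up is never observed as exposure
                    tvc = None
                    n_normalized += 1
        subjects.append(SubjectRecord(sid, t, int(status_raw), tvc))

    if n_normalized:
        warnings.warn(
            f"{n_normalized} subject(s) had tvc_time >= followup_time; "
            "normalized to 'never changed'",
            stacklevel=2,
        )
    return Cohort(subjects, n_tvc_normalized=n_normalized)


def _as_float(value, sid: str, what: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise CohortValidationError(
            f"subject {sid!r}: could not parse {what} {value!r} as a number"
        ) from exc


def to_counting_process(subjects: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Long-format ``(start, stop]`` intervals with a constant TVC value.

    Non-changers contribute one unexposed interval ``(0, followup]``;
    changers contribute ``(0, tvc_time]`` unexposed and
    ``(tvc_time, followup]`` exposed (a change at time 0 yields a single
    exposed interval).  The event flag sits on the final interval only.

    Returns a DataFrame with columns ``id, start, stop, event, tvc``.
    """
    ids: list[str] = []
    start: list[float] = []
    stop: list[float] = []
    event: list[int] = []
    tvc: list[int] = []
    for s in subjects:
        if s.tvc_time is None or s.tvc_time == 0:
            ids.append(s.subject_id)
            start.append(0.0)
            stop.append(s.followup_time)
            event.append(s.event_indicator)
            tvc.append(0 if s.tvc_time is None else 1)
        else:
            ids.extend([s.subject_id, s.subject_id])
            start.extend([0.0, s.tvc_time])
            stop.extend([s.tvc_time, s.followup_time])
            event.extend([0, s.event_indicator])
            tvc.extend([0, 1])
    return pd.DataFrame(
        {"id": ids, "start": start, "stop": stop, "event": event, "tvc": tvc}
    )


def make_naive_dataset(subjects: Iterable[SubjectRecord]) -> NaiveDataset:
    """Collapse each subject to ``x_fix = 1{TVC ever changed}``."""
    subjects = list(subjects)
    return NaiveDataset(
        pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in subjects],
                "time": [s.followup_time for s in subjects],
                "event": [s.event_indicator for s in subjects],
                "x_fix": [int(s.is_changer) for s in subjects],
            }
        )
    )


def make_landmark_dataset(
    subjects: Iterable[SubjectRecord], landmark_time: float
) -> LandmarkDataset:
    """Restrict to subjects at risk strictly beyond ``landmark_time``.

    Group membership is the TVC status at the landmark
    (``x_landmark = 1{tvc_time <= T*}``); later changes are ignored.  The
    residual clock starts at the landmark.

    Raises
    ------
    CohortValidationError
        If ``landmark_time <= 0`` or no subject survives the landmark.
    """
    if landmark_time <= 0:
        raise CohortValidationError("landmark_time must be positive")
    subjects = list(subjects)
    retained = [s for s in subjects if s.followup_time > landmark_time]
    if not retained:
        raise CohortValidationError(
            f"empty landmark cohort: no subject at risk beyond T*={landmark_time}"
        )
    table = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in retained],
            "residual_time": [s.followup_time - landmark_time for s in retained],
            "event": [s.event_indicator for s in retained],
            "x_landmark": [
                int(s.is_changer and s.tvc_time <= landmark_time) for s in retained
            ],
        }
    )
    return LandmarkDataset(
        landmark_time=float(landmark_time),
        table=table,
        n_excluded=len(subjects) - len(retained),
    )


def default_landmark_times(
    subjects: Iterable[SubjectRecord],
) -> tuple[float, float]:
    """Median and 0.95 quantile of the TVC change time among changers.

    Quantiles use linear interpolation between order statistics.  These are
    the conventional data-driven landmark choices: the median splits changers
    50/50, the 0.95 quantile places the landmark after nearly all changes.
    """
    tvc = np.asarray(
        [s.tvc_time for s in subjects if s.is_changer], dtype=float
    )
    if tvc.size == 0:
        raise CohortValidationError("no changers: landmark times undefined")
    med, q95 = np.quantile(tvc, [0.5, 0.95], method="linear")
    return float(med), float(q95)
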