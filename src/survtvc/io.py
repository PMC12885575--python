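"""CSV input/output for subject tables, reports and curves."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data_model import Cohort, CohortValidationError, SubjectRecord, normalize_subjects

__all__ = [
    "read_subject_table",
    "write_subject_table",
    "write_counting_process",
    "write_run_log",
]


def read_subject_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> Cohort:
    """Read a subject-level CSV and return a validated :class:`Cohort`.

    The file must have a header; logical columns ``id, time, status, tvc``
    are resolved through ``column_map`` (defaults ``id, time, status,
    tvc_time``).  An empty string or NA token in the TVC column means the
    covariate never changed.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise CohortValidationError(f"no records in {path}") from exc
    if raw.empty:
        raise CohortValidationError(f"no records in {path}")
    return normalize_subjects(raw, column_map)


def write_subject_table(subjects: Iterable[SubjectRecord], path: str | Path) -> Path:
    """Write subjects as CSV with columns ``id, time, status, tvc_time``.

    Round-trip stable with :func:`read_subject_table` for normalized
    cohorts: absent TVC times are written as empty fields.
    """
    path = Path(path)
    subjects = list(subjects)
    df = pd.DataFrame(
        {
            "id": [s.subject_id for s in subjects],
            "time": [s.followup_time for s in subjects],
            "status": [s.event_indicator for s in subjects],
            "tvc_time": [s.tvc_time for s in subjects],
        }
    )
    # no float_format: pandas writes shortest round-trip repr, so
    # write -> read reproduces the records exactly
    df.to_csv(path, index=False)
    return path


def write_counting_process(rows: pd.DataFrame, path: str | Path) -> Path:
    """Write long-format rows (columns ``id, start, stop, event, tvc``)."""
    path = Path(path)
    rows.to_csv(path, index=False)
    return path


def write_run_log(path: str | Path, **entries) -> Path:
    """Record versions, seed and configuration of a run as JSON."""
    from . import __version__

    path = Path(path)
    log = {
        "survtvc_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    log.update({k: _jsonable(v) for k, v in entries.items()})
    path.write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return path


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
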