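import numpy as np
import pandas as pd
import pytest

from survtvc import Cohort, SubjectRecord


@pytest.fixture
def toy_tied_rows():
    """Two subjects, both events at t=1, covariate 1 and 0."""
    return pd.DataFrame(
        {"id": [1, 2], "start": [0.0, 0.0], "stop": [1.0, 1.0],
         "event": [1, 1], "x": [1, 0]}
    )


def random_cohort(rng: np.random.Generator, n: int = 25) -> Cohort:
    """A small random cohort with a mix of changers, events and censoring."""
    subjects = []
    for i in range(n):
        t = float(rng.exponential(10.0)) + 1e-3
        event = int(rng.random() < 0.7)
        tvc = None
        if rng.random() < 0.5:
            cand = float(rng.uniform(0, t * 1.2))
            tvc = cand if cand < t else None
        subjects.append(SubjectRecord(f"s{i}", t, event, tvc))
    return Cohort(subjects)


def tiny_cox_rows(rng: np.random.Generator):
    """Counting-process rows for n <= 8 subjects, <= 2 intervals each,
    integer-ish times so tied event times occur."""
    n = int(rng.integers(3, 9))
    rows = []
    for i in range(n):
        stop = float(rng.integers(1, 7))
        event = int(rng.random() < 0.8)
        x = int(rng.random() < 0.5)
        if x and rng.random() < 0.5 and stop > 1:
            split = float(rng.integers(1, int(stop)))
            rows.append((i, 0.0, split, 0, 0))
            rows.append((i, split, stop, event, 1))
        else:
            rows.append((i, 0.0, stop, event, x))
    return pd.DataFrame(rows, columns=["id", "start", "stop", "event", "x"])


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
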