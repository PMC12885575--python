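"""Small deterministic cohorts for examples, demos and tests.

The two ``toy_*`` cohorts are the hand-checkable three-subject examples used
throughout the documentation.  The two ``cs_like_*`` cohorts are synthetic
stand-ins for the kinds of real cohorts this toolkit targets (which are not
public): ``cs_like_early_tvc`` emulates a trial where the covariate changes
early and events come late (naive and TD estimates roughly agree), while
``cs_like_late_tvc`` emulates a registry cohort where the covariate changes
late and events come early, the regime where the naive hazard ratio is
dragged far below the TD one by immortal-time bias.
"""

from __future__ import annotations

import numpy as np

from .data_model import Cohort, SubjectRecord
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["FIXTURE_NAMES", "make_fixture_cohort"]

FIXTURE_NAMES = ("toy_km", "toy_extended", "cs_like_early_tvc", "cs_like_late_tvc")

# stable per-fixture stream identifiers mixed into the seed
_FIXTURE_KEY = {name: i + 1 for i, name in enumerate(FIXTURE_NAMES)}


def make_fixture_cohort(name: str, seed: int = 0) -> Cohort:
    """Return a named deterministic cohort.

    ``toy_km``: three subjects, times (1, 2, 3), events (1, 1, 0), no TVC.
    ``toy_extended``: A (event at 3, change at 1), B (event at 2, no change),
    C (censored at 4, change at 2.5).
    ``cs_like_early_tvc``: simulated, early TVC / late events, protective
    effect (HR 0.5), administrative censoring.
    ``cs_like_late_tvc``: simulated, late TVC / early events, null effect.
    """
    if name == "toy_km":
        return Cohort(
            [
                SubjectRecord("t1", 1.0, 1),
                SubjectRecord("t2", 2.0, 1),
                SubjectRecord("t3", 3.0, 0),
            ]
        )
    if name == "toy_extended":
        return Cohort(
            [
                SubjectRecord("A", 3.0, 1, tvc_time=1.0),
                SubjectRecord("B", 2.0, 1),
                SubjectRecord("C", 4.0, 0, tvc_time=2.5),
            ]
        )
    if name in ("cs_like_early_tvc", "cs_like_late_tvc"):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(_FIXTURE_KEY[name],))
        )
        if name == "cs_like_early_tvc":
            cfg = SimulationConfig(
                n=300,
                alpha_E=1.5,
                alpha_TVC=0.5,
                beta_TVC=float(np.log(0.5)),
                censor_horizon=36.0,
            )
        else:
            # registry-like scale (months): events early, TVC change late
            cfg = SimulationConfig(
                n=400,
                alpha_E=0.5,
                lambda_E=0.15,
                alpha_TVC=1.5,
                lambda_TVC=0.002,
                beta_TVC=0.0,
                censor_horizon=60.0,
            )
        return simulate_cohort(cfg, rng=rng)
    raise ValueError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
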