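"""The 80-trial monetary incentive force (MIF) task.

The task has 2 blocks x 2 sessions x 20 trials.  Each session holds 15
action trials -- 5 at each incentive (CHF 0.2, 0.5, 1) in pseudorandom
order -- interleaved with 5 rest trials, one rest after every 3 action
trials.  The force threshold is 50% of the participant's maximal
voluntary contraction (MVC).

This module builds seeded task schedules, simulates trial-level outcomes
as independent Bernoulli draws from the model's success probabilities,
and summarises an outcome record into the 12 performance measures
(success rate per session x incentive cell; 5 trials per cell, so cell
values have granularity 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    INCENTIVES,
    N_SESSIONS,
    ModelParameters,
    PerformanceMatrix,
    predict_performance,
)

N_TRIALS = 80
TRIALS_PER_SESSION = 20
ACTION_PER_SESSION = 15
REST_PER_SESSION = 5
TRIALS_PER_CELL = 5  # action trials per incentive per session
MVC_FRACTION = 0.5  # force threshold as fraction of MVC


@dataclass(frozen=True)
class TrialRecord:
    """One MIF trial, possibly before its outcome is realised."""

    block: int
    session: int
    trial_index: int  # 1..80 over the whole task
    kind: str  # "action" | "rest"
    incentive: Optional[float] = None  # CHF; None for rest trials
    success: Optional[bool] = None  # None for rest / pre-outcome

    def __post_init__(self) -> None:
        if self.kind not in ("action", "rest"):
            raise ValueError(f"unknown trial kind {self.kind!r}")
        if self.kind == "rest" and self.incentive is not None:
            raise ValueError("rest trials carry no incentive")
        if self.kind == "action" and self.incentive not in INCENTIVES:
            raise ValueError(f"incentive must be one of {INCENTIVES}")


@dataclass(frozen=True)
class TaskSchedule:
    """An ordered 80-trial schedule (pre-outcome)."""

    trials: tuple
    mvc_fraction: float = MVC_FRACTION

    def __post_init__(self) -> None:
        if len(self.trials) != N_TRIALS:
            raise ValueError(f"schedule must have {N_TRIALS} trials")

    def to_frame(self) -> pd.DataFrame:
        """Schedule (or outcome record) as a tidy DataFrame."""
        return pd.DataFrame(
            {
                "block": [t.block for t in self.trials],
                "session": [t.session for t in self.trials],
                "trial_index": [t.trial_index for t in self.trials],
                "kind": [t.kind for t in self.trials],
                "incentive_chf": [t.incentive for t in self.trials],
                "success": [t.success for t in self.trials],
            }
        )


def build_schedule(seed: int) -> TaskSchedule:
    """Build a seeded 80-trial schedule.

    Each session is 5 repeating groups of [3 action, 1 rest]; the 15
    action-trial incentives are a uniform random permutation of five
    copies of each incentive level under the given seed.  Deterministic:
    the same seed always yields the same schedule.
    """
    rng = np.random.default_rng(seed)
    trials = []
    idx = 0
    for session in range(1, N_SESSIONS + 1):
        block = 1 if session <= 2 else 2
        labels = np.repeat(np.asarray(INCENTIVES), TRIALS_PER_CELL)
        labels = rng.permutation(labels)
        it = iter(labels)
        for _group in range(REST_PER_SESSION):
            for _ in range(3):
                idx += 1
                trials.append(
                    TrialRecord(block, session, idx, "action", float(next(it)))
                )
            idx += 1
            trials.append(TrialRecord(block, session, idx, "rest"))
    return TaskSchedule(tuple(trials))


def simulate_trials(
    params: ModelParameters, schedule: TaskSchedule, seed: int
) -> tuple:
    """Realise trial outcomes under the model.

    Each action trial succeeds independently with the model's predicted
    success probability at its (incentive, session) cell; rest trials
    have no outcome.  Reproducible given the seed.
    """
    pm = predict_performance(params).values
    inc_index = {x: i for i, x in enumerate(INCENTIVES)}
    rng = np.random.default_rng(seed)
    out = []
    for t in schedule.trials:
        if t.kind == "rest":
            out.append(t)
            continue
        p = pm[inc_index[t.incentive], t.session - 1]
        out.append(replace(t, success=bool(rng.random() < p)))
    return tuple(out)


def summarize(trials: Sequence[TrialRecord]) -> PerformanceMatrix:
    """Reduce a complete 80-trial outcome record to the 12 PMs.

    Each cell is the proportion of successes among its 5 action trials.
    Raises if the record is incomplete (wrong counts or missing
    outcomes).
    """
    if len(trials) != N_TRIALS:
        raise ValueError(f"expected a complete {N_TRIALS}-trial record")
    counts = np.zeros((len(INCENTIVES), N_SESSIONS), dtype=int)
    hits = np.zeros_like(counts)
    inc_index = {x: i for i, x in enumerate(INCENTIVES)}
    for t in trials:
        if t.kind == "rest":
            continue
        if t.success is None:
            raise ValueError("action trial without an outcome")
        i, s = inc_index[t.incentive], t.session - 1
        counts[i, s] += 1
        hits[i, s] += int(t.success)
    if not np.all(counts == TRIALS_PER_CELL):
        raise ValueError("record does not have 5 action trials per cell")
    return PerformanceMatrix(hits / counts)


def marginal_rates(trials: Sequence[TrialRecord]) -> dict:
    """Per-session and per-incentive marginal success rates + overall."""
    pm = summarize(trials).values
    return {
        "by_session": pm.mean(axis=0),
        "by_incentive": pm.mean(axis=1),
        "overall": float(pm.mean()),
    }


def trials_to_frame(trials: Sequence[TrialRecord], subject_id=None) -> pd.DataFrame:
    """Tidy per-trial table, optionally tagged with a subject id."""
    df = TaskSchedule(tuple(trials)).to_frame()
    if subject_id is not None:
        df.insert(0, "subject_id", subject_id)
    return df


def frame_to_trials(df: pd.DataFrame) -> tuple:
    """Inverse of :func:`trials_to_frame`; round-trips exactly."""
    out = []
    for row in df.itertuples(index=False):
        rest = row.kind == "rest"
        success = row.success
        if success is not None and not rest and not pd.isna(success):
            success = bool(success)
        else:
            success = None
        out.append(
            TrialRecord(
                int(row.block),
                int(row.session),
                int(row.trial_index),
                str(row.kind),
                None if rest or pd.isna(row.incentive_chf) else float(row.incentive_chf),
                success,
            )
        )
    return tuple(out)
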