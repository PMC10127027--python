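"""Behavioral indicators and phase labeling for the detour navigation task.

A session is a sequence of maze trials.  The animal first learns a preferred
start-to-goal route (acquisition); the route is then blocked, forcing
exploratory path adjustment, until a new route stabilizes (recovery).  The
two behavioral indicators are the trial duration (start gate to goal arrival)
and the walked path length; both are elevated during adjustment.

Route identity is tracked by the *path signature* — the ordered sequence of
maze pathlet (edge) ids crossed during the trial — rather than by trajectory
geometry, which jitters from trial to trial while gate sequences do not.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


class BehaviorError(ValueError):
    pass


@dataclass
class TrialRecord:
    """One maze trial: events, trajectory and route signature."""

    trial_id: int
    t_start_s: float
    t_goal_s: float | None  # goal-arrival time; None if goal never reached
    trajectory: np.ndarray  # (n, 3) columns t, x, y, time-ordered
    path_signature: tuple = ()
    phase: str | None = None
    correct: bool = True
    day_index: int = 0
    session_id: str = "sim"

    def __post_init__(self) -> None:
        self.trajectory = np.asarray(self.trajectory, dtype=float)
        if self.trajectory.size and self.trajectory.ndim != 2:
            raise BehaviorError("trajectory must be (n, 3): t, x, y")
        if self.trajectory.size and self.trajectory.shape[1] != 3:
            raise BehaviorError("trajectory must have columns t, x, y")
        if self.trajectory.shape[0] > 1:
            if not np.all(np.diff(self.trajectory[:, 0]) > 0):
                raise BehaviorError(
                    f"trial {self.trial_id}: trajectory timestamps must strictly increase"
                )


@dataclass
class BehaviorMetrics:
    trial_id: int
    phase: str | None
    duration_s: float
    path_length: float


def compute_duration(trial: TrialRecord) -> float:
    """Seconds from start-gate opening to goal arrival."""
    if trial.t_goal_s is None:
        raise BehaviorError(f"trial {trial.trial_id}: no goal-arrival event")
    if trial.t_goal_s <= trial.t_start_s:
        raise BehaviorError(
            f"trial {trial.trial_id}: goal arrival precedes trial start"
        )
    return float(trial.t_goal_s - trial.t_start_s)


def compute_path_length(trial: TrialRecord) -> float:
    """Summed Euclidean step distance along the trajectory, arena units."""
    xy = trial.trajectory[:, 1:3]
    if xy.shape[0] < 2:
        raise BehaviorError(
            f"trial {trial.trial_id}: need at least 2 trajectory points"
        )
    return float(np.sqrt((np.diff(xy, axis=0) ** 2).sum(axis=1)).sum())


def behavior_metrics(trial: TrialRecord) -> BehaviorMetrics:
    return BehaviorMetrics(
        trial_id=trial.trial_id,
        phase=trial.phase,
        duration_s=compute_duration(trial),
        path_length=compute_path_length(trial),
    )


def acquisition_complete(
    trials_by_day: Mapping[int, Sequence[TrialRecord]],
    preferred: tuple,
) -> bool:
    """Has the preferred route been acquired?

    True iff there exist two consecutive days on each of which *strictly more
    than* 90% of that day's trials follow ``preferred`` (exactly 90% does not
    qualify).
    """
    if len(trials_by_day) < 2:
        return False
    days = sorted(trials_by_day)
    frac = {}
    for day in days:
        trials = trials_by_day[day]
        if len(trials) == 0:
            raise BehaviorError(f"day {day} has zero trials")
        frac[day] = sum(t.path_signature == preferred for t in trials) / len(trials)
    return any(
        b == a + 1 and frac[a] > 0.9 and frac[b] > 0.9
        for a, b in zip(days, days[1:])
    )


def dominant_signature(trials: Sequence[TrialRecord]) -> tuple | None:
    """Most common path signature, ties broken by first appearance."""
    if not trials:
        return None
    counts = Counter(t.path_signature for t in trials)
    best = max(counts.values())
    for t in trials:
        if counts[t.path_signature] == best:
            return t.path_signature
    return None


def label_phases(
    session: Sequence[TrialRecord],
    blockade_trial: int,
    recovery_rule_k: int = 5,
) -> list[str]:
    """Assign acquisition / adjustment / recovery labels to a session.

    Trials before ``blockade_trial`` (a trial id) are acquisition.  Recovery
    starts at the first trial of the earliest run of ``recovery_rule_k``
    consecutive post-blockade trials sharing one *new* path signature
    (different from the pre-blockade dominant route) that is then used in at
    least 90% of the trials through session end.  Everything between the
    blockade and recovery onset is adjustment.  If no qualifying run exists,
    all post-blockade trials are labeled adjustment with a warning.
    """
    ids = [t.trial_id for t in session]
    if blockade_trial not in ids:
        raise BehaviorError(f"blockade trial {blockade_trial} not in session")
    b = ids.index(blockade_trial)
    if b == 0:
        warnings.warn("blockade at the first trial: session has no acquisition phase")
    preferred = dominant_signature(session[:b])
    post = session[b:]
    k = recovery_rule_k
    onset = None
    for i in range(len(post) - k + 1):
        sig = post[i].path_signature
        if sig == preferred:
            continue
        if any(post[i + j].path_signature != sig for j in range(1, k)):
            continue
        tail = post[i:]
        usage = sum(t.path_signature == sig for t in tail) / len(tail)
        if usage >= 0.9:
            onset = i
            break
    labels = ["acquisition"] * b
    if onset is None:
        warnings.warn(
            "no stable new route found after the blockade; labeling all "
            "post-blockade trials as adjustment"
        )
        labels += ["adjustment"] * len(post)
    else:
        if onset == 0:
            warnings.warn(
                "new route stable from the first post-blockade trial: "
                "adjustment phase is empty"
            )
        labels += ["adjustment"] * onset + ["recovery"] * (len(post) - onset)
    return labels
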