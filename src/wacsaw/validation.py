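"""Scoring predictions against activity logs, and rule-based log adjustment.

Validation is done on 1-second epochs.  Three percentages are reported,
following the convention that "sensitivity" refers to detecting sleep:

    accuracy          = correct seconds / log-covered seconds
    sleep sensitivity = correctly classified sleep / total logged sleep
    sleep specificity = correctly classified wake  / total logged wake

Participant logs record estimated rather than exact transition times, so an
adjusted variant snaps each logged transition to the nearest detected
change point within 20 minutes — the change points are precisely the
detector of "a sudden change in movement volatility" that a human adjuster
would look for.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import SLEEP, WAKE, StateSeries
from .errors import ValidationError
from .ingest import ActivityLog

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "log_to_series",
    "score_against_log",
    "adjust_log",
]


@dataclass
class ConfusionCounts:
    """Per-second confusion cells; ``uncovered`` counts seconds with no log label."""

    true_sleep: int
    false_sleep: int
    true_wake: int
    false_wake: int
    uncovered: int

    @property
    def covered(self) -> int:
        return self.true_sleep + self.false_sleep + self.true_wake + self.false_wake

    @property
    def total(self) -> int:
        return self.covered + self.uncovered


@dataclass
class MetricsReport:
    """Percentages in [0, 100]; a metric with an empty denominator is None."""

    accuracy: float | None
    sleep_sensitivity: float | None
    sleep_specificity: float | None


def log_to_series(log: ActivityLog, start_time, total_seconds: int) -> np.ndarray:
    """Per-second log labels aligned to ``start_time``; '' marks gaps."""
    states = np.full(total_seconds, "", dtype="<U5")
    for s, e, state in log.intervals:
        i = int(np.ceil((s - start_time).total_seconds()))
        j = int(np.floor((e - start_time).total_seconds()))
        i, j = max(i, 0), min(j, total_seconds)
        if j > i:
            states[i:j] = state
    return states


def score_against_log(pred: StateSeries, truth) -> tuple[MetricsReport, ConfusionCounts]:
    """Score per-second predictions against a log or a reference state series.

    Log gaps are excluded from every denominator.  Zero covered seconds is a
    validation error; a reference with no sleep (or no wake) leaves the
    corresponding metric as None rather than silently 0.
    """
    if isinstance(truth, ActivityLog):
        ref = log_to_series(truth, pred.start_time, len(pred))
    elif isinstance(truth, StateSeries):
        ref = truth.states
    else:
        ref = np.asarray(truth, dtype="<U5")
    n = min(len(pred), len(ref))
    if n == 0:
        raise ValidationError("prediction and reference do not overlap")
    p, r = pred.states[:n], ref[:n]
    covered = r != ""
    counts = ConfusionCounts(
        true_sleep=int(((p == SLEEP) & (r == SLEEP)).sum()),
        false_sleep=int(((p == SLEEP) & (r == WAKE)).sum()),
        true_wake=int(((p == WAKE) & (r == WAKE)).sum()),
        false_wake=int(((p == WAKE) & (r == SLEEP)).sum()),
        uncovered=int((~covered).sum()) + (len(pred) - n),
    )
    if counts.covered == 0:
        raise ValidationError("no log-covered seconds to score")
    n_sleep = counts.true_sleep + counts.false_wake
    n_wake = counts.true_wake + counts.false_sleep
    report = MetricsReport(
        accuracy=100.0 * (counts.true_sleep + counts.true_wake) / counts.covered,
        sleep_sensitivity=100.0 * counts.true_sleep / n_sleep if n_sleep else None,
        sleep_specificity=100.0 * counts.true_wake / n_wake if n_wake else None,
    )
    return report, counts


def adjust_log(
    log: ActivityLog,
    change_points,
    start_time,
    max_shift_seconds: int = 1200,
) -> ActivityLog:
    """Snap each logged transition to the nearest change point within 20 min.

    ``change_points`` are detector output in seconds from ``start_time``.
    A transition with no change point in range is kept as logged.  A snap
    that would reorder the log — cross a neighbouring (already adjusted)
    transition — is rejected, so intervals never overlap and the operation
    is idempotent (a transition already on a change point snaps to itself).
    """
    if not log.intervals or len(change_points) == 0:
        return ActivityLog(intervals=list(log.intervals))
    cps = np.asarray(sorted(change_points), dtype=float)

    # every unique interval endpoint is one transition; endpoints shared by
    # contiguous intervals must move together
    times = sorted({ts for s, e, _ in log.intervals for ts in (s, e)})
    adjusted: dict = {}
    prev = None
    for i, ts in enumerate(times):
        t = (ts - start_time).total_seconds()
        k = int(np.argmin(np.abs(cps - t)))
        new_ts = ts
        if abs(cps[k] - t) <= max_shift_seconds:
            candidate = start_time + pd.Timedelta(seconds=float(cps[k]))
            nxt = times[i + 1] if i + 1 < len(times) else None
            crosses = (prev is not None and candidate <= prev) or (
                nxt is not None and candidate >= nxt
            )
            if not crosses:
                new_ts = candidate
        adjusted[ts] = new_ts
        prev = new_ts
    return ActivityLog(
        intervals=[(adjusted[s], adjusted[e], state) for s, e, state in log.intervals]
    )
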