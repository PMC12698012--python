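"""Posture-change comparator in the style of GGIR's sedentary-bout detection.

This is a deliberately small mimic of the published posture-based process,
built for benchmarking, not a reimplementation of the full GGIR ecosystem.
The tilt angle is averaged over short epochs (5 s); a posture change is
recorded whenever the epoch mean drifts more than 5 degrees away from the
tilt at the last recorded change (reference-point detection, so slow drifts
accumulate into a change).  Posture changes closer together than the time
threshold (5 min) link into one active period and are labelled wake; spans
with no change for at least the threshold imply sedentary behaviour and are
labelled sleep.  The recording start and end act as virtual boundaries, and
the epoch containing each posture change is itself wake (a posture change
is, by definition, movement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import SLEEP, WAKE, StateSeries
from .errors import InputError
from .ingest import TiltSeries

__all__ = ["PostureChangeList", "posture_changes", "classify_ggir"]


@dataclass
class PostureChangeList:
    """Strictly increasing posture-change times (seconds from record start)."""

    change_times: np.ndarray
    angle_threshold_deg: float = 5.0
    epoch_seconds: float = 5.0

    def __len__(self) -> int:
        return len(self.change_times)


def posture_changes(
    tilt: TiltSeries, angle_threshold_deg: float = 5.0, epoch_seconds: float = 5.0
) -> PostureChangeList:
    """Detect posture changes on epoch-averaged tilt.

    The first epoch initialises the reference; epoch e triggers a change
    when |mean tilt(e) - tilt at the last change| exceeds the threshold,
    after which it becomes the new reference.
    """
    samples_per_epoch = int(round(epoch_seconds * tilt.rate_hz))
    n_epochs = len(tilt.theta) // samples_per_epoch
    if n_epochs < 2:
        raise InputError("recording must span at least two epochs")
    means = tilt.theta[: n_epochs * samples_per_epoch].reshape(n_epochs, -1).mean(axis=1)
    thr = np.deg2rad(angle_threshold_deg)
    ref = means[0]
    times = []
    for e in range(1, n_epochs):
        if abs(means[e] - ref) > thr:
            times.append(e * epoch_seconds)
            ref = means[e]
    return PostureChangeList(
        change_times=np.asarray(times, dtype=float),
        angle_threshold_deg=angle_threshold_deg,
        epoch_seconds=epoch_seconds,
    )


def classify_ggir(
    changes: PostureChangeList,
    total_seconds: int,
    time_threshold_seconds: int = 300,
    start_time=None,
) -> StateSeries:
    """Label every second sleep or wake from inter-change spacing.

    Gaps between consecutive posture changes (with the recording start and
    end as virtual boundaries) shorter than the time threshold are wake —
    the linked active period; gaps at least as long imply no significant
    posture change and are sleep.  The epoch of each change is wake.
    """
    states = np.full(total_seconds, "", dtype="<U5")
    bounds = [0.0] + [float(t) for t in changes.change_times] + [float(total_seconds)]
    for a, b in zip(bounds, bounds[1:]):
        i, j = int(np.floor(a)), min(int(np.ceil(b)), total_seconds)
        if j > i:
            states[i:j] = WAKE if (b - a) < time_threshold_seconds else SLEEP
    for t in changes.change_times:
        i = int(np.floor(t))
        j = min(int(np.floor(t + changes.epoch_seconds)), total_seconds)
        states[i:j] = WAKE
    if start_time is None:
        start_time = pd.Timestamp(0, unit="s", tz="UTC")
    return StateSeries(start_time=start_time, states=states, meta={"method": "ggir_mimic"})
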