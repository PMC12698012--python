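"""Reading accelerometer recordings and activity logs, and the tilt-angle transform.

A wrist-worn MEMS accelerometer reports the gravity component along three
orthogonal axes (units of g) at a fixed rate, 10 Hz by default.  The whole
downstream pipeline operates on a single derived signal: the tilt angle

    theta_t = arccos( z_t / sqrt(x_t^2 + y_t^2 + z_t^2) )

(the angle between the device z axis and gravity) and its first difference
dtheta_t = theta_t - theta_{t-1}, the "movement" signal.  Periods of sleep,
quiet wakefulness and active wakefulness differ in the volatility of dtheta,
not in its mean, which is what the segmentation stage exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, LogError, SamplingError

__all__ = [
    "AccelSeries",
    "TiltSeries",
    "FirstDiffSeries",
    "ActivityLog",
    "read_accel_csv",
    "compute_tilt",
    "first_difference",
    "read_activity_log",
]

DEFAULT_COLUMNS = {"time": "time", "x": "x", "y": "y", "z": "z"}


@dataclass
class AccelSeries:
    """Uniformly sampled tri-axial gravity-component record.

    Attributes
    ----------
    start_time : pd.Timestamp
        UTC instant of the first sample.  Sample ``i`` covers the half-open
        interval ``[start + i/rate, start + (i+1)/rate)``.
    rate_hz : float
        Sampling rate in samples per second (> 0).
    x, y, z : np.ndarray
        Equal-length per-axis gravity components in units of g.
    """

    start_time: pd.Timestamp
    rate_hz: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise InputError("axis sequences must have equal length")
        if self.rate_hz <= 0:
            raise InputError("rate_hz must be positive")
        if len(self.x) < 2:
            raise InputError("an accelerometer record needs at least 2 samples")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class TiltSeries:
    """Tilt-angle series in radians; every value lies in [0, pi]."""

    start_time: pd.Timestamp
    rate_hz: float
    theta: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)

    def __len__(self) -> int:
        return len(self.theta)


@dataclass
class FirstDiffSeries:
    """First difference of the tilt angle (signed radians).

    ``start_time`` is the instant of the *second* sample of the parent tilt
    series; the series is one sample shorter than its parent.
    """

    start_time: pd.Timestamp
    rate_hz: float
    dtheta: np.ndarray

    def __post_init__(self) -> None:
        self.dtheta = np.asarray(self.dtheta, dtype=float)

    def __len__(self) -> int:
        return len(self.dtheta)

    @property
    def n_seconds(self) -> int:
        """Whole seconds covered by the series (floor)."""
        return int(len(self.dtheta) // int(round(self.rate_hz)))


@dataclass
class ActivityLog:
    """Ordered, non-overlapping (start, end, state) intervals; gaps allowed.

    States are the strings ``"sleep"`` and ``"wake"``.
    """

    intervals: list  # list[tuple[pd.Timestamp, pd.Timestamp, str]]

    def __post_init__(self) -> None:
        iv = sorted(self.intervals, key=lambda r: r[0])
        for start, end, state in iv:
            if not start < end:
                raise LogError(f"interval start {start} not before end {end}")
            if state not in ("sleep", "wake"):
                raise FormatError(f"unknown state token: {state!r}")
        for (s0, e0, _), (s1, _, _) in zip(iv, iv[1:]):
            if s1 < e0:
                raise LogError(f"overlapping log intervals at {s1}")
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)


def _parse_times(raw: pd.Series) -> pd.Series:
    """Accept ISO-8601 strings or epoch seconds; return tz-aware UTC stamps."""
    if pd.api.types.is_numeric_dtype(raw):
        return pd.to_datetime(raw, unit="s", utc=True)
    try:
        return pd.to_datetime(raw, utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable timestamps: {exc}") from exc


def read_accel_csv(
    path,
    columns: dict | None = None,
    gap_policy: str = "strict",
) -> AccelSeries:
    """Read a delimited accelerometer export into an :class:`AccelSeries`.

    Parameters
    ----------
    path : path-like
        CSV file with a header row.
    columns : dict, optional
        Maps the logical names ``time``, ``x``, ``y``, ``z`` to column names
        in the file.  Defaults to the identity mapping.
    gap_policy : {"strict", "fill-hold"}
        ``strict`` rejects any inter-sample gap larger than twice the nominal
        sampling interval.  ``fill-hold`` fills such gaps by carrying the last
        sample forward, recording the count in ``meta["held_samples"]``.

    Raises
    ------
    FormatError
        Missing column or unparseable values.
    SamplingError
        Non-increasing timestamps, or a gap under the strict policy.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path}")
    times = _parse_times(df[colmap["time"]])
    tsec = times.astype("int64").to_numpy() / 1e9
    if len(tsec) < 2:
        raise FormatError("accelerometer file must contain at least 2 rows")
    dt = np.diff(tsec)
    if np.any(dt <= 0):
        raise SamplingError("timestamps must be strictly increasing")
    step = float(np.median(dt))
    rate = float(np.round(1.0 / step, 6))
    axes = [df[colmap[a]].to_numpy(dtype=float) for a in ("x", "y", "z")]
    gap = dt > 2.0 * step
    held = 0
    if np.any(gap):
        if gap_policy == "strict":
            i = int(np.argmax(gap))
            raise SamplingError(
                f"sampling gap of {dt[i]:.3f} s at row {i + 1} "
                f"(nominal interval {step:.3f} s); use gap_policy='fill-hold' to fill"
            )
        if gap_policy != "fill-hold":
            raise InputError(f"unknown gap policy: {gap_policy!r}")
        filled = [[], [], []]
        for i in range(len(tsec)):
            for k in range(3):
                filled[k].append(axes[k][i])
            if i < len(dt) and gap[i]:
                n_missing = int(round(dt[i] / step)) - 1
                held += n_missing
                for k in range(3):
                    filled[k].extend([axes[k][i]] * n_missing)
        axes = [np.asarray(a) for a in filled]
    return AccelSeries(
        start_time=times.iloc[0],
        rate_hz=rate,
        x=axes[0],
        y=axes[1],
        z=axes[2],
        meta={"held_samples": held},
    )


def compute_tilt(a: AccelSeries) -> TiltSeries:
    """Tilt angle of each sample: arccos of the normalised z component.

    Zero-norm samples (sensor dropouts) carry the previous angle forward (the
    first sample falls back to 0); the count is reported in
    ``meta["zero_norm_samples"]`` rather than aborting a multi-day run.
    The result is scale-invariant in (x, y, z) and always lies in [0, pi].
    """
    norm = np.sqrt(a.x**2 + a.y**2 + a.z**2)
    zero = norm == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(zero, np.nan, a.z / np.where(zero, 1.0, norm))
    theta = np.arccos(np.clip(cosang, -1.0, 1.0))
    if zero.any():
        theta[0] = 0.0 if zero[0] else theta[0]
        # forward-fill dropped samples
        idx = np.where(~np.isnan(theta), np.arange(len(theta)), 0)
        np.maximum.accumulate(idx, out=idx)
        theta = theta[idx]
    return TiltSeries(
        start_time=a.start_time,
        rate_hz=a.rate_hz,
        theta=theta,
        meta={"zero_norm_samples": int(zero.sum())},
    )


def first_difference(t: TiltSeries) -> FirstDiffSeries:
    """dtheta_t = theta_t - theta_{t-1}; output is one sample shorter."""
    if len(t) < 2:
        raise InputError("first_difference needs at least 2 samples")
    return FirstDiffSeries(
        start_time=t.start_time + pd.Timedelta(seconds=1.0 / t.rate_hz),
        rate_hz=t.rate_hz,
        dtheta=np.diff(t.theta),
    )


def read_activity_log(path) -> ActivityLog:
    """Read a start/end/state log file into an :class:`ActivityLog`.

    State tokens are matched case-insensitively; an empty file yields an
    empty (valid) log.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return ActivityLog(intervals=[])
    for col in ("start", "end", "state"):
        if col not in df.columns:
            raise FormatError(f"activity log missing column {col!r}")
    if len(df) == 0:
        return ActivityLog(intervals=[])
    starts = _parse_times(df["start"])
    ends = _parse_times(df["end"])
    states = df["state"].astype(str).str.strip().str.lower()
    bad = sorted(set(states) - {"sleep", "wake"})
    if bad:
        raise FormatError(f"unknown state token(s) in log: {bad}")
    intervals = list(zip(starts, ends, states))
    return ActivityLog(intervals=intervals)
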