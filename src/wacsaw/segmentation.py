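"""Change-point segmentation of the movement signal.

The segmentation stage turns the first-difference series into a per-second
change score, the Wasserstein Time Series (WTS): for each whole second t the
empirical 1-Wasserstein distance between the movement distribution of the
5 minutes before t and the 5 minutes after t.  For equal-size 1-d samples
this distance has a closed form, the mean gap between sorted values:

    W_p(x, z) = ( (1/n) sum_k |x_(k) - z_(k)|^p )^(1/p)

Seconds whose score exceeds an adaptive threshold (the Change Point
Threshold, an empirical quantile of the scores recomputed over disjoint
2-day blocks) form candidate regions; the peak of each region is a change
point.  The resulting fine partition is then coarsened: segments shorter
than 3 s are concatenated to their predecessor, and adjacent segments whose
movement variances are statistically indistinguishable under a
Brown-Forsythe (median-centred Levene) test at alpha = 1e-25 are merged.
The extraordinarily small alpha requires evaluating F-distribution tail
probabilities far below double-precision underflow, which is done in
arbitrary-precision arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import mpmath as mp
import numpy as np

from .errors import InputError
from .ingest import FirstDiffSeries

__all__ = [
    "WassersteinSeries",
    "CptSchedule",
    "Segment",
    "SegmentationResult",
    "empirical_wasserstein",
    "wasserstein_time_series",
    "compute_cpt",
    "detect_change_points",
    "initial_segments",
    "merge_short_segments",
    "levene_filter",
    "levene_pvalue",
    "merge_by_levene",
    "segment_recording",
]


@dataclass
class WassersteinSeries:
    """Per-second change scores with a validity mask.

    ``valid_mask`` is False wherever a full backward *and* forward window is
    unavailable (the first and last ``window_seconds`` of the recording);
    scores there are 0 and must be ignored.
    """

    scores: np.ndarray
    valid_mask: np.ndarray
    window_seconds: int = 300
    order_p: float = 1.0

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class CptSchedule:
    """One change-point threshold per disjoint block of the recording."""

    block_seconds: int
    thresholds: np.ndarray
    quantile_q: float

    def threshold_at(self, second: int) -> float:
        """Threshold of the block containing ``second``."""
        return float(self.thresholds[min(second // self.block_seconds, len(self.thresholds) - 1)])


@dataclass(frozen=True)
class Segment:
    """Half-open range of whole seconds, [start_s, end_s)."""

    start_s: int
    end_s: int

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise InputError(f"empty segment [{self.start_s}, {self.end_s})")

    @property
    def seconds(self) -> int:
        return self.end_s - self.start_s

    def sample_range(self, rate_hz: float) -> tuple[int, int]:
        """Corresponding half-open index range into the first-difference series."""
        r = int(round(rate_hz))
        return self.start_s * r, self.end_s * r

    def values(self, fd: FirstDiffSeries) -> np.ndarray:
        i, j = self.sample_range(fd.rate_hz)
        return fd.dtheta[i:j]


@dataclass
class SegmentationResult:
    """Final partition of [0, total seconds) plus the evidence behind it."""

    segments: list
    change_points: list
    cpt: CptSchedule
    wts: WassersteinSeries | None = None
    meta: dict = field(default_factory=dict)

    @property
    def total_seconds(self) -> int:
        return self.segments[-1].end_s


def empirical_wasserstein(x, z, p: float = 1.0) -> float:
    """Empirical p-Wasserstein distance between two equal-size 1-d samples.

    Both samples are sorted ascending and coupled by rank (the optimal
    monotone coupling); the distance is the p-power mean of the rank-wise
    gaps to the 1/p.  Inputs are not mutated.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape or x.ndim != 1 or len(x) < 1:
        raise InputError("samples must be equal-length non-empty 1-d sequences")
    gaps = np.abs(np.sort(x) - np.sort(z))
    if p == 1.0:
        return float(gaps.mean())
    return float((gaps**p).mean() ** (1.0 / p))


def wasserstein_time_series(
    fd: FirstDiffSeries, window_seconds: int = 300, p: float = 1.0
) -> WassersteinSeries:
    """Per-second change score: sorted-coupling distance of +-window movement.

    For each whole second t with a full 5-minute window on both sides,
    ``score[t] = W_p(dtheta over [t - w, t), dtheta over [t, t + w))``; the
    point-of-interest second belongs to the forward window.  Sorted windows
    are kept in a rolling buffer so each window is sorted exactly once.
    """
    rate = int(round(fd.rate_hz))
    nsec = fd.n_seconds
    if nsec < 2 * window_seconds:
        raise InputError(
            f"recording of {nsec} s is shorter than two windows ({2 * window_seconds} s)"
        )
    w = window_seconds
    wn = w * rate
    values = fd.dtheta
    scores = np.zeros(nsec)
    valid = np.zeros(nsec, dtype=bool)
    buf: dict[int, np.ndarray] = {}
    inv_p = None if p == 1.0 else 1.0 / p
    # window starting at second s spans samples [s*rate, s*rate + wn)
    for s in range(0, nsec - w + 1):
        win = np.sort(values[s * rate : s * rate + wn])
        buf[s] = win
        t = s  # score at second t needs windows starting at t - w and t
        if t >= w:
            gaps = np.abs(buf[t - w] - win)
            scores[t] = gaps.mean() if inv_p is None else (gaps**p).mean() ** inv_p
            del buf[t - w]
    valid[w : nsec - w + 1] = True
    return WassersteinSeries(scores=scores, valid_mask=valid, window_seconds=w, order_p=p)


def _quantile(values: np.ndarray, q: float) -> float:
    # linear interpolation between order statistics (numpy's default rule),
    # fixed here so documented examples are reproducible
    return float(np.quantile(values, q))


def compute_cpt(
    wts: WassersteinSeries, block_seconds: int = 172800, quantile_q: float = 0.95
) -> CptSchedule:
    """Adaptive per-block threshold: an empirical quantile of valid scores.

    The threshold is recomputed over disjoint blocks (2 days by default) so
    it tracks slow changes in an individual's movement profile; a trailing
    partial block gets its own threshold.  A block with no valid scores
    inherits its predecessor's threshold (the first such block falls back to
    the global quantile).
    """
    if not wts.valid_mask.any():
        raise InputError("Wasserstein series has no valid scores")
    nsec = len(wts)
    n_blocks = max(1, math.ceil(nsec / block_seconds))
    global_thr = _quantile(wts.scores[wts.valid_mask], quantile_q)
    thresholds = np.empty(n_blocks)
    for b in range(n_blocks):
        lo, hi = b * block_seconds, min((b + 1) * block_seconds, nsec)
        mask = wts.valid_mask[lo:hi]
        if mask.any():
            thresholds[b] = _quantile(wts.scores[lo:hi][mask], quantile_q)
        else:
            thresholds[b] = thresholds[b - 1] if b > 0 else global_thr
    return CptSchedule(block_seconds=block_seconds, thresholds=thresholds, quantile_q=quantile_q)


def detect_change_points(wts: WassersteinSeries, cpt: CptSchedule) -> list:
    """Peak second of every contiguous supra-threshold run of valid scores.

    A region spanning a block boundary is judged against the threshold of
    the block containing the region's start.  Ties in the peak go to the
    earliest second (determinism).
    """
    nsec = len(wts)
    change_points = []
    t = 0
    while t < nsec:
        if wts.valid_mask[t] and wts.scores[t] > cpt.threshold_at(t):
            thr = cpt.threshold_at(t)
            start = t
            while t < nsec and wts.valid_mask[t] and wts.scores[t] > thr:
                t += 1
            region = wts.scores[start:t]
            change_points.append(start + int(np.argmax(region)))
        else:
            t += 1
    return change_points


def initial_segments(change_points, total_seconds: int) -> list:
    """Cut [0, total_seconds) at each change point."""
    bounds = [0] + list(change_points) + [total_seconds]
    for a, b in zip(bounds, bounds[1:]):
        if not a <= b:
            raise InputError("change points must be strictly increasing and in range")
    if change_points and not (0 < change_points[0] and change_points[-1] < total_seconds):
        raise InputError("change points must lie strictly inside (0, total_seconds)")
    return [Segment(a, b) for a, b in zip(bounds, bounds[1:]) if b > a]


def merge_short_segments(segments, min_seconds: int = 3) -> list:
    """Concatenate every segment shorter than ``min_seconds`` to its predecessor.

    A short first segment is absorbed into its successor instead.
    """
    out: list[Segment] = []
    for seg in segments:
        if seg.seconds < min_seconds and out:
            out[-1] = Segment(out[-1].start_s, seg.end_s)
        elif out and out[-1].seconds < min_seconds:
            # first segment was short: absorb into this one
            out[-1] = Segment(out[-1].start_s, seg.end_s)
        else:
            out.append(seg)
    return out


def levene_filter(values, segment_seconds: float, long_seconds: float = 30.0) -> np.ndarray:
    """Outlier filtration applied to long segments before the variance test.

    Long segments (> ``long_seconds``) accumulate movement artifacts, so the
    largest 25% of |dtheta| are dropped and the remainder is further trimmed
    to within one standard deviation of its mean.  Segments of 3-30 s carry
    too little data for this to be meaningful and pass through as plain
    absolute values.  If the +-1 SD trim would empty the sample, the
    pre-trim set is returned instead.
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        raise InputError("levene_filter requires a non-empty sample")
    a = np.abs(values)
    if segment_seconds <= long_seconds:
        return a
    n = len(a)
    k = int(0.25 * n)
    if k > 0:
        a = np.partition(a, n - k - 1)[: n - k]
    m = a.mean()
    s = a.std(ddof=1) if len(a) > 1 else 0.0
    kept = a[(a >= m - s) & (a <= m + s)]
    return kept if len(kept) else a


def levene_pvalue(a, b) -> tuple[float, float]:
    """Two-group Brown-Forsythe test, with an arbitrary-precision tail.

    Absolute deviations from each group's median enter a one-way F test
    (df 1, n_a + n_b - 2).  The upper-tail probability is evaluated through
    the regularised incomplete beta function at 50 significant digits, so
    p-values far below 1e-25 are resolved exactly rather than underflowing.

    Returns
    -------
    (p, log10_p) : tuple of float
        ``p`` may underflow to 0.0 below ~1e-308; ``log10_p`` never does.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs at least 2 values")
    za = np.abs(a - np.median(a))
    zb = np.abs(b - np.median(b))
    na, nb = len(za), len(zb)
    ma, mb = za.mean(), zb.mean()
    grand = (na * ma + nb * mb) / (na + nb)
    ss_between = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ss_within = ((za - ma) ** 2).sum() + ((zb - mb) ** 2).sum()
    df2 = na + nb - 2
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 1.0, 0.0  # no spread anywhere: F = 0
        return 0.0, float("-inf")
    f_stat = df2 * ss_between / ss_within
    if f_stat <= 0.0:
        return 1.0, 0.0
    # survival function of F(1, df2) via the regularised incomplete beta
    x = df2 / (df2 + f_stat)
    with mp.workdps(50):
        p = mp.betainc(df2 / 2.0, 0.5, 0, x, regularized=True)
        log10p = mp.log10(p) if p > 0 else mp.mpf("-inf")
        return float(p), float(log10p)


def _merge_test_values(seg_a: Segment, seg_b: Segment, fd: FirstDiffSeries, long_seconds: float):
    """Filtered |dtheta| samples for a pairwise Levene comparison.

    Outlier filtration is applied only when *both* segments exceed the
    long-segment cutoff; comparing a filtered side against an unfiltered one
    would manufacture a variance difference out of the filtration itself.
    """
    both_long = seg_a.seconds > long_seconds and seg_b.seconds > long_seconds
    if both_long:
        return (
            levene_filter(seg_a.values(fd), seg_a.seconds, long_seconds),
            levene_filter(seg_b.values(fd), seg_b.seconds, long_seconds),
        )
    return np.abs(seg_a.values(fd)), np.abs(seg_b.values(fd))


def merge_by_levene(
    segments,
    fd: FirstDiffSeries,
    alpha: float = 1e-25,
    long_seconds: float = 30.0,
) -> list:
    """Merge adjacent variance-homogeneous segments, left to right.

    For each segment in turn: if it is not significantly different from its
    (possibly already merged) predecessor it is merged into it; otherwise it
    is tested against its successor and merged forward on a non-significant
    result; otherwise it stands alone.  Merged segments re-enter subsequent
    comparisons as a unit.  Comparisons are done in log10 space against
    log10(alpha) to avoid any dependence on linear-scale underflow.
    """
    if len(segments) <= 1:
        return list(segments)
    log_alpha = math.log10(alpha)

    def differs(sa: Segment, sb: Segment) -> bool:
        va, vb = _merge_test_values(sa, sb, fd, long_seconds)
        _, log10p = levene_pvalue(va, vb)
        return log10p < log_alpha

    out = [segments[0]]
    i = 1
    while i < len(segments):
        cur = segments[i]
        if not differs(out[-1], cur):
            out[-1] = Segment(out[-1].start_s, cur.end_s)
            i += 1
        elif i + 1 < len(segments) and not differs(cur, segments[i + 1]):
            out.append(Segment(cur.start_s, segments[i + 1].end_s))
            i += 2
        else:
            out.append(cur)
            i += 1
    return out


def segment_recording(
    fd: FirstDiffSeries,
    window_seconds: int = 300,
    order_p: float = 1.0,
    cpt_block_seconds: int = 172800,
    cpt_quantile: float = 0.95,
    min_segment_seconds: int = 3,
    levene_alpha: float = 1e-25,
    levene_long_seconds: float = 30.0,
) -> SegmentationResult:
    """Run the full segmentation stage and return the final partition."""
    wts = wasserstein_time_series(fd, window_seconds, order_p)
    cpt = compute_cpt(wts, cpt_block_seconds, cpt_quantile)
    change_points = detect_change_points(wts, cpt)
    segs = initial_segments(change_points, fd.n_seconds)
    n_initial = len(segs)
    segs = merge_short_segments(segs, min_segment_seconds)
    segs = merge_by_levene(segs, fd, levene_alpha, levene_long_seconds)
    return SegmentationResult(
        segments=segs,
        change_points=change_points,
        cpt=cpt,
        wts=wts,
        meta={"n_initial_segments": n_initial, "n_final_segments": len(segs)},
    )
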