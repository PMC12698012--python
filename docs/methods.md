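# Methods

This note documents the model behind the package, the parameters that
matter, the synthetic world the tests run in, and the choices made where the
procedure was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Signal model

The classifier assumes that behavioural state modulates the *volatility* of
wrist movement, not its mean. The working signal is the first difference
Δθ_t of the tilt angle, sampled at 10 Hz. Within a behavioural state Δθ is
treated as (approximately) exchangeable draws from a state-specific,
zero-centred, heavy-tailed distribution; a change of behaviour is a change
of that distribution. Nothing downstream uses temporal ordering within a
window — every statistic (Wasserstein score, variance test, transport
energy, characteristic curve) is a functional of window- or segment-level
*marginal* distributions. That is what makes the method robust to the exact
dependence structure of real movement, and also what the synthetic
generator must reproduce faithfully.

Degenerate inputs are handled by contract rather than by failure:
zero-norm accelerometer samples inherit the previous tilt angle (counted
and reported), an all-zero recording yields a single segment labelled
sleep, and sampling gaps abort a run unless `fill-hold` is requested.

## Segmentation

* **Wasserstein score.** For equal-size one-dimensional samples the
  p-Wasserstein distance reduces to the rank-wise coupling of sorted
  values; sorting is applied to the *signed* first differences (the
  standard quantile coupling). Order p = 1 (default, configurable):
  lower orders emphasise the subtle distributional differences that
  separate quiet wakefulness from sleep.
* **Window.** 300 s on each side of the point of interest; the
  point-of-interest second belongs to the forward window. Seconds without
  a full window on both sides are invalid and are absorbed by the first and
  last segments. One score per whole second keeps the series aligned to
  the 1 s epoch grid of validation.
* **Change Point Threshold (CPT).** The published procedure does not fix a
  functional form for the threshold; this implementation uses the
  empirical quantile (default
  q = 0.95, linear interpolation between order statistics) of valid scores,
  recomputed over disjoint 2-day blocks. This keeps the stated properties —
  individual-specific, slowly adaptive — with a single interpretable knob.
  A block with no valid scores inherits its predecessor's threshold.
* **Peak detection.** Contiguous supra-threshold runs form regions; the
  earliest argmax of each region is the change point. A region straddling
  a block boundary is judged by the threshold of the block containing its
  start.
* **Merging.** Segments under 3 s concatenate to their predecessor first
  (a short first segment joins its successor). Then one left-to-right
  Brown–Forsythe pass at α = 10⁻²⁵: merge into the predecessor if not
  significantly different; otherwise try the successor; otherwise stand
  alone. Merged segments re-enter comparison as a unit; passes do not
  iterate to a fixed point. Comparisons run in log10 space, and the
  F-distribution tail is computed through the regularised incomplete beta
  function at 50 significant digits (mpmath), so p-values far below
  double-precision underflow (~10⁻³⁰⁸) are still ordered correctly.
* **Outlier filtration.** For long segments the largest 25% of |Δθ| are
  dropped and the remainder trimmed to ±1 SD of its mean before testing.
  The filtration is applied only when *both* segments of a comparison
  exceed 30 s. Filtering one side of a comparison but not the other
  manufactures a variance difference out of the filtration itself: a short
  segment of identical distribution then tests as different from its long
  neighbour at any α, which leaves spurious slivers in the partition. With
  the symmetric rule, seeded recovery experiments return exactly the
  constructed number of epochs.

## Classification

* **Transport energy.** The distance of a subsegment from idealized sleep
  (all differences zero) is the order-k power mean of |Δθ| after censoring
  values outside the segment's middle 95% to zero — substitution, not
  deletion, so the count n is unchanged. k = 20 (default): at high order
  the mean tracks the bulk's upper envelope, which separates states whose
  distributions overlap near zero. Computed with max-rescaling so 20th
  powers of milliradian angles cannot underflow; per-segment evaluation
  uses a prefix sum of the rescaled powers, making 1000 subsegments O(n)
  rather than O(1000·n) (the two routes agree to 1e−9 by test).
* **Subsegments.** 1000 per segment; lengths uniform between 100 samples
  (10 s at 10 Hz — enough points for a stable order-20 mean; the published
  procedure says only "random lengths") and the full segment; starts
  uniform; overlap permitted. Sampling is seeded per segment from the
  configured seed keyed by segment start, so labels are invariant to
  segment ordering and to edits elsewhere in the recording.
* **Characteristic curves.** |φ(ξ)| on 256 evenly spaced points of
  [0, 500] rad⁻¹ (configurable). The grid is an implementation choice: at
  sleep scales (|Δθ| ~ 10⁻³ rad) |φ| stays near 1 across this range, at
  wake scales it decays early, so the curves are separable; beyond
  ~500 rad⁻¹ all curves flatten and add no contrast.
* **Anchors and assignment.** Curves of segments with mean energy below
  0.015 average into the sleep anchor; those in (0.015, 0.1] into the wake
  anchor; noisier curves above 0.1 join neither but are still classified.
  Assignment is nearest anchor by Euclidean distance on the grid — with
  exactly two anchor objects, k-nearest-neighbours reduces to this. Exact
  ties go to wake (the conservative call for sleep estimation). If either
  seed set is empty the classifier degrades to the bare 0.015 threshold
  with a warning; a dedicated test demonstrates on a heavy-tailed
  quiet-wake construction that this fallback is strictly less accurate
  than curve clustering, which is why it is only a fallback. The cut-offs
  are population constants; the anchors are recomputed per recording,
  which is where the individual tuning lives.

## Validation and log adjustment

Scoring uses 1 s epochs; log gaps are excluded from all denominators, and a
reference with no sleep (or no wake) reports the corresponding metric as
undefined rather than 0. "Sensitivity" refers to detecting sleep and
"specificity" to detecting wake, following the methods-section convention.
The manual log adjustment is automated as snapping each logged transition
to the nearest detected change point within ±20 min: detected change
points are exactly the "sudden change in movement volatility" a human
adjuster looks for. Unique transition times are snapped in order; a snap
that would cross a neighbouring transition (original or already snapped)
is rejected, which preserves ordering and makes the operation idempotent.
Free-text log events without times are out of scope.

## Posture-change comparator

The benchmarking mimic epoch-averages the tilt over 5 s, records a posture
change when the mean drifts more than 5° from the tilt at the last change
(reference-point detection, so slow drifts accumulate), and labels spans
between changes by duration: under 5 min ⇒ linked active period (wake), at
least 5 min ⇒ sedentary (sleep), with the recording ends as virtual
boundaries and each change's epoch labelled wake. Note the duration rule
implies that *raising* the time threshold can only shrink total sleep
(fewer gaps qualify); the corresponding monotonicity test asserts that
direction. This is a comparator, not a reimplementation of the full GGIR
ecosystem.

## Synthetic world

Defaults: 10 Hz; Laplace Δθ scales 0.001 (sleep), 0.008 (quiet wake),
0.08 (active wake) radians; rollover bursts at 4/h during sleep lasting
2–10 s at active scale, labelled sleep in truth; schedules with ≥60 s
states (standard day = wake blocks of 20–90 min alternating quiet/active,
then one sleep block covering the final third). The scales are generator
choices — chosen once so that the three states straddle the 0.015/0.1
energy cut-offs the way distinguishable human states do (sleep ≈ 0.002,
quiet ≈ 0.019, active ≈ 0.19 in segment mean energy) — not measurements.

The tilt path is not a free random walk: each scheduled interval draws a
posture baseline in [0.7, 2.0] rad and the tilt reverts toward it at 0.05
per sample. A free random walk at quiet-wake scale drifts through the 5°
posture threshold within minutes, which would make quiet wakefulness look
*active* to any posture-based method — the opposite of real quiet
wakefulness, which is posturally stable. The reversion term is an order of
magnitude below the innovation scale, inflating the Δθ SD by only ~1.3%
(inside the 5% tolerance the generator tests assert), so the marginal
distributions the classifier consumes are unchanged. Reflection at 0 and π
keeps the path a valid tilt angle; the azimuth, unconstrained by tilt,
performs a slow random walk so the recoverable tri-axial record is
non-degenerate.

What a green test does establish: exact-recovery of well-separated
volatility epochs, ≥95% per-second agreement on the default day,
insensitivity to rollover bursts, and a specificity advantage over the
posture comparator when quiet wake is 8× sleep scale. What it does not:
performance on real recordings — the generator has no circadian amplitude
modulation, no device noise spectrum, no non-wear, no log errors beyond
the transition-time snapping model, and within-state movement is
exchangeable rather than autocorrelated.

## Known limitations

* The CPT quantile stands in for an unpublished rule; q = 0.95 is a
  documented default, not a reproduction. Because the quantile scales with
  the busiest transitions in a block, a day dense with strong wake
  transitions can lift the threshold above the subtler sleep-onset peak;
  on one seeded synthetic day this merged the final quiet-wake block into
  the sleep segment (per-second accuracy 94.7% instead of the typical
  99%+). Boundaries the threshold misses cannot be recovered downstream —
  the merge step only removes boundaries, never adds them. Lowering
  `cpt_quantile` trades this risk for more (harmless, merge-corrected)
  candidate cuts.
* Integer sampling rates are assumed by the second-aligned windowing.
* Non-wear and device-off periods are treated as wear time.
* Sleep-parameter summaries (latency, WASO, total sleep time) are not
  emitted; the per-second series and segment table are the outputs.
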