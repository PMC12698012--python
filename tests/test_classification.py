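"""Transport energies, characteristic curves and sleep/wake assignment."""

import mpmath as mp
import numpy as np
import pytest

from wacsaw.classification import (
    SLEEP,
    WAKE,
    NucleatedClusters,
    censoring_band,
    characteristic_modulus,
    classify_segments,
    default_xi_grid,
    labels_to_series,
    nucleate_clusters,
    sample_subsegments,
    segment_energy_distribution,
    transport_energy,
)
from wacsaw.errors import InputError
from wacsaw.segmentation import Segment

from conftest import make_fd

WIDE = (-np.inf, np.inf)


def naive_energy_mp(values, band, k):
    """Extended-precision brute-force power mean, independent of the
    max-rescaled implementation."""
    with mp.workdps(60):
        total = mp.mpf(0)
        for v in values:
            v = mp.mpf(float(v))
            if not (band[0] <= v <= band[1]):
                v = mp.mpf(0)
            total += abs(v) ** k
        return float((total / len(values)) ** (mp.mpf(1) / k))


class TestSampleSubsegments:
    def test_minimum_length_segment_replicates(self):
        seg = Segment(0, 10)  # 100 samples at 10 Hz = the minimum
        ranges = sample_subsegments(seg, 10.0, count=50, min_samples=100, rng=0)
        assert ranges == [(0, 100)] * 50

    def test_deterministic_under_seed(self):
        seg = Segment(0, 600)
        a = sample_subsegments(seg, 10.0, count=200, rng=42)
        b = sample_subsegments(seg, 10.0, count=200, rng=42)
        assert a == b

    def test_ranges_inside_segment(self):
        seg = Segment(30, 630)
        lo, hi = seg.sample_range(10.0)
        for s, e in sample_subsegments(seg, 10.0, count=300, rng=7):
            assert lo <= s < e <= hi
            assert e - s >= 100


class TestTransportEnergy:
    def test_idealized_sleep_is_zero(self):
        assert transport_energy(np.zeros(100), WIDE) == 0.0

    @pytest.mark.parametrize("k", [1.0, 2.0, 20.0])
    def test_constant_equals_constant(self, k):
        assert transport_energy(np.full(64, 0.37), WIDE, k=k) == pytest.approx(0.37)

    def test_homogeneity(self, rng):
        v = rng.laplace(0, 0.01, 200)
        band = censoring_band(v)
        d = transport_energy(v, band, k=20.0)
        c = 7.3
        scaled = transport_energy(c * v, (c * band[0], c * band[1]), k=20.0)
        assert scaled == pytest.approx(c * d, rel=1e-12)

    def test_matches_extended_precision_oracle(self, rng):
        v = rng.laplace(0, 0.005, 50)
        band = censoring_band(v)
        got = transport_energy(v, band, k=20.0)
        assert got == pytest.approx(naive_energy_mp(v, band, 20), rel=1e-9)

    def test_monotone_in_k(self, rng):
        """Power-mean inequality: D is non-decreasing in the order k."""
        for _ in range(5):
            v = rng.laplace(0, 0.01, 120)
            d = [transport_energy(v, WIDE, k=k) for k in (1.0, 2.0, 20.0)]
            assert d[0] <= d[1] + 1e-15 <= d[2] + 2e-15

    def test_censoring_zeroes_outside_band(self):
        v = np.array([0.01] * 90 + [5.0] * 10)
        d = transport_energy(v, (-0.02, 0.02), k=1.0)
        assert d == pytest.approx(0.01 * 0.9)


class TestSegmentEnergyDistribution:
    def test_pure_zero_segment(self):
        fd = make_fd(np.zeros(3000))
        dist = segment_energy_distribution(Segment(0, 300), fd, count=100, rng=np.random.default_rng(0))
        assert np.all(dist.energies == 0.0) and dist.mean_energy == 0.0

    def test_prefix_sum_equals_direct_evaluation(self, rng):
        """The O(n) prefix-sum path must agree with per-subsegment evaluation."""
        v = rng.laplace(0, 0.01, 6000)
        fd = make_fd(v)
        seg = Segment(0, 600)
        dist = segment_energy_distribution(seg, fd, count=50, rng=np.random.default_rng(5))
        band = censoring_band(v)
        ranges = sample_subsegments(seg, 10.0, count=50, rng=np.random.default_rng(5))
        direct = [transport_energy(v[s:e], band, k=20.0) for s, e in ranges]
        np.testing.assert_allclose(dist.energies, direct, rtol=1e-9)

    def test_mean_energy_monotone_in_scale(self, rng):
        means = []
        for scale in (0.001, 0.004, 0.016, 0.064):
            fd = make_fd(rng.laplace(0, scale, 6000))
            dist = segment_energy_distribution(
                Segment(0, 600), fd, count=200, rng=np.random.default_rng(1)
            )
            means.append(dist.mean_energy)
        assert all(a < b for a, b in zip(means, means[1:]))


class TestCharacteristicModulus:
    def test_modulus_at_zero_is_one(self, rng):
        curve = characteristic_modulus(rng.normal(size=500), default_xi_grid())
        assert curve.modulus[0] == pytest.approx(1.0)
        assert np.all((curve.modulus >= 0) & (curve.modulus <= 1))

    def test_zero_movement_is_flat_one(self):
        curve = characteristic_modulus(np.zeros(100), default_xi_grid())
        np.testing.assert_allclose(curve.modulus, 1.0)

    def test_rademacher_closed_form(self):
        c = 0.01
        xi = default_xi_grid(500.0, 64)
        curve = characteristic_modulus(np.array([c, -c] * 200), xi)
        np.testing.assert_allclose(curve.modulus, np.abs(np.cos(c * xi)), atol=1e-12)

    def test_chunking_invariance(self, rng):
        v = rng.laplace(0, 0.01, 1000)
        xi = default_xi_grid(500.0, 32)
        a = characteristic_modulus(v, xi, chunk=64)
        b = characteristic_modulus(v, xi, chunk=10**6)
        np.testing.assert_allclose(a.modulus, b.modulus, atol=1e-12)


def curve_of(values, seg_id=0):
    return characteristic_modulus(values, default_xi_grid(500.0, 64), segment_id=seg_id)


class TestNucleationAndAssignment:
    def test_two_segment_anchors(self, rng):
        curves = [curve_of(rng.laplace(0, 0.001, 2000)), curve_of(rng.laplace(0, 0.01, 2000))]
        anchors = nucleate_clusters(curves, [0.005, 0.05])
        np.testing.assert_array_equal(anchors.sleep_anchor, curves[0].modulus)
        np.testing.assert_array_equal(anchors.wake_anchor, curves[1].modulus)
        assert anchors.n_sleep_seed == anchors.n_wake_seed == 1

    def test_high_energy_curves_excluded_from_anchors(self, rng):
        curves = [
            curve_of(rng.laplace(0, 0.001, 2000)),
            curve_of(rng.laplace(0, 0.01, 2000)),
            curve_of(rng.laplace(0, 0.1, 2000)),
        ]
        anchors = nucleate_clusters(curves, [0.005, 0.05, 0.5])
        np.testing.assert_array_equal(anchors.wake_anchor, curves[1].modulus)
        assert np.all(anchors.sleep_anchor <= 1.0) and np.all(anchors.wake_anchor >= 0.0)
        # ... but the excluded segment is still classified
        labels = classify_segments(curves, anchors)
        assert labels[2] == WAKE

    def test_anchor_curves_label_themselves(self, rng):
        sleep_c = curve_of(rng.laplace(0, 0.001, 2000))
        wake_c = curve_of(rng.laplace(0, 0.01, 2000))
        anchors = nucleate_clusters([sleep_c, wake_c], [0.005, 0.05])
        assert classify_segments([sleep_c, wake_c], anchors) == [SLEEP, WAKE]

    def test_exact_tie_goes_to_wake(self):
        xi = default_xi_grid(500.0, 8)
        mid = NucleatedClusters(
            sleep_anchor=np.full(8, 0.8), wake_anchor=np.full(8, 0.4), xi_grid=xi
        )
        from wacsaw.classification import CharacteristicCurve

        curve = CharacteristicCurve(0, xi, np.full(8, 0.6))
        assert classify_segments([curve], mid) == [WAKE]

    def test_degenerate_mode_uses_energy_threshold(self, rng):
        curves = [curve_of(rng.laplace(0, 0.001, 2000))]
        anchors = nucleate_clusters(curves, [0.005])  # no wake seed
        assert anchors.degenerate
        assert classify_segments(curves, anchors, [0.005]) == [SLEEP]
        assert classify_segments(curves, anchors, [0.05]) == [WAKE]

    def test_ordering_invariance(self, rng):
        """Shuffling segment order leaves every per-segment label unchanged."""
        samples = [rng.laplace(0, s, 2000) for s in (0.001, 0.004, 0.01, 0.05, 0.0012)]
        energies = [0.003, 0.012, 0.03, 0.09, 0.004]
        curves = [curve_of(v, i) for i, v in enumerate(samples)]
        anchors = nucleate_clusters(curves, energies)
        labels = classify_segments(curves, anchors, energies)
        order = [3, 0, 4, 1, 2]
        anchors2 = nucleate_clusters([curves[i] for i in order], [energies[i] for i in order])
        labels2 = classify_segments([curves[i] for i in order], anchors2, [energies[i] for i in order])
        assert [labels2[order.index(i)] for i in range(5)] == labels

    def test_curve_clustering_beats_bare_threshold_on_heavy_tails(self):
        """A heavy-tailed quiet-wake segment whose censored energy dips below
        the 0.015 cut-off is rescued by curve clustering: the full movement
        distribution, which the curve retains and the censored energy does
        not, still looks wakeful."""
        rng = np.random.default_rng(1)
        n = 20000
        quiet = rng.laplace(0, 0.005, n)
        spikes = rng.random(n) < 0.03  # heavy tail, censored away entirely
        quiet[spikes] = np.sign(rng.normal(size=spikes.sum())) * 0.05
        segs = {
            "sleep": rng.laplace(0, 0.001, n),
            "quiet": quiet,
            "active": rng.laplace(0, 0.008, n),
        }
        energies, curves = [], []
        for i, v in enumerate(segs.values()):
            fd = make_fd(v)
            dist = segment_energy_distribution(
                Segment(0, n // 10), fd, count=300, rng=np.random.default_rng(i)
            )
            energies.append(dist.mean_energy)
            curves.append(curve_of(v, i))
        assert energies[1] < 0.015  # censoring hides the quiet-wake tail
        threshold_labels = [SLEEP if e < 0.015 else WAKE for e in energies]
        anchors = nucleate_clusters(curves, energies)
        cluster_labels = classify_segments(curves, anchors, energies)
        truth = [SLEEP, WAKE, WAKE]
        correct = lambda lab: sum(a == b for a, b in zip(lab, truth))
        assert correct(cluster_labels) > correct(threshold_labels)


class TestLabelsToSeries:
    def test_single_sleep_segment(self):
        series = labels_to_series([Segment(0, 600)], [SLEEP], 600)
        assert len(series) == 600 and np.all(series.states == SLEEP)

    def test_half_open_boundary(self):
        series = labels_to_series([Segment(0, 100), Segment(100, 200)], [SLEEP, WAKE], 200)
        assert series.states[99] == SLEEP and series.states[100] == WAKE

    def test_uncovered_second_rejected(self):
        with pytest.raises(InputError):
            labels_to_series([Segment(0, 100)], [SLEEP], 200)
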