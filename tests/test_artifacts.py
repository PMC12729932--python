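import numpy as np
import pytest

from mer_pipelines import bck_scan, cov_scan, background_level, enforce_min_length, exp_filter
from mer_pipelines.artifacts import (
    amplitude_flags,
    frequency_flags,
    longest_clean_run,
    _pairwise_variance_distance,
    truth_rejection_labels,
)
from mer_pipelines.synth import inject_artifacts
from conftest import make_trace, noise_trace
from oracles import brute_longest_clean_run


class TestCovScan:
    def test_identical_segments_fully_retained(self, rng):
        pattern = rng.normal(size=1000)  # one 0.5 s segment at fs=2000
        t = make_trace(np.tile(pattern, 20), fs=2000)
        scan, cleaned = cov_scan(t)
        assert np.allclose(scan.distances, 1.0)
        assert scan.retained_run == (0, 19)
        assert scan.rejected_fraction == 0.0
        assert len(cleaned.samples) == len(t.samples)

    def test_amplitude_burst_segment_excluded(self, rng):
        x = rng.normal(size=20_000)
        x[7000:7500] *= 10  # one 0.5 s segment at 10x amplitude
        scan, _ = cov_scan(make_trace(x, fs=2000))
        i, j = scan.retained_run
        assert not (i <= 7 <= j)
        assert scan.retained_run == brute_longest_clean_run(scan.adjacency)

    def test_rejected_fraction_arithmetic(self):
        # m=20, clean run of 17 -> rejected fraction 0.15
        A = np.zeros((20, 20), bool)
        A[17, :17] = A[:17, 17] = True  # segment 17 clashes with all before it
        assert longest_clean_run(A) == (0, 16)
        # via the scan arithmetic: 1 - 17/20
        assert 1 - 17 / 20 == pytest.approx(0.15)

    def test_retained_run_matches_bruteforce_on_random_adjacency(self, rng):
        for _ in range(200):
            m = int(rng.integers(2, 15))
            A = rng.random((m, m)) < 0.2
            A = A | A.T
            np.fill_diagonal(A, False)
            assert longest_clean_run(A) == brute_longest_clean_run(A)

    def test_tie_broken_to_earliest_start(self):
        A = np.zeros((5, 5), bool)
        A[2, :2] = A[:2, 2] = True  # runs [0,1] and [2,4]... lengths 2 and 3
        assert longest_clean_run(A) == (2, 4)
        B = np.zeros((4, 4), bool)
        B[2, 1] = B[1, 2] = True  # runs [0,1] and [2,3]: tie -> earliest
        assert longest_clean_run(B) == (0, 1)

    def test_zero_variance_segment_always_flagged(self):
        d = _pairwise_variance_distance(np.array([1.0, 0.0, 2.0]))
        assert np.isinf(d[0, 1]) and np.isinf(d[1, 2])
        assert d[0, 2] == 2.0

    def test_trace_shorter_than_two_segments_rejected(self, rng):
        with pytest.raises(ValueError):
            cov_scan(make_trace(rng.normal(size=1200), fs=2000))


class TestBackgroundLevel:
    def test_zero_signal(self):
        assert background_level(np.zeros(100)) == 0.0

    def test_unit_sine_envelope_is_one(self):
        t = np.arange(20_000) / 2000
        x = np.sin(2 * np.pi * 50 * t)
        assert background_level(x) == pytest.approx(1.0, rel=0.01)

    def test_gaussian_noise_rayleigh_median(self, rng):
        # envelope of white noise is Rayleigh(sigma); median = sigma sqrt(2 ln 2)
        sigma = 2.5
        x = rng.normal(0, sigma, 100_000)
        expected = sigma * np.sqrt(2 * np.log(2))
        assert background_level(x) == pytest.approx(expected, rel=0.02)


class TestBckScan:
    def test_homogeneous_noise_unflagged(self, rng):
        t = noise_trace(rng, fs=2000, duration=10.0)
        scan, cleaned = bck_scan(t)
        assert not scan.combined_flags.any()
        np.testing.assert_array_equal(cleaned.samples, t.samples)

    def test_25x_amplitude_segment_amp_flagged(self, rng):
        x = rng.normal(size=20_000)
        x[4000:5000] *= 25
        scan, _ = bck_scan(make_trace(x, fs=2000))
        assert scan.amp_flags[4]
        assert scan.combined_flags[4]

    def test_strong_sinusoid_freq_flagged(self, rng):
        x = rng.normal(size=20_000)
        t = np.arange(1000) / 2000
        # tone large enough for a 3x spectral max but amplitude < 20x
        x[6000:7000] += 12 * np.sin(2 * np.pi * 150 * t)
        scan, _ = bck_scan(make_trace(x, fs=2000))
        assert scan.freq_flags[6]
        assert not scan.amp_flags[6]

    def test_flagged_segments_removed_in_time_order(self, rng):
        x = rng.normal(size=20_000)
        x[0:1000] *= 25
        x[10_000:11_000] *= 25
        scan, cleaned = bck_scan(make_trace(x, fs=2000))
        assert scan.combined_flags.sum() == 2
        assert len(cleaned.samples) == 18_000
        np.testing.assert_array_equal(cleaned.samples[:1000], x[1000:2000])

    @pytest.mark.parametrize("scale", [0.1, 3.0, 1000.0])
    def test_flags_invariant_under_global_scaling(self, rng, scale):
        x = rng.normal(size=20_000)
        x[4000:5000] *= 25
        base, _ = bck_scan(make_trace(x, fs=2000))
        scaled, _ = bck_scan(make_trace(x * scale, fs=2000))
        np.testing.assert_array_equal(base.amp_flags, scaled.amp_flags)
        np.testing.assert_array_equal(base.freq_flags, scaled.freq_flags)

    def test_cov_distances_invariant_under_global_scaling(self, rng):
        x = rng.normal(size=20_000)
        x[2000:3000] *= 10
        a, _ = cov_scan(make_trace(x, fs=2000))
        b, _ = cov_scan(make_trace(x * 7.0, fs=2000))
        np.testing.assert_allclose(a.distances, b.distances, rtol=1e-9)


class TestThresholdSemantics:
    def test_exactly_at_amplitude_threshold_is_clean(self):
        flags = amplitude_flags(np.array([20.0, 20.0001]), bck_tot=1.0)
        assert not flags[0] and flags[1]

    def test_exactly_at_frequency_threshold_is_clean(self):
        # median of [1, 1, 2.5] is 1 -> threshold 2.5; 2.5 is clean
        assert not frequency_flags(np.array([1.0, 1.0, 2.5]))[2]
        assert frequency_flags(np.array([1.0, 1.0, 2.51]))[2]

    def test_distance_exactly_at_cov_threshold_is_clean(self):
        d = _pairwise_variance_distance(np.array([1.0, 1.8]))
        A = d > 1.8
        assert not A.any()
        d2 = _pairwise_variance_distance(np.array([1.0, 1.801]))
        assert (d2 > 1.8)[0, 1]


class TestExpFilterAndMinLength:
    def test_no_labels_identity(self, rng):
        traces = [noise_trace(rng, fs=1000, duration=1.0) for _ in range(3)]
        assert exp_filter(traces, {}) == traces

    def test_labeled_traces_removed_whole(self, rng):
        traces = [
            noise_trace(rng, fs=1000, duration=1.0, timestamp=i) for i in range(10)
        ]
        labels = {traces[i].trace_id: True for i in (0, 4, 7)}
        assert len(exp_filter(traces, labels)) == 7

    def test_all_labeled_annihilates(self, rng):
        traces = [noise_trace(rng, fs=1000, duration=1.0, timestamp=i) for i in range(3)]
        assert exp_filter(traces, {t.trace_id: True for t in traces}) == []

    def test_unknown_trace_id_error(self, rng):
        with pytest.raises(KeyError):
            exp_filter([noise_trace(rng, fs=1000, duration=1.0)], {"nope": True})

    def test_truth_labels_reject_artifactual_traces(self, rng):
        clean = noise_trace(rng, fs=1000, duration=2.0, timestamp=0)
        dirty = inject_artifacts(
            noise_trace(rng, fs=1000, duration=2.0, timestamp=1),
            "mechanical",
            [(0.5, 0.2, 10.0)],
        )
        labels = truth_rejection_labels([clean, dirty])
        assert exp_filter([clean, dirty], labels) == [clean]

    @pytest.mark.parametrize(
        "duration,keep", [(3.5, False), (4.0, True), (10.0, True)]
    )
    def test_min_residual_length_rule(self, rng, duration, keep):
        t = noise_trace(rng, fs=1000, duration=duration)
        assert enforce_min_length(t) is keep
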