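"""Spike detection, onset rapidness, and train statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurostab import (
    MembraneTraceSpec,
    TraceRecord,
    detect_spikes,
    gen_gamma_train,
    gen_membrane_trace,
    local_variation,
    onset_rapidness,
    spike_stats,
    SpikeTrainSpec,
    SpikeDetector,
)


def _pulse_trace(peaks, n=5000, dt=1e-4, baseline=-60.0, height=50.0, width=10):
    v = np.full(n, baseline)
    for p in peaks:
        v[p - width : p + width + 1] += height * np.hanning(2 * width + 1)
    return TraceRecord(v, dt)


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        trace = TraceRecord(np.full(1000, -60.0), 1e-4)
        assert detect_spikes(trace, threshold=-20.0).n_spikes == 0

    def test_three_known_peaks(self):
        peaks = [500, 1500, 3000]
        trace = _pulse_trace(peaks)
        train = detect_spikes(trace, threshold=-30.0)
        np.testing.assert_array_equal(train.peak_indices, peaks)

    def test_exact_threshold_touch_does_not_trigger(self):
        v = np.full(100, -60.0)
        v[50] = -20.0  # touches exactly
        assert detect_spikes(TraceRecord(v, 1e-4), threshold=-20.0).n_spikes == 0
        v[50] = -19.999  # strictly above
        assert detect_spikes(TraceRecord(v, 1e-4), threshold=-20.0).n_spikes == 1

    def test_refractory_suppression(self):
        trace = _pulse_trace([500, 515], width=5)  # 1.5 ms apart at 10 kHz
        assert detect_spikes(trace, -30.0, refractory=2e-3).n_spikes == 1
        assert detect_spikes(trace, -30.0, refractory=1e-3).n_spikes == 2

    def test_negative_polarity(self):
        trace = _pulse_trace([500, 1500])
        flipped = TraceRecord(-trace.samples, trace.dt)
        train = detect_spikes(flipped, threshold=30.0, polarity=-1)
        np.testing.assert_array_equal(train.peak_indices, [500, 1500])

    def test_non_finite_rejected(self):
        v = np.full(100, -60.0)
        v[10] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            detect_spikes(TraceRecord(v, 1e-4), -20.0)

    def test_recovery_on_noisy_synthetic(self):
        # SNR >= 10: spike height 100 mV, noise sd 1 mV
        spec = MembraneTraceSpec(duration=20.0, noise_sd=1.0, seed=4)
        trace, truth, _ = gen_membrane_trace(spec)
        train = detect_spikes(trace, threshold=-20.0)
        matched = 0
        for t in truth.times:
            if np.min(np.abs(train.times - t)) <= 1e-3:
                matched += 1
        assert matched / truth.n_spikes >= 0.99
        # zero false positives: every detection near a true spike
        for t in train.times:
            assert np.min(np.abs(truth.times - t)) <= 1e-3


class TestOnsetRapidness:
    def test_linear_ramp_exact(self):
        dt = 1e-4
        v = np.full(1000, -60.0)
        ramp = np.arange(50) * 20.0 * dt * 1e3  # 20 V/s in mV steps
        v[500 : 500 + 50] += ramp
        trace = TraceRecord(v, dt)
        train = detect_spikes(trace, threshold=-30.0)
        rap = onset_rapidness(trace, train, window=2e-3)
        assert rap[0] == pytest.approx(20.0, rel=1e-9)

    def test_sine_peak_derivative(self):
        dt = 1e-4
        f, A = 100.0, 30.0
        t = np.arange(0, 2.5e-3, dt)  # rising quarter-cycle
        v = np.full(1000, -60.0)
        v[200 : 200 + t.size] += A * np.sin(2 * np.pi * f * t)
        trace = TraceRecord(v, dt)
        train = detect_spikes(trace, threshold=-40.0)
        # window must reach back to the sine's zero-phase point, where the
        # analytic slope 2*pi*f*A is attained
        rap = onset_rapidness(trace, train, window=2.4e-3)
        assert rap[0] == pytest.approx(2 * np.pi * f * A / 1e3, rel=0.01)

    def test_five_sample_hand_case(self):
        dt = 1e-4
        v = np.full(20, -60.0)
        v[10:15] = [-60.0, -55.0, -40.0, -10.0, 10.0]
        trace = TraceRecord(v, dt)
        train = detect_spikes(trace, threshold=-20.0)
        assert train.peak_indices[0] == 14
        rap = onset_rapidness(trace, train, window=4 * dt)
        # central difference at the 4th sample: (10 - (-40)) / (2 * 0.1 ms)
        assert rap[0] == pytest.approx(250.0)

    def test_spike_too_close_to_start_flagged(self):
        trace = _pulse_trace([15, 3000], width=10)
        train = detect_spikes(trace, -30.0)
        rap = onset_rapidness(trace, train, window=2e-3)
        assert np.isnan(rap[0]) and np.isfinite(rap[1])


class TestLocalVariation:
    def test_constant_isis_zero(self):
        assert local_variation(np.full(100, 0.2)) == 0.0

    def test_alternating_hand_case(self):
        isis = np.tile([1.0, 2.0], 50)
        assert local_variation(isis) == pytest.approx(1 / 3, rel=1e-12)

    def test_poisson_expectation(self):
        train = gen_gamma_train(SpikeTrainSpec(rate=5, shape=1.0, n_spikes=10001, seed=5))
        assert local_variation(np.diff(train.times)) == pytest.approx(1.0, abs=0.03)

    @pytest.mark.parametrize("bad", [[0.1], [0.1, -0.2, 0.3], [0.1, 0.0, 0.3]])
    def test_invalid_isis(self, bad):
        with pytest.raises(ValueError):
            local_variation(bad)

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=25, deadline=None)
    def test_time_rescaling_invariance(self, scale, seed):
        isis = np.random.default_rng(seed).gamma(2.0, 0.1, 200)
        assert local_variation(isis * scale) == pytest.approx(
            local_variation(isis), rel=1e-9
        )


class TestSpikeStats:
    def test_mean_rate(self):
        from neurostab import SpikeTrain

        train = SpikeTrain(times=np.linspace(0.1, 4.6, 10))
        assert spike_stats(train, duration=5.0).mean_rate == pytest.approx(2.0)

    def test_instantaneous_frequency(self):
        from neurostab import SpikeTrain

        train = SpikeTrain(times=np.array([0.0, 0.1, 0.3]))
        st_ = spike_stats(train, duration=1.0)
        np.testing.assert_allclose(st_.isis, [0.1, 0.2])
        np.testing.assert_allclose(st_.inst_freq, [10.0, 5.0])
        assert st_.isi_hist_probs.sum() == pytest.approx(1.0)

    def test_few_spikes_rate_still_defined(self):
        from neurostab import SpikeTrain

        st_ = spike_stats(SpikeTrain(times=np.array([1.0])), duration=2.0)
        assert st_.mean_rate == 0.5
        assert st_.isis.size == 0 and np.isnan(st_.lv)

    def test_gamma_histogram_mode(self):
        train = gen_gamma_train(SpikeTrainSpec(rate=5, shape=2.0, n_spikes=10001, seed=6))
        st_ = spike_stats(train, duration=train.times[-1], n_bins=60)
        centers = 0.5 * (st_.isi_hist_edges[:-1] + st_.isi_hist_edges[1:])
        mode = centers[np.argmax(st_.isi_hist_probs)]
        assert mode == pytest.approx(0.1, abs=0.03)  # (kappa-1)/(kappa*rate)


def test_spike_detector_estimator_api():
    spec = MembraneTraceSpec(duration=5.0, seed=7)
    trace, truth, _ = gen_membrane_trace(spec)
    det = SpikeDetector(threshold=-20.0)
    assert det.get_params()["threshold"] == -20.0
    det.fit(trace)
    assert det.n_spikes_ == truth.n_spikes
    assert det.spike_train_.onset_rapidness.shape == det.spike_train_.times.shape
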