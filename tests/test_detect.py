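"""Spike detection and electrode QC: threshold behaviour, robustness of the
noise estimator, artifact rejection, and QC boundary cases."""

import numpy as np
import pytest
from scipy import stats

from meanet.config import DataError, DetectionConfig
from meanet.containers import DeviceSpikes, RawRecording
from meanet.detect import (apply_electrode_qc, detect_spikes,
                           estimate_noise_sd, percent_active_electrodes,
                           remove_cross_channel_artifacts)
from meanet.synth import SimConfig, simulate_raw_traces

FS = 22300.0


def _recording(traces):
    traces = np.atleast_2d(traces)
    return RawRecording(traces=traces, sampling_rate_hz=FS,
                        duration_s=traces.shape[1] / FS,
                        channel_ids=list(range(1, traces.shape[0] + 1)))


class TestNoiseSD:
    def test_consistent_for_gaussian(self, rng):
        x = rng.normal(0, 1.0, size=1_000_000)
        assert abs(estimate_noise_sd(x) - 1.0) < 0.01

    def test_zero_for_constant_trace(self):
        assert estimate_noise_sd(np.zeros(1000)) == 0.0

    def test_robust_to_sparse_spikes(self, rng):
        x = rng.normal(0, 1.0, size=1_000_000)
        idx = rng.choice(x.size, size=x.size // 1000, replace=False)
        x[idx] = -10.0
        assert abs(estimate_noise_sd(x) - 1.0) < 0.02

    def test_empty_trace_raises(self):
        with pytest.raises(DataError):
            estimate_noise_sd(np.array([]))


class TestDetection:
    def test_constant_trace_warns_and_yields_no_events(self):
        rec = _recording(np.zeros((1, 2230)))
        with pytest.warns(UserWarning):
            spikes = detect_spikes(rec)
        assert spikes.trains[1].size == 0

    def test_planted_spikes_recovered_exactly(self):
        """20 biphasic spikes at -10 sigma, >=10 ms apart, recovered to
        within 0.5 ms of ground truth."""
        truth = np.arange(20) * 0.05 + 0.02
        cfg = SimConfig(n_electrodes=1, duration_s=1.5, sampling_rate_hz=FS,
                        seed=8, background_rate_hz=0.0, noise_sd=1e-5,
                        spike_amplitude_sd_units=10.0)
        spikes = DeviceSpikes(trains={1: truth}, duration_s=1.5)
        rec = simulate_raw_traces(spikes, cfg)
        out = detect_spikes(rec).trains[1]
        assert out.size == 20
        assert np.max(np.abs(out - truth)) < 5e-4

    def test_below_threshold_peak_not_detected(self):
        # deterministic baseline of alternating +/-1 -> noise SD ~ 1.4826
        trace = np.tile([1.0, -1.0], 2230)
        sd = estimate_noise_sd(trace)
        trace[2000:2010] = -4.0 * sd          # below 5x threshold
        assert detect_spikes(_recording(trace)).trains[1].size == 0
        trace[2000:2010] = -10.0 * sd
        assert detect_spikes(_recording(trace)).trains[1].size == 1

    def test_translation_equivariance(self, rng):
        trace = rng.normal(0, 1.0, size=44600)
        for i in (5000, 15000, 30000):
            trace[i:i + 5] = -12.0
        shift = 223
        shifted = np.roll(trace, shift)
        a = detect_spikes(_recording(trace)).trains[1]
        b = detect_spikes(_recording(shifted)).trains[1]
        assert np.allclose(b, a + shift / FS, atol=1e-9)

    def test_raising_threshold_never_adds_events(self, rng):
        trace = rng.normal(0, 1.0, size=223_000)
        trace[rng.choice(trace.size, 50, replace=False)] = -6.0
        counts = []
        for mult in (3.0, 4.0, 5.0, 6.0, 8.0):
            cfg = DetectionConfig(threshold_sd_multiplier=mult)
            counts.append(detect_spikes(_recording(trace), cfg).trains[1].size)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_false_positives_on_pure_noise_below_gaussian_bound(self, rng):
        """Events on pure Gaussian noise stay below the tail-probability
        oracle: n_samples * P(X < -5 sigma), with Poisson headroom."""
        n = int(600 * FS)
        trace = rng.normal(0, 1.0, size=n)
        events = detect_spikes(_recording(trace)).trains[1]
        expected = n * stats.norm.cdf(-5.0)   # ~3.8 over 10 minutes
        assert events.size < 10
        assert events.size < expected + 4 * np.sqrt(expected) + 1


class TestArtifacts:
    def _device(self):
        rng = np.random.default_rng(4)
        trains = {e: np.sort(rng.uniform(0, 600, 50)) for e in range(1, 61)}
        return trains

    def test_array_wide_event_removed_everywhere(self):
        trains = self._device()
        before = {e: t.size for e, t in trains.items()}
        trains = {e: np.unique(np.append(t, 5.0)) for e, t in trains.items()}
        spikes = DeviceSpikes(trains=trains, duration_s=600)
        out = remove_cross_channel_artifacts(spikes)
        for e in trains:
            assert not np.any(np.isclose(out.trains[e], 5.0))
            assert out.trains[e].size == before[e]

    def test_no_coincidences_is_identity(self):
        # events spread far apart on 3 channels: nothing removed
        trains = {1: np.array([1.0, 10.0]), 2: np.array([3.0, 20.0]),
                  3: np.array([5.0, 30.0])}
        spikes = DeviceSpikes(trains=trains, duration_s=60)
        out = remove_cross_channel_artifacts(spikes)
        for e in trains:
            assert np.array_equal(out.trains[e], trains[e])

    def test_half_array_coincidence_retained(self):
        trains = self._device()
        for e in list(trains)[:30]:           # 50% of channels
            trains[e] = np.unique(np.append(trains[e], 5.0))
        spikes = DeviceSpikes(trains=trains, duration_s=600)
        out = remove_cross_channel_artifacts(spikes)
        kept = sum(np.any(np.isclose(out.trains[e], 5.0)) for e in trains)
        assert kept == 30


class TestQC:
    def _spikes(self, counts):
        rng = np.random.default_rng(0)
        trains = {e: np.sort(rng.uniform(0, 600, n))
                  for e, n in counts.items()}
        return DeviceSpikes(trains=trains, duration_s=600)

    def test_boundaries_strict(self):
        out = apply_electrode_qc(self._spikes({1: 4001, 2: 4000, 3: 10,
                                               4: 9, 5: 0, 6: 100}))
        assert out.qc_status == {1: "noisy", 2: "active", 3: "active",
                                 4: "silent", 5: "silent", 6: "active"}

    def test_idempotent(self):
        once = apply_electrode_qc(self._spikes({1: 5000, 2: 5, 3: 50}))
        twice = apply_electrode_qc(once)
        assert once.qc_status == twice.qc_status
        assert all(np.array_equal(once.trains[e], twice.trains[e])
                   for e in once.trains)

    def test_excluded_electrodes_not_active(self):
        out = apply_electrode_qc(self._spikes({1: 5000, 2: 5, 3: 50}))
        assert out.active_ids() == [3]


class TestPercentActive:
    def test_half_active(self):
        status = {e: ("active" if e <= 30 else "silent")
                  for e in range(1, 61)}
        spikes = DeviceSpikes(trains={e: np.array([]) for e in status},
                              duration_s=600, qc_status=status)
        assert percent_active_electrodes(spikes) == 50.0

    def test_none_active_is_zero(self):
        spikes = DeviceSpikes(trains={1: np.array([])}, duration_s=600,
                              qc_status={1: "silent"})
        assert percent_active_electrodes(spikes, total_electrodes=60) == 0.0

    def test_simulated_device_45_of_60(self, rng):
        trains = {e: np.sort(rng.uniform(0, 600, 50)) for e in range(1, 46)}
        trains.update({e: np.array([]) for e in range(46, 61)})
        out = apply_electrode_qc(DeviceSpikes(trains=trains, duration_s=600))
        assert percent_active_electrodes(out, total_electrodes=60) == 75.0

    def test_zero_total_raises(self):
        spikes = DeviceSpikes(trains={}, duration_s=600)
        with pytest.raises(DataError):
            percent_active_electrodes(spikes)
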