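"""SPIKE-distance and surrogate normalization: metric properties, the
dense-grid integration oracle, and chance-level calibration."""

import numpy as np
import pytest

from meanet.config import DataError, SynchronyConfig
from meanet.containers import DeviceSpikes
from meanet.synchrony import (pair_rng, spike_distance,
                              surrogate_normalized_synchrony,
                              synchrony_matrix)
from tests.conftest import random_train


def grid_spike_distance(t1, t2, T, dt=1e-4):
    """Dense-grid trapezoid oracle for the SPIKE-distance.

    Evaluates the dissimilarity profile pointwise on a regular grid
    (midpoint sampling so grid points never sit on profile
    discontinuities) and averages — an independent numerical route to
    the same integral the implementation computes piecewise.
    """
    a1 = np.unique(np.concatenate(([0.0], t1, [T])))
    a2 = np.unique(np.concatenate(([0.0], t2, [T])))
    g = np.arange(0.0, T, dt) + dt / 2
    g = g[g < T]

    def nearest(arr, x):
        i = np.searchsorted(arr, x)
        lo = arr[np.clip(i - 1, 0, arr.size - 1)]
        hi = arr[np.clip(i, 0, arr.size - 1)]
        return np.minimum(np.abs(x - lo), np.abs(x - hi))

    def term(a, other):
        idx = np.searchsorted(a, g, side="right") - 1
        tp, tf = a[idx], a[idx + 1]
        xisi = tf - tp
        s = (nearest(other, tp) * (tf - g) + nearest(other, tf) * (g - tp)) / xisi
        return xisi, s

    x1, s1 = term(a1, a2)
    x2, s2 = term(a2, a1)
    S = (s1 * x2 + s2 * x1) / (2 * ((x1 + x2) / 2) ** 2)
    return float(np.mean(S))


class TestSpikeDistance:
    def test_identical_trains_zero(self, rng):
        t = np.sort(rng.uniform(0, 600, 50))
        assert spike_distance(t, t, 600.0) == 0.0

    def test_shifted_pair_matches_grid_oracle(self):
        t1 = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        t2 = t1 + 0.05
        d = spike_distance(t1, t2, 600.0)
        assert d == pytest.approx(grid_spike_distance(t1, t2, 600.0),
                                  abs=1e-4)
        assert 0 < d < 1

    def test_random_pairs_match_grid_oracle(self, rng):
        for _ in range(20):
            t1 = random_train(rng, 3.0, 10.0)
            t2 = random_train(rng, 3.0, 10.0)
            if t1.size == 0 or t2.size == 0:
                continue
            d = spike_distance(t1, t2, 10.0)
            assert d == pytest.approx(grid_spike_distance(t1, t2, 10.0),
                                      abs=1e-4)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            t1 = random_train(rng, 2.0, 30.0)
            t2 = random_train(rng, 4.0, 30.0)
            if t1.size == 0 or t2.size == 0:
                continue
            d12 = spike_distance(t1, t2, 30.0)
            assert d12 == spike_distance(t2, t1, 30.0)
            assert 0.0 <= d12 <= 1.0

    def test_distinct_trains_strictly_positive(self, rng):
        t1 = random_train(rng, 2.0, 60.0)
        t2 = random_train(rng, 2.0, 60.0)
        assert spike_distance(t1, t2, 60.0) > 0.0

    def test_empty_train_raises(self):
        with pytest.raises(DataError):
            spike_distance(np.array([]), np.array([1.0]), 10.0)

    def test_out_of_range_raises(self):
        with pytest.raises(DataError):
            spike_distance(np.array([11.0]), np.array([1.0]), 10.0)


class TestSurrogateNormalization:
    def test_identical_trains_synchrony_one(self, rng):
        t = np.sort(rng.uniform(0, 600, 20))
        cfg = SynchronyConfig(n_surrogates=5, recording_duration_s=600.0,
                              surrogate_seed=1)
        assert surrogate_normalized_synchrony(t, t, cfg) == 1.0

    def test_independent_poisson_pair_near_zero(self, rng):
        """An independent pair is surrogate-distributed, so unclamped
        synchrony sits within Monte-Carlo error of zero."""
        cfg = SynchronyConfig(n_surrogates=100, recording_duration_s=600.0,
                              surrogate_seed=2, clamp=False)
        t1 = random_train(rng, 2.0, 600.0)
        t2 = random_train(rng, 2.0, 600.0)
        s = surrogate_normalized_synchrony(t1, t2, cfg)
        assert abs(s) < 0.05

    def test_self_consistency_mean_near_zero(self, rng):
        """Feeding surrogate-distributed pairs returns synchrony with mean
        ~0 over repetitions (clamping off: the clamp would fold the
        negative half of the distribution to zero)."""
        cfg = SynchronyConfig(n_surrogates=50, recording_duration_s=60.0,
                              surrogate_seed=3, clamp=False)
        vals = []
        for k in range(200):
            t1 = np.sort(rng.uniform(0, 60.0, 30))
            t2 = np.sort(rng.uniform(0, 60.0, 30))
            vals.append(surrogate_normalized_synchrony(
                t1, t2, cfg, rng=pair_rng(3, k, k + 1)))
        assert abs(np.mean(vals)) < 0.02

    def test_jittered_copy_pair_strongly_synchronous(self):
        rng = np.random.default_rng(21)
        mother = random_train(rng, 3.0, 600.0)
        t2 = np.sort(mother + rng.normal(0, 0.005, mother.size))
        t2 = t2[(t2 >= 0) & (t2 <= 600.0)]
        cfg = SynchronyConfig(n_surrogates=50, recording_duration_s=600.0,
                              surrogate_seed=4)
        assert surrogate_normalized_synchrony(mother, t2, cfg) > 0.5

    def test_mean_of_ratios_close_to_default(self, rng):
        t1 = random_train(rng, 2.0, 120.0)
        t2 = np.sort(t1 + rng.normal(0, 0.01, t1.size))
        t2 = t2[(t2 >= 0) & (t2 <= 120.0)]
        a = surrogate_normalized_synchrony(
            t1, t2, SynchronyConfig(n_surrogates=50,
                                    recording_duration_s=120.0,
                                    surrogate_seed=5))
        b = surrogate_normalized_synchrony(
            t1, t2, SynchronyConfig(n_surrogates=50,
                                    recording_duration_s=120.0,
                                    surrogate_seed=5,
                                    normalization="mean_of_ratios"))
        assert a == pytest.approx(b, abs=0.05)


class TestSynchronyMatrix:
    def _device(self, trains, duration=600.0):
        spikes = DeviceSpikes(trains=trains, duration_s=duration)
        return spikes

    def test_three_identical_trains_all_ones(self, rng):
        t = np.sort(rng.uniform(0, 600, 30))
        sync = synchrony_matrix(
            self._device({1: t, 2: t.copy(), 3: t.copy()}),
            SynchronyConfig(n_surrogates=5, surrogate_seed=0))
        assert np.allclose(sync.values, 1.0)
        assert sync.device_synchrony() == 1.0

    def test_two_electrodes_device_synchrony_is_pair_value(self, rng):
        t1 = random_train(rng, 1.0, 600.0)
        t2 = random_train(rng, 1.0, 600.0)
        cfg = SynchronyConfig(n_surrogates=20, surrogate_seed=7)
        sync = synchrony_matrix(self._device({1: t1, 2: t2}), cfg)
        pair = surrogate_normalized_synchrony(t1, t2, cfg,
                                              rng=pair_rng(7, 1, 2))
        assert sync.device_synchrony() == pair

    def test_fixed_seed_bit_identical(self, rng):
        trains = {e: random_train(rng, 1.0, 120.0) for e in (1, 2, 3)}
        cfg = SynchronyConfig(n_surrogates=10, surrogate_seed=11,
                              recording_duration_s=120.0)
        a = synchrony_matrix(self._device(trains, 120.0), cfg)
        b = synchrony_matrix(self._device(trains, 120.0), cfg)
        assert np.array_equal(a.values, b.values)

    def test_single_active_electrode_flagged_undefined(self, rng):
        sync = synchrony_matrix(
            self._device({1: random_train(rng, 1.0, 600.0)}),
            SynchronyConfig(n_surrogates=5))
        assert np.isnan(sync.device_synchrony())

    def test_values_symmetric_in_unit_interval(self, assembly_device):
        spikes, _ = assembly_device
        sub = DeviceSpikes(
            trains={e: spikes.trains[e] for e in (1, 2, 11, 21)},
            duration_s=600.0)
        sync = synchrony_matrix(sub, SynchronyConfig(n_surrogates=10,
                                                     surrogate_seed=9))
        assert np.array_equal(sync.values, sync.values.T)
        assert np.all((sync.values >= 0) & (sync.values <= 1))
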