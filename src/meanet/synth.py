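"""Synthetic MEA recordings with known ground truth.

The generator emulates the statistical structure the analysis chain
assumes — tonic Poisson firing, burst episodes at a controlled rate,
synchronized assemblies built as jittered copies of a shared mother
train, and raw voltage traces of Gaussian noise plus injected biphasic
spike waveforms — so that spike detection, burst features, synchrony and
community detection can each be tested against planted truth.

All spike times are seconds, double precision, in [0, duration_s).
Identical :class:`~meanet.config.SimConfig` (including seed) yields
bit-identical output.
"""

from __future__ import annotations

import numpy as np

from meanet.config import ConfigError, SimConfig
from meanet.containers import DeviceSpikes, GroundTruth, RawRecording

# jittered copies closer than this are collapsed to one spike
# (physical refractoriness; keeps trains strictly increasing)
_DEDUP_GAP_S = 1e-4

# background spikes this close to a burst window are removed so the
# detector's max-end-ISI rule terminates generated bursts cleanly
_BURST_GUARD_S = 0.2


def _poisson_train(rng: np.random.Generator, rate_hz: float,
                   duration_s: float) -> np.ndarray:
    """Homogeneous Poisson train: Poisson count, uniform order statistics."""
    if rate_hz == 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _dedup(times: np.ndarray, min_gap: float = _DEDUP_GAP_S) -> np.ndarray:
    """Drop spikes closer than ``min_gap`` to their predecessor."""
    if times.size < 2:
        return times
    keep = np.empty(times.size, dtype=bool)
    keep[0] = True
    last = times[0]
    for i in range(1, times.size):
        if times[i] - last >= min_gap:
            keep[i] = True
            last = times[i]
        else:
            keep[i] = False
    return times[keep]


def simulate_poisson_device(cfg: SimConfig) -> tuple[DeviceSpikes, GroundTruth]:
    """Independent homogeneous Poisson train per electrode.

    The null model for synchrony and burst tests: no bursts, no
    correlations, spike counts with mean ``background_rate_hz x
    duration_s`` per electrode.
    """
    rng = np.random.default_rng(cfg.seed)
    trains = {e: _poisson_train(rng, cfg.background_rate_hz, cfg.duration_s)
              for e in range(1, cfg.n_electrodes + 1)}
    spikes = DeviceSpikes(trains=trains, duration_s=cfg.duration_s,
                          device_id=f"poisson-seed{cfg.seed}")
    truth = GroundTruth(
        spike_times={e: t.copy() for e, t in trains.items()},
        burst_windows={e: [] for e in trains},
        assembly_of={e: None for e in trains})
    return spikes, truth


def _place_burst_onsets(rng: np.random.Generator, n_bursts: int,
                        burst_len_s: float, min_gap_s: float,
                        duration_s: float, max_tries: int = 10_000,
                        ) -> np.ndarray:
    """Place ``n_bursts`` non-overlapping onsets uniformly in the recording.

    Onsets are drawn uniformly and offending ones resampled until every
    pair of consecutive bursts is separated by at least ``min_gap_s``
    (gap measured end-to-start) and every burst fits inside the
    recording. Drawing the count first and then placing keeps the
    expected burst count unbiased.
    """
    if n_bursts == 0:
        return np.empty(0)
    lo, hi = 0.0, duration_s - burst_len_s
    if hi <= 0 or n_bursts * (burst_len_s + min_gap_s) > duration_s:
        raise ConfigError(
            f"cannot fit {n_bursts} bursts of {burst_len_s:.3f} s with "
            f"{min_gap_s} s gaps into {duration_s} s")
    onsets = np.sort(rng.uniform(lo, hi, size=n_bursts))
    for _ in range(max_tries):
        gaps = np.diff(onsets) - burst_len_s
        bad = np.flatnonzero(gaps < min_gap_s)
        if bad.size == 0:
            return onsets
        # resample one offender and re-sort
        onsets[bad[0] + 1] = rng.uniform(lo, hi)
        onsets = np.sort(onsets)
    raise ConfigError("could not place non-overlapping bursts; "
                      "burst rate too high for the recording duration")


def simulate_bursting_train(cfg: SimConfig,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """One spike train with burst episodes over tonic background firing.

    Burst onsets form a Poisson process at ``burst_rate_per_min`` (count
    drawn first, onsets then placed without overlap and with >= 0.5 s
    inter-burst separation); each burst is ``spikes_per_burst`` spikes at
    ``intra_burst_isi_s`` spacing. Background spikes within 0.2 s of a
    burst window are removed so generated bursts satisfy the
    max-interval detector's parameters by construction.

    Returns the merged sorted spike times and the burst windows
    (first spike, last spike).
    """
    if cfg.burst_rate_per_min > 0:
        if cfg.spikes_per_burst < 10:
            raise ConfigError("spikes_per_burst must be >= 10 so generated "
                              "bursts satisfy the burst-detection parameters")
        if cfg.intra_burst_isi_s > 0.1:
            raise ConfigError("intra_burst_isi_s must be <= 0.1 s so generated "
                              "bursts satisfy the burst-detection parameters")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    burst_len = (cfg.spikes_per_burst - 1) * cfg.intra_burst_isi_s
    n_bursts = rng.poisson(cfg.burst_rate_per_min * cfg.duration_s / 60.0)
    onsets = _place_burst_onsets(rng, n_bursts, burst_len,
                                 min_gap_s=0.5 + _BURST_GUARD_S,
                                 duration_s=cfg.duration_s)
    windows = [(float(t0), float(t0 + burst_len)) for t0 in onsets]
    burst_spikes = (onsets[:, None]
                    + np.arange(cfg.spikes_per_burst) * cfg.intra_burst_isi_s
                    ).ravel() if n_bursts else np.empty(0)

    background = _poisson_train(rng, cfg.background_rate_hz, cfg.duration_s)
    if windows and background.size:
        keep = np.ones(background.size, dtype=bool)
        for a, b in windows:
            keep &= ~((background > a - _BURST_GUARD_S)
                      & (background < b + _BURST_GUARD_S))
        background = background[keep]

    times = _dedup(np.sort(np.concatenate([burst_spikes, background])))
    return times, windows


def simulate_bursting_device(cfg: SimConfig) -> tuple[DeviceSpikes, GroundTruth]:
    """A device of independent bursting electrodes (one substream each)."""
    root = np.random.default_rng(cfg.seed)
    streams = root.spawn(cfg.n_electrodes)
    trains, wins = {}, {}
    for e, stream in zip(range(1, cfg.n_electrodes + 1), streams):
        t, w = simulate_bursting_train(cfg, rng=stream)
        trains[e], wins[e] = t, w
    spikes = DeviceSpikes(trains=trains, duration_s=cfg.duration_s,
                          device_id=f"bursting-seed{cfg.seed}")
    truth = GroundTruth(spike_times={e: t.copy() for e, t in trains.items()},
                        burst_windows=wins,
                        assembly_of={e: None for e in trains})
    return spikes, truth


def simulate_assembly_device(cfg: SimConfig, mother_rate_hz: float = 3.0,
                             ) -> tuple[DeviceSpikes, GroundTruth]:
    """Planted synchronized assemblies (jittered-copy communities).

    One 'mother' Poisson train per assembly at ``mother_rate_hz``; each
    member electrode copies each mother spike with probability
    ``copy_prob`` plus Gaussian jitter (SD ``jitter_sd_s``), on top of
    independent background spikes at ``background_rate_hz``. Electrodes
    outside assemblies fire as independent Poisson at the background
    rate. Member electrodes of the same assembly are therefore highly
    synchronous; the assembly map is returned as ground truth for
    community-recovery tests.
    """
    if cfg.n_assemblies < 1:
        raise ConfigError("n_assemblies must be >= 1 for an assembly device")
    rng = np.random.default_rng(cfg.seed)
    trains: dict[int, np.ndarray] = {}
    assembly_of: dict[int, int | None] = {}
    electrode = 1
    for a in range(cfg.n_assemblies):
        mother = _poisson_train(rng, mother_rate_hz, cfg.duration_s)
        for _ in range(cfg.assembly_size):
            if cfg.copy_prob == 1.0 and cfg.jitter_sd_s == 0.0:
                copied = mother.copy()
            else:
                kept = mother[rng.uniform(size=mother.size) < cfg.copy_prob]
                copied = kept + rng.normal(0.0, cfg.jitter_sd_s, size=kept.size)
                copied = copied[(copied >= 0) & (copied < cfg.duration_s)]
            background = _poisson_train(rng, cfg.background_rate_hz,
                                        cfg.duration_s)
            t = _dedup(np.sort(np.concatenate([copied, background])))
            trains[electrode] = t
            assembly_of[electrode] = a
            electrode += 1
    while electrode <= cfg.n_electrodes:
        trains[electrode] = _poisson_train(rng, cfg.background_rate_hz,
                                           cfg.duration_s)
        assembly_of[electrode] = None
        electrode += 1
    spikes = DeviceSpikes(trains=trains, duration_s=cfg.duration_s,
                          device_id=f"assembly-seed{cfg.seed}")
    truth = GroundTruth(spike_times={e: t.copy() for e, t in trains.items()},
                        burst_windows={e: [] for e in trains},
                        assembly_of=assembly_of)
    return spikes, truth


def biphasic_template(sampling_rate_hz: float, width_s: float = 0.001,
                      ) -> np.ndarray:
    """Unit-amplitude biphasic spike waveform (negative then positive lobe).

    The negative lobe peaks at -1; the positive rebound reaches +0.4.
    Total width ~1 ms — the shape of an extracellular action potential
    recorded on a planar electrode, where the negative peak dominates.
    """
    n = max(int(round(width_s * sampling_rate_hz)), 4)
    n_neg = max(int(round(0.6 * n)), 2)
    n_pos = n - n_neg
    neg = np.sin(np.pi * np.arange(n_neg) / n_neg)
    neg = -neg / neg.max()                 # negative peak exactly -1
    pos = np.sin(np.pi * np.arange(n_pos) / max(n_pos, 1))
    pos = 0.4 * pos / max(pos.max(), 1e-12)
    return np.concatenate([neg, pos])


def simulate_raw_traces(spikes: DeviceSpikes, cfg: SimConfig) -> RawRecording:
    """Raw voltage traces: Gaussian noise plus injected spike waveforms.

    Each spike inserts a biphasic template (negative peak
    ``spike_amplitude_sd_units x noise_sd``, ~1 ms wide) at its spike
    time on its channel. The result is the test input for the
    threshold-crossing detector.
    """
    if cfg.spike_amplitude_sd_units <= 0:
        raise ConfigError("spike_amplitude_sd_units must be > 0")
    n_samples = round(cfg.duration_s * cfg.sampling_rate_hz)
    rng = np.random.default_rng(cfg.seed)
    template = biphasic_template(cfg.sampling_rate_hz)
    amp = cfg.spike_amplitude_sd_units * cfg.noise_sd
    channel_ids = spikes.electrode_ids
    traces = (rng.normal(0.0, cfg.noise_sd, size=(len(channel_ids), n_samples))
              if cfg.noise_sd > 0 else np.zeros((len(channel_ids), n_samples)))
    for row, e in enumerate(channel_ids):
        t = spikes.trains[e]
        if t.size and (t[0] < 0 or t[-1] > cfg.duration_s):
            raise ConfigError(f"electrode {e}: spike time outside recording")
        idx = np.round(t * cfg.sampling_rate_hz).astype(int)
        for i in idx:
            j = min(i + template.size, n_samples)
            traces[row, i:j] += amp * template[: j - i]
    return RawRecording(traces=traces, sampling_rate_hz=cfg.sampling_rate_hz,
                        duration_s=cfg.duration_s, channel_ids=channel_ids)
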