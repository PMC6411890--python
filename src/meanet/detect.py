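"""Spike detection and electrode quality control on raw MEA traces.

The chain mirrors standard MEA processing: per-electrode thresholding at
a multiple (default 5x) of the baseline-noise SD on negative-going
crossings, removal of noise artifacts coincident across (nearly) all
channels, and exclusion of noisy (>4000 spikes) and silent (<10 spikes)
electrodes from a 10-minute recording.

Baseline noise SD is estimated robustly as median(|x|)/0.6745 (the MAD
estimator for centred Gaussian noise), so that the spikes themselves do
not inflate the threshold.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from meanet.config import DataError, DetectionConfig
from meanet.containers import DeviceSpikes, RawRecording


def estimate_noise_sd(trace: np.ndarray) -> float:
    """Robust baseline-noise SD: median(|trace|)/0.6745.

    Consistent for centred Gaussian noise and insensitive to sparse
    large-amplitude spikes riding on it. An all-constant (e.g. all-zero)
    trace returns 0; the caller treats the resulting zero threshold as a
    degenerate input.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise DataError("empty trace")
    return float(np.median(np.abs(trace)) / 0.6745)


def bandpass_filter(trace: np.ndarray, sampling_rate_hz: float,
                    low_hz: float, high_hz: float) -> np.ndarray:
    """Optional 4th-order zero-phase Butterworth bandpass.

    Off by default in the pipeline: acquisition systems typically filter
    in hardware (e.g. 268-8036 Hz), and re-filtering already-filtered
    data is a no-op at best.
    """
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass",
                        fs=sampling_rate_hz, output="sos")
    return signal.sosfiltfilt(sos, trace)


def _detect_channel(trace: np.ndarray, sampling_rate_hz: float,
                    cfg: DetectionConfig) -> np.ndarray:
    """Negative threshold crossings with dead time; event = negative peak.

    An event starts where the voltage first crosses below
    -(multiplier x noise SD); detection is then suppressed for
    ``dead_time_s`` and the event time is the minimum of the trace
    within that window.
    """
    sd = estimate_noise_sd(trace)
    if sd == 0.0:
        if np.any(trace != trace[0]):
            raise DataError("zero noise estimate on a non-constant trace")
        warnings.warn("all-constant trace: zero threshold, no events detected",
                      stacklevel=3)
        return np.empty(0)
    thr = -cfg.threshold_sd_multiplier * sd
    below = trace < thr
    # first samples of each below-threshold excursion
    crossings = np.flatnonzero(below & ~np.concatenate(([False], below[:-1])))
    dead = max(int(round(cfg.dead_time_s * sampling_rate_hz)), 1)
    events = []
    i = 0
    n = trace.size
    while i < crossings.size:
        c = crossings[i]
        stop = min(c + dead, n)
        peak = c + int(np.argmin(trace[c:stop]))
        events.append(peak)
        # suppress further crossings inside the dead-time window
        i += 1
        while i < crossings.size and crossings[i] < stop:
            i += 1
    return np.asarray(events, dtype=float) / sampling_rate_hz


def detect_spikes(rec: RawRecording, cfg: DetectionConfig | None = None,
                  ) -> DeviceSpikes:
    """Threshold-crossing spike detection on every channel.

    Returns a :class:`DeviceSpikes` with all electrodes marked active
    (QC is a separate step).
    """
    cfg = cfg or DetectionConfig()
    if rec.sampling_rate_hz <= 0:
        raise DataError("sampling_rate_hz must be > 0")
    trains = {}
    for row, e in enumerate(rec.channel_ids):
        trace = rec.traces[row]
        if cfg.bandpass_hz is not None:
            trace = bandpass_filter(trace, rec.sampling_rate_hz,
                                    *cfg.bandpass_hz)
        trains[e] = _detect_channel(trace, rec.sampling_rate_hz, cfg)
    return DeviceSpikes(trains=trains, duration_s=rec.duration_s)


def remove_cross_channel_artifacts(spikes: DeviceSpikes,
                                   cfg: DetectionConfig | None = None,
                                   ) -> DeviceSpikes:
    """Delete events coincident across (nearly) all channels.

    An event is an artifact when electrodes on at least
    ``artifact_channel_fraction`` of all recorded channels have an event
    within ``+/- artifact_window_s`` of it; every coincident copy is
    removed. Electrical noise couples into all electrodes at once, so
    array-wide coincidence at sub-millisecond precision is essentially
    never biological.
    """
    cfg = cfg or DetectionConfig()
    ids = spikes.electrode_ids
    if len(ids) < 2:
        raise DataError("artifact removal needs >= 2 electrodes")
    w = cfg.artifact_window_s
    need = int(np.ceil(cfg.artifact_channel_fraction * len(ids)))
    trains = {e: spikes.trains[e] for e in ids}
    keep: dict[int, np.ndarray] = {}
    for e in ids:
        t = trains[e]
        if t.size == 0:
            keep[e] = t
            continue
        hits = np.zeros(t.size, dtype=int)
        for other in ids:
            to = trains[other]
            if to.size == 0:
                continue
            lo = np.searchsorted(to, t - w, side="left")
            hi = np.searchsorted(to, t + w, side="right")
            hits += (hi > lo)
        keep[e] = t[hits < need]
    return DeviceSpikes(trains=keep, duration_s=spikes.duration_s,
                        device_id=spikes.device_id, div=spikes.div,
                        qc_status=dict(spikes.qc_status))


def apply_electrode_qc(spikes: DeviceSpikes,
                       cfg: DetectionConfig | None = None) -> DeviceSpikes:
    """Mark noisy (>4000 spikes) and silent (<10 spikes) electrodes.

    The inequalities are strict: exactly 4000 or exactly 10 spikes keep
    an electrode active. Idempotent — previously excluded electrodes are
    re-evaluated from their counts, which never changes a decision.
    """
    cfg = cfg or DetectionConfig()
    status = {}
    for e, t in spikes.trains.items():
        n = t.size
        if n > cfg.noisy_max_spikes:
            status[e] = "noisy"
        elif n < cfg.silent_min_spikes:
            status[e] = "silent"
        else:
            status[e] = "active"
    return DeviceSpikes(trains=dict(spikes.trains), duration_s=spikes.duration_s,
                        device_id=spikes.device_id, div=spikes.div,
                        qc_status=status)


def percent_active_electrodes(spikes: DeviceSpikes,
                              total_electrodes: int | None = None) -> float:
    """Percentage of recorded electrodes passing QC.

    ``total_electrodes`` is the device's electrode count (60 on the
    target arrays); it defaults to the number of recorded electrodes so
    that partial recordings still give a sensible fraction.
    """
    total = (total_electrodes if total_electrodes is not None
             else len(spikes.qc_status))
    if total <= 0:
        raise DataError("zero recorded electrodes")
    return 100.0 * len(spikes.active_ids()) / total
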