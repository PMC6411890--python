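"""Burst detection (max-interval method) and the six activity features.

Bursts are found with the classic three-phase max-interval algorithm:

1. a candidate burst begins at the first spike of an inter-spike
   interval (ISI) <= ``max_begin_isi_s`` and extends while the ISI stays
   <= ``max_end_isi_s``;
2. candidate bursts whose gap is smaller than ``min_ibi_s`` are merged;
3. candidates shorter than ``min_burst_duration_s`` or with fewer than
   ``min_spikes_per_burst`` spikes are discarded.

The defaults (0.1 s / 0.2 s / 0.5 s / 0.05 s / 10 spikes) are the
standard parameter set for cortical cultures on MEAs.

The six features per active electrode: overall firing rate, mean ISI,
bursts per minute, % of spikes inside bursts, mean burst duration, and
mean inter-burst interval (IBI). Burst duration is last spike minus
first spike (unpadded); IBI is next burst's start minus current burst's
end. Device-level values are unweighted means over active electrodes
with a defined value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from meanet.config import BurstConfig, DataError
from meanet.containers import Burst, BurstSet, DeviceSpikes


def detect_bursts_train(train: np.ndarray,
                        cfg: BurstConfig | None = None) -> list[Burst]:
    """Max-interval burst detection on one sorted spike train."""
    cfg = cfg or BurstConfig()
    t = np.asarray(train, dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise DataError("spike train must be sorted")
    if t.size < 2:
        return []
    isi = np.diff(t)

    # phase 1: candidate runs
    candidates: list[tuple[int, int]] = []  # [first, last] spike indices
    i = 0
    n = t.size
    while i < n - 1:
        if isi[i] <= cfg.max_begin_isi_s:
            j = i + 1
            while j < n - 1 and isi[j] <= cfg.max_end_isi_s:
                j += 1
            candidates.append((i, j))
            i = j + 1
        else:
            i += 1

    # phase 2: merge candidates separated by < min_ibi_s
    merged: list[tuple[int, int]] = []
    for c in candidates:
        if merged and t[c[0]] - t[merged[-1][1]] < cfg.min_ibi_s:
            merged[-1] = (merged[-1][0], c[1])
        else:
            merged.append(c)

    # phase 3: minimum duration and spike count
    bursts = []
    for a, b in merged:
        n_spk = b - a + 1
        dur = t[b] - t[a]
        if n_spk >= cfg.min_spikes_per_burst and dur >= cfg.min_burst_duration_s:
            bursts.append(Burst(start_s=float(t[a]), end_s=float(t[b]),
                                n_spikes=n_spk))
    return bursts


def detect_bursts(spikes: DeviceSpikes | np.ndarray,
                  cfg: BurstConfig | None = None) -> BurstSet | list[Burst]:
    """Burst detection for a whole device (or a bare train).

    Given a :class:`DeviceSpikes`, returns a :class:`BurstSet` over its
    active electrodes; given a bare array of spike times, returns the
    burst list for that train.
    """
    if isinstance(spikes, DeviceSpikes):
        return BurstSet(bursts={e: detect_bursts_train(t, cfg)
                                for e, t in spikes.active_trains().items()})
    return detect_bursts_train(np.asarray(spikes), cfg)


def _electrode_features(t: np.ndarray, bursts: list[Burst],
                        duration_s: float) -> dict[str, float]:
    n = t.size
    row: dict[str, float] = {
        "n_spikes": float(n),
        "firing_rate_hz": n / duration_s,
        "mean_isi_s": float(np.mean(np.diff(t))) if n >= 2 else np.nan,
        "n_bursts": float(len(bursts)),
        "bursts_per_min": len(bursts) / (duration_s / 60.0),
    }
    if n > 0:
        in_burst = np.zeros(n, dtype=bool)
        for b in bursts:
            in_burst |= (t >= b.start_s) & (t <= b.end_s)
        row["pct_spikes_in_bursts"] = 100.0 * in_burst.sum() / n
    else:
        row["pct_spikes_in_bursts"] = np.nan
    row["mean_burst_duration_s"] = (
        float(np.mean([b.duration_s for b in bursts])) if bursts else np.nan)
    if len(bursts) >= 2:
        ibis = [bursts[k + 1].start_s - bursts[k].end_s
                for k in range(len(bursts) - 1)]
        row["mean_ibi_s"] = float(np.mean(ibis))
    else:
        row["mean_ibi_s"] = np.nan
    return row


FEATURE_COLUMNS = ["firing_rate_hz", "mean_isi_s", "bursts_per_min",
                   "pct_spikes_in_bursts", "mean_burst_duration_s",
                   "mean_ibi_s"]


def compute_features(spikes: DeviceSpikes, bursts: BurstSet | None = None,
                     cfg: BurstConfig | None = None) -> pd.DataFrame:
    """Feature table: one row per active electrode plus a device row.

    The device row (``electrode_id`` = 'device') is the unweighted mean
    over active electrodes with a defined value for each feature;
    electrodes without bursts contribute 0 to bursts/min and % spikes in
    bursts but are excluded from burst-duration/IBI means. Undefined
    values stay NaN (never zero) so they cannot bias aggregates.
    """
    if bursts is None:
        bursts = detect_bursts(spikes, cfg)
    active = spikes.active_trains()
    rows = []
    for e, t in active.items():
        row = _electrode_features(t, bursts.bursts.get(e, []),
                                  spikes.duration_s)
        row["electrode_id"] = e
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["electrode_id", "n_spikes", "n_bursts",
                                   *FEATURE_COLUMNS])
    device = {"electrode_id": "device",
              "n_spikes": df["n_spikes"].sum() if len(df) else 0.0,
              "n_bursts": df["n_bursts"].sum() if len(df) else 0.0}
    for col in FEATURE_COLUMNS:
        vals = df[col].dropna() if len(df) else []
        device[col] = float(np.mean(vals)) if len(vals) else np.nan
    device["n_active_electrodes"] = float(len(df))
    if len(df):
        df["n_active_electrodes"] = np.nan
        out = pd.concat([df, pd.DataFrame([device])], ignore_index=True)
    else:
        out = pd.DataFrame([device])
    cols = ["electrode_id", "n_spikes", "n_bursts", "n_active_electrodes",
            *FEATURE_COLUMNS]
    return out[cols]
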