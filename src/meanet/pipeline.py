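"""End-to-end device analysis and longitudinal study aggregation.

``run_device`` takes one device recording (raw traces or spike trains)
through the whole chain — detection, artifact removal, electrode QC,
burst features, surrogate-normalized synchrony, edge filtering, Louvain
communities — and emits one tidy study-table row per device per DIV:

    device_id, div, group, pct_active_electrodes, firing_rate_hz,
    mean_isi_s, bursts_per_min, pct_spikes_in_bursts,
    mean_burst_duration_s, mean_ibi_s, n_active_electrodes,
    device_synchrony, n_communities, n_singletons, modularity_q

Undefined quantities (a device with no measurable network, an electrode
with no bursts) stay NaN, never zero, so they cannot bias aggregates.
``aggregate_study`` then summarizes rows as mean and SEM per
(group, DIV) — the shape of a longitudinal multi-device MEA study.
Group-level inferential statistics are deliberately out of scope: the
tables are ready for any stats package.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from meanet.config import DataError, PipelineConfig
from meanet.containers import DeviceSpikes, RawRecording
from meanet.detect import (apply_electrode_qc, detect_spikes,
                           percent_active_electrodes,
                           remove_cross_channel_artifacts)
from meanet.features import FEATURE_COLUMNS, compute_features, detect_bursts
from meanet.network import build_graph, count_communities, louvain
from meanet.synchrony import synchrony_matrix

log = logging.getLogger("meanet")

ROW_COLUMNS = ["device_id", "div", "group", "pct_active_electrodes",
               *FEATURE_COLUMNS, "n_active_electrodes", "device_synchrony",
               "n_communities", "n_singletons", "modularity_q"]


def _empty_row(cfg: PipelineConfig) -> dict:
    row = {c: np.nan for c in ROW_COLUMNS}
    row.update(device_id=cfg.device_id, div=cfg.div, group=cfg.group)
    return row


def run_device(data: RawRecording | DeviceSpikes | str | Path,
               cfg: PipelineConfig | None = None) -> dict:
    """Analyze one device end-to-end; returns one study-table row.

    ``data`` may be a :class:`RawRecording`, a :class:`DeviceSpikes`, or
    a path (HDF5 for raw mode, CSV for spike mode). Identical config and
    seed give bit-identical results. Intermediate files (QC report,
    burst set, feature table, synchrony matrix, partition) are written
    under ``cfg.out_dir`` when set.
    """
    cfg = cfg or PipelineConfig()
    t0 = time.perf_counter()
    if isinstance(data, (str, Path)):
        if cfg.input_mode == "raw":
            data = RawRecording.from_hdf5(data)
        else:
            data = DeviceSpikes.from_csv(
                data, duration_s=cfg.synchrony.recording_duration_s,
                device_id=cfg.device_id, div=cfg.div)

    if isinstance(data, RawRecording):
        log.info("detecting spikes on %d channels", data.n_channels)
        spikes = detect_spikes(data, cfg.detection)
    else:
        spikes = data
    spikes.device_id, spikes.div = cfg.device_id, cfg.div

    row = _empty_row(cfg)
    if len(spikes.trains) >= 2:
        spikes = remove_cross_channel_artifacts(spikes, cfg.detection)
    spikes = apply_electrode_qc(spikes, cfg.detection)
    row["pct_active_electrodes"] = percent_active_electrodes(
        spikes, total_electrodes=cfg.total_electrodes)

    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        spikes.to_csv(out / "spikes.csv")
        spikes.qc_report().to_csv(out / "qc_report.csv", index=False)

    bursts = detect_bursts(spikes, cfg.burst)
    features = compute_features(spikes, bursts)
    device_row = features[features["electrode_id"] == "device"].iloc[0]
    for col in FEATURE_COLUMNS + ["n_active_electrodes"]:
        row[col] = device_row[col]
    if out:
        bursts.to_csv(out / "bursts.csv")
        features.to_csv(out / "features.csv", index=False)

    if len(spikes.active_ids()) < 2:
        log.warning("%s: fewer than 2 active electrodes; no network measures",
                    cfg.device_id)
        return row

    sync = synchrony_matrix(spikes, cfg.synchrony)
    row["device_synchrony"] = sync.device_synchrony()
    if out:
        sync.to_csv(out / "synchrony.csv")

    graph = build_graph(sync, threshold=cfg.network.edge_filter_threshold)
    if graph.size(weight="weight") > 0:
        part = louvain(graph, seed=cfg.network.seed,
                       resolution=cfg.network.resolution,
                       restarts=cfg.network.restarts)
        row["n_communities"] = count_communities(
            part, count_singletons=cfg.network.count_singletons)
        row["n_singletons"] = part.n_singletons
        row["modularity_q"] = part.modularity_q
        if out:
            part.to_json(out / "partition.json")
    else:
        # every link filtered: all electrodes isolated, no community structure
        row["n_communities"] = 0
        row["n_singletons"] = graph.number_of_nodes()
        row["modularity_q"] = np.nan
    log.info("%s DIV %s done in %.1f s", cfg.device_id, cfg.div,
             time.perf_counter() - t0)
    return row


def aggregate_study(rows: pd.DataFrame | list[dict]) -> pd.DataFrame:
    """Mean and SEM per (group, DIV) over devices for every measure.

    SEM uses ddof=1 and is NaN for a single device (flagged missing, not
    zero). Returns a tidy table with one row per (group, div).
    """
    df = pd.DataFrame(rows)
    if df.empty:
        raise DataError("aggregate_study needs at least one device row")
    value_cols = [c for c in ROW_COLUMNS
                  if c not in ("device_id", "div", "group")]
    grouped = df.groupby(["group", "div"], dropna=False)[value_cols]
    mean = grouped.mean().add_suffix("_mean")
    sem = grouped.sem(ddof=1).add_suffix("_sem")
    n = grouped.size().rename("n_devices")
    return pd.concat([n, mean, sem], axis=1).reset_index()
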