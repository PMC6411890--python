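"""Data containers exchanged between pipeline stages, with file I/O.

On-disk formats are deliberately plain: spike trains travel as
long-format CSV (``electrode_id,spike_time_s``), raw traces as HDF5
(``/traces`` dataset with ``sampling_rate_hz`` / ``duration_s``
attributes), ground truth and partitions as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from meanet.config import DataError


def _as_train(times) -> np.ndarray:
    """Validate and return one spike train as a float64 array."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise DataError("spike train must be one-dimensional")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise DataError("spike times must be strictly increasing")
    return t


@dataclass
class RawRecording:
    """Multichannel voltage traces plus sampling metadata.

    ``traces`` is channels x samples in volts; ``channel_ids`` labels the
    electrodes (1-60 on the target devices).
    """

    traces: np.ndarray
    sampling_rate_hz: float
    duration_s: float
    channel_ids: list[int]

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise DataError("traces must be channels x samples")
        if len(self.channel_ids) != self.traces.shape[0]:
            raise DataError("channel_ids must match the number of trace rows")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise DataError("channel_ids must be unique")
        expected = round(self.duration_s * self.sampling_rate_hz)
        if self.traces.shape[1] != expected:
            raise DataError(
                f"samples ({self.traces.shape[1]}) != duration_s x sampling_rate_hz "
                f"({expected})")

    @property
    def n_channels(self) -> int:
        return self.traces.shape[0]

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("traces", data=self.traces)
            ds.attrs["sampling_rate_hz"] = self.sampling_rate_hz
            ds.attrs["duration_s"] = self.duration_s
            f.create_dataset("channel_ids", data=np.asarray(self.channel_ids))

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "RawRecording":
        with h5py.File(path, "r") as f:
            ds = f["traces"]
            traces = ds[()]
            rate = float(ds.attrs["sampling_rate_hz"])
            dur = float(ds.attrs["duration_s"])
            if "channel_ids" in f:
                ids = [int(i) for i in f["channel_ids"][()]]
            else:
                ids = list(range(1, traces.shape[0] + 1))
        return cls(traces=traces, sampling_rate_hz=rate, duration_s=dur,
                   channel_ids=ids)


@dataclass
class DeviceSpikes:
    """Per-electrode spike trains for one device at one DIV.

    The pipeline's central exchange object. ``qc_status`` maps each
    electrode to 'active', 'noisy', 'silent' or 'excluded'; before QC
    every recorded electrode is 'active'.
    """

    trains: dict[int, np.ndarray]
    duration_s: float
    device_id: str = "device"
    div: int | None = None
    qc_status: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.trains = {int(e): _as_train(t) for e, t in self.trains.items()}
        for e, t in self.trains.items():
            if t.size and (t[0] < 0 or t[-1] > self.duration_s):
                raise DataError(f"electrode {e}: spike times outside [0, duration_s]")
        if not self.qc_status:
            self.qc_status = {e: "active" for e in self.trains}

    @property
    def electrode_ids(self) -> list[int]:
        return sorted(self.trains)

    def active_ids(self) -> list[int]:
        return sorted(e for e, s in self.qc_status.items() if s == "active")

    def active_trains(self) -> dict[int, np.ndarray]:
        return {e: self.trains[e] for e in self.active_ids()}

    def spike_counts(self) -> dict[int, int]:
        return {e: int(t.size) for e, t in self.trains.items()}

    def to_csv(self, path: str | Path) -> None:
        rows = [(e, t) for e in self.electrode_ids for t in self.trains[e]]
        df = pd.DataFrame(rows, columns=["electrode_id", "spike_time_s"])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, duration_s: float,
                 device_id: str = "device", div: int | None = None,
                 ) -> "DeviceSpikes":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = {"electrode_id", "spike_time_s"} - set(df.columns)
        if missing:
            raise DataError(f"{path}: missing columns {sorted(missing)}")
        trains = {
            int(e): np.sort(g["spike_time_s"].to_numpy(float))
            for e, g in df.groupby("electrode_id")
        }
        return cls(trains=trains, duration_s=duration_s,
                   device_id=device_id, div=div)

    def qc_report(self) -> pd.DataFrame:
        counts = self.spike_counts()
        return pd.DataFrame(
            [(e, counts.get(e, 0), s) for e, s in sorted(self.qc_status.items())],
            columns=["electrode_id", "spike_count", "status"])


@dataclass
class GroundTruth:
    """Simulator ground truth for recovery tests."""

    spike_times: dict[int, np.ndarray]
    burst_windows: dict[int, list[tuple[float, float]]] = field(default_factory=dict)
    assembly_of: dict[int, int | None] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "spike_times": {str(e): list(map(float, t))
                            for e, t in self.spike_times.items()},
            "burst_windows": {str(e): [[float(a), float(b)] for a, b in w]
                              for e, w in self.burst_windows.items()},
            "assembly_of": {str(e): a for e, a in self.assembly_of.items()},
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        return cls(
            spike_times={int(e): np.asarray(t, float)
                         for e, t in obj["spike_times"].items()},
            burst_windows={int(e): [tuple(w) for w in ws]
                           for e, ws in obj["burst_windows"].items()},
            assembly_of={int(e): a for e, a in obj["assembly_of"].items()},
        )


@dataclass
class Burst:
    """One detected burst: window endpoints are spike times."""

    start_s: float
    end_s: float
    n_spikes: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class BurstSet:
    """Detected bursts per electrode."""

    bursts: dict[int, list[Burst]]

    def to_csv(self, path: str | Path) -> None:
        rows = [(e, b.start_s, b.end_s, b.n_spikes)
                for e in sorted(self.bursts) for b in self.bursts[e]]
        pd.DataFrame(rows, columns=["electrode_id", "start_s", "end_s", "n_spikes"]
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BurstSet":
        df = pd.read_csv(path)
        bursts: dict[int, list[Burst]] = {}
        for e, g in df.groupby("electrode_id"):
            bursts[int(e)] = [Burst(r.start_s, r.end_s, int(r.n_spikes))
                              for r in g.itertuples()]
        return cls(bursts=bursts)


@dataclass
class SynchronyMatrix:
    """Symmetric matrix of surrogate-normalized synchrony among active
    electrodes; diagonal fixed at 1."""

    electrode_ids: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.electrode_ids)
        if self.values.shape != (n, n):
            raise DataError("synchrony matrix shape must match electrode count")

    def device_synchrony(self) -> float:
        """Mean over off-diagonal upper-triangle entries; NaN if < 2 electrodes."""
        n = len(self.electrode_ids)
        if n < 2:
            return float("nan")
        iu = np.triu_indices(n, k=1)
        return float(np.mean(self.values[iu]))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.electrode_ids,
                     columns=self.electrode_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SynchronyMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls(electrode_ids=[int(c) for c in df.columns],
                   values=df.to_numpy(float))


@dataclass
class Partition:
    """Community assignment of electrodes plus its modularity score.

    ``n_communities`` counts communities with >= 2 members; singleton
    communities are reported separately in ``n_singletons``.
    """

    labels: dict[int, int]
    modularity_q: float

    @property
    def communities(self) -> list[list[int]]:
        groups: dict[int, list[int]] = {}
        for node, c in self.labels.items():
            groups.setdefault(c, []).append(node)
        return [sorted(g) for _, g in sorted(groups.items())]

    @property
    def n_communities(self) -> int:
        return sum(1 for g in self.communities if len(g) >= 2)

    @property
    def n_singletons(self) -> int:
        return sum(1 for g in self.communities if len(g) == 1)

    def to_json(self, path: str | Path) -> None:
        obj = {"labels": {str(e): int(c) for e, c in self.labels.items()},
               "modularity_q": self.modularity_q,
               "n_communities": self.n_communities,
               "n_singletons": self.n_singletons}
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Partition":
        obj = json.loads(Path(path).read_text())
        return cls(labels={int(e): int(c) for e, c in obj["labels"].items()},
                   modularity_q=float(obj["modularity_q"]))
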