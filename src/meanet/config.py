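"""Configuration objects for every pipeline stage, with validation.

All time quantities are in seconds, rates in Hz (except burst rates,
which follow the field's bursts-per-minute convention), voltages in
volts. Defaults encode the recording protocol the pipeline targets:
60-electrode MEAs, 10-minute recordings sampled at 22.3 kHz.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


class DataError(ValueError):
    """Raised when input data violate a structural precondition."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class SimConfig:
    """Parameters of the synthetic-recording generator.

    The generator emulates the statistical structure of cultured-network
    recordings: tonic (Poisson) background firing, burst episodes at a
    controlled rate, and synchronized assemblies built as jittered copies
    of a shared mother train.
    """

    n_electrodes: int = 60
    duration_s: float = 600.0
    sampling_rate_hz: float = 22300.0
    seed: int = 0
    background_rate_hz: float = 0.5
    burst_rate_per_min: float = 0.0
    spikes_per_burst: int = 15
    intra_burst_isi_s: float = 0.01
    n_assemblies: int = 0
    assembly_size: int = 0
    copy_prob: float = 0.9
    jitter_sd_s: float = 0.005
    noise_sd: float = 1e-5
    spike_amplitude_sd_units: float = 8.0

    def __post_init__(self) -> None:
        _require(self.n_electrodes >= 1, "n_electrodes must be >= 1")
        _require(self.duration_s > 0, "duration_s must be > 0")
        _require(self.sampling_rate_hz > 0, "sampling_rate_hz must be > 0")
        _require(self.background_rate_hz >= 0, "background_rate_hz must be >= 0")
        _require(self.burst_rate_per_min >= 0, "burst_rate_per_min must be >= 0")
        _require(0.0 <= self.copy_prob <= 1.0, "copy_prob must be in [0, 1]")
        _require(self.jitter_sd_s >= 0, "jitter_sd_s must be >= 0")
        _require(self.n_assemblies >= 0 and self.assembly_size >= 0,
                 "assembly counts must be >= 0")
        _require(self.n_assemblies * self.assembly_size <= self.n_electrodes,
                 "assemblies cannot cover more electrodes than the device has")


@dataclass
class DetectionConfig:
    """Spike detection and electrode QC parameters.

    ``threshold_sd_multiplier`` sets the lower-limit threshold at that
    multiple of the per-electrode baseline-noise SD (negative-going
    crossings only). Electrodes with more than ``noisy_max_spikes`` are
    marked noisy, fewer than ``silent_min_spikes`` silent; both are
    excluded downstream. The inequalities are strict, so counts of
    exactly 4000 or 10 remain active.
    """

    threshold_sd_multiplier: float = 5.0
    dead_time_s: float = 0.001
    artifact_window_s: float = 0.001
    artifact_channel_fraction: float = 0.9
    noisy_max_spikes: int = 4000
    silent_min_spikes: int = 10
    bandpass_hz: tuple[float, float] | None = None  # optional Butterworth re-filter

    def __post_init__(self) -> None:
        _require(self.threshold_sd_multiplier > 0,
                 "threshold_sd_multiplier must be > 0")
        _require(self.dead_time_s >= 0, "dead_time_s must be >= 0")
        _require(0 < self.artifact_channel_fraction <= 1,
                 "artifact_channel_fraction must be in (0, 1]")


@dataclass
class BurstConfig:
    """Max-interval burst-detection parameters (seconds / counts)."""

    max_begin_isi_s: float = 0.1
    max_end_isi_s: float = 0.2
    min_ibi_s: float = 0.5
    min_burst_duration_s: float = 0.05
    min_spikes_per_burst: int = 10

    def __post_init__(self) -> None:
        for f in fields(self):
            _require(getattr(self, f.name) > 0, f"{f.name} must be > 0")
        _require(self.max_begin_isi_s <= self.max_end_isi_s,
                 "max_begin_isi_s must be <= max_end_isi_s")


@dataclass
class SynchronyConfig:
    """Surrogate-normalized synchrony parameters.

    Normalization divides the observed SPIKE-distance by the mean
    distance over ``n_surrogates`` pairs of uniformly random trains with
    matched spike counts (``divide_by_mean_surrogate``); the alternative
    ``mean_of_ratios`` averages the per-surrogate ratios instead.
    Synchrony is 1 minus the normalized distance, clamped to [0, 1]
    when ``clamp`` is set.
    """

    n_surrogates: int = 1000
    recording_duration_s: float = 600.0
    surrogate_seed: int = 0
    normalization: str = "divide_by_mean_surrogate"
    clamp: bool = True
    edge_correction: bool = True

    def __post_init__(self) -> None:
        _require(self.n_surrogates >= 1, "n_surrogates must be >= 1")
        _require(self.recording_duration_s > 0, "recording_duration_s must be > 0")
        _require(self.normalization in ("divide_by_mean_surrogate", "mean_of_ratios"),
                 f"unknown normalization {self.normalization!r}")


@dataclass
class NetworkConfig:
    """Graph construction and community-detection parameters."""

    edge_filter_threshold: float = 0.10
    resolution: float = 1.0
    seed: int = 0
    restarts: int = 1
    count_singletons: bool = False

    def __post_init__(self) -> None:
        _require(0 <= self.edge_filter_threshold <= 1,
                 "edge_filter_threshold must be in [0, 1]")
        _require(self.restarts >= 1, "restarts must be >= 1")


@dataclass
class PipelineConfig:
    """End-to-end configuration for one device at one DIV.

    A single global seed propagates deterministic substreams to every
    stochastic stage (surrogates, Louvain node order).
    """

    device_id: str = "device"
    div: int | None = None
    input_mode: str = "spikes"  # "raw" or "spikes"
    group: str = ""
    out_dir: str | None = None
    seed: int = 0
    total_electrodes: int = 60
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    burst: BurstConfig = field(default_factory=BurstConfig)
    synchrony: SynchronyConfig = field(default_factory=SynchronyConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        _require(self.input_mode in ("raw", "spikes"),
                 f"input_mode must be 'raw' or 'spikes', got {self.input_mode!r}")
        self.synchrony.surrogate_seed = self.seed
        self.network.seed = self.seed


_NESTED = {"detection": DetectionConfig, "burst": BurstConfig,
           "synchrony": SynchronyConfig, "network": NetworkConfig}


def load_config(path: str | Path, kind: type = PipelineConfig) -> Any:
    """Load a config dataclass of type ``kind`` from a YAML file.

    Unknown keys raise :class:`ConfigError`; nested sections of a
    :class:`PipelineConfig` are parsed into their own dataclasses.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return config_from_dict(raw, kind)


def config_from_dict(raw: dict, kind: type = PipelineConfig) -> Any:
    valid = {f.name for f in fields(kind)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown config keys for {kind.__name__}: {sorted(unknown)}")
    kwargs = dict(raw)
    if kind is PipelineConfig:
        for key, sub in _NESTED.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = config_from_dict(kwargs[key], sub)
    if "bandpass_hz" in kwargs and isinstance(kwargs["bandpass_hz"], list):
        kwargs["bandpass_hz"] = tuple(kwargs["bandpass_hz"])
    return kind(**kwargs)


def config_to_dict(cfg: Any) -> dict:
    return asdict(cfg)
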