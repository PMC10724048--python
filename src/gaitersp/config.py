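"""Configuration objects for the simulator and the analysis pipeline.

The simulator is parameterized by the geometry of the walking task (a 6 m
path with motion sensors near its start that trigger obstacle projection),
the per-group walking-speed distributions, and the oscillatory effects to
embed (theta burst at obstacle appearance, planning-phase beta suppression,
post-crossing beta rebound and theta increase).  The parkinsonian-like group
receives a multiplicative attenuation of each effect.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Experimental conditions: free walking, obstacle visible from trial onset,
#: obstacle appearing only once the walker passes the laser beam.
CONDITIONS = ("no_adjustment", "preset", "online")

#: Group labels: parkinsonian-like and neurotypical-control-like.
GROUPS = ("PD", "NC")

#: Default 32-electrode 10-20 montage (includes all ROI channels).
DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "POz", "O1", "O2", "AF3", "AF4", "M1", "M2",
)

#: Per group x condition walking speed (mean, sd) in m/s.
DEFAULT_SPEEDS: dict[str, dict[str, tuple[float, float]]] = {
    "PD": {
        "no_adjustment": (0.81, 0.17),
        "preset": (0.82, 0.12),
        "online": (0.81, 0.15),
    },
    "NC": {
        "no_adjustment": (1.088, 0.07),
        "preset": (1.056, 0.14),
        "online": (1.158, 0.37),
    },
}


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class ThetaBurstParams:
    """Hann-windowed theta-band sinusoid injected at obstacle appearance.

    ``onset_s`` is relative to the approach event (the obstacle in the
    online condition appears when the walker breaks the laser beam).
    """

    center_freq: float = 6.0
    amplitude: float = 5.0  # uV
    onset_s: float = 0.0
    duration_s: float = 2.0


@dataclass
class AttenuationParams:
    """Multiplicative effect-size factors for the PD-like group (1 = no group difference)."""

    theta_burst: float = 1.0
    beta_suppression: float = 1.0
    beta_rebound: float = 1.0
    theta_resetting: float = 1.0

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic obstacle-avoidance walking cohort."""

    n_per_group: int = 15
    sampling_rate: float = 250.0
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    n_trials: int = 160
    n_blocks: int = 4
    path_length: float = 6.0          # m
    laser_offset: float = 0.5         # m from path start to the first laser beam
    obstacle_distance_preset: float = 2.5      # m from the laser beam
    obstacle_distances_online: tuple[float, ...] = (1.6, 3.1)
    speed: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(c) for g, c in DEFAULT_SPEEDS.items()}
    )
    speed_floor: float = 0.3          # m/s, truncation of the speed normal
    noise_exponent: float = 1.0       # 1/f slope of the background PSD
    noise_scale: float = 15.0         # uV RMS of the background
    gait_artifact_amplitude: float = 2.0  # uV, cadence-locked artifact
    step_length: float = 0.65         # m; cadence = speed / step_length
    theta_burst: ThetaBurstParams = field(default_factory=ThetaBurstParams)
    beta_suppression: float = -0.3    # fractional beta change approach->crossing
    beta_rebound: float = 0.4         # fractional beta change in [0, 0.6] s post-crossing
    beta_rebound_free_walk_scale: float = 0.5  # rebound scale in the no-obstacle condition
    theta_resetting: float = 0.3      # fractional theta change post-crossing
    reset_window_s: float = 0.6
    effect_ramp_s: float = 0.05       # raised-cosine ramp of effect windows
    attenuation: AttenuationParams = field(default_factory=AttenuationParams)
    inter_trial_gap_s: float = 2.0    # minimum gap; jitter added on top
    gap_jitter_s: float = 2.0
    lead_in_s: float = 6.0
    lead_out_s: float = 5.0
    seed: int = 0

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.obstacle_distances_online = tuple(self.obstacle_distances_online)
        if isinstance(self.theta_burst, Mapping):
            self.theta_burst = ThetaBurstParams(**self.theta_burst)
        if isinstance(self.attenuation, Mapping):
            self.attenuation = AttenuationParams(**self.attenuation)
        self.speed = {
            g: {c: tuple(ms) for c, ms in by_cond.items()}
            for g, by_cond in self.speed.items()
        }
        self.validate()

    def validate(self) -> None:
        if self.n_per_group < 1 or self.n_trials < 1 or self.n_blocks < 1:
            raise ConfigurationError("counts must be positive")
        for name in ("sampling_rate", "path_length", "laser_offset", "step_length",
                     "speed_floor", "reset_window_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.noise_exponent < 0:
            raise ConfigurationError("noise_exponent must be >= 0")
        if self.noise_scale < 0 or self.gait_artifact_amplitude < 0:
            raise ConfigurationError("amplitudes must be >= 0")
        if self.theta_burst.duration_s <= 0 or self.theta_burst.center_freq <= 0:
            raise ConfigurationError("theta burst frequency and duration must be > 0")
        if self.theta_burst.amplitude < 0:
            raise ConfigurationError("theta burst amplitude must be >= 0")
        for value in dataclasses.asdict(self.attenuation).values():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError("attenuation factors must lie in [0, 1]")
        distances = (self.obstacle_distance_preset, *self.obstacle_distances_online)
        for d in distances:
            if not 0 < d < self.path_length:
                raise ConfigurationError(
                    f"obstacle distance {d} m must lie inside the {self.path_length} m path"
                )
        if self.laser_offset >= self.path_length:
            raise ConfigurationError("laser_offset must be smaller than path_length")
        if set(self.speed) != set(GROUPS):
            raise ConfigurationError(f"speed must be configured for groups {GROUPS}")
        for group, by_cond in self.speed.items():
            if set(by_cond) != set(CONDITIONS):
                raise ConfigurationError(
                    f"speed[{group!r}] must be configured for conditions {CONDITIONS}"
                )
            for cond, (mean, sd) in by_cond.items():
                if mean <= self.speed_floor or sd <= 0:
                    raise ConfigurationError(
                        f"speed[{group!r}][{cond!r}]: mean must exceed the "
                        f"{self.speed_floor} m/s floor and sd must be > 0"
                    )
        if self.inter_trial_gap_s < 2.0:
            raise ConfigurationError("inter-trial gap must be at least 2 s")
        missing = [ch for roi in ROI_CHANNELS.values() for ch in roi
                   if ch not in self.channel_labels]
        if missing:
            raise ConfigurationError(f"channel_labels must include ROI channels, missing {missing}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["channel_labels"] = list(self.channel_labels)
        d["obstacle_distances_online"] = list(self.obstacle_distances_online)
        d["speed"] = {g: {c: list(ms) for c, ms in bc.items()} for g, bc in self.speed.items()}
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation config fields: {sorted(unknown)}")
        return cls(**data)


#: ROI channel sets used by the aggregation stage (kept here so the config
#: validator can assert the montage covers them).
ROI_CHANNELS: dict[str, tuple[str, ...]] = {
    "frontal": ("FC1", "FC2", "Fz"),
    "central": ("CP1", "CP2", "Cz"),
    "posterior": ("P3", "P4", "POz"),
}


@dataclass
class ProcessingConfig:
    """Epoching, rejection, time-frequency and ERSP parameters."""

    epoch_tmin: float = -5.0
    epoch_tmax: float = 3.0
    peak_to_peak_max_uV: float = 1000.0
    flat_min_uV: float = 0.1
    fmin: float = 3.0
    fmax: float = 40.0
    fstep: float = 1.0
    cycles_scale: float = 0.5         # n_cycles = clip(freq * scale, min, max)
    cycles_min: float = 3.0
    cycles_max: float = 10.0
    decim: int | None = None          # None -> coarsest grid with dt <= 50 ms
    baseline: tuple[float, float] = (-4.5, 2.0)
    warp_events: tuple[str, ...] = ("start", "approach")
    warp_pooling: str = "pooled"      # "pooled" | "per_condition"
    common_average: bool = False

    def __post_init__(self) -> None:
        self.baseline = tuple(self.baseline)
        self.warp_events = tuple(self.warp_events)
        if self.epoch_tmin >= self.epoch_tmax:
            raise ConfigurationError("epoch_tmin must be < epoch_tmax")
        if self.peak_to_peak_max_uV <= 0 or self.flat_min_uV <= 0:
            raise ConfigurationError("rejection thresholds must be > 0")
        if not 0 < self.fmin < self.fmax:
            raise ConfigurationError("need 0 < fmin < fmax")
        if self.warp_pooling not in ("pooled", "per_condition"):
            raise ConfigurationError("warp_pooling must be 'pooled' or 'per_condition'")


@dataclass
class StatsConfig:
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")


@dataclass
class PipelineConfig:
    """Top-level configuration: simulation + processing + stats + output."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    output_dir: str = "gaitersp_out"
    seed: int | None = None           # overrides simulation.seed when set

    def __post_init__(self) -> None:
        if isinstance(self.simulation, Mapping):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        if isinstance(self.processing, Mapping):
            self.processing = ProcessingConfig(**self.processing)
        if isinstance(self.stats, Mapping):
            self.stats = StatsConfig(**self.stats)
        if self.seed is not None:
            self.simulation.seed = int(self.seed)

    def to_dict(self) -> dict[str, Any]:
        return {
            "simulation": self.simulation.to_dict(),
            "processing": dataclasses.asdict(self.processing),
            "stats": dataclasses.asdict(self.stats),
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def config_hash(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
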