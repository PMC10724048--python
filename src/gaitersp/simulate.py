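"""Synthetic obstacle-avoidance walking EEG cohorts.

Generates continuous multi-channel recordings for two groups (PD-like and
neurotypical-control-like) walking a 6 m path under three conditions:
free walking (``no_adjustment``), an obstacle visible from trial onset
(``preset``), and an obstacle triggered by a laser beam (``online``).
Trial timing follows the task geometry; the signal is 1/f background noise
plus a cadence-locked gait artifact and condition-dependent oscillatory
effects whose size is attenuated in the PD-like group:

* a theta burst at obstacle appearance (online condition),
* beta-band suppression while approaching an obstacle,
* a post-crossing beta rebound (all conditions, larger with an obstacle),
* a post-crossing theta increase.

The band-limited effects are realized by band-pass filtering the signal
itself and adding back a scaled, windowed copy, so that band variance over
an effect window changes by exactly ``(1 + gain)^2`` (up to filter leakage
and the short window ramps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .config import CONDITIONS, GROUPS, ConfigurationError, SimulationConfig

EVENT_COLUMNS = ["subject_id", "group", "trial_id", "block", "condition", "event_name", "onset"]

#: Band edges (Hz, inclusive) used for effect injection; identical to the
#: analysis bands downstream.
THETA_BAND = (4.0, 7.0)
BETA_BAND = (13.0, 35.0)


@dataclass
class TrialTiming:
    """Events of a single trial, in seconds from the trial's start event."""

    speed: float                       # m/s
    events: dict[str, float]           # start/approach[/crossing]/stop
    obstacle_distance: float | None    # m from laser beam; None without obstacle


@dataclass
class RecordingSession:
    """One subject's continuous multichannel recording (channels x samples, uV)."""

    subject_id: str
    group: str
    sampling_rate: float
    channel_labels: tuple[str, ...]
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channel_labels):
            raise ValueError("signal must be channels x samples matching channel_labels")
        if not np.isfinite(self.signal).all():
            raise ValueError("signal contains non-finite samples")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Cohort:
    """Materialized cohort: sessions plus one tidy event table."""

    config: SimulationConfig
    sessions: list[RecordingSession]
    events: pd.DataFrame = field(repr=False)

    def events_for(self, subject_id: str) -> pd.DataFrame:
        return self.events[self.events["subject_id"] == subject_id].reset_index(drop=True)


def sample_trial_timing(
    cfg: SimulationConfig, group: str, condition: str, rng: np.random.Generator
) -> TrialTiming:
    """Draw one trial's walking speed and event latencies.

    Speed is drawn from the configured group x condition normal, truncated
    below at ``cfg.speed_floor``.  The approach event marks the laser beam,
    ``laser_offset`` m into the path; the crossing event (obstacle
    conditions only) follows at the obstacle's distance from the beam.
    """
    if condition not in CONDITIONS:
        raise ConfigurationError(f"unknown condition {condition!r}")
    if group not in cfg.speed or condition not in cfg.speed[group]:
        raise ConfigurationError(f"no speed parameters for {group!r} x {condition!r}")
    mean, sd = cfg.speed[group][condition]
    if mean <= 0 or sd <= 0:
        raise ConfigurationError("speed parameters must be positive")
    # rejection sampling draws exactly from the truncated normal
    speed = rng.normal(mean, sd)
    while speed < cfg.speed_floor:
        speed = rng.normal(mean, sd)
    speed = float(speed)

    events = {"start": 0.0, "approach": cfg.laser_offset / speed,
              "stop": cfg.path_length / speed}
    if condition == "preset":
        d: float | None = cfg.obstacle_distance_preset
    elif condition == "online":
        d = float(rng.choice(np.asarray(cfg.obstacle_distances_online)))
    else:
        d = None
    if d is not None:
        events["crossing"] = events["approach"] + d / speed
    return TrialTiming(speed=speed, events=events, obstacle_distance=d)


def synthesize_background(
    n_channels: int,
    n_samples: int,
    fs: float,
    exponent: float,
    scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean channel-independent noise with a ``1/f**exponent`` PSD.

    The PSD follows the power law above 1 Hz and is held flat below it (the
    analysis band starts well above); ``scale`` sets the per-channel RMS in
    uV.  ``scale = 0`` returns exact zeros.
    """
    if exponent < 0:
        raise ConfigurationError("noise exponent must be >= 0")
    if n_samples <= fs:
        raise ConfigurationError("need at least one second of signal")
    if scale == 0.0:
        # still consume the stream so seeded runs are invariant to scale
        rng.standard_normal((n_channels, n_samples))
        return np.zeros((n_channels, n_samples))
    from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

    n_fft = next_fast_len(n_samples)
    white = rng.standard_normal((n_channels, n_samples))
    spec = rfft(white, n=n_fft, axis=1)
    freqs = rfftfreq(n_fft, 1.0 / fs)
    amp = np.maximum(freqs, 1.0) ** (-exponent / 2.0)
    amp[0] = 0.0
    spec *= amp
    out = irfft(spec, n=n_fft, axis=1)[:, :n_samples]
    out -= out.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.einsum("ij,ij->i", out, out) / n_samples)[:, None]
    rms[rms == 0] = 1.0
    return out / rms * scale


_window_cache: dict[tuple[int, int], np.ndarray] = {}


def _effect_window(n: int, ramp_n: int) -> np.ndarray:
    """Flat window with raised-cosine ramps (Tukey); ramps shrink for short windows."""
    ramp_n = min(ramp_n, n // 2)
    key = (n, ramp_n)
    if key not in _window_cache:
        if len(_window_cache) > 4096:
            _window_cache.clear()
        if ramp_n == 0:
            _window_cache[key] = np.ones(n)
        else:
            _window_cache[key] = sps.windows.tukey(n, alpha=2.0 * ramp_n / n)
    return _window_cache[key]


def _band_sos(band: tuple[float, float], fs: float):
    hi = min(band[1], 0.45 * fs)
    return sps.butter(4, (band[0], hi), btype="bandpass", fs=fs, output="sos")


def inject_effects(
    sig: np.ndarray,
    events: pd.DataFrame,
    group: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    *,
    copy: bool = True,
) -> np.ndarray:
    """Add gait artifact and group-attenuated oscillatory effects in place.

    ``events`` holds one subject's trials (tidy: trial_id, condition,
    event_name, onset in seconds from recording onset).  Free-walking trials
    carry no crossing event; their post-crossing effects are anchored to
    ``approach + 2.0 s``, matching the virtual crossing marker added during
    analysis.
    """
    fs = cfg.sampling_rate
    n = sig.shape[1]
    out = sig.copy() if copy else sig
    att = cfg.attenuation if group == "PD" else None

    def factor(name: str) -> float:
        return getattr(att, name) if att is not None else 1.0

    wide = (events.drop_duplicates(["trial_id", "event_name"])
            .pivot(index="trial_id", columns="event_name", values="onset"))
    cond_by_trial = events.drop_duplicates("trial_id").set_index("trial_id")["condition"]

    # Band-limited copies of the raw signal (before any multiplicative
    # modulation) used to realize fractional band-amplitude changes.
    need_beta = cfg.beta_suppression != 0 or cfg.beta_rebound != 0
    need_theta_mod = cfg.theta_resetting != 0
    base32 = out.astype(np.float32)  # band extraction in single precision
    x_beta = sps.sosfiltfilt(_band_sos(BETA_BAND, fs), base32, axis=1) if need_beta else None
    x_theta = (sps.sosfiltfilt(_band_sos(THETA_BAND, fs), base32, axis=1)
               if need_theta_mod else None)
    del base32

    ramp_n = int(round(cfg.effect_ramp_s * fs))

    def add_band_gain(x_band: np.ndarray, t0: float, t1: float, gain: float, trial: int) -> None:
        if gain == 0.0:
            return
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        if i0 < 0 or i1 > n or i1 <= i0:
            raise ValueError(
                f"trial {trial}: effect interval [{t0:.3f}, {t1:.3f}] s outside recording"
            )
        out[:, i0:i1] += gain * x_band[:, i0:i1] * _effect_window(i1 - i0, ramp_n)

    for trial_id, row in wide.iterrows():
        condition = cond_by_trial.loc[trial_id]
        start, approach, stop = row["start"], row["approach"], row["stop"]
        has_obstacle = condition in ("preset", "online")
        crossing = row.get("crossing", np.nan)
        anchor_cross = crossing if np.isfinite(crossing) else approach + 2.0

        # (i) theta burst at obstacle appearance -- online condition only
        if condition == "online" and cfg.theta_burst.amplitude > 0:
            amp = cfg.theta_burst.amplitude * factor("theta_burst")
            t_on = approach + cfg.theta_burst.onset_s
            dur = cfg.theta_burst.duration_s
            i0, i1 = int(round(t_on * fs)), int(round((t_on + dur) * fs))
            if i0 < 0 or i1 > n:
                raise ValueError(f"trial {trial_id}: theta burst window outside recording")
            t = np.arange(i1 - i0) / fs
            taper = np.hanning(i1 - i0)
            phases = rng.uniform(0, 2 * np.pi, size=out.shape[0])
            burst = amp * taper * np.sin(
                2 * np.pi * cfg.theta_burst.center_freq * t[None, :] + phases[:, None]
            )
            out[:, i0:i1] += burst

        if has_obstacle and not np.isfinite(crossing):
            raise ValueError(f"trial {trial_id}: obstacle trial lacks a crossing event")

        # (ii) planning beta suppression over approach -> crossing
        if has_obstacle and cfg.beta_suppression != 0:
            add_band_gain(x_beta, approach, crossing,
                          cfg.beta_suppression * factor("beta_suppression"), trial_id)

        # (iii) post-crossing beta rebound, all conditions
        if cfg.beta_rebound != 0:
            gain = cfg.beta_rebound * factor("beta_rebound")
            if not has_obstacle:
                gain *= cfg.beta_rebound_free_walk_scale
            add_band_gain(x_beta, anchor_cross, anchor_cross + cfg.reset_window_s,
                          gain, trial_id)

        # (iv) post-crossing theta increase
        if cfg.theta_resetting != 0:
            add_band_gain(x_theta, anchor_cross, anchor_cross + cfg.reset_window_s,
                          cfg.theta_resetting * factor("theta_resetting"), trial_id)

        # (v) cadence-locked gait artifact throughout walking
        if cfg.gait_artifact_amplitude > 0:
            speed = cfg.path_length / (stop - start)
            step_freq = speed / cfg.step_length
            i0, i1 = int(round(start * fs)), int(round(stop * fs))
            if i0 < 0 or i1 > n:
                raise ValueError(f"trial {trial_id}: walking interval outside recording")
            t = np.arange(i1 - i0) / fs
            ph = rng.uniform(0, 2 * np.pi, size=(2, out.shape[0]))
            w = _effect_window(i1 - i0, ramp_n)
            art = cfg.gait_artifact_amplitude * (
                np.sin(2 * np.pi * step_freq * t[None, :] + ph[0][:, None])
                + 0.3 * np.sin(4 * np.pi * step_freq * t[None, :] + ph[1][:, None])
            )
            out[:, i0:i1] += art * w

    return out


def _condition_sequence(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Near-equal allocation of trials to conditions, shuffled per subject."""
    base = [CONDITIONS[i % len(CONDITIONS)] for i in range(cfg.n_trials)]
    order = rng.permutation(cfg.n_trials)
    return [base[i] for i in order]


def simulate_subject(
    cfg: SimulationConfig, group: str, subject_id: str, seed: np.random.SeedSequence
) -> tuple[RecordingSession, pd.DataFrame]:
    """Generate one subject's continuous recording and event table."""
    rng = np.random.default_rng(seed)
    conditions = _condition_sequence(cfg, rng)
    block_len = int(np.ceil(cfg.n_trials / cfg.n_blocks))

    rows: list[dict] = []
    cursor = cfg.lead_in_s
    for trial_id, condition in enumerate(conditions):
        timing = sample_trial_timing(cfg, group, condition, rng)
        block = trial_id // block_len + 1
        for name in ("start", "approach", "crossing", "stop"):
            if name not in timing.events:
                continue
            rows.append({
                "subject_id": subject_id, "group": group, "trial_id": trial_id,
                "block": block, "condition": condition, "event_name": name,
                "onset": cursor + timing.events[name],
            })
        gap = cfg.inter_trial_gap_s + rng.uniform(0.0, cfg.gap_jitter_s)
        cursor += timing.events["stop"] + gap
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events = events.sort_values(["trial_id", "onset"], kind="stable").reset_index(drop=True)

    n_samples = int(np.ceil((cursor - cfg.inter_trial_gap_s + cfg.lead_out_s)
                            * cfg.sampling_rate))
    sig = synthesize_background(cfg.n_channels, n_samples, cfg.sampling_rate,
                                cfg.noise_exponent, cfg.noise_scale, rng)
    sig = inject_effects(sig, events, group, cfg, rng, copy=False)
    session = RecordingSession(
        subject_id=subject_id, group=group, sampling_rate=cfg.sampling_rate,
        channel_labels=cfg.channel_labels, signal=sig,
    )
    return session, events


def subject_plan(cfg: SimulationConfig) -> list[tuple[str, str, np.random.SeedSequence]]:
    """Deterministic (group, subject_id, seed) roster for a cohort."""
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(2 * cfg.n_per_group)
    plan = []
    i = 0
    for group in GROUPS:
        for k in range(cfg.n_per_group):
            plan.append((group, f"{group}{k + 1:02d}", children[i]))
            i += 1
    return plan


def iter_cohort(cfg: SimulationConfig):
    """Yield ``(session, events)`` per subject without holding the cohort in memory."""
    for group, subject_id, seed in subject_plan(cfg):
        yield simulate_subject(cfg, group, subject_id, seed)


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Materialize a full cohort; a pure function of the config (incl. seed)."""
    sessions: list[RecordingSession] = []
    tables: list[pd.DataFrame] = []
    for session, events in iter_cohort(cfg):
        sessions.append(session)
        tables.append(events)
    events = pd.concat(tables, ignore_index=True)
    return Cohort(config=cfg, sessions=sessions, events=events)
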