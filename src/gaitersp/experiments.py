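"""End-to-end in-memory cohort analyses and simulation studies.

``analyze_cohort`` runs the full chain for one synthetic cohort without
touching disk: simulate -> virtual crossing -> epoch -> reject ->
single-trial spectrograms -> time-warp to pooled median latencies -> ERSP ->
band x ROI x window table -> split-plot ANOVAs (planning and resetting,
per band) plus the walking-speed analysis.

The module also defines the scaled-down study configuration used for effect
recovery experiments (15 subjects per group, 40 trials, 128 Hz, nine ROI
electrodes, 2 Hz frequency grid) and sweep helpers that repeat the analysis
over many seeded cohorts to estimate detection and false-positive rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregate import (BANDS, PLANNING_WINDOWS, RESETTING_WINDOWS, WindowSpec,
                        build_band_power_table, make_windows)
from .config import ROI_CHANNELS, ProcessingConfig, SimulationConfig
from .epochs import (add_virtual_crossing, compute_walking_speed, epoch_around_crossing,
                     mean_speed_table, reject_epochs)
from .simulate import iter_cohort, sample_trial_timing
from .spectral import TFParams, compute_ersp, compute_median_latencies, compute_spectrograms, time_warp
from .stats import MixedAnovaResult, analyze_speed, mixed_anova

#: The nine ROI electrodes, the minimal montage the aggregation stage needs.
ROI_ONLY_CHANNELS = tuple(ch for roi in ROI_CHANNELS.values() for ch in roi)


@dataclass
class CohortAnalysis:
    """Everything the pipeline computes for one cohort."""

    band_table: pd.DataFrame
    speed_trials: pd.DataFrame
    speed_means: pd.DataFrame
    anovas: dict[tuple[str, str], MixedAnovaResult]
    speed_anova: MixedAnovaResult
    speed_tests: pd.DataFrame
    windows: list[WindowSpec]
    median_latencies: dict[str, float]
    counts: pd.DataFrame
    ersps: list = field(default_factory=list, repr=False)


def warp_anchor_pairs(
    rel_latencies: dict[str, float],
    targets: dict[str, float],
    tmin: float,
    warp_events: tuple[str, ...],
) -> tuple[list[float], list[float]]:
    """Anchor pairs for one trial; events outside the epoch are skipped."""
    a_from, a_to = [], []
    for name in warp_events:
        src = rel_latencies.get(name)
        dst = targets.get(name)
        if src is None or dst is None:
            continue
        if src <= tmin or dst <= tmin or src >= 0 or dst >= 0:
            continue
        a_from.append(src)
        a_to.append(dst)
    return a_from, a_to


def phase_anova(
    band_table: pd.DataFrame, phase: str, band: str, subject: str = "subject_id"
) -> MixedAnovaResult:
    """Split-plot ANOVA of one band in one task phase.

    Within factors: condition x time window (four planning or two resetting
    windows) x ROI; between factor: group.
    """
    windows = PLANNING_WINDOWS if phase == "planning" else RESETTING_WINDOWS
    sub = band_table[(band_table["band"] == band)
                     & (band_table["window"].isin(windows))]
    return mixed_anova(sub, dv="mean_dB", within=["condition", "window", "roi"],
                       between="group", subject=subject)


def analyze_cohort(
    sim_cfg: SimulationConfig,
    proc: ProcessingConfig | None = None,
    keep_ersps: bool = False,
) -> CohortAnalysis:
    """Simulate one cohort and run the full analysis chain in memory."""
    proc = proc or ProcessingConfig()
    params = TFParams.from_processing(proc, sim_cfg.sampling_rate)

    all_specs = []           # per-subject lists of (possibly large) spectrograms
    all_events = []
    count_rows = []
    for session, events in iter_cohort(sim_cfg):
        if proc.common_average:
            from .epochs import common_average_reference

            session = common_average_reference(session)
        all_events.append(events)
        events = add_virtual_crossing(events)
        epochs, drop_log = epoch_around_crossing(session, events,
                                                 proc.epoch_tmin, proc.epoch_tmax)
        kept, rej_log = reject_epochs(epochs, proc.peak_to_peak_max_uV, proc.flat_min_uV)
        count_rows.append({
            "subject_id": session.subject_id, "group": session.group,
            "n_trials": sim_cfg.n_trials, "n_dropped": len(drop_log),
            "n_rejected": len(epochs) - len(kept), "n_kept": len(kept),
        })
        specs = compute_spectrograms(kept, params)
        for s in specs:
            if s.values.dtype != np.float32:
                s.values = s.values.astype(np.float32)   # bound cohort memory
        all_specs.append(specs)

    flat = [s for specs in all_specs for s in specs]
    medians = {name: compute_median_latencies(flat, name) for name in ("start", "approach")}
    windows = make_windows(medians["start"])
    if proc.warp_pooling == "per_condition":
        targets_by_cond = {
            cond: {name: compute_median_latencies(
                [x for x in flat if x.condition == cond], name)
                for name in proc.warp_events}
            for cond in {x.condition for x in flat}
        }
    else:
        pooled = {name: medians[name] for name in proc.warp_events}
        targets_by_cond = None

    ersps = []
    for specs in all_specs:
        by_cond: dict[str, list] = {}
        for s in specs:
            tg = targets_by_cond[s.condition] if targets_by_cond is not None else pooled
            a_from, a_to = warp_anchor_pairs(s.rel_latencies, tg,
                                             float(s.times[0]), proc.warp_events)
            warped = time_warp(s, a_from, a_to) if a_from else s
            by_cond.setdefault(s.condition, []).append(warped)
        for cond_specs in by_cond.values():
            ersps.append(compute_ersp(cond_specs, baseline=proc.baseline))

    band_table = build_band_power_table(ersps, windows)

    events = pd.concat(all_events, ignore_index=True)
    speed_trials = compute_walking_speed(events, sim_cfg.path_length)
    speed_means = mean_speed_table(speed_trials)
    speed_anova, speed_tests = analyze_speed(speed_means)

    anovas = {(phase, band): phase_anova(band_table, phase, band)
              for phase in ("planning", "resetting") for band in BANDS}

    return CohortAnalysis(
        band_table=band_table, speed_trials=speed_trials, speed_means=speed_means,
        anovas=anovas, speed_anova=speed_anova, speed_tests=speed_tests,
        windows=windows, median_latencies=medians,
        counts=pd.DataFrame(count_rows),
        ersps=ersps if keep_ersps else [],
    )


# ---------------------------------------------------------------------------
# Scaled-down recovery studies
# ---------------------------------------------------------------------------

def reduced_study_config(seed: int, theta_attenuation: float = 0.5,
                         **overrides) -> SimulationConfig:
    """Scaled-down study conditions for repeated cohort simulation.

    15 subjects per group, 40 trials each, 128 Hz, the nine ROI electrodes.
    ``theta_attenuation`` scales the PD-like group's theta burst (0.5 for
    the effect study, 1.0 for the null).
    """
    base = dict(
        n_per_group=15, sampling_rate=128.0, channel_labels=ROI_ONLY_CHANNELS,
        n_trials=40, seed=seed,
        attenuation={"theta_burst": theta_attenuation, "beta_suppression": 1.0,
                     "beta_rebound": 1.0, "theta_resetting": 1.0},
    )
    base.update(overrides)
    return SimulationConfig(**base)


def reduced_processing() -> ProcessingConfig:
    """2 Hz frequency grid over 3-39 Hz; ~47 ms spectrogram time step."""
    return ProcessingConfig(fstep=2.0, decim=6)


def cohort_seeds(base_seed: int, n_cohorts: int) -> list[int]:
    state = np.random.SeedSequence(base_seed).generate_state(n_cohorts, np.uint32)
    return [int(s % (2**31)) for s in state]


def recovery_record(analysis: CohortAnalysis, alpha: float = 0.05) -> dict:
    """Per-cohort summary quantities used by the simulation studies."""
    theta_plan = analysis.anovas[("planning", "theta")]
    bt = analysis.band_table
    t5_beta = bt[(bt["band"] == "beta") & (bt["roi"] == "central")
                 & (bt["window"] == "T5")]
    cond_means = t5_beta.groupby("condition")["mean_dB"].mean()
    obstacle = float(cond_means[["preset", "online"]].mean())
    free = float(cond_means["no_adjustment"])
    # between-group t-tests on resetting beta (null calibration check)
    from .stats import posthoc_tests

    beta_reset = bt[(bt["band"] == "beta") & (bt["roi"] == "central")
                    & (bt["window"].isin(["T5", "T6"]))]
    group_tests = posthoc_tests(
        beta_reset.groupby(["subject_id", "group", "window"], as_index=False)["mean_dB"].mean(),
        [{"label": w, "kind": "independent",
          "a": {"group": "NC", "window": w}, "b": {"group": "PD", "window": w}}
         for w in ("T5", "T6")],
        dv="mean_dB", correction="none",
    )
    return {
        "p_theta_condition_group": theta_plan.p("condition:group"),
        "theta_interaction_significant": theta_plan.p("condition:group") < alpha,
        "t5_beta_obstacle_mean_dB": obstacle,
        "t5_beta_free_mean_dB": free,
        "t5_beta_positive_and_larger": obstacle > 0 and obstacle > free,
        "p_beta_t5_group": float(group_tests.loc[group_tests["contrast"] == "T5",
                                                 "p_raw"].iloc[0]),
        "p_beta_t6_group": float(group_tests.loc[group_tests["contrast"] == "T6",
                                                 "p_raw"].iloc[0]),
        "p_speed_group": analysis.speed_anova.p("group"),
    }


def run_recovery_sweep(
    n_cohorts: int,
    base_seed: int,
    theta_attenuation: float,
    alpha: float = 0.05,
    progress: bool = False,
) -> pd.DataFrame:
    """Repeat the scaled-down cohort analysis over seeded replicates."""
    rows = []
    for i, seed in enumerate(cohort_seeds(base_seed, n_cohorts)):
        cfg = reduced_study_config(seed, theta_attenuation=theta_attenuation)
        analysis = analyze_cohort(cfg, reduced_processing())
        rec = recovery_record(analysis, alpha)
        rec["cohort"] = i
        rec["seed"] = seed
        rows.append(rec)
        if progress and (i + 1) % 10 == 0:
            print(f"  cohort {i + 1}/{n_cohorts}", flush=True)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Walking-speed simulation study (timing only; no EEG needed)
# ---------------------------------------------------------------------------

def simulate_speed_table(
    cfg: SimulationConfig,
    n_pd: int,
    n_nc: int,
    rng: np.random.Generator,
    trials_per_condition: int = 53,
) -> pd.DataFrame:
    """Per-subject per-condition mean walking speed for an unequal-n cohort.

    Speeds are recovered from simulated start/stop event timestamps, not
    read off the sampled values, so the timing arithmetic is exercised.
    """
    rows = []
    for group, n_sub in (("PD", n_pd), ("NC", n_nc)):
        for k in range(n_sub):
            sid = f"{group}{k + 1:02d}"
            ev_rows = []
            trial = 0
            for cond in cfg.speed[group]:
                for _ in range(trials_per_condition):
                    timing = sample_trial_timing(cfg, group, cond, rng)
                    for name in ("start", "stop"):
                        ev_rows.append({"subject_id": sid, "group": group,
                                        "trial_id": trial, "condition": cond,
                                        "event_name": name,
                                        "onset": trial * 20.0 + timing.events[name]})
                    trial += 1
            ev = pd.DataFrame(ev_rows)
            rows.append(mean_speed_table(compute_walking_speed(ev, cfg.path_length)))
    return pd.concat(rows, ignore_index=True)


def run_speed_study(
    n_sims: int,
    base_seed: int,
    null: bool = False,
    n_pd: int = 14,
    n_nc: int = 17,
    alpha: float = 0.05,
    trials_per_condition: int = 12,
) -> pd.DataFrame:
    """Group-effect p-values over repeated speed cohorts.

    Under ``null=True`` both groups share the control-group speed
    distributions, so rejections are pure type-I errors.
    """
    cfg = SimulationConfig()
    if null:
        cfg = dataclasses.replace(cfg)
        cfg.speed = {"PD": dict(cfg.speed["NC"]), "NC": dict(cfg.speed["NC"])}
    rows = []
    for i, seed in enumerate(cohort_seeds(base_seed, n_sims)):
        rng = np.random.default_rng(seed)
        table = simulate_speed_table(cfg, n_pd, n_nc, rng,
                                     trials_per_condition=trials_per_condition)
        anova, _ = analyze_speed(table)
        p = anova.p("group")
        rows.append({"sim": i, "seed": seed, "p_group": p,
                     "significant_001": p < 0.001, "significant_alpha": p < alpha})
    return pd.DataFrame(rows)
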