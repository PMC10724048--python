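"""Stage-wise, file-based orchestration of the full analysis.

Stages (each resumable from the previous stage's persisted artifacts):

``simulate``    EDF recordings + events.tsv + JSON sidecars per subject
``preprocess``  virtual crossings, epoching, rejection; epochs as .npz;
                rejection/dropped logs; walking-speed tables
``ersp``        single-trial spectrograms, pooled median latencies,
                time-warping, per subject x condition ERSPs (.npy + JSON)
``aggregate``   band x ROI x window table (tidy CSV)
``stats``       split-plot ANOVAs + post hoc tests (JSON + CSV) and
                diagnostic figures

Given identical config and seed, every CSV/JSON artifact is byte-identical
across runs (the run log carries timing and is excluded from that
guarantee).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import edf
from .aggregate import BANDS, build_band_power_table, make_windows
from .config import GROUPS, PipelineConfig
from .epochs import (TrialEpoch, add_virtual_crossing, compute_walking_speed,
                     epoch_around_crossing, mean_speed_table, reject_epochs)
from .experiments import phase_anova
from .simulate import iter_cohort
from .spectral import (ERSPResult, Spectrogram, TFParams, compute_ersp,
                       compute_median_latencies, compute_spectrograms, time_warp)
from .stats import analyze_speed

logger = logging.getLogger("gaitersp")

STAGES = ("simulate", "preprocess", "ersp", "aggregate", "stats")


def _ensure_dir(path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    return path


def _float_fmt(df: pd.DataFrame) -> str:
    return df.to_csv(index=False, lineterminator="\n")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.write_text(_float_fmt(df))


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _subject_ids(out: Path) -> list[str]:
    return sorted(p.stem.replace("_eeg", "") for p in (out / "raw").glob("*_eeg.edf"))


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    raw = _ensure_dir(out / "raw")
    n = 0
    for session, events in iter_cohort(cfg.simulation):
        sid = session.subject_id
        edf.write_edf(session, raw / f"{sid}_eeg.edf")
        edf.write_sidecar(session, raw / f"{sid}_eeg.json", seed=cfg.simulation.seed)
        edf.write_events_tsv(events, raw / f"{sid}_events.tsv")
        n += 1
    _write_json(cfg.to_dict(), out / "config_used.json")
    logger.info("simulate: wrote %d subjects to %s", n, raw)


def _load_subject(out: Path, sid: str):
    raw = out / "raw"
    session = edf.read_session(raw / f"{sid}_eeg.edf", raw / f"{sid}_eeg.json")
    events = edf.read_events_tsv(raw / f"{sid}_events.tsv", session.subject_id,
                                 session.group)
    return session, events


def stage_preprocess(cfg: PipelineConfig, out: Path) -> None:
    proc = cfg.processing
    epo_dir = _ensure_dir(out / "epochs")
    rej_logs, drop_logs, speeds = [], [], []
    for sid in _subject_ids(out):
        session, events = _load_subject(out, sid)
        if proc.common_average:
            from .epochs import common_average_reference

            session = common_average_reference(session)
        speeds.append(compute_walking_speed(events, cfg.simulation.path_length))
        events = add_virtual_crossing(events)
        epochs, drop_log = epoch_around_crossing(session, events,
                                                 proc.epoch_tmin, proc.epoch_tmax)
        kept, rej_log = reject_epochs(epochs, proc.peak_to_peak_max_uV, proc.flat_min_uV)
        drop_logs.append(drop_log)
        rej_logs.append(rej_log)
        if not kept:
            raise RuntimeError(f"preprocess: no epochs survived for {sid}")
        np.savez(
            epo_dir / f"{sid}_epochs.npz",
            data=np.stack([ep.data for ep in kept]).astype(np.float32),
            trial_id=np.array([ep.trial_id for ep in kept]),
            condition=np.array([ep.condition for ep in kept]),
            rel_start=np.array([ep.rel_latencies.get("start", np.nan) for ep in kept]),
            rel_approach=np.array([ep.rel_latencies.get("approach", np.nan) for ep in kept]),
            sfreq=session.sampling_rate, tmin=proc.epoch_tmin, tmax=proc.epoch_tmax,
            group=session.group, channel_labels=np.array(session.channel_labels),
        )
        logger.info("preprocess: %s kept %d/%d epochs", sid, len(kept), len(epochs))
    _write_csv(pd.concat(rej_logs, ignore_index=True), out / "rejection_log.tsv")
    _write_csv(pd.concat(drop_logs, ignore_index=True)
               if drop_logs and any(len(d) for d in drop_logs)
               else pd.DataFrame(columns=["subject_id", "trial_id", "condition", "reason"]),
               out / "dropped_log.tsv")
    trial_speeds = pd.concat(speeds, ignore_index=True)
    _write_csv(trial_speeds, out / "trial_speeds.csv")
    _write_csv(mean_speed_table(trial_speeds), out / "mean_speeds.csv")


def _load_epochs(out: Path, sid: str) -> list[TrialEpoch]:
    z = np.load(out / "epochs" / f"{sid}_epochs.npz", allow_pickle=False)
    labels = tuple(str(c) for c in z["channel_labels"])
    epochs = []
    for i in range(z["data"].shape[0]):
        rel = {}
        if np.isfinite(z["rel_start"][i]):
            rel["start"] = float(z["rel_start"][i])
        if np.isfinite(z["rel_approach"][i]):
            rel["approach"] = float(z["rel_approach"][i])
        epochs.append(TrialEpoch(
            subject_id=sid, group=str(z["group"]), condition=str(z["condition"][i]),
            trial_id=int(z["trial_id"][i]), sfreq=float(z["sfreq"]),
            channel_labels=labels, data=z["data"][i].astype(np.float64),
            rel_latencies=rel, tmin=float(z["tmin"]), tmax=float(z["tmax"]),
        ))
    return epochs


def stage_ersp(cfg: PipelineConfig, out: Path) -> None:
    proc = cfg.processing
    ersp_dir = _ensure_dir(out / "ersp")
    sids = _subject_ids(out)
    per_subject: dict[str, list[Spectrogram]] = {}
    for sid in sids:
        epochs = _load_epochs(out, sid)
        params = TFParams.from_processing(proc, epochs[0].sfreq)
        specs = compute_spectrograms(epochs, params)
        for s in specs:
            s.values = s.values.astype(np.float32)
        per_subject[sid] = specs
    flat = [s for specs in per_subject.values() for s in specs]
    medians = {name: compute_median_latencies(flat, name)
               for name in ("start", "approach")}
    _write_json(medians, out / "median_latencies.json")

    def targets_for(condition: str) -> dict[str, float]:
        if proc.warp_pooling == "per_condition":
            pool = [s for s in flat if s.condition == condition]
            return {name: compute_median_latencies(pool, name)
                    for name in proc.warp_events}
        return {name: medians[name] for name in proc.warp_events}

    from .experiments import warp_anchor_pairs

    n_written = 0
    for sid, specs in per_subject.items():
        by_cond: dict[str, list[Spectrogram]] = {}
        for s in specs:
            a_from, a_to = warp_anchor_pairs(s.rel_latencies, targets_for(s.condition),
                                             float(s.times[0]), proc.warp_events)
            warped = time_warp(s, a_from, a_to) if a_from else s
            by_cond.setdefault(s.condition, []).append(warped)
        for condition, cond_specs in by_cond.items():
            ersp = compute_ersp(cond_specs, baseline=proc.baseline)
            np.save(ersp_dir / f"{sid}_{condition}_ersp.npy",
                    ersp.values.astype(np.float64))
            _write_json({
                "subject_id": ersp.subject_id, "group": ersp.group,
                "condition": ersp.condition, "n_trials": ersp.n_trials,
                "baseline": list(ersp.baseline), "edge_s": ersp.edge_s,
                "channel_labels": list(ersp.channel_labels),
                "freqs": [float(f) for f in ersp.freqs],
                "times": [float(t) for t in ersp.times],
            }, ersp_dir / f"{sid}_{condition}_ersp.json")
            n_written += 1
    logger.info("ersp: wrote %d subject x condition ERSPs", n_written)


def load_ersp(ersp_dir: Path, sid: str, condition: str) -> ERSPResult:
    meta = json.loads((ersp_dir / f"{sid}_{condition}_ersp.json").read_text())
    values = np.load(ersp_dir / f"{sid}_{condition}_ersp.npy")
    return ERSPResult(
        subject_id=meta["subject_id"], group=meta["group"], condition=meta["condition"],
        channel_labels=tuple(meta["channel_labels"]), freqs=np.array(meta["freqs"]),
        times=np.array(meta["times"]), values=values, n_trials=meta["n_trials"],
        baseline=tuple(meta["baseline"]), edge_s=meta["edge_s"],
    )


def _all_ersps(out: Path) -> list[ERSPResult]:
    ersp_dir = out / "ersp"
    items = sorted(p.stem.replace("_ersp", "") for p in ersp_dir.glob("*_ersp.npy"))
    out_list = []
    for item in items:
        sid, condition = item.split("_", 1)
        out_list.append(load_ersp(ersp_dir, sid, condition))
    return out_list


def stage_aggregate(cfg: PipelineConfig, out: Path) -> None:
    medians = json.loads((out / "median_latencies.json").read_text())
    windows = make_windows(medians["start"])
    ersps = _all_ersps(out)
    table = build_band_power_table(ersps, windows)
    _write_csv(table, out / "band_power.csv")
    _write_json([w.__dict__ for w in windows], out / "windows.json")
    logger.info("aggregate: %d rows from %d ERSPs", len(table), len(ersps))


def _anova_records(result) -> list[dict]:
    recs = result.table.replace([np.inf, -np.inf], None).to_dict(orient="records")
    for r in recs:
        for key, val in r.items():
            if isinstance(val, float) and not np.isfinite(val):
                r[key] = None
    return recs


def stage_stats(cfg: PipelineConfig, out: Path, figures: bool = True) -> None:
    table = pd.read_csv(out / "band_power.csv")
    speed_means = pd.read_csv(out / "mean_speeds.csv")
    results = {}
    flat_rows = []
    for phase in ("planning", "resetting"):
        for band in BANDS:
            res = phase_anova(table, phase, band)
            results[f"{phase}_{band}"] = _anova_records(res)
            for rec in _anova_records(res):
                flat_rows.append({"analysis": f"{phase}_{band}", **rec})
    speed_anova, speed_tests = analyze_speed(speed_means)
    results["speed"] = _anova_records(speed_anova)
    results["speed_posthoc"] = speed_tests.to_dict(orient="records")
    for rec in _anova_records(speed_anova):
        flat_rows.append({"analysis": "speed", **rec})
    _write_json(results, out / "stats.json")
    _write_csv(pd.DataFrame(flat_rows), out / "stats.csv")
    if figures:
        try:
            _write_figures(out, table)
        except Exception as exc:  # figures are diagnostics, never fatal
            logger.warning("figure generation failed: %s", exc)
    logger.info("stats: wrote %d analyses", len(results))


def _write_figures(out: Path, band_table: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = _ensure_dir(out / "figures")
    ersps = _all_ersps(out)

    # condition x group average ERSP heatmaps for a representative channel
    for channel in ("Fz", "Cz", "POz"):
        fig, axes = plt.subplots(len(GROUPS), 3, figsize=(12, 6), sharex=True,
                                 sharey=True, squeeze=False)
        for gi, group in enumerate(GROUPS):
            for ci, condition in enumerate(("no_adjustment", "preset", "online")):
                sel = [e for e in ersps if e.group == group and e.condition == condition]
                ax = axes[gi][ci]
                if not sel:
                    ax.set_axis_off()
                    continue
                ch = sel[0].channel_labels.index(channel)
                data = np.mean([e.values[ch] for e in sel], axis=0)
                t, f = sel[0].times, sel[0].freqs
                im = ax.pcolormesh(t, f, data, shading="auto", cmap="RdBu_r",
                                   vmin=-3, vmax=3)
                ax.axvline(0.0, color="k", lw=0.8)
                ax.set_title(f"{group} / {condition}", fontsize=9)
        fig.colorbar(im, ax=axes, label="dB vs baseline")
        fig.suptitle(f"Average time-warped ERSP at {channel}")
        fig.savefig(fig_dir / f"ersp_{channel}.png", dpi=110)
        plt.close(fig)

    # ROI bar charts of band power per condition and group
    for band in BANDS:
        sub = band_table[band_table["band"] == band]
        agg = (sub.groupby(["group", "condition", "roi", "window"])["mean_dB"]
               .agg(["mean", "sem"]).reset_index())
        fig, axes = plt.subplots(1, 3, figsize=(13, 4), sharey=True)
        for ax, roi in zip(axes, ("frontal", "central", "posterior")):
            roi_data = agg[agg["roi"] == roi]
            windows = sorted(roi_data["window"].unique())
            x = np.arange(len(windows))
            width = 0.12
            for i, (group, condition) in enumerate(
                [(g, c) for g in GROUPS for c in ("no_adjustment", "preset", "online")]
            ):
                cell = roi_data[(roi_data["group"] == group)
                                & (roi_data["condition"] == condition)]
                cell = cell.set_index("window").reindex(windows)
                ax.bar(x + (i - 2.5) * width, cell["mean"], width,
                       yerr=cell["sem"], label=f"{group} {condition}", capsize=2)
            ax.set_xticks(x, windows)
            ax.set_title(roi)
            ax.axhline(0, color="k", lw=0.5)
        axes[0].set_ylabel("dB vs baseline")
        axes[-1].legend(fontsize=7)
        fig.suptitle(f"{band} band power by ROI and time window")
        fig.tight_layout()
        fig.savefig(fig_dir / f"band_{band}.png", dpi=110)
        plt.close(fig)


def run_full_pipeline(
    config: PipelineConfig | str | Path,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    stages: tuple[str, ...] = STAGES,
    figures: bool = True,
) -> Path:
    """Run the requested stages; returns the output directory."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    if seed is not None:
        config.seed = seed
        config.simulation.seed = int(seed)
    out = Path(out_dir) if out_dir is not None else Path(config.output_dir)
    _ensure_dir(out)

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("config hash %s, seed %s", config.config_hash(),
                     config.simulation.seed)
        for stage in stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
            t0 = time.time()
            fn = {
                "simulate": stage_simulate, "preprocess": stage_preprocess,
                "ersp": stage_ersp, "aggregate": stage_aggregate,
                "stats": lambda c, o: stage_stats(c, o, figures=figures),
            }[stage]
            try:
                fn(config, out)
            except Exception:
                logger.exception("stage %s failed", stage)
                raise
            logger.info("stage %s finished in %.1f s", stage, time.time() - t0)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
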