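"""Crossing-locked epoching, virtual crossing markers, rejection, walking speed.

Epochs span the half-open window [-5.0, +3.0) s around the obstacle
crossing event (time 0), i.e. exactly ``8 * fs`` samples.  Free-walking
trials receive a virtual crossing at ``approach + 2.0 s`` so that all three
conditions share a common time lock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import RecordingSession

EPOCH_TMIN = -5.0
EPOCH_TMAX = 3.0
VIRTUAL_CROSSING_DELAY_S = 2.0


@dataclass
class TrialEpoch:
    """One trial's channels x samples window locked to the crossing event."""

    subject_id: str
    group: str
    condition: str
    trial_id: int
    sfreq: float
    channel_labels: tuple[str, ...]
    data: np.ndarray = field(repr=False)
    rel_latencies: dict[str, float] = field(default_factory=dict)
    tmin: float = EPOCH_TMIN
    tmax: float = EPOCH_TMAX
    included: bool = True
    rejection_reason: str | None = None

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        n_expected = int(round((self.tmax - self.tmin) * self.sfreq))
        if self.data.shape != (len(self.channel_labels), n_expected):
            raise ValueError(
                f"epoch data must be {len(self.channel_labels)} x {n_expected}, "
                f"got {self.data.shape}"
            )
        for name in ("start", "approach"):
            if name in self.rel_latencies and self.rel_latencies[name] >= 0:
                raise ValueError(f"{name} latency must precede the crossing")

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[1]
        return self.tmin + np.arange(n) / self.sfreq


def add_virtual_crossing(events: pd.DataFrame) -> pd.DataFrame:
    """Insert ``crossing = approach + 2.0 s`` into free-walking trials.

    Raises if a ``no_adjustment`` trial already carries a crossing event, so
    a second application fails loudly instead of silently double-shifting.
    """
    required = {"trial_id", "condition", "event_name", "onset"}
    if not required.issubset(events.columns):
        raise ValueError(f"event table must have columns {sorted(required)}")
    key_cols = [c for c in ("subject_id", "trial_id") if c in events.columns]
    free = events[events["condition"] == "no_adjustment"]
    if free.empty:
        return events.copy()
    bad = free[free["event_name"] == "crossing"]
    if not bad.empty:
        label = bad[key_cols].iloc[0].to_dict()
        raise ValueError(
            f"no_adjustment trial ({label}) already has a crossing event; "
            "was add_virtual_crossing applied twice?"
        )
    approach = free[free["event_name"] == "approach"]
    have_approach = set(map(tuple, approach[key_cols].itertuples(index=False)))
    all_free = set(map(tuple, free[key_cols].drop_duplicates().itertuples(index=False)))
    missing = all_free - have_approach
    if missing:
        raise ValueError(
            f"no_adjustment trials lacking an approach event: {sorted(missing)[:5]}"
        )
    virtual = approach.copy()
    virtual["event_name"] = "crossing"
    virtual["onset"] = virtual["onset"] + VIRTUAL_CROSSING_DELAY_S
    out = pd.concat([events, virtual], ignore_index=True)
    return out.sort_values(key_cols + ["onset"], kind="stable").reset_index(drop=True)


def epoch_around_crossing(
    session: RecordingSession,
    events: pd.DataFrame,
    tmin: float = EPOCH_TMIN,
    tmax: float = EPOCH_TMAX,
) -> tuple[list[TrialEpoch], pd.DataFrame]:
    """Cut one [tmin, tmax) epoch (default [-5, +3) s) per crossing event.

    Trials whose window exceeds the recording bounds are dropped and listed
    in the returned log (columns: subject_id, trial_id, condition, reason).
    """
    if "subject_id" in events.columns:
        subjects = set(events["subject_id"].unique())
        if subjects != {session.subject_id}:
            raise ValueError(
                f"event table is for {sorted(subjects)}, session is {session.subject_id}"
            )
    fs = session.sampling_rate
    n_pre = int(round(-tmin * fs))
    n_post = int(round(tmax * fs))
    wide = (events.drop_duplicates(["trial_id", "event_name"])
            .pivot(index="trial_id", columns="event_name", values="onset"))
    cond = events.drop_duplicates("trial_id").set_index("trial_id")["condition"]
    epochs: list[TrialEpoch] = []
    dropped: list[dict] = []
    for trial_id, row in wide.iterrows():
        crossing = row.get("crossing", np.nan)
        if not np.isfinite(crossing):
            raise ValueError(
                f"trial {trial_id} has no crossing event; run add_virtual_crossing first"
            )
        ic = int(round(crossing * fs))
        i0, i1 = ic - n_pre, ic + n_post
        if i0 < 0 or i1 > session.n_samples:
            dropped.append({
                "subject_id": session.subject_id, "trial_id": trial_id,
                "condition": cond.loc[trial_id],
                "reason": f"epoch window [{i0}, {i1}) exceeds recording bounds "
                          f"[0, {session.n_samples})",
            })
            continue
        rel = {name: float(row[name] - crossing)
               for name in ("start", "approach") if np.isfinite(row.get(name, np.nan))}
        epochs.append(TrialEpoch(
            subject_id=session.subject_id, group=session.group,
            condition=cond.loc[trial_id], trial_id=int(trial_id), sfreq=fs,
            channel_labels=session.channel_labels,
            data=session.signal[:, i0:i1].copy(), rel_latencies=rel,
            tmin=tmin, tmax=tmax,
        ))
    log = pd.DataFrame(dropped, columns=["subject_id", "trial_id", "condition", "reason"])
    return epochs, log


def common_average_reference(session: RecordingSession) -> RecordingSession:
    """Re-reference to the instantaneous mean across channels (optional)."""
    sig = session.signal - session.signal.mean(axis=0, keepdims=True)
    return RecordingSession(subject_id=session.subject_id, group=session.group,
                            sampling_rate=session.sampling_rate,
                            channel_labels=session.channel_labels, signal=sig)


def reject_epochs(
    epochs: list[TrialEpoch],
    peak_to_peak_max_uV: float = 1000.0,
    flat_min_uV: float = 0.1,
) -> tuple[list[TrialEpoch], pd.DataFrame]:
    """Deterministic amplitude-based trial rejection.

    An epoch is excluded when any channel's peak-to-peak amplitude exceeds
    ``peak_to_peak_max_uV`` (artifact) or falls below ``flat_min_uV`` (flat
    channel).  Stands in for the visual artifact screening used with real
    recordings; returns the kept epochs plus a per-trial decision log.
    """
    if peak_to_peak_max_uV <= 0 or flat_min_uV <= 0:
        raise ValueError("rejection thresholds must be > 0")
    kept: list[TrialEpoch] = []
    rows: list[dict] = []
    for ep in epochs:
        ptp = ep.data.max(axis=1) - ep.data.min(axis=1)
        reason = None
        if ptp.max() > peak_to_peak_max_uV:
            ch = ep.channel_labels[int(ptp.argmax())]
            reason = f"peak_to_peak {ptp.max():.1f} uV > {peak_to_peak_max_uV} uV on {ch}"
        elif ptp.min() < flat_min_uV:
            ch = ep.channel_labels[int(ptp.argmin())]
            reason = f"flat channel {ch}: peak_to_peak {ptp.min():.3g} uV < {flat_min_uV} uV"
        ep.included = reason is None
        ep.rejection_reason = reason
        rows.append({
            "subject_id": ep.subject_id, "trial_id": ep.trial_id,
            "condition": ep.condition,
            "decision": "keep" if ep.included else "reject",
            "reason": reason or "",
        })
        if ep.included:
            kept.append(ep)
    log = pd.DataFrame(rows, columns=["subject_id", "trial_id", "condition",
                                      "decision", "reason"])
    return kept, log


def compute_walking_speed(events: pd.DataFrame, path_length: float = 6.0) -> pd.DataFrame:
    """Per-trial walking speed: path length over the start->stop interval."""
    group_cols = [c for c in ("subject_id", "group") if c in events.columns]
    idx = group_cols + ["trial_id", "condition"]
    wide = (events.drop_duplicates(idx + ["event_name"])
            .pivot(index=idx, columns="event_name", values="onset"))
    if "start" not in wide.columns or "stop" not in wide.columns:
        raise ValueError("event table must contain start and stop events")
    missing = wide.index[wide["start"].isna() | wide["stop"].isna()]
    if len(missing):
        raise ValueError(f"trials missing start/stop events: {list(missing)[:5]}")
    dt = wide["stop"] - wide["start"]
    bad = wide.index[dt <= 0]
    if len(bad):
        raise ValueError(f"stop <= start in trials {list(bad)[:5]}")
    out = wide.reset_index()[group_cols + ["trial_id", "condition"]].copy()
    out["speed"] = (path_length / dt).to_numpy()
    return out


def mean_speed_table(trial_speeds: pd.DataFrame) -> pd.DataFrame:
    """Per-subject per-condition mean speed (the speed ANOVA's dependent variable)."""
    group_cols = [c for c in ("subject_id", "group") if c in trial_speeds.columns]
    return (trial_speeds.groupby(group_cols + ["condition"], sort=True)["speed"]
            .mean().reset_index())
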