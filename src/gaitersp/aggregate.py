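"""Reduce ERSPs to band x ROI x time-window means for the statistics.

Frequency bands are theta (4-7 Hz) and beta (13-35 Hz), both edges
inclusive.  ROIs are frontal (FC1, FC2, Fz), central (CP1, CP2, Cz) and
posterior (P3, P4, POz).  The planning phase [median start latency, 0) is
split into four equal consecutive windows T1-T4; the resetting phase is
covered by two 600 ms windows T5 [0, 0.6) and T6 [0.6, 1.2).  Window
membership is half-open, consistent with the epoching convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ROI_CHANNELS
from .spectral import ERSPResult

#: Analysis bands in Hz, inclusive on both edges.
BANDS: dict[str, tuple[float, float]] = {"theta": (4.0, 7.0), "beta": (13.0, 35.0)}

RESET_WINDOW_S = 0.6

BAND_POWER_COLUMNS = ["subject_id", "group", "condition", "band", "roi", "window", "mean_dB"]

PLANNING_WINDOWS = ("T1", "T2", "T3", "T4")
RESETTING_WINDOWS = ("T5", "T6")


@dataclass(frozen=True)
class WindowSpec:
    """Half-open [start, end) analysis window relative to the crossing."""

    phase: str   # "planning" | "resetting"
    label: str   # T1..T6
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window {self.label}: end must exceed start")


def make_windows(median_start_latency: float) -> list[WindowSpec]:
    """Partition the epoch into the six analysis windows.

    Planning spans [median start latency, 0) in four equal windows; the
    approach event falls inside the early planning windows under the
    default task geometry.  Resetting is two consecutive 600 ms windows
    after the crossing.
    """
    if median_start_latency >= 0:
        raise ValueError("the median start latency must precede the crossing (be < 0)")
    edges = np.linspace(median_start_latency, 0.0, 5)
    windows = [
        WindowSpec("planning", f"T{i + 1}", float(edges[i]), float(edges[i + 1]))
        for i in range(4)
    ]
    windows.append(WindowSpec("resetting", "T5", 0.0, RESET_WINDOW_S))
    windows.append(WindowSpec("resetting", "T6", RESET_WINDOW_S, 2 * RESET_WINDOW_S))
    return windows


def aggregate_power(
    ersp: ERSPResult,
    windows: Sequence[WindowSpec],
    bands: Mapping[str, tuple[float, float]] = BANDS,
    rois: Mapping[str, Sequence[str]] = ROI_CHANNELS,
) -> pd.DataFrame:
    """Mean ERSP (dB) per band x ROI x window for one subject x condition."""
    label_index = {ch: i for i, ch in enumerate(ersp.channel_labels)}
    roi_idx: dict[str, list[int]] = {}
    for roi, channels in rois.items():
        for ch in channels:
            if ch not in label_index:
                raise ValueError(f"ROI {roi!r} channel {ch!r} missing from the montage")
        roi_idx[roi] = [label_index[ch] for ch in channels]
    for band, (f0, f1) in bands.items():
        if not np.any((ersp.freqs >= f0) & (ersp.freqs <= f1)):
            raise ValueError(f"frequency axis does not cover the {band} band [{f0}, {f1}] Hz")

    rows = []
    for band, (f0, f1) in bands.items():
        fmask = (ersp.freqs >= f0) & (ersp.freqs <= f1)
        for roi, idx in roi_idx.items():
            sub = ersp.values[np.ix_(idx, np.flatnonzero(fmask))]
            for win in windows:
                tmask = (ersp.times >= win.start) & (ersp.times < win.end)
                if not tmask.any():
                    raise ValueError(f"window {win.label} contains no time samples")
                rows.append({
                    "subject_id": ersp.subject_id, "group": ersp.group,
                    "condition": ersp.condition, "band": band, "roi": roi,
                    "window": win.label,
                    "mean_dB": float(sub[:, :, tmask].mean()),
                })
    return pd.DataFrame(rows, columns=BAND_POWER_COLUMNS)


def build_band_power_table(
    ersps: Iterable[ERSPResult],
    windows: Sequence[WindowSpec],
    bands: Mapping[str, tuple[float, float]] = BANDS,
    rois: Mapping[str, Sequence[str]] = ROI_CHANNELS,
) -> pd.DataFrame:
    """Concatenate per-subject x condition aggregates into one tidy table."""
    parts = [aggregate_power(e, windows, bands, rois) for e in ersps]
    if not parts:
        raise ValueError("no ERSPs supplied")
    table = pd.concat(parts, ignore_index=True)
    validate_band_power_table(table)
    return table


def validate_band_power_table(table: pd.DataFrame) -> None:
    """Assert the table is fully crossed: one row per subject x condition x cell."""
    counts = table.groupby(
        ["subject_id", "condition", "band", "roi", "window"], sort=False
    ).size()
    if (counts != 1).any():
        dup = counts[counts != 1].index[:5].tolist()
        raise ValueError(f"band power table is not uniquely crossed at cells {dup}")
    n_sub = table["subject_id"].nunique()
    expected = (n_sub * table["condition"].nunique() * table["band"].nunique()
                * table["roi"].nunique() * table["window"].nunique())
    if len(table) != expected:
        raise ValueError(
            f"band power table incomplete: {len(table)} rows, expected {expected}"
        )
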