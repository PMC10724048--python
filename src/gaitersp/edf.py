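"""File interchange: EDF recordings, BIDS-style events.tsv, JSON sidecars.

Writing uses a minimal self-contained EDF encoder (16-bit samples, 1 s data
records, per-channel physical scaling); reading goes through
``mne.io.read_raw_edf`` so the written files are validated against an
independent parser.  The JSON sidecar carries subject identity, group,
sampling rate, the exact sample count (EDF pads the last record) and the
generator seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import EVENT_COLUMNS, RecordingSession

_DIG_MAX = 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ascii characters")
    return s.ljust(width).encode("ascii")


def write_edf(session: RecordingSession, path: str | Path) -> None:
    """Write a recording as 16-bit EDF (one data record per second)."""
    fs = session.sampling_rate
    if fs != int(fs):
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(fs)
    n_ch = len(session.channel_labels)
    n_records = int(np.ceil(session.n_samples / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, : session.n_samples] = session.signal

    pmax = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    scale = _DIG_MAX / pmax
    digital = np.round(padded * scale[:, None]).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii(f"{session.subject_id} group {session.group}", 80))
        fh.write(_ascii("gaitersp synthetic walking EEG", 80))
        fh.write(_ascii("01.01.01", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(256 * (n_ch + 1), 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(n_records, 8))
        fh.write(_ascii("1", 8))
        fh.write(_ascii(n_ch, 4))
        for label in session.channel_labels:
            fh.write(_ascii(label, 16))
        for _ in session.channel_labels:
            fh.write(_ascii("AgAgCl electrode", 80))
        for _ in session.channel_labels:
            fh.write(_ascii("uV", 8))
        for p in pmax:
            fh.write(_ascii(f"{-p:.6g}"[:8], 8))
        for p in pmax:
            fh.write(_ascii(f"{p:.6g}"[:8], 8))
        for _ in session.channel_labels:
            fh.write(_ascii(-_DIG_MAX, 8))
        for _ in session.channel_labels:
            fh.write(_ascii(_DIG_MAX, 8))
        for _ in session.channel_labels:
            fh.write(_ascii("", 80))
        for _ in session.channel_labels:
            fh.write(_ascii(fs, 8))
        for _ in session.channel_labels:
            fh.write(_ascii("", 32))
        # data records: per record, per signal, fs contiguous samples
        rec = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(rec).tobytes())


def write_sidecar(session: RecordingSession, path: str | Path, seed: int | None = None) -> None:
    meta = {
        "subject_id": session.subject_id,
        "group": session.group,
        "sampling_rate": session.sampling_rate,
        "n_samples": int(session.n_samples),
        "seed": seed,
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_session(edf_path: str | Path, sidecar_path: str | Path) -> RecordingSession:
    """Read an EDF + sidecar pair back into a RecordingSession (uV)."""
    import mne

    meta = json.loads(Path(sidecar_path).read_text())
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    n = int(meta["n_samples"])
    return RecordingSession(
        subject_id=meta["subject_id"], group=meta["group"],
        sampling_rate=float(meta["sampling_rate"]),
        channel_labels=tuple(raw.ch_names), signal=data[:, :n],
    )


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    """BIDS-style events table: onset, duration, trial_type, event_name, trial_id."""
    out = pd.DataFrame({
        "onset": events["onset"],
        "duration": 0.0,
        "trial_type": events["condition"],
        "event_name": events["event_name"],
        "trial_id": events["trial_id"],
        "block": events.get("block", pd.Series([1] * len(events))),
    })
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path: str | Path, subject_id: str, group: str) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    out = pd.DataFrame({
        "subject_id": subject_id,
        "group": group,
        "trial_id": tab["trial_id"],
        "block": tab.get("block", 1),
        "condition": tab["trial_type"],
        "event_name": tab["event_name"],
        "onset": tab["onset"],
    })
    return out[EVENT_COLUMNS]
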