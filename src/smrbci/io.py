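"""File I/O: EDF export/import, trial tables, seed sidecars.

EDF export is a minimal 16-bit writer (physical units µV, 1 s data
records); reading goes through MNE's native EDF reader, which also serves
as an independent round-trip check in the test suite.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .recording import EEGRecording
from .task import RunResult, SessionResult


# ---------------------------------------------------------------------------
# EDF


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: EEGRecording, path, patient: str = "X",
              recording_id: str = "smrbci synthetic EEG") -> None:
    """Write a recording as 16-bit EDF with 1 s data records.

    The sampling rate must be an integer.  A partial final second is
    zero-padded (EDF stores whole data records), so a read-back recording
    may be up to one second longer than the input.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise InvalidArgumentError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = recording.n_channels
    n_rec = int(np.ceil(recording.n_samples / fs))
    data = np.zeros((n_ch, n_rec * fs))
    data[:, : recording.n_samples] = recording.data
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    same = pmax - pmin < 1e-12
    pmin[same] -= 1.0
    pmax[same] += 1.0
    dmin, dmax = -32768, 32767
    header = b"".join([
        _pad("0", 8), _pad(patient, 80), _pad(recording_id, 80),
        _pad("01.01.00", 8), _pad("00.00.00", 8),
        _pad(str(256 * (n_ch + 1)), 8), _pad("", 44),
        _pad(str(n_rec), 8), _pad("1", 8), _pad(str(n_ch), 4),
    ])
    fields = [
        [_pad(lab, 16) for lab in recording.labels],
        [_pad("AgAgCl electrode", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{v:.8g}"[:8], 8) for v in pmin],
        [_pad(f"{v:.8g}"[:8], 8) for v in pmax],
        [_pad(str(dmin), 8)] * n_ch,
        [_pad(str(dmax), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(fs), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    # physical range actually written must match the 8-char ascii header
    pmin_w = np.array([float(f[:8]) for f in (f"{v:.8g}" for v in pmin)])
    pmax_w = np.array([float(f[:8]) for f in (f"{v:.8g}" for v in pmax)])
    scale = (dmax - dmin) / (pmax_w - pmin_w)
    with open(path, "wb") as fh:
        fh.write(header)
        for col in fields:
            fh.write(b"".join(col))
        for r in range(n_rec):
            seg = data[:, r * fs : (r + 1) * fs]
            dig = np.rint((seg - pmin_w[:, None]) * scale[:, None] + dmin)
            fh.write(np.clip(dig, dmin, dmax).astype("<i2").tobytes())


def read_edf(path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (µV) via MNE."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(raw.get_data() * 1e6, float(raw.info["sfreq"]),
                        tuple(raw.ch_names))


# ---------------------------------------------------------------------------
# trial tables


def trials_to_frame(runs: Iterable[RunResult], subject: str = "",
                    session: int = 1, part: int = 1) -> pd.DataFrame:
    """Flat table: one row per trial."""
    rows = []
    for run_idx, run in enumerate(runs):
        for trial_idx, t in enumerate(run.trials):
            rows.append({
                "subject": subject, "session": session, "part": part,
                "run": run_idx, "trial": trial_idx, "task": t.task,
                "target": t.target, "outcome": t.outcome,
                "duration_s": t.duration, "practice": run.practice,
            })
    return pd.DataFrame(rows)


def session_to_frame(session: SessionResult, subject: str = "",
                     session_idx: int = 1) -> pd.DataFrame:
    parts = [trials_to_frame(session.part1, subject, session_idx, part=1),
             trials_to_frame(session.part2, subject, session_idx, part=2)]
    return pd.concat(parts, ignore_index=True)


def write_sidecar(path, seeds: dict, extra: dict | None = None) -> None:
    """Record the seeds (and any extra metadata) next to generated output."""
    payload = {"seeds": {k: int(v) for k, v in seeds.items()}}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
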