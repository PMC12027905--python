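"""Session file format: one long CSV of samples plus a JSON sidecar.

``session.csv`` columns: participant, condition, trial, sample_index,
time_s, x_deg, y_deg, pupil_px — time in seconds from trial onset, floats at
full (round-trippable) precision.  ``session.json`` holds each trial's
metadata and, for synthetic sessions, its ground truth.  A missing sidecar
puts the reader in metadata-less mode (preprocessing and OKN extraction still
work; group statistics need the labels).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .session import GroundTruth, TrialMeta, TrialRecording

__all__ = ["write_session", "read_session", "SessionFormatError"]

CSV_COLUMNS = ["participant", "condition", "trial", "sample_index",
               "time_s", "x_deg", "y_deg", "pupil_px"]


class SessionFormatError(ValueError):
    """The on-disk session does not match the expected layout."""


def _trial_key(rec: TrialRecording, fallback: int) -> tuple[str, str, int]:
    if rec.meta is not None:
        return (rec.meta.participant_id, rec.meta.condition, rec.meta.trial_index)
    return ("P00", "unknown", fallback)


def write_session(trials: Sequence[TrialRecording], out_dir: str | Path,
                  sampling_rate: float = 500.0) -> tuple[Path, Path]:
    """Write ``session.csv`` + ``session.json`` under ``out_dir``; returns both
    paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    sidecar = []
    for i, rec in enumerate(trials):
        pid, cond, idx = _trial_key(rec, i)
        n = rec.n_samples
        frames.append(pd.DataFrame({
            "participant": pid,
            "condition": cond,
            "trial": idx,
            "sample_index": np.arange(n),
            "time_s": np.arange(n) / sampling_rate,
            "x_deg": rec.x,
            "y_deg": rec.y,
            "pupil_px": rec.pupil,
        }))
        sidecar.append({
            "participant": pid,
            "condition": cond,
            "trial": idx,
            "meta": rec.meta.to_dict() if rec.meta is not None else None,
            "ground_truth": (rec.ground_truth.to_dict()
                             if rec.ground_truth is not None else None),
        })
    csv_path = out / "session.csv"
    json_path = out / "session.json"
    pd.concat(frames, ignore_index=True)[CSV_COLUMNS].to_csv(
        csv_path, index=False, float_format="%.17g")
    json_path.write_text(json.dumps(
        {"sampling_rate": sampling_rate, "trials": sidecar}, indent=1))
    return csv_path, json_path


def read_session(path: str | Path) -> tuple[list[TrialRecording], float]:
    """Read a session directory (or its CSV path); returns (trials, rate).

    Validates column presence, per-trial length consistency and a uniform
    sampling rate; raises :class:`SessionFormatError` on malformed input.
    """
    path = Path(path)
    csv_path = path / "session.csv" if path.is_dir() else path
    json_path = csv_path.with_suffix(".json")
    if not csv_path.exists():
        raise SessionFormatError(f"no session CSV at {csv_path}")
    try:
        df = pd.read_csv(csv_path, float_precision="round_trip")
    except Exception as exc:  # malformed / truncated file
        raise SessionFormatError(f"cannot parse {csv_path}: {exc}") from exc
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SessionFormatError(f"session CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise SessionFormatError("session CSV holds no samples")

    sidecar = None
    if json_path.exists():
        sidecar = json.loads(json_path.read_text())
    rate: float | None = sidecar["sampling_rate"] if sidecar else None

    meta_by_key: dict[tuple[str, str, int], dict] = {}
    if sidecar:
        for entry in sidecar["trials"]:
            meta_by_key[(entry["participant"], entry["condition"],
                         int(entry["trial"]))] = entry

    trials: list[TrialRecording] = []
    lengths = set()
    for (pid, cond, idx), g in df.groupby(["participant", "condition", "trial"],
                                          sort=False):
        g = g.sort_values("sample_index")
        n = len(g)
        lengths.add(n)
        if not np.array_equal(g["sample_index"].to_numpy(), np.arange(n)):
            raise SessionFormatError(
                f"trial {(pid, cond, idx)} has non-contiguous sample indices")
        t = g["time_s"].to_numpy()
        if n >= 2:
            steps = np.diff(t)
            implied = 1.0 / np.median(steps)
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise SessionFormatError(
                    f"trial {(pid, cond, idx)} is not uniformly sampled")
            if rate is None:
                rate = implied
            elif not np.isclose(rate, implied, rtol=1e-6):
                raise SessionFormatError("inconsistent sampling rate across trials")
        entry = meta_by_key.get((str(pid), str(cond), int(idx)))
        meta = gt = None
        if entry is not None:
            if entry.get("meta") is not None:
                meta = TrialMeta.from_dict(entry["meta"])
            if entry.get("ground_truth") is not None:
                gt = GroundTruth.from_dict(entry["ground_truth"])
        trials.append(TrialRecording(
            x=g["x_deg"].to_numpy(), y=g["y_deg"].to_numpy(),
            pupil=g["pupil_px"].to_numpy(), meta=meta, ground_truth=gt))
    if len(lengths) > 1:
        raise SessionFormatError(f"trials differ in length: {sorted(lengths)}")
    if rate is None:
        raise SessionFormatError("cannot determine sampling rate")
    return trials, float(rate)
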