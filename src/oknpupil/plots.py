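"""Minimal trace plots for quick inspection of sessions and analyses."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .session import StimulusSpec, TrialRecording

__all__ = ["plot_trial", "plot_panel_averages"]


def plot_trial(rec: TrialRecording, spec: StimulusSpec, path: str | Path) -> Path:
    """Raw horizontal position and pupil size of one trial, cues marked."""
    t = np.arange(rec.n_samples) / spec.sampling_rate
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    x = np.where(rec.x > 100_000, np.nan, rec.x)
    pupil = np.where(rec.pupil == 0, np.nan, rec.pupil)
    ax1.plot(t, x, lw=0.6)
    ax1.set_ylabel("horizontal position (deg)")
    ax2.plot(t, pupil, lw=0.6, color="tab:red")
    ax2.set_ylabel("pupil size (px)")
    ax2.set_xlabel("time from trial onset (s)")
    if rec.meta is not None:
        for ax in (ax1, ax2):
            ax.axvline(rec.meta.cue1_time, color="k", ls=":", lw=0.8)
            ax.axvline(rec.meta.cue2_time, color="k", ls="--", lw=0.8)
        ax1.set_title(f"{rec.meta.participant_id} {rec.meta.condition} "
                      f"{rec.meta.cue_relation}")
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def plot_panel_averages(times: np.ndarray, group_a: np.ndarray, group_b: np.ndarray,
                        labels: Sequence[str], sig_mask: np.ndarray,
                        ylabel: str, path: str | Path) -> Path:
    """Two group-mean traces with a significance bar underneath."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for g, lab in zip((group_a, group_b), labels):
        mean = g.mean(axis=0)
        sem = g.std(axis=0, ddof=1) / np.sqrt(g.shape[0])
        ax.plot(times, mean, label=lab)
        ax.fill_between(times, mean - 1.96 * sem, mean + 1.96 * sem, alpha=0.2)
    if sig_mask.any():
        y0 = ax.get_ylim()[0]
        ax.plot(times[sig_mask], np.full(sig_mask.sum(), y0), "k.", ms=2)
    ax.set_xlabel("time (s)")
    ax.set_ylabel(ylabel)
    ax.legend()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
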