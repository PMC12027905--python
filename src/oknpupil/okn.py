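"""Slow-phase velocity reconstruction for optokinetic nystagmus (OKN).

OKN alternates slow phases that track large-field motion with fast resetting
quick phases.  To recover the slow component from horizontal gaze position
the pipeline: (1) smooths position with an 11-point moving average,
(2) differentiates (central differences), (3) smooths the velocity with the
same 11-point average, (4) detects saccadic fast phases as velocity extrema
exceeding +/- 20 deg/s expanded to the flanking velocity extrema of opposite
type, (5) excises them and bridges the gaps by linear interpolation, and
(6) applies a Gaussian-weighted moving average (window 1000 samples at
500 Hz).  The result is a dense, finite slow-phase velocity trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import gaussian_smooth, moving_average
from .trace import CleanTrace

__all__ = [
    "SaccadeInterval",
    "SlowPhaseTrace",
    "differentiate",
    "detect_saccades",
    "excise_and_interpolate",
    "slow_phase_velocity",
]

#: Saccade detection threshold (deg/s); stimulus speed is ~11.4 deg/s so any
#: event faster than this is a fast phase, not tracking.
SACCADE_THRESHOLD = 20.0

#: Final Gaussian smoothing window for the slow-phase velocity (samples).
FINAL_SMOOTH_WINDOW = 1000

#: Moving-average window applied to position and raw velocity (samples).
MA_WINDOW = 11


@dataclass(frozen=True)
class SaccadeInterval:
    """Inclusive sample span of one saccadic (fast) phase."""

    start: int
    end: int
    peak_velocity: float  # deg/s, signed

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("saccade interval start must not exceed end")

    @property
    def n_samples(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SlowPhaseTrace:
    """Desaccaded, smoothed slow-phase velocity plus the excised intervals."""

    velocity: np.ndarray  # deg/s per sample, fully finite
    saccades: tuple[SaccadeInterval, ...]
    sampling_rate: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.velocity.size) / self.sampling_rate


def differentiate(position: CleanTrace) -> CleanTrace:
    """Time derivative by central differences (forward/backward at the edges).

    A derivative sample is missing whenever any sample it touches (the
    central-difference neighbours, or the sample itself) is missing.
    """
    x = position.values
    if x.size < 3:
        raise ValueError("differentiation needs at least 3 samples")
    fs = position.sampling_rate
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) * (fs / 2.0)
    v[0] = (x[1] - x[0]) * fs
    v[-1] = (x[-1] - x[-2]) * fs
    # conservative missing propagation: centre sample counts as "touched"
    missing = np.isnan(x)
    touched = missing.copy()
    touched[1:-1] |= missing[2:] | missing[:-2]
    touched[0] |= missing[1]
    touched[-1] |= missing[-2]
    v[touched] = np.nan
    units = position.units + "/s"
    return CleanTrace(v, fs, units)


def _local_extrema(v: np.ndarray, threshold: float) -> list[int]:
    """Indices of interior local maxima/minima of v with |v| > threshold.

    A plateau contributes its first sample.  Samples adjacent to NaNs never
    qualify (comparisons with NaN are False).
    """
    out: list[int] = []
    with np.errstate(invalid="ignore"):
        is_max = np.zeros(v.size, dtype=bool)
        is_min = np.zeros(v.size, dtype=bool)
        is_max[1:-1] = (v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]) & (v[1:-1] > threshold)
        is_min[1:-1] = (v[1:-1] < v[:-2]) & (v[1:-1] <= v[2:]) & (v[1:-1] < -threshold)
    out = sorted(np.flatnonzero(is_max | is_min).tolist())
    return out


def _walk_to_flank(v: np.ndarray, peak: int, direction: int) -> int:
    """Walk from a velocity extremum toward the flanking extremum of opposite
    type: from a positive peak, descend while the velocity is non-increasing;
    from a trough, ascend while it is non-decreasing.  The walk then retreats
    across the final equal-valued run to its sample nearest the peak, so a
    plateau minimum contributes its inner edge and flat stretches beyond the
    flank are not excised.  Stops at trace edges and at missing samples."""
    sign = 1.0 if v[peak] > 0 else -1.0
    j = peak
    while 0 <= j + direction < v.size:
        nxt = v[j + direction]
        if not np.isfinite(nxt):
            break
        if sign * nxt <= sign * v[j]:
            j += direction
        else:
            break
    while j != peak and v[j - direction] == v[j]:
        j -= direction
    return j


def detect_saccades(
    velocity: CleanTrace, threshold: float = SACCADE_THRESHOLD
) -> list[SaccadeInterval]:
    """Detect saccadic phases on a smoothed velocity trace.

    Velocity peaks and troughs exceeding ``+/- threshold`` are located; each is
    expanded outward to the nearest flanking extremum of the opposite type
    (where the velocity stops falling away from the peak), and the inclusive
    span is one saccadic phase.  Overlapping or adjacent spans are merged.
    """
    v = velocity.values
    spans: list[tuple[int, int]] = []
    for peak in _local_extrema(v, threshold):
        left = _walk_to_flank(v, peak, -1)
        right = _walk_to_flank(v, peak, +1)
        spans.append((left, right))
    if not spans:
        return []
    spans.sort()
    merged: list[list[int]] = [list(spans[0])]
    for start, end in spans[1:]:
        if start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    out = []
    for start, end in merged:
        seg = v[start : end + 1]
        finite = seg[np.isfinite(seg)]
        peak_vel = finite[np.argmax(np.abs(finite))] if finite.size else np.nan
        out.append(SaccadeInterval(start, end, float(peak_vel)))
    return out


def excise_and_interpolate(
    velocity: CleanTrace, saccades: list[SaccadeInterval] | tuple[SaccadeInterval, ...]
) -> CleanTrace:
    """Blank every saccadic span (and pre-existing missing samples) and bridge
    the gaps by linear interpolation between the nearest finite neighbours.

    Leading/trailing gaps are filled by nearest-value extension (there is no
    outer anchor to interpolate toward).
    """
    v = velocity.values.copy()
    n = v.size
    for sac in saccades:
        if sac.start < 0 or sac.end >= n:
            raise ValueError("saccade interval outside the trace")
        v[sac.start : sac.end + 1] = np.nan
    finite = np.flatnonzero(np.isfinite(v))
    if finite.size == 0:
        raise ValueError("cannot interpolate an all-missing velocity trace")
    idx = np.arange(n)
    filled = np.interp(idx, finite, v[finite])  # extends by edge values
    return velocity.with_values(filled)


def slow_phase_velocity(
    position: CleanTrace,
    *,
    ma_window: int = MA_WINDOW,
    threshold: float = SACCADE_THRESHOLD,
    final_window: int = FINAL_SMOOTH_WINDOW,
) -> SlowPhaseTrace:
    """Full desaccading chain from cleaned horizontal position to slow-phase
    velocity.

    ``position`` must already have sentinel samples marked missing (see
    :func:`oknpupil.preprocess.mark_invalid_samples`).
    """
    pos_s = moving_average(position, ma_window)
    vel = differentiate(pos_s)
    vel_s = moving_average(vel, ma_window)
    saccades = detect_saccades(vel_s, threshold)
    desacc = excise_and_interpolate(vel_s, saccades)
    smooth = gaussian_smooth(desacc, final_window)
    return SlowPhaseTrace(
        velocity=smooth.values,
        saccades=tuple(saccades),
        sampling_rate=position.sampling_rate,
    )
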