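"""Raw-trace cleaning: sentinel handling, NaN-aware smoothing, pupil z-scoring.

The eye tracker emits two kinds of invalid samples: exact zeros (lost pupil,
e.g. during blinks) and implausibly large sentinel values (> 100,000).  Both
become missing samples here.  The smoothers are *normalized* (NaN-aware)
moving averages: weights over missing samples are dropped and the remaining
weights renormalized, so a smoothed sample is defined whenever its truncated
window contains at least one present sample.  Consequently smoothing also
imputes isolated missing samples from their neighbours.
"""

from __future__ import annotations

import numpy as np
from scipy.signal.windows import gaussian as _gaussian_window

from .trace import CleanTrace

__all__ = [
    "DegenerateTrialError",
    "mark_invalid_samples",
    "moving_average",
    "gaussian_smooth",
    "zscore_trial",
    "pad_missing_runs",
]

#: Samples strictly above this value are treated as tracker sentinels.
SENTINEL_HIGH = 100_000.0


class DegenerateTrialError(ValueError):
    """A trial is unusable for normalization (e.g. constant or empty pupil)."""


def mark_invalid_samples(
    raw: np.ndarray | CleanTrace,
    sampling_rate: float | None = None,
    units: str = "deg",
    sentinel_high: float = SENTINEL_HIGH,
) -> CleanTrace:
    """Replace sentinel samples (exactly 0, or > ``sentinel_high``) with missing.

    Non-finite input samples are also treated as missing.  An all-missing
    result is returned as such (callers decide how to fail); length is
    preserved.
    """
    if isinstance(raw, CleanTrace):
        values = raw.values.copy()
        sampling_rate = raw.sampling_rate
        units = raw.units
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for array input")
        values = np.asarray(raw, dtype=float).copy()
    bad = (values > sentinel_high) | (values == 0.0) | ~np.isfinite(values)
    values[bad] = np.nan
    return CleanTrace(values, sampling_rate, units)


def _nan_convolve(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Centered normalized convolution ignoring NaNs, truncated at the edges.

    The kernel center is at index ``(len(kernel) - 1) // 2`` (numpy 'same'
    convention).  Output is NaN only where every in-window sample is missing.
    """
    present = np.isfinite(values)
    filled = np.where(present, values, 0.0)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(present.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den <= 0.0] = np.nan
    return out


def moving_average(trace: CleanTrace, window: int) -> CleanTrace:
    """Centered boxcar mean of odd length ``window``, NaN-aware, edge-truncated."""
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ValueError("moving-average window must be a positive odd integer")
    if window == 1:
        return trace.with_values(trace.values.copy())
    kernel = np.ones(window)
    return trace.with_values(_nan_convolve(trace.values, kernel))


def gaussian_smooth(trace: CleanTrace, window: int) -> CleanTrace:
    """Gaussian-weighted moving average with kernel length ``window``.

    The kernel standard deviation is ``window / 5`` samples, truncated to the
    window and renormalized (also at the trace edges), so a constant trace is
    left exactly unchanged.
    """
    window = int(window)
    if window < 1:
        raise ValueError("gaussian window must be a positive integer")
    if window == 1:
        return trace.with_values(trace.values.copy())
    kernel = _gaussian_window(window, std=window / 5.0)
    kernel = kernel / kernel.sum()
    return trace.with_values(_nan_convolve(trace.values, kernel))


def zscore_trial(
    pupil: CleanTrace,
    analysis_window: tuple[float, float] | None = None,
) -> CleanTrace:
    """Standardize a pupil trace to z-scores over the analysis window.

    Mean and standard deviation (ddof=1) are computed over the non-missing
    samples whose times fall inside ``analysis_window`` (seconds from trace
    start; default = the whole trace), then applied to every sample.  Missing
    samples stay missing.

    Raises
    ------
    DegenerateTrialError
        If fewer than 2 non-missing samples lie in the window or their
        variance is zero; such trials must be excluded from averaging.
    """
    values = pupil.values
    if analysis_window is None:
        in_window = np.ones(values.size, dtype=bool)
    else:
        start, end = analysis_window
        if start >= end:
            raise ValueError("analysis window start must precede end")
        t = pupil.times
        if start < 0 or end > (values.size) / pupil.sampling_rate:
            raise ValueError("analysis window outside the trial")
        in_window = (t >= start) & (t <= end)
    sel = values[in_window]
    sel = sel[np.isfinite(sel)]
    if sel.size < 2:
        raise DegenerateTrialError(
            "pupil z-scoring needs >= 2 valid samples in the analysis window")
    mean = sel.mean()
    sd = sel.std(ddof=1)
    if sd == 0.0:
        raise DegenerateTrialError("pupil trace has zero variance in the analysis window")
    return pupil.with_values((values - mean) / sd, units="zscore")


def pad_missing_runs(trace: CleanTrace, pad_s: float = 0.05) -> CleanTrace:
    """Widen every missing run by ``pad_s`` seconds on each side.

    Optional guard against partially occluded samples at blink edges; off by
    default in the pipeline (blink detection proper is delegated upstream).
    """
    if pad_s < 0:
        raise ValueError("pad must be non-negative")
    pad = int(round(pad_s * trace.sampling_rate))
    if pad == 0:
        return trace.with_values(trace.values.copy())
    missing = trace.missing_mask
    widened = np.convolve(missing.astype(float), np.ones(2 * pad + 1), mode="same") > 0
    values = trace.values.copy()
    values[widened] = np.nan
    return trace.with_values(values)
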