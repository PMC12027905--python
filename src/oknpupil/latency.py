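"""Event-locked latency from the deepest acceleration valley near a cue.

The latency of an oculomotor or pupillary response to a cue is read off the
*acceleration* of the underlying signal: differentiate the input down to
acceleration with central differences, smooth the acceleration with a
Gaussian-weighted moving average (window 500 samples at 500 Hz), detect its
strict local minima over the whole trace, and report the deepest one whose
time falls within +/- 1.5 s of the cue.  Latency is that valley time minus
the cue time (negative = anticipatory).

How many derivatives reach "acceleration" depends on what the input already
is: a z-scored pupil-size trace is position-like and needs two, a slow-phase
velocity trace is already a first derivative of gaze position and needs one.
``diff_order`` expresses this; the valley location is what makes the
estimator land on the injected transition for both signal types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import gaussian_smooth
from .trace import CleanTrace
from .okn import differentiate

__all__ = ["LatencyEstimate", "estimate_latency"]

#: Half-width of the search window around the cue (seconds).
SEARCH_HALFWIDTH = 1.5

#: Gaussian smoothing window applied to the acceleration (samples).
ACCEL_SMOOTH_WINDOW = 500


@dataclass(frozen=True)
class LatencyEstimate:
    """Latency relative to the cue, or an explicit failure.

    ``latency`` is NaN when ``valid`` is False (no acceleration valley fell
    inside the search window).
    """

    latency: float  # seconds relative to the cue; negative = before it
    valley_value: float  # smoothed acceleration at the valley
    valid: bool

    def __post_init__(self) -> None:
        if self.valid and not abs(self.latency) <= SEARCH_HALFWIDTH + 1e-12:
            # the search window is a hard bound on any valid output
            raise ValueError("valid latency outside the search window")


def estimate_latency(
    trace: np.ndarray | CleanTrace,
    cue_time: float,
    sampling_rate: float | None = None,
    *,
    search_halfwidth: float = SEARCH_HALFWIDTH,
    accel_smooth_window: int = ACCEL_SMOOTH_WINDOW,
    diff_order: int = 2,
) -> LatencyEstimate:
    """Deepest-acceleration-valley latency of ``trace`` relative to ``cue_time``.

    Parameters
    ----------
    trace
        Fully finite signal (post-pipeline): z-scored smoothed pupil size, or
        smoothed slow-phase velocity.
    cue_time
        Event time in seconds from trace start; the window
        ``cue_time +/- search_halfwidth`` must lie inside the trace.
    diff_order
        Number of central-difference derivatives that turn the input into an
        acceleration: 2 for position-like input (default), 1 for velocity
        input.

    Returns
    -------
    LatencyEstimate
        Invalid (``valid=False``) when no strict local minimum of the smoothed
        acceleration falls inside the window (e.g. a linear input has no
        valley at all).
    """
    if isinstance(trace, CleanTrace):
        values = trace.values
        sampling_rate = trace.sampling_rate
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for array input")
        values = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("latency estimation requires a fully finite trace")
    if diff_order not in (1, 2):
        raise ValueError("diff_order must be 1 (velocity input) or 2 (position input)")
    n = values.size
    duration = (n - 1) / sampling_rate
    if cue_time - search_halfwidth < 0 or cue_time + search_halfwidth > duration:
        raise ValueError("search window exceeds the trace bounds")

    accel = CleanTrace(values, sampling_rate, "signal")
    for _ in range(diff_order):
        accel = differentiate(accel)
    accel = gaussian_smooth(accel, accel_smooth_window)
    a = accel.values

    # a numerically flat acceleration (e.g. a linear input, whose derivatives
    # are rounding dust) has no genuine valley; the tolerance scales with the
    # input so the estimate stays amplitude-scale invariant
    flat_tol = np.ptp(values) * sampling_rate ** diff_order * 1e-13
    if np.ptp(a) <= flat_tol:
        return LatencyEstimate(np.nan, np.nan, False)

    # strict interior local minima over the whole trace, then windowed
    is_min = np.zeros(n, dtype=bool)
    is_min[1:-1] = (a[1:-1] < a[:-2]) & (a[1:-1] < a[2:])
    cand = np.flatnonzero(is_min)
    if cand.size == 0:
        return LatencyEstimate(np.nan, np.nan, False)
    t = cand / sampling_rate
    in_window = (t >= cue_time - search_halfwidth) & (t <= cue_time + search_halfwidth)
    cand = cand[in_window]
    if cand.size == 0:
        return LatencyEstimate(np.nan, np.nan, False)
    best = cand[np.argmin(a[cand])]
    return LatencyEstimate(best / sampling_rate - cue_time, float(a[best]), True)
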