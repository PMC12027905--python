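"""Uniformly sampled per-trial signal with explicit missing-sample support.

Missing samples are stored as NaN; ``missing_mask`` is always derived from the
values so the two can never disagree.  Every preprocessing and analysis step in
this package preserves trace length and sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["CleanTrace"]


@dataclass(frozen=True)
class CleanTrace:
    """A fixed-rate signal (gaze position, velocity, or pupil size).

    Parameters
    ----------
    values
        Per-sample values, float64. NaN marks a missing sample.
    sampling_rate
        Samples per second (Hz), > 0.
    units
        Physical units of the values, e.g. ``"deg"``, ``"deg/s"``,
        ``"pixels"``, ``"zscore"``.
    """

    values: np.ndarray
    sampling_rate: float
    units: str = "deg"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True exactly where a sample is missing."""
        return np.isnan(self.values)

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from trace start."""
        return np.arange(self.values.size) / self.sampling_rate

    def with_values(self, values: np.ndarray, units: str | None = None) -> "CleanTrace":
        """Copy of this trace with new values (and optionally new units)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       units=self.units if units is None else units)
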