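"""Domain types shared across the package: stimulus geometry, trial metadata,
per-trial recordings, and simulation ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "StimulusSpec",
    "TrialMeta",
    "GroundTruth",
    "TrialRecording",
    "CONDITIONS",
    "CUE_RELATIONS",
    "DIRECTIONS",
    "BRIGHTNESSES",
]

CONDITIONS = ("gaze", "attention")
CUE_RELATIONS = ("same", "opposite")
DIRECTIONS = ("left", "right")
BRIGHTNESSES = ("white", "black")

#: Duration each target numeral stays on screen (seconds).
TARGET_DURATION = 0.83


@dataclass(frozen=True)
class StimulusSpec:
    """Display and acquisition parameters of the two-field motion stimulus.

    Two random-dot fields (white 32.06 and black 0.04 cd/m^2 dots moving in
    opposite directions) flank a central fixation line; gaze position and
    pupil size are sampled at 500 Hz over 9-s trials (3 s static dots, then
    6 s of motion at 11.36 deg/s).
    """

    stimulus_speed: float = 11.36  # deg/s
    dot_luminances: tuple[float, float] = (32.06, 0.04)  # cd/m^2 (white, black)
    field_size: tuple[float, float] = (18.45, 31.7)  # deg (width, height)
    field_separation: float = 12.0  # deg between the two fields
    sampling_rate: float = 500.0  # Hz
    trial_duration: float = 9.0  # s
    motion_onset: float = 3.0  # s from trial start

    def __post_init__(self) -> None:
        if not self.stimulus_speed >= 0:
            raise ValueError("stimulus_speed must be non-negative")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.motion_onset < self.trial_duration:
            raise ValueError("motion_onset must lie inside the trial")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))

    @property
    def field_center_offset(self) -> float:
        """Horizontal eccentricity of each field's centre (deg)."""
        return (self.field_separation + self.field_size[0]) / 2.0


@dataclass(frozen=True)
class TrialMeta:
    """Condition labels and event timing of one trial.

    ``cue_relation`` states whether the second auditory cue redirects
    gaze/attention to the same field (labels repeat) or the opposite one
    (side, tracked motion direction and attended brightness all flip).
    """

    participant_id: str
    condition: str  # "gaze" | "attention"
    cue_relation: str  # "same" | "opposite"
    motion_dir_first: str  # "left" | "right"
    motion_dir_second: str
    brightness_first: str  # "white" | "black"
    brightness_second: str
    cue_side_first: str  # "left" | "right" field holding the first cue
    cue_side_second: str
    cue1_time: float  # s from trial start (= motion onset)
    cue2_time: float  # s from trial start
    target_windows: tuple[tuple[float, float], tuple[float, float]]  # (start, duration) s
    both_correct: bool
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.cue_relation not in CUE_RELATIONS:
            raise ValueError(f"unknown cue relation {self.cue_relation!r}")
        for name in ("motion_dir_first", "motion_dir_second",
                     "cue_side_first", "cue_side_second"):
            if getattr(self, name) not in DIRECTIONS:
                raise ValueError(f"{name} must be one of {DIRECTIONS}")
        for name in ("brightness_first", "brightness_second"):
            if getattr(self, name) not in BRIGHTNESSES:
                raise ValueError(f"{name} must be one of {BRIGHTNESSES}")
        gap = self.cue2_time - self.cue1_time
        if not 2.9 - 1e-9 <= gap <= 3.3 + 1e-9:
            raise ValueError("second cue must follow the first by 2.9-3.3 s")
        if self.cue_relation == "same":
            if (self.motion_dir_first != self.motion_dir_second
                    or self.brightness_first != self.brightness_second
                    or self.cue_side_first != self.cue_side_second):
                raise ValueError("same-cue trials must repeat all first-cue labels")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["target_windows"] = [list(w) for w in self.target_windows]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialMeta":
        d = dict(d)
        d["target_windows"] = tuple(tuple(w) for w in d["target_windows"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Known simulation parameters of one synthetic trial, for recovery tests.

    Latencies are seconds relative to the second cue; intervals are (start,
    end) in seconds from trial start, sorted and non-overlapping.
    """

    okn_latency: float
    pupil_latency: float
    okn_gain: float
    saccade_intervals: list[tuple[float, float]] = field(default_factory=list)
    blink_intervals: list[tuple[float, float]] = field(default_factory=list)
    gaze_offset_trace: np.ndarray | None = None  # deg per sample

    def __post_init__(self) -> None:
        if not 0 < self.okn_gain <= 1.2:
            raise ValueError("okn_gain must lie in (0, 1.2]")
        for name in ("saccade_intervals", "blink_intervals"):
            ivals = getattr(self, name)
            for (a, b) in ivals:
                if a > b:
                    raise ValueError(f"{name} entries must have start <= end")
            for (_, b), (a2, _) in zip(ivals, ivals[1:]):
                if a2 <= b:
                    raise ValueError(f"{name} must be sorted and non-overlapping")

    def to_dict(self) -> dict:
        return {
            "okn_latency": self.okn_latency,
            "pupil_latency": self.pupil_latency,
            "okn_gain": self.okn_gain,
            "saccade_intervals": [list(iv) for iv in self.saccade_intervals],
            "blink_intervals": [list(iv) for iv in self.blink_intervals],
            "gaze_offset_trace": (None if self.gaze_offset_trace is None
                                  else self.gaze_offset_trace.tolist()),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["saccade_intervals"] = [tuple(iv) for iv in d["saccade_intervals"]]
        d["blink_intervals"] = [tuple(iv) for iv in d["blink_intervals"]]
        if d.get("gaze_offset_trace") is not None:
            d["gaze_offset_trace"] = np.asarray(d["gaze_offset_trace"], dtype=float)
        return cls(**d)


@dataclass
class TrialRecording:
    """One trial's raw 500 Hz samples plus metadata (and, when synthetic,
    ground truth)."""

    x: np.ndarray  # horizontal gaze position, deg
    y: np.ndarray  # vertical gaze position, deg
    pupil: np.ndarray  # pupil size, camera pixels
    meta: TrialMeta | None
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        if not (self.x.shape == self.y.shape == self.pupil.shape):
            raise ValueError("x, y and pupil must have identical lengths")

    @property
    def n_samples(self) -> int:
        return self.x.size
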