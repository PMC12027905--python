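import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oknpupil import SimulationParams, StimulusSpec, TrialMeta
from oknpupil.session import TARGET_DURATION

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec() -> StimulusSpec:
    return StimulusSpec()


@pytest.fixture(scope="session")
def quiet_params() -> SimulationParams:
    """Noise-free, blink-free simulation parameters."""
    return SimulationParams().noise_free()


def make_meta(
    condition: str = "gaze",
    cue_relation: str = "same",
    motion_dir_first: str = "left",
    brightness_first: str = "black",
    cue_side_first: str = "left",
    cue2_time: float = 6.1,
    both_correct: bool = True,
    participant_id: str = "P01",
    trial_index: int = 0,
) -> TrialMeta:
    """Trial metadata with second-cue labels derived from the relation."""
    opp = {"left": "right", "right": "left"}
    flip = {"white": "black", "black": "white"}
    if cue_relation == "same":
        d2, b2, s2 = motion_dir_first, brightness_first, cue_side_first
    else:
        d2 = opp[motion_dir_first]
        b2 = flip[brightness_first]
        s2 = opp[cue_side_first]
    return TrialMeta(
        participant_id=participant_id,
        condition=condition,
        cue_relation=cue_relation,
        motion_dir_first=motion_dir_first,
        motion_dir_second=d2,
        brightness_first=brightness_first,
        brightness_second=b2,
        cue_side_first=cue_side_first,
        cue_side_second=s2,
        cue1_time=3.0,
        cue2_time=cue2_time,
        target_windows=((4.9, TARGET_DURATION), (7.8, TARGET_DURATION)),
        both_correct=both_correct,
        trial_index=trial_index,
    )


@pytest.fixture
def meta_factory():
    return make_meta
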