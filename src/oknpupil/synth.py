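"""Synthetic eye-tracking sessions with known ground truth.

The generator reproduces the study design this package analyses: 9-s trials
(3 s static dots, 6 s motion at 11.36 deg/s), an auditory cue at motion onset
and a second one 2.9-3.3 s later, 16-trial blocks fully crossing motion
direction x dot brightness x cue side x cue relation, and two conditions —
overt gaze shifts toward the cued field versus covert attention under central
fixation (lower OKN gain, weaker pupil modulation plus a cognitive-load
drift).

Signal model
------------
* Slow-phase velocity tracks the cued motion at ``gain x stimulus_speed``;
  each cue switches the tracked direction through a logistic transition of
  half-width 0.25 s centred at ``cue + okn_latency``.
* Quick phases are linear resets of amplitude A (2 deg over 40 ms) triggered
  whenever the accumulated slow-phase eccentricity from the fixation locus
  exceeds A, so a noise-free trace contains exactly
  ``floor(total slow displacement / A)`` of them.
* In the gaze condition the fixation locus jumps to the cued field's centre
  via a 30-ms refixation saccade 0.2 s after the cue; under covert attention
  it stays at screen centre.
* Pupil size relaxes first-order (tau = 1 s) toward a brightness-dependent
  asymptote that switches at ``cue + pupil_latency`` (black = dilate, white
  = constrict); the attention condition shrinks the step and adds a slow
  dilation drift.
* Blinks (pupil = 0, position = a sentinel > 100,000) and Gaussian
  measurement noise are injected last, mirroring the tracker's failure modes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .session import (
    BRIGHTNESSES,
    CUE_RELATIONS,
    DIRECTIONS,
    TARGET_DURATION,
    GroundTruth,
    StimulusSpec,
    TrialMeta,
    TrialRecording,
)

__all__ = [
    "SimulationParams",
    "simulate_okn_position",
    "simulate_pupil",
    "inject_artifacts",
    "simulate_trial",
    "generate_metas",
    "simulate_session",
]

_OPPOSITE = {"left": "right", "right": "left"}
_FLIP_BRIGHT = {"white": "black", "black": "white"}


@dataclass(frozen=True)
class SimulationParams:
    """All tunables of the synthetic generator (defaults = study conditions)."""

    # --- OKN ---
    okn_gain_gaze: float = 1.0  # slow-phase speed / stimulus speed
    okn_gain_attention: float = 0.4
    okn_latency: float = 0.4  # s, logistic transition centre after each cue
    quick_phase_amplitude: float = 2.0  # deg
    quick_phase_duration: float = 0.040  # s
    transition_halfwidth: float = 0.25  # s, centre -> 90% of the switch
    fixation_noise_sd: float = 0.05  # deg, white positional jitter
    refixation_delay: float = 0.2  # s after a cue (gaze condition)
    refixation_duration: float = 0.030  # s
    # --- pupil ---
    pupil_tau: float = 1.0  # s, first-order time constant
    pupil_latency: float = 0.9  # s after each cue
    pupil_amplitude: float = 20.0  # px asymptote offset per brightness step
    attention_amplitude_gain: float = 0.4  # < 1: covert steps are weaker
    pupil_baseline: float = 100.0  # px
    attention_drift_slope: float = 1.0  # px/s cognitive-load dilation
    # --- artifacts ---
    blink_rate: float = 0.15  # blinks per second
    blink_duration_range: tuple[float, float] = (0.1, 0.3)  # s
    position_sentinel: float = 150_000.0  # written into x/y during blinks
    position_noise_sd: float = 0.05  # deg measurement noise
    pupil_noise_sd: float = 0.5  # px measurement noise
    vertical_noise_sd: float = 0.05  # deg, vertical channel is noise only
    # --- session-level distributions ---
    correct_rate_gaze: float = 0.9382
    correct_rate_attention: float = 0.5699
    okn_latency_mean: float = 0.4
    okn_latency_sd: float = 0.15
    pupil_latency_mean: float = 0.9
    pupil_latency_sd: float = 0.2
    pupil_latency_bounds: tuple[float, float] = (0.0, 1.4)

    def __post_init__(self) -> None:
        if self.pupil_tau <= 0:
            raise ValueError("pupil time constant must be positive")
        if self.pupil_baseline <= 0:
            raise ValueError("pupil baseline must be positive")
        if self.blink_rate < 0:
            raise ValueError("blink rate must be non-negative")
        if self.quick_phase_amplitude <= 0 or self.quick_phase_duration <= 0:
            raise ValueError("quick-phase amplitude and duration must be positive")

    def gain(self, condition: str) -> float:
        return self.okn_gain_gaze if condition == "gaze" else self.okn_gain_attention

    def noise_free(self) -> "SimulationParams":
        """Copy with every stochastic corruption disabled."""
        return dataclasses.replace(
            self, fixation_noise_sd=0.0, position_noise_sd=0.0,
            pupil_noise_sd=0.0, vertical_noise_sd=0.0, blink_rate=0.0)


def _smooth_transition(t: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Sigmoid 0->1 transition reaching 0.9 at ``center + halfwidth``.

    Raised-cosine shape with compact support (fully 0/1 beyond
    ``center +/- W`` with ``W = pi*halfwidth / (2 asin(0.8))``), so plateaus
    between transitions are *exactly* constant — an infinite-tailed sigmoid
    would leave every noise-free plateau monotonically sloped at float
    precision, which no discrete local-extremum rule can treat as flat.
    """
    w = math.pi * halfwidth / (2.0 * math.asin(0.8))
    u = np.clip((t - center) / w, -1.0, 1.0)
    return 0.5 * (1.0 + np.sin(0.5 * math.pi * u))


def _dir_sign(direction: str) -> float:
    return 1.0 if direction == "right" else -1.0


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    out = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(iv) for iv in out]


def simulate_okn_position(
    meta: TrialMeta,
    spec: StimulusSpec,
    params: SimulationParams,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, GroundTruth]:
    """Horizontal gaze position (deg) of one trial plus its ground truth.

    The returned :class:`GroundTruth` has ``pupil_latency`` filled with the
    params value and ``blink_intervals`` empty (artifact injection updates
    them).
    """
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    fs = spec.sampling_rate
    dt = 1.0 / fs
    t = np.arange(n) * dt

    lat = params.okn_latency
    switch1 = meta.cue1_time + lat
    switch2 = meta.cue2_time + lat
    if not 0.0 <= switch2 <= spec.trial_duration:
        raise ValueError(
            f"okn_latency {lat} places the direction switch at {switch2:.3f} s, "
            f"outside the {spec.trial_duration}-s trial")

    gain = params.gain(meta.condition)
    d1 = _dir_sign(meta.motion_dir_first)
    d2 = _dir_sign(meta.motion_dir_second)
    ramp1 = _smooth_transition(t, switch1, params.transition_halfwidth)
    v = gain * spec.stimulus_speed * d1 * ramp1
    if d2 != d1:
        ramp2 = _smooth_transition(t, switch2, params.transition_halfwidth)
        v = v + gain * spec.stimulus_speed * (d2 - d1) * ramp2

    # slow-phase integration with quick-phase resets.  The trigger runs on the
    # ideal eccentricity (slow displacement minus one full amplitude per
    # completed reset), so on a noise-free trace the number of quick phases is
    # exactly floor(total slow displacement / A).
    amp = params.quick_phase_amplitude
    n_quick = max(1, int(round(params.quick_phase_duration * fs)))
    rel = np.empty(n)
    e_book = 0.0  # ideal eccentricity from the fixation locus
    ramp_left = 0
    ramp_step = 0.0
    quick_spans: list[tuple[float, float]] = []
    for i in range(n):
        e_book += v[i] * dt
        if ramp_left == 0 and abs(e_book) > amp:
            sgn = 1.0 if e_book > 0 else -1.0
            e_book -= sgn * amp
            ramp_left = n_quick
            ramp_step = -sgn * amp / n_quick
            quick_spans.append((i * dt, min(i + n_quick - 1, n - 1) * dt))
        if ramp_left > 0:
            ramp_left -= 1
        # rendered eccentricity: bookkeeping value minus the not-yet-executed
        # portion of the active reset
        rel[i] = e_book - ramp_left * ramp_step

    # fixation locus: centre, stepping to the cued field in the gaze condition
    locus = np.zeros(n)
    refix_spans: list[tuple[float, float]] = []
    if meta.condition == "gaze":
        offset = spec.field_center_offset
        targets = [(meta.cue1_time, _dir_sign(meta.cue_side_first) * offset)]
        if meta.cue_side_second != meta.cue_side_first:
            targets.append((meta.cue2_time, _dir_sign(meta.cue_side_second) * offset))
        for cue_time, target in targets:
            start = cue_time + params.refixation_delay
            dur = params.refixation_duration
            i0 = int(round(start * fs))
            i1 = min(int(round((start + dur) * fs)), n - 1)
            if i0 >= n:
                continue
            current = locus[i0]
            ramp = np.linspace(current, target, max(i1 - i0 + 1, 2))
            locus[i0 : i1 + 1] = ramp[: i1 - i0 + 1]
            locus[i1 + 1 :] = target
            refix_spans.append((i0 * dt, i1 * dt))

    pos = locus + rel
    if params.fixation_noise_sd > 0:
        pos = pos + rng.normal(0.0, params.fixation_noise_sd, n)

    gt = GroundTruth(
        okn_latency=lat,
        pupil_latency=params.pupil_latency,
        okn_gain=gain,
        saccade_intervals=_merge_intervals(quick_spans + refix_spans),
        blink_intervals=[],
        gaze_offset_trace=locus,
    )
    return pos, gt


def simulate_pupil(
    meta: TrialMeta,
    spec: StimulusSpec,
    params: SimulationParams,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Pupil-size trace (camera pixels) and the injected pupil latency (s).

    First-order relaxation toward a brightness-dependent asymptote: attending
    black dots dilates (higher asymptote), white constricts; the asymptote
    switches ``pupil_latency`` after each cue.  Covert attention scales the
    step by ``attention_amplitude_gain`` and adds a linear dilation drift.
    """
    n = spec.n_samples
    fs = spec.sampling_rate
    dt = 1.0 / fs
    t = np.arange(n) * dt
    tau = params.pupil_tau
    base = params.pupil_baseline

    attention = meta.condition == "attention"
    amp = params.pupil_amplitude * (params.attention_amplitude_gain if attention else 1.0)
    drift = params.attention_drift_slope if attention else 0.0

    def asymptote(brightness: str) -> float:
        return base + (amp if brightness == "black" else -amp)

    sw1 = meta.cue1_time + params.pupil_latency
    sw2 = meta.cue2_time + params.pupil_latency
    a = np.full(n, base)
    a[t >= sw1] = asymptote(meta.brightness_first)
    a[t >= sw2] = asymptote(meta.brightness_second)

    p = np.empty(n)
    p[0] = base
    decay = math.exp(-dt / tau)
    for i in range(1, n):
        p[i] = a[i] + (p[i - 1] - a[i]) * decay
    p = p + drift * t
    if np.any(p[np.isfinite(p)] <= 0):
        raise ValueError("pupil parameters produced non-positive sizes")
    return p, params.pupil_latency


def inject_artifacts(
    recording: TrialRecording,
    params: SimulationParams,
    seed: int | np.random.Generator,
    spec: StimulusSpec | None = None,
) -> TrialRecording:
    """Add measurement noise and blink sentinels; record blinks in the
    ground truth.

    Within each blink the pupil reads exactly 0 and both position channels
    read ``position_sentinel`` (> 100,000) — precisely the pathologies the
    preprocessing sentinel rule targets.  Blink count is Poisson
    (``blink_rate x duration``); overlapping draws are discarded.
    """
    rng = np.random.default_rng(seed)
    n = recording.n_samples
    fs = spec.sampling_rate if spec is not None else 500.0
    duration = n / fs

    x = recording.x.copy()
    y = recording.y.copy()
    pupil = recording.pupil.copy()
    if params.position_noise_sd > 0:
        x += rng.normal(0.0, params.position_noise_sd, n)
        y += rng.normal(0.0, params.position_noise_sd, n)
    if params.pupil_noise_sd > 0:
        pupil += rng.normal(0.0, params.pupil_noise_sd, n)

    blinks: list[tuple[float, float]] = []
    n_blinks = rng.poisson(params.blink_rate * duration)
    lo, hi = params.blink_duration_range
    for _ in range(n_blinks):
        start = rng.uniform(0.0, duration)
        end = min(start + rng.uniform(lo, hi), duration)
        if any(s <= end and start <= e for s, e in blinks):
            continue  # keep blink intervals non-overlapping
        blinks.append((start, end))
    blinks.sort()
    for start, end in blinks:
        i0 = int(round(start * fs))
        i1 = min(int(round(end * fs)), n - 1)
        pupil[i0 : i1 + 1] = 0.0
        x[i0 : i1 + 1] = params.position_sentinel
        y[i0 : i1 + 1] = params.position_sentinel

    gt = recording.ground_truth
    if gt is not None:
        gt = dataclasses.replace(gt, blink_intervals=blinks)
    return TrialRecording(x=x, y=y, pupil=pupil, meta=recording.meta, ground_truth=gt)


def simulate_trial(
    meta: TrialMeta,
    spec: StimulusSpec,
    params: SimulationParams,
    seed: int | np.random.SeedSequence,
    artifacts: bool = True,
) -> TrialRecording:
    """Complete synthetic trial: OKN position, vertical noise, pupil, artifacts."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_pos, rng_y, rng_art = (np.random.default_rng(s) for s in ss.spawn(3))
    x, gt = simulate_okn_position(meta, spec, params, rng_pos)
    pupil, pupil_lat = simulate_pupil(meta, spec, params, rng_y)
    gt.pupil_latency = pupil_lat
    n = spec.n_samples
    y = (rng_y.normal(0.0, params.vertical_noise_sd, n)
         if params.vertical_noise_sd > 0 else np.zeros(n))
    rec = TrialRecording(x=x, y=y, pupil=pupil, meta=meta, ground_truth=gt)
    if artifacts:
        rec = inject_artifacts(rec, params, rng_art, spec)
    return rec


def _block_factors(rng: np.random.Generator) -> list[tuple[str, str, str, str]]:
    """One block: the 16 combinations of direction x brightness x cue side x
    relation, in random order."""
    combos = [
        (d, b, s, r)
        for d in DIRECTIONS
        for b in BRIGHTNESSES
        for s in DIRECTIONS
        for r in CUE_RELATIONS
    ]
    rng.shuffle(combos)
    return combos


def generate_metas(
    n_participants: int,
    blocks_per_condition: int,
    spec: StimulusSpec,
    params: SimulationParams,
    seed: int | np.random.Generator,
) -> list[TrialMeta]:
    """Trial metadata for a full session (no signals).

    Per participant and condition: ``blocks x 16`` trials, each block a full
    factorial crossing in randomized order; cue timing and target windows
    drawn per trial; ``both_correct`` Bernoulli with the per-condition rates.
    """
    rng = np.random.default_rng(seed)
    metas: list[TrialMeta] = []
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        for condition in ("gaze", "attention"):
            rate = (params.correct_rate_gaze if condition == "gaze"
                    else params.correct_rate_attention)
            trial_idx = 0
            for _ in range(blocks_per_condition):
                for d, b, s, r in _block_factors(rng):
                    if r == "same":
                        d2, b2, s2 = d, b, s
                    else:
                        d2, b2, s2 = _OPPOSITE[d], _FLIP_BRIGHT[b], _OPPOSITE[s]
                    cue1 = spec.motion_onset
                    cue2 = cue1 + rng.uniform(2.9, 3.3)
                    t1 = cue1 + rng.uniform(1.66, 2.16)
                    t2 = cue1 + rng.uniform(4.66, 5.16)
                    metas.append(TrialMeta(
                        participant_id=pid,
                        condition=condition,
                        cue_relation=r,
                        motion_dir_first=d,
                        motion_dir_second=d2,
                        brightness_first=b,
                        brightness_second=b2,
                        cue_side_first=s,
                        cue_side_second=s2,
                        cue1_time=cue1,
                        cue2_time=cue2,
                        target_windows=((t1, TARGET_DURATION), (t2, TARGET_DURATION)),
                        both_correct=bool(rng.random() < rate),
                        trial_index=trial_idx,
                    ))
                    trial_idx += 1
    return metas


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    for _ in range(1000):
        draw = rng.normal(mean, sd)
        if lo < draw < hi:
            return float(draw)
    raise RuntimeError("truncated normal rejection sampling failed")


def simulate_session(
    n_participants: int = 1,
    blocks_per_condition: int = 3,
    spec: StimulusSpec | None = None,
    params: SimulationParams | None = None,
    seed: int | np.random.SeedSequence = 0,
    artifacts: bool = True,
) -> list[TrialRecording]:
    """Simulate a cohort: participants x conditions x (blocks x 16) trials.

    Per-participant ground-truth latencies are drawn once (OKN ~
    Normal(0.4, 0.15) s; pupil ~ Normal(0.9, 0.2) s truncated to (0, 1.4) s,
    keeping every injected valley inside the +/-1.5-s search window) and
    shared by all of that participant's trials.
    """
    spec = spec or StimulusSpec()
    params = params or SimulationParams()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    meta_seed, latency_seed, trial_root = ss.spawn(3)
    metas = generate_metas(n_participants, blocks_per_condition, spec, params,
                           np.random.default_rng(meta_seed))

    lat_rng = np.random.default_rng(latency_seed)
    per_participant: dict[str, tuple[float, float]] = {}
    for p in range(n_participants):
        pid = f"P{p + 1:02d}"
        okn_lat = lat_rng.normal(params.okn_latency_mean, params.okn_latency_sd)
        pupil_lat = _truncated_normal(
            lat_rng, params.pupil_latency_mean, params.pupil_latency_sd,
            params.pupil_latency_bounds)
        per_participant[pid] = (okn_lat, pupil_lat)

    trial_seeds = trial_root.spawn(len(metas))
    recordings: list[TrialRecording] = []
    for meta, tseed in zip(metas, trial_seeds):
        okn_lat, pupil_lat = per_participant[meta.participant_id]
        trial_params = dataclasses.replace(
            params, okn_latency=okn_lat, pupil_latency=pupil_lat)
        recordings.append(
            simulate_trial(meta, spec, trial_params, tseed, artifacts=artifacts))
    return recordings
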