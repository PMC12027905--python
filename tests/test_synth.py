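"""Synthetic session generator: signal morphology, ground truth, design."""

import dataclasses
import math

import numpy as np
import pytest

from oknpupil import (SimulationParams, StimulusSpec, generate_metas,
                      inject_artifacts, mark_invalid_samples,
                      simulate_okn_position, simulate_pupil, simulate_session,
                      simulate_trial)
from tests.conftest import make_meta

FS = 500.0
DT = 1.0 / FS


def transition_oracle(t, center, halfwidth):
    """Independent reimplementation of the raised-cosine switch."""
    w = math.pi * halfwidth / (2.0 * math.asin(0.8))
    u = np.clip((t - center) / w, -1.0, 1.0)
    return 0.5 * (1.0 + np.sin(0.5 * math.pi * u))


class TestOknPosition:
    def test_prestimulus_fixation_near_zero(self, spec, quiet_params):
        pos, _ = simulate_okn_position(make_meta(), spec, quiet_params, 0)
        assert np.all(np.abs(pos[: int(2.5 * FS)]) < 1e-9)

    def test_slow_segment_slopes_equal_gain_times_speed(self, spec,
                                                        quiet_params):
        """Between quick phases on the steady plateau the position slope is
        exactly gain x stimulus speed."""
        meta = make_meta(condition="attention", cue_relation="same",
                         motion_dir_first="left")
        pos, gt = simulate_okn_position(meta, spec, quiet_params, 0)
        want = -gt.okn_gain * spec.stimulus_speed
        bounds = [int(round(s * FS)) for iv in gt.saccade_intervals for s in iv]
        segments = list(zip([0] + bounds[1::2], bounds[0::2] + [pos.size - 1]))
        checked = 0
        for a, b in segments:
            a, b = a + 2, b - 1  # stay clear of the reset ramps
            if a * DT < 4.5 or b * DT > 8.9 or b - a < 10:
                continue  # only fully steady-state segments
            slope = (pos[b] - pos[a]) / ((b - a) * DT)
            assert abs(slope - want) < 1e-9
            checked += 1
        assert checked >= 3

    def test_zero_stimulus_speed_gives_constant_position(self, quiet_params):
        spec0 = StimulusSpec(stimulus_speed=0.0)
        pos, gt = simulate_okn_position(make_meta(condition="attention"),
                                        spec0, quiet_params, 0)
        assert np.allclose(pos, 0.0)
        assert gt.saccade_intervals == []

    def test_quick_phase_count_is_floor_of_displacement(self, spec,
                                                        quiet_params):
        """Brute-force oracle: integrate the commanded slow-phase velocity and
        count amplitude-threshold crossings of the running eccentricity."""
        meta = make_meta(condition="attention", cue_relation="same",
                         motion_dir_first="right")
        pos, gt = simulate_okn_position(meta, spec, quiet_params, 0)
        t = np.arange(spec.n_samples) * DT
        v = (quiet_params.okn_gain_attention * spec.stimulus_speed
             * transition_oracle(t, meta.cue1_time + quiet_params.okn_latency,
                                 quiet_params.transition_halfwidth))
        total = np.sum(np.abs(v)) * DT
        expected = math.floor(total / quiet_params.quick_phase_amplitude)
        assert len(gt.saccade_intervals) == expected

    def test_ground_truth_intervals_sorted_within_trial(self, spec):
        rec = simulate_trial(make_meta(condition="gaze", cue_relation="opposite"),
                             spec, SimulationParams(), 12)
        gt = rec.ground_truth
        for ivals in (gt.saccade_intervals, gt.blink_intervals):
            for (a, b) in ivals:
                assert 0 <= a <= b <= spec.trial_duration
            assert ivals == sorted(ivals)

    def test_latency_outside_trial_rejected(self, spec, quiet_params):
        bad = dataclasses.replace(quiet_params, okn_latency=5.0)
        with pytest.raises(ValueError):
            simulate_okn_position(make_meta(), spec, bad, 0)

    def test_gaze_locus_steps_to_cued_field(self, spec, quiet_params):
        meta = make_meta(condition="gaze", cue_side_first="right")
        _, gt = simulate_okn_position(meta, spec, quiet_params, 0)
        offset = spec.field_center_offset
        assert np.isclose(gt.gaze_offset_trace[-1], offset)
        assert gt.gaze_offset_trace[0] == 0.0

    def test_attention_locus_stays_central(self, spec, quiet_params):
        meta = make_meta(condition="attention", cue_side_first="right")
        _, gt = simulate_okn_position(meta, spec, quiet_params, 0)
        assert np.all(gt.gaze_offset_trace == 0.0)


class TestPupil:
    def test_single_step_matches_closed_form(self, spec, quiet_params):
        meta = make_meta(condition="gaze", cue_relation="same",
                         brightness_first="black")
        pupil, _ = simulate_pupil(meta, spec, quiet_params, 0)
        tau = quiet_params.pupil_tau
        base = quiet_params.pupil_baseline
        a = base + quiet_params.pupil_amplitude
        sw = meta.cue1_time + quiet_params.pupil_latency
        i0 = int(np.searchsorted(np.arange(spec.n_samples) * DT, sw))
        i = np.arange(i0, spec.n_samples)
        closed = a + (base - a) * np.exp(-((i - i0 + 1) * DT) / tau)
        dev = np.max(np.abs(pupil[i0:] - closed))
        assert dev < 1e-6 * quiet_params.pupil_amplitude
        assert np.allclose(pupil[:i0], base)

    def test_same_cue_converges_to_fixed_point(self, spec, quiet_params):
        meta = make_meta(condition="gaze", cue_relation="same",
                         brightness_first="white")
        pupil, _ = simulate_pupil(meta, spec, quiet_params, 0)
        a = quiet_params.pupil_baseline - quiet_params.pupil_amplitude
        tail = pupil[-250:]
        assert np.all(np.abs(np.diff(tail)) < 1e-3)
        assert abs(tail[-1] - a) < quiet_params.pupil_amplitude * 0.01

    def test_black_to_white_dilates_then_constricts(self, spec, quiet_params):
        meta = make_meta(condition="gaze", cue_relation="opposite",
                         brightness_first="black")
        pupil, plat = simulate_pupil(meta, spec, quiet_params, 0)
        t = np.arange(spec.n_samples) * DT
        seg1 = pupil[(t > meta.cue1_time + plat + 0.05)
                     & (t < meta.cue2_time + plat)]
        seg2 = pupil[t > meta.cue2_time + plat + 0.05]
        assert np.all(np.diff(seg1) > 0)  # dilation toward the black asymptote
        assert np.all(np.diff(seg2) < 0)  # constriction after the switch

    def test_attention_weaker_step_and_positive_drift(self, spec, quiet_params):
        mg = make_meta(condition="gaze", cue_relation="same",
                       brightness_first="black")
        ma = make_meta(condition="attention", cue_relation="same",
                       brightness_first="black")
        pg, _ = simulate_pupil(mg, spec, quiet_params, 0)
        pa, _ = simulate_pupil(ma, spec, quiet_params, 0)
        base = quiet_params.pupil_baseline
        drift = quiet_params.attention_drift_slope * 9.0
        assert (pg[-1] - base) > (pa[-1] - base - drift)
        assert pa[-1] > base  # drift keeps covert trials dilating

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(pupil_tau=0.0)
        with pytest.raises(ValueError):
            SimulationParams(pupil_baseline=-1.0)

    def test_strictly_positive_output(self, spec):
        params = SimulationParams()
        for seed in range(3):
            meta = make_meta(condition="attention", brightness_first="white")
            pupil, _ = simulate_pupil(meta, spec, params, seed)
            assert np.all(pupil > 0)


class TestArtifacts:
    def test_zero_blink_rate_only_noise(self, spec):
        params = dataclasses.replace(SimulationParams().noise_free(),
                                     blink_rate=0.0)
        rec = simulate_trial(make_meta(), spec, params, 0, artifacts=False)
        out = inject_artifacts(rec, params, 0, spec)
        assert np.array_equal(out.x, rec.x)
        assert np.array_equal(out.pupil, rec.pupil)
        assert out.ground_truth.blink_intervals == []

    def test_blinks_fully_inside_invalid_mask(self, spec):
        params = dataclasses.replace(SimulationParams(), blink_rate=1.0)
        rec = simulate_trial(make_meta(), spec, params, 5)
        assert rec.ground_truth.blink_intervals  # rate 1/s over 9 s
        pupil_missing = mark_invalid_samples(rec.pupil, FS).missing_mask
        pos_missing = mark_invalid_samples(rec.x, FS).missing_mask
        for (a, b) in rec.ground_truth.blink_intervals:
            i0, i1 = int(round(a * FS)), min(int(round(b * FS)), rec.n_samples - 1)
            assert pupil_missing[i0 : i1 + 1].all()
            assert pos_missing[i0 : i1 + 1].all()

    def test_fixed_seed_is_deterministic(self, spec):
        params = SimulationParams()
        a = simulate_trial(make_meta(), spec, params, 99)
        b = simulate_trial(make_meta(), spec, params, 99)
        assert np.array_equal(a.x, b.x)
        assert np.array_equal(a.y, b.y)
        assert np.array_equal(a.pupil, b.pupil)


class TestSessionDesign:
    def test_default_three_blocks_give_48_per_condition(self, spec):
        metas = generate_metas(1, 3, spec, SimulationParams(), 0)
        per_cond = {}
        for m in metas:
            per_cond[m.condition] = per_cond.get(m.condition, 0) + 1
        assert per_cond == {"gaze": 48, "attention": 48}
        assert len(metas) == 96

    def test_single_block_is_full_factorial(self, spec):
        metas = generate_metas(1, 1, spec, SimulationParams(), 1)
        for cond in ("gaze", "attention"):
            combos = {(m.motion_dir_first, m.brightness_first,
                       m.cue_side_first, m.cue_relation)
                      for m in metas if m.condition == cond}
            assert len(combos) == 16

    def test_correct_rate_matches_binomial(self, spec):
        # 10,000 gaze trials: empirical rate within 3 sigma of 0.9382
        metas = generate_metas(1, 625, spec, SimulationParams(), 7)
        gaze = [m.both_correct for m in metas if m.condition == "gaze"]
        assert len(gaze) == 10_000
        rate = np.mean(gaze)
        sigma = math.sqrt(0.9382 * (1 - 0.9382) / 10_000)
        assert abs(rate - 0.9382) < 3 * sigma

    def test_opposite_relation_flips_all_labels(self, spec):
        metas = generate_metas(2, 1, spec, SimulationParams(), 3)
        flip = {"left": "right", "right": "left",
                "white": "black", "black": "white"}
        for m in metas:
            if m.cue_relation == "opposite":
                assert m.motion_dir_second == flip[m.motion_dir_first]
                assert m.brightness_second == flip[m.brightness_first]
                assert m.cue_side_second == flip[m.cue_side_first]

    def test_session_bit_reproducible(self, spec):
        params = SimulationParams()
        a = simulate_session(1, 1, spec, params, seed=5)
        b = simulate_session(1, 1, spec, params, seed=5)
        assert len(a) == len(b) == 32
        for ra, rb in zip(a, b):
            assert ra.meta == rb.meta
            assert np.array_equal(ra.x, rb.x)
            assert np.array_equal(ra.pupil, rb.pupil)

    def test_per_participant_latencies_shared_and_bounded(self, spec):
        trials = simulate_session(2, 1, spec, SimulationParams(), seed=2)
        by_pid = {}
        for tr in trials:
            by_pid.setdefault(tr.meta.participant_id, set()).add(
                (tr.ground_truth.okn_latency, tr.ground_truth.pupil_latency))
        assert set(by_pid) == {"P01", "P02"}
        for lats in by_pid.values():
            assert len(lats) == 1  # one draw per participant
            (okn_lat, pupil_lat), = lats
            assert 0.0 < pupil_lat < 1.4
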