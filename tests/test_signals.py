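"""Characteristic-signal extraction and event detection against ground truth."""

import numpy as np
import pytest

import mocapqc as m
from mocapqc.recording import JOINT_INDEX

from conftest import make_skeleton_recording

D, K, T = m.DefectSpec, m.DefectKind, m.TaskType


# ---------------------------------------------------------------------------
# Position signals
# ---------------------------------------------------------------------------

def test_quiet_stance_position_is_stable(poco_clean):
    rec, _ = poco_clean
    z = m.extract_position_signals(rec).signals["position_z"].values
    assert np.nanmax(np.abs(z - z[0])) < 0.05


def test_forward_drift_recovered_from_position_signal():
    cfg = m.task_defaults(T.SIP, seed=31, render_depth=False)
    rec, _ = m.simulate_recording(cfg, [D(K.FORWARD_DRIFT, 0.6)])
    z = m.extract_position_signals(rec).signals["position_z"].values
    assert z[-1] - z[0] == pytest.approx(-0.60, abs=0.02)


def test_walk_speed_recovered_by_regression():
    cfg = m.task_defaults(T.SCSW, seed=32, render_depth=False)
    rec, _ = m.simulate_recording(cfg)
    sig = m.extract_position_signals(rec).signals["position_z"]
    sel = (sig.t >= 1.2) & (sig.t <= 2.9)  # steady part of the walk window
    slope = np.polyfit(sig.t[sel], sig.values[sel], 1)[0]
    assert slope == pytest.approx(-1.2, abs=0.05)


def test_low_confidence_gaps_are_interpolated_up_to_half_second():
    rec = make_skeleton_recording(T.POCO, np.arange(0, 3, 1 / 30))
    t, P, C = rec.skeleton_arrays()
    pelvis = JOINT_INDEX["SpineBase"]
    C[30:40, pelvis] = 0.0   # 0.33 s gap: interpolated
    C[60:90, pelvis] = 0.0   # 1.0 s gap: left missing
    z = m.extract_position_signals(rec).signals["position_z"].values
    assert np.all(np.isfinite(z[30:40]))
    assert np.all(np.isnan(z[61:89]))


# ---------------------------------------------------------------------------
# Knee amplitude and arm sway
# ---------------------------------------------------------------------------

def test_knee_amplitude_matches_injected_lift(sip_clean):
    rec, _ = sip_clean
    from scipy.signal import find_peaks

    for name in ("knee_amplitude_left", "knee_amplitude_right"):
        sig = m.extract_knee_amplitude(rec).signals[name]
        peaks, _ = find_peaks(sig.values, height=0.05)
        assert np.mean(sig.values[peaks]) == pytest.approx(0.15, abs=0.01)


def test_knee_amplitude_without_stepping_stays_in_noise_band():
    cfg = m.task_defaults(T.SIP, seed=33, render_depth=False, knee_lift_m=0.0)
    rec, _ = m.simulate_recording(cfg)
    sig = m.extract_knee_amplitude(rec).signals["knee_amplitude_left"]
    assert np.nanmax(sig.values) < 0.03


def test_arm_sway_quiet_when_arms_still(poco_clean):
    rec, _ = poco_clean
    sway = m.extract_arm_sway(rec)
    for name in ("arm_sway_left", "arm_sway_right"):
        assert np.nanmax(sway.signals[name].values) < 0.03


def test_arm_movement_defect_visible_at_injection_time():
    cfg = m.task_defaults(T.POCO, seed=34, render_depth=False)
    rec, _ = m.simulate_recording(cfg, [D(K.ARM_MOVEMENT, 0.2, onset_s=22.0)])
    sig = m.extract_arm_sway(rec).signals["arm_sway_right"]
    sel = (sig.t >= 20) & (sig.t <= 24)
    assert np.nanmax(sig.values[sel]) >= 0.15


def test_arm_sway_invariant_to_whole_body_translation():
    cfg = m.task_defaults(T.SCSW, seed=35, render_depth=False)
    rec, _ = m.simulate_recording(cfg)
    sway = m.extract_arm_sway(rec)
    for name in ("arm_sway_left", "arm_sway_right"):
        assert np.nanmax(sway.signals[name].values) < 0.05


def test_translation_offset_leaves_relative_signals_unchanged(sip_clean):
    rec, _ = sip_clean
    t, P, C = rec.skeleton_arrays()
    shifted = m.Recording(
        metadata=rec.metadata,
        skeleton_frames=[
            m.SkeletonFrame(float(ti), lm + np.array([1.3, 0.0, 0.7]), c)
            for ti, lm, c in zip(t, P, C)
        ],
    )
    a = m.extract_knee_amplitude(rec).signals["knee_amplitude_left"].values
    b = m.extract_knee_amplitude(shifted).signals["knee_amplitude_left"].values
    np.testing.assert_allclose(a, b, atol=1e-9)
    a = m.extract_arm_sway(rec).signals["arm_sway_left"].values
    b = m.extract_arm_sway(shifted).signals["arm_sway_left"].values
    np.testing.assert_allclose(a, b, atol=1e-9)


# ---------------------------------------------------------------------------
# Step detection
# ---------------------------------------------------------------------------

def test_clean_sip_steps_exact_count_and_alternation(sip_clean):
    rec, gt = sip_clean
    events = m.detect_steps(rec)
    assert len(events) == len(gt.true_step_times) == 40
    sides = [e.side for e in events]
    assert all(a != b for a, b in zip(sides, sides[1:]))
    times = [e.t_contact for e in events]
    assert times == sorted(times)


def test_flat_signal_yields_no_steps():
    cfg = m.task_defaults(T.SIP, seed=36, render_depth=False, knee_lift_m=0.0)
    rec, _ = m.simulate_recording(cfg)
    assert m.detect_steps(rec) == []


def test_step_count_matches_local_maxima_oracle_on_noiseless_input():
    cfg = m.task_defaults(T.SIP, seed=37, render_depth=False,
                          landmark_noise_m=0.0)
    rec, _ = m.simulate_recording(cfg)
    t, P, _ = rec.skeleton_arrays()
    gate = 0.05
    oracle = 0
    for joint in ("AnkleLeft", "AnkleRight"):
        y = P[:, JOINT_INDEX[joint], 1]
        h = y - np.percentile(y, 10)
        above = h > gate
        # brute force: count maximal runs above the gate
        oracle += int(np.sum(np.diff(above.astype(int)) == 1)
                      + (1 if above[0] else 0))
    assert len(m.detect_steps(rec)) == oracle


def test_stance_phases_are_ordered_and_positive(sip_clean):
    rec, _ = sip_clean
    for e in m.detect_steps(rec):
        if e.stance is not None:
            assert e.stance[0] < e.stance[1]


# ---------------------------------------------------------------------------
# Sit-to-stand phases
# ---------------------------------------------------------------------------

def test_clean_sas_three_alternating_cycles(sas_clean):
    rec, _ = sas_clean
    phases = m.detect_sas_phases(rec)
    kinds = [p.kind for p in phases]
    assert kinds == ["stand_up", "sit_down"] * 3
    assert all(p.complete for p in phases)
    for a, b in zip(phases, phases[1:]):
        assert a.end <= b.start  # non-overlapping, time-ordered


def test_truncation_mid_rise_marks_final_phase_incomplete():
    cfg = m.task_defaults(T.SAS, seed=38, render_depth=False, duration_s=18.8)
    rec, _ = m.simulate_recording(cfg)  # ends inside the third rise (18-19.5)
    phases = m.detect_sas_phases(rec)
    assert phases[-1].complete is False
    assert phases[-1].end == pytest.approx(rec.duration_s, abs=0.05)


def test_constant_height_yields_no_phases():
    rec = make_skeleton_recording(T.SAS, np.arange(0, 5, 1 / 30))
    assert m.detect_sas_phases(rec) == []


@pytest.mark.parametrize("seed", range(5))
def test_phase_segments_tile_over_random_clean_recordings(seed):
    rec, _ = m.simulate_recording(
        m.task_defaults(T.SAS, seed=200 + seed, render_depth=False))
    phases = m.detect_sas_phases(rec)
    kinds = [p.kind for p in phases]
    assert all(a != b for a, b in zip(kinds, kinds[1:]))
    for a, b in zip(phases, phases[1:]):
        assert a.end <= b.start


# ---------------------------------------------------------------------------
# Stance width and dispatcher
# ---------------------------------------------------------------------------

def test_stance_width_recovers_ankle_separation(poco_clean):
    rec, _ = poco_clean
    width = m.compute_stance_width(rec).signals["stance_width"].values
    assert np.median(width) == pytest.approx(0.08, abs=0.01)
    assert np.all(width >= 0)


def test_stance_width_recovers_open_feet_defect():
    cfg = m.task_defaults(T.POCO, seed=39, render_depth=False)
    rec, _ = m.simulate_recording(cfg, [D(K.OPEN_FEET, 0.30)])
    width = m.compute_stance_width(rec).signals["stance_width"].values
    assert np.median(width) == pytest.approx(0.30, abs=0.02)


def test_task_signal_dispatcher_vocabulary(sip_clean, poco_clean):
    vocabulary = {
        "position_x", "position_y", "position_z", "stance_width",
        "arm_sway_left", "arm_sway_right", "knee_amplitude_left",
        "knee_amplitude_right", "pelvis_height",
    }
    sip_rec, _ = sip_clean
    names = set(m.extract_task_signals(sip_rec).signals)
    assert {"knee_amplitude_left", "knee_amplitude_right", "arm_sway_left",
            "arm_sway_right", "position_z"} <= names
    assert names <= vocabulary

    poco_rec, _ = poco_clean
    names = set(m.extract_task_signals(poco_rec).signals)
    assert "stance_width" in names
    assert not any(n.startswith("knee_amplitude") for n in names)
    assert names <= vocabulary


def test_tidy_csv_export_shape(sip_clean):
    rec, _ = sip_clean
    df = m.extract_task_signals(rec).to_frame("rec-1")
    assert list(df.columns) == ["recording_id", "signal", "t", "value", "unit"]
    assert (df["recording_id"] == "rec-1").all()


@pytest.mark.parametrize("op,task", [
    (m.extract_knee_amplitude, T.POCO),
    (m.detect_steps, T.SAS),
    (m.detect_sas_phases, T.SIP),
    (m.compute_stance_width, T.SCSW),
])
def test_wrong_task_raises_applicability_error(op, task):
    rec = make_skeleton_recording(task, np.arange(0, 2, 1 / 30))
    with pytest.raises(m.ApplicabilityError):
        op(rec)
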