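"""Automated quality-flag detectors: thresholds, boundaries, applicability."""

import numpy as np
import pytest

import mocapqc as m
from mocapqc.recording import JOINT_INDEX

from conftest import make_skeleton_recording

D, K, T, Q = m.DefectSpec, m.DefectKind, m.TaskType, m.QualityCriterion
PELVIS = JOINT_INDEX["SpineBase"]


# ---------------------------------------------------------------------------
# Duration: 40 +/- 1 s, strictly "more than"
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("task,duration,raised,evidence", [
    (T.POCO, 40.0, False, 0.0),
    (T.SIP, 38.5, True, 1.5),
    (T.POCO_DUAL, 41.0, False, 1.0),  # deviation exactly 1 s: strict >
    (T.SIP, 41.5, True, 1.5),
])
def test_duration_flag_boundary(task, duration, raised, evidence):
    cfg = m.task_defaults(task, seed=1, render_depth=False,
                          duration_s=duration)
    rec, _ = m.simulate_recording(cfg)
    flag = m.flag_duration(rec)
    assert flag.raised is raised
    assert flag.evidence == pytest.approx(evidence, abs=0.05)


# ---------------------------------------------------------------------------
# Forward / backward drift: 50 cm, strict; 0.80 m tolerant preset
# ---------------------------------------------------------------------------

def _sip_with_exact_drift(drift_m, sign=-1.0):
    """Noise-free SIP recording whose pelvis z ramps by exactly ``drift_m``.

    The first second is held still so the detector's start reference equals
    the true starting position exactly.
    """
    t = np.arange(0, 40, 1 / 30)

    def transform(i, ti, lm):
        lm[:, 2] += sign * drift_m * min(max(ti - 1.0, 0.0) / 30.0, 1.0)
        return lm

    return make_skeleton_recording(T.SIP, t, transform)


def test_forward_flag_strict_threshold():
    assert m.flag_forward(_sip_with_exact_drift(0.60)).raised
    assert not m.flag_forward(_sip_with_exact_drift(0.0)).raised
    # evidence exactly at the 0.50 m threshold never raises
    flag = m.flag_forward(_sip_with_exact_drift(0.50))
    assert flag.evidence == pytest.approx(0.50, abs=1e-9)
    assert not flag.raised


def test_forward_flag_tolerant_preset():
    cfg = m.FlagConfig.tolerant_forward()
    assert cfg.forward_m == 0.80
    assert not m.flag_forward(_sip_with_exact_drift(0.60), cfg).raised
    assert m.flag_forward(_sip_with_exact_drift(0.90), cfg).raised


def test_backward_flag_threshold_and_correction():
    assert m.flag_backward(_sip_with_exact_drift(0.60, sign=+1.0)).raised
    assert not m.flag_backward(_sip_with_exact_drift(0.0)).raised
    # forward 0.4 m then back to start: the correction heuristic raises
    cfg = m.task_defaults(T.SIP, seed=2, render_depth=False)
    rec, _ = m.simulate_recording(cfg, [D(K.FORWARD_DRIFT, 0.4, onset_s=5.0),
                                        D(K.BACKWARD_DRIFT, 0.4, onset_s=22.0)])
    flag = m.flag_backward(rec)
    assert flag.raised and flag.note == "correction"
    assert flag.evidence < 0.5  # net backward never exceeded the threshold


# ---------------------------------------------------------------------------
# Feet / movements / sidestep / arms
# ---------------------------------------------------------------------------

def test_feet_flag_open_vs_closed(poco_clean):
    rec, _ = poco_clean
    assert not m.flag_feet(rec).raised
    cfg = m.task_defaults(T.POCO, seed=3, render_depth=False)
    rec_open, _ = m.simulate_recording(cfg, [D(K.OPEN_FEET, 0.30)])
    assert m.flag_feet(rec_open).raised


def test_feet_flag_exact_threshold_does_not_raise():
    # ankles exactly 0.15 m apart, noise-free: strict boundary
    from mocapqc.simulate import base_pose

    t = np.arange(0, 10, 1 / 30)
    rec = make_skeleton_recording(T.POCO, t)
    for f in rec.skeleton_frames:
        f.landmarks[JOINT_INDEX["AnkleLeft"], 0] = 0.075
        f.landmarks[JOINT_INDEX["AnkleRight"], 0] = -0.075
    flag = m.flag_feet(rec)
    assert flag.evidence == pytest.approx(0.15, abs=1e-12)
    assert not flag.raised


def test_movements_flag_with_dual_task_caveat():
    for task, note_expected in ((T.POCO, ""), (T.POCO_DUAL, "task-associated")):
        cfg = m.task_defaults(task, seed=4, render_depth=False)
        rec, _ = m.simulate_recording(cfg, [D(K.ARM_MOVEMENT, 0.2, 22.0)])
        flag = m.flag_movements(rec)
        assert flag.raised
        assert note_expected in flag.note
    clean, _ = m.simulate_recording(
        m.task_defaults(T.POCO, seed=4, render_depth=False))
    assert not m.flag_movements(clean).raised


def test_sas_movements_ignore_transition_windows(sas_clean):
    rec, _ = sas_clean
    assert not m.flag_movements(rec).raised
    cfg = m.task_defaults(T.SAS, seed=5, render_depth=False)
    rec_def, _ = m.simulate_recording(cfg, [D(K.ARM_MOVEMENT, 0.2, 4.2)])
    assert m.flag_movements(rec_def).raised


def test_sidestep_flag_fast_step_vs_slow_lean():
    cfg = m.task_defaults(T.POCO, seed=6, render_depth=False)
    rec, _ = m.simulate_recording(cfg, [D(K.SIDESTEP, 0.25)])
    assert m.flag_sidestep(rec).raised
    clean, _ = m.simulate_recording(
        m.task_defaults(T.POCO, seed=6, render_depth=False))
    assert not m.flag_sidestep(clean).raised
    # a 0.25 m lateral lean over 10 s is rate-limited out
    t = np.arange(0, 12, 1 / 30)

    def lean(i, ti, lm):
        lm[:, 0] += 0.25 * min(ti / 10.0, 1.0)
        return lm

    rec_lean = make_skeleton_recording(T.POCO, t, lean)
    flag = m.flag_sidestep(rec_lean)
    assert flag.evidence == pytest.approx(0.025, abs=0.005)
    assert not flag.raised


def test_arms_start_flag(sas_clean):
    rec, _ = sas_clean
    assert not m.flag_arms_start(rec).raised
    cfg = m.task_defaults(T.SAS, seed=7, render_depth=False)
    rec_def, _ = m.simulate_recording(cfg, [D(K.ARMS_NOT_DOWN_AT_START, 0.10)])
    flag = m.flag_arms_start(rec_def)
    assert flag.raised
    assert flag.evidence == pytest.approx(0.10, abs=0.02)


def test_arms_start_one_hand_raised_uses_max_of_sides():
    t = np.arange(0, 10, 1 / 30)
    hand_joints = [JOINT_INDEX[n] for n in
                   ("HandLeft", "WristLeft", "HandTipLeft", "ThumbLeft")]

    def raise_left(i, ti, lm):
        for j in hand_joints:
            lm[j, 1] = lm[JOINT_INDEX["HipLeft"], 1] + 0.2
        return lm

    rec = make_skeleton_recording(T.SAS, t, raise_left)
    assert m.flag_arms_start(rec).raised


# ---------------------------------------------------------------------------
# Disturbances / step detection / up-down phases
# ---------------------------------------------------------------------------

def _depth_cfg(task, seed):
    return m.task_defaults(task, seed=seed, depth_width=96, depth_height=80,
                           depth_fps=2.0)


def test_disturbances_flag_and_dose_response():
    clean, _ = m.simulate_recording(_depth_cfg(T.POCO, 8))
    assert not m.flag_disturbances(clean).raised
    evidences = []
    for mag in (0.05, 0.15, 0.30):
        rec, _ = m.simulate_recording(_depth_cfg(T.POCO, 8),
                                      [D(K.CLOTHING_NOISE, mag)])
        evidences.append(m.flag_disturbances(rec).evidence)
    assert evidences[0] < evidences[1] < evidences[2]
    assert not (evidences[0] > 0.10)
    assert evidences[2] > 0.10


def test_floor_noise_raises_disturbances():
    rec, _ = m.simulate_recording(_depth_cfg(T.SCSW, 9),
                                  [D(K.FLOOR_NOISE, 0.30)])
    assert m.flag_disturbances(rec).raised


def test_step_detection_flag_clean_and_broken():
    clean, _ = m.simulate_recording(
        m.task_defaults(T.SCSW, seed=10, render_depth=False))
    assert not m.flag_step_detection(clean).raised
    rec, _ = m.simulate_recording(
        m.task_defaults(T.SIP, seed=10, render_depth=False),
        [D(K.MISSING_STEPS, 10)])
    flag = m.flag_step_detection(rec)
    assert flag.raised and "alternate" in flag.note


def test_smsw_truncated_before_full_gait_cycle():
    cfg = m.task_defaults(T.SMSW, seed=11, render_depth=False, duration_s=1.9)
    rec, _ = m.simulate_recording(cfg)
    flag = m.flag_step_detection(rec)
    assert flag.raised
    assert "no full gait cycle" in flag.note


def test_updown_phase_flag(sas_clean):
    rec, _ = sas_clean
    assert not m.flag_updown_phase(rec).raised
    cfg = m.task_defaults(T.SAS, seed=12, render_depth=False)
    rec_trunc, _ = m.simulate_recording(cfg, [D(K.TRUNCATED_DURATION, 4.0)])
    assert m.flag_updown_phase(rec_trunc).raised
    # only two full cycles simulated -> count mismatch
    rec_two, _ = m.simulate_recording(
        m.task_defaults(T.SAS, seed=12, render_depth=False, duration_s=18.0))
    assert m.flag_updown_phase(rec_two).raised


# ---------------------------------------------------------------------------
# Orchestration invariants
# ---------------------------------------------------------------------------

def test_applicability_closure_over_all_tasks():
    for task in T:
        rec, _ = m.simulate_recording(
            m.task_defaults(task, seed=13, render_depth=False))
        flags = m.run_autoflag(rec)
        emitted = [f.criterion for f in flags]
        assert emitted == [c for c in Q if task in m.CRITERION_TASKS[c]]
        for f in flags:
            assert task in m.CRITERION_TASKS[f.criterion]
    # a walk task never yields a FORWARD flag object
    rec, _ = m.simulate_recording(
        m.task_defaults(T.SCSW, seed=13, render_depth=False))
    assert Q.FORWARD not in {f.criterion for f in m.run_autoflag(rec)}


def test_support_and_other_are_manual_only(poco_clean):
    rec, _ = poco_clean
    by_crit = {f.criterion: f for f in m.run_autoflag(rec)}
    for crit in (Q.SUPPORT, Q.OTHER):
        assert by_crit[crit].raised is False
        assert by_crit[crit].note == "manual-only"


def test_threshold_monotonicity():
    """Raising a threshold never converts not-raised into raised."""
    cases = [
        (m.flag_forward, _sip_with_exact_drift(0.60), "forward_m"),
        (m.flag_feet, None, "feet_width_m"),
        (m.flag_sidestep, None, "sidestep_m"),
        (m.flag_movements, None, "movement_excursion_m"),
    ]
    cfg_poco = m.task_defaults(T.POCO, seed=14, render_depth=False)
    rec_feet, _ = m.simulate_recording(cfg_poco, [D(K.OPEN_FEET, 0.30)])
    rec_side, _ = m.simulate_recording(cfg_poco, [D(K.SIDESTEP, 0.30)])
    rec_move, _ = m.simulate_recording(cfg_poco, [D(K.ARM_MOVEMENT, 0.2, 22.0)])
    cases[1] = (m.flag_feet, rec_feet, "feet_width_m")
    cases[2] = (m.flag_sidestep, rec_side, "sidestep_m")
    cases[3] = (m.flag_movements, rec_move, "movement_excursion_m")
    for detector, rec, key in cases:
        ev = detector(rec).evidence
        low = m.FlagConfig(**{key: ev * 0.99})
        high = m.FlagConfig(**{key: ev * 1.01})
        assert detector(rec, low).raised
        assert not detector(rec, high).raised


def test_combined_defects_raise_exactly_their_criteria():
    cfg = m.task_defaults(T.SIP, seed=15, depth_width=96, depth_height=80,
                          depth_fps=2.0)
    rec, _ = m.simulate_recording(cfg, [D(K.FORWARD_DRIFT, 0.6),
                                        D(K.CLOTHING_NOISE, 0.3)])
    raised = {f.criterion for f in m.run_autoflag(rec) if f.raised}
    assert {Q.FORWARD, Q.DISTURBANCES} <= raised
    assert raised <= {Q.FORWARD, Q.DISTURBANCES, Q.STEP_DETECTION}


def test_run_autoflag_without_depth_notes_disturbances(poco_clean):
    rec, _ = poco_clean
    by_crit = {f.criterion: f for f in m.run_autoflag(rec)}
    assert by_crit[Q.DISTURBANCES].note == "no depth stream"
    assert by_crit[Q.DISTURBANCES].raised is False


def test_flag_applicability_errors():
    rec = make_skeleton_recording(T.SCSW, np.arange(0, 2, 1 / 30))
    for detector in (m.flag_duration, m.flag_forward, m.flag_backward,
                     m.flag_feet, m.flag_arms_start, m.flag_updown_phase,
                     m.flag_sidestep, m.flag_movements):
        with pytest.raises(m.ApplicabilityError):
            detector(rec)


def test_flags_export_table(poco_clean):
    rec, _ = poco_clean
    df = m.flags_to_frame(m.run_autoflag(rec), "rec-9")
    assert set(df.columns) == {"recording_id", "criterion", "category",
                               "raised", "evidence", "unit", "threshold",
                               "note"}
    assert (df["recording_id"] == "rec-9").all()
    assert set(df["category"]) <= {"technical", "performance", "either"}
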