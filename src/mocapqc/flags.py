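"""Automated detectors for the 12-criterion recording-quality taxonomy.

Each detector measures a scalar piece of evidence for one quality criterion
and compares it against a configurable threshold. The boundary convention is
strict everywhere: evidence exactly equal to the threshold never raises a
flag ("more than" semantics). Two thresholds come from the assessment
protocol itself — recording duration 40 +/- 1 s for the timed tasks, and
50 cm of forward/backward drift during in-place stepping (with a tolerant
0.80 m preset for the forward criterion). All other thresholds are explicit
heuristic defaults of this package; internal consistency with the synthetic
defect battery is what the tests establish, not equivalence with human
raters.

SUPPORT (external support object) and OTHER are kept in the taxonomy for
manual-rating compatibility but are never auto-raised (note "manual-only"):
detecting a walking aid would require object recognition, out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from enum import Enum

import numpy as np
import pandas as pd

from .recording import JOINT_INDEX, Recording, TaskType
from .signals import (
    ApplicabilityError,
    detect_sas_phases,
    detect_steps,
    compute_stance_width,
    extract_arm_sway,
    extract_position_signals,
)
from .simulate import body_and_leg_masks

_J = JOINT_INDEX


class QualityCriterion(Enum):
    DISTURBANCES = "DISTURBANCES"      # technical: noisy background/floor/clothing
    DURATION = "DURATION"              # technical: duration deviates > 1 s from 40 s
    STEP_DETECTION = "STEP_DETECTION"  # technical: implausible step events
    UP_DOWN_PHASE = "UP_DOWN_PHASE"    # technical: incomplete/incorrect SAS phases
    ARMS = "ARMS"                      # performance: arms not down at start (SAS)
    BACKWARD = "BACKWARD"              # performance: > 50 cm backward or correction
    FEET = "FEET"                      # performance: feet not closed (stance tasks)
    FORWARD = "FORWARD"                # performance: > 50 cm forward drift (SIP)
    MOVEMENTS = "MOVEMENTS"            # performance: task-unassociated movements
    SIDESTEP = "SIDESTEP"              # performance: one or more sidesteps
    SUPPORT = "SUPPORT"                # performance: external support (manual-only)
    OTHER = "OTHER"                    # either: unlisted concern (manual-only)


CRITERION_CATEGORY: dict[QualityCriterion, str] = {
    QualityCriterion.DISTURBANCES: "technical",
    QualityCriterion.DURATION: "technical",
    QualityCriterion.STEP_DETECTION: "technical",
    QualityCriterion.UP_DOWN_PHASE: "technical",
    QualityCriterion.ARMS: "performance",
    QualityCriterion.BACKWARD: "performance",
    QualityCriterion.FEET: "performance",
    QualityCriterion.FORWARD: "performance",
    QualityCriterion.MOVEMENTS: "performance",
    QualityCriterion.SIDESTEP: "performance",
    QualityCriterion.SUPPORT: "performance",
    QualityCriterion.OTHER: "either",
}

_ALL = frozenset(TaskType)
_STANCE = frozenset({TaskType.POCO, TaskType.POCO_DUAL})

CRITERION_TASKS: dict[QualityCriterion, frozenset[TaskType]] = {
    QualityCriterion.DISTURBANCES: _ALL,
    QualityCriterion.DURATION: frozenset(
        {TaskType.POCO, TaskType.POCO_DUAL, TaskType.SIP}),
    QualityCriterion.STEP_DETECTION: frozenset(
        {TaskType.SCSW, TaskType.SMSW, TaskType.SIP, TaskType.SLW}),
    QualityCriterion.UP_DOWN_PHASE: frozenset({TaskType.SAS}),
    QualityCriterion.ARMS: frozenset({TaskType.SAS}),
    QualityCriterion.BACKWARD: frozenset({TaskType.SIP}),
    QualityCriterion.FEET: _STANCE,
    QualityCriterion.FORWARD: frozenset({TaskType.SIP}),
    QualityCriterion.MOVEMENTS: frozenset(
        {TaskType.POCO, TaskType.POCO_DUAL, TaskType.SLW, TaskType.SIP,
         TaskType.SAS}),
    QualityCriterion.SIDESTEP: frozenset(
        {TaskType.POCO, TaskType.POCO_DUAL, TaskType.SLW}),
    QualityCriterion.SUPPORT: _ALL,
    QualityCriterion.OTHER: _ALL,
}


@dataclass
class AutoFlag:
    criterion: QualityCriterion
    raised: bool
    evidence: float | None
    threshold: float | None
    unit: str = ""
    note: str = ""


@dataclass
class FlagConfig:
    """All detector thresholds; every field is overridable.

    ``duration_nominal_s``/``duration_tol_s`` and ``forward_m``/``backward_m``
    follow the assessment protocol; the rest are heuristic package defaults.
    ``tolerant_forward()`` gives the 0.80 m alternative preset discussed for
    the forward criterion.
    """

    duration_nominal_s: float = 40.0
    duration_tol_s: float = 1.0
    forward_m: float = 0.50
    backward_m: float = 0.50
    correction_excursion_m: float = 0.25
    feet_width_m: float = 0.15
    feet_window_s: float = 5.0
    movement_excursion_m: float = 0.10
    sidestep_m: float = 0.15
    sidestep_window_s: float = 1.0
    arms_tol_m: float = 0.05
    arms_window_s: float = 2.0
    noise_fraction: float = 0.10
    depth_change_mm: float = 200.0
    cadence_min_hz: float = 0.3
    cadence_max_hz: float = 3.5
    alternation_fail_max: float = 0.20
    sas_expected_cycles: int = 3

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "sas_expected_cycles":
                continue
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name}: thresholds must be > 0")

    @classmethod
    def tolerant_forward(cls, forward_m: float = 0.80) -> "FlagConfig":
        return cls(forward_m=forward_m)

    def replace(self, **kw) -> "FlagConfig":
        return replace(self, **kw)


def _require(rec: Recording, criterion: QualityCriterion) -> None:
    if rec.metadata.task not in CRITERION_TASKS[criterion]:
        raise ApplicabilityError(
            f"{criterion.value} does not apply to task {rec.metadata.task.value}"
        )


def _position_z(rec: Recording) -> tuple[np.ndarray, np.ndarray]:
    sig = extract_position_signals(rec).signals["position_z"]
    return sig.t, sig.values


def _start_ref(t: np.ndarray, v: np.ndarray, window_s: float = 0.5) -> float:
    """Noise-robust starting value: mean over the first ``window_s``."""
    sel = t <= t[0] + window_s
    return float(np.nanmean(v[sel]))


# ---------------------------------------------------------------------------
# Individual detectors
# ---------------------------------------------------------------------------

def flag_duration(rec: Recording, cfg: FlagConfig | None = None) -> AutoFlag:
    """Recording duration deviating by more than 1 s from the nominal 40 s."""
    cfg = cfg or FlagConfig()
    _require(rec, QualityCriterion.DURATION)
    deviation = abs(rec.duration_s - cfg.duration_nominal_s)
    return AutoFlag(QualityCriterion.DURATION,
                    raised=deviation > cfg.duration_tol_s,
                    evidence=deviation, threshold=cfg.duration_tol_s, unit="s")


def flag_forward(rec: Recording, cfg: FlagConfig | None = None) -> AutoFlag:
    """Subject moving forward (toward the camera) by more than the threshold."""
    cfg = cfg or FlagConfig()
    _require(rec, QualityCriterion.FORWARD)
    t, z = _position_z(rec)
    z0 = _start_ref(t, z)
    evidence = float(np.nanmax(z0 - z))
    return AutoFlag(QualityCriterion.FORWARD, raised=evidence > cfg.forward_m,
                    evidence=evidence, threshold=cfg.forward_m, unit="m")


def flag_backward(rec: Recording, cfg: FlagConfig | None = None) -> AutoFlag:
    """Backward drift beyond the threshold, or a deliberate-looking correction.

    The correction heuristic: a backward excursion of at least
    ``correction_excursion_m`` occurring after a forward excursion of the
    same size (the subject walked forward, noticed, and stepped back).
    """
    cfg = cfg or FlagConfig()
    _require(rec, QualityCriterion.BACKWARD)
    t, z = _position_z(rec)
    z0 = _start_ref(t, z)
    evidence = float(np.nanmax(z - z0))
    fwd = z0 - z  # forward displacement, positive toward camera
    fwd = np.where(np.isnan(fwd), -np.inf, fwd)
    run_max = np.maximum.accumulate(fwd)
    back_after_fwd = np.where(run_max >= cfg.correction_excursion_m,
                              run_max - fwd, -np.inf)
    correction = bool(np.max(back_after_fwd) >= cfg.correction_excursion_m)
    raised = evidence > cfg.backward_m or correction
    return AutoFlag(QualityCriterion.BACKWARD, raised=raised,
                    evidence=evidence, threshold=cfg.backward_m, unit="m",
                    note="correction" if correction else "")


def flag_feet(rec: Recording, cfg: FlagConfig | None = None) -> AutoFlag:
    """Deviation from the closed-feet stance position (median early width)."""
    cfg = cfg or FlagConfig()
    _require(rec, QualityCriterion.FEET)
    sig = compute_stance_width(rec).signals["stance_width"]
    sel = sig.t <= sig.t[0] + cfg.feet_window_s
    evidence = float(np.nanmedian(sig.values[sel]))
    return AutoFlag(QualityCriterion.FEET, raised=evidence > cfg.feet_width_m,
                    evidence=evidence, threshold=cfg.feet_width_m, unit="m")


def flag_movements(rec: Recording, cfg: FlagConfig | None = None) -> AutoFlag:
    """Task-unassociated movements: arm-sway peaks outside expected windows.

    For SAS the detected stand-up/sit-down transitions (+/- 0.5 s) are
    excluded, since arms legitimately move there. For the dual-task stance
    the note records that gesturing may be task-associated (mental
    arithmetic), so the flag is decision support rather than a verdict.
    """
    cfg = cfg or FlagConfig()
    _require(rec, QualityCriterion.MOVEMENTS)
    sway = extract_arm_sway(rec)
    task = rec.metadata.task
    exclude: list[tuple[float, float]] = []
    if task is TaskType.SAS:
        exclude = [(p.start - 0.5, p.end + 0.5) for p in detect_sas_phases(rec)]
    evidence = 0.0
    for name in ("arm_sway_left", "arm_sway_right"):
        s = sway.signals[name]
        keep = np.ones(len(s.t), dtype=bool)
        for a, b in exclude:
            keep &= ~((s.t >= a) & (s.t <= b))
        if keep.any():
            evidence = max(evidence, float(np.nanmax(s.values[keep])))
    note = ("dual-task gesturing may be task-associated"
            if task is TaskType.POCO_DUAL else "")
    return AutoFlag(QualityCriterion.MOVEMENTS,
                    raised=evidence > cfg.movement_excursion_m,
                    evidence=evidence, threshold=cfg.movement_excursion_m,
                    unit="m", note=note)


def flag_sidestep(rec: Recording, cfg: FlagConfig | None = None) -> AutoFlag:
    """Rapid mediolateral pelvis displacement within any 1 s window.

    The rate-limited window separates a sidestep (fast) from a slow lateral
    lean of the same total extent.
    """
    cfg = cfg or FlagConfig()
    _require(rec, QualityCriterion.SIDESTEP)
    sig = extract_position_signals(rec).signals["position_x"]
    t, x = sig.t, sig.values
    lag = max(1, int(round(cfg.sidestep_window_s * _fs_of(t))))
    if len(x) <= lag:
        evidence = 0.0
    else:
        d = np.abs(x[lag:] - x[:-lag])
        evidence = float(np.nanmax(d)) if np.isfinite(d).any() else 0.0
    return AutoFlag(QualityCriterion.SIDESTEP, raised=evidence > cfg.sidestep_m,
                    evidence=evidence, threshold=cfg.sidestep_m, unit="m")


def flag_arms_start(rec: Recording, cfg: FlagConfig | None = None) -> AutoFlag:
    """Arms not hanging loosely down at the beginning of the recording (SAS).

    Evidence: the larger side's mean hand height above hip height over the
    first 2 s; hanging arms give a clearly negative value.
    """
    cfg = cfg or FlagConfig()
    _require(rec, QualityCriterion.ARMS)
    t, P, _ = rec.skeleton_arrays()
    sel = t <= t[0] + cfg.arms_window_s
    evidence = -np.inf
    for hand, hip in (("HandLeft", "HipLeft"), ("HandRight", "HipRight")):
        diff = P[sel, _J[hand], 1] - P[sel, _J[hip], 1]
        evidence = max(evidence, float(np.nanmean(diff)))
    return AutoFlag(QualityCriterion.ARMS, raised=evidence > cfg.arms_tol_m,
                    evidence=evidence, threshold=cfg.arms_tol_m, unit="m")


def flag_disturbances(rec: Recording, cfg: FlagConfig | None = None) -> AutoFlag:
    """Signal disturbances: corrupt silhouette pixels or spurious floor returns.

    For each depth frame, an eroded body/leg silhouette is predicted from the
    time-matched skeleton sample using the documented pinhole model; the
    evidence is the per-frame maximum of (a) the fraction of below-knee
    silhouette pixels that are invalid or deviate by more than
    ``depth_change_mm`` from the predicted surface, and (b) the fraction of
    background pixels in the floor band carrying spurious returns, averaged
    over frames.
    """
    cfg = cfg or FlagConfig()
    if not rec.depth_frames:
        raise ValueError("flag_disturbances requires a non-empty depth stream")
    t_s, P, _ = rec.skeleton_arrays()
    cam = rec.metadata.camera or {}
    first = rec.depth_frames[0]

    class _Cam:  # duck-typed camera fields for the mask projection
        depth_width = first.width
        depth_height = first.height
        focal_px_at_512 = float(cam.get("focal_px_at_512", 365.0))
        camera_height_m = float(cam.get("camera_height_m", 1.0))

    fractions = []
    for f in rec.depth_frames:
        i = int(np.argmin(np.abs(t_s - f.t)))
        body, leg, expected = body_and_leg_masks(P[i], _Cam)
        d = np.asarray(f.depth, dtype=float)
        leg_bad = 0.0
        if leg.any():
            bad = (d[leg] == 0) | (np.abs(d[leg] - expected[leg])
                                   > cfg.depth_change_mm)
            leg_bad = float(np.mean(bad))
        band = int(d.shape[0] * 0.85)
        bg = ~body[band:, :]
        bg_bad = float(np.mean(d[band:, :][bg] > 0)) if bg.any() else 0.0
        fractions.append(max(leg_bad, bg_bad))
    evidence = float(np.mean(fractions)) if fractions else 0.0
    return AutoFlag(QualityCriterion.DISTURBANCES,
                    raised=evidence > cfg.noise_fraction,
                    evidence=evidence, threshold=cfg.noise_fraction,
                    unit="fraction")


def flag_step_detection(rec: Recording, cfg: FlagConfig | None = None) -> AutoFlag:
    """Plausibility check on detected steps: cadence, alternation, gait cycles.

    Raised if the overall cadence falls outside [0.3, 3.5] steps/s, if more
    than 20% of side transitions fail to alternate, or if (for the walks) no
    full gait cycle — two successive contacts of the same side — was captured.
    Evidence is the alternation-failure fraction; the note names the reason.
    """
    cfg = cfg or FlagConfig()
    _require(rec, QualityCriterion.STEP_DETECTION)
    events = detect_steps(rec)
    walk = rec.metadata.task in (TaskType.SCSW, TaskType.SMSW, TaskType.SLW)
    n = len(events)
    reasons = []
    fail_frac = 0.0
    if n < 2:
        reasons.append("no full gait cycle" if walk else "fewer than 2 steps")
    else:
        times = np.array([e.t_contact for e in events])
        cadence = (n - 1) / (times[-1] - times[0])
        if not (cfg.cadence_min_hz <= cadence <= cfg.cadence_max_hz):
            reasons.append(f"implausible cadence {cadence:.2f} steps/s")
        sides = [e.side for e in events]
        fails = sum(a == b for a, b in zip(sides, sides[1:]))
        fail_frac = fails / (n - 1)
        if fail_frac > cfg.alternation_fail_max:
            reasons.append("sides fail to alternate")
        if walk and max(sides.count("left"), sides.count("right")) < 2:
            reasons.append("no full gait cycle")
    return AutoFlag(QualityCriterion.STEP_DETECTION, raised=bool(reasons),
                    evidence=fail_frac, threshold=cfg.alternation_fail_max,
                    unit="fraction", note="; ".join(reasons))


def flag_updown_phase(rec: Recording, cfg: FlagConfig | None = None) -> AutoFlag:
    """Incomplete or incorrectly detected stand-up/sit-down phases (SAS)."""
    cfg = cfg or FlagConfig()
    _require(rec, QualityCriterion.UP_DOWN_PHASE)
    phases = detect_sas_phases(rec)
    ups = sum(p.kind == "stand_up" for p in phases)
    downs = sum(p.kind == "sit_down" for p in phases)
    reasons = []
    if ups != cfg.sas_expected_cycles or downs != cfg.sas_expected_cycles:
        reasons.append(f"expected {cfg.sas_expected_cycles}+"
                       f"{cfg.sas_expected_cycles} phases, got {ups}+{downs}")
    kinds = [p.kind for p in phases]
    if any(a == b for a, b in zip(kinds, kinds[1:])):
        reasons.append("phases fail to alternate")
    if phases and not phases[-1].complete:
        reasons.append("final phase incomplete")
    n_expected = 2 * cfg.sas_expected_cycles
    return AutoFlag(QualityCriterion.UP_DOWN_PHASE, raised=bool(reasons),
                    evidence=float(len(phases)), threshold=float(n_expected),
                    unit="count", note="; ".join(reasons))


def _fs_of(t: np.ndarray) -> float:
    return 1.0 / float(np.median(np.diff(t)))


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

_DETECTORS = {
    QualityCriterion.DISTURBANCES: flag_disturbances,
    QualityCriterion.DURATION: flag_duration,
    QualityCriterion.STEP_DETECTION: flag_step_detection,
    QualityCriterion.UP_DOWN_PHASE: flag_updown_phase,
    QualityCriterion.ARMS: flag_arms_start,
    QualityCriterion.BACKWARD: flag_backward,
    QualityCriterion.FEET: flag_feet,
    QualityCriterion.FORWARD: flag_forward,
    QualityCriterion.MOVEMENTS: flag_movements,
    QualityCriterion.SIDESTEP: flag_sidestep,
}


def run_autoflag(rec: Recording, cfg: FlagConfig | None = None) -> list[AutoFlag]:
    """Run every criterion applicable to ``rec``'s task, in enumeration order.

    SUPPORT and OTHER are always returned unraised with note "manual-only";
    DISTURBANCES on a recording without a depth stream is returned unraised
    with note "no depth stream" (the detector needs depth data).
    """
    cfg = cfg or FlagConfig()
    out: list[AutoFlag] = []
    task = rec.metadata.task
    for crit in QualityCriterion:
        if task not in CRITERION_TASKS[crit]:
            continue
        if crit in (QualityCriterion.SUPPORT, QualityCriterion.OTHER):
            out.append(AutoFlag(crit, raised=False, evidence=None,
                                threshold=None, note="manual-only"))
        elif crit is QualityCriterion.DISTURBANCES and not rec.depth_frames:
            out.append(AutoFlag(crit, raised=False, evidence=None,
                                threshold=None, note="no depth stream"))
        else:
            out.append(_DETECTORS[crit](rec, cfg))
    return out


def flags_to_frame(flags: list[AutoFlag], recording_id: str = "") -> pd.DataFrame:
    """Tabular flag export (one row per criterion)."""
    return pd.DataFrame([
        {
            "recording_id": recording_id,
            "criterion": f.criterion.value,
            "category": CRITERION_CATEGORY[f.criterion],
            "raised": f.raised,
            "evidence": f.evidence,
            "unit": f.unit,
            "threshold": f.threshold,
            "note": f.note,
        }
        for f in flags
    ])
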