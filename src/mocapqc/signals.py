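"""Per-task characteristic signals and event segmentations.

These are the 1-D curves shown alongside the motion profiles (subject
positioning over time, knee amplitudes, arm sway, stance width) and the two
event segmentations (step contacts with stance phases; stand-up/sit-down
phases) consumed by the automated quality flags.

All signal definitions are this package's own, chosen as the simplest
landmark-based quantity consistent with each curve's purpose:

* pelvis landmark = SpineBase; hands = HandLeft/HandRight; per-side hip,
  knee and ankle landmarks by their Kinect names;
* positions are gated on landmark confidence (default threshold 0.5) and
  gaps up to 0.5 s are linearly interpolated, longer gaps stay missing;
* arm sway is measured on the hand position *relative to the pelvis*, which
  makes it exactly invariant to whole-body translation, then expressed as
  the deviation from a rolling 2 s median;
* step detection is peak-based on per-side ankle height/velocity: a contact
  is the downward-to-zero velocity crossing following a lift that exceeds an
  amplitude gate (default 0.05 m), with a 0.25 s minimum inter-event
  interval; in-place stepping counts each leg's lift as one step;
* sit-to-stand segmentation is threshold-crossing on pelvis height between
  per-recording seated (lower 25% of range) and standing (upper 25%)
  plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt, find_peaks

from .recording import JOINT_INDEX, Recording, TaskType, ValidationError

_J = JOINT_INDEX
PELVIS = _J["SpineBase"]

CONFIDENCE_THRESHOLD = 0.5
MAX_INTERP_GAP_S = 0.5
STEP_GATE_M = 0.05
STEP_MIN_INTERVAL_S = 0.25
SWAY_WINDOW_S = 2.0


class ApplicabilityError(ValueError):
    """An operation was requested for a task it does not apply to."""


@dataclass
class Signal:
    t: np.ndarray
    values: np.ndarray
    unit: str


@dataclass
class SignalSet:
    """Named signals plus the landmarks each one was derived from."""

    signals: dict[str, Signal] = field(default_factory=dict)
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def add(self, name: str, t: np.ndarray, values: np.ndarray, unit: str,
            landmarks: tuple[str, ...]) -> None:
        self.signals[name] = Signal(t=t, values=values, unit=unit)
        self.provenance[name] = landmarks

    def update(self, other: "SignalSet") -> None:
        self.signals.update(other.signals)
        self.provenance.update(other.provenance)

    def to_frame(self, recording_id: str = "") -> pd.DataFrame:
        """Tidy export: recording_id, signal, t, value, unit."""
        rows = []
        for name, s in self.signals.items():
            rows.append(pd.DataFrame({
                "recording_id": recording_id, "signal": name,
                "t": s.t, "value": s.values, "unit": s.unit,
            }))
        if not rows:
            return pd.DataFrame(
                columns=["recording_id", "signal", "t", "value", "unit"])
        return pd.concat(rows, ignore_index=True)


@dataclass
class StepEvent:
    t_contact: float
    side: str  # "left" | "right"
    stance: tuple[float, float] | None = None  # (start, end) of ground contact


@dataclass
class PhaseSegment:
    kind: str  # "stand_up" | "sit_down"
    start: float
    end: float
    complete: bool = True


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _gate_and_interp(t: np.ndarray, v: np.ndarray, conf: np.ndarray,
                     threshold: float = CONFIDENCE_THRESHOLD,
                     max_gap_s: float = MAX_INTERP_GAP_S) -> np.ndarray:
    """NaN out low-confidence samples, fill gaps up to ``max_gap_s`` linearly."""
    out = np.asarray(v, dtype=float).copy()
    bad = conf < threshold
    if not bad.any():
        return out
    out[bad] = np.nan
    good = ~bad
    if good.sum() < 2:
        return out
    # identify bad runs and fill the short interior ones
    idx = np.flatnonzero(bad)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, splits + 1)
    interp_all = np.interp(t, t[good], out[good])
    for run in runs:
        lo, hi = run[0], run[-1]
        if lo == 0 or hi == len(t) - 1:
            continue  # boundary gaps stay missing
        if t[hi + 1] - t[lo - 1] <= max_gap_s:
            out[run] = interp_all[run]
    return out


def _fs(t: np.ndarray) -> float:
    return 1.0 / float(np.median(np.diff(t)))


def _lowpass(v: np.ndarray, fs: float, cutoff: float = 6.0) -> np.ndarray:
    if len(v) < 10 or cutoff >= fs / 2:
        return v
    b, a = butter(2, cutoff / (fs / 2))
    return filtfilt(b, a, v)


def _require_skeleton(rec: Recording) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not rec.skeleton_frames:
        raise ValidationError("operation requires a non-empty skeleton stream")
    return rec.skeleton_arrays()


def _require_task(rec: Recording, allowed: set[TaskType], op: str) -> None:
    if rec.metadata.task not in allowed:
        raise ApplicabilityError(
            f"{op} applies to {sorted(t.value for t in allowed)}, "
            f"not {rec.metadata.task.value}"
        )


# ---------------------------------------------------------------------------
# Signal extractors
# ---------------------------------------------------------------------------

def extract_position_signals(rec: Recording) -> SignalSet:
    """Pelvis anterior-posterior z(t), mediolateral x(t) and height y(t), m."""
    t, P, C = _require_skeleton(rec)
    conf = C[:, PELVIS]
    out = SignalSet()
    for name, axis in (("position_x", 0), ("position_y", 1), ("position_z", 2)):
        v = _gate_and_interp(t, P[:, PELVIS, axis], conf)
        out.add(name, t, v, "m", ("SpineBase",))
    return out


def extract_knee_amplitude(rec: Recording) -> SignalSet:
    """Per-side knee height above its 10th-percentile baseline (m, SIP only)."""
    _require_task(rec, {TaskType.SIP}, "extract_knee_amplitude")
    t, P, C = _require_skeleton(rec)
    out = SignalSet()
    for side, joint in (("left", "KneeLeft"), ("right", "KneeRight")):
        j = _J[joint]
        y = _gate_and_interp(t, P[:, j, 1], C[:, j])
        baseline = np.nanpercentile(y, 10)
        out.add(f"knee_amplitude_{side}", t, y - baseline, "m", (joint,))
    return out


def extract_arm_sway(rec: Recording) -> SignalSet:
    """Per-side hand displacement from its rolling 2 s median (m).

    Measured on the hand position relative to the pelvis, so the signal is
    invariant to whole-body translation by construction.
    """
    t, P, C = _require_skeleton(rec)
    fs = _fs(t)
    win = max(3, int(round(SWAY_WINDOW_S * fs)) | 1)  # odd
    out = SignalSet()
    for side, joint in (("left", "HandLeft"), ("right", "HandRight")):
        j = _J[joint]
        rel = P[:, j, :] - P[:, PELVIS, :]
        dev = np.empty_like(rel)
        for axis in range(3):
            med = median_filter(rel[:, axis], size=win, mode="nearest")
            dev[:, axis] = rel[:, axis] - med
        sway = np.linalg.norm(dev, axis=1)
        out.add(f"arm_sway_{side}", t, sway, "m", (joint, "SpineBase"))
    return out


def compute_stance_width(rec: Recording) -> SignalSet:
    """Horizontal ankle separation over time (m); quiet-stance tasks only."""
    _require_task(rec, {TaskType.POCO, TaskType.POCO_DUAL},
                  "compute_stance_width")
    t, P, _ = _require_skeleton(rec)
    dl = P[:, _J["AnkleLeft"], :] - P[:, _J["AnkleRight"], :]
    width = np.hypot(dl[:, 0], dl[:, 2])
    out = SignalSet()
    out.add("stance_width", t, width, "m", ("AnkleLeft", "AnkleRight"))
    return out


def extract_pelvis_height(rec: Recording) -> SignalSet:
    t, P, C = _require_skeleton(rec)
    y = _gate_and_interp(t, P[:, PELVIS, 1], C[:, PELVIS])
    out = SignalSet()
    out.add("pelvis_height", t, y, "m", ("SpineBase",))
    return out


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

_STEP_TASKS = {TaskType.SCSW, TaskType.SMSW, TaskType.SLW, TaskType.SIP}


def detect_steps(rec: Recording, gate_m: float = STEP_GATE_M,
                 min_interval_s: float = STEP_MIN_INTERVAL_S) -> list[StepEvent]:
    """Detect step contacts per side from ankle height and vertical velocity.

    A lift is a smoothed ankle-height peak exceeding ``gate_m`` above the
    per-side 10th-percentile baseline; the contact is the first
    downward-to-zero velocity crossing (or return below 0.3x the gate) after
    the peak. The stance phase spans from a contact to the same side's next
    lift start. Events are returned time-ordered across sides.
    """
    _require_task(rec, _STEP_TASKS, "detect_steps")
    t, P, C = _require_skeleton(rec)
    fs = _fs(t)
    events: list[StepEvent] = []
    for side, joint in (("left", "AnkleLeft"), ("right", "AnkleRight")):
        j = _J[joint]
        y = _gate_and_interp(t, P[:, j, 1], C[:, j], threshold=0.1)
        y = np.where(np.isnan(y), np.nanmedian(y), y)
        ys = _lowpass(y, fs)
        h = ys - np.percentile(ys, 10)
        peaks, _ = find_peaks(h, height=gate_m,
                              distance=max(1, int(round(min_interval_s * fs))))
        vel = np.gradient(ys, t)
        low = 0.3 * gate_m
        for p in peaks:
            contact = None
            i = p
            while i < len(t) - 1:
                i += 1
                if (vel[i] >= 0 and vel[i - 1] < 0) or h[i] < low:
                    contact = i
                    break
            if contact is None:
                contact = len(t) - 1
            # lift start: walk back from the peak below 0.3x gate
            i = p
            while i > 0 and h[i] >= low:
                i -= 1
            events.append(StepEvent(t_contact=float(t[contact]), side=side,
                                    stance=(float(t[contact]), float(t[i]))))
    events.sort(key=lambda e: e.t_contact)

    # stance phase: contact -> next lift start of the same side
    for side in ("left", "right"):
        side_events = [e for e in events if e.side == side]
        lift_starts = [e.stance[1] for e in side_events]  # temp: own lift start
        for k, e in enumerate(side_events):
            nxt = lift_starts[k + 1] if k + 1 < len(side_events) else None
            if nxt is not None and nxt > e.t_contact:
                e.stance = (e.t_contact, float(nxt))
            else:
                e.stance = None
    return events


def detect_sas_phases(rec: Recording, min_range_m: float = 0.2
                      ) -> list[PhaseSegment]:
    """Segment stand-up / sit-down transitions from pelvis height (SAS only).

    Seated/standing plateaus are the lower/upper 25% of the per-recording
    height range; a transition runs between the 25% and 75% crossings. A
    transition still in progress at the recording end is returned with
    ``complete=False`` and ``end`` = recording end. A constant height signal
    yields an empty list.
    """
    _require_task(rec, {TaskType.SAS}, "detect_sas_phases")
    t, P, C = _require_skeleton(rec)
    fs = _fs(t)
    y = _gate_and_interp(t, P[:, PELVIS, 1], C[:, PELVIS])
    y = np.where(np.isnan(y), np.nanmedian(y), y)
    ys = _lowpass(y, fs, cutoff=2.0)
    lo, hi = np.percentile(ys, [5, 95])
    if hi - lo < min_range_m:
        return []
    th_lo = lo + 0.25 * (hi - lo)
    th_hi = lo + 0.75 * (hi - lo)

    segments: list[PhaseSegment] = []
    state = "seated" if ys[0] < th_lo else ("standing" if ys[0] > th_hi else "mid")
    t_start = None
    kind = None
    for i in range(1, len(t)):
        v = ys[i]
        if state == "seated" and v >= th_lo:
            state, kind, t_start = "mid", "stand_up", float(t[i])
        elif state == "standing" and v <= th_hi:
            state, kind, t_start = "mid", "sit_down", float(t[i])
        elif state == "mid":
            if kind == "stand_up":
                if v >= th_hi:
                    segments.append(PhaseSegment("stand_up", t_start, float(t[i])))
                    state = "standing"
                elif v < th_lo:
                    state = "seated"  # aborted rise
            else:
                if v <= th_lo:
                    segments.append(PhaseSegment("sit_down", t_start, float(t[i])))
                    state = "seated"
                elif v > th_hi:
                    state = "standing"  # aborted descent
    if state == "mid" and t_start is not None and float(t[-1]) > t_start:
        segments.append(PhaseSegment(kind, t_start, float(t[-1]), complete=False))
    return segments


# ---------------------------------------------------------------------------
# Dispatcher
# ---------------------------------------------------------------------------

def extract_task_signals(rec: Recording) -> SignalSet:
    """The union of signals applicable to ``rec``'s task (closed vocabulary).

    POCO/POCO-DUAL: positions + stance width + arm sway; SIP: knee
    amplitudes + arm sway + positions; walks: positions (step events are an
    overlay, not a signal); SAS: pelvis height + arm sway.
    """
    task = rec.metadata.task
    out = extract_position_signals(rec)
    if task in (TaskType.POCO, TaskType.POCO_DUAL):
        out.update(compute_stance_width(rec))
        out.update(extract_arm_sway(rec))
    elif task is TaskType.SIP:
        out.update(extract_knee_amplitude(rec))
        out.update(extract_arm_sway(rec))
    elif task is TaskType.SAS:
        out.update(extract_pelvis_height(rec))
        out.update(extract_arm_sway(rec))
    return out
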