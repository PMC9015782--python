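"""Domain model and on-disk container for depth-camera motor-task recordings.

A recording of one short structured motor task (quiet stance, stepping in
place, short walks, sit-to-stand) holds up to two streams captured by a
consumer depth camera such as the Kinect v2:

* a depth stream: 16-bit depth images in millimetres, 0 = invalid / no return;
* a skeleton stream: 25 tracked anatomical landmarks (the canonical Kinect-v2
  joint set) as 3-D positions in metres, with per-landmark confidence in [0, 1].

Container layout (one directory per recording)::

    metadata.json          recording / subject / task metadata (UTF-8 JSON)
    skeleton.csv           wide table: t, then x/y/z/conf per landmark name
    depth/frame_%06d.png   16-bit grayscale PNG, pixel value = millimetres
    depth_index.csv        columns frame,timestamp_s

Coordinate convention (documented once, used everywhere): right-handed camera
frame; x lateral (subject's left positive as seen from the camera), y up,
z away from the camera. Skeleton coordinates in metres, depth pixels in
millimetres. Timestamps are float seconds from the first frame (0-based);
frames need not be exactly equidistant, and the two streams may carry
independent timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image


class ValidationError(ValueError):
    """A recording violates one of its structural invariants."""


class FormatError(ValueError):
    """An on-disk container does not follow the documented layout."""


#: Canonical Kinect-v2 joint names, in sensor order. Index 0 (SpineBase) is
#: used as the pelvis landmark throughout the package.
KINECT_JOINTS = [
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
]
N_LANDMARKS = 25
JOINT_INDEX = {name: i for i, name in enumerate(KINECT_JOINTS)}

GROUPS = ("HC", "PwMS", "synthetic")

#: Maximum plausible landmark distance from the camera (m).
MAX_LANDMARK_Z_M = 8.0


class TaskType(Enum):
    """The seven structured motor tasks covered by the QC pipeline."""

    POCO = "POCO"            # Postural Control: 40 s quiet stance
    POCO_DUAL = "POCO_DUAL"  # Postural Control with serial-subtraction dual task
    SCSW = "SCSW"            # Short Comfortable Speed Walk
    SMSW = "SMSW"            # Short Maximum Speed Walk
    SLW = "SLW"              # Short Line (tandem-style) Walk
    SIP = "SIP"              # Stepping In Place: 40 s in-place marching
    SAS = "SAS"              # Stand up And Sit down cycles

    @property
    def nominal_duration_s(self) -> float | None:
        """Protocol-nominal recording duration; only the 40 s tasks have one."""
        if self in (TaskType.POCO, TaskType.POCO_DUAL, TaskType.SIP):
            return 40.0
        return None

    @property
    def is_static(self) -> bool:
        """True for quiet-stance tasks (no intended locomotion)."""
        return self in (TaskType.POCO, TaskType.POCO_DUAL)


@dataclass
class SkeletonFrame:
    """One skeleton sample: 25 landmark positions (m) and confidences."""

    t: float
    landmarks: np.ndarray   # (25, 3) float, columns x/y/z in metres
    confidence: np.ndarray  # (25,) float in [0, 1]


@dataclass
class DepthFrame:
    """One depth image: millimetre distances, 0 = invalid / no return."""

    t: float
    depth: np.ndarray  # (height, width) uint16, millimetres

    @property
    def height(self) -> int:
        return int(self.depth.shape[0])

    @property
    def width(self) -> int:
        return int(self.depth.shape[1])


@dataclass
class RecordingMetadata:
    recording_id: str
    subject_id: str
    group: str  # HC | PwMS | synthetic
    task: TaskType
    frame_rate_hz: float
    operator_comment: str = ""
    study_site: str = ""
    #: Optional pinhole camera model used for depth rendering / silhouette
    #: checks: {"focal_px_at_512": float, "camera_height_m": float}.
    camera: dict | None = None


@dataclass
class Recording:
    """Metadata plus synchronized depth and skeleton streams for one trial.

    At least one stream must be non-empty; timestamps must increase strictly
    within each stream. ``duration_s`` is the last timestamp of the longer
    stream (computed, never stored independently of the streams).
    """

    metadata: RecordingMetadata
    depth_frames: list[DepthFrame] = field(default_factory=list)
    skeleton_frames: list[SkeletonFrame] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        ends = []
        if self.skeleton_frames:
            ends.append(self.skeleton_frames[-1].t)
        if self.depth_frames:
            ends.append(self.depth_frames[-1].t)
        if not ends:
            raise ValidationError("recording has no frames in either stream")
        return float(max(ends))

    # -- array views (cached: the battery calls these repeatedly) ----------
    def skeleton_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (t, positions, confidence) as (T,), (T,25,3), (T,25) arrays."""
        cached = getattr(self, "_skel_cache", None)
        if cached is None:
            if not self.skeleton_frames:
                raise ValidationError("recording has no skeleton stream")
            t = np.array([f.t for f in self.skeleton_frames], dtype=float)
            pos = np.stack([f.landmarks for f in self.skeleton_frames])
            conf = np.stack([f.confidence for f in self.skeleton_frames])
            cached = (t, pos, conf)
            object.__setattr__(self, "_skel_cache", cached)
        return cached


def validate_recording(rec: Recording) -> list[str]:
    """Check every structural invariant; return one message per violation.

    Total function: never raises, an empty list means the recording is valid.
    """
    issues: list[str] = []
    md = rec.metadata
    if not (md.frame_rate_hz > 0):
        issues.append(f"frame_rate_hz: must be > 0, got {md.frame_rate_hz}")
    if md.group not in GROUPS:
        issues.append(f"group: expected one of {GROUPS}, got {md.group!r}")
    if not rec.depth_frames and not rec.skeleton_frames:
        issues.append("streams: at least one of depth/skeleton must be non-empty")

    prev_t = -np.inf
    for f in rec.skeleton_frames:
        if f.t < 0:
            issues.append(f"skeleton: negative timestamp t={f.t}")
        if f.t <= prev_t:
            issues.append(f"skeleton: timestamps not strictly increasing at t={f.t}")
        prev_t = f.t
        lm = np.asarray(f.landmarks)
        if lm.shape != (N_LANDMARKS, 3):
            issues.append(
                f"landmarks: expected {N_LANDMARKS}, got {lm.shape[0]} at t={f.t}"
            )
            continue
        conf = np.asarray(f.confidence)
        if conf.shape != (N_LANDMARKS,):
            issues.append(f"confidence: expected {N_LANDMARKS} values at t={f.t}")
            continue
        if np.any(conf < 0) or np.any(conf > 1):
            issues.append(f"confidence: values outside [0, 1] at t={f.t}")
        tracked = conf > 0
        z = lm[tracked, 2]
        if z.size and (np.any(z <= 0) or np.any(z >= MAX_LANDMARK_Z_M)):
            issues.append(
                f"landmarks: tracked z outside (0, {MAX_LANDMARK_Z_M}) m at t={f.t}"
            )

    prev_t = -np.inf
    dims = None
    for f in rec.depth_frames:
        if f.t < 0:
            issues.append(f"depth: negative timestamp t={f.t}")
        if f.t <= prev_t:
            issues.append(f"depth: timestamps not strictly increasing at t={f.t}")
        prev_t = f.t
        d = np.asarray(f.depth)
        if d.ndim != 2:
            issues.append(f"depth: frame at t={f.t} is not a 2-D grid")
            continue
        if dims is None:
            dims = d.shape
        elif d.shape != dims:
            issues.append(
                f"depth: dimensions {d.shape} differ from first frame {dims} at t={f.t}"
            )
        if np.any(np.asarray(d, dtype=np.int64) < 0):
            issues.append(f"depth: negative value at t={f.t}")
    return issues


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

_SKELETON_COLUMNS = ["t"] + [
    f"{name}_{c}" for name in KINECT_JOINTS for c in ("x", "y", "z", "conf")
]


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``rec`` to a container directory; returns the manifest path.

    Raises :class:`ValidationError` (naming the offending field) if the
    recording violates an invariant, so no partial container of an invalid
    recording is ever produced with a complete manifest.
    """
    issues = validate_recording(rec)
    if issues:
        raise ValidationError("; ".join(issues))
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    md = rec.metadata
    manifest = {
        "recording_id": md.recording_id,
        "subject_id": md.subject_id,
        "group": md.group,
        "task": md.task.value,
        "frame_rate_hz": md.frame_rate_hz,
        "operator_comment": md.operator_comment,
        "study_site": md.study_site,
        "camera": md.camera,
        "duration_s": rec.duration_s,
        "n_skeleton_frames": len(rec.skeleton_frames),
        "n_depth_frames": len(rec.depth_frames),
        "landmark_names": KINECT_JOINTS,
        "units": {"skeleton": "m", "depth": "mm", "time": "s"},
    }
    manifest_path = path / "metadata.json"
    manifest_path.write_text(json.dumps(manifest, indent=1), encoding="utf-8")

    if rec.skeleton_frames:
        t, pos, conf = rec.skeleton_arrays()
        wide = np.empty((len(t), 1 + 4 * N_LANDMARKS))
        wide[:, 0] = t
        wide[:, 1::4] = pos[:, :, 0]
        wide[:, 2::4] = pos[:, :, 1]
        wide[:, 3::4] = pos[:, :, 2]
        wide[:, 4::4] = conf
        # default float repr round-trips exactly, keeping the <=1e-6 m contract
        pd.DataFrame(wide, columns=_SKELETON_COLUMNS).to_csv(
            path / "skeleton.csv", index=False
        )

    if rec.depth_frames:
        depth_dir = path / "depth"
        depth_dir.mkdir(exist_ok=True)
        index_rows = []
        for i, f in enumerate(rec.depth_frames):
            fname = f"frame_{i:06d}.png"
            Image.fromarray(np.asarray(f.depth, dtype=np.uint16)).save(
                depth_dir / fname
            )
            index_rows.append((fname, f.t))
        pd.DataFrame(index_rows, columns=["frame", "timestamp_s"]).to_csv(
            path / "depth_index.csv", index=False
        )
    return manifest_path


def read_recording(path: str | Path) -> Recording:
    """Read a container directory written by :func:`write_recording`.

    A missing optional stream yields an empty sequence; structural problems
    raise :class:`FormatError` naming the file (and row, where applicable).
    """
    path = Path(path)
    manifest_path = path / "metadata.json"
    if not manifest_path.is_file():
        raise FormatError(f"{path}: missing metadata.json")
    manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    try:
        md = RecordingMetadata(
            recording_id=manifest["recording_id"],
            subject_id=manifest["subject_id"],
            group=manifest["group"],
            task=TaskType(manifest["task"]),
            frame_rate_hz=float(manifest["frame_rate_hz"]),
            operator_comment=manifest.get("operator_comment", ""),
            study_site=manifest.get("study_site", ""),
            camera=manifest.get("camera"),
        )
    except (KeyError, ValueError) as exc:
        raise FormatError(f"metadata.json: {exc}") from exc

    skeleton_frames: list[SkeletonFrame] = []
    skel_path = path / "skeleton.csv"
    if skel_path.is_file():
        df = pd.read_csv(skel_path)
        if list(df.columns) != _SKELETON_COLUMNS:
            raise FormatError("skeleton.csv: unexpected column layout")
        arr = df.to_numpy(dtype=float)
        t = arr[:, 0]
        for i in range(1, len(t)):
            if t[i] <= t[i - 1]:
                raise FormatError(
                    f"skeleton.csv row {i + 2}: timestamp {t[i]} not greater "
                    f"than previous {t[i - 1]}"
                )
        pos = np.stack(
            [arr[:, 1::4], arr[:, 2::4], arr[:, 3::4]], axis=-1
        )  # (T, 25, 3)
        conf = arr[:, 4::4]
        skeleton_frames = [
            SkeletonFrame(t=float(t[i]), landmarks=pos[i], confidence=conf[i])
            for i in range(len(t))
        ]

    depth_frames: list[DepthFrame] = []
    index_path = path / "depth_index.csv"
    if index_path.is_file():
        index = pd.read_csv(index_path)
        prev_t = -np.inf
        for row_no, row in enumerate(index.itertuples(index=False), start=2):
            ts = float(row.timestamp_s)
            if ts <= prev_t:
                raise FormatError(
                    f"depth_index.csv row {row_no}: timestamp {ts} not strictly "
                    "increasing"
                )
            prev_t = ts
            img = Image.open(path / "depth" / str(row.frame))
            if img.mode not in ("I;16", "I"):
                raise FormatError(
                    f"depth/{row.frame}: expected PNG bit depth 16, got mode "
                    f"{img.mode}"
                )
            depth = np.asarray(img, dtype=np.uint16)
            depth_frames.append(DepthFrame(t=ts, depth=depth))

    rec = Recording(metadata=md, depth_frames=depth_frames,
                    skeleton_frames=skeleton_frames)
    issues = validate_recording(rec)
    if issues:
        raise FormatError(f"{path}: " + "; ".join(issues))
    return rec
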