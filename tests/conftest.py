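import numpy as np
import pytest
from hypothesis import settings

import mocapqc as m

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sip_clean():
    """Clean 40 s stepping-in-place recording (skeleton only)."""
    return m.simulate_recording(
        m.task_defaults(m.TaskType.SIP, seed=101, render_depth=False))


@pytest.fixture(scope="session")
def poco_clean():
    return m.simulate_recording(
        m.task_defaults(m.TaskType.POCO, seed=102, render_depth=False))


@pytest.fixture(scope="session")
def sas_clean():
    return m.simulate_recording(
        m.task_defaults(m.TaskType.SAS, seed=103, render_depth=False))


@pytest.fixture(scope="session")
def small_depth_recording():
    """Short SIP recording with a low-resolution depth stream."""
    cfg = m.task_defaults(m.TaskType.SIP, seed=104, duration_s=5.0,
                          depth_width=64, depth_height=53, depth_fps=3.0)
    return m.simulate_recording(cfg)


def make_skeleton_recording(task, t, transform=None, recording_id="manual"):
    """Recording built directly from the standing base pose, no noise.

    ``transform(i, ti, landmarks)`` may modify the (25, 3) landmark array of
    each frame in place and return it; used to construct exact trajectories
    (for strict threshold-boundary checks).
    """
    from mocapqc.simulate import base_pose

    pose = base_pose(1.75, 0.40, 0.08)
    frames = []
    for i, ti in enumerate(np.asarray(t, dtype=float)):
        lm = pose.copy()
        lm[:, 2] += 2.5
        if transform is not None:
            lm = transform(i, float(ti), lm)
        frames.append(m.SkeletonFrame(t=float(ti), landmarks=lm,
                                      confidence=np.ones(25)))
    md = m.RecordingMetadata(recording_id=recording_id, subject_id="manual",
                             group="synthetic", task=task, frame_rate_hz=30.0)
    return m.Recording(metadata=md, skeleton_frames=frames)
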