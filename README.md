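# mocapqc

Post hoc quality control for markerless motion-capture recordings of short
structured motor tasks.

Clinical movement analysis increasingly relies on consumer depth cameras
that track a 25-landmark skeleton without attached markers. Recordings of
short standardized tasks — quiet stance (POCO, POCO-DUAL), stepping in
place (SIP), short walks (SCSW, SMSW, SLW), and sit-to-stand cycles (SAS) —
feed kinematic outcome parameters, but technical artifacts (clothing-related
depth noise, floor reflections, truncated recordings) and performance issues
(drifting forward, open feet, gesturing, sidesteps) can silently corrupt
those outcomes. `mocapqc` provides the screening layer that catches them
after acquisition:

* **Motion profiles** — a depth recording condensed into three images: the
  time-average of valid depth and the per-frame averages over the vertical
  and horizontal axes, `P_frontal(r,c) = mean{ d_t(r,c) : d_t(r,c) > 0 }`.
  Protocol deviations show up as visible structure (e.g. drift as a moving
  ridge along the time axis).
* **Characteristic signals** — pelvis position x/y/z(t), per-side knee
  amplitudes, arm sway relative to the pelvis, stance width, pelvis height,
  plus step-contact and stand-up/sit-down segmentations.
* **Automated quality flags** — detectors for the quantifiable criteria of
  a 12-criterion taxonomy (disturbances, duration, step detection,
  up/down phases, arms, backward, feet, forward, movements, sidestep,
  support, other), each reporting evidence vs a configurable threshold with
  strict "more than" semantics. Duration (40 ± 1 s) and forward/backward
  drift (0.50 m, tolerant 0.80 m preset) follow the assessment protocol.
* **Rating concordance** — a two-rater usability-rating data model (keep /
  discard / undecided + criterion multiselect) on CSV sheets, with per-task
  3×3 confusion matrices, concordance = trace/n, unanimous and strict-
  disagreement rates, criterion selection frequencies and median rating
  duration.
* **A synthetic recording simulator** — kinematic skeleton models plus a
  capsule-based depth renderer for all seven tasks, with injectable,
  ground-truth-labelled defects mirroring the taxonomy one-to-one, so the
  whole pipeline is testable without clinical data.

See `docs/methods.md` for the models, thresholds, and their rationale.

## Worked example

```python
import mocapqc as m

# simulate a 40 s stepping-in-place trial that drifts 0.6 m toward the camera
cfg = m.task_defaults(m.TaskType.SIP, seed=1, render_depth=False)
rec, truth = m.simulate_recording(cfg, [m.DefectSpec(m.DefectKind.FORWARD_DRIFT, 0.6)])

steps = m.detect_steps(rec)
print(len(truth.true_step_times), len(steps))

for f in m.run_autoflag(rec):
    if f.evidence is not None:
        print(f"{f.criterion.value:14s} raised={f.raised!s:5s} "
              f"evidence={f.evidence:.3f} {f.unit} (threshold {f.threshold})")
```

prints

```
40 40
DURATION       raised=False evidence=0.000 s (threshold 1.0)
STEP_DETECTION raised=False evidence=0.000 fraction (threshold 0.2)
BACKWARD       raised=False evidence=0.021 m (threshold 0.5)
FORWARD        raised=True  evidence=0.610 m (threshold 0.5)
MOVEMENTS      raised=False evidence=0.019 m (threshold 0.1)
```

All 40 injected step lifts are recovered with alternating sides, and only
the forward-drift criterion raises: the measured 0.610 m maximum anterior
pelvis displacement exceeds the 0.50 m protocol threshold (with the
tolerant preset, `m.FlagConfig.tolerant_forward()`, the same trial would
pass). The `mocapqc` command-line tool wraps the same pipeline for batch
use: `simulate` writes container directories with `ground_truth.json`,
`figures` renders the profile+signal rating figures and a rating-sheet
template, `autoflag` writes `flags.csv`/`flags.json`, and `stats` computes
the concordance summaries from rating sheets.

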