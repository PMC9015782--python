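# Methods

`mocapqc` implements a post hoc quality-control pipeline for markerless
(depth-camera) motion-capture recordings of short structured motor tasks,
of the kind used in clinical movement analysis of people with multiple
sclerosis and other motor disorders. A recording consists of a 16-bit depth
stream (millimetres, 0 = no return) and/or a 25-landmark 3-D skeleton time
series (Kinect-v2 joint set) captured at nominally 30 Hz with the subject
1.5–4.5 m from the camera. The pipeline condenses each recording into
reviewable images and signals, screens it with automated detectors for a
12-criterion quality taxonomy, and summarizes two independent raters'
usability decisions (keep / discard / undecided) as concordance statistics.

## Motion profiles

A depth recording is condensed into three 2-D images: the per-pixel average
over time (frontal), the per-frame average over the vertical image axis
(top, one row per frame), and the per-frame average over the horizontal axis
(side). Averages run over *valid* (nonzero) pixels only; a pixel with no
valid contributor is 0 with a recorded valid fraction of 0. The reduction is
the arithmetic mean rather than the raw sum because the mean is scale-stable
across recordings of different lengths; a `reduction="sum"` switch restores
summation-style profiles. Axis orientation is fixed and documented: profile
rows are time increasing downward; raw arrays are never display-normalized
(rendering applies a 1st–99th percentile contrast stretch only). Protocol
deviations such as drift toward the camera appear as a moving ridge along
the time axis of the top profile.

## Characteristic signals

All signal definitions are this package's own, chosen as the simplest
landmark-based quantity serving each QC purpose; no equivalence with any
proprietary kinematic software is claimed.

| signal | definition | units |
|---|---|---|
| position x/y/z | pelvis (SpineBase) coordinates over time | m |
| knee amplitude | per-side knee height minus its 10th-percentile baseline | m |
| arm sway | per-side hand position relative to the pelvis, deviation from its rolling 2 s median | m |
| stance width | horizontal ankle separation | m |
| pelvis height | SpineBase height (sit-to-stand tasks) | m |

Positions are gated on landmark confidence (threshold 0.5); gaps up to
0.5 s are linearly interpolated, longer gaps stay missing. Measuring arm
sway relative to the pelvis makes it exactly invariant to whole-body
translation, so walking does not register as arm movement.

Step detection is peak-based on per-side ankle height (low-passed at 6 Hz):
a lift is a peak exceeding a 0.05 m gate above the per-side 10th-percentile
baseline with a 0.25 s minimum inter-event interval; the ground contact is
the first downward-to-zero velocity crossing after the peak; the stance
phase runs from a contact to the same side's next lift start. In-place
stepping counts each leg's lift as one step (both legs counted).

Sit-to-stand segmentation is threshold-crossing on low-passed pelvis
height: seated and standing plateaus are the lower and upper 25% of the
per-recording 5th–95th percentile range; a stand-up segment spans the
rising 25%→75% crossing (sit-down symmetric). A transition still in
progress at the recording end is returned marked incomplete. A height range
under 0.2 m yields no segments (degenerate input guard).

## Automated quality flags

Each detector reduces a recording to one scalar of evidence and compares it
to a configurable threshold with a strict boundary: evidence exactly equal
to the threshold never raises ("more than" semantics). Two thresholds come
from the assessment protocol itself — recording duration 40 ± 1 s for the
timed tasks, and 0.50 m of forward/backward drift during in-place stepping,
with a tolerant 0.80 m preset for the forward criterion. All others are
explicit heuristic defaults of this package:

* feet (stance width, median over the first 5 s): 0.15 m
* task-unassociated movements (max arm sway outside expected windows): 0.10 m
* sidestep (max mediolateral pelvis displacement within any 1 s window,
  which separates a fast sidestep from a slow lean of equal extent): 0.15 m
* arms-down-at-start (mean hand-above-hip height, first 2 s): 0.05 m
* signal disturbances (corrupt-silhouette fraction, below): 0.10
* step plausibility: cadence within [0.3, 3.5] steps/s, at most 20% of side
  transitions failing to alternate, and (walks) at least one full gait
  cycle — two successive same-side contacts.

The backward detector additionally raises on a "deliberate correction"
pattern — a backward excursion of ≥ 0.25 m following a forward excursion of
≥ 0.25 m — independently of the 0.50 m threshold; for that detector the
raised state is therefore not a pure function of evidence vs threshold.
This heuristic is an operationalization, flagged as interpretation.

The disturbance detector predicts an eroded body/leg silhouette from the
time-matched skeleton sample using the package's documented pinhole camera
model (focal length 365 px at 512×424, scaled proportionally; camera height
1.0 m), and measures the per-frame maximum of (a) the fraction of
below-knee silhouette pixels that are invalid or deviate by more than
200 mm from the predicted surface and (b) the fraction of floor-band
background pixels carrying spurious returns, averaged over frames. The
below-knee region is targeted because clothing-related depth corruption
concentrates on the legs.

The dual-task stance uses the single-task detectors unchanged; its
movements flag carries a caveat note that gesturing may be task-associated
(mental arithmetic) rather than a different threshold. Support-object use
and the catch-all "other" criterion remain manual-only (detecting a walking
aid would need object recognition): they are always emitted unraised so the
taxonomy stays complete for rating sheets.

## Synthetic recordings

The simulator produces ground-truth-labelled recordings for all seven
tasks. The gait model is kinematic — sinusoidal limb lifts superimposed on
linear translation — not biomechanical; this is sufficient because every
detector operates on displacement and periodicity features. Study-condition
defaults: 30 Hz, 512×424 depth resolution, 40 s quiet-stance/stepping
tasks; stepping cadence 1.0 steps/s with 0.15 m knee lifts; comfortable and
maximum-speed walks at 1.2 and 1.8 m/s from 4.2 m; a slow tandem-style line
walk at 0.2 m/s (a stand-in: the protocol describes the line walk only by
name); three sit-to-stand cycles with 1.5 s transitions; landmark tracking
noise 3 mm SD; depth sensor noise 5 mm SD; postural sway modelled as two
bounded oscillatory components of 3–6 mm amplitude (quiet-stance scale).
One NumPy random stream per recording, seeded from the configuration, makes
output bit-identical under a fixed seed; noise is the only stochastic
element.

Depth rendering rasterizes capsules between connected joints under the
pinhole model; background is 0 and silhouette pixels carry the
front-surface distance in millimetres. Injectable defects mirror the
criterion taxonomy one-to-one: forward/backward drift ramps, sidesteps,
open feet, arm excursions, arms-raised starts, a support pole in the depth
image, clothing noise (zeroing/jittering a stated fraction of below-knee
silhouette pixels), floor noise (spurious returns in the floor band),
truncation, and extra/missing steps.

Clothing noise also degrades the skeleton's leg-landmark tracking, with a
noise SD growing quadratically in the injected fraction (0.4·m² metres).
This reproduces the observed coupling between clothing-related disturbances
and step-detection failures as a threshold phenomenon: mild depth noise
(fractions ≈ 0.2) leaves step events intact, while heavy noise (≈ 0.5)
corrupts them.

What the simulator does **not** emulate: soft-tissue and clothing physics,
photorealistic depth artifacts (multipath, edge noise), tracking-model
failure modes of real skeleton estimators, multi-subject scenes, and
impairment-specific gait patterns. Passing the battery therefore
demonstrates internal consistency of detectors against constructed defects
at stated magnitudes — not agreement with human raters on clinical data.

## Defect-recovery battery

The battery simulates every automatically detectable (task, defect) pair at
twice its detector's threshold magnitude, 50 seeds each, plus 20 clean
seeds per task, and scores raised flags against ground truth: per-criterion
precision and recall over the defect runs, false-positive rates over the
clean runs. Step-count defects have no scalar threshold to double; their
canonical magnitudes are set per task to break side alternation beyond the
detector's 20% bound (stepping-in-place: 12 extra / 10 missing; line walk:
3; short walks: 2 extra / 1 missing). Problem sizes: kinematic entries run
skeleton-only (their detectors never read depth); depth is rendered at
96×80 / 2 Hz — ample for silhouette-fraction statistics — for the
disturbance entries and all clean runs, so the disturbance detector is
scored for both hits and false alarms.

## Rating concordance

Rating sheets are plain CSV, one row per (recording, rater); loading
validates the decision vocabulary and that every selected criterion is
applicable to the recording's task. Two raters' sheets are inner-joined on
recording id (single-rated recordings reported separately) and summarized
per task as a 3×3 decision confusion matrix with derived rates: concordance
(trace/n), unanimous keep/discard/undecided, strict disagreement
(keep-vs-discard only) and discordance involving an undecided vote. Raters
are interchangeable by default, so off-diagonal pairs pool (an ordered mode
exists). Criterion selection frequencies use the per-rating denominator
(each rater's selection counts once); as a multiselect they need not sum to
100%. Rates are exact count ratios; rounding happens only at presentation.
Chance-corrected agreement (kappa) is deliberately out of scope.

## Numerical and design notes

* Container: `metadata.json`, wide `skeleton.csv` (full-precision floats,
  round-trips to ≤ 1e-6 m), 16-bit grayscale PNGs plus `depth_index.csv`.
  Depth round-trips bit-exactly. Coordinate convention: right-handed camera
  frame, x lateral (subject's left positive as seen by the camera), y up,
  z away from the camera; metres for the skeleton, millimetres for depth.
  Timestamps are float seconds from the first frame; the two streams may
  carry independent timestamps.
* Landmark names are the 25 canonical Kinect-v2 joints in sensor order;
  pelvis = SpineBase, hands = HandLeft/HandRight.
* Figure rendering is deterministic (fixed styling, no embedded
  timestamps), so repeated renders are byte-identical.
* Boundary convention everywhere: strict `>` against thresholds; ties never
  raise.
* Known limitations: detectors are tuned for single-subject recordings
  following the task protocols; the disturbance detector requires a
  skeleton stream alongside depth to predict the silhouette; thresholds for
  the non-protocol criteria are heuristics whose agreement with human
  raters is untested by construction.
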