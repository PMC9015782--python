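"""Condensed motion-profile images of a depth stream, and the rating figure.

A motion profile summarizes an entire depth recording as three 2-D images:

* ``frontal`` (height x width): per-pixel average over time;
* ``top``     (time x width):  per-frame average over the vertical axis;
* ``side``    (time x height): per-frame average over the horizontal axis.

Averages are taken over *valid* (nonzero) pixels only — a depth value of 0
means "no return" and must not dilute the mean. A pixel with no valid
contributor is 0 in the output and 0 in ``valid_fraction``. The reduction is
the arithmetic mean by default because it is scale-stable across recordings
of different lengths; a raw-sum mode is available (``reduction="sum"``) for
compatibility with summation-style profiles.

Axis orientation: ``top``/``side`` rows are time increasing downward;
``top`` columns are image x, ``side`` columns are image y.

Raw profile arrays are never display-normalized; a 1st-99th percentile
contrast stretch is applied at render time only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure
from PIL import Image

from .recording import Recording, RecordingMetadata, ValidationError


@dataclass
class MotionProfile:
    frontal: np.ndarray         # (H, W)
    top: np.ndarray             # (T, W)
    side: np.ndarray            # (T, H)
    valid_fraction: np.ndarray  # (H, W), fraction of frames with valid depth


def compute_motion_profiles(rec: Recording,
                            reduction: str = "mean") -> MotionProfile:
    """Compute the three condensed images from ``rec``'s depth stream.

    Each output value is the arithmetic mean (or sum) over contributing
    valid (nonzero) pixels only. Streams are processed frame by frame, so
    memory stays O(frame size) regardless of recording length.
    """
    if not rec.depth_frames:
        raise ValidationError("motion profiles require a non-empty depth stream")
    if reduction not in ("mean", "sum"):
        raise ValueError(f"reduction must be 'mean' or 'sum', got {reduction!r}")

    shape = rec.depth_frames[0].depth.shape
    n = len(rec.depth_frames)
    frontal_sum = np.zeros(shape)
    frontal_cnt = np.zeros(shape)
    top = np.zeros((n, shape[1]))
    side = np.zeros((n, shape[0]))

    for i, f in enumerate(rec.depth_frames):
        d = np.asarray(f.depth, dtype=float)
        valid = d > 0
        frontal_sum += np.where(valid, d, 0.0)
        frontal_cnt += valid

        col_cnt = valid.sum(axis=0)  # per column, over the vertical axis
        col_sum = np.where(valid, d, 0.0).sum(axis=0)
        row_cnt = valid.sum(axis=1)  # per row, over the horizontal axis
        row_sum = np.where(valid, d, 0.0).sum(axis=1)
        if reduction == "mean":
            top[i] = np.divide(col_sum, col_cnt, out=np.zeros_like(col_sum),
                               where=col_cnt > 0)
            side[i] = np.divide(row_sum, row_cnt, out=np.zeros_like(row_sum),
                                where=row_cnt > 0)
        else:
            top[i] = col_sum
            side[i] = row_sum

    if reduction == "mean":
        frontal = np.divide(frontal_sum, frontal_cnt,
                            out=np.zeros_like(frontal_sum),
                            where=frontal_cnt > 0)
    else:
        frontal = frontal_sum
    return MotionProfile(frontal=frontal, top=top, side=side,
                         valid_fraction=frontal_cnt / n)


def _stretch(img: np.ndarray) -> np.ndarray:
    """Display-only 1st-99th percentile contrast stretch of nonzero values."""
    nz = img[img > 0]
    if nz.size == 0:
        return np.zeros_like(img)
    lo, hi = np.percentile(nz, [1, 99])
    if hi <= lo:
        hi = lo + 1.0
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def render_profile_figure(mp: MotionProfile | None, sig, meta: RecordingMetadata,
                          out: str | Path) -> Path:
    """Write the rating figure: 3 profile panels plus one panel per signal.

    Deterministic for fixed inputs (fixed styling, no timestamps embedded),
    so re-rendering produces byte-identical files. ``sig`` is a
    :class:`~mocapqc.signals.SignalSet` (may be empty); ``mp`` may be None
    for skeleton-only recordings, dropping the profile panels.
    """
    fig = build_profile_figure(mp, sig, meta)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    FigureCanvasAgg(fig)
    fig.savefig(out, format="png", dpi=100, metadata={"Software": "mocapqc"})
    return out


def build_profile_figure(mp: MotionProfile | None, sig,
                         meta: RecordingMetadata) -> Figure:
    """Assemble the figure object; exposed so callers can count panels."""
    names = list(sig.signals) if sig is not None else []
    n_profiles = 3 if mp is not None else 0
    n_panels = n_profiles + len(names)
    if n_panels == 0:
        raise ValueError("nothing to render: no profiles and no signals")

    fig = Figure(figsize=(4.0 * min(n_panels, 4), 3.0 * ((n_panels + 3) // 4)),
                 constrained_layout=True)
    ncols = min(n_panels, 4)
    nrows = (n_panels + ncols - 1) // ncols
    axes = [fig.add_subplot(nrows, ncols, i + 1) for i in range(n_panels)]

    k = 0
    if mp is not None:
        for img, title, ylab in (
            (mp.frontal, "frontal (time-averaged depth)", "image y"),
            (mp.top, "top (vertical-axis average)", "time (frames)"),
            (mp.side, "side (horizontal-axis average)", "time (frames)"),
        ):
            ax = axes[k]
            ax.imshow(_stretch(img), cmap="gray", aspect="auto",
                      interpolation="nearest")
            ax.set_title(title, fontsize=9)
            ax.set_ylabel(ylab, fontsize=8)
            ax.tick_params(labelsize=7)
            k += 1
    for name in names:
        s = sig.signals[name]
        ax = axes[k]
        ax.plot(s.t, s.values, lw=0.8, color="#1f5fa8")
        ax.set_title(f"{name} [{s.unit}]", fontsize=9)
        ax.set_xlabel("t (s)", fontsize=8)
        ax.tick_params(labelsize=7)
        k += 1

    fig.suptitle(f"{meta.recording_id}  —  {meta.task.value}", fontsize=11)
    return fig


def export_profile_pngs(mp: MotionProfile, out_dir: str | Path) -> Path:
    """Export raw profile arrays as 16-bit PNGs with a JSON scale sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scales = {}
    for name in ("frontal", "top", "side"):
        arr = getattr(mp, name)
        peak = float(arr.max()) if arr.size else 0.0
        scale = 65535.0 / peak if peak > 0 else 1.0
        Image.fromarray(
            np.clip(arr * scale, 0, 65535).astype(np.uint16)
        ).save(out_dir / f"{name}.png")
        scales[name] = {"values_per_count": 1.0 / scale, "unit": "mm"}
    sidecar = out_dir / "profile_scale.json"
    sidecar.write_text(json.dumps(scales, indent=1), encoding="utf-8")
    return sidecar
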