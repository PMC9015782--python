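"""Two-rater usability ratings: data model, CSV sheets, concordance statistics.

Each recording receives, from each of two independent raters, an overall
usability decision (keep / discard / undecided), a multiselect of quality
criteria applicable to the recording's task, an optional free-text comment
and the rating duration. Sheets are plain CSV, one row per (recording,
rater):

    recording_id, rater_id, task, decision, criteria, comment,
    rating_duration_s

with criteria as semicolon-joined codes. Concordance statistics summarize a
paired table per task as a 3x3 confusion matrix of decisions with derived
rates. Raters are treated as interchangeable by default, so the matrix is
unordered: pair counts (a, b) and (b, a) pool into one cell (an ordered mode
is available). All rates are exact fractions internally; percentages are a
presentation of counts/n.

Chance-corrected agreement (kappa-style statistics) is deliberately not
implemented; raw concordance is the reported quantity.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .flags import CRITERION_TASKS, QualityCriterion
from .recording import TaskType

DECISIONS = ("keep", "discard", "undecided")

RATING_COLUMNS = ["recording_id", "rater_id", "task", "decision", "criteria",
                  "comment", "rating_duration_s"]


class RatingFormatError(ValueError):
    """A rating sheet row is malformed or inconsistent."""


@dataclass
class RatingRecord:
    recording_id: str
    rater_id: str
    task: TaskType
    decision: str  # keep | discard | undecided
    criteria: set[QualityCriterion] = field(default_factory=set)
    comment: str = ""
    rating_duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.decision not in DECISIONS:
            raise RatingFormatError(
                f"decision must be one of {DECISIONS}, got {self.decision!r}")
        for c in self.criteria:
            if self.task not in CRITERION_TASKS[c]:
                raise RatingFormatError(
                    f"criterion {c.value} is not applicable to task "
                    f"{self.task.value}")


def save_ratings(records: list[RatingRecord], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(RATING_COLUMNS)
        for r in records:
            crits = ";".join(sorted(c.value for c in r.criteria))
            dur = "" if r.rating_duration_s is None else repr(r.rating_duration_s)
            w.writerow([r.recording_id, r.rater_id, r.task.value, r.decision,
                        crits, r.comment, dur])
    return path


def load_ratings(path: str | Path) -> list[RatingRecord]:
    """Read a rating sheet; malformed rows raise with their row number."""
    path = Path(path)
    records: list[RatingRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != RATING_COLUMNS:
            raise RatingFormatError(f"{path.name}: unexpected header {header}")
        for row_no, row in enumerate(reader, start=2):
            if len(row) != len(RATING_COLUMNS):
                raise RatingFormatError(
                    f"{path.name} row {row_no}: expected "
                    f"{len(RATING_COLUMNS)} fields, got {len(row)}")
            rid, rater, task_s, decision, crit_s, comment, dur_s = row
            try:
                task = TaskType(task_s)
                criteria = set()
                for code in filter(None, crit_s.split(";")):
                    criteria.add(QualityCriterion(code))
                duration = float(dur_s) if dur_s else None
                records.append(RatingRecord(
                    recording_id=rid, rater_id=rater, task=task,
                    decision=decision, criteria=criteria, comment=comment,
                    rating_duration_s=duration))
            except (ValueError, RatingFormatError) as exc:
                raise RatingFormatError(
                    f"{path.name} row {row_no}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Pairing and concordance
# ---------------------------------------------------------------------------

@dataclass
class PairedRatings:
    """Inner join of two raters' sheets on recording_id."""

    table: pd.DataFrame  # recording_id, task, decision_a, decision_b
    unpaired_a: list[str] = field(default_factory=list)
    unpaired_b: list[str] = field(default_factory=list)


def merge_rater_pair(a: list[RatingRecord], b: list[RatingRecord]
                     ) -> PairedRatings:
    """Pair two raters' sheets; single-rated recordings reported separately.

    Raises :class:`RatingFormatError` if either rater rated a recording
    more than once.
    """
    def index(records: list[RatingRecord], label: str) -> dict[str, RatingRecord]:
        out: dict[str, RatingRecord] = {}
        for r in records:
            if r.recording_id in out:
                raise RatingFormatError(
                    f"duplicate rating of {r.recording_id} by rater "
                    f"{r.rater_id} ({label})")
            out[r.recording_id] = r
        return out

    ia, ib = index(a, "first sheet"), index(b, "second sheet")
    common = sorted(set(ia) & set(ib))
    rows = [{
        "recording_id": rid,
        "task": ia[rid].task.value,
        "decision_a": ia[rid].decision,
        "decision_b": ib[rid].decision,
    } for rid in common]
    table = pd.DataFrame(rows, columns=["recording_id", "task",
                                        "decision_a", "decision_b"])
    return PairedRatings(table=table,
                         unpaired_a=sorted(set(ia) - set(ib)),
                         unpaired_b=sorted(set(ib) - set(ia)))


@dataclass
class ConcordanceSummary:
    task: TaskType
    n: int
    confusion: np.ndarray  # 3x3 counts indexed by DECISIONS order
    ordered: bool
    concordance_pct: float
    unanimous_keep_pct: float
    unanimous_discard_pct: float
    unanimous_undecided_pct: float
    strict_disagreement_pct: float
    undecided_involved_pct: float


def concordance_summary(paired: PairedRatings, task: TaskType,
                        ordered: bool = False) -> ConcordanceSummary:
    """Decision confusion matrix and derived rates for one task.

    ``concordance`` is trace/n; strict disagreement counts only
    keep-vs-discard pairs; ``undecided_involved`` counts discordant pairs
    where at least one decision is undecided (the dominant discordance
    pattern). With ``ordered=False`` (default) rater order is ignored and
    off-diagonal counts pool into the upper triangle.
    """
    df = paired.table[paired.table["task"] == task.value]
    n = len(df)
    if n == 0:
        raise ValueError(f"no paired ratings for task {task.value}")
    idx = {d: i for i, d in enumerate(DECISIONS)}
    confusion = np.zeros((3, 3), dtype=int)
    for da, db in zip(df["decision_a"], df["decision_b"]):
        i, j = idx[da], idx[db]
        if not ordered and i > j:
            i, j = j, i
        confusion[i, j] += 1

    trace = int(np.trace(confusion))
    kk = int(confusion[idx["keep"], idx["keep"]])
    dd = int(confusion[idx["discard"], idx["discard"]])
    uu = int(confusion[idx["undecided"], idx["undecided"]])
    i_k, i_d, i_u = idx["keep"], idx["discard"], idx["undecided"]
    strict = int(confusion[i_k, i_d] + confusion[i_d, i_k])
    und_involved = int(confusion[i_k, i_u] + confusion[i_u, i_k]
                       + confusion[i_d, i_u] + confusion[i_u, i_d])

    pct = lambda c: 100.0 * c / n
    return ConcordanceSummary(
        task=task, n=n, confusion=confusion, ordered=ordered,
        concordance_pct=pct(trace),
        unanimous_keep_pct=pct(kk),
        unanimous_discard_pct=pct(dd),
        unanimous_undecided_pct=pct(uu),
        strict_disagreement_pct=pct(strict),
        undecided_involved_pct=pct(und_involved),
    )


def criterion_frequencies(ratings: list[RatingRecord],
                          group_labels: dict[str, str] | None = None
                          ) -> pd.DataFrame:
    """Per (task, criterion[, group]) selection percentage among ratings.

    The denominator is the number of ratings of that task (per-rating
    convention; each rater's selection counts once). Criteria are
    multiselect, so per-task percentages may sum to more than 100.
    """
    rows = []
    groups = (lambda rid: group_labels.get(rid, "")) if group_labels else None
    by_key: dict[tuple, list[RatingRecord]] = {}
    for r in ratings:
        key = (r.task, groups(r.recording_id)) if groups else (r.task,)
        by_key.setdefault(key, []).append(r)
    for key, recs in sorted(by_key.items(), key=lambda kv: str(kv[0])):
        task = key[0]
        denom = len(recs)
        for crit in QualityCriterion:
            if task not in CRITERION_TASKS[crit]:
                continue
            count = sum(crit in r.criteria for r in recs)
            row = {
                "task": task.value,
                "criterion": crit.value,
                "n_ratings": denom,
                "n_selected": count,
                "pct": 100.0 * count / denom,
            }
            if groups:
                row["group"] = key[1]
            rows.append(row)
    return pd.DataFrame(rows)


def median_rating_duration(ratings: list[RatingRecord]) -> float:
    """Median rating duration (s) over records that carry one."""
    durations = [r.rating_duration_s for r in ratings
                 if r.rating_duration_s is not None]
    if not durations:
        raise ValueError("no rating durations present")
    return float(np.median(durations))


def plot_confusion_matrices(summaries: list[ConcordanceSummary],
                            out: str | Path) -> Path:
    """One confusion-matrix panel per task, written as a PNG."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    n = len(summaries)
    ncols = min(n, 4)
    nrows = (n + ncols - 1) // ncols
    fig = Figure(figsize=(3.2 * ncols, 3.2 * nrows), constrained_layout=True)
    for i, s in enumerate(summaries):
        ax = fig.add_subplot(nrows, ncols, i + 1)
        ax.imshow(s.confusion, cmap="Blues")
        for r in range(3):
            for c in range(3):
                ax.text(c, r, str(s.confusion[r, c]), ha="center",
                        va="center", fontsize=9)
        ax.set_xticks(range(3), DECISIONS, fontsize=7)
        ax.set_yticks(range(3), DECISIONS, fontsize=7)
        ax.set_title(f"{s.task.value} (n={s.n}, "
                     f"conc. {s.concordance_pct:.1f}%)", fontsize=9)
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    FigureCanvasAgg(fig)
    fig.savefig(out, format="png", dpi=100, metadata={"Software": "mocapqc"})
    return out


def summary_to_dict(s: ConcordanceSummary) -> dict:
    return {
        "task": s.task.value,
        "n": s.n,
        "ordered": s.ordered,
        "confusion": s.confusion.tolist(),
        "decisions": list(DECISIONS),
        "concordance_pct": s.concordance_pct,
        "unanimous_keep_pct": s.unanimous_keep_pct,
        "unanimous_discard_pct": s.unanimous_discard_pct,
        "unanimous_undecided_pct": s.unanimous_undecided_pct,
        "strict_disagreement_pct": s.strict_disagreement_pct,
        "undecided_involved_pct": s.undecided_involved_pct,
    }
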