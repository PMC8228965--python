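"""Time-point evaluation protocol.

Labeled and predicted classes are paired every 320 ms and tallied into one
multiclass confusion matrix per task (behaviors, postures), pooled over
videos and folds.  Exclusion rules absorb annotation/alignment jitter:

* timepoints outside VALID regions are never tallied;
* timepoints within 1 s of a class transition on the task channel are
  excluded — except on the SHAKE side of a boundary, where only the outer
  one-third second is excluded (SHAKE bouts are too short for a 1 s rule);
* behavior timepoints carrying more than one simultaneous labeled behavior
  are excluded (NONE counts as exactly one label);
* posture timepoints labeled MIXED are dropped, and MIXED *predictions*
  are replaced with the next most likely posture.

Per-class metrics are one-vs-rest reductions of the confusion matrix;
undefined ratios are reported as NaN, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from collarml.ethogram import (
    BehaviorClass,
    LabelTrack,
    PostureClass,
    StructuralError,
    _assignment,
    channel_boundaries,
)
from collarml.grid import (
    BEHAVIOR_CLASSES,
    MULTI,
    POSTURE_CLASSES,
    PredictionTrack,
    grid_centers,
    grid_labels,
    n_gridpoints,
)

__all__ = [
    "ExclusionPolicy",
    "ConfusionTally",
    "eligible_timepoints",
    "resolve_posture_prediction",
    "argmax_class",
    "tally",
    "class_metrics",
    "per_video_f1",
    "position_breakdown",
    "f1_score",
]

SHAKE = BehaviorClass.SHAKE.value
MIXED = PostureClass.MIXED.value


@dataclass(frozen=True)
class ExclusionPolicy:
    transition_margin_s: float = 1.0
    shake_margin_s: float = 1.0 / 3.0
    drop_multilabel: bool = True

    def __post_init__(self) -> None:
        if self.transition_margin_s <= 0 or self.shake_margin_s <= 0:
            raise ValueError("margins must be > 0")


def _side_margin(side: object, policy: ExclusionPolicy) -> float:
    """Exclusion margin on one side of a boundary, by the class there.

    The SHAKE margin applies when the side is exactly a lone SHAKE label
    (behavior channel assignments are frozensets of class names)."""
    if side == frozenset({SHAKE}) or side == SHAKE:
        return policy.shake_margin_s
    return policy.transition_margin_s


def _excluded_by_transitions(
    track: LabelTrack, channel: str, centers: np.ndarray, policy: ExclusionPolicy
) -> np.ndarray:
    """Mask of gridpoint centers inside any boundary's exclusion window.

    Valid-region boundaries count as transitions; their margins are also
    class-resolved on the task channel.  Windows are open intervals
    ``(t - m_before, t + m_after)``.
    """
    excluded = np.zeros(centers.size, dtype=bool)
    eps = 1e-9
    boundaries = list(channel_boundaries(track, channel))
    for bt, _, _ in channel_boundaries(track, "valid"):
        # valid-region edges count as transitions; margins resolved by the
        # task-channel class on each side
        boundaries.append(
            (bt, _assignment(track, channel, bt - eps), _assignment(track, channel, bt + eps))
        )
    for bt, before, after in boundaries:
        m_b = _side_margin(before, policy)
        m_a = _side_margin(after, policy)
        excluded |= (centers > bt - m_b) & (centers < bt + m_a)
    return excluded


def eligible_timepoints(
    track: LabelTrack,
    policy: ExclusionPolicy,
    task: str,
    n: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gridpoints that enter the confusion tally, with their resolved label.

    Returns ``(centers, eligible, labels)``; ``labels[i]`` is meaningful
    only where ``eligible[i]``.
    """
    if task not in ("behavior", "posture"):
        raise ValueError(f"unknown task {task!r}")
    valid, beh, post, _ = grid_labels(track, n)
    centers = grid_centers(track.extent_s, n)
    excl_trans = _excluded_by_transitions(track, task, centers, policy)
    eligible = valid & ~excl_trans
    if task == "behavior":
        labels = beh
        if policy.drop_multilabel:
            eligible &= labels != MULTI
    else:
        labels = post
        eligible &= (labels != MIXED) & (labels != "")
    return centers, eligible, labels


def argmax_class(probs: np.ndarray, classes: tuple[str, ...] | list[str]) -> str:
    """Most likely class; exact ties go to the lexicographically smaller name."""
    top = np.flatnonzero(probs == probs.max())
    return min(classes[i] for i in top)


def resolve_posture_prediction(
    probs: np.ndarray, classes: tuple[str, ...] | list[str] = tuple(POSTURE_CLASSES)
) -> str:
    """Predicted posture with MIXED replaced by the next most likely class."""
    best = argmax_class(probs, classes)
    if best != MIXED:
        return best
    keep = [i for i, c in enumerate(classes) if c != MIXED]
    sub = [classes[i] for i in keep]
    return argmax_class(probs[keep], sub)


@dataclass
class ConfusionTally:
    """Multiclass time-point confusion counts for one task.

    ``counts[i, j]`` tallies gridpoints labeled ``classes[i]`` and
    predicted ``classes[j]``."""

    task: str
    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.classes)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, class_name: str) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one class against all others."""
        i = self.classes.index(class_name)
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn

    def __add__(self, other: "ConfusionTally") -> "ConfusionTally":
        if other.task != self.task or other.classes != self.classes:
            raise ValueError("incompatible tallies")
        return ConfusionTally(self.task, self.classes, self.counts + other.counts)


def _predicted_classes(pred: PredictionTrack, task: str) -> list[str]:
    if task == "behavior":
        return [
            argmax_class(pred.behavior_probs[i], pred.behavior_classes)
            for i in range(len(pred))
        ]
    return [
        resolve_posture_prediction(pred.posture_probs[i], pred.posture_classes)
        for i in range(len(pred))
    ]


def _task_classes(task: str) -> tuple[str, ...]:
    if task == "behavior":
        return tuple(BEHAVIOR_CLASSES)
    return tuple(c for c in POSTURE_CLASSES if c != MIXED)


def tally(
    tracks: list[LabelTrack],
    predictions: dict[str, PredictionTrack],
    policy: ExclusionPolicy = ExclusionPolicy(),
    task: str = "behavior",
) -> ConfusionTally:
    """Pool label/prediction pairs at eligible gridpoints across videos."""
    classes = _task_classes(task)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for track in tracks:
        pred = predictions[track.video_id]
        n_track = n_gridpoints(track.extent_s)
        if abs(len(pred) - n_track) > 1:
            raise StructuralError(
                f"video {track.video_id}: prediction grid has {len(pred)} points, "
                f"track implies {n_track}"
            )
        n = min(len(pred), n_track)
        _, eligible, labels = eligible_timepoints(track, policy, task, n=n)
        pred_cls = _predicted_classes(pred, task)
        for i in np.flatnonzero(eligible[:n]):
            counts[index[labels[i]], index[pred_cls[i]]] += 1
    return ConfusionTally(task=task, classes=classes, counts=counts)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (NaN when undefined)."""
    if not np.isfinite(precision) or not np.isfinite(sensitivity):
        return float("nan")
    return _safe_div(2 * precision * sensitivity, precision + sensitivity)


def class_metrics(t: ConfusionTally) -> pd.DataFrame:
    """One-vs-rest prevalence/sensitivity/specificity/accuracy/precision/F1
    per class, from the stored counts."""
    rows = {}
    for c in t.classes:
        tp, fp, fn, tn = t.one_vs_rest(c)
        n = tp + fp + fn + tn
        prec = _safe_div(tp, tp + fp)
        sens = _safe_div(tp, tp + fn)
        rows[c] = {
            "prevalence": _safe_div(tp + fn, n),
            "sensitivity": sens,
            "specificity": _safe_div(tn, tn + fp),
            "accuracy": _safe_div(tp + tn, n),
            "precision": prec,
            "f1": f1_score(prec, sens),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def per_video_f1(
    tracks: list[LabelTrack],
    predictions: dict[str, PredictionTrack],
    policy: ExclusionPolicy,
    task: str,
    class_name: str,
) -> pd.DataFrame:
    """Per-video one-vs-rest F1 for one class (NaN where undefined)."""
    rows = []
    for track in tracks:
        t = tally([track], predictions, policy, task)
        f1 = class_metrics(t).loc[class_name, "f1"]
        rows.append({"video_id": track.video_id, "f1": f1})
    return pd.DataFrame(rows)


def position_breakdown(
    per_video: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean F1 per device position with a percentile-bootstrap 95% CI.

    ``per_video`` needs columns ``position`` and ``f1``; NaN F1s (classes
    absent from a video) are ignored.  Positions with fewer than two
    usable videos get NaN CI bounds and ``ci_omitted=True``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pos, grp in per_video.dropna(subset=["f1"]).groupby("position", sort=True):
        f1s = grp["f1"].to_numpy()
        mean = float(f1s.mean())
        if len(f1s) < 2:
            rows.append(
                {"position": pos, "n_videos": len(f1s), "mean_f1": mean,
                 "ci_low": np.nan, "ci_high": np.nan, "ci_omitted": True}
            )
            continue
        idx = rng.integers(0, len(f1s), size=(n_boot, len(f1s)))
        boot_means = f1s[idx].mean(axis=1)
        lo, hi = np.percentile(boot_means, [2.5, 97.5])
        rows.append(
            {"position": pos, "n_videos": len(f1s), "mean_f1": mean,
             "ci_low": float(lo), "ci_high": float(hi), "ci_omitted": False}
        )
    return pd.DataFrame(rows)
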