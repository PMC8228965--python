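"""The 320 ms prediction/evaluation grid and per-gridpoint label resolution.

Every downstream stage (training targets, prediction, confusion tallies,
event detection) works on a fixed grid of 320 ms steps on the video clock;
each gridpoint is represented by its center time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from collarml.ethogram import BehaviorClass, LabelTrack, PostureClass

__all__ = [
    "GRID_STEP_S",
    "BEHAVIOR_CLASSES",
    "POSTURE_CLASSES",
    "n_gridpoints",
    "grid_centers",
    "grid_labels",
    "PredictionTrack",
]

GRID_STEP_S = 0.320

BEHAVIOR_CLASSES: list[str] = [b.value for b in BehaviorClass]
POSTURE_CLASSES: list[str] = [p.value for p in PostureClass]

#: sentinel for gridpoints excluded from a task (multi-label, invalid, ...)
MULTI = "<MULTI>"


def n_gridpoints(duration_s: float) -> int:
    return max(int(np.ceil(duration_s / GRID_STEP_S - 1e-9)), 1)


def grid_centers(duration_s: float | None = None, n: int | None = None) -> np.ndarray:
    if n is None:
        if duration_s is None:
            raise ValueError("give duration_s or n")
        n = n_gridpoints(duration_s)
    return (np.arange(n) + 0.5) * GRID_STEP_S


def grid_labels(
    track: LabelTrack, n: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Resolve labels at every gridpoint center of a track.

    Returns ``(valid, behavior, posture, n_behaviors)`` where ``valid`` is a
    boolean mask, ``behavior``/``posture`` are class-name arrays ('' where
    unlabeled/invalid; behavior is NONE where valid but no behavior covers,
    and MULTI where several do), and ``n_behaviors`` counts simultaneous
    behavior labels.
    """
    c = grid_centers(track.extent_s, n)
    m = c.size
    valid = np.zeros(m, dtype=bool)
    beh = np.full(m, "", dtype=object)
    post = np.full(m, "", dtype=object)
    n_beh = np.zeros(m, dtype=int)
    for s in track.segments:
        cover = (c >= s.start_s) & (c < s.stop_s)
        if s.channel == "valid":
            valid |= cover
        elif s.channel == "posture":
            post[cover] = s.class_name
        else:
            n_beh[cover] += 1
            beh[cover] = s.class_name
    beh[(n_beh == 0)] = BehaviorClass.NONE.value
    beh[(n_beh > 1)] = MULTI
    beh[~valid] = ""
    post[~valid] = ""
    return valid, beh, post, n_beh


@dataclass
class PredictionTrack:
    """Per-gridpoint class probability distributions for one video.

    ``behavior_probs`` is ``(n, 10)`` over :data:`BEHAVIOR_CLASSES` and
    ``posture_probs`` is ``(n, 6)`` over :data:`POSTURE_CLASSES`; each row
    sums to 1.  ``t_grid`` holds gridpoint centers on the video clock.
    """

    video_id: str
    t_grid: np.ndarray
    behavior_probs: np.ndarray
    posture_probs: np.ndarray
    grid_step_s: float = GRID_STEP_S
    behavior_classes: tuple[str, ...] = tuple(BEHAVIOR_CLASSES)
    posture_classes: tuple[str, ...] = tuple(POSTURE_CLASSES)

    def __post_init__(self) -> None:
        n = len(self.t_grid)
        if self.behavior_probs.shape != (n, len(self.behavior_classes)):
            raise ValueError("behavior_probs shape mismatch")
        if self.posture_probs.shape != (n, len(self.posture_classes)):
            raise ValueError("posture_probs shape mismatch")

    def __len__(self) -> int:
        return len(self.t_grid)

    def behavior_series(self, class_name: str) -> np.ndarray:
        return self.behavior_probs[:, self.behavior_classes.index(class_name)]
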