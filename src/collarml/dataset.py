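"""Dataset assembly: per-dog caps, subject-disjoint folds, and summaries.

Cross-validation folds are built per dog: every video of a dog lands in a
single fold, so no model is ever trained and evaluated on the same animal.
Folds are balanced by labeled duration with a greedy largest-first packer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from collarml.errors import ConfigError
from collarml.ethogram import AccelTrace, LabelTrack

__all__ = [
    "AlignedRecording",
    "FoldAssignment",
    "cap_per_dog",
    "assign_folds",
    "summarize",
    "format_hms",
]

N_FOLDS = 5


@dataclass
class AlignedRecording:
    """One clock-aligned recording ready for training/evaluation.

    ``trace`` is on the video clock (offset already removed)."""

    trace: AccelTrace
    track: LabelTrack
    dog_id: str
    video_id: str
    position: str | None = None


@dataclass
class FoldAssignment:
    """dog_id -> fold index in {0..4}; every dog maps to exactly one fold."""

    by_dog: dict[str, int] = field(default_factory=dict)
    n_folds: int = N_FOLDS

    def fold_of(self, dog_id: str) -> int:
        return self.by_dog[dog_id]

    def dogs_in(self, fold: int) -> set[str]:
        return {d for d, f in self.by_dog.items() if f == fold}


def cap_per_dog(
    entries: Sequence[AlignedRecording], cap: int = 30, seed: int = 0
) -> list[AlignedRecording]:
    """Keep at most ``cap`` videos per dog (some dogs are overrepresented).

    Selection is uniform without replacement, deterministic under ``seed``.
    Output preserves the input order of the retained entries.
    """
    if cap < 1:
        raise ConfigError(f"cap must be >= 1, got {cap}")
    rng = np.random.default_rng(seed)
    by_dog: dict[str, list[int]] = {}
    for i, e in enumerate(entries):
        by_dog.setdefault(e.dog_id, []).append(i)
    keep: set[int] = set()
    for dog_id in sorted(by_dog):
        idx = by_dog[dog_id]
        if len(idx) <= cap:
            keep.update(idx)
        else:
            keep.update(rng.choice(idx, size=cap, replace=False).tolist())
    return [e for i, e in enumerate(entries) if i in keep]


def _labeled_duration_s(track: LabelTrack) -> float:
    return sum(s.stop_s - s.start_s for s in track.segments if s.channel == "valid")


def assign_folds(
    entries: Sequence[AlignedRecording], k: int = N_FOLDS, seed: int = 0
) -> FoldAssignment:
    """Partition dogs into ``k`` folds balanced by labeled duration.

    Greedy largest-first: dogs are sorted by total valid-labeled duration
    (descending, seeded random tie-break) and each is placed into the
    currently lightest fold.  Disjointness holds by construction.
    """
    durations: dict[str, float] = {}
    for e in entries:
        durations[e.dog_id] = durations.get(e.dog_id, 0.0) + _labeled_duration_s(e.track)
    if len(durations) < k:
        raise ConfigError(f"need >= {k} dogs, got {len(durations)}")
    rng = np.random.default_rng(seed)
    dogs = sorted(durations)
    tiebreak = {d: rng.random() for d in dogs}
    order = sorted(dogs, key=lambda d: (-durations[d], tiebreak[d]))
    loads = np.zeros(k)
    assignment: dict[str, int] = {}
    for d in order:
        f = int(np.argmin(loads))
        assignment[d] = f
        loads[f] += durations[d]
    return FoldAssignment(by_dog=assignment, n_folds=k)


def format_hms(seconds: float) -> str:
    """Render a duration as H:MM:SS (hours unpadded)."""
    s = int(round(seconds))
    return f"{s // 3600}:{(s % 3600) // 60:02d}:{s % 60:02d}"


def _overlap_with_valid(track: LabelTrack, start: float, stop: float) -> float:
    out = 0.0
    for v in track.segments:
        if v.channel == "valid":
            out += max(0.0, min(stop, v.stop_s) - max(start, v.start_s))
    return out


def summarize(entries: Iterable[AlignedRecording]) -> pd.DataFrame:
    """Per-class label summary over VALID regions only.

    Columns: ``class, channel, n_videos, n_labels, mean_length_s,
    total_length_s, total_hms``.  A label counts for a video if any part of
    it overlaps a valid region; its counted length is the overlap.
    """
    rows: dict[tuple[str, str], dict] = {}
    for e in entries:
        seen: set[tuple[str, str]] = set()
        for s in e.track.segments:
            if s.channel == "valid":
                continue
            ov = _overlap_with_valid(e.track, s.start_s, s.stop_s)
            if ov <= 0:
                continue
            key = (s.channel, s.class_name)
            r = rows.setdefault(
                key,
                {"channel": s.channel, "class": s.class_name,
                 "n_videos": 0, "n_labels": 0, "total_length_s": 0.0},
            )
            r["n_labels"] += 1
            r["total_length_s"] += ov
            if key not in seen:
                r["n_videos"] += 1
                seen.add(key)
    if not rows:
        return pd.DataFrame(
            columns=["class", "channel", "n_videos", "n_labels",
                     "mean_length_s", "total_length_s", "total_hms"]
        )
    df = pd.DataFrame(rows.values())
    df["mean_length_s"] = df["total_length_s"] / df["n_labels"]
    df["total_hms"] = df["total_length_s"].map(format_hms)
    df = df.sort_values(["channel", "class"]).reset_index(drop=True)
    return df[["class", "channel", "n_videos", "n_labels",
               "mean_length_s", "total_length_s", "total_hms"]]
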