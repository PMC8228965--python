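"""Ethogram domain types and label algebra.

Annotation model: each video is divided into *valid* regions (dog fully
visible and wearing the device) and invalid remainder.  Within valid
regions the labeler records exactly one *posture* at every instant
(postures tile the valid regions) and zero or more simultaneous
*behaviors*.  All intervals are half-open ``[start_s, stop_s)`` so that
abutting segments share no timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorClass",
    "PostureClass",
    "VALID",
    "LabelSegment",
    "LabelTrack",
    "AccelTrace",
    "StructuralError",
    "labels_at",
    "class_transitions",
    "channel_boundaries",
    "read_label_csv",
    "write_label_csv",
    "read_accel_csv",
    "write_accel_csv",
]


class BehaviorClass(str, Enum):
    """The ten behavior classes; NONE is the default/background class."""

    DRINK = "DRINK"
    EAT = "EAT"
    LICKOBJECT = "LICKOBJECT"
    LICKSELF = "LICKSELF"
    PETTING = "PETTING"
    RUBBING = "RUBBING"
    SCRATCH = "SCRATCH"
    SHAKE = "SHAKE"
    SNIFF = "SNIFF"
    NONE = "NONE"


class PostureClass(str, Enum):
    """The six posture classes; MIXED is the catch-all."""

    LIE_DOWN = "LIE_DOWN"
    SIT = "SIT"
    STAND = "STAND"
    WALK = "WALK"
    VIGOROUS = "VIGOROUS"
    MIXED = "MIXED"


#: Class name used on the validity channel.
VALID = "VALID"

_CHANNELS = ("valid", "posture", "behavior")


class StructuralError(ValueError):
    """A label track violates a structural invariant (e.g. overlapping postures)."""


@dataclass(frozen=True)
class LabelSegment:
    """One labeled interval on one channel, times in video-clock seconds."""

    channel: str
    class_name: str
    start_s: float
    stop_s: float

    def __post_init__(self) -> None:
        if self.channel not in _CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if not self.stop_s > self.start_s:
            raise ValueError(
                f"segment must have stop_s > start_s, got [{self.start_s}, {self.stop_s})"
            )
        if self.channel == "valid":
            if self.class_name != VALID:
                raise ValueError("valid-channel segments must be class VALID")
        elif self.channel == "posture":
            PostureClass(self.class_name)
        else:
            b = BehaviorClass(self.class_name)
            if b is BehaviorClass.NONE:
                # NONE is an evaluation class, never an annotation.
                raise ValueError("NONE must not be stored as a behavior segment")

    def covers(self, time_s: float) -> bool:
        return self.start_s <= time_s < self.stop_s


@dataclass
class LabelTrack:
    """All label segments for one video of one dog."""

    video_id: str
    dog_id: str
    segments: list[LabelSegment] = field(default_factory=list)
    video_start_epoch_s: float = 0.0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (s.channel, s.start_s, s.stop_s, s.class_name)
        )
        if self.duration_s is None and self.segments:
            self.duration_s = max(s.stop_s for s in self.segments)

    def channel_segments(self, channel: str) -> list[LabelSegment]:
        if channel not in _CHANNELS:
            raise ValueError(f"unknown channel {channel!r}")
        return [s for s in self.segments if s.channel == channel]

    @property
    def extent_s(self) -> float:
        if self.duration_s is not None:
            return self.duration_s
        return 0.0

    def shifted(self, offset_s: float) -> "LabelTrack":
        """Return a copy with all segment times shifted by ``offset_s``."""
        segs = [
            replace(s, start_s=s.start_s + offset_s, stop_s=s.stop_s + offset_s)
            for s in self.segments
        ]
        return LabelTrack(
            video_id=self.video_id,
            dog_id=self.dog_id,
            segments=segs,
            video_start_epoch_s=self.video_start_epoch_s,
            duration_s=self.duration_s,
        )


@dataclass
class AccelTrace:
    """Timestamped 3-axis acceleration samples for one recording.

    ``t`` is in device-clock seconds and strictly increasing; ``a`` is an
    ``(n, 3)`` array in units of g, device-local axes.  Devices record
    opportunistically (only while motion is detected) so gaps may occur.
    """

    device_id: str
    t: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.t.ndim != 1 or self.a.shape != (self.t.size, 3):
            raise ValueError("t must be (n,), a must be (n, 3)")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def sampling_rate_hz(self) -> float:
        """Median sampling rate; robust to gaps."""
        if self.t.size < 2:
            return float("nan")
        return float(1.0 / np.median(np.diff(self.t)))

    @property
    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.a, axis=1)


def labels_at(
    track: LabelTrack, time_s: float
) -> tuple[bool, PostureClass | None, set[BehaviorClass]]:
    """Resolve (validity, posture, behaviors) at one instant.

    Outside valid regions returns ``(False, None, set())``.  Inside a valid
    region exactly one posture must cover the instant; an uncovered set of
    behaviors is normalized to ``{NONE}``.

    Raises
    ------
    StructuralError
        If more than one posture segment covers ``time_s``.
    """
    valid = any(s.covers(time_s) for s in track.segments if s.channel == "valid")
    if not valid:
        return False, None, set()
    postures = [
        PostureClass(s.class_name)
        for s in track.segments
        if s.channel == "posture" and s.covers(time_s)
    ]
    if len(postures) > 1:
        raise StructuralError(
            f"{len(postures)} posture segments cover t={time_s} in video {track.video_id}"
        )
    posture = postures[0] if postures else None
    behaviors = {
        BehaviorClass(s.class_name)
        for s in track.segments
        if s.channel == "behavior" and s.covers(time_s)
    }
    if not behaviors:
        behaviors = {BehaviorClass.NONE}
    return True, posture, behaviors


def _assignment(track: LabelTrack, channel: str, time_s: float) -> object:
    """Channel class assignment at an instant, as a hashable value."""
    if channel == "valid":
        return any(s.covers(time_s) for s in track.segments if s.channel == "valid")
    if channel == "posture":
        covering = [
            s.class_name
            for s in track.segments
            if s.channel == "posture" and s.covers(time_s)
        ]
        return covering[0] if covering else None
    return frozenset(
        s.class_name
        for s in track.segments
        if s.channel == "behavior" and s.covers(time_s)
    )


def channel_boundaries(
    track: LabelTrack, channel: str
) -> list[tuple[float, object, object]]:
    """Class transitions on a channel with the assignment on each side.

    Returns ``(time, before, after)`` triples at every instant where the
    channel's class assignment changes, in increasing time order.  For the
    behavior channel assignments are frozensets of class names (empty set =
    background); for posture, a class name or None; for valid, a boolean.
    """
    eps = 1e-9
    boundary_times = sorted(
        {s.start_s for s in track.segments if s.channel == channel}
        | {s.stop_s for s in track.segments if s.channel == channel}
    )
    out: list[tuple[float, object, object]] = []
    for bt in boundary_times:
        before = _assignment(track, channel, bt - eps)
        after = _assignment(track, channel, bt + eps)
        if before != after:
            out.append((bt, before, after))
    return out


def class_transitions(track: LabelTrack, channel: str) -> list[float]:
    """Times where the channel's class assignment changes.

    Segment starts and ends against background count; abutting segments of
    the same class do not (half-open intervals make this unambiguous).
    """
    return [t for t, _, _ in channel_boundaries(track, channel)]


# ---------------------------------------------------------------------------
# CSV interchange
#
# One row per segment: video_id,dog_id,channel,class,start_s,stop_s
# UTF-8, '.' decimal separator, times to 3 decimals.


def write_label_csv(tracks: Iterable[LabelTrack], path: str) -> None:
    rows = []
    for tr in tracks:
        for s in tr.segments:
            rows.append(
                {
                    "video_id": tr.video_id,
                    "dog_id": tr.dog_id,
                    "channel": s.channel,
                    "class": s.class_name,
                    "start_s": round(s.start_s, 3),
                    "stop_s": round(s.stop_s, 3),
                }
            )
    pd.DataFrame(
        rows, columns=["video_id", "dog_id", "channel", "class", "start_s", "stop_s"]
    ).to_csv(path, index=False, float_format="%.3f")


def read_label_csv(path: str) -> list[LabelTrack]:
    df = pd.read_csv(path, dtype={"video_id": str, "dog_id": str})
    tracks = []
    for (vid, dog), grp in df.groupby(["video_id", "dog_id"], sort=True):
        segs = [
            LabelSegment(
                channel=str(r["channel"]),
                class_name=str(r["class"]),
                start_s=float(r["start_s"]),
                stop_s=float(r["stop_s"]),
            )
            for r in grp.to_dict("records")
        ]
        tracks.append(LabelTrack(video_id=str(vid), dog_id=str(dog), segments=segs))
    return tracks


def write_accel_csv(trace: AccelTrace, path: str) -> None:
    pd.DataFrame(
        {
            "device_id": trace.device_id,
            "t_s": trace.t,
            "ax_g": trace.a[:, 0],
            "ay_g": trace.a[:, 1],
            "az_g": trace.a[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.6f")


def read_accel_csv(path: str) -> AccelTrace:
    df = pd.read_csv(path, dtype={"device_id": str})
    if df.empty:
        raise ValueError(f"empty accelerometer file: {path}")
    return AccelTrace(
        device_id=str(df["device_id"].iloc[0]),
        t=df["t_s"].to_numpy(float),
        a=df[["ax_g", "ay_g", "az_g"]].to_numpy(float),
    )
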