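"""Sustained-behavior event detection and user-validation analytics.

Per-gridpoint behavior confidences are segmented into discrete events
(e.g. meals) with a hysteresis automaton; each event carries a confidence
score — the mean per-gridpoint probability of the behavior over the
event's extent — and events scoring below 0.3 are dropped.  Validation
responses ("Yes"/"No"/"Not Sure") are summarized per behavior after
excluding "Not Sure" answers and responses arriving more than 60 min after
the event's end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from collarml.grid import PredictionTrack

__all__ = [
    "EventRecord",
    "ValidationResponse",
    "CONFIDENCE_FLOOR",
    "detect_events",
    "validation_summary",
    "confidence_binned_tpr",
]

CONFIDENCE_FLOOR = 0.3
RESPONSE_CUTOFF_S = 3600.0


@dataclass(frozen=True)
class EventRecord:
    """A detected sustained-behavior event on the epoch clock."""

    event_id: str
    behavior: str
    start_s: float
    end_s: float
    confidence: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("end_s must exceed start_s")


@dataclass(frozen=True)
class ValidationResponse:
    event_id: str
    answer: str  # Yes | No | NotSure
    response_epoch_s: float

    def __post_init__(self) -> None:
        if self.answer not in ("Yes", "No", "NotSure"):
            raise ValueError(f"unknown answer {self.answer!r}")


def detect_events(
    pred: PredictionTrack,
    behavior: str,
    enter_thr: float = 0.7,
    exit_thr: float = 0.5,
    min_dur_s: float = 60.0,
    max_gap_s: float = 30.0,
    epoch_offset_s: float = 0.0,
) -> list[EventRecord]:
    """Hysteresis segmentation of one behavior's probability series.

    A segment opens when the probability reaches ``enter_thr`` and closes
    once it has stayed below ``exit_thr`` for more than ``max_gap_s``
    (short dips stay inside the event).  Segments separated by at most
    ``max_gap_s`` are merged, segments shorter than ``min_dur_s`` are
    dropped, and events with mean confidence below 0.3 are dropped.
    """
    if enter_thr < exit_thr:
        raise ValueError("enter_thr must be >= exit_thr")
    p = pred.behavior_series(behavior)
    step = pred.grid_step_s
    gap_pts = int(np.floor(max_gap_s / step))
    segments: list[tuple[int, int]] = []  # inclusive gridpoint index ranges
    open_start: int | None = None
    last_high = -1
    for i, v in enumerate(p):
        if open_start is None:
            if v >= enter_thr:
                open_start, last_high = i, i
        else:
            if v >= exit_thr:
                last_high = i
            elif i - last_high > gap_pts:
                segments.append((open_start, last_high))
                open_start = None
    if open_start is not None:
        segments.append((open_start, last_high))
    # merge segments separated by <= max_gap_s
    merged: list[tuple[int, int]] = []
    for s, e in segments:
        if merged and (s - merged[-1][1]) * step <= max_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    events = []
    for k, (s, e) in enumerate(merged):
        start = pred.t_grid[s] - step / 2
        end = pred.t_grid[e] + step / 2
        if end - start < min_dur_s:
            continue
        conf = float(p[s : e + 1].mean())
        if conf < CONFIDENCE_FLOOR:
            continue
        events.append(
            EventRecord(
                event_id=f"{pred.video_id}-{behavior}-{k}",
                behavior=behavior,
                start_s=start + epoch_offset_s,
                end_s=end + epoch_offset_s,
                confidence=conf,
            )
        )
    return events


def _valid_responses(
    responses: Iterable[ValidationResponse], events: Sequence[EventRecord]
) -> pd.DataFrame:
    by_id = {e.event_id: e for e in events}
    rows = []
    for r in responses:
        ev = by_id.get(r.event_id)
        if ev is None:
            warnings.warn(f"response to unknown event {r.event_id!r}; skipped")
            continue
        if r.answer == "NotSure":
            continue
        if r.response_epoch_s - ev.end_s > RESPONSE_CUTOFF_S:
            continue
        rows.append(
            {"event_id": r.event_id, "behavior": ev.behavior,
             "answer": r.answer, "confidence": ev.confidence}
        )
    return pd.DataFrame(rows, columns=["event_id", "behavior", "answer", "confidence"])


def validation_summary(
    responses: Iterable[ValidationResponse], events: Sequence[EventRecord]
) -> pd.DataFrame:
    """Per-behavior Yes/No counts and Yes-rate (percent).

    Valid responses are Yes/No answers arriving within 60 min of the
    event's end; the Yes-rate is ``100 * Yes / (Yes + No)`` (NaN when no
    valid responses exist)."""
    df = _valid_responses(responses, events)
    rows = []
    for beh in sorted({e.behavior for e in events}):
        sub = df[df["behavior"] == beh]
        n_yes = int((sub["answer"] == "Yes").sum())
        n_no = int((sub["answer"] == "No").sum())
        rate = 100.0 * n_yes / (n_yes + n_no) if (n_yes + n_no) else float("nan")
        rows.append(
            {"behavior": beh, "n_yes": n_yes, "n_no": n_no, "yes_rate_pct": rate}
        )
    return pd.DataFrame(rows)


def confidence_binned_tpr(
    responses: Iterable[ValidationResponse],
    events: Sequence[EventRecord],
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Yes-rate by event-confidence bin.

    Bins are half-open ``[lo, lo + width)`` from 0.3 upward, except the top
    bin which closes at 1.0; empty bins are reported with count 0."""
    df = _valid_responses(responses, events)
    edges = np.round(np.arange(CONFIDENCE_FLOOR, 1.0 + 1e-9, bin_width), 10)
    rows = []
    for lo in edges[:-1]:
        hi = round(lo + bin_width, 10)
        top = hi >= 1.0 - 1e-9
        if top:
            sel = (df["confidence"] >= lo) & (df["confidence"] <= 1.0)
        else:
            sel = (df["confidence"] >= lo) & (df["confidence"] < hi)
        sub = df[sel]
        n = len(sub)
        n_yes = int((sub["answer"] == "Yes").sum())
        rows.append(
            {
                "bin_low": round(float(lo), 10),
                "bin_high": round(float(min(hi, 1.0)), 10),
                "n_responses": n,
                "yes_rate_pct": 100.0 * n_yes / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
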