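"""Device/video clock-offset estimation.

Device and video clocks disagree by several seconds (sometimes much more),
which matters most for sub-second behaviors.  The estimator correlates the
device's movement-energy envelope against a binary indicator of
high-intensity labels (SHAKE and SCRATCH behaviors, WALK and VIGOROUS
postures) over a bounded offset search, on a 10 Hz grid.  A separate
detector finds the deliberate synchronization shake performed in view of
the camera before collar placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from collarml.ethogram import AccelTrace, LabelTrack

__all__ = [
    "AlignmentResult",
    "NotAlignableError",
    "HIGH_INTENSITY_BEHAVIORS",
    "HIGH_INTENSITY_POSTURES",
    "energy_envelope",
    "auto_align",
    "detect_sync_shake",
    "apply_offset",
]

ENVELOPE_RATE_HZ = 10.0
HIGH_INTENSITY_BEHAVIORS = frozenset({"SHAKE", "SCRATCH"})
HIGH_INTENSITY_POSTURES = frozenset({"WALK", "VIGOROUS"})


class NotAlignableError(RuntimeError):
    """The label track lacks enough high-intensity labels to align against."""


@dataclass(frozen=True)
class AlignmentResult:
    """Estimated device-minus-video clock offset."""

    offset_s: float
    score: float  # normalized cross-correlation peak, in [-1, 1]
    accepted: bool


def energy_envelope(
    trace: AccelTrace, window_s: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Gravity-removed, rectified, smoothed movement energy at 10 Hz.

    Gravity is removed with a ~0.5 Hz low-pass on the acceleration
    magnitude; the residual is rectified and smoothed over ``window_s``.
    Recording gaps (no sample within 0.3 s of a grid point) contribute zero
    energy.  Returns ``(times, envelope)`` on the device clock.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    fs = trace.sampling_rate_hz
    mag = trace.magnitude
    if len(trace) < 8 or not np.isfinite(fs):
        hp = np.abs(mag - np.mean(mag))
    else:
        # sigma for ~0.5 Hz cutoff: f_c = 1 / (2*pi*sigma_t)
        sigma_lp = fs / (2 * np.pi * 0.5)
        hp = np.abs(mag - gaussian_filter1d(mag, sigma=sigma_lp))
        hp = gaussian_filter1d(hp, sigma=max(window_s * fs / 2.0, 1.0))
    t0, t1 = trace.t[0], trace.t[-1]
    n = max(int(np.floor((t1 - t0) * ENVELOPE_RATE_HZ)) + 1, 1)
    tg = t0 + np.arange(n) / ENVELOPE_RATE_HZ
    env = np.interp(tg, trace.t, hp)
    # zero out grid points inside recording gaps
    idx = np.searchsorted(trace.t, tg)
    idx_lo = np.clip(idx - 1, 0, len(trace) - 1)
    idx_hi = np.clip(idx, 0, len(trace) - 1)
    nearest = np.minimum(np.abs(tg - trace.t[idx_lo]), np.abs(trace.t[idx_hi] - tg))
    env = np.where(nearest > 0.3, 0.0, env)
    return tg, env


def _high_intensity_indicator(track: LabelTrack, rate_hz: float = ENVELOPE_RATE_HZ):
    """Binary indicator of high-intensity labels on the video clock."""
    T = track.extent_s
    n = max(int(np.floor(T * rate_hz)) + 1, 1)
    tg = np.arange(n) / rate_hz
    ind = np.zeros(n)
    for s in track.segments:
        hi = (s.channel == "behavior" and s.class_name in HIGH_INTENSITY_BEHAVIORS) or (
            s.channel == "posture" and s.class_name in HIGH_INTENSITY_POSTURES
        )
        if hi:
            i0 = int(np.ceil(s.start_s * rate_hz))
            i1 = min(int(np.ceil(s.stop_s * rate_hz)), n)
            ind[i0:i1] = 1.0
    return tg, ind


def auto_align(
    trace: AccelTrace,
    track: LabelTrack,
    search_half_width_s: float = 30.0,
    accept_score: float = 0.3,
) -> AlignmentResult:
    """Estimate the device-minus-video clock offset.

    Maximizes the normalized (Pearson) cross-correlation between the
    device's energy envelope and the track's high-intensity-label indicator
    over offsets in ``[-search_half_width_s, +search_half_width_s]`` at
    0.1 s resolution.  Ties break toward the smallest ``|offset|``.  The
    result is accepted iff the peak score reaches ``accept_score`` and the
    peak is unique (no rival within 0.01 of the peak score more than 1 s
    away).

    Raises
    ------
    NotAlignableError
        If the track has less than 2 s of high-intensity labels.
    """
    tg_ind, ind = _high_intensity_indicator(track)
    if ind.sum() / ENVELOPE_RATE_HZ < 2.0:
        raise NotAlignableError(
            f"video {track.video_id}: <2 s of high-intensity labels"
        )
    te, env = energy_envelope(trace)
    # soft-saturate so one violent bout cannot dominate the correlation:
    # the indicator is binary, so the envelope should be quasi-binary too
    env = env / (env + 0.1)
    step = 1.0 / ENVELOPE_RATE_HZ
    n_off = int(round(search_half_width_s / step))
    offsets = np.arange(-n_off, n_off + 1) * step
    scores = np.full(offsets.shape, -np.inf)
    for i, d in enumerate(offsets):
        # device time t corresponds to video time t - d
        v = np.interp(te - d, tg_ind, ind, left=np.nan, right=np.nan)
        ok = np.isfinite(v)
        if ok.sum() < 20:
            continue
        e, vv = env[ok], v[ok]
        se, sv = e.std(), vv.std()
        if se == 0 or sv == 0:
            continue
        scores[i] = float(np.corrcoef(e, vv)[0, 1])
    best = np.max(scores)
    if not np.isfinite(best):
        return AlignmentResult(offset_s=0.0, score=-1.0, accepted=False)
    # ties toward smallest |offset|
    cand = np.flatnonzero(scores >= best - 1e-12)
    offset = float(offsets[cand[np.argmin(np.abs(offsets[cand]))]])
    rivals = np.flatnonzero(scores >= best - 0.01)
    unique = bool(np.all(np.abs(offsets[rivals] - offset) <= 1.0))
    accepted = bool(best >= accept_score and unique)
    return AlignmentResult(offset_s=offset, score=float(best), accepted=accepted)


def detect_sync_shake(
    trace: AccelTrace, threshold_ratio: float = 8.0
) -> float | None:
    """Time of the earliest isolated synchronization spike, or None.

    A spike is a point where the energy envelope exceeds ``threshold_ratio``
    times its median (and an absolute 0.2 g floor, so a resting trace never
    triggers).  Returns the local peak time of the earliest excursion.
    """
    tg, env = energy_envelope(trace, window_s=0.3)
    med = float(np.median(env))
    thr = max(threshold_ratio * med, 0.2)
    above = np.flatnonzero(env > thr)
    if above.size == 0:
        return None
    first = above[0]
    # refine to the local maximum within 1 s of the first crossing
    w = int(ENVELOPE_RATE_HZ)
    lo, hi = first, min(first + w, env.size)
    return float(tg[lo + int(np.argmax(env[lo:hi]))])


def apply_offset(trace: AccelTrace, offset_s: float) -> AccelTrace:
    """Rebase a device-clock trace onto the video clock by removing the
    device-minus-video offset."""
    return AccelTrace(device_id=trace.device_id, t=trace.t - offset_s, a=trace.a)
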