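"""Seeded generator of collar-accelerometer recordings with ground-truth labels.

The generator emulates the salient structure of video-labeled collar
accelerometry so the full pipeline (alignment, fold construction, training,
evaluation, event detection) can be exercised end to end at desk scale:

* a NONE-dominant semi-Markov behavior schedule with per-class mean bout
  durations taken from the labeled-dataset summaries (exponential bouts,
  hence right-skewed length distributions; SHAKE uses a narrow gamma and
  is much less skewed, matching its short, uninterrupted character);
* acceleration synthesized in a body frame as a pitched gravity vector
  (head-down behaviors like eating/drinking/sniffing tilt the neck) plus a
  band-limited per-behavior motif oscillation, posture movement energy and
  white sensor noise;
* a fixed per-recording collar rotation about the dog's neck axis — the
  device rides the collar band, so rotation mixes the two off-neck axes
  while the neck-axis component and the magnitude are preserved;
* a per-recording device-minus-video clock offset of several seconds;
* per-dog jitter of motif parameters so cross-dog generalization is
  strictly harder than within-dog memorization.

All randomness descends from ``SimConfig.seed``; identical configs give
bit-identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.ndimage import gaussian_filter1d

from collarml.errors import ConfigError
from collarml.ethogram import (
    VALID,
    AccelTrace,
    BehaviorClass,
    LabelSegment,
    LabelTrack,
    PostureClass,
)

__all__ = [
    "MotifParams",
    "PostureParams",
    "SimConfig",
    "Recording",
    "DEFAULT_MOTIFS",
    "DEFAULT_POSTURES",
    "DEFAULT_MEAN_DURATIONS_S",
    "CANONICAL_POSITIONS",
    "generate_recording",
    "generate_cohort",
    "position_from_angle",
]


@dataclass(frozen=True)
class MotifParams:
    """Oscillatory signature of one behavior.

    freq_hz must stay below the Nyquist frequency of the slowest supported
    sampling rate (12.5 Hz), i.e. below 6.25 Hz.  pitch_offset_rad models
    the neck angle relative to the posture baseline (negative = head down).
    """

    freq_hz: float
    amplitude_g: float
    pitch_offset_rad: float = 0.0
    burstiness: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq_hz < 6.25:
            raise ConfigError(f"motif frequency {self.freq_hz} Hz >= 6.25 Hz Nyquist floor")
        if self.amplitude_g < 0:
            raise ConfigError("motif amplitude must be >= 0")


@dataclass(frozen=True)
class PostureParams:
    """Baseline neck pitch and movement energy of one posture."""

    base_pitch_rad: float
    energy_g: float
    energy_freq_hz: float = 2.0


DEFAULT_MOTIFS: dict[BehaviorClass, MotifParams] = {
    # head-down, fast lapping
    BehaviorClass.DRINK: MotifParams(4.6, 0.28, -1.00, 0.3),
    # head-down, slower chewing
    BehaviorClass.EAT: MotifParams(2.6, 0.20, -0.85, 0.2),
    BehaviorClass.LICKOBJECT: MotifParams(3.4, 0.12, -0.45, 0.2),
    BehaviorClass.LICKSELF: MotifParams(2.2, 0.15, -0.25, 0.3),
    BehaviorClass.PETTING: MotifParams(1.4, 0.22, 0.10, 0.4),
    BehaviorClass.RUBBING: MotifParams(1.9, 0.38, 0.00, 0.4),
    BehaviorClass.SCRATCH: MotifParams(5.6, 0.70, 0.15, 0.2),
    # whole-body shake: very short, very high energy
    BehaviorClass.SHAKE: MotifParams(6.1, 2.00, 0.00, 0.1),
    BehaviorClass.SNIFF: MotifParams(1.7, 0.10, -0.70, 0.3),
}

DEFAULT_POSTURES: dict[PostureClass, PostureParams] = {
    PostureClass.LIE_DOWN: PostureParams(-0.25, 0.010, 0.8),
    PostureClass.SIT: PostureParams(0.15, 0.020, 1.0),
    PostureClass.STAND: PostureParams(0.00, 0.030, 1.2),
    PostureClass.WALK: PostureParams(0.00, 0.280, 2.0),
    PostureClass.VIGOROUS: PostureParams(0.00, 0.600, 3.0),
    PostureClass.MIXED: PostureParams(0.05, 0.100, 1.5),
}

#: Default per-behavior mean bout durations in seconds (labeled-dataset means).
DEFAULT_MEAN_DURATIONS_S: dict[BehaviorClass, float] = {
    BehaviorClass.DRINK: 12.6,
    BehaviorClass.EAT: 43.4,
    BehaviorClass.LICKOBJECT: 5.6,
    BehaviorClass.LICKSELF: 12.4,
    BehaviorClass.PETTING: 6.7,
    BehaviorClass.RUBBING: 7.0,
    BehaviorClass.SCRATCH: 6.8,
    BehaviorClass.SHAKE: 1.7,
    BehaviorClass.SNIFF: 3.9,
}

# Relative draw probabilities of active (non-NONE) behavior bouts.  Together
# with the 25 s mean NONE dwell these keep NONE above ~55% of labeled time
# and SHAKE rare, mirroring the strong class imbalance of real recordings.
_BEHAVIOR_PROBS: dict[BehaviorClass, float] = {
    BehaviorClass.SNIFF: 0.24,
    BehaviorClass.EAT: 0.18,
    BehaviorClass.DRINK: 0.12,
    BehaviorClass.LICKOBJECT: 0.09,
    BehaviorClass.SCRATCH: 0.09,
    BehaviorClass.SHAKE: 0.08,
    BehaviorClass.LICKSELF: 0.07,
    BehaviorClass.PETTING: 0.07,
    BehaviorClass.RUBBING: 0.06,
}

# Posture adopted during each behavior bout.
_BEHAVIOR_POSTURE: dict[BehaviorClass, PostureClass] = {
    BehaviorClass.DRINK: PostureClass.STAND,
    BehaviorClass.EAT: PostureClass.STAND,
    BehaviorClass.LICKOBJECT: PostureClass.STAND,
    BehaviorClass.LICKSELF: PostureClass.LIE_DOWN,
    BehaviorClass.PETTING: PostureClass.SIT,
    BehaviorClass.RUBBING: PostureClass.STAND,
    BehaviorClass.SCRATCH: PostureClass.SIT,
    BehaviorClass.SHAKE: PostureClass.STAND,
    BehaviorClass.SNIFF: PostureClass.STAND,
}

# Posture distribution during background (NONE) bouts.
_NONE_POSTURE_PROBS: dict[PostureClass, float] = {
    PostureClass.LIE_DOWN: 0.20,
    PostureClass.SIT: 0.15,
    PostureClass.STAND: 0.28,
    PostureClass.WALK: 0.22,
    PostureClass.VIGOROUS: 0.05,
    PostureClass.MIXED: 0.10,
}

# Canonical device positions around the collar, degrees about the neck axis.
CANONICAL_POSITIONS: dict[str, float] = {
    "ventral": 0.0,
    "right": 90.0,
    "dorsal": 180.0,
    "left": 270.0,
}


def position_from_angle(angle_deg: float) -> str:
    """Nearest canonical collar position for a rotation angle."""
    a = float(angle_deg) % 360.0
    names = list(CANONICAL_POSITIONS)
    dists = [min(abs(a - v), 360.0 - abs(a - v)) for v in CANONICAL_POSITIONS.values()]
    return names[int(np.argmin(dists))]


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort."""

    n_dogs: int = 10
    videos_per_dog: int = 3
    sampling_rate_hz: float = 32.0
    video_duration_s: float = 600.0
    #: fixed rotation about the neck axis; None draws uniform [0, 360) per recording
    collar_rotation_deg: float | None = None
    #: injected device-minus-video clock offset; None draws uniform [-5, 5] s
    clock_offset_s: float | None = None
    mean_durations_s: dict[BehaviorClass, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_DURATIONS_S)
    )
    none_dwell_mean_s: float = 25.0
    noise_sigma_g: float = 0.05
    #: scale of per-dog motif jitter; 0 disables inter-individual variability
    dog_jitter: float = 1.0
    invalid_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 25.0 <= self.sampling_rate_hz <= 50.0:
            raise ConfigError(
                f"sampling_rate_hz must be in [25, 50], got {self.sampling_rate_hz}"
            )
        if self.n_dogs < 1 or self.videos_per_dog < 1:
            raise ConfigError("n_dogs and videos_per_dog must be >= 1")
        if any(d <= 0 for d in self.mean_durations_s.values()):
            raise ConfigError("mean durations must be > 0")


@dataclass
class Recording:
    """One simulated device recording with its ground-truth label track."""

    trace: AccelTrace
    track: LabelTrack
    dog_id: str
    video_id: str
    true_offset_s: float
    collar_rotation_deg: float

    @property
    def position(self) -> str:
        return position_from_angle(self.collar_rotation_deg)


@dataclass(frozen=True)
class _DogProfile:
    """Per-dog multiplicative/additive jitter of motif parameters."""

    freq_scale: float = 1.0
    amp_scale: float = 1.0
    pitch_shift: float = 0.0


def _dog_profile(cfg: SimConfig, rng: np.random.Generator) -> _DogProfile:
    if cfg.dog_jitter <= 0:
        return _DogProfile()
    j = cfg.dog_jitter
    return _DogProfile(
        freq_scale=float(np.exp(rng.normal(0.0, 0.08 * j))),
        amp_scale=float(np.exp(rng.normal(0.0, 0.18 * j))),
        pitch_shift=float(rng.normal(0.0, 0.12 * j)),
    )


def _stable_hash(s: str) -> int:
    return zlib.crc32(s.encode("utf-8"))


def _recording_rng(cfg: SimConfig, dog_id: str, video_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence([cfg.seed, _stable_hash(dog_id), video_index])
    return np.random.default_rng(ss)


@dataclass
class _Bout:
    behavior: BehaviorClass | None  # None = background
    posture: PostureClass
    start_s: float
    stop_s: float


def _draw_schedule(cfg: SimConfig, rng: np.random.Generator) -> list[_Bout]:
    """Alternating background/active semi-Markov schedule over one video."""
    behaviors = list(_BEHAVIOR_PROBS)
    probs = np.array([_BEHAVIOR_PROBS[b] for b in behaviors])
    probs = probs / probs.sum()
    none_postures = list(_NONE_POSTURE_PROBS)
    none_probs = np.array([_NONE_POSTURE_PROBS[p] for p in none_postures])
    none_probs = none_probs / none_probs.sum()

    bouts: list[_Bout] = []
    t = 0.0
    T = cfg.video_duration_s
    active = rng.random() < 0.3  # occasionally start mid-behavior
    while t < T:
        if active:
            beh = behaviors[rng.choice(len(behaviors), p=probs)]
            mean = cfg.mean_durations_s.get(beh, 5.0)
            if beh is BehaviorClass.SHAKE:
                # narrow gamma: short, low-skew bout lengths
                dur = rng.gamma(shape=9.0, scale=mean / 9.0)
            else:
                dur = rng.exponential(mean)
            dur = max(dur, 0.4)
            stop = min(t + dur, T)
            bouts.append(_Bout(beh, _BEHAVIOR_POSTURE[beh], t, stop))
        else:
            dur = max(rng.exponential(cfg.none_dwell_mean_s), 1.0)
            stop = min(t + dur, T)
            posture = none_postures[rng.choice(len(none_postures), p=none_probs)]
            bouts.append(_Bout(None, posture, t, stop))
        t = stop
        active = not active
    return bouts


def _invalid_windows(cfg: SimConfig, rng: np.random.Generator) -> list[tuple[float, float]]:
    if cfg.invalid_fraction <= 0:
        return []
    T = cfg.video_duration_s
    n_win = 2
    w = cfg.invalid_fraction * T / n_win
    wins = []
    for _ in range(n_win):
        start = rng.uniform(0.0, T - w)
        wins.append((start, start + w))
    # merge overlaps
    wins.sort()
    merged = [wins[0]]
    for s, e in wins[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _rotation_about_neck(angle_deg: float) -> np.ndarray:
    """Rotation matrix about the body x-axis (the neck axis)."""
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


# Fixed unit directions (body frame) of motif and posture oscillations.
_MOTIF_DIR = np.array([0.30, 0.65, 0.70])
_MOTIF_DIR = _MOTIF_DIR / np.linalg.norm(_MOTIF_DIR)
_POSTURE_DIR = np.array([0.45, 0.20, 0.87])
_POSTURE_DIR = _POSTURE_DIR / np.linalg.norm(_POSTURE_DIR)


def generate_recording(
    cfg: SimConfig,
    dog_id: str,
    video_index: int = 0,
    profile: _DogProfile | None = None,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Simulate one device recording and its ground-truth label track.

    The label track is on the video clock; the acceleration trace is on the
    device clock, shifted by the (returned) true device-minus-video offset.
    Fully reproducible from the config, dog id, and video index.
    """
    if rng is None:
        rng = _recording_rng(cfg, dog_id, video_index)
    if profile is None:
        prof_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, _stable_hash(dog_id), 10**6])
        )
        profile = _dog_profile(cfg, prof_rng)

    fs = cfg.sampling_rate_hz
    T = cfg.video_duration_s
    n = int(round(T * fs))
    t_video = np.arange(n) / fs

    bouts = _draw_schedule(cfg, rng)
    invalid = _invalid_windows(cfg, rng)

    # --- per-sample parameter tracks -------------------------------------
    pitch = np.zeros(n)
    amp = np.zeros(n)
    freq = np.zeros(n)
    burst = np.zeros(n)
    post_energy = np.zeros(n)
    post_freq = np.full(n, 1.0)
    for b in bouts:
        i0, i1 = int(b.start_s * fs), min(int(np.ceil(b.stop_s * fs)), n)
        pp = DEFAULT_POSTURES[b.posture]
        pitch[i0:i1] = pp.base_pitch_rad + profile.pitch_shift
        post_energy[i0:i1] = pp.energy_g * profile.amp_scale
        post_freq[i0:i1] = pp.energy_freq_hz
        if b.behavior is not None:
            mp = DEFAULT_MOTIFS[b.behavior]
            pitch[i0:i1] += mp.pitch_offset_rad
            amp[i0:i1] = mp.amplitude_g * profile.amp_scale
            freq[i0:i1] = min(mp.freq_hz * profile.freq_scale, 6.2)
            burst[i0:i1] = mp.burstiness
    # neck pitch changes are smooth on ~150 ms scale
    pitch = gaussian_filter1d(pitch, sigma=max(1.0, 0.15 * fs))

    # --- body-frame signal ------------------------------------------------
    gravity = np.column_stack([np.sin(pitch), np.zeros(n), np.cos(pitch)])

    motif_phase = 2 * np.pi * np.cumsum(freq) / fs + rng.uniform(0, 2 * np.pi)
    am = 1.0 + burst * np.sin(2 * np.pi * 0.5 * t_video + rng.uniform(0, 2 * np.pi))
    motif = (amp * am * np.sin(motif_phase))[:, None] * _MOTIF_DIR

    post_phase = 2 * np.pi * np.cumsum(post_freq) / fs + rng.uniform(0, 2 * np.pi)
    posture_osc = (post_energy * np.sin(post_phase))[:, None] * _POSTURE_DIR

    noise = rng.normal(0.0, cfg.noise_sigma_g, size=(n, 3))
    body = gravity + motif + posture_osc + noise

    # --- device frame: fixed collar rotation about the neck axis ----------
    if cfg.collar_rotation_deg is None:
        angle = float(rng.uniform(0.0, 360.0))
    else:
        angle = float(cfg.collar_rotation_deg) % 360.0
    R = _rotation_about_neck(angle)
    device = body @ R.T

    if cfg.clock_offset_s is None:
        offset = float(rng.uniform(-5.0, 5.0))
    else:
        offset = float(cfg.clock_offset_s)

    video_id = f"{dog_id}-v{video_index:03d}"
    trace = AccelTrace(device_id=f"dev-{video_id}", t=t_video + offset, a=device)

    # --- label track (video clock) ----------------------------------------
    segments: list[LabelSegment] = []
    edges = sorted({0.0, T, *(x for w in invalid for x in w)})
    inv = np.array(invalid).reshape(-1, 2) if invalid else np.empty((0, 2))
    for s, e in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (s + e)
        if not any(lo <= mid < hi for lo, hi in inv):
            segments.append(LabelSegment("valid", VALID, s, e))
    for b in bouts:
        segments.append(LabelSegment("posture", b.posture.value, b.start_s, b.stop_s))
        if b.behavior is not None:
            segments.append(LabelSegment("behavior", b.behavior.value, b.start_s, b.stop_s))

    track = LabelTrack(video_id=video_id, dog_id=dog_id, segments=segments, duration_s=T)
    return Recording(
        trace=trace,
        track=track,
        dog_id=dog_id,
        video_id=video_id,
        true_offset_s=offset,
        collar_rotation_deg=angle,
    )


def generate_cohort(cfg: SimConfig) -> list[Recording]:
    """Simulate a multi-dog cohort; per-dog motif jitter makes cross-dog
    generalization strictly harder than within-dog fitting."""
    recs: list[Recording] = []
    for d in range(cfg.n_dogs):
        dog_id = f"dog{d:03d}"
        prof_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, _stable_hash(dog_id), 10**6])
        )
        profile = _dog_profile(cfg, prof_rng)
        for v in range(cfg.videos_per_dog):
            recs.append(
                generate_recording(cfg, dog_id, video_index=v, profile=profile)
            )
    return recs


def cohort_manifest(recs: Iterable[Recording]) -> dict:
    """JSON-ready manifest: dog -> videos, plus true offsets (for alignment
    tests only — the pipeline never reads the truth)."""
    manifest: dict = {"dogs": {}, "true_offsets_s": {}, "positions": {}}
    for r in recs:
        manifest["dogs"].setdefault(r.dog_id, []).append(r.video_id)
        manifest["true_offsets_s"][r.video_id] = r.true_offset_s
        manifest["positions"][r.video_id] = r.position
    return manifest
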