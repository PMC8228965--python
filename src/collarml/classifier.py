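"""Multi-task sequence classifier at 320 ms output resolution.

The model maps a 3-axis accelerometer recording to per-gridpoint
probability distributions over behaviors and postures.  It is built from
multi-scale temporal features pooled around each gridpoint (0.32 s, 1.28 s
and 5.12 s windows) feeding two small multilayer-perceptron heads, one per
task.  All features are invariant to device rotation about the collar/neck
axis: they use only the neck-axis component, the off-neck magnitude, the
total magnitude and its band-limited energies — the basis of the system's
device-position invariance.

Class imbalance (background NONE dominates; SHAKE is two orders of
magnitude rarer than EAT) is countered by inverse-frequency oversampling
capped at 20x.  Training is subject-disjoint: :func:`train_fold` only sees
dogs outside the held-out fold, and :func:`cross_validated_predictions`
predicts every video with the one model that never saw its dog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import butter, sosfiltfilt
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from collarml.dataset import AlignedRecording, FoldAssignment
from collarml.errors import ConfigError
from collarml.ethogram import AccelTrace
from collarml.grid import (
    BEHAVIOR_CLASSES,
    GRID_STEP_S,
    MULTI,
    POSTURE_CLASSES,
    PredictionTrack,
    grid_labels,
)

__all__ = [
    "ModelConfig",
    "UniformSeries",
    "TrainedModel",
    "preprocess",
    "extract_features",
    "train_fold",
    "predict",
    "cross_validated_predictions",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the multi-scale classifier."""

    input_rate_hz: float = 32.0
    #: temporal pooling scales (s); the largest sets the receptive field
    scales_s: tuple[float, ...] = (0.32, 1.28, 5.12)
    hidden_layer_sizes: tuple[int, ...] = (64, 32)
    max_iter: int = 60
    learning_rate_init: float = 1e-3
    alpha: float = 1e-4
    #: cap on inverse-frequency oversampling of rare classes
    max_class_weight: float = 20.0
    seed: int = 0

    @property
    def receptive_field_s(self) -> float:
        return max(self.scales_s)

    def __post_init__(self) -> None:
        if self.receptive_field_s < 4.0:
            raise ConfigError("receptive field must be >= 4 s")
        if self.input_rate_hz <= 2 * 8.0:
            raise ConfigError("input rate too low for the 8 Hz feature band")


@dataclass
class UniformSeries:
    """Uniformly resampled 3-axis series with an observed-data mask."""

    t0: float
    rate_hz: float
    x: np.ndarray  # (n, 3)
    mask: np.ndarray  # (n,) True where observed

    def __len__(self) -> int:
        return len(self.mask)

    @property
    def duration_s(self) -> float:
        return len(self.mask) / self.rate_hz


def preprocess(trace: AccelTrace, input_rate_hz: float = 32.0) -> UniformSeries:
    """Linearly resample a trace to a uniform rate.

    Gaps longer than 2 s are zero-filled and flagged False in the mask.
    Output length is ``ceil(duration * input_rate_hz)`` (minimum 1).
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    duration = float(trace.t[-1] - trace.t[0])
    n = max(int(np.ceil(duration * input_rate_hz - 1e-9)), 1)
    tg = trace.t[0] + np.arange(n) / input_rate_hz
    x = np.column_stack([np.interp(tg, trace.t, trace.a[:, i]) for i in range(3)])
    mask = np.ones(n, dtype=bool)
    dts = np.diff(trace.t)
    for gi in np.flatnonzero(dts > 2.0):
        inside = (tg > trace.t[gi]) & (tg < trace.t[gi + 1])
        mask[inside] = False
        x[inside] = 0.0
    return UniformSeries(t0=float(trace.t[0]), rate_hz=input_rate_hz, x=x, mask=mask)


_BANDS = ((0.5, 1.5), (1.5, 3.0), (3.0, 6.5))


def _base_channels(u: UniformSeries) -> np.ndarray:
    """Rotation-invariant per-sample channels, shape (n, 8).

    A ~0.5 Hz per-axis low-pass estimates the gravity vector; its
    neck-axis component is the pitch cue and the norm of its two off-neck
    components is rotation-invariant.  The per-axis high-pass residual
    carries the motion: its vector norm (dynamic energy), per-band vector
    energies, and the zero-crossing rate of its neck-axis component
    (dominant-frequency proxy) are all invariant to rotation about the
    neck axis.  The signed neck-axis residual is kept for windowed-std
    pooling.
    """
    fs = u.rate_hz
    sigma_lp = fs / (2 * np.pi * 0.5)  # ~0.5 Hz gravity low-pass
    g_lp = gaussian_filter1d(u.x, sigma=sigma_lp, axis=0)
    pitch = g_lp[:, 0]
    perp_lp = np.hypot(g_lp[:, 1], g_lp[:, 2])
    hp = u.x - g_lp
    dyn = np.linalg.norm(hp, axis=1)
    # light smoothing before zero-crossing so sensor noise does not
    # dominate the crossing rate during quiet stretches
    hp_neck = gaussian_filter1d(hp[:, 0], sigma=max(fs / 32.0, 0.5))
    zc = np.zeros_like(hp_neck)
    zc[1:] = (hp_neck[1:] * hp_neck[:-1] < 0).astype(float) * fs / 2.0
    cols = [pitch, perp_lp, dyn, zc]
    for lo, hi in _BANDS:
        sos = butter(2, [lo, hi], btype="band", fs=fs, output="sos")
        cols.append((sosfiltfilt(sos, hp, axis=0) ** 2).sum(axis=1))
    cols.append(hp[:, 0])
    return np.column_stack(cols)


def extract_features(u: UniformSeries, cfg: ModelConfig) -> np.ndarray:
    """Multi-scale pooled features at every 320 ms gridpoint.

    Per scale: windowed mean of each base channel, windowed std of the
    pitch and high-pass channels, and the observed-data fraction.
    Returns an ``(n_grid, n_features)`` array.
    """
    ch = _base_channels(u)
    fs = u.rate_hz
    n = len(u)
    stride = GRID_STEP_S * fs
    n_grid = max(int(np.ceil(n / stride - 1e-9)), 1)
    centers = np.clip(np.round((np.arange(n_grid) + 0.5) * stride).astype(int), 0, n - 1)
    feats = []
    maskf = u.mask.astype(float)
    for scale in cfg.scales_s:
        w = max(int(round(scale * fs)), 1)
        mean = uniform_filter1d(ch, size=w, axis=0, mode="nearest")
        sq = uniform_filter1d(ch**2, size=w, axis=0, mode="nearest")
        std = np.sqrt(np.maximum(sq - mean**2, 0.0))
        mfrac = uniform_filter1d(maskf, size=w, mode="nearest")
        feats.append(mean[centers][:, :-1])  # signed hp enters via std only
        feats.append(std[centers][:, [0, -1]])  # pitch, signed high-pass
        feats.append(mfrac[centers][:, None])
    return np.concatenate(feats, axis=1)


@dataclass
class TrainedModel:
    """One cross-validation model: two per-task heads plus vocabularies."""

    cfg: ModelConfig
    behavior_head: Pipeline
    posture_head: Pipeline
    behavior_classes: tuple[str, ...] = tuple(BEHAVIOR_CLASSES)
    posture_classes: tuple[str, ...] = tuple(POSTURE_CLASSES)
    held_out_fold: int | None = None
    train_dogs: frozenset[str] = field(default_factory=frozenset)


def _make_head(cfg: ModelConfig, seed: int) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=cfg.hidden_layer_sizes,
                    max_iter=cfg.max_iter,
                    learning_rate_init=cfg.learning_rate_init,
                    alpha=cfg.alpha,
                    random_state=seed,
                ),
            ),
        ]
    )


def _oversample(y: np.ndarray, cap: float, rng: np.random.Generator) -> np.ndarray:
    """Indices with rare classes repeated ~inverse-frequency, capped."""
    classes, counts = np.unique(y, return_counts=True)
    target = len(y) / len(classes)
    reps = {
        c: int(np.clip(round(target / n), 1, cap)) for c, n in zip(classes, counts)
    }
    idx = np.concatenate([np.repeat(i, reps[y[i]]) for i in range(len(y))])
    rng.shuffle(idx)
    return idx


def _fit_head(
    cfg: ModelConfig, X: np.ndarray, y: np.ndarray, seed: int
) -> Pipeline:
    head = _make_head(cfg, seed)
    rng = np.random.default_rng(seed)
    idx = _oversample(y, cfg.max_class_weight, rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        head.fit(X[idx], y[idx])
    return head


def _training_matrix(
    entries: list[AlignedRecording], cfg: ModelConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack features and per-gridpoint targets over entries.

    Behavior targets are '' where untrainable (invalid region or multiple
    simultaneous behaviors — mirroring their exclusion from evaluation);
    posture targets are '' where invalid.
    """
    Xs, yb, yp = [], [], []
    for e in entries:
        u = preprocess(e.trace, cfg.input_rate_hz)
        X = extract_features(u, cfg)
        valid, beh, post, _ = grid_labels(e.track, n=len(X))
        beh = beh.copy()
        beh[beh == MULTI] = ""
        Xs.append(X)
        yb.append(beh)
        yp.append(post)
    return np.vstack(Xs), np.concatenate(yb), np.concatenate(yp)


def train_fold(
    entries: list[AlignedRecording],
    folds: FoldAssignment,
    held_out: int,
    cfg: ModelConfig,
) -> TrainedModel:
    """Train one model on all dogs outside ``held_out``."""
    if not 0 <= held_out < folds.n_folds:
        raise ConfigError(f"held_out must be in 0..{folds.n_folds - 1}")
    train = [e for e in entries if folds.fold_of(e.dog_id) != held_out]
    if not train:
        raise ConfigError("empty training partition")
    X, yb, yp = _training_matrix(train, cfg)
    mb, mp = yb != "", yp != ""
    seed = cfg.seed * 100 + held_out
    beh_head = _fit_head(cfg, X[mb], yb[mb], seed)
    post_head = _fit_head(cfg, X[mp], yp[mp], seed + 50)
    return TrainedModel(
        cfg=cfg,
        behavior_head=beh_head,
        posture_head=post_head,
        held_out_fold=held_out,
        train_dogs=frozenset(e.dog_id for e in train),
    )


def _expand_probs(
    probs: np.ndarray, head_classes: np.ndarray, all_classes: tuple[str, ...]
) -> np.ndarray:
    out = np.zeros((len(probs), len(all_classes)))
    for j, c in enumerate(head_classes):
        out[:, all_classes.index(c)] = probs[:, j]
    return out


def predict(
    model: TrainedModel, trace: AccelTrace, video_id: str = ""
) -> PredictionTrack:
    """Per-gridpoint behavior and posture distributions for one trace.

    Deterministic given the model and input.  Traces shorter than the
    receptive field are evaluated with edge padding (the pooling windows
    clamp at the trace boundaries).
    """
    cfg = model.cfg
    u = preprocess(trace, cfg.input_rate_hz)
    X = extract_features(u, cfg)
    bp = _expand_probs(
        model.behavior_head.predict_proba(X),
        model.behavior_head.classes_,
        model.behavior_classes,
    )
    pp = _expand_probs(
        model.posture_head.predict_proba(X),
        model.posture_head.classes_,
        model.posture_classes,
    )
    t_grid = u.t0 + (np.arange(len(X)) + 0.5) * GRID_STEP_S
    return PredictionTrack(
        video_id=video_id or trace.device_id,
        t_grid=t_grid,
        behavior_probs=bp,
        posture_probs=pp,
    )


def save_model(model: TrainedModel, path: str) -> None:
    """Persist a trained model; the checkpoint carries its ModelConfig and
    class vocabularies."""
    import joblib

    joblib.dump(model, path)


def load_model(path: str) -> TrainedModel:
    import joblib

    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise ValueError(f"{path} is not a collarml model checkpoint")
    return model


def cross_validated_predictions(
    entries: list[AlignedRecording],
    folds: FoldAssignment,
    cfg: ModelConfig,
) -> tuple[dict[str, PredictionTrack], list[TrainedModel]]:
    """Train one model per fold and predict every video exactly once,
    always with the model that did not train on its dog."""
    models = [train_fold(entries, folds, f, cfg) for f in range(folds.n_folds)]
    preds: dict[str, PredictionTrack] = {}
    for e in entries:
        m = models[folds.fold_of(e.dog_id)]
        preds[e.video_id] = predict(m, e.trace, video_id=e.video_id)
    return preds, models
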