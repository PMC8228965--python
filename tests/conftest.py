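import numpy as np
import pytest

from collarml import alignment as al
from collarml import classifier as clf
from collarml import dataset as ds
from collarml import synth
from collarml.ethogram import VALID, LabelSegment, LabelTrack


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small multi-dog cohort used across module tests."""
    cfg = synth.SimConfig(n_dogs=6, videos_per_dog=2, video_duration_s=180.0, seed=11)
    return cfg, synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def aligned_entries(tiny_cohort):
    _, recs = tiny_cohort
    entries = []
    for r in recs:
        try:
            res = al.auto_align(r.trace, r.track)
        except al.NotAlignableError:
            continue
        if res.accepted:
            entries.append(
                ds.AlignedRecording(
                    trace=al.apply_offset(r.trace, res.offset_s),
                    track=r.track,
                    dog_id=r.dog_id,
                    video_id=r.video_id,
                    position=r.position,
                )
            )
    assert len(entries) >= 8
    assert len({e.dog_id for e in entries}) >= 5  # enough dogs for 5 folds
    return entries


@pytest.fixture(scope="session")
def trained(aligned_entries):
    """Cross-validated models and pooled predictions on the tiny cohort."""
    folds = ds.assign_folds(aligned_entries, seed=0)
    cfg = clf.ModelConfig(seed=0, max_iter=15)
    preds, models = clf.cross_validated_predictions(aligned_entries, folds, cfg)
    return folds, cfg, preds, models


def make_track(segments, video_id="v0", dog_id="d0", duration=None):
    return LabelTrack(
        video_id=video_id,
        dog_id=dog_id,
        segments=[LabelSegment(*s) for s in segments],
        duration_s=duration,
    )


@pytest.fixture()
def simple_track():
    """60 s all-valid video: STAND throughout, one EAT meal, one overlapping
    SCRATCH+SHAKE episode."""
    return make_track(
        [
            ("valid", VALID, 0.0, 60.0),
            ("posture", "STAND", 0.0, 60.0),
            ("behavior", "EAT", 5.0, 25.0),
            ("behavior", "SCRATCH", 40.0, 44.0),
            ("behavior", "SHAKE", 41.0, 43.0),
        ]
    )


@pytest.fixture()
def rest_trace():
    """Pure gravity plus faint noise, 60 s at 32 Hz."""
    rng = np.random.default_rng(0)
    t = np.arange(60 * 32) / 32.0
    a = np.tile([0.0, 0.0, 1.0], (t.size, 1)) + rng.normal(0, 0.01, (t.size, 3))
    from collarml.ethogram import AccelTrace

    return AccelTrace(device_id="rest", t=t, a=a)
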