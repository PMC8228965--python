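import numpy as np
import pandas as pd
import pytest

from collarml.ethogram import VALID, labels_at
from collarml.evaluation import (
    ConfusionTally,
    ExclusionPolicy,
    class_metrics,
    eligible_timepoints,
    f1_score,
    per_video_f1,
    position_breakdown,
    resolve_posture_prediction,
    tally,
)
from collarml.grid import BEHAVIOR_CLASSES, PredictionTrack, grid_centers, n_gridpoints
from conftest import make_track

POLICY = ExclusionPolicy()


class TestEligibleTimepoints:
    def test_transition_margin_around_meal(self):
        track = make_track(
            [
                ("valid", VALID, 0.0, 80.0),
                ("posture", "STAND", 0.0, 80.0),
                ("behavior", "EAT", 10.0, 70.0),
            ]
        )
        c, elig, _ = eligible_timepoints(track, POLICY, "behavior")
        for x, ok in zip(c, elig):
            if (9 < x < 11) or (69 < x < 71) or x < 1 or x > 79:
                assert not ok, x
            else:
                assert ok, x

    def test_shake_keeps_interior_of_short_bout(self):
        track = make_track(
            [
                ("valid", VALID, 0.0, 60.0),
                ("posture", "STAND", 0.0, 60.0),
                ("behavior", "SHAKE", 20.0, 21.7),
            ]
        )
        c, elig, lab = eligible_timepoints(track, POLICY, "behavior")
        kept = c[(lab == "SHAKE") & elig]
        # only the outer third second is excluded on the SHAKE side, so the
        # ~1 s interior (3 gridpoints) survives; a 1 s margin would kill it
        assert len(kept) == 3
        assert kept.min() > 20.0 + 1.0 / 3.0
        assert kept.max() < 21.7 - 1.0 / 3.0

    def test_multilabel_points_excluded(self):
        track = make_track(
            [
                ("valid", VALID, 0.0, 60.0),
                ("posture", "STAND", 0.0, 60.0),
                ("behavior", "SCRATCH", 10.0, 30.0),
                ("behavior", "SHAKE", 18.0, 22.0),
            ]
        )
        c, elig, _ = eligible_timepoints(track, POLICY, "behavior")
        overlap = (c > 19.5) & (c < 20.5)
        assert not elig[overlap].any()

    def test_mixed_posture_dropped(self):
        track = make_track(
            [
                ("valid", VALID, 0.0, 60.0),
                ("posture", "MIXED", 0.0, 30.0),
                ("posture", "STAND", 30.0, 60.0),
            ]
        )
        _, elig, lab = eligible_timepoints(track, POLICY, "posture")
        assert not elig[lab == "MIXED"].any()
        assert elig[lab == "STAND"].any()

    def test_invalid_regions_excluded(self):
        track = make_track(
            [
                ("valid", VALID, 0.0, 20.0),
                ("valid", VALID, 40.0, 60.0),
                ("posture", "SIT", 0.0, 60.0),
            ],
            duration=60.0,
        )
        c, elig, _ = eligible_timepoints(track, POLICY, "posture")
        assert not elig[(c > 20) & (c < 40)].any()

    def test_margin_monotonicity(self):
        from collarml import synth

        cfg = synth.SimConfig(n_dogs=1, videos_per_dog=1, video_duration_s=300, seed=17)
        track = synth.generate_recording(cfg, "d", 0).track
        counts = []
        for margin in (0.5, 1.0, 2.0, 4.0):
            pol = ExclusionPolicy(transition_margin_s=margin, shake_margin_s=margin / 3)
            _, elig, _ = eligible_timepoints(track, pol, "behavior")
            counts.append(int(elig.sum()))
        assert counts == sorted(counts, reverse=True)


class TestResolvePosture:
    def test_mixed_argmax_replaced_by_runner_up(self):
        probs = np.array([0.0, 0.2, 0.3, 0.0, 0.0, 0.5])  # MIXED last
        classes = ("LIE_DOWN", "SIT", "STAND", "WALK", "VIGOROUS", "MIXED")
        assert resolve_posture_prediction(probs, classes) == "STAND"

    def test_clear_argmax_stands(self):
        probs = np.array([0.0, 0.05, 0.9, 0.0, 0.05, 0.0])
        classes = ("LIE_DOWN", "SIT", "STAND", "WALK", "VIGOROUS", "MIXED")
        assert resolve_posture_prediction(probs, classes) == "STAND"

    def test_exact_tie_breaks_lexicographically(self):
        probs = np.array([0.0, 0.0, 0.5, 0.5, 0.0, 0.0])
        classes = ("LIE_DOWN", "SIT", "STAND", "WALK", "VIGOROUS", "MIXED")
        assert resolve_posture_prediction(probs, classes) == "STAND"


def _random_prediction(n, seed, classes=tuple(BEHAVIOR_CLASSES)):
    rng = np.random.default_rng(seed)
    bp = rng.dirichlet(np.ones(len(classes)), size=n)
    pp = rng.dirichlet(np.ones(6), size=n)
    return bp, pp


def _brute_force_tally(track, pred, policy):
    """Independent per-gridpoint loop: first-principles eligibility and
    label/prediction pairing for the behavior task."""
    n = n_gridpoints(track.extent_s)
    counts: dict[tuple, int] = {}
    for k in range(min(n, len(pred))):
        t = (k + 0.5) * 0.32
        valid, _, behaviors = labels_at(track, t)
        if not valid or len(behaviors) != 1:
            continue
        label = next(iter(behaviors)).value
        # scan 1 ms grid for the nearest class change, with per-side margins
        excluded = False
        for s in [seg for seg in track.segments if seg.channel in ("behavior", "valid")]:
            for edge in (s.start_s, s.stop_s):
                segs_at = lambda x: frozenset(
                    seg.class_name
                    for seg in track.segments
                    if seg.channel == "behavior" and seg.start_s <= x < seg.stop_s
                )
                b_raw, a_raw = segs_at(edge - 1e-4), segs_at(edge + 1e-4)
                v_b = any(
                    seg.start_s <= edge - 1e-4 < seg.stop_s
                    for seg in track.segments
                    if seg.channel == "valid"
                )
                v_a = any(
                    seg.start_s <= edge + 1e-4 < seg.stop_s
                    for seg in track.segments
                    if seg.channel == "valid"
                )
                changed = (b_raw != a_raw) or (v_b != v_a)
                if not changed:
                    continue
                m_b = policy.shake_margin_s if b_raw == frozenset({"SHAKE"}) else policy.transition_margin_s
                m_a = policy.shake_margin_s if a_raw == frozenset({"SHAKE"}) else policy.transition_margin_s
                if edge - m_b < t < edge + m_a:
                    excluded = True
        if excluded:
            continue
        probs = pred.behavior_probs[k]
        top = np.flatnonzero(probs == probs.max())
        predicted = min(pred.behavior_classes[i] for i in top)
        counts[(label, predicted)] = counts.get((label, predicted), 0) + 1
    return counts


class TestTally:
    def _track_and_pred(self, seed=0):
        track = make_track(
            [
                ("valid", VALID, 0.0, 60.0),
                ("posture", "STAND", 0.0, 60.0),
                ("behavior", "EAT", 5.0, 25.0),
                ("behavior", "DRINK", 30.0, 40.0),
                ("behavior", "SHAKE", 45.0, 46.7),
            ]
        )
        n = n_gridpoints(60.0)
        bp, pp = _random_prediction(n, seed)
        pred = PredictionTrack("v0", grid_centers(60.0), bp, pp)
        return track, pred

    def test_matches_brute_force_oracle(self):
        for seed in range(5):
            track, pred = self._track_and_pred(seed)
            t = tally([track], {"v0": pred}, POLICY, "behavior")
            want = _brute_force_tally(track, pred, POLICY)
            got = {
                (t.classes[i], t.classes[j]): int(t.counts[i, j])
                for i in range(len(t.classes))
                for j in range(len(t.classes))
                if t.counts[i, j]
            }
            assert got == want

    def test_perfect_predictions_are_diagonal(self):
        track, pred = self._track_and_pred()
        _, elig, lab = eligible_timepoints(track, POLICY, "behavior")
        bp = np.zeros_like(pred.behavior_probs)
        for k in range(len(pred)):
            cls = lab[k] if lab[k] in pred.behavior_classes else "NONE"
            bp[k, pred.behavior_classes.index(cls)] = 1.0
        perfect = PredictionTrack("v0", pred.t_grid, bp, pred.posture_probs)
        t = tally([track], {"v0": perfect}, POLICY, "behavior")
        assert (t.counts == np.diag(np.diag(t.counts))).all()

    def test_row_sums_equal_eligible_counts(self):
        track, pred = self._track_and_pred()
        t = tally([track], {"v0": pred}, POLICY, "behavior")
        _, elig, lab = eligible_timepoints(track, POLICY, "behavior")
        for i, cls in enumerate(t.classes):
            assert t.counts[i].sum() == int(((lab == cls) & elig).sum())

    def test_pooled_equals_sum_of_parts(self):
        t1, p1 = self._track_and_pred(1)
        t2, p2 = self._track_and_pred(2)
        t2.video_id = "v1"
        preds = {"v0": p1, "v1": PredictionTrack("v1", p2.t_grid, p2.behavior_probs, p2.posture_probs)}
        pooled = tally([t1, t2], preds, POLICY, "behavior")
        parts = tally([t1], preds, POLICY, "behavior") + tally([t2], preds, POLICY, "behavior")
        assert (pooled.counts == parts.counts).all()


class TestClassMetrics:
    def test_f1_identity_examples(self):
        assert f1_score(0.870, 0.874) == pytest.approx(0.872, abs=5e-4)
        assert f1_score(0.676, 0.870) == pytest.approx(0.761, abs=5e-4)

    def test_against_sklearn_oracle(self):
        from sklearn.metrics import precision_score, recall_score

        rng = np.random.default_rng(0)
        classes = ("A", "B", "C", "D")
        for _ in range(50):
            counts = rng.integers(0, 40, size=(4, 4))
            t = ConfusionTally("behavior", classes, counts)
            m = class_metrics(t)
            y_true, y_pred = [], []
            for i in range(4):
                for j in range(4):
                    y_true += [classes[i]] * counts[i, j]
                    y_pred += [classes[j]] * counts[i, j]
            for c in classes:
                tp, fp, fn, tn = t.one_vs_rest(c)
                if tp + fp:
                    assert abs(
                        m.loc[c, "precision"]
                        - precision_score(y_true, y_pred, labels=[c], average="macro", zero_division=0)
                    ) < 1e-12
                if tp + fn:
                    assert abs(
                        m.loc[c, "sensitivity"]
                        - recall_score(y_true, y_pred, labels=[c], average="macro", zero_division=0)
                    ) < 1e-12
                if tn + fp:
                    assert abs(m.loc[c, "specificity"] - tn / (tn + fp)) < 1e-12
                assert abs(m.loc[c, "accuracy"] - (tp + tn) / t.total) < 1e-12

    def test_undefined_ratios_are_nan_not_zero(self):
        t = ConfusionTally(
            "behavior", ("A", "B"), np.array([[10, 0], [0, 0]])
        )
        m = class_metrics(t)
        assert m.loc["A", "sensitivity"] == 1.0
        assert np.isnan(m.loc["A", "specificity"])
        assert np.isnan(m.loc["B", "sensitivity"])

    def test_metric_identities_bit_exact(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 1000, size=(3, 3))
        t = ConfusionTally("behavior", ("A", "B", "C"), counts)
        m = class_metrics(t)
        for c in t.classes:
            tp, fp, fn, tn = t.one_vs_rest(c)
            assert m.loc[c, "sensitivity"] == tp / (tp + fn)
            assert m.loc[c, "specificity"] == tn / (tn + fp)
            assert m.loc[c, "accuracy"] == (tp + tn) / t.total


class TestPositionBreakdown:
    def test_identical_f1s_give_zero_width_ci(self):
        df = pd.DataFrame(
            {"video_id": [f"v{i}" for i in range(12)],
             "position": ["ventral", "dorsal", "left", "right"] * 3,
             "f1": [0.8] * 12}
        )
        out = position_breakdown(df, n_boot=500, seed=0)
        assert (out["ci_high"] - out["ci_low"] == 0).all()
        assert out["mean_f1"].to_numpy() == pytest.approx(0.8)

    def test_ci_contains_grand_mean_for_homogeneous_data(self):
        rng = np.random.default_rng(2)
        n = 48
        df = pd.DataFrame(
            {"video_id": [f"v{i}" for i in range(n)],
             "position": (["ventral", "dorsal", "left", "right"] * (n // 4)),
             "f1": rng.normal(0.8, 0.03, n)}
        )
        out = position_breakdown(df, n_boot=2000, seed=0)
        grand = df["f1"].mean()
        assert ((out["ci_low"] <= grand) & (grand <= out["ci_high"])).all()

    def test_single_video_position_flagged(self):
        df = pd.DataFrame(
            {"video_id": ["a", "b", "c"],
             "position": ["ventral", "ventral", "dorsal"],
             "f1": [0.7, 0.9, 0.8]}
        )
        out = position_breakdown(df, n_boot=100, seed=0).set_index("position")
        assert out.loc["dorsal", "ci_omitted"]
        assert not out.loc["ventral", "ci_omitted"]


def test_per_video_f1_undefined_when_class_absent(simple_track):
    n = n_gridpoints(simple_track.extent_s)
    bp, pp = _random_prediction(n, 3)
    pred = PredictionTrack(simple_track.video_id, grid_centers(n=n), bp, pp)
    df = per_video_f1([simple_track], {simple_track.video_id: pred}, POLICY, "behavior", "DRINK")
    # no DRINK labels and (almost surely) some DRINK predictions -> precision 0
    assert len(df) == 1
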