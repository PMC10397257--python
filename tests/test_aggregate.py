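"""Ensemble combination and the two patient-level aggregation statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import endodx as e


def _stream(scores, pid="A", rid="0", fps=10.0):
    return e.ScoreStream(pid, fps, np.asarray(scores, float), repeat_id=rid)


# --- independent oracles -----------------------------------------------------

def brute_max_run(scores, tau):
    best = 0
    for positive, grp in itertools.groupby(s >= tau for s in scores):
        if positive:
            best = max(best, len(list(grp)))
    return best


def brute_max_window_mean(scores, w):
    scores = np.asarray(scores, float)
    w = max(1, min(w, scores.size))
    return max(scores[i:i + w].mean() for i in range(scores.size - w + 1))


class TestEnsemble:
    def test_idempotent_on_identical_streams(self):
        streams = [_stream([0.2, 0.7, 0.4], rid=str(i)) for i in range(3)]
        out = e.ensemble_stream(streams, exclude_repeat="0")
        np.testing.assert_allclose(out.scores, [0.2, 0.7, 0.4])

    def test_two_point_mean(self):
        streams = [_stream([0.2, 0.8], rid="0"), _stream([0.6, 0.4], rid="1"),
                   _stream([0.0, 0.0], rid="2")]
        out = e.ensemble_stream(streams, exclude_repeat="2")
        np.testing.assert_allclose(out.scores, [0.4, 0.6])

    def test_leave_one_out_means_average_to_grand_mean(self, rng):
        """Averaging the R leave-one-out ensembles recovers the all-R mean."""
        streams = [_stream(rng.random(50), rid=str(i)) for i in range(25)]
        loo = np.stack([
            e.ensemble_stream(streams, exclude_repeat=str(i)).scores
            for i in range(25)])
        grand = e.ensemble_all(streams).scores
        np.testing.assert_allclose(loo.mean(axis=0), grand, atol=1e-12)

    def test_majority_vote_rule(self):
        streams = [_stream([0.9, 0.1], rid="0"), _stream([0.8, 0.2], rid="1"),
                   _stream([0.1, 0.9], rid="2"), _stream([0.5, 0.5], rid="3")]
        out = e.ensemble_stream(streams, exclude_repeat="3", rule="vote")
        np.testing.assert_allclose(out.scores, [1.0, 0.0])

    @pytest.mark.parametrize("streams,exc,err", [
        ([_stream([0.1], rid="0")], "0", "at least 2"),
        ([_stream([0.1], rid="0"), _stream([0.1, 0.2], rid="1")], "0", "length"),
        ([_stream([0.1], rid="0"), _stream([0.2], rid="1")], "9", "not among"),
        ([_stream([0.1], rid="0"), _stream([0.2], pid="B", rid="1")], "0", "mix"),
    ])
    def test_invalid_ensembles_rejected(self, streams, exc, err):
        with pytest.raises(ValueError, match=err):
            e.ensemble_stream(streams, exclude_repeat=exc)


class TestFrameDecision:
    def test_basic_and_boundary(self):
        assert e.frame_decision(0.7, 0.5) == "IP"
        assert e.frame_decision(0.5, 0.5) == "IP"   # boundary counts positive
        assert e.frame_decision(0.49, 0.5) == "CRSwNP"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            e.frame_decision(1.2, 0.5)


class TestMaxRunLength:
    def test_examples(self):
        assert e.max_run_length(_stream([0.1, 0.2, 0.3]), 0.5) == 0
        assert e.max_run_length(_stream([0.9, 0.9, 0.2, 0.9, 0.9, 0.9]), 0.5) == 3
        assert e.max_run_length(_stream([0.9] * 7), 0.5) == 7

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            e.max_run_length(np.array([]), 0.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=120),
           st.floats(0.05, 0.95))
    def test_agrees_with_brute_force(self, scores, tau):
        assert e.max_run_length(np.array(scores), tau) == brute_max_run(scores, tau)


class TestMaxWindowMean:
    def test_constant_stream(self):
        assert e.max_window_mean(_stream([0.3] * 20, fps=2.0), 5.0) == pytest.approx(0.3)

    def test_worked_window(self):
        # fps=1, 3-s window over [0,0,1,1,1,0]: the all-ones window wins
        assert e.max_window_mean(_stream([0, 0, 1, 1, 1, 0], fps=1.0), 3.0) == 1.0

    def test_window_clipped_to_stream(self):
        s = _stream([0.2, 0.4, 0.6], fps=1.0)
        assert e.max_window_mean(s, 100.0) == pytest.approx(0.4)

    def test_clinical_window_is_599_frames(self):
        assert e.window_frames(5.0, 119.88, 10_000) == 599

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            e.max_window_mean(np.array([]), 5.0, fps=1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=120),
           st.integers(1, 130))
    def test_agrees_with_brute_force(self, scores, w):
        got = e.max_window_mean(np.array(scores), float(w), fps=1.0)
        assert got == pytest.approx(brute_max_window_mean(scores, w), abs=1e-9)


class TestStatisticProperties:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=60),
           st.data())
    def test_raising_one_score_never_lowers_either_statistic(self, scores, data):
        i = data.draw(st.integers(0, len(scores) - 1))
        bumped = list(scores)
        bumped[i] = min(1.0, bumped[i] + data.draw(st.floats(0.0, 1.0)))
        a, b = np.array(scores), np.array(bumped)
        assert e.max_run_length(b, 0.5) >= e.max_run_length(a, 0.5)
        assert e.max_window_mean(b, 3.0, fps=1.0) >= \
            e.max_window_mean(a, 3.0, fps=1.0) - 1e-12

    def test_order_matters_beyond_unit_windows(self):
        """Both statistics see temporal structure once W, L > 1."""
        contiguous = np.array([0.9, 0.9, 0.9, 0.1, 0.1, 0.1])
        scattered = np.array([0.9, 0.1, 0.9, 0.1, 0.9, 0.1])
        assert e.max_run_length(contiguous, 0.5) != e.max_run_length(scattered, 0.5)
        assert e.max_window_mean(contiguous, 3.0, fps=1.0) != \
            e.max_window_mean(scattered, 3.0, fps=1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.permutations(list(np.linspace(0.05, 0.95, 8))))
    def test_unit_window_is_permutation_invariant(self, perm):
        arr = np.array(perm)
        assert e.max_window_mean(arr, 1.0, fps=1.0) == pytest.approx(arr.max())
        # L=1 continuity degenerates to "any frame positive"
        assert (e.max_run_length(arr, 0.5) >= 1) == bool((arr >= 0.5).any())


class TestPatientDecision:
    def test_examples_and_boundary(self):
        assert e.patient_decision(3, 5) == "CRSwNP"
        assert e.patient_decision(0.8, 0.6) == "IP"
        assert e.patient_decision(5, 5) == "IP"  # tie counts positive


class TestThresholdSelection:
    def test_picks_ss_avg_maximizer(self):
        stats = {"a": 10.0, "b": 8.0, "c": 2.0, "d": 1.0}
        labels = {"a": "IP", "b": "IP", "c": "CRSwNP", "d": "CRSwNP"}
        t = e.select_threshold(stats, labels)
        assert 2.0 < t <= 8.0
        decisions = {p: e.patient_decision(v, t) for p, v in stats.items()}
        assert decisions == {"a": "IP", "b": "IP", "c": "CRSwNP", "d": "CRSwNP"}

    def test_fold_thresholds_ignore_evaluation_fold(self):
        """Fold 0's outlier statistics must not move fold 0's cutoff."""
        stats = {"p0": 100.0, "p1": 5.0, "p2": 1.0, "p3": 6.0, "p4": 2.0}
        labels = {"p0": "CRSwNP", "p1": "IP", "p2": "CRSwNP",
                  "p3": "IP", "p4": "CRSwNP"}
        asg = e.GroupAssignment(k=2, mapping={"p0": 0, "p1": 1, "p2": 1,
                                              "p3": 1, "p4": 1})
        ths = e.select_fold_thresholds(stats, labels, asg)
        # chosen on folds != 0, where 5 and 6 are IP, 1 and 2 CRSwNP
        assert 2.0 < ths[0] <= 5.0

    def test_threshold_sweep_enumerates_roc_operating_points(self):
        """confusion o patient_decision over all cutoffs == roc points."""
        rng = np.random.default_rng(3)
        stats = {f"p{i}": float(v) for i, v in enumerate(rng.random(30))}
        labels = {p: ("IP" if rng.random() < 0.5 else "CRSwNP") for p in stats}
        if len(set(labels.values())) < 2:  # pragma: no cover
            labels["p0"] = "IP"; labels["p1"] = "CRSwNP"
        curve = e.roc(stats, labels)
        swept = {(0.0, 0.0)}
        for t in sorted(set(stats.values())):
            cm = e.confusion({p: e.patient_decision(v, t)
                              for p, v in stats.items()}, labels)
            swept.add((round(cm.fpr, 12), round(cm.sensitivity, 12)))
        curve_pts = {(round(f, 12), round(t, 12)) for f, t in curve.points}
        assert swept == curve_pts
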