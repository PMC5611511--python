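import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpnet import (
    Hyperellipse,
    build_space,
    classify_behavioral,
    confidence_intervals,
    evaluate_classification,
    hyperellipse_indicator,
    precision_recall,
    radius_sweep,
    rec_score,
    recognize_trial,
)


def sphere(center, r=0.65):
    return Hyperellipse.sphere(np.asarray(center, dtype=float), r)


class TestIndicator:
    def test_center_is_inside(self):
        e = sphere([0.2, 0.3, 0.4])
        assert hyperellipse_indicator(e.center, e) == 1

    def test_boundary_counts_as_inside(self):
        e = Hyperellipse(center=np.zeros(2), radii=np.array([0.5, 2.0]))
        assert hyperellipse_indicator([0.5, 0.0], e) == 1
        assert hyperellipse_indicator([0.0, 2.0], e) == 1

    def test_double_radius_point_is_outside(self):
        # q = (1.30/0.65)^2 - 1 = 3 > 0
        e = sphere([0.0], r=0.65)
        assert hyperellipse_indicator([1.30], e) == 0

    def test_positive_radii_required(self):
        with pytest.raises(ValueError):
            Hyperellipse(center=np.zeros(2), radii=np.array([0.5, 0.0]))


class TestRecScore:
    def test_trajectory_at_center_scores_one(self):
        e = sphere([0.1, 0.2])
        traj = np.tile(e.center[:, None], (1, 40))
        assert rec_score(traj, e).rec == 1.0

    def test_trajectory_far_outside_scores_zero(self):
        e = sphere([0.0, 0.0])
        traj = np.full((2, 40), 10.0)
        assert rec_score(traj, e).rec == 0.0

    def test_constructed_count_matches_counting_oracle(self, rng):
        e = sphere([0.0], r=1.0)
        traj = np.concatenate([np.zeros(30), np.full(20, 5.0)])[None, :]
        perm = rng.permutation(50)
        score = rec_score(traj[:, perm], e, window=np.arange(50))
        assert score.inside_count == 30
        assert score.rec == pytest.approx(0.6)

    def test_invariant_under_window_permutation(self, rng):
        e = sphere([0.0, 0.0], r=0.8)
        traj = rng.normal(size=(2, 60))
        base = rec_score(traj, e).rec
        assert rec_score(traj[:, rng.permutation(60)], e).rec == base

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(1.0, 3.0), seed=st.integers(0, 100))
    def test_rec_nondecreasing_in_radius(self, scale, seed):
        rng = np.random.default_rng(seed)
        traj = rng.normal(size=(3, 30))
        e1 = Hyperellipse(np.zeros(3), np.array([0.5, 1.0, 1.5]))
        e2 = Hyperellipse(np.zeros(3), e1.radii * scale)
        assert rec_score(traj, e2).rec >= rec_score(traj, e1).rec

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            rec_score(np.zeros((2, 10)), sphere([0.0, 0.0]), window=[])


class TestDecisionLine:
    def test_known_mean_gives_midpoint(self):
        # normalized scores (1.0, 0.2, 0.2, 0.2): mean 0.4 -> d = 0.7
        res = classify_behavioral({"a": 1.0, "b": 0.2, "c": 0.2, "d": 0.2})
        assert res.decision_line == pytest.approx(0.7)
        np.testing.assert_array_equal(res.predicted_behavioral, [True, False, False, False])

    def test_normalization_by_max(self):
        res = classify_behavioral({"a": 0.5, "b": 0.1})
        assert res.normalized_scores.max() == 1.0
        np.testing.assert_allclose(res.normalized_scores, [1.0, 0.2])

    def test_score_exactly_at_line_is_non_behavioral(self):
        # normalized (1, 0.6, 0.2): mean 0.6 -> d = 0.8; no score sits above? 1 > 0.8
        res = classify_behavioral({"a": 1.0, "b": 0.6, "c": 0.2})
        assert res.decision_line == pytest.approx(0.8)
        # strict comparison: a value equal to d would not be behavioral
        assert not (res.normalized_scores[1] > res.decision_line)

    def test_all_zero_scores_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            classify_behavioral({"a": 0.0, "b": 0.0})


class TestPrecisionRecall:
    def test_arithmetic_example(self):
        p, r, acc = precision_recall([1, 1, 1, 1], [1, 1, 1, 0])
        assert (p, r, acc) == (0.75, 1.0, 0.75)

    def test_perfect_prediction(self):
        p, r, acc = precision_recall([1, 0, 1], [1, 0, 1])
        assert (p, r, acc) == (1.0, 1.0, 1.0)

    def test_empty_denominators_report_zero(self):
        p, r, acc = precision_recall([0, 0], [0, 0])
        assert (p, r, acc) == (0.0, 0.0, 0.0)

    def test_matches_confusion_count_oracle(self, rng):
        pred = rng.integers(0, 2, size=200).astype(bool)
        truth = rng.integers(0, 2, size=200).astype(bool)
        p, r, acc = precision_recall(pred, truth)
        tp = sum(1 for a, b in zip(pred, truth) if a and b)
        fp = sum(1 for a, b in zip(pred, truth) if a and not b)
        fn = sum(1 for a, b in zip(pred, truth) if not a and b)
        assert p == pytest.approx(tp / (tp + fp))
        assert r == pytest.approx(tp / (tp + fn))
        assert acc == pytest.approx(p * r)


class TestRecognizeTrial:
    def test_target_recognizes_itself(self):
        e = sphere([0.0, 0.0], r=0.5)
        traj = np.zeros((2, 50))
        assert recognize_trial(traj, e, target_rec=1.0)

    def test_always_outside_not_recognized(self):
        e = sphere([0.0, 0.0], r=0.5)
        assert not recognize_trial(np.full((2, 50), 9.0), e, target_rec=1.0)

    @pytest.mark.parametrize("n_inside,expected", [(69, False), (71, True)])
    def test_threshold_at_seventy_percent(self, n_inside, expected):
        e = sphere([0.0], r=1.0)
        traj = np.concatenate([np.zeros(n_inside), np.full(100 - n_inside, 5.0)])
        assert recognize_trial(traj[None, :], e, target_rec=1.0) is expected


class TestConfidenceIntervals:
    def test_constant_scores_zero_width(self):
        out = confidence_intervals({"b": [0.8, 0.8, 0.8]})
        lo, hi = out["intervals"]["b"]
        assert lo == hi == pytest.approx(0.8)

    def test_separated_classes_disjoint(self, rng):
        a = rng.normal(0.9, 0.01, size=20)
        b = rng.normal(0.1, 0.01, size=20)
        out = confidence_intervals({"behavioral": a, "non-behavioral": b})
        assert out["separable"]

    def test_identical_distributions_usually_overlap(self):
        overlaps = 0
        n_seeds = 60
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            out = confidence_intervals(
                {"a": r.normal(0.5, 0.1, 20), "b": r.normal(0.5, 0.1, 20)}
            )
            overlaps += not out["separable"]
        assert overlaps / n_seeds >= 0.95

    def test_bootstrap_interval_contains_mean(self, rng):
        v = rng.uniform(0.2, 0.8, size=30)
        out = confidence_intervals({"a": v}, method="bootstrap", seed=1)
        lo, hi = out["intervals"]["a"]
        assert lo <= v.mean() <= hi


class TestRadiusSweep:
    def test_nonpositive_radius_rejected(self, benchmark_snr10):
        collection, _ = benchmark_snr10
        space = build_space(collection, "oetr", [f"S{i}" for i in range(1, 9)])
        with pytest.raises(ValueError):
            radius_sweep(collection, space, "B1", radii=[0.5, 0.0])

    def test_default_grid_spans_half_to_085(self, benchmark_snr10):
        collection, _ = benchmark_snr10
        space = build_space(collection, "oetr", [f"S{i}" for i in range(1, 9)])
        sweep = radius_sweep(collection, space, "B1")
        assert sweep["radii"][0] == pytest.approx(0.5)
        assert sweep["radii"][-1] == pytest.approx(0.85)

    def test_high_snr_has_perfect_precision_interval(self, benchmark_snr10):
        collection, _ = benchmark_snr10
        space = build_space(collection, "oetr", [f"S{i}" for i in range(1, 9)])
        sweep = radius_sweep(collection, space, "B1")
        assert sweep["perfect_precision_width"] > 0.0


class TestEndToEnd:
    def test_interval_dominance_oetr_over_etr(self):
        """Whenever ETR separates behavioral vs non-behavioral Rec intervals,
        so does OETR (checked over seeds at the default configuration)."""
        from fpnet import SyntheticConfig, generate_benchmark_like, target_ellipse
        from fpnet.recognition import mean_rec_scores

        monos = [f"S{i}" for i in range(1, 9)]
        for seed in range(5):
            collection, _ = generate_benchmark_like(
                SyntheticConfig(snr=10.0, seed=seed)
            )
            separable = {}
            for method in ("etr", "oetr"):
                space = build_space(collection, method, monos)
                ellipse = target_ellipse(collection, space, "B1")
                _, per_trial = mean_rec_scores(collection, space, ellipse)
                by_class = {"behavioral": [], "non-behavioral": []}
                for s, scores in per_trial.items():
                    cls = collection.class_labels[s]
                    key = "behavioral" if cls == "behavioral" else "non-behavioral"
                    by_class[key].extend(scores)
                separable[method] = confidence_intervals(by_class)["separable"]
            if separable["etr"]:
                assert separable["oetr"]

    def test_behavioral_mixtures_recovered_at_high_snr(self, benchmark_snr10):
        collection, _ = benchmark_snr10
        space = build_space(collection, "oetr", [f"S{i}" for i in range(1, 9)])
        res = evaluate_classification(collection, space, "B1")
        predicted = {
            s for s, p in zip(res.stimuli, res.predicted_behavioral) if p
        }
        assert predicted == {"B1", "B2", "B3"}
        assert res.accuracy == 1.0
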