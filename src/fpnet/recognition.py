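"""Hyperellipse recognition scoring and behavioral classification.

A projected trajectory x(t) in the m-dimensional classification space is
compared against a target region — an m-dimensional hyperellipse centered
at the target's fixed point.  The pointwise membership metric is

    q(x) = sum_i ((x_i - c_i) / r_i)^2 - 1,    s = 1 if q <= 0 else 0,

and the recognition ratio Rec = S / T is the fraction of the trajectory's
time samples (over the stimulus-ON window) that fall inside.  Behavioral
classification normalizes the per-stimulus mean scores <Rec> by their
maximum and thresholds them at the decision line d = (mean + 1) / 2, the
midpoint between the distribution mean and the maximal value 1.  Accuracy
is reported as precision x recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .classification_space import ClassificationSpace, project
from .data_model import ResponseCollection

__all__ = [
    "Hyperellipse",
    "RecScore",
    "ClassificationResult",
    "hyperellipse_indicator",
    "rec_score",
    "classify_behavioral",
    "precision_recall",
    "recognize_trial",
    "confidence_intervals",
    "radius_sweep",
    "target_ellipse",
    "mean_rec_scores",
    "evaluate_classification",
]

DEFAULT_RADIUS = 0.65
DEFAULT_RADIUS_GRID = np.round(np.arange(0.50, 0.85 + 1e-9, 0.01), 2)
RECOGNITION_FRACTION = 0.7


@dataclass
class Hyperellipse:
    """Axis-aligned hyperellipse: center c and per-axis radii r (all > 0)."""

    center: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        if self.radii.shape != self.center.shape:
            raise ValueError("center and radii must have the same dimension")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")

    @classmethod
    def sphere(cls, center: np.ndarray, radius: float = DEFAULT_RADIUS) -> "Hyperellipse":
        center = np.atleast_1d(np.asarray(center, dtype=float))
        return cls(center=center, radii=np.full(center.shape, float(radius)))


@dataclass
class RecScore:
    """Inside-count S out of T window samples; Rec = S / T."""

    inside_count: int
    total: int

    def __post_init__(self) -> None:
        if not (0 <= self.inside_count <= self.total) or self.total <= 0:
            raise ValueError("need 0 <= S <= T with T > 0")

    @property
    def rec(self) -> float:
        return self.inside_count / self.total


@dataclass
class ClassificationResult:
    """Outcome of behavioral/non-behavioral classification of mean Rec scores."""

    stimuli: list[str]
    mean_scores: np.ndarray
    normalized_scores: np.ndarray
    decision_line: float
    predicted_behavioral: np.ndarray  # bool per stimulus
    precision: float = float("nan")
    recall: float = float("nan")
    accuracy: float = float("nan")
    extras: dict = field(default_factory=dict)


def hyperellipse_indicator(x: np.ndarray, e: Hyperellipse) -> int:
    """Pointwise membership s for a single point (boundary counts as inside)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    q = float(np.sum(((x - e.center) / e.radii) ** 2) - 1.0)
    return 1 if q <= 0 else 0


def _inside_mask(trajectory: np.ndarray, e: Hyperellipse) -> np.ndarray:
    z = (trajectory - e.center[:, None]) / e.radii[:, None]
    return np.sum(z**2, axis=0) <= 1.0


def rec_score(
    trajectory: np.ndarray,
    e: Hyperellipse,
    window: Sequence[int] | None = None,
) -> RecScore:
    """Fraction of window samples of an m x T trajectory inside the ellipse."""
    trajectory = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if trajectory.shape[0] != e.center.shape[0]:
        raise ValueError("trajectory dimension does not match ellipse")
    if window is None:
        window = np.arange(trajectory.shape[1])
    window = np.asarray(window, dtype=int)
    if window.size == 0:
        raise ValueError("window must be nonempty")
    if window.min() < 0 or window.max() >= trajectory.shape[1]:
        raise ValueError("window indices out of range")
    inside = _inside_mask(trajectory[:, window], e)
    return RecScore(inside_count=int(inside.sum()), total=int(window.size))


def classify_behavioral(mean_scores: Mapping[str, float]) -> ClassificationResult:
    """Threshold normalized per-stimulus mean Rec scores at the decision line.

    Scores are normalized by their maximum; the decision line is
    d = (mean of normalized scores + 1) / 2 and stimuli strictly above d
    are predicted behavioral.
    """
    stimuli = list(mean_scores)
    scores = np.array([mean_scores[s] for s in stimuli], dtype=float)
    if np.any(scores < 0):
        raise ValueError("mean Rec scores must be nonnegative")
    m = scores.max() if scores.size else 0.0
    if m <= 0:
        raise ValueError("degenerate input: all mean Rec scores are zero")
    normalized = scores / m
    d = (normalized.mean() + 1.0) / 2.0
    predicted = normalized > d
    return ClassificationResult(
        stimuli=stimuli,
        mean_scores=scores,
        normalized_scores=normalized,
        decision_line=float(d),
        predicted_behavioral=predicted,
    )


def precision_recall(
    predicted: Sequence[bool], truth: Sequence[bool]
) -> tuple[float, float, float]:
    """Precision, recall and their product (the accuracy used throughout).

    Empty denominators are reported as 0 (no positive predictions means
    undefined precision; no positive truths means undefined recall).
    """
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    tp = int(np.sum(predicted & truth))
    fp = int(np.sum(predicted & ~truth))
    fn = int(np.sum(~predicted & truth))
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r, p * r


def recognize_trial(
    trajectory: np.ndarray,
    target: Hyperellipse,
    target_rec: float,
    window: Sequence[int] | None = None,
    fraction: float = RECOGNITION_FRACTION,
) -> bool:
    """Single-trial recognition: Rec(trajectory) >= fraction * target Rec."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    return rec_score(trajectory, target, window).rec >= fraction * target_rec


def confidence_intervals(
    scores_by_class: Mapping[str, Sequence[float]],
    alpha: float = 0.01,
    method: str = "t",
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Two-sided (1 - alpha) confidence intervals of per-trial Rec by class.

    ``method='t'`` gives Student-t intervals on the mean (zero-width for
    constant scores); ``method='bootstrap'`` gives seeded percentile
    bootstrap intervals.  The result carries a ``separable`` flag: True iff
    all pairwise class intervals are disjoint.
    """
    intervals: dict[str, tuple[float, float]] = {}
    for cls, vals in scores_by_class.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            raise ValueError(f"class {cls!r} has no scores")
        mean = float(v.mean())
        if method == "t":
            if v.size < 2 or np.all(v == v[0]):
                intervals[cls] = (float(v[0]), float(v[0]))
                continue
            sd = float(v.std(ddof=1))
            if sd == 0.0:
                intervals[cls] = (mean, mean)
            else:
                half = stats.t.ppf(1 - alpha / 2, v.size - 1) * sd / np.sqrt(v.size)
                intervals[cls] = (mean - half, mean + half)
        elif method == "bootstrap":
            rng = np.random.default_rng(seed)
            boots = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
            lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            intervals[cls] = (float(lo), float(hi))
        else:
            raise ValueError(f"unknown interval method {method!r}")
    keys = list(intervals)
    separable = all(
        intervals[a][1] < intervals[b][0] or intervals[b][1] < intervals[a][0]
        for i, a in enumerate(keys)
        for b in keys[i + 1 :]
    )
    return {"intervals": intervals, "separable": separable, "alpha": alpha}


# ---------------------------------------------------------------------------
# collection-level evaluation helpers

def target_ellipse(
    collection: ResponseCollection,
    space: ClassificationSpace,
    target_stimulus: str,
    radius: float = DEFAULT_RADIUS,
) -> Hyperellipse:
    """Sphere of the given radius at the target's center.

    For a stimulus that is an axis of the space the center is its fixed
    point's coordinates (the corresponding row of L^T B); for any other
    stimulus (e.g. a mixture) the center is the mean projected training
    trajectory over the ON window.
    """
    if target_stimulus in space.stimulus_order and space.method in ("etr", "oetr"):
        i = space.stimulus_order.index(target_stimulus)
        center = space.fixed_points[i, :]
    else:
        window = collection.get(target_stimulus, 0).on_sample_indices()
        trajs = [
            project(rm, space)[:, window]
            for rm in collection.trials[target_stimulus]
        ]
        center = np.mean(trajs, axis=(0, 2))
    return Hyperellipse.sphere(center, radius)


def mean_rec_scores(
    collection: ResponseCollection,
    space: ClassificationSpace,
    ellipse: Hyperellipse,
) -> tuple[dict[str, float], dict[str, list[float]]]:
    """Per-stimulus mean Rec over trials, plus the raw per-trial scores."""
    means: dict[str, float] = {}
    per_trial: dict[str, list[float]] = {}
    for stim in collection.stimuli:
        scores = []
        for rm in collection.trials[stim]:
            traj = project(rm, space)
            scores.append(rec_score(traj, ellipse, rm.on_sample_indices()).rec)
        per_trial[stim] = scores
        means[stim] = float(np.mean(scores))
    return means, per_trial


def evaluate_classification(
    collection: ResponseCollection,
    space: ClassificationSpace,
    target_stimulus: str,
    radius: float = DEFAULT_RADIUS,
) -> ClassificationResult:
    """End-to-end behavioral classification against a target stimulus sphere.

    Builds the target hyperellipse, scores every trial of every stimulus,
    classifies the per-stimulus mean scores, and evaluates precision,
    recall and their product against the collection's class labels
    (behavioral = positive).
    """
    ellipse = target_ellipse(collection, space, target_stimulus, radius)
    means, per_trial = mean_rec_scores(collection, space, ellipse)
    result = classify_behavioral(means)
    truth = np.array(
        [collection.class_labels.get(s) == "behavioral" for s in result.stimuli]
    )
    p, r, acc = precision_recall(result.predicted_behavioral, truth)
    result.precision, result.recall, result.accuracy = p, r, acc
    result.extras["per_trial_scores"] = per_trial
    result.extras["radius"] = radius
    result.extras["target"] = target_stimulus
    return result


def radius_sweep(
    collection: ResponseCollection,
    space: ClassificationSpace,
    target_stimulus: str,
    radii: Sequence[float] | None = None,
) -> dict:
    """Precision/recall/accuracy as the target-sphere radius is varied.

    Also reports the widest contiguous radius interval achieving perfect
    precision (P = 1).
    """
    if radii is None:
        radii = DEFAULT_RADIUS_GRID
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    rows = []
    for r in radii:
        try:
            res = evaluate_classification(collection, space, target_stimulus, r)
            rows.append((float(r), res.precision, res.recall, res.accuracy))
        except ValueError:  # all-zero scores at tiny radii: no classification
            rows.append((float(r), 0.0, 0.0, 0.0))
    precisions = np.array([p for _, p, _, _ in rows])
    best_len, best_span, cur_start = 0, (None, None), None
    for i, p in enumerate(precisions):
        if p == 1.0:
            if cur_start is None:
                cur_start = i
            if i - cur_start + 1 > best_len:
                best_len = i - cur_start + 1
                best_span = (radii[cur_start], radii[i])
        else:
            cur_start = None
    width = 0.0 if best_span[0] is None else float(best_span[1] - best_span[0])
    return {
        "radii": radii,
        "table": rows,
        "perfect_precision_interval": best_span,
        "perfect_precision_width": width,
    }
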