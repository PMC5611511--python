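"""Direct-classification baselines: SVM and RUSBoost on raw node-space points.

These methods attempt binary classification (stimuli of interest vs. the
rest) straight from the high-dimensional node-space samples, without any
low-dimensional state-space construction, and serve as the comparison
point for the ETR/OETR pipelines.  Featurization is shared: each ON-window
time sample of each trial is one point in node space.

The SVM is the regularized hinge-loss classifier (linear or Gaussian
kernel), delegated to scikit-learn.  RUSBoost combines random
under-sampling of the majority class with AdaBoost.M2-style boosting of a
depth-limited decision tree: each round under-samples to class balance,
fits the weak learner, computes the pseudo-loss

    eps_t = sum_{(i, y): y != y_i} D_t(i) * (1 - h_t(x_i, y_i) + h_t(x_i, y)) / 2,

sets alpha_t = eps_t / (1 - eps_t), updates the example weights, and the
final hypothesis is the argmax over classes of sum_t h_t(x, y) log(1/alpha_t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .data_model import ResponseCollection
from .recognition import precision_recall

__all__ = [
    "LabeledPointSet",
    "featurize",
    "train_test_split_by_trial",
    "svm_binary",
    "RUSBoostClassifier",
    "rusboost",
]


@dataclass
class LabeledPointSet:
    """Node-space points with binary labels in {-1, +1}."""

    points: np.ndarray  # n_points x n_features
    labels: np.ndarray  # n_points, values in {-1, +1}
    trial_ids: np.ndarray | None = None  # group id per point, for splitting

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.points.shape[0] != self.labels.shape[0]:
            raise ValueError("points and labels disagree in length")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be -1 or +1")

    def require_both_classes(self) -> None:
        if len(np.unique(self.labels)) < 2:
            raise ValueError("training requires both classes present")


def featurize(
    collection: ResponseCollection,
    positive_stimuli: Sequence[str],
    per_trial_vectors: bool = False,
) -> LabeledPointSet:
    """Turn a collection into labeled node-space points.

    By default each ON-window time sample of each trial is one point
    (label +1 iff its stimulus is in ``positive_stimuli``); with
    ``per_trial_vectors=True`` each trial's ON-window matrix is flattened
    into a single vector instead.
    """
    positive = set(positive_stimuli)
    if not positive:
        raise ValueError("positive stimulus set must be nonempty")
    unknown = positive - set(collection.stimuli)
    if unknown:
        raise KeyError(f"unknown positive stimuli {sorted(unknown)}")
    pts, labels, groups = [], [], []
    gid = 0
    for stim in collection.stimuli:
        y = 1 if stim in positive else -1
        for rm in collection.trials[stim]:
            window = rm.on_sample_indices()
            if per_trial_vectors:
                pts.append(rm.rates[:, window].ravel())
                labels.append(y)
                groups.append(gid)
            else:
                block = rm.rates[:, window].T  # samples x nodes
                pts.extend(block)
                labels.extend([y] * block.shape[0])
                groups.extend([gid] * block.shape[0])
            gid += 1
    return LabeledPointSet(
        points=np.asarray(pts),
        labels=np.asarray(labels),
        trial_ids=np.asarray(groups),
    )


def train_test_split_by_trial(
    data: LabeledPointSet, test_fraction: float = 0.2, seed: int = 0
) -> tuple[LabeledPointSet, LabeledPointSet]:
    """Seeded split in which all points of a trial stay on one side."""
    if data.trial_ids is None:
        raise ValueError("point set carries no trial ids")
    rng = np.random.default_rng(seed)
    # stratify trials by their label so both classes appear on both sides
    test_trials: list[int] = []
    for y in (-1, 1):
        trials = np.unique(data.trial_ids[data.labels == y])
        n_test = max(1, int(round(test_fraction * trials.size)))
        test_trials.extend(rng.choice(trials, size=n_test, replace=False))
    mask = np.isin(data.trial_ids, test_trials)

    def subset(m: np.ndarray) -> LabeledPointSet:
        return LabeledPointSet(
            points=data.points[m], labels=data.labels[m], trial_ids=data.trial_ids[m]
        )

    return subset(~mask), subset(mask)


def svm_binary(
    data: LabeledPointSet,
    lam: float = 1.0,
    kernel: str = "linear",
    test_fraction: float = 0.2,
    seed: int = 0,
):
    """Hinge-loss SVM baseline with held-out evaluation.

    ``lam`` is the weight penalty of the regularized hinge objective
    (mapped to scikit-learn's C = 1 / lam).  Returns the fitted classifier
    and (precision, recall, accuracy=P*R) on the trial-stratified held-out
    split.
    """
    if kernel not in ("linear", "gaussian"):
        raise ValueError("kernel must be 'linear' or 'gaussian'")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    train, test = train_test_split_by_trial(data, test_fraction, seed)
    train.require_both_classes()
    clf = SVC(
        C=1.0 / lam,
        kernel={"linear": "linear", "gaussian": "rbf"}[kernel],
        random_state=seed,
    )
    clf.fit(train.points, train.labels)
    pred = clf.predict(test.points)
    p, r, acc = precision_recall(pred == 1, test.labels == 1)
    return clf, (p, r, acc)


@dataclass
class RUSBoostClassifier:
    """Boosted ensemble produced by :func:`rusboost`."""

    learners: list = field(default_factory=list)
    alphas: list = field(default_factory=list)
    classes: np.ndarray = field(default_factory=lambda: np.array([-1, 1]))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class weighted-vote scores sum_t h_t(x, y) log(1/alpha_t)."""
        X = np.asarray(X, dtype=float)
        scores = np.zeros((X.shape[0], self.classes.size))
        for h, alpha in zip(self.learners, self.alphas):
            proba = _class_proba(h, X, self.classes)
            scores += proba * np.log(1.0 / alpha)
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.learners:
            raise ValueError("empty ensemble")
        return self.classes[np.argmax(self.decision_scores(X), axis=1)]


def _class_proba(h, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """h_t(x, y) for all y, aligned to ``classes`` order."""
    proba = np.zeros((X.shape[0], classes.size))
    p = h.predict_proba(X)
    for i, c in enumerate(h.classes_):
        proba[:, np.flatnonzero(classes == c)[0]] = p[:, i]
    return proba


def rusboost(
    data: LabeledPointSet,
    rounds: int = 50,
    seed: int = 0,
    max_depth: int = 3,
    max_retries: int = 5,
) -> RUSBoostClassifier:
    """Random under-sampling + boosting for imbalanced binary data.

    Each round draws a balanced subsample (all minority points plus an
    equal-size random draw of majority points, respecting the current
    example weights), fits a depth-limited decision tree, and performs the
    pseudo-loss weight update.  Rounds with pseudo-loss >= 0.5 are
    discarded and resampled (bounded retries); boosting stops early once
    retries are exhausted or the pseudo-loss vanishes.
    """
    data.require_both_classes()
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    X, y = data.points, data.labels
    classes = np.array([-1, 1])
    counts = {c: int(np.sum(y == c)) for c in classes}
    minority = min(classes, key=lambda c: counts[c])
    majority = -minority
    rng = np.random.default_rng(seed)

    n = X.shape[0]
    D = np.full(n, 1.0 / n)
    ens = RUSBoostClassifier(classes=classes)
    y_idx = (y == 1).astype(int)  # column of the true class

    for _ in range(rounds):
        for attempt in range(max_retries + 1):
            min_idx = np.flatnonzero(y == minority)
            maj_idx = np.flatnonzero(y == majority)
            p = D[maj_idx] / D[maj_idx].sum()
            take = rng.choice(
                maj_idx, size=min(min_idx.size, maj_idx.size), replace=False, p=p
            )
            sel = np.concatenate([min_idx, take])
            h = DecisionTreeClassifier(
                max_depth=max_depth, random_state=int(rng.integers(2**31))
            )
            h.fit(X[sel], y[sel], sample_weight=D[sel])
            proba = _class_proba(h, X, classes)
            h_true = proba[np.arange(n), y_idx]
            h_false = proba[np.arange(n), 1 - y_idx]
            # pseudo-loss over mislabel pairs (binary: one wrong label each)
            eps = float(np.sum(D * 0.5 * (1.0 - h_true + h_false)))
            if eps < 0.5:
                break
        else:
            break  # could not find a useful weak learner; stop boosting
        if eps <= 0:
            ens.learners.append(h)
            ens.alphas.append(1e-10)
            break
        alpha = eps / (1.0 - eps)
        ens.learners.append(h)
        ens.alphas.append(alpha)
        D = D * alpha ** (0.5 * (1.0 + h_true - h_false))
        D = D / D.sum()
    if not ens.learners:
        raise RuntimeError("boosting failed to fit any weak learner")
    return ens
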