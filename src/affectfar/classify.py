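"""Multiclass one-vs-all linear SVM over mid-level features, with LOO evaluation.

One binary linear SVM is trained per affect class against the rest; a test
video receives the label of the classifier with the highest response, ties
resolving to the class earliest in the domain's fixed order.  Because the
cohorts are small (n ~ 25) and some labels rare, leave-one-out folds can be
degenerate (a class present only in the held-out sample, or a rater with a
single label overall); these are handled by constant most-negative scorers
for absent classes and a flagged always-predict model for single-label
training sets, never by raising inside a fold.

Features are standardized with training-fold statistics only (switchable):
the concatenated kinds mix scales (a gray-level SD next to a transition
count) and would otherwise be dominated by one component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .features import ABSENT_CLASS_SCORE

DEFAULT_C = 1.0


@dataclass
class OvaModel:
    """One-vs-all linear scorers for one affect domain."""

    classes: tuple[str, ...]
    weights: np.ndarray  # (n_classes, n_features)
    biases: np.ndarray  # (n_classes,)
    mean: np.ndarray
    scale: np.ndarray
    C: float = DEFAULT_C
    degenerate_label: str | None = None  # set when training saw a single class

    def __post_init__(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("an OVA model needs at least 2 classes")
        if self.weights.shape != (len(self.classes), self.mean.size):
            raise ValueError("inconsistent scorer shapes")

    @property
    def n_features(self) -> int:
        return self.mean.size

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_features,):
            raise ValueError(f"expected a length-{self.n_features} feature vector")
        return self.weights @ ((x - self.mean) / self.scale) + self.biases


def train_ova(
    features: np.ndarray,
    labels: list[str] | np.ndarray,
    classes: tuple[str, ...],
    C: float = DEFAULT_C,
    standardize: bool = True,
) -> OvaModel:
    """Train one binary linear SVM per class in ``classes`` (one-vs-all).

    Classes absent from the training labels get a constant most-negative
    scorer.  A single-label training set yields a degenerate model that
    always predicts that label (flagged via ``degenerate_label``), which
    leave-one-out folds require.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D (n_samples, n_features) array")
    labels = [str(l) for l in labels]
    if len(labels) != len(X):
        raise ValueError("one label per feature vector required")
    unknown = set(labels) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class list: {sorted(unknown)}")
    if standardize:
        mean, scale = X.mean(axis=0), X.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
    else:
        mean, scale = np.zeros(X.shape[1]), np.ones(X.shape[1])
    weights = np.zeros((len(classes), X.shape[1]))
    biases = np.full(len(classes), ABSENT_CLASS_SCORE)
    present = set(labels)
    if len(present) == 1:
        only = labels[0]
        biases[classes.index(only)] = 0.0
        return OvaModel(classes, weights, biases, mean, scale, C, degenerate_label=only)
    Xs = (X - mean) / scale
    y = np.asarray(labels)
    for k, cls in enumerate(classes):
        if cls not in present:
            continue
        svc = SVC(kernel="linear", C=C).fit(Xs, (y == cls).astype(int))
        weights[k] = svc.coef_[0]
        biases[k] = svc.intercept_[0]
    return OvaModel(classes, weights, biases, mean, scale, C)


def predict_ova(model: OvaModel, x: np.ndarray) -> str:
    """Label of the binary classifier with the highest response (ties: lowest index)."""
    if model.degenerate_label is not None:
        return model.degenerate_label
    return model.classes[int(np.argmax(model.decision_scores(x)))]


@dataclass
class LOOReport:
    """Leave-one-out accuracy of one rater's domain labels, with baseline."""

    rater_id: str
    domain: str
    accuracy: float
    baseline: float  # frequency of the rater's most common label, in [0,1]
    improvement: float  # accuracy / baseline
    predicted: list[str] = field(default_factory=list)
    true: list[str] = field(default_factory=list)
    degenerate: bool = False
    feature_kind: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must lie in [0, 1]")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if abs(self.improvement - self.accuracy / self.baseline) > 1e-9:
            raise ValueError("improvement must equal accuracy / baseline")

    def to_dict(self) -> dict:
        return {
            "rater": self.rater_id,
            "domain": self.domain,
            "feature_kind": self.feature_kind,
            "accuracy": self.accuracy,
            "baseline": self.baseline,
            "improvement": self.improvement,
            "n": len(self.true),
            "degenerate": self.degenerate,
        }


def improvement_coefficient(accuracy: float, distribution: dict[str, float]) -> float:
    """Accuracy divided by the frequency of the most common label.

    ``accuracy`` and the frequencies must share a scale (both fractions or
    both percentages).
    """
    if not distribution:
        raise ValueError("label distribution is empty")
    top = max(distribution.values())
    if top <= 0:
        raise ValueError("most common label has zero frequency")
    return accuracy / top


def loo_folds(n: int):
    """Yield (train_indices, test_index) pairs for leave-one-out over n samples."""
    for i in range(n):
        yield [j for j in range(n) if j != i], i


def loo_evaluate(
    features: np.ndarray,
    labels: list[str] | np.ndarray,
    classes: tuple[str, ...],
    C: float = DEFAULT_C,
    rater_id: str = "",
    domain: str = "",
    feature_kind: str | None = None,
    standardize: bool = True,
) -> LOOReport:
    """Leave-one-out evaluation: each patient is the test sample exactly once.

    The baseline is the frequency of the most common label over the full
    label set and the improvement coefficient is accuracy / baseline.
    """
    X = np.asarray(features, dtype=float)
    labels = [str(l) for l in labels]
    n = len(labels)
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 patients")
    if len(X) != n:
        raise ValueError("one feature vector per patient required")
    predicted = []
    degenerate = False
    for train_idx, test_idx in loo_folds(n):
        assert test_idx not in train_idx
        model = train_ova(
            X[train_idx], [labels[j] for j in train_idx], classes, C, standardize=standardize
        )
        if model.degenerate_label is not None:
            degenerate = True
        predicted.append(predict_ova(model, X[test_idx]))
    accuracy = float(np.mean([p == t for p, t in zip(predicted, labels)]))
    counts = {c: labels.count(c) for c in classes if c in labels}
    baseline = max(counts.values()) / n
    return LOOReport(
        rater_id=rater_id,
        domain=domain,
        accuracy=accuracy,
        baseline=baseline,
        improvement=accuracy / baseline,
        predicted=predicted,
        true=labels,
        degenerate=degenerate,
        feature_kind=feature_kind,
    )
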