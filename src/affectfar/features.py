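"""Mid-level per-video features: expression, label, motion, and combinations.

A video is summarised by one of five fixed-length descriptors computed from
its cell-intensity series X[r][n]:

1. ``expression`` (length 7) — per-frame scores of seven expression classes
   (norm, anger, disgust, fear, happiness, sadness, surprise) from linear
   one-vs-all scorers over the cell-intensity vector, averaged over frames;
2. ``label`` (length 1) — the number of transitions of the per-frame
   dominating (argmax) expression label along the video;
3. ``motion`` (length 1) — the standard deviation over frames of the
   per-frame mean gray level (population denominator), over the whole face
   or any subset of cells;
4. ``motion_label`` (length 2) and 5. ``motion_expression`` (length 8) —
   concatenations with the motion component first.

Per-part analyses use the motion feature only: the expression and label
features depend on an expression classifier that sees the entire face.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .facegrid import CellIntensitySeries
from .vocab import EXPRESSION_CLASSES, FEATURE_KINDS

#: Constant decision value assigned to expression/affect classes absent from
#: training: finite, but below any reachable trained score.
ABSENT_CLASS_SCORE = -1e6


@dataclass
class ExpressionModel:
    """Seven linear one-vs-all expression scorers over cell-intensity vectors.

    Scores are ``W @ ((x - mean) / scale) + b`` with per-feature training
    statistics; classes absent from training receive a constant
    most-negative score so they can never dominate.
    """

    weights: np.ndarray  # (7, n_cells)
    biases: np.ndarray  # (7,)
    mean: np.ndarray  # (n_cells,)
    scale: np.ndarray  # (n_cells,)
    grid: tuple[int, int] | None = None
    seed: int | None = None
    classes: tuple[str, ...] = EXPRESSION_CLASSES

    def __post_init__(self) -> None:
        if len(self.classes) != 7:
            raise ValueError("an expression model has exactly 7 classes")
        if self.weights.shape != (7, self.mean.size) or self.biases.shape != (7,):
            raise ValueError("inconsistent scorer shapes")

    @property
    def n_inputs(self) -> int:
        return self.mean.size


def train_expression_model(
    vectors: np.ndarray,
    labels: np.ndarray,
    C: float = 1.0,
    seed: int = 0,
    grid: tuple[int, int] | None = None,
) -> ExpressionModel:
    """Train one linear binary scorer per expression class (one-vs-all).

    ``vectors`` holds one cell-intensity vector per labeled frame.  Inputs
    are standardized with training statistics; each present class gets a
    linear SVM against the rest; absent classes get a constant
    most-negative scorer.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValueError("vectors must be a 2-D array of equal-length frame vectors")
    labels = np.asarray(labels)
    if len(labels) != len(X):
        raise ValueError("one label required per frame vector")
    present = set(str(l) for l in labels)
    unknown = present - set(EXPRESSION_CLASSES)
    if unknown:
        raise ValueError(f"unknown expression labels: {sorted(unknown)}")
    if len(present) < 2:
        raise ValueError("training requires at least 2 distinct expression classes")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    weights = np.zeros((7, X.shape[1]))
    biases = np.full(7, ABSENT_CLASS_SCORE)
    for k, cls in enumerate(EXPRESSION_CLASSES):
        if cls not in present:
            continue
        y = (labels == cls).astype(int)
        svc = SVC(kernel="linear", C=C, random_state=seed).fit(Xs, y)
        weights[k] = svc.coef_[0]
        biases[k] = svc.intercept_[0]
    return ExpressionModel(weights, biases, mean, scale, grid=grid, seed=seed)


def expression_scores(frame_vector: np.ndarray, model: ExpressionModel) -> np.ndarray:
    """Seven expression scores for one frame's cell-intensity vector."""
    v = np.asarray(frame_vector, dtype=float)
    if v.shape != (model.n_inputs,):
        raise ValueError(f"expected a length-{model.n_inputs} cell vector, got {v.shape}")
    return model.weights @ ((v - model.mean) / model.scale) + model.biases


def _frame_scores(series: CellIntensitySeries, model: ExpressionModel) -> np.ndarray:
    if series.n_cells != model.n_inputs:
        raise ValueError("series cell count does not match the expression model")
    Xs = (series.X.T - model.mean) / model.scale  # (n_frames, n_cells)
    return Xs @ model.weights.T + model.biases  # (n_frames, 7)


@dataclass
class MidLevelFeature:
    """One per-video descriptor with its provenance (patient, face region)."""

    kind: str
    values: np.ndarray
    patient_id: str | None = None
    part: str = "face"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.values = np.atleast_1d(np.asarray(self.values, dtype=float))
        expected = FEATURE_KINDS[self.kind]
        if self.values.shape != (expected,):
            raise ValueError(f"{self.kind} feature must have length {expected}")
        if self.kind in ("motion", "motion_label", "motion_expression") and self.values[0] < 0:
            raise ValueError("motion component must be non-negative")
        if self.kind == "label" and (self.values[0] < 0 or self.values[0] != int(self.values[0])):
            raise ValueError("label feature must be a non-negative integer count")


def expression_feature(series: CellIntensitySeries, model: ExpressionModel) -> MidLevelFeature:
    """Per-frame 7-score vectors averaged arithmetically over frames."""
    scores = _frame_scores(series, model)
    return MidLevelFeature("expression", scores.mean(axis=0), series.patient_id, "face")


def dominating_labels(series: CellIntensitySeries, model: ExpressionModel) -> np.ndarray:
    """Argmax expression index per frame (ties resolve to the lowest index)."""
    return np.argmax(_frame_scores(series, model), axis=1)


def label_feature(series: CellIntensitySeries, model: ExpressionModel) -> MidLevelFeature:
    """Count of frames whose dominating expression differs from the previous frame."""
    lab = dominating_labels(series, model)
    transitions = int(np.count_nonzero(np.diff(lab)))
    return MidLevelFeature("label", [transitions], series.patient_id, "face")


def motion_feature(
    series: CellIntensitySeries,
    cells: frozenset[int] | list[int] | None = None,
    part: str = "face",
) -> MidLevelFeature:
    """Population SD over frames of the mean gray level of the selected cells."""
    if cells is None:
        idx = np.arange(series.n_cells)
    else:
        idx = np.fromiter(sorted(cells), dtype=int)
        if idx.size == 0:
            raise ValueError("cell subset must be non-empty")
        if idx.min() < 0 or idx.max() >= series.n_cells:
            raise ValueError("cell index out of range")
    m = series.X[idx].mean(axis=0)
    return MidLevelFeature("motion", [float(np.std(m))], series.patient_id, part)


def combined_feature(
    kind: str, motion: MidLevelFeature, other: MidLevelFeature
) -> MidLevelFeature:
    """Concatenate motion with label or expression (motion component first)."""
    expected_other = {"motion_label": "label", "motion_expression": "expression"}
    if kind not in expected_other:
        raise ValueError(f"combined kind must be motion_label or motion_expression, got {kind!r}")
    if motion.kind != "motion" or other.kind != expected_other[kind]:
        raise ValueError(
            f"{kind} requires a motion and a {expected_other[kind]} feature, "
            f"got {motion.kind}/{other.kind}"
        )
    if motion.patient_id != other.patient_id:
        raise ValueError("cannot combine features from different patients")
    return MidLevelFeature(
        kind, np.concatenate([motion.values, other.values]), motion.patient_id, motion.part
    )


def video_features(
    series: CellIntensitySeries, model: ExpressionModel
) -> dict[str, MidLevelFeature]:
    """All five whole-face feature kinds for one video."""
    expr = expression_feature(series, model)
    lab = label_feature(series, model)
    mot = motion_feature(series)
    return {
        "expression": expr,
        "label": lab,
        "motion": mot,
        "motion_label": combined_feature("motion_label", mot, lab),
        "motion_expression": combined_feature("motion_expression", mot, expr),
    }
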