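"""Published summary statistics of the pilot affect-annotation study.

The pipeline was motivated by a pilot study in which five senior
psychiatrists annotated the affect of 25 male schizophrenia inpatients from
videotaped semi-structured interviews.  The raw videos are private, but the
study's summary tables — per-rater label distributions, rater-by-rater
percent-agreement matrices, and the leave-one-out accuracies of the
machine-learning predictor — are public, and several derived quantities
(agreement summaries, improvement-over-baseline coefficients) are computed
from them.  This module ships those printed values as reference inputs.

All percentages are stored exactly as printed (hence the mixed rounding,
e.g. 4.17 next to 4.16).
"""

from __future__ import annotations

import numpy as np

from .vocab import QUALITY_LABELS, RANGE_LABELS, SUBTYPE_LABELS

RATERS: tuple[str, ...] = ("rater_1", "rater_2", "rater_3", "rater_4", "rater_5")

#: Per-rater label distributions (percent), quality domain; rows follow
#: RATERS, columns follow QUALITY_LABELS.
QUALITY_DISTRIBUTION = {
    "rater_1": dict(zip(QUALITY_LABELS, (0.0, 100.0, 0.0))),
    "rater_2": dict(zip(QUALITY_LABELS, (12.5, 70.8, 16.6))),
    "rater_3": dict(zip(QUALITY_LABELS, (54.1, 41.6, 4.17))),
    "rater_4": dict(zip(QUALITY_LABELS, (4.16, 87.5, 8.33))),
    "rater_5": dict(zip(QUALITY_LABELS, (8.33, 91.66, 0.0))),
}

#: Per-rater label distributions (percent), range domain.
RANGE_DISTRIBUTION = {
    "rater_1": dict(zip(RANGE_LABELS, (4.1, 25.0, 50.0, 20.8))),
    "rater_2": dict(zip(RANGE_LABELS, (0.0, 12.5, 66.6, 20.8))),
    "rater_3": dict(zip(RANGE_LABELS, (16.6, 41.6, 25.0, 16.6))),
    "rater_4": dict(zip(RANGE_LABELS, (8.33, 50.0, 37.5, 4.16))),
    "rater_5": dict(zip(RANGE_LABELS, (4.16, 12.5, 54.16, 29.16))),
}

#: Per-rater label distributions (percent), subtype domain (12 classes).
_SUBTYPE_COLUMNS = {
    "unknown": (21, 33, 0, 50, 88),
    "stupid": (54, 13, 17, 8, 8),
    "euphoria": (4, 8, 8, 4, 0),
    "empathetic": (8, 0, 8, 4, 0),
    "self_contempt": (0, 0, 0, 0, 0),
    "anxious": (13, 4, 17, 17, 0),
    "suspicious": (0, 13, 4, 0, 0),
    "hopeless": (0, 4, 0, 8, 0),
    "frightened": (0, 0, 13, 0, 0),
    "irritable": (0, 13, 8, 4, 0),
    "vacancy": (0, 13, 25, 4, 4),
    "sense_of_guilt": (0, 0, 0, 0, 0),
}
SUBTYPE_DISTRIBUTION = {
    rater: {label: float(_SUBTYPE_COLUMNS[label][i]) for label in SUBTYPE_LABELS}
    for i, rater in enumerate(RATERS)
}

#: Rater-by-rater percent-agreement matrices (rows/cols follow RATERS).
QUALITY_AGREEMENT = np.array(
    [
        [100, 71, 42, 88, 92],
        [71, 100, 46, 58, 63],
        [42, 46, 100, 38, 33],
        [88, 58, 38, 100, 88],
        [92, 63, 33, 88, 100],
    ],
    dtype=float,
)

RANGE_AGREEMENT = np.array(
    [
        [100, 58, 38, 38, 58],
        [58, 100, 25, 33, 75],
        [38, 25, 100, 42, 33],
        [38, 33, 42, 100, 29],
        [58, 75, 33, 29, 100],
    ],
    dtype=float,
)

SUBTYPE_AGREEMENT = np.array(
    [
        [100, 17, 25, 17, 21],
        [17, 100, 29, 29, 38],
        [25, 29, 100, 21, 0],
        [17, 29, 21, 100, 50],
        [21, 38, 0, 50, 100],
    ],
    dtype=float,
)

AGREEMENT_MATRICES = {
    "quality": QUALITY_AGREEMENT,
    "range": RANGE_AGREEMENT,
    "subtype": SUBTYPE_AGREEMENT,
}

DISTRIBUTIONS = {
    "quality": QUALITY_DISTRIBUTION,
    "range": RANGE_DISTRIBUTION,
    "subtype": SUBTYPE_DISTRIBUTION,
}

#: Leave-one-out SVM accuracies (percent) of the study's predictor, per
#: rater and domain.  Rater 1 had no variability in quality and was skipped.
LOO_ACCURACY = {
    "quality": {"rater_2": 75.0, "rater_3": 79.1, "rater_4": 91.6, "rater_5": 91.6},
    "range": {"rater_1": 75.0, "rater_2": 75.0, "rater_3": 50.0, "rater_4": 70.8, "rater_5": 70.8},
}
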