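import numpy as np
import pytest

from affectfar.facegrid import CellIntensitySeries, cell_means
from affectfar.features import ExpressionModel, train_expression_model
from affectfar.synthetic import generate_expression_trainingset
from affectfar.vocab import EXPRESSION_CLASSES

SMALL_SIZE = 48  # divisible by the default 8x8 grid
GRID = (8, 8)


def make_series(X, grid=(2, 2), out_size=4, patient_id=None):
    """CellIntensitySeries straight from a cells x frames matrix."""
    return CellIntensitySeries(np.asarray(X, dtype=float), grid, out_size,
                               patient_id=patient_id)


@pytest.fixture(scope="session")
def expression_model():
    """Expression model trained on a small synthetic training set (48px, 8x8)."""
    frames, labels = generate_expression_trainingset(30, SMALL_SIZE, seed=11)
    vectors = np.stack([cell_means(f, GRID) for f in frames])
    return train_expression_model(vectors, labels, grid=GRID)


@pytest.fixture
def indicator_model():
    """Hand-built model whose score for class k is the intensity of cell k.

    With frames that put their largest value in cell j, the dominating
    expression of the frame is EXPRESSION_CLASSES[j]; used to script exact
    argmax label sequences.
    """
    w = np.zeros((7, 8))
    for k in range(7):
        w[k, k] = 1.0
    return ExpressionModel(w, np.zeros(7), np.zeros(8), np.ones(8), grid=(2, 4))


def frames_for_labels(label_indices, n_cells=8, high=10.0):
    """Cells x frames matrix whose frame n peaks at cell label_indices[n]."""
    X = np.zeros((n_cells, len(label_indices)))
    for n, k in enumerate(label_indices):
        X[k, n] = high
    return X


def expr_index(name):
    return EXPRESSION_CLASSES.index(name)
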