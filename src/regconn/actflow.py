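"""Activity flow mapping: predicting node activations from connectivity.

A target node's activation is modeled as the sum of every other node's
activation weighted by its connectivity with the target,
A_hat_j = sum_{i != j} A_i W_ij. Because FC matrices carry a zero diagonal,
the matrix-vector product never lets a node predict itself.
"""

from __future__ import annotations

import numpy as np


def predict_activations(fc: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Predicted activation pattern from FC and an actual pattern.

    ``actual`` may be a length-p vector (one condition) or a p x c matrix
    (one column per condition); the output has the same shape.
    """
    fc = np.asarray(fc, dtype=float)
    A = np.asarray(actual, dtype=float)
    if fc.shape[0] != fc.shape[1]:
        raise ValueError("fc must be square")
    if A.shape[0] != fc.shape[0]:
        raise ValueError("activation length must match FC dimension")
    W = fc.copy()
    np.fill_diagonal(W, 0.0)  # enforce i != j in the flow sum
    return W.T @ A


def prediction_accuracy(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Pearson r between predicted and actual activations.

    Multi-condition inputs are pooled by concatenating the node x condition
    entries into one vector before correlating (one r per subject across
    regions and conditions).
    """
    a = np.asarray(predicted, dtype=float).ravel()
    b = np.asarray(actual, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("predicted and actual must have matching shapes")
    return float(np.corrcoef(a, b)[0, 1])
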