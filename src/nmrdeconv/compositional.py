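"""Compositional statistics on the unit simplex.

Relative concentrations live on the simplex (non-negative parts summing to
one), so central tendency is summarised by the geometric-mean *center* —
the closure of per-component geometric means — rather than the arithmetic
mean.  Mixture recovery error is reported as the mean absolute error of mole
fractions, and present/absent calls are scored by classification accuracy.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "closure",
    "center",
    "composition_mae",
    "classification_accuracy",
    "subcomposition",
]

#: Floor applied to zero parts before taking geometric means.
ZERO_FLOOR = 1e-12


def closure(v: np.ndarray) -> np.ndarray:
    """Project a non-negative vector onto the unit simplex (divide by its sum)."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("closure requires non-negative parts")
    s = v.sum()
    if s <= 0:
        raise ValueError("closure of a zero-sum vector is undefined")
    return v / s


def center(samples: np.ndarray) -> np.ndarray:
    """Geometric-mean center of N compositional samples (rows).

    Zeros are floored at ``ZERO_FLOOR`` before the geometric mean.  Because
    the closure removes any per-row scale, the input rows need not be closed.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if np.any(arr < 0):
        raise ValueError("compositional samples must be non-negative")
    g = np.exp(np.mean(np.log(np.maximum(arr, ZERO_FLOOR)), axis=0))
    return closure(g)


def composition_mae(est: np.ndarray, true: np.ndarray) -> float:
    """Mean absolute error of mole fractions, in percent.

    ``(100/D) * sum_i |x_i_est - x_i_true|`` over all D parts of the
    composition, including parts whose true fraction is zero.
    """
    est = np.asarray(est, dtype=float)
    true = np.asarray(true, dtype=float)
    if est.shape != true.shape:
        raise ValueError("compositions must have equal dimension")
    return float(100.0 * np.mean(np.abs(est - true)))


def classification_accuracy(pred_present, true_present) -> float:
    """(TP + TN) / (TP + TN + FP + FN) over present/absent calls."""
    pred = np.asarray(pred_present, dtype=bool)
    true = np.asarray(true_present, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth must have equal length")
    if pred.size == 0:
        raise ValueError("empty classification")
    return float(np.mean(pred == true))


def subcomposition(c: np.ndarray, indices) -> np.ndarray:
    """Closure of a selected subset of parts (a C-part subcomposition, C < D)."""
    c = np.asarray(c, dtype=float)
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise ValueError("subcomposition requires at least one index")
    return closure(c[idx])
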