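"""Smooth per-cohort loss functions (value + gradient) and prediction.

Both losses are in *mean* form, i.e. normalized by the cohort's sample count,
so that cohorts of different sizes contribute comparably to a joint
objective.  Intercepts are fitted but never penalized.
"""

from __future__ import annotations

import numpy as np

from .data import CoefficientModel


def least_squares_value_grad(X, y, w, c):
    """Mean-form squared-error loss.

    value = 1/(2 n) ||X w + c 1 - y||^2 ;
    grad_w = 1/n X^T (X w + c 1 - y) ; grad_c = mean residual.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float).ravel()
    if X.shape[1] != w.shape[0] or X.shape[0] != y.shape[0]:
        raise ValueError(
            f"dimension mismatch: X {X.shape}, y {y.shape}, w {w.shape}"
        )
    n = X.shape[0]
    r = X @ w + c - y
    value = float(r @ r) / (2.0 * n)
    grad_w = X.T @ r / n
    grad_c = float(r.mean())
    return value, grad_w, grad_c


def logistic_value_grad(X, y, w, c):
    """Mean logistic negative log-likelihood with labels in {-1,+1}.

    value = 1/n sum_i log(1 + exp(-y_i (x_i^T w + c))), evaluated with
    ``logaddexp`` for overflow safety.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float).ravel()
    if not set(np.unique(y)).issubset({-1.0, 1.0}):
        raise ValueError("logistic loss requires labels in {-1,+1}")
    if X.shape[1] != w.shape[0] or X.shape[0] != y.shape[0]:
        raise ValueError(
            f"dimension mismatch: X {X.shape}, y {y.shape}, w {w.shape}"
        )
    n = X.shape[0]
    m = y * (X @ w + c)
    value = float(np.logaddexp(0.0, -m).mean())
    # d/dm log(1+e^{-m}) = -sigmoid(-m)
    s = -y * _sigmoid(-m) / n
    grad_w = X.T @ s
    grad_c = float(s.sum())
    return value, grad_w, grad_c


def _sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def optimal_intercept(y, loss: str) -> float:
    """Intercept-only optimum of the mean-form loss.

    Least squares: the outcome mean.  Logistic: the log-odds of the
    positive class (requires both classes present).
    """
    y = np.asarray(y, dtype=float)
    if loss == "ls":
        return float(y.mean())
    if loss == "logistic":
        pos = int(np.count_nonzero(y > 0))
        neg = y.shape[0] - pos
        if pos == 0 or neg == 0:
            raise ValueError("logistic intercept requires both classes present")
        return float(np.log(pos / neg))
    raise ValueError(f"unknown loss {loss!r}")


def predict(model: CoefficientModel, X, task_id: str, labels: bool | None = None):
    """Linear scores X w_t + c_t for one task; optionally class labels.

    For logistic models ``labels=True`` (the default for a logistic model)
    returns labels in {-1,+1} by the sign of the score, ties mapping to +1.
    If the model records server-side standardization, it is reversed here.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(f"X must have {model.n_features} columns")
    w, c = model.column(task_id)
    if model.standardize is not None:
        mu = np.asarray(model.standardize["mean"][task_id], dtype=float)
        sd = np.asarray(model.standardize["scale"][task_id], dtype=float)
        X = (X - mu) / sd
    scores = X @ w + c
    if labels is None:
        labels = model.loss == "logistic"
    if labels:
        return np.where(scores >= 0, 1.0, -1.0)
    return scores
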