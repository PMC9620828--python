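"""Client-side penalties: proximal operators for the non-smooth terms and
gradients for the smooth ones.

The non-smooth penalty S(W) couples tasks: entrywise L1 (lasso), row-wise
L2,1 (joint feature selection) or trace norm (shared low-dimensional
subspace).  The smooth penalty is a ridge or a task-graph coupling
||W R||_F^2, with the mean-regularization graph R = I - (1/T) 11^T built in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TaskGraph:
    """Penalty-inducing linear map over tasks: penalty = ||W R||_F^2."""

    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))

    @property
    def n_tasks(self) -> int:
        return self.R.shape[0]


def mean_graph(T: int) -> TaskGraph:
    """Mean-regularization graph R = I - (1/T) 11^T.

    Idempotent and symmetric; annihilates the shared direction, so identical
    task columns are unpenalized and the penalty pulls every task toward the
    across-task mean.  T=1 yields the zero map (no penalty).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    return TaskGraph(np.eye(T) - np.ones((T, T)) / T)


def prox_l1(W, t: float):
    """Entrywise soft-threshold: sign(w) * max(|w| - t, 0)."""
    if t < 0:
        raise ValueError("threshold t must be >= 0")
    W = np.asarray(W, dtype=float)
    return np.sign(W) * np.maximum(np.abs(W) - t, 0.0)


def prox_l21(W, t: float):
    """Row-wise group soft-threshold: row *= max(1 - t/||row||_2, 0)."""
    if t < 0:
        raise ValueError("threshold t must be >= 0")
    W = np.atleast_2d(np.asarray(W, dtype=float))
    norms = np.linalg.norm(W, axis=1)
    shrink = np.zeros_like(norms)
    nz = norms > 0
    shrink[nz] = np.maximum(1.0 - t / norms[nz], 0.0)
    return W * shrink[:, None]


def prox_trace(W, t: float):
    """Singular-value soft-threshold: U max(S - t, 0) V^T."""
    if t < 0:
        raise ValueError("threshold t must be >= 0")
    W = np.atleast_2d(np.asarray(W, dtype=float))
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    s = np.maximum(s - t, 0.0)
    return (U * s) @ Vt


_PROX = {"l1": prox_l1, "l21": prox_l21, "trace": prox_trace}


def prox(kind: str, W, t: float):
    """Dispatch to the proximal operator of penalty ``kind``."""
    try:
        return _PROX[kind](W, t)
    except KeyError:
        raise ValueError(f"unknown penalty kind {kind!r}") from None


def penalty_value(kind: str, W) -> float:
    """Value of the non-smooth penalty: ||W||_1, sum of row L2 norms, or
    the sum of singular values."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if kind == "l1":
        return float(np.abs(W).sum())
    if kind == "l21":
        return float(np.linalg.norm(W, axis=1).sum())
    if kind == "trace":
        return float(np.linalg.svd(W, compute_uv=False).sum())
    raise ValueError(f"unknown penalty kind {kind!r}")


def graph_penalty_value_grad(W, R):
    """Task-graph coupling: value = ||W R||_F^2, grad = 2 W R R^T."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    R = R.R if isinstance(R, TaskGraph) else np.atleast_2d(np.asarray(R, dtype=float))
    if R.shape[0] != W.shape[1]:
        raise ValueError(
            f"graph has {R.shape[0]} task rows but W has {W.shape[1]} task columns"
        )
    WR = W @ R
    return float(np.sum(WR * WR)), 2.0 * WR @ R.T


def ridge_value_grad(W):
    """Ridge stabilizer: value = 1/2 ||W||_F^2, grad = W."""
    W = np.asarray(W, dtype=float)
    return 0.5 * float(np.sum(W * W)), W.copy()
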