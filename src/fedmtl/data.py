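"""Core containers: one cohort's dataset and the exchanged coefficient model."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class TaskDataset:
    """One cohort's samples-by-features matrix with its outcome vector.

    A ``TaskDataset`` lives on exactly one server node of a federation.
    Continuous outcomes are arbitrary reals; binary outcomes are stored
    internally as labels in ``{-1, +1}`` (``{0, 1}`` is accepted on input
    and converted).

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
    y : ndarray of shape (n_samples,)
    feature_names : sequence of str, one per column of ``X``
    task_id : str
        Identifier of the cohort / prediction task.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    task_id: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        if self.y.ndim != 1 or self.y.shape[0] != self.X.shape[0]:
            raise ValueError(
                f"y has length {self.y.shape[0] if self.y.ndim == 1 else self.y.shape}, "
                f"expected {self.X.shape[0]}"
            )
        if self.X.shape[0] < 1 or self.X.shape[1] < 1:
            raise ValueError("need at least one sample and one feature")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError(f"dataset {self.task_id!r} contains missing/non-finite values")
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {self.X.shape[1]} columns"
            )
        # {0,1} labels are converted to the internal {-1,+1} encoding
        if set(np.unique(self.y)) == {0.0, 1.0}:
            self.y = np.where(self.y > 0, 1.0, -1.0)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def is_binary(self) -> bool:
        return set(np.unique(self.y)).issubset({-1.0, 1.0})


@dataclass
class CoefficientModel:
    """Feature-by-task coefficient matrix plus per-task intercepts.

    This is the unit exchanged between client and servers during supervised
    fitting: column ``t`` of ``W`` is the coefficient vector for task ``t``
    and ``c[t]`` its (never penalized) intercept.  ``standardize`` optionally
    records per-task feature means/scales applied server-side during fitting
    so that prediction can reverse them.
    """

    W: np.ndarray
    c: np.ndarray
    feature_names: list[str]
    task_ids: list[str]
    loss: str = "ls"
    standardize: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if self.W.ndim != 2:
            raise ValueError("W must be a matrix (features x tasks)")
        self.c = np.atleast_1d(np.asarray(self.c, dtype=float))
        if self.c.shape[0] != self.W.shape[1]:
            raise ValueError("one intercept per task required")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.c))):
            raise ValueError("coefficient model contains non-finite entries")
        self.feature_names = [str(f) for f in self.feature_names]
        self.task_ids = [str(t) for t in self.task_ids]
        if len(self.feature_names) != self.W.shape[0]:
            raise ValueError("feature_names length must match rows of W")
        if len(self.task_ids) != self.W.shape[1]:
            raise ValueError("task_ids length must match columns of W")

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.W.shape[1]

    def column(self, task_id: str) -> tuple[np.ndarray, float]:
        """Coefficient vector and intercept for one task."""
        try:
            t = self.task_ids.index(task_id)
        except ValueError:
            raise KeyError(f"unknown task_id {task_id!r}") from None
        return self.W[:, t], float(self.c[t])


def validate_feature_alignment(datasets: Sequence[TaskDataset]) -> list[str]:
    """Check all datasets share one feature list (same names, same order).

    Returns the common feature list; raises ``ValueError`` naming the first
    offending cohort otherwise.
    """
    if len(datasets) == 0:
        raise ValueError("at least one dataset is required")
    ref = datasets[0].feature_names
    for d in datasets[1:]:
        if d.feature_names != ref:
            raise ValueError(
                f"feature list of cohort {d.task_id!r} does not match "
                f"cohort {datasets[0].task_id!r} (names must agree in order)"
            )
    return list(ref)
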