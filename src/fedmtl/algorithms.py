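"""User-facing federated fits and cross-validation.

Four supervised algorithms compose the losses, penalties and solver:

``fit_l21``
    Multi-task fit with the row-coupling L2,1 penalty — features are
    selected jointly across cohorts, signs may differ per cohort.
``fit_trace``
    Multi-task fit with the trace-norm penalty — coefficient vectors share
    a low-dimensional subspace.
``fit_net``
    Multi-task fit with a sparse L1 penalty plus a smooth task-graph
    coupling ||W R||_F^2 (mean-regularization graph by default).
``fit_lasso``
    Federated lasso: a single coefficient vector over the union of all
    servers' samples (classical federated ML baseline).

``cross_validate`` selects the penalty weight on a warm-started
regularization path with server-local folds: samples never move between
servers; held-out metrics are computed server-side and aggregated.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .federation import FederationSession, Request
from .regularizers import TaskGraph, mean_graph
from .solver import (
    ProblemSpec,
    RegularizationPath,
    SolveResult,
    SolverOptions,
    fista_solve,
    lambda_max,
    lambda_sequence,
    solve_path,
)


def _fit(problem: ProblemSpec, lam, options: SolverOptions | None, depth=20,
         min_ratio=0.01):
    """Single fit for a scalar lam; warm-started path for "path"/sequence."""
    if isinstance(lam, str) and lam == "path":
        lam = lambda_sequence(lambda_max(problem), min_ratio=min_ratio, depth=depth)
    if np.ndim(lam) > 0:
        return solve_path(problem, np.asarray(lam, dtype=float), options)
    return fista_solve(replace(problem, lam=float(lam)), options)


def fit_l21(
    session: FederationSession,
    loss: str = "ls",
    lam: float | str | np.ndarray = "path",
    C: float = 0.0,
    options: SolverOptions | None = None,
    **path_kw,
) -> SolveResult | RegularizationPath:
    """Joint feature selection across cohorts via the L2,1 row penalty.

    ``lam`` may be a scalar, an explicit descending sequence, or ``"path"``
    to fit a warm-started log-scale sequence from the estimated lambda_max.
    ``C`` adds an optional ridge stabilizer.
    """
    problem = ProblemSpec(
        session=session, loss=loss, penalty="l21",
        smooth="ridge" if C > 0 else "none", C=C, coupling="multi_task",
    )
    return _fit(problem, lam, options, **path_kw)


def fit_trace(
    session: FederationSession,
    loss: str = "ls",
    lam: float | str | np.ndarray = "path",
    C: float = 0.0,
    options: SolverOptions | None = None,
    **path_kw,
) -> SolveResult | RegularizationPath:
    """Shared low-rank structure across cohorts via the trace-norm penalty."""
    problem = ProblemSpec(
        session=session, loss=loss, penalty="trace",
        smooth="ridge" if C > 0 else "none", C=C, coupling="multi_task",
    )
    return _fit(problem, lam, options, **path_kw)


def fit_net(
    session: FederationSession,
    loss: str = "ls",
    graph: TaskGraph | None = None,
    lam: float | str | np.ndarray = "path",
    C: float = 0.0,
    ridge_eps: float = 0.0,
    options: SolverOptions | None = None,
    **path_kw,
) -> SolveResult | RegularizationPath:
    """Sparse fit with a smooth task-network coupling C * ||W R||_F^2.

    The default graph is the mean-regularization map R = I - (1/T) 11^T,
    which pulls every cohort's coefficients toward the across-task mean.
    With ``C=0`` the tasks decouple into independent lasso fits.
    """
    if graph is None:
        graph = mean_graph(session.n_servers)
    problem = ProblemSpec(
        session=session, loss=loss, penalty="l1", smooth="graph", C=C,
        graph=graph, ridge_eps=ridge_eps, coupling="multi_task",
    )
    return _fit(problem, lam, options, **path_kw)


def fit_lasso(
    session: FederationSession,
    loss: str = "ls",
    lam: float | str | np.ndarray = "path",
    options: SolverOptions | None = None,
    **path_kw,
) -> SolveResult | RegularizationPath:
    """Federated lasso: one sparse model over the union of all cohorts."""
    problem = ProblemSpec(
        session=session, loss=loss, penalty="l1", coupling="pooled",
    )
    return _fit(problem, lam, options, **path_kw)


_ALGORITHMS = {
    "l21": fit_l21,
    "trace": fit_trace,
    "net": fit_net,
    "lasso": fit_lasso,
}


def _problem_for(algorithm: str, session, loss, C, fold=None) -> ProblemSpec:
    if algorithm == "l21":
        return ProblemSpec(session=session, loss=loss, penalty="l21",
                           smooth="ridge" if C > 0 else "none", C=C,
                           coupling="multi_task", fold=fold)
    if algorithm == "trace":
        return ProblemSpec(session=session, loss=loss, penalty="trace",
                           smooth="ridge" if C > 0 else "none", C=C,
                           coupling="multi_task", fold=fold)
    if algorithm == "net":
        return ProblemSpec(session=session, loss=loss, penalty="l1",
                           smooth="graph", C=C, graph=mean_graph(session.n_servers),
                           coupling="multi_task", fold=fold)
    if algorithm == "lasso":
        return ProblemSpec(session=session, loss=loss, penalty="l1",
                           coupling="pooled", fold=fold)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _holdout_metric(session, problem: ProblemSpec, model, fold_spec, metric) -> float:
    """Server-side held-out evaluation, aggregated to one mean metric."""
    reqs = {}
    for t, sid in enumerate(session.server_ids):
        col = model.W[:, t] if problem.coupling == "multi_task" else model.W[:, 0]
        c = model.c[t] if problem.coupling == "multi_task" else model.c[0]
        reqs[sid] = Request(
            "summary_stats",
            {
                "stat": "cv_metric",
                "w": col,
                "c": float(c),
                "metric": metric,
                "fold": {**fold_spec, "part": "test"},
            },
        )
    resp = session.broadcast(reqs)
    total = sum(resp[sid]["metric_sum"] for sid in session.server_ids)
    count = sum(resp[sid]["n"] for sid in session.server_ids)
    return total / count


def cross_validate(
    session: FederationSession,
    algorithm: str = "l21",
    loss: str = "ls",
    k_folds: int = 5,
    sequence: np.ndarray | None = None,
    metric: str | None = None,
    C: float = 0.0,
    options: SolverOptions | None = None,
    seed: int = 0,
    depth: int = 20,
    min_ratio: float = 0.01,
):
    """K-fold cross-validation over a warm-started lambda path.

    Folds are drawn within each server (seeded; stratified for binary
    outcomes), so no sample ever leaves its server: each fold's models are
    fitted on the in-fold union and scored server-side on the held-out
    union.  Returns ``{"lam_best", "cv_table", "model"}`` where ``model``
    is the final refit on all data at the selected lambda.

    The default metric is mean squared error for continuous outcomes and
    the misclassification rate for binary ones.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    for sid, n in session.sizes().items():
        if n < k_folds:
            raise ValueError(f"server {sid!r} has {n} samples < {k_folds} folds")
    if metric is None:
        metric = "mse" if loss == "ls" else "misclassification"

    base = _problem_for(algorithm, session, loss, C)
    if sequence is None:
        sequence = lambda_sequence(lambda_max(base), min_ratio=min_ratio, depth=depth)
    sequence = np.asarray(sequence, dtype=float)

    scores = np.zeros((k_folds, len(sequence)))
    for fold in range(k_folds):
        fold_spec = {"k_folds": k_folds, "fold": fold, "seed": seed}
        problem = replace(base, fold={**fold_spec, "part": "train"})
        path = solve_path(problem, sequence, options)
        for j, res in enumerate(path.results):
            scores[fold, j] = _holdout_metric(session, problem, res.model,
                                              fold_spec, metric)
    mean_scores = scores.mean(axis=0)
    best = int(np.argmin(mean_scores))  # ties -> largest lambda (first index)
    lam_best = float(sequence[best])
    final = fista_solve(replace(base, lam=lam_best), options)
    cv_table = pd.DataFrame(
        {
            "lambda": sequence,
            "mean_metric": mean_scores,
            **{f"fold{f}": scores[f] for f in range(k_folds)},
        }
    )
    return {"lam_best": lam_best, "cv_table": cv_table, "model": final}
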