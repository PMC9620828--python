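"""Federated accelerated proximal gradient solver.

All supervised fits minimize one objective over the federation,

    min_{W,c}  L(W,c) + lam * S(W) + C * N(W)

where L is the sum of per-server smooth losses (one coefficient column per
server in ``multi_task`` coupling; a single shared column with sample-size
weighted aggregation in ``pooled`` coupling), S is a non-smooth coupling
penalty with a cheap proximal operator, and N is a smooth stabilizer.
Gradients of L are computed server-side and aggregated by the client; each
gradient or objective evaluation is one synchronization round.

The solver is the monotone variant of FISTA (accelerated proximal gradient
with backtracking line search): the candidate from the momentum point is
only accepted when it does not increase the objective, so the recorded
objective history is non-increasing by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .data import CoefficientModel
from .federation import FederationSession, Request, UNLIMITED
from .regularizers import (
    TaskGraph,
    graph_penalty_value_grad,
    penalty_value,
    prox,
    ridge_value_grad,
)

POOLED_TASK = "pooled"  #: task id of the single column fitted under pooled coupling


@dataclass
class ProblemSpec:
    """One federated optimization problem.

    coupling:
        ``"multi_task"`` fits one coefficient column per server (T = number
        of servers); ``"pooled"`` fits a single column over the union of all
        servers' samples (classical federated ML).
    smooth:
        ``"none"``, ``"ridge"`` (N = 1/2 ||W||_F^2) or ``"graph"``
        (N = ||W R||_F^2 + ridge_eps ||W||_F^2 with task graph R).
    fold:
        Optional cross-validation row restriction forwarded to the servers,
        ``{"k_folds": int, "fold": int, "seed": int, "part": "train"}``.
    """

    session: FederationSession
    loss: str = "ls"
    penalty: str = "l21"
    lam: float = 0.0
    smooth: str = "none"
    C: float = 0.0
    graph: TaskGraph | None = None
    ridge_eps: float = 0.0
    coupling: str = "multi_task"
    fit_intercept: bool = True
    standardize: bool = False
    fold: dict | None = None

    def __post_init__(self) -> None:
        if self.lam < 0 or self.C < 0:
            raise ValueError("lam and C must be >= 0")
        if self.coupling not in ("multi_task", "pooled"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.smooth not in ("none", "ridge", "graph"):
            raise ValueError(f"unknown smooth penalty {self.smooth!r}")
        if self.smooth == "graph" and self.graph is None:
            raise ValueError("graph smooth penalty requires a TaskGraph")

    @property
    def n_tasks(self) -> int:
        return self.session.n_servers if self.coupling == "multi_task" else 1

    @property
    def task_ids(self) -> list[str]:
        if self.coupling == "multi_task":
            return self.session.server_ids
        return [POOLED_TASK]

    @property
    def n_features(self) -> int:
        return len(self.session.feature_names)


@dataclass
class SolverOptions:
    max_iter: int = 1000
    tol: float = 1e-5
    rule: str = "objective_rel"  # objective_rel | param_rel | iter_only
    step: float = 1.0  # initial step size (inverse Lipschitz estimate)
    shrink: float = 0.5  # step multiplier on a failed line-search probe
    digits: int | None = UNLIMITED  # payload quantization, overrides the policy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol < 0:
            raise ValueError("tol must be >= 0")
        if not (0.0 < self.shrink < 1.0):
            raise ValueError("shrink must be in (0, 1)")
        if self.rule not in ("objective_rel", "param_rel", "iter_only"):
            raise ValueError(f"unknown termination rule {self.rule!r}")


@dataclass
class SolveResult:
    model: CoefficientModel
    objective: list[float]
    n_iter: int
    comm: dict
    lam: float
    converged: bool
    retries: int
    rounds_used: int

    def to_dict(self) -> dict:
        return {
            "lam": self.lam,
            "W": self.model.W.tolist(),
            "c": self.model.c.tolist(),
            "objective": list(self.objective),
            "n_iter": self.n_iter,
            "converged": self.converged,
            "comm": self.comm,
        }


@dataclass
class RegularizationPath:
    """Descending lambda sequence with one warm-started fit per value."""

    lambdas: np.ndarray
    results: list[SolveResult]
    warm_started: bool = True

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if np.any(np.diff(self.lambdas) >= 0):
            raise ValueError("lambda sequence must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, i: int) -> SolveResult:
        return self.results[i]

    def to_dict(self) -> dict:
        return {
            "lambdas": self.lambdas.tolist(),
            "warm_started": self.warm_started,
            "results": [r.to_dict() for r in self.results],
        }


# ---------------------------------------------------------------------------
# smooth part: federated loss + client-side smooth penalty


def _effective_digits(problem: ProblemSpec, options: SolverOptions | None):
    if options is not None and options.digits is not UNLIMITED:
        return options.digits
    return problem.session.policy.digits


def _loss_round(
    problem: ProblemSpec,
    W: np.ndarray,
    c: np.ndarray,
    want_grad: bool,
    digits=UNLIMITED,
):
    """One broadcast: per-server loss (and gradient) at quantized (W, c)."""
    session = problem.session
    kind = "loss_value_grad" if want_grad else "loss_value"
    reqs = {}
    for t, sid in enumerate(session.server_ids):
        col = W[:, t] if problem.coupling == "multi_task" else W[:, 0]
        cc = c[t] if problem.coupling == "multi_task" else c[0]
        payload = {
            "loss": problem.loss,
            "w": session.quantize_payload(col, digits),
            "c": float(session.quantize_payload(float(cc), digits)),
        }
        if problem.fold is not None:
            payload["fold"] = problem.fold
        if problem.standardize:
            payload["standardize"] = True
        reqs[sid] = Request(kind, payload)
    resp = session.broadcast(reqs)
    p, T = problem.n_features, problem.n_tasks
    grad_W = np.zeros((p, T)) if want_grad else None
    grad_c = np.zeros(T) if want_grad else None
    if problem.coupling == "multi_task":
        value = 0.0
        for t, sid in enumerate(session.server_ids):
            r = resp[sid]
            value += r["value"]
            if want_grad:
                grad_W[:, t] = r["grad_w"]
                grad_c[t] = r["grad_c"]
    else:
        N = sum(resp[sid]["n"] for sid in session.server_ids)
        value = 0.0
        for sid in session.server_ids:
            r = resp[sid]
            wgt = r["n"] / N
            value += wgt * r["value"]
            if want_grad:
                grad_W[:, 0] += wgt * r["grad_w"]
                grad_c[0] += wgt * r["grad_c"]
    return (value, grad_W, grad_c) if want_grad else value


def _smooth_penalty(problem: ProblemSpec, W: np.ndarray, want_grad: bool):
    if problem.C == 0.0 or problem.smooth == "none":
        return (0.0, np.zeros_like(W)) if want_grad else 0.0
    if problem.smooth == "ridge":
        v, g = ridge_value_grad(W)
    else:  # graph
        v, g = graph_penalty_value_grad(W, problem.graph)
        if problem.ridge_eps > 0:
            v += problem.ridge_eps * float(np.sum(W * W))
            g = g + 2.0 * problem.ridge_eps * W
    if want_grad:
        return problem.C * v, problem.C * g
    return problem.C * v


def smooth_value_grad(problem: ProblemSpec, W, c, options: SolverOptions | None = None):
    """Value and gradient of the smooth part L + C*N at (W, c).

    Costs exactly one synchronization round (one access per server).
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    c = np.atleast_1d(np.asarray(c, dtype=float))
    digits = _effective_digits(problem, options)
    value, grad_W, grad_c = _loss_round(problem, W, c, want_grad=True, digits=digits)
    pv, pg = _smooth_penalty(problem, W, want_grad=True)
    return value + pv, grad_W + pg, grad_c


def _smooth_value(problem, W, c, digits):
    value = _loss_round(problem, W, c, want_grad=False, digits=digits)
    return value + _smooth_penalty(problem, W, want_grad=False)


def _initial_intercepts(problem: ProblemSpec) -> np.ndarray:
    """Per-task (or pooled) intercept-only optimum, from one summary round."""
    session = problem.session
    resp = session.broadcast(Request("summary_stats", {"stat": "basic"}))
    ids = session.server_ids
    if problem.loss == "ls":
        if problem.coupling == "multi_task":
            return np.array([resp[sid]["y_mean"] for sid in ids])
        N = sum(resp[sid]["n"] for sid in ids)
        return np.array([sum(resp[sid]["n"] * resp[sid]["y_mean"] for sid in ids) / N])
    # logistic: log odds of the positive class
    if problem.coupling == "multi_task":
        return np.array(
            [math.log(resp[sid]["y_pos"] / resp[sid]["y_neg"]) for sid in ids]
        )
    pos = sum(resp[sid]["y_pos"] for sid in ids)
    neg = sum(resp[sid]["y_neg"] for sid in ids)
    return np.array([math.log(pos / neg)])


# ---------------------------------------------------------------------------
# lambda scale


def lambda_max(problem: ProblemSpec) -> float:
    """Smallest lam for which the all-zero W (intercept-only fit) is optimal.

    From the first-order (subgradient) optimality condition at W = 0 with the
    intercept at its unpenalized optimum: the dual norm of the smooth-loss
    gradient — max |entry| for L1, max row L2 norm for L2,1, and the largest
    singular value for the trace norm.
    """
    c0 = _initial_intercepts(problem) if problem.fit_intercept else np.zeros(problem.n_tasks)
    W0 = np.zeros((problem.n_features, problem.n_tasks))
    _, G, _ = _loss_round(problem, W0, c0, want_grad=True, digits=UNLIMITED)
    if problem.penalty == "l1":
        return float(np.abs(G).max())
    if problem.penalty == "l21":
        return float(np.linalg.norm(G, axis=1).max())
    if problem.penalty == "trace":
        return float(np.linalg.svd(G, compute_uv=False).max())
    raise ValueError(f"unknown penalty {problem.penalty!r}")


def lambda_sequence(lam_max: float, min_ratio: float = 0.01, depth: int = 20) -> np.ndarray:
    """Geometric (log-scale) sequence from lam_max down to min_ratio*lam_max."""
    if not (0.0 < min_ratio < 1.0):
        raise ValueError("min_ratio must be in (0, 1)")
    if depth < 2:
        raise ValueError("depth must be >= 2")
    if lam_max <= 0:
        raise ValueError("lam_max must be > 0")
    return np.geomspace(lam_max, lam_max * min_ratio, depth)


# ---------------------------------------------------------------------------
# termination


def check_termination(history: Sequence, rule: str, tol: float) -> bool:
    """Relaxable termination rules.

    ``objective_rel`` expects a history of objective values and triggers when
    |f_k - f_{k-1}| / max(|f_{k-1}|, 1) <= tol; ``param_rel`` expects a
    history of coefficient matrices and uses the analogous relative
    Frobenius change; ``iter_only`` never triggers (max_iter governs).
    Histories shorter than 2 never terminate.
    """
    if rule == "iter_only":
        return False
    if len(history) < 2:
        return False
    if rule == "objective_rel":
        prev, cur = float(history[-2]), float(history[-1])
        return abs(cur - prev) / max(abs(prev), 1.0) <= tol
    if rule == "param_rel":
        prev = np.asarray(history[-2], dtype=float)
        cur = np.asarray(history[-1], dtype=float)
        return float(np.linalg.norm(cur - prev)) / max(float(np.linalg.norm(prev)), 1.0) <= tol
    raise ValueError(f"unknown termination rule {rule!r}")


# ---------------------------------------------------------------------------
# monotone FISTA


def fista_solve(
    problem: ProblemSpec,
    options: SolverOptions | None = None,
    W0: np.ndarray | None = None,
    c0: np.ndarray | None = None,
) -> SolveResult:
    """Monotone FISTA with backtracking line search on the federated objective.

    Each iteration evaluates the smooth gradient at the momentum point (one
    round) and the smooth value at each proximal candidate (one round per
    line-search probe).  The returned objective history is non-increasing.
    """
    options = options or SolverOptions()
    session = problem.session
    digits = _effective_digits(problem, options)
    p, T = problem.n_features, problem.n_tasks
    log0 = session.log.snapshot()

    if W0 is None:
        x_W = np.zeros((p, T))
    else:
        x_W = np.array(W0, dtype=float, copy=True).reshape(p, T)
    if c0 is not None:
        x_c = np.array(c0, dtype=float, copy=True).reshape(T)
    elif problem.fit_intercept:
        x_c = _initial_intercepts(problem)
    else:
        x_c = np.zeros(T)

    lam = problem.lam
    S = lambda W: penalty_value(problem.penalty, W) if lam > 0 else 0.0

    y_W, y_c = x_W.copy(), x_c.copy()
    f_y, g_W, g_c = smooth_value_grad(problem, y_W, y_c, options)
    f_x = f_y  # x == y initially
    F_x = f_x + lam * S(x_W)
    history = [F_x]
    L = 1.0 / options.step
    t_mom = 1.0
    total_retries = 0
    converged = False
    n_iter = 0
    # with finite-precision payloads a sufficient decrease smaller than the
    # wire granularity cannot be certified; allow for it in the line search
    quant_slack = 0.0
    if digits is not UNLIMITED:
        quant_slack = (session.n_servers + 1) * 10.0 ** (-int(digits))

    for n_iter in range(1, options.max_iter + 1):
        # backtracking line search from the momentum point
        while True:
            z_W = prox(problem.penalty, y_W - g_W / L, lam / L)
            z_c = y_c - g_c / L if problem.fit_intercept else y_c
            f_z = _smooth_value(problem, z_W, z_c, digits)
            dW, dc = z_W - y_W, z_c - y_c
            quad = (
                f_y
                + float(np.sum(g_W * dW))
                + float(g_c @ dc)
                + 0.5 * L * (float(np.sum(dW * dW)) + float(dc @ dc))
            )
            if f_z <= quad + 1e-12 * max(abs(f_y), 1.0) + quant_slack:
                break
            L /= options.shrink
            total_retries += 1
            if L > 1e18:
                raise FloatingPointError(
                    "line search failed: step shrank below 1e-18 "
                    f"(objective {f_z!r}); the problem may be badly scaled"
                )
        if not np.isfinite(f_z):
            raise FloatingPointError("non-finite objective encountered")

        F_z = f_z + lam * S(z_W)
        accepted = F_z <= F_x
        t_next = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_mom * t_mom))
        if accepted:
            x_prev_W, x_prev_c = x_W, x_c
            x_W, x_c, F_x = z_W, z_c, F_z
            coef = (t_mom - 1.0) / t_next
            y_W = x_W + coef * (x_W - x_prev_W)
            y_c = x_c + coef * (x_c - x_prev_c)
        else:
            # monotone safeguard: keep x, steer momentum toward the candidate
            x_prev_W = None
            coef = t_mom / t_next
            y_W = x_W + coef * (z_W - x_W)
            y_c = x_c + coef * (z_c - x_c)
        t_mom = t_next
        history.append(F_x)

        if accepted and options.rule != "iter_only":
            if options.rule == "objective_rel":
                terminate = check_termination(history, "objective_rel", options.tol)
            else:
                terminate = check_termination([x_prev_W, x_W], "param_rel", options.tol)
            if terminate:
                converged = True
                break

        f_y, g_W, g_c = smooth_value_grad(problem, y_W, y_c, options)

    model = CoefficientModel(
        W=x_W,
        c=x_c,
        feature_names=list(session.feature_names),
        task_ids=problem.task_ids,
        loss=problem.loss,
        standardize=_standardization_record(problem) if problem.standardize else None,
    )
    end = session.log
    comm = {
        "rounds": end.rounds - log0.rounds,
        "total_accesses": end.total_accesses() - log0.total_accesses(),
        "per_server_accesses": {
            sid: end.accesses.get(sid, 0) - log0.accesses.get(sid, 0)
            for sid in session.server_ids
        },
    }
    return SolveResult(
        model=model,
        objective=history,
        n_iter=n_iter,
        comm=comm,
        lam=lam,
        converged=converged,
        retries=total_retries,
        rounds_used=comm["rounds"],
    )


def _standardization_record(problem: ProblemSpec) -> dict:
    """Per-task standardization constants for prediction-time reversal.

    Column means/scales are aggregate statistics and may cross the boundary.
    """
    session = problem.session
    resp = session.broadcast(Request("summary_stats", {"stat": "standardization"}))
    mean = {sid: resp[sid]["x_col_mean"] for sid in session.server_ids}
    scale = {sid: resp[sid]["x_col_scale"] for sid in session.server_ids}
    if problem.coupling == "pooled":
        # pooled model standardizes with the union constants
        sizes = session.sizes()
        N = sum(sizes.values())
        mu = sum(sizes[s] * np.asarray(mean[s]) for s in mean) / N
        sd = sum(sizes[s] * np.asarray(scale[s]) for s in scale) / N
        return {"mean": {POOLED_TASK: mu}, "scale": {POOLED_TASK: sd}}
    return {"mean": mean, "scale": scale}


def solve_path(
    problem: ProblemSpec,
    sequence: Sequence[float],
    options: SolverOptions | None = None,
) -> RegularizationPath:
    """Fit the whole descending lambda sequence, warm-starting each fit from
    the previous solution; the first fit starts from zero."""
    sequence = np.asarray(sequence, dtype=float)
    if np.any(np.diff(sequence) >= 0):
        raise ValueError("lambda sequence must be strictly decreasing")
    results: list[SolveResult] = []
    W0 = None
    c0 = None
    for lam in sequence:
        res = fista_solve(replace(problem, lam=float(lam)), options, W0=W0, c0=c0)
        results.append(res)
        W0 = res.model.W
        c0 = res.model.c
    return RegularizationPath(lambdas=sequence, results=results, warm_started=True)
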