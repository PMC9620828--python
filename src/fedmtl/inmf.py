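"""Federated integrative non-negative matrix factorization.

Each cohort's non-negative matrix X_k (samples x genes) is factorized as

    X_k  ~  W_k (H + V_k),     all factors >= 0,

where H (rank x genes) is the shared metagene matrix, V_k the cohort-specific
metagenes and W_k the sample loadings.  The joint objective is

    sum_k ||X_k - W_k (H + V_k)||_F^2  +  lam_het * sum_k ||W_k V_k||_F^2,

minimized by alternating multiplicative updates.  W_k and V_k are updated
locally on each server and never cross the network under the default policy;
the client updates H from server-aggregated numerator/denominator matrices
(one access per server per round, independent of the data size).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .federation import FederationSession, Request

_EPS = 1e-12


@dataclass
class INMFState:
    """Client-visible iNMF state: the shared factor plus bookkeeping.

    The cohort-specific factors of the same model live on the servers,
    keyed by ``start``.
    """

    H: np.ndarray
    lam_het: float
    start: int = 0
    objective_history: list[float] = field(default_factory=list)


@dataclass
class INMFModel:
    """Fitted federated iNMF model (client side).

    Under the shared-only policy the client-side model contains the shared
    metagene matrix ``H``, the scalar objective and bookkeeping — never the
    cohort-specific factors.
    """

    H: np.ndarray
    rank: int
    lam_het: float
    objective: float
    objective_history: list[float]
    n_iter: int
    start: int
    seed: int
    feature_names: list[str]

    @property
    def state(self) -> INMFState:
        return INMFState(H=self.H, lam_het=self.lam_het, start=self.start,
                         objective_history=list(self.objective_history))


def _data_scale(session: FederationSession, rank: int) -> float:
    """Global mean of the stacked data divided by the rank (init scale)."""
    resp = session.broadcast(Request("summary_stats", {"stat": "basic"}))
    total = sum(r["x_sum"] for r in resp.values())
    entries = sum(r["x_n_entries"] for r in resp.values())
    return (total / entries) / rank


def _init_start(session, rank, lam_het, start, seeds, scale) -> INMFState:
    """One round: client draws H, each server draws its local W_k, V_k."""
    p = len(session.feature_names)
    client_seed, server_seeds = seeds
    rng = np.random.default_rng(client_seed)
    H = rng.uniform(0.0, 1.0, size=(rank, p)) * scale
    reqs = {
        sid: Request(
            "inmf_local_update",
            {"start": start,
             "init": {"rank": rank, "seed": int(server_seeds[i]), "scale": scale}},
        )
        for i, sid in enumerate(session.server_ids)
    }
    session.broadcast(reqs)
    return INMFState(H=H, lam_het=lam_het, start=start)


def inmf_update_round(session: FederationSession, state: INMFState) -> INMFState:
    """One alternating-update round; exactly one access per server.

    Each server multiplicatively updates its local W_k and V_k against the
    current H and returns the r x p numerator/denominator statistics
    A_k = W_k^T X_k and B_k = W_k^T W_k (H + V_k) plus its local objective;
    the client then updates H <- H * (sum A_k) / (sum B_k).  The recorded
    objective (local losses at the incoming H) is non-increasing over rounds.
    """
    req = Request(
        "inmf_local_update",
        {"start": state.start, "H": state.H, "lam_het": state.lam_het},
    )
    resp = session.broadcast(req)
    A = sum(np.asarray(r["A"], dtype=float) for r in resp.values())
    B = sum(np.asarray(r["B"], dtype=float) for r in resp.values())
    H = state.H * (A / (B + _EPS))
    obj = float(sum(r["objective_local"] for r in resp.values()))
    hist = state.objective_history + [obj]
    return INMFState(H=H, lam_het=state.lam_het, start=state.start,
                     objective_history=hist)


def inmf_objective(session: FederationSession, state: INMFState) -> float:
    """Exact objective at the current state; one access per server."""
    req = Request(
        "inmf_H_stats",
        {"start": state.start, "H": state.H, "lam_het": state.lam_het},
    )
    resp = session.broadcast(req)
    return float(sum(r["objective_local"] for r in resp.values()))


def fit_inmf(
    session: FederationSession,
    rank: int,
    lam_het: float = 1.0,
    n_starts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> INMFModel:
    """Fit federated iNMF, keeping the best of ``n_starts`` random starts.

    Every start runs alternating multiplicative updates until the relative
    objective change drops below ``tol`` or ``max_iter`` rounds; the start
    with the smallest final (exact) objective wins and its server-local
    factors are retained on the servers.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if lam_het < 0:
        raise ValueError("lam_het must be >= 0")
    scale = _data_scale(session, rank)
    master = np.random.default_rng(seed)
    best: tuple[float, INMFState, int] | None = None
    for start in range(n_starts):
        seeds = (
            int(master.integers(2**31)),
            [int(master.integers(2**31)) for _ in session.server_ids],
        )
        state = _init_start(session, rank, lam_het, start, seeds, scale)
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            state = inmf_update_round(session, state)
            h = state.objective_history
            if len(h) >= 2 and abs(h[-1] - h[-2]) <= tol * max(abs(h[-2]), 1.0):
                break
        final = inmf_objective(session, state)
        if best is None or final < best[0]:
            best = (final, state, n_iter)
    final_obj, state, n_iter = best
    # keep only the winning start's factors on the servers
    session.broadcast(
        Request("inmf_local_update", {"select_start": state.start})
    )
    return INMFModel(
        H=state.H,
        rank=rank,
        lam_het=lam_het,
        objective=final_obj,
        objective_history=list(state.objective_history),
        n_iter=n_iter,
        start=state.start,
        seed=seed,
        feature_names=list(session.feature_names),
    )


def _select_by_score(score: np.ndarray, names: list[str], top_k, threshold) -> list[str]:
    if top_k is not None:
        order = np.lexsort((np.arange(score.size), -score))
        idx = np.sort(order[: int(top_k)])
    else:
        idx = np.flatnonzero(score > threshold)
    return [names[i] for i in idx]


def extract_signatures(
    session: FederationSession,
    model: INMFModel,
    top_k: int | None = None,
) -> dict:
    """Shared and cohort-specific gene sets from a fitted model.

    The shared set comes from H client-side: a gene is selected when its
    maximum metagene weight exceeds mean(H) + 2 sd(H) (or the ``top_k``
    genes by that score).  The specific set of each cohort is computed
    *server-side* from V_k under the same rule and returned as gene names
    only, so factor values never cross the boundary.
    """
    H = model.H
    score = H.max(axis=0)
    thr = float(H.mean() + 2.0 * H.std())
    shared = _select_by_score(score, model.feature_names, top_k, thr)
    req = Request(
        "summary_stats",
        {"stat": "inmf_specific_genes", "start": model.start, "top_k": top_k},
    )
    resp = session.broadcast(req)
    specific = {sid: list(resp[sid]["genes"]) for sid in session.server_ids}
    return {"shared": shared, "specific": specific}


def select_rank(
    session: FederationSession,
    rank_candidates,
    lam_het: float = 1.0,
    n_starts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> int:
    """Pick the factorization rank at the elbow of the objective curve.

    Fits every candidate rank and returns the candidate with the largest
    positive second difference of the objective-vs-rank curve (the point
    where adding rank stops paying off).  A single candidate is returned
    as-is; at least three candidates are required otherwise.
    """
    ranks = sorted(int(r) for r in rank_candidates)
    if len(ranks) == 1:
        return ranks[0]
    if len(ranks) < 3:
        raise ValueError("rank selection needs 1 or >= 3 candidates")
    objs = [
        fit_inmf(session, r, lam_het=lam_het, n_starts=n_starts,
                 max_iter=max_iter, tol=tol, seed=seed).objective
        for r in ranks
    ]
    d2 = [objs[i - 1] - 2.0 * objs[i] + objs[i + 1] for i in range(1, len(ranks) - 1)]
    return ranks[1 + int(np.argmax(d2))]
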