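"""In-process simulation of the client-server federation.

Server nodes hold the raw cohort data; the client sees only what comes back
from :func:`server_compute`: scalar losses, gradient vectors, factor-update
numerator/denominator matrices and summary aggregates.  Every request-response
exchange is metered, every transmitted numeric payload can be quantized to a
fixed number of decimal digits, and two disclosure policies are enforced at
the boundary: a nonzero-count guard on released coefficient vectors and a
shared-factor-only rule for integrative NMF.

The transport is a plain method call so that a networked backend could be
substituted without touching the algorithms; the client-side code only ever
goes through ``FederationSession.request`` / ``broadcast``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .data import TaskDataset, validate_feature_alignment
from . import losses as _losses

UNLIMITED = None  #: sentinel for "no quantization"

_EPS = 1e-12  # denominator guard for multiplicative updates

_REQUEST_KINDS = (
    "loss_value",
    "loss_value_grad",
    "inmf_local_update",
    "inmf_H_stats",
    "summary_stats",
)


def quantize(values, digits):
    """Round transmitted numbers to ``digits`` decimal places (half-to-even).

    ``digits=None`` (unlimited) is the identity.  Scalars come back as
    floats, arrays as float arrays.  Idempotent by construction.
    """
    if digits is UNLIMITED:
        return values
    digits = int(digits)
    if digits < 1:
        raise ValueError("digits must be >= 1 or unlimited (None)")
    arr = np.asarray(values, dtype=float)
    out = np.round(arr, digits)
    if np.isscalar(values) or arr.ndim == 0:
        return float(out)
    return out


def disclosure_guard(coefficients, n_subjects: int) -> bool:
    """Server-side release rule for fitted coefficient vectors.

    Returns ``True`` (pass) unless the number of nonzero coefficients
    exceeds the number of subjects on the server, in which case the model
    would be saturated enough to support reconstruction attacks and is
    rejected (``False``).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    nnz = int(np.count_nonzero(np.asarray(coefficients)))
    return nnz <= n_subjects


@dataclass
class PrivacyPolicy:
    """What a server is willing to transmit.

    digits:
        Decimal places retained on any transmitted numeric payload
        (``None`` = unlimited precision).
    enforce_nonzero_guard:
        Apply :func:`disclosure_guard` whenever a fitted coefficient vector
        would be released from a server context.
    inmf_return_shared_only:
        Only the shared metagene matrix ``H`` (and aggregate update
        statistics) may appear in client-visible payloads; the
        cohort-specific factors never leave the server.
    """

    digits: int | None = UNLIMITED
    enforce_nonzero_guard: bool = True
    inmf_return_shared_only: bool = True

    def __post_init__(self) -> None:
        if self.digits is not UNLIMITED and int(self.digits) < 1:
            raise ValueError("digits must be >= 1 when finite")


@dataclass
class CommLog:
    """Communication meter: client-initiated rounds and per-server accesses."""

    rounds: int = 0
    accesses: dict[str, int] = field(default_factory=dict)

    def total_accesses(self) -> int:
        return int(sum(self.accesses.values()))

    def snapshot(self) -> "CommLog":
        return CommLog(self.rounds, dict(self.accesses))

    def to_dict(self) -> dict:
        return {
            "rounds": self.rounds,
            "total_accesses": self.total_accesses(),
            "per_server_accesses": dict(self.accesses),
        }


@dataclass
class Request:
    kind: str
    payload: dict = field(default_factory=dict)


def _fold_ids(n: int, y: np.ndarray | None, k_folds: int, seed: int) -> np.ndarray:
    """Deterministic fold assignment for the local samples.

    Stratified by class when ``y`` is a binary label vector: within each
    class, samples are shuffled and dealt round-robin so every fold sees
    both classes whenever possible.
    """
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    if y is not None and set(np.unique(y)).issubset({-1.0, 1.0}):
        counter = 0
        for cls in (-1.0, 1.0):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            for j, i in enumerate(idx):
                fold[i] = (counter + j) % k_folds
            counter += len(idx)
    else:
        perm = rng.permutation(n)
        for j, i in enumerate(perm):
            fold[i] = j % k_folds
    return fold


class ServerNode:
    """One data owner: holds a :class:`TaskDataset` behind the policy boundary.

    The raw data is reachable only through :meth:`handle`; no request kind
    returns row-level data.
    """

    def __init__(self, server_id: str, dataset: TaskDataset, policy: PrivacyPolicy):
        self.server_id = server_id
        self.policy = policy
        self._dataset = dataset
        # iNMF server-local state, keyed by start id: {"W": n_k x r, "V": r x p}
        self._inmf_states: dict[int, dict[str, np.ndarray]] = {}
        self._std: tuple[np.ndarray, np.ndarray] | None = None

    # -- internals ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self._dataset.n_samples

    @property
    def n_features(self) -> int:
        return self._dataset.n_features

    def _rows(self, fold_spec: Mapping | None) -> np.ndarray:
        """Boolean row mask selected by an (optional) cross-validation fold."""
        n = self._dataset.n_samples
        if fold_spec is None:
            return np.ones(n, dtype=bool)
        ids = _fold_ids(n, self._dataset.y, int(fold_spec["k_folds"]), int(fold_spec["seed"]))
        mask = ids == int(fold_spec["fold"])
        return mask if fold_spec.get("part", "test") == "test" else ~mask

    def _std_constants(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-column mean/scale of the full local cohort (scale floored)."""
        if self._std is None:
            mu = self._dataset.X.mean(axis=0)
            sd = self._dataset.X.std(axis=0)
            sd = np.where(sd < 1e-12, 1.0, sd)
            self._std = (mu, sd)
        return self._std

    def _check_w(self, w) -> np.ndarray:
        w = np.asarray(w, dtype=float).ravel()
        if w.shape[0] != self.n_features:
            raise ValueError(
                f"server {self.server_id!r}: payload has {w.shape[0]} coefficients "
                f"for {self.n_features} features"
            )
        return w

    # -- request handlers --------------------------------------------------

    def handle(self, request: Request) -> dict:
        if request.kind not in _REQUEST_KINDS:
            raise ValueError(f"unknown request kind {request.kind!r}")
        out = getattr(self, "_handle_" + request.kind)(dict(request.payload))
        return self._quantize_response(out)

    def _quantize_response(self, response: dict) -> dict:
        d = self.policy.digits
        if d is UNLIMITED:
            return response
        out = {}
        for k, v in response.items():
            if isinstance(v, float) or (isinstance(v, np.ndarray) and v.dtype.kind == "f"):
                out[k] = quantize(v, d)
            else:
                out[k] = v
        return out

    def _loss_common(self, payload: dict, want_grad: bool) -> dict:
        loss = payload.get("loss", "ls")
        mask = self._rows(payload.get("fold"))
        X = self._dataset.X[mask]
        y = self._dataset.y[mask]
        if payload.get("standardize"):
            mu, sd = self._std_constants()
            X = (X - mu) / sd
        n = X.shape[0]
        if n == 0:
            raise ValueError(f"server {self.server_id!r}: empty row selection")
        w = payload.get("w")
        w = np.zeros(self.n_features) if w is None else self._check_w(w)
        c = payload.get("c", 0.0)
        c_opt = None
        if c == "optimal":
            c = c_opt = _losses.optimal_intercept(y, loss)
        if loss == "ls":
            value, grad_w, grad_c = _losses.least_squares_value_grad(X, y, w, float(c))
        elif loss == "logistic":
            value, grad_w, grad_c = _losses.logistic_value_grad(X, y, w, float(c))
        else:
            raise ValueError(f"unknown loss {loss!r}")
        resp: dict[str, Any] = {"value": float(value), "n": int(n)}
        if c_opt is not None:
            resp["c_opt"] = float(c_opt)
        if want_grad:
            resp["grad_w"] = grad_w
            resp["grad_c"] = float(grad_c)
        return resp

    def _handle_loss_value(self, payload: dict) -> dict:
        return self._loss_common(payload, want_grad=False)

    def _handle_loss_value_grad(self, payload: dict) -> dict:
        return self._loss_common(payload, want_grad=True)

    def _handle_summary_stats(self, payload: dict) -> dict:
        stat = payload.get("stat", "basic")
        X, y = self._dataset.X, self._dataset.y
        if stat == "basic":
            return {
                "n": int(X.shape[0]),
                "p": int(X.shape[1]),
                "y_mean": float(y.mean()),
                "y_pos": int(np.count_nonzero(y > 0)),
                "y_neg": int(np.count_nonzero(y < 0)),
                "x_mean": float(X.mean()),
                "x_sum": float(X.sum()),
                "x_n_entries": int(X.size),
            }
        if stat == "standardization":
            mu, sd = self._std_constants()
            return {"x_col_mean": mu.copy(), "x_col_scale": sd.copy()}
        if stat == "cv_metric":
            mask = self._rows(payload["fold"])
            Xs, ys = X[mask], y[mask]
            if payload.get("standardize"):
                mu, sd = self._std_constants()
                Xs = (Xs - mu) / sd
            w = self._check_w(payload["w"])
            c = float(payload.get("c", 0.0))
            scores = Xs @ w + c
            if payload.get("metric", "mse") == "mse":
                total = float(np.sum((scores - ys) ** 2))
            else:  # misclassification on {-1,+1} labels; ties predict +1
                labels = np.where(scores >= 0, 1.0, -1.0)
                total = float(np.count_nonzero(labels != ys))
            return {"metric_sum": total, "n": int(mask.sum())}
        if stat == "inmf_specific_genes":
            return self._inmf_specific_genes(payload)
        if stat == "release_check":
            # disclosure guard on a coefficient vector about to be released
            ok = True
            if self.policy.enforce_nonzero_guard:
                ok = disclosure_guard(payload["w"], self.n_samples)
            return {"release_ok": bool(ok), "n": int(self.n_samples)}
        raise ValueError(f"unknown summary statistic {stat!r}")

    # -- integrative NMF server side ---------------------------------------

    def _inmf_state(self, start: int) -> dict[str, np.ndarray]:
        try:
            return self._inmf_states[int(start)]
        except KeyError:
            raise ValueError(
                f"server {self.server_id!r}: iNMF start {start} not initialized"
            ) from None

    def _inmf_local_objective(self, W: np.ndarray, V: np.ndarray, H: np.ndarray,
                              lam_het: float) -> float:
        X = self._dataset.X
        resid = X - W @ (H + V)
        return float(np.sum(resid * resid) + lam_het * np.sum((W @ V) ** 2))

    def _handle_inmf_local_update(self, payload: dict) -> dict:
        start = int(payload.get("start", 0))
        if "init" in payload:
            init = payload["init"]
            r = int(init["rank"])
            X = self._dataset.X
            if np.any(X < 0):
                raise ValueError(f"server {self.server_id!r}: negative entries in data")
            if r > min(X.shape):
                raise ValueError(
                    f"server {self.server_id!r}: rank {r} exceeds min dimension {min(X.shape)}"
                )
            rng = np.random.default_rng(int(init["seed"]))
            scale = float(init["scale"])
            self._inmf_states[start] = {
                "W": rng.uniform(0.0, 1.0, size=(X.shape[0], r)) * scale,
                "V": rng.uniform(0.0, 1.0, size=(r, X.shape[1])) * scale,
            }
            return {"n": int(X.shape[0]), "initialized": True}
        if "select_start" in payload:
            keep = int(payload["select_start"])
            self._inmf_state(keep)  # must exist
            self._inmf_states = {keep: self._inmf_states[keep]}
            return {"selected": keep}
        H = np.asarray(payload["H"], dtype=float)
        lam = float(payload.get("lam_het", 0.0))
        st = self._inmf_state(start)
        X = self._dataset.X
        W, V = st["W"], st["V"]
        if H.shape != V.shape:
            raise ValueError(
                f"server {self.server_id!r}: H shape {H.shape} != local factor shape {V.shape}"
            )
        # multiplicative updates; each block step is non-increasing in the
        # objective  sum ||X - W(H+V)||^2 + lam ||W V||^2
        Z = H + V
        num = X @ Z.T
        den = W @ (Z @ Z.T) + lam * (W @ (V @ V.T)) + _EPS
        W = W * (num / den)
        WtW = W.T @ W
        WtX = W.T @ X
        den = WtW @ (H + V) + lam * (WtW @ V) + _EPS
        V = V * (WtX / den)
        st["W"], st["V"] = W, V
        A = W.T @ X
        B = (W.T @ W) @ (H + V)
        return {
            "A": A,
            "B": B,
            "objective_local": self._inmf_local_objective(W, V, H, lam),
            "n": int(X.shape[0]),
        }

    def _handle_inmf_H_stats(self, payload: dict) -> dict:
        start = int(payload.get("start", 0))
        st = self._inmf_state(start)
        H = np.asarray(payload["H"], dtype=float)
        lam = float(payload.get("lam_het", 0.0))
        W, V = st["W"], st["V"]
        resp: dict[str, Any] = {
            "A": W.T @ self._dataset.X,
            "B": (W.T @ W) @ (H + V),
            "objective_local": self._inmf_local_objective(W, V, H, lam),
        }
        if payload.get("include_factors"):
            if self.policy.inmf_return_shared_only:
                raise PermissionError(
                    f"server {self.server_id!r}: policy forbids releasing "
                    "cohort-specific factors"
                )
            resp["W_k"] = W.copy()
            resp["V_k"] = V.copy()
        return resp

    def _inmf_specific_genes(self, payload: dict) -> dict:
        """Names (only) of this cohort's specific-signature genes, from V_k."""
        st = self._inmf_state(int(payload.get("start", 0)))
        V = st["V"]
        score = V.max(axis=0)
        top_k = payload.get("top_k")
        if top_k is not None:
            order = np.lexsort((np.arange(score.size), -score))
            idx = np.sort(order[: int(top_k)])
        else:
            thr = float(V.mean() + 2.0 * V.std())
            idx = np.flatnonzero(score > thr)
        names = [self._dataset.feature_names[i] for i in idx]
        return {"genes": names}


class FederationSession:
    """The client's handle on a set of server nodes plus the comm meter."""

    def __init__(self, servers: dict[str, ServerNode], policy: PrivacyPolicy):
        self.servers = servers
        self.policy = policy
        self.log = CommLog(rounds=0, accesses={sid: 0 for sid in servers})
        self.feature_names = validate_feature_alignment(
            [node._dataset for node in servers.values()]
        )

    @property
    def server_ids(self) -> list[str]:
        return list(self.servers)

    @property
    def n_servers(self) -> int:
        return len(self.servers)

    def request(self, server_id: str, req: Request) -> dict:
        """One request-response exchange with one server (one network access)."""
        if server_id not in self.servers:
            raise KeyError(f"unknown server {server_id!r}")
        self.log.accesses[server_id] += 1
        return self.servers[server_id].handle(req)

    def broadcast(self, requests: Mapping[str, Request] | Request) -> dict[str, dict]:
        """One client-initiated synchronization round touching every server.

        ``requests`` is either one request sent to all servers or a mapping
        server_id -> request.
        """
        self.log.rounds += 1
        if isinstance(requests, Request):
            requests = {sid: requests for sid in self.servers}
        return {sid: self.request(sid, req) for sid, req in requests.items()}

    def quantize_payload(self, values, digits=UNLIMITED):
        """Client-side quantization of an outgoing payload per policy."""
        d = digits if digits is not UNLIMITED else self.policy.digits
        return quantize(values, d)

    def sizes(self) -> dict[str, int]:
        """Per-server sample counts (aggregate; no metering, fixed metadata)."""
        return {sid: node.n_samples for sid, node in self.servers.items()}


def create_session(
    datasets: Sequence[TaskDataset], policy: PrivacyPolicy | None = None
) -> FederationSession:
    """Stand up one server node per cohort and an empty communication log."""
    if len(datasets) < 1:
        raise ValueError("at least one dataset is required")
    validate_feature_alignment(list(datasets))
    policy = policy if policy is not None else PrivacyPolicy()
    ids = [d.task_id for d in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError("task_id of each cohort must be unique")
    servers = {d.task_id: ServerNode(d.task_id, d, policy) for d in datasets}
    return FederationSession(servers, policy)


def server_compute(session: FederationSession, server_id: str, request: Request) -> dict:
    """Metered request-response exchange; the only path to server data."""
    return session.request(server_id, request)


def comm_summary(session: FederationSession) -> dict:
    """Pure read of the communication log."""
    return session.log.to_dict()
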