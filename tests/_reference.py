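"""Independent single-process reference implementations used as oracles.

These deliberately avoid the package's federation, solver and update code:
the supervised reference is plain ISTA (no momentum, no monotone machinery)
on the concatenated data; the factorization reference runs the alternating
multiplicative updates directly on the list of matrices.  Agreement between
a federated fit and these references is the master correctness check.
"""

from __future__ import annotations

import numpy as np


def _soft(W, t):
    return np.sign(W) * np.maximum(np.abs(W) - t, 0.0)


def _prox_ref(penalty, W, t):
    if penalty == "l1":
        return _soft(W, t)
    if penalty == "l21":
        norms = np.linalg.norm(W, axis=1, keepdims=True)
        scale = np.where(norms > 0, np.maximum(1.0 - t / np.where(norms > 0, norms, 1.0), 0.0), 0.0)
        return W * scale
    if penalty == "trace":
        U, s, Vt = np.linalg.svd(W, full_matrices=False)
        return (U * np.maximum(s - t, 0.0)) @ Vt
    raise ValueError(penalty)


def _pen_ref(penalty, W):
    if penalty == "l1":
        return np.abs(W).sum()
    if penalty == "l21":
        return np.linalg.norm(W, axis=1).sum()
    if penalty == "trace":
        return np.linalg.svd(W, compute_uv=False).sum()
    raise ValueError(penalty)


def solve_centralized(
    Xs,
    ys,
    loss="ls",
    penalty="l21",
    lam=0.0,
    coupling="multi_task",
    C=0.0,
    smooth="none",
    R=None,
    fit_intercept=True,
    max_iter=100_000,
    tol=1e-15,
):
    """Plain proximal gradient (ISTA) with backtracking on pooled/stacked data.

    Returns (W, c, objective) at the (unique, for the instances used in the
    tests) minimizer of

        sum_t mean_loss_t(w_t, c_t) + lam * S(W) + C * N(W).
    """
    Xs = [np.asarray(X, dtype=float) for X in Xs]
    ys = [np.asarray(y, dtype=float) for y in ys]
    if coupling == "pooled":
        Xs = [np.vstack(Xs)]
        ys = [np.concatenate(ys)]
    T = len(Xs)
    p = Xs[0].shape[1]

    def smooth_parts(W, c, want_grad):
        val = 0.0
        gW = np.zeros_like(W) if want_grad else None
        gc = np.zeros(T) if want_grad else None
        for t in range(T):
            X, y, n = Xs[t], ys[t], Xs[t].shape[0]
            z = X @ W[:, t] + c[t]
            if loss == "ls":
                r = z - y
                val += r @ r / (2 * n)
                if want_grad:
                    gW[:, t] = X.T @ r / n
                    gc[t] = r.mean()
            else:
                m = y * z
                val += np.logaddexp(0.0, -m).mean()
                if want_grad:
                    s = -y / (1.0 + np.exp(m)) / n
                    gW[:, t] = X.T @ s
                    gc[t] = s.sum()
        if C > 0 and smooth == "ridge":
            val += C * 0.5 * np.sum(W * W)
            if want_grad:
                gW += C * W
        elif C > 0 and smooth == "graph":
            WR = W @ R
            val += C * np.sum(WR * WR)
            if want_grad:
                gW += C * 2.0 * WR @ R.T
        return (val, gW, gc) if want_grad else val

    W = np.zeros((p, T))
    c = np.zeros(T)
    if fit_intercept:
        for t in range(T):
            if loss == "ls":
                c[t] = ys[t].mean()
            else:
                pos = np.count_nonzero(ys[t] > 0)
                c[t] = np.log(pos / (len(ys[t]) - pos))

    L = 1.0
    prev_obj = None
    for _ in range(max_iter):
        f, gW, gc = smooth_parts(W, c, True)
        while True:
            Wn = _prox_ref(penalty, W - gW / L, lam / L)
            cn = c - gc / L if fit_intercept else c
            fn = smooth_parts(Wn, cn, False)
            dW, dc = Wn - W, cn - c
            if fn <= f + np.sum(gW * dW) + gc @ dc + 0.5 * L * (np.sum(dW * dW) + dc @ dc) + 1e-14:
                break
            L *= 2.0
        W, c = Wn, cn
        obj = fn + lam * _pen_ref(penalty, W)
        if prev_obj is not None and abs(prev_obj - obj) <= tol * max(abs(prev_obj), 1.0):
            break
        prev_obj = obj
    return W, c, obj


def inmf_centralized(Xs, rank, lam_het, client_seed, server_seeds, scale, n_rounds):
    """Alternating multiplicative updates on the list of matrices, single
    process, mirroring the factor initialization from explicit seeds.

    Returns (H, per-cohort (W_k, V_k), objective history evaluated at the
    incoming H of each round).
    """
    Xs = [np.asarray(X, dtype=float) for X in Xs]
    p = Xs[0].shape[1]
    rng = np.random.default_rng(client_seed)
    H = rng.uniform(0.0, 1.0, size=(rank, p)) * scale
    factors = []
    for X, seed in zip(Xs, server_seeds):
        r = np.random.default_rng(seed)
        factors.append(
            [r.uniform(0.0, 1.0, size=(X.shape[0], rank)) * scale,
             r.uniform(0.0, 1.0, size=(rank, p)) * scale]
        )
    eps = 1e-12
    history = []
    for _ in range(n_rounds):
        A_sum = np.zeros_like(H)
        B_sum = np.zeros_like(H)
        obj = 0.0
        for X, fac in zip(Xs, factors):
            W, V = fac
            Z = H + V
            W = W * (X @ Z.T) / (W @ (Z @ Z.T) + lam_het * (W @ (V @ V.T)) + eps)
            WtW = W.T @ W
            V = V * (W.T @ X) / (WtW @ (H + V) + lam_het * (WtW @ V) + eps)
            fac[0], fac[1] = W, V
            A_sum += W.T @ X
            B_sum += (W.T @ W) @ (H + V)
            resid = X - W @ (H + V)
            obj += np.sum(resid * resid) + lam_het * np.sum((W @ V) ** 2)
        history.append(obj)
        H = H * (A_sum / (B_sum + eps))
    return H, factors, history
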