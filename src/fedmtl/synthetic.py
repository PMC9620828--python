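"""Synthetic multi-cohort generators with known ground truth.

Two study designs are emulated.  Case 1 plants a sparse linear signal with a
support shared across cohorts; in the "heterogeneous" mode each cohort flips
the signs of the shared coefficients independently (the comorbidity setting:
the same genes change, in cohort-dependent directions).  Case 2 composes
non-negative expression-like matrices from a shared metagene signature plus
disjoint cohort-specific signatures, the setting disentangled by integrative
NMF.  Truth objects are returned separately from the data so any selection
metric can be scored without re-deriving the generative process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import TaskDataset
from .federation import PrivacyPolicy, create_session


def _feature_names(p: int, prefix: str = "g") -> list[str]:
    width = len(str(p - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(p)]


@dataclass
class Case1Spec:
    """Sparse linear signal shared across T cohorts.

    ``mode="heterogeneous"`` draws independent Rademacher signs per cohort
    over the shared support; ``"homogeneous"`` shares one sign vector.
    ``support_size`` defaults to 10% of the features.
    """

    T: int = 3
    p: int = 200
    n_per_task: int = 30
    support_size: int | None = None
    mode: str = "heterogeneous"
    noise_sd: float = 1.0
    magnitude: float = 1.0
    outcome: str = "continuous"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.support_size is None:
            self.support_size = max(1, round(0.1 * self.p))
        if self.support_size > self.p:
            raise ValueError("support_size must be <= p")
        if self.n_per_task < 1:
            raise ValueError("n_per_task must be >= 1")
        if self.mode not in ("heterogeneous", "homogeneous"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.outcome not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome {self.outcome!r}")


def gen_case1(spec: Case1Spec) -> tuple[list[TaskDataset], dict]:
    """Generate T cohorts with a planted shared-support signal.

    Returns ``(datasets, truth)`` with
    ``truth = {"support", "signs" (support_size x T), "W_true" (p x T)}``.
    """
    rng = np.random.default_rng(spec.seed)
    names = _feature_names(spec.p)
    support = np.sort(rng.choice(spec.p, size=spec.support_size, replace=False))
    if spec.mode == "homogeneous":
        base = rng.choice([-1.0, 1.0], size=spec.support_size)
        signs = np.tile(base[:, None], (1, spec.T))
    else:
        signs = rng.choice([-1.0, 1.0], size=(spec.support_size, spec.T))
    W_true = np.zeros((spec.p, spec.T))
    W_true[support, :] = spec.magnitude * signs

    datasets = []
    for t in range(spec.T):
        X = rng.standard_normal((spec.n_per_task, spec.p))
        lin = X @ W_true[:, t]
        if spec.outcome == "continuous":
            y = lin + spec.noise_sd * rng.standard_normal(spec.n_per_task)
        else:
            prob = 1.0 / (1.0 + np.exp(-lin))
            y = np.where(rng.uniform(size=spec.n_per_task) < prob, 1.0, -1.0)
        datasets.append(TaskDataset(X=X, y=y, feature_names=names, task_id=f"task{t}"))
    truth = {"support": support, "signs": signs, "W_true": W_true}
    return datasets, truth


@dataclass
class Case2Spec:
    """Non-negative matrices composed of shared + cohort-specific signatures.

    ``n_signal`` outcome-associated genes are partitioned, disjointly, into
    a shared set (``shared_fraction`` of them) and equally sized
    cohort-specific sets.  Each signature gene loads one of ``rank``
    metagenes with weight ~ signal * U(0.5, 1.5); specific genes load the
    cohort's V_k on the same metagene grid, so shared and specific structure
    share sample loadings and only joint factorization can separate them.
    """

    K: int = 2
    p: int = 300
    n_k: int = 100
    rank: int = 4
    shared_fraction: float = 0.2
    n_signal: int | None = None
    signal: float = 1.0
    noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal is None:
            # a third of the genes carry signal, capped at 100
            self.n_signal = min(100, max(self.K + 1, self.p // 3))
        if not (0.0 < self.shared_fraction < 1.0):
            raise ValueError("shared_fraction must be in (0, 1)")
        if self.n_signal > self.p:
            raise ValueError("n_signal must be <= p")
        if self.K < 1 or self.rank < 1:
            raise ValueError("K and rank must be >= 1")


def gen_case2(spec: Case2Spec) -> tuple[list[TaskDataset], dict]:
    """Generate K non-negative cohort matrices with planted signatures.

    Returns ``(datasets, truth)``; the outcome vector of each dataset is an
    all-zero placeholder (the design is unsupervised).  Truth holds the
    planted gene names: ``{"shared", "specific": {task_id: [...]},
    "H_true", "V_true"}``; shared and specific sets are disjoint by
    construction.
    """
    rng = np.random.default_rng(spec.seed)
    names = _feature_names(spec.p)
    sig_genes = rng.choice(spec.p, size=spec.n_signal, replace=False)
    n_shared = int(round(spec.shared_fraction * spec.n_signal))
    shared = np.sort(sig_genes[:n_shared])
    rest = sig_genes[n_shared:]
    per_k = len(rest) // spec.K
    specific = {
        f"cohort{k}": np.sort(rest[k * per_k: (k + 1) * per_k]) for k in range(spec.K)
    }

    r = spec.rank
    H_true = np.zeros((r, spec.p))
    for j, g in enumerate(shared):
        H_true[j % r, g] = spec.signal * rng.uniform(0.5, 1.5)
    V_true = {}
    datasets = []
    for k in range(spec.K):
        tid = f"cohort{k}"
        V = np.zeros((r, spec.p))
        for j, g in enumerate(specific[tid]):
            V[j % r, g] = spec.signal * rng.uniform(0.5, 1.5)
        V_true[tid] = V
        W = rng.uniform(0.0, 1.0, size=(spec.n_k, r))
        X = W @ (H_true + V) + np.abs(rng.normal(0.0, spec.noise, size=(spec.n_k, spec.p)))
        X = np.maximum(X, 0.0)
        datasets.append(
            TaskDataset(X=X, y=np.zeros(spec.n_k), feature_names=names, task_id=tid)
        )
    truth = {
        "shared": [names[g] for g in shared],
        "specific": {tid: [names[g] for g in idx] for tid, idx in specific.items()},
        "H_true": H_true,
        "V_true": V_true,
    }
    return datasets, truth


def gen_scalability_suite(
    K_range=range(1, 21),
    n_per_task: int = 50,
    p: int = 100,
    seed: int = 0,
    policy: PrivacyPolicy | None = None,
    **case1_kw,
):
    """One federation session per K in ``K_range``, each of K case-1 cohorts.

    All cohorts are drawn from the same case-1 distribution at fixed
    per-task sample size, so communication cost can be compared across
    federation sizes.  Returns a list of ``(session, truth)`` pairs in the
    order of ``K_range``.
    """
    out = []
    for i, K in enumerate(K_range):
        spec = Case1Spec(T=int(K), p=p, n_per_task=n_per_task,
                         seed=seed + 1000 * i, **case1_kw)
        datasets, truth = gen_case1(spec)
        out.append((create_session(datasets, policy), truth))
    return out
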