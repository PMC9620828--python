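"""Metrics, local (non-collaborative) baselines and experiment drivers.

The baselines deliberately bypass the federation: each cohort fits its own
model on local data only (scikit-learn lasso / NMF) and the per-cohort
results are aggregated afterwards — the classical "ensemble of local
models" comparator.  They therefore incur zero network accesses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF
from sklearn.linear_model import LassoCV

from .algorithms import cross_validate, fit_l21, fit_lasso
from .data import CoefficientModel, TaskDataset
from .federation import comm_summary, create_session
from .inmf import extract_signatures, fit_inmf
from .solver import SolverOptions, lambda_max, lambda_sequence, ProblemSpec
from .synthetic import Case1Spec, Case2Spec, gen_case1, gen_case2, gen_scalability_suite


# ---------------------------------------------------------------------------
# elementary metrics


def mse(pred, y) -> float:
    """Mean squared error."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if pred.shape != y.shape:
        raise ValueError("pred and y must have the same shape")
    return float(np.mean((pred - y) ** 2))


def misclassification_rate(pred_labels, y) -> float:
    """Fraction of label disagreements."""
    pred_labels = np.asarray(pred_labels)
    y = np.asarray(y)
    if pred_labels.shape != y.shape:
        raise ValueError("pred_labels and y must have the same shape")
    return float(np.mean(pred_labels != y))


def feature_scores(model: CoefficientModel) -> np.ndarray:
    """Per-feature relevance of a multi-task model: row L2 norm of W."""
    return np.linalg.norm(model.W, axis=1)


def selection_accuracy(scores, truth_support, k: int | None = None) -> float:
    """Precision of the top-k ranked features against the true support.

    ``k`` defaults to the size of the true support.  Ties in the score are
    broken by feature index, so the ranking is deterministic.
    """
    scores = np.asarray(scores, dtype=float)
    truth = set(int(i) for i in np.asarray(truth_support).ravel())
    if k is None:
        k = len(truth)
    if k > scores.size:
        raise ValueError("k must be <= number of features")
    order = np.lexsort((np.arange(scores.size), -scores))
    top = set(int(i) for i in order[:k])
    return len(top & truth) / k


def signature_overlap(top_a, top_b, k: int = 200) -> dict:
    """Reproducibility of two ranked, signed gene lists.

    ``top_a`` / ``top_b`` map gene name -> signed score (e.g. a pandas
    Series of coefficients).  The top ``k`` genes of each list by absolute
    score are compared: ``n_overlap`` counts genes present in both top
    lists, ``n_consistent`` those whose association direction agrees.
    """
    a = pd.Series(top_a, dtype=float)
    b = pd.Series(top_b, dtype=float)
    ka = min(k, len(a))
    kb = min(k, len(b))
    top_a_set = set(a.abs().sort_values(ascending=False, kind="stable").index[:ka])
    top_b_set = set(b.abs().sort_values(ascending=False, kind="stable").index[:kb])
    common = top_a_set & top_b_set
    consistent = sum(1 for g in common if np.sign(a[g]) == np.sign(b[g]))
    return {"n_overlap": len(common), "n_consistent": int(consistent)}


# ---------------------------------------------------------------------------
# local (ensemble-of-local-models) baselines


def _nmf_select(X: np.ndarray, rank: int, seed: int, top_k=None, max_iter=2000):
    """Local NMF gene scores and the selected gene-index set.

    The factorization runs on a fixed iteration budget; the budget warning
    is silenced since the gene ranking is stable well before the default
    tolerance is reached.
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    nmf = NMF(
        n_components=rank,
        init="random",
        random_state=seed % (2**32 - 1),
        max_iter=max_iter,
        tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        nmf.fit(np.asarray(X, dtype=float))
    Hk = nmf.components_
    score = Hk.max(axis=0)
    if top_k is not None:
        order = np.lexsort((np.arange(score.size), -score))
        idx = set(int(i) for i in order[:top_k])
    else:
        thr = float(Hk.mean() + 2.0 * Hk.std())
        idx = set(int(i) for i in np.flatnonzero(score > thr))
    return score, idx


def bagging_baseline(
    datasets: list[TaskDataset],
    learner: str = "lasso_local",
    rank: int = 4,
    seed: int = 0,
    cv: int = 5,
    top_k: int | None = None,
) -> dict:
    """Strictly local per-cohort fits, aggregated client-side.

    ``lasso_local``
        One cross-validated lasso per cohort; the bagged per-feature score
        is the mean absolute coefficient across cohorts.
    ``nmf_local``
        One NMF per cohort (no sharing).  Each cohort's selected gene set
        (metagene weight above mean + 2 sd, or ``top_k``) is its
        specific-signature estimate; the bagged shared-set estimate is the
        intersection of the per-cohort sets.
    """
    if learner == "lasso_local":
        per = []
        for i, d in enumerate(datasets):
            las = LassoCV(cv=cv, random_state=seed + i, alphas=50, max_iter=5000)
            las.fit(d.X, d.y)
            per.append(np.abs(las.coef_))
        scores = np.mean(per, axis=0)
        return {"scores": scores, "per_cohort": per}
    if learner == "nmf_local":
        sets, scores = {}, {}
        for i, d in enumerate(datasets):
            s, idx = _nmf_select(d.X, rank, seed + i, top_k=top_k)
            sets[d.task_id] = idx
            scores[d.task_id] = s
        shared = set.intersection(*sets.values()) if sets else set()
        return {"shared": shared, "specific": sets, "scores": scores}
    raise ValueError(f"unknown learner {learner!r}")


# ---------------------------------------------------------------------------
# experiment drivers


def comm_cost_experiment(
    K_range=range(1, 21),
    n_sweep=(50,),
    algorithms=("l21", "lasso"),
    reps: int = 1,
    seed: int = 0,
    p: int = 100,
    lam_ratio: float = 0.1,
    options: SolverOptions | None = None,
    **case1_kw,
) -> pd.DataFrame:
    """Communication cost of federated fits versus federation size.

    For every (algorithm, K, n) cell a fresh suite of K same-distribution
    cohorts is generated and a single fit at ``lam = lam_ratio * lam_max``
    is run to convergence; synchronization rounds and per-server network
    accesses are recorded from the session meter and averaged over
    ``reps`` repetitions.
    """
    options = options or SolverOptions()
    rows = []
    for rep in range(reps):
        for n in n_sweep:
            suite = gen_scalability_suite(
                K_range, n_per_task=int(n), p=p, seed=seed + 10_000 * rep, **case1_kw
            )
            for (session, _truth), K in zip(suite, K_range):
                for alg in algorithms:
                    session.log.rounds = 0
                    session.log.accesses = {s: 0 for s in session.server_ids}
                    base = ProblemSpec(
                        session=session,
                        penalty="l21" if alg == "l21" else "l1",
                        coupling="multi_task" if alg == "l21" else "pooled",
                    )
                    lam = lam_ratio * lambda_max(base)
                    fit = fit_l21 if alg == "l21" else fit_lasso
                    res = fit(session, lam=lam, options=options)
                    cs = comm_summary(session)
                    rows.append(
                        {
                            "algorithm": alg,
                            "K": int(K),
                            "n": int(n),
                            "rep": rep,
                            "iterations": res.n_iter,
                            "rounds": cs["rounds"],
                            "total_accesses": cs["total_accesses"],
                        }
                    )
    df = pd.DataFrame(rows)
    return (
        df.groupby(["algorithm", "K", "n"], as_index=False)[
            ["iterations", "rounds", "total_accesses"]
        ].mean()
    )


def heterogeneous_signature_study(
    n_reps: int = 20,
    seed: int = 0,
    n_over_p: float = 0.15,
    p: int = 200,
    T: int = 3,
    depth: int = 20,
    k_folds: int = 5,
    options: SolverOptions | None = None,
) -> pd.DataFrame:
    """Joint versus local feature selection under sign-flipped signatures.

    Each repetition plants a shared-support signal with independent signs
    per cohort at subject/feature ratio ``n_over_p``, fits the L2,1
    multi-task model with ``k_folds``-fold cross-validation over a
    ``depth``-value lambda path, fits the per-cohort lasso-bagging baseline,
    and scores precision@k (k = true support size) of each method's feature
    ranking against the planted support.
    """
    master = np.random.default_rng(seed)
    rows = []
    for rep in range(n_reps):
        rep_seed = int(master.integers(2**31))
        spec = Case1Spec(T=T, p=p, n_per_task=round(n_over_p * p),
                         mode="heterogeneous", seed=rep_seed)
        datasets, truth = gen_case1(spec)
        session = create_session(datasets)
        cv = cross_validate(session, algorithm="l21", seed=rep_seed,
                            depth=depth, k_folds=k_folds, options=options)
        acc_mtl = selection_accuracy(feature_scores(cv["model"].model),
                                     truth["support"])
        bag = bagging_baseline(datasets, "lasso_local", seed=rep_seed)
        acc_bag = selection_accuracy(bag["scores"], truth["support"])
        rows.append({"rep": rep, "seed": rep_seed, "accuracy_l21": acc_mtl,
                     "accuracy_bagging": acc_bag})
    return pd.DataFrame(rows)


def _precision(est: set, truth: set) -> float:
    return len(est & truth) / max(len(est), 1)


def signature_disentanglement_study(
    fractions=(0.2, 0.4, 0.6, 0.8),
    n_reps: int = 3,
    seed: int = 0,
    rank: int = 4,
    lam_het: float = 0.01,
    n_starts: int = 5,
    max_iter: int = 500,
    **case2_kw,
) -> pd.DataFrame:
    """Federated iNMF versus local-NMF bagging across heterogeneity levels.

    For each shared fraction and repetition, plants shared + cohort-specific
    non-negative signatures, fits federated iNMF (``n_starts`` random
    starts) and independent per-cohort NMFs, extracts gene sets by the
    mean + 2 sd rule, and scores precision of: the iNMF shared set (from H),
    the iNMF specific sets (from the server-local V_k), the bagged local-NMF
    shared set (intersection of per-cohort sets) and the local-NMF specific
    sets (each cohort's own set).
    """
    master = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        for rep in range(n_reps):
            rep_seed = int(master.integers(2**31))
            spec = Case2Spec(shared_fraction=float(frac), rank=rank,
                             seed=rep_seed, **case2_kw)
            datasets, truth = gen_case2(spec)
            names = datasets[0].feature_names
            session = create_session(datasets)
            model = fit_inmf(session, rank=rank, lam_het=lam_het,
                             n_starts=n_starts, max_iter=max_iter,
                             seed=rep_seed)
            sig = extract_signatures(session, model)
            truth_shared = set(truth["shared"])
            inmf_shared = _precision(set(sig["shared"]), truth_shared)
            inmf_specific = np.mean([
                _precision(set(sig["specific"][d.task_id]),
                           set(truth["specific"][d.task_id]))
                for d in datasets
            ])
            bag = bagging_baseline(datasets, "nmf_local", rank=rank,
                                   seed=rep_seed)
            bag_shared = _precision({names[i] for i in bag["shared"]},
                                    truth_shared)
            bag_specific = np.mean([
                _precision({names[i] for i in bag["specific"][d.task_id]},
                           set(truth["specific"][d.task_id]))
                for d in datasets
            ])
            rows.append({
                "shared_fraction": float(frac), "rep": rep, "seed": rep_seed,
                "inmf_shared": inmf_shared, "inmf_specific": inmf_specific,
                "bagging_shared": bag_shared, "bagging_specific": bag_specific,
            })
    return pd.DataFrame(rows)


def reproducibility_experiment(
    datasets: list[TaskDataset],
    algorithm: str = "l21",
    k: int = 200,
    loss: str = "ls",
    seed: int = 0,
    options: SolverOptions | None = None,
    depth: int = 10,
) -> dict:
    """Split-half signature reproducibility (generic over synthetic cohorts).

    The cohorts are split into two groups; the chosen federated algorithm is
    cross-validated within each group; the top-``k`` signed gene scores
    (mean coefficient across the group's tasks) of the two fits are compared
    with :func:`signature_overlap`.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two cohorts to split")
    half = len(datasets) // 2
    groups = [datasets[:half], datasets[half:]]
    signed = []
    for g in groups:
        session = create_session(g)
        cvres = cross_validate(session, algorithm=algorithm, loss=loss,
                               seed=seed, options=options, depth=depth)
        W = cvres["model"].model.W
        names = cvres["model"].model.feature_names
        signed.append(pd.Series(W.mean(axis=1), index=names))
    overlap = signature_overlap(signed[0], signed[1], k=k)
    return {"overlap": overlap, "signed_scores": signed}
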