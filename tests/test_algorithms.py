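"""User-facing fits against the centralized reference, algorithm-specific
structure, and cross-validation behavior."""

import numpy as np
import pytest

import fedmtl as fm
from fedmtl.solver import ProblemSpec, SolverOptions, lambda_max, lambda_sequence
from tests._reference import solve_centralized
from tests.conftest import make_datasets

TIGHT = SolverOptions(tol=1e-15, max_iter=20000)


def datasets_and_session(T=3, p=10, n=60, seed=0, loss="ls"):
    ds = make_datasets(T=T, p=p, n=n, seed=seed, loss=loss)
    return ds, fm.create_session(ds)


def ref_args(ds):
    return [d.X for d in ds], [d.y for d in ds]


class TestMasterOracle:
    """Federated fits equal a single-process reference on the concatenated
    data (quantization off)."""

    def test_l21(self):
        ds, s = datasets_and_session(seed=11)
        prob = ProblemSpec(session=s, penalty="l21")
        lam = 0.3 * lambda_max(prob)
        res = fm.fit_l21(s, lam=lam, options=TIGHT)
        Xs, ys = ref_args(ds)
        W, c, _ = solve_centralized(Xs, ys, penalty="l21", lam=lam)
        assert np.allclose(res.model.W, W, atol=1e-6)
        assert np.allclose(res.model.c, c, atol=1e-6)

    def test_trace(self):
        ds, s = datasets_and_session(seed=12)
        prob = ProblemSpec(session=s, penalty="trace")
        lam = 0.3 * lambda_max(prob)
        res = fm.fit_trace(s, lam=lam, options=TIGHT)
        Xs, ys = ref_args(ds)
        W, c, _ = solve_centralized(Xs, ys, penalty="trace", lam=lam)
        assert np.allclose(res.model.W, W, atol=1e-6)

    def test_net(self):
        ds, s = datasets_and_session(seed=13)
        prob = ProblemSpec(session=s, penalty="l1")
        lam = 0.2 * lambda_max(prob)
        R = fm.mean_graph(3)
        res = fm.fit_net(s, lam=lam, C=0.5, options=TIGHT)
        Xs, ys = ref_args(ds)
        W, c, _ = solve_centralized(Xs, ys, penalty="l1", lam=lam, C=0.5,
                                    smooth="graph", R=R.R)
        assert np.allclose(res.model.W, W, atol=1e-6)

    def test_lasso(self):
        ds, s = datasets_and_session(seed=14)
        prob = ProblemSpec(session=s, penalty="l1", coupling="pooled")
        lam = 0.3 * lambda_max(prob)
        res = fm.fit_lasso(s, lam=lam, options=TIGHT)
        Xs, ys = ref_args(ds)
        W, c, _ = solve_centralized(Xs, ys, penalty="l1", lam=lam, coupling="pooled")
        assert np.allclose(res.model.W, W, atol=1e-6)
        assert res.model.c[0] == pytest.approx(c[0], abs=1e-6)

    def test_l21_logistic(self):
        ds, s = datasets_and_session(seed=15, loss="logistic", n=80)
        prob = ProblemSpec(session=s, loss="logistic", penalty="l21")
        lam = 0.3 * lambda_max(prob)
        res = fm.fit_l21(s, loss="logistic", lam=lam, options=TIGHT)
        Xs, ys = ref_args(ds)
        W, c, _ = solve_centralized(Xs, ys, loss="logistic", penalty="l21", lam=lam)
        assert np.allclose(res.model.W, W, atol=1e-6)


class TestAlgorithmStructure:
    def test_huge_lambda_zero_model(self):
        _, s = datasets_and_session()
        res = fm.fit_l21(s, lam=1e6)
        assert np.count_nonzero(res.model.W) == 0

    def test_l21_single_task_equals_lasso(self):
        ds, _ = datasets_and_session(T=1, seed=21)
        s1 = fm.create_session(ds)
        s2 = fm.create_session(ds)
        lam = 0.2
        a = fm.fit_l21(s1, lam=lam, options=TIGHT)
        b = fm.fit_lasso(s2, lam=lam, options=TIGHT)
        assert np.allclose(a.model.W, b.model.W, atol=1e-8)

    def test_net_C0_reduces_to_per_task_lasso(self):
        ds, s = datasets_and_session(seed=22)
        lam = 0.15
        res = fm.fit_net(s, lam=lam, C=0.0, options=TIGHT)
        for t, d in enumerate(ds):
            single = fm.create_session([d])
            ref = fm.fit_lasso(single, lam=lam, options=TIGHT)
            assert np.allclose(res.model.W[:, t], ref.model.W[:, 0], atol=1e-6)

    def test_net_large_C_pulls_columns_together(self):
        _, s = datasets_and_session(seed=23)
        lam = 0.05
        loose = fm.fit_net(s, lam=lam, C=0.0, options=TIGHT)
        tight = fm.fit_net(s, lam=lam, C=100.0, options=TIGHT)
        var_loose = np.var(loose.model.W, axis=1).sum()
        var_tight = np.var(tight.model.W, axis=1).sum()
        assert var_tight < 0.05 * var_loose

    def test_trace_rank_non_increasing_in_lambda(self):
        _, s = datasets_and_session(seed=24)
        prob = ProblemSpec(session=s, penalty="trace")
        lams = lambda_sequence(lambda_max(prob), 0.02, 6)[::-1]  # ascending
        ranks = []
        for lam in lams:
            res = fm.fit_trace(s, lam=float(lam), options=TIGHT)
            sv = np.linalg.svd(res.model.W, compute_uv=False)
            ranks.append(int(np.sum(sv > 1e-8)))
        assert all(r2 <= r1 for r1, r2 in zip(ranks, ranks[1:]))

    def test_lasso_split_equals_unsplit(self, rng):
        X = rng.standard_normal((50, 8))
        w = np.zeros(8)
        w[:3] = [1.0, -2.0, 0.5]
        y = X @ w + 0.3 * rng.standard_normal(50)
        names = [f"g{i}" for i in range(8)]
        whole = fm.create_session([fm.TaskDataset(X, y, names, "all")])
        split = fm.create_session(
            [fm.TaskDataset(X[:25], y[:25], names, "a"),
             fm.TaskDataset(X[25:], y[25:], names, "b")]
        )
        a = fm.fit_lasso(whole, lam=0.1, options=TIGHT)
        b = fm.fit_lasso(split, lam=0.1, options=TIGHT)
        assert np.allclose(a.model.W, b.model.W, atol=1e-7)


class TestL21Selection:
    def test_selected_rows_cover_true_support(self):
        spec = fm.Case1Spec(T=3, p=30, n_per_task=60, support_size=4,
                            noise_sd=0.3, seed=5)
        ds, truth = fm.gen_case1(spec)
        s = fm.create_session(ds)
        prob = ProblemSpec(session=s, penalty="l21")
        seq = lambda_sequence(lambda_max(prob), 0.01, 10)
        path = fm.solve_path(prob, seq, SolverOptions(tol=1e-8))
        covered = False
        for res in path.results:
            rows = set(np.flatnonzero(np.linalg.norm(res.model.W, axis=1) > 1e-8))
            if set(truth["support"]).issubset(rows):
                covered = True
                break
        assert covered


class TestCrossValidate:
    def test_deterministic_given_seed(self):
        results = []
        for _ in range(2):
            ds, _ = fm.gen_case1(fm.Case1Spec(T=2, p=15, n_per_task=20, seed=8))
            s = fm.create_session(ds)
            results.append(fm.cross_validate(s, algorithm="lasso", seed=42, depth=8))
        assert results[0]["lam_best"] == results[1]["lam_best"]
        assert np.array_equal(results[0]["cv_table"]["mean_metric"],
                              results[1]["cv_table"]["mean_metric"])

    def test_small_server_rejected(self):
        ds = make_datasets(T=2, p=4, n=3)
        s = fm.create_session(ds)
        with pytest.raises(ValueError, match="folds"):
            fm.cross_validate(s, k_folds=5)

    def test_recovers_near_oracle_test_error(self):
        """The CV-selected lambda's model predicts fresh data nearly as well
        as the best model on the path."""
        spec = fm.Case1Spec(T=2, p=30, n_per_task=40, support_size=3,
                            noise_sd=1.0, seed=17)
        ds, truth = fm.gen_case1(spec)
        s = fm.create_session(ds)
        cv = fm.cross_validate(s, algorithm="l21", seed=1, depth=10)
        # fresh evaluation data from the same truth
        rng = np.random.default_rng(999)
        prob = ProblemSpec(session=s, penalty="l21")
        seq = lambda_sequence(lambda_max(prob), 0.01, 10)
        path = fm.solve_path(prob, seq, SolverOptions())
        Xe = rng.standard_normal((400, 30))
        errors = []
        for res in path.results:
            err = 0.0
            for t in range(2):
                pred = Xe @ res.model.W[:, t] + res.model.c[t]
                ytrue = Xe @ truth["W_true"][:, t]
                err += np.mean((pred - ytrue) ** 2)
            errors.append(err / 2)
        cv_err = 0.0
        for t in range(2):
            pred = Xe @ cv["model"].model.W[:, t] + cv["model"].model.c[t]
            cv_err += np.mean((pred - Xe @ truth["W_true"][:, t]) ** 2) / 2
        assert cv_err <= max(1.3 * min(errors), min(errors) + 0.1)

    def test_binary_outcome_stratified_cv_runs(self):
        ds, _ = fm.gen_case1(fm.Case1Spec(T=2, p=10, n_per_task=40,
                                          outcome="binary", seed=30))
        s = fm.create_session(ds)
        out = fm.cross_validate(s, algorithm="l21", loss="logistic", seed=3,
                                depth=5, k_folds=3)
        assert 0.0 <= out["cv_table"]["mean_metric"].min() <= 1.0
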