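"""Solver correctness: closed forms, lambda scale, paths, termination,
metering, and quantization behavior."""

import numpy as np
import pytest

import fedmtl as fm
from fedmtl.federation import PrivacyPolicy
from fedmtl.solver import (
    ProblemSpec,
    SolverOptions,
    check_termination,
    fista_solve,
    lambda_max,
    lambda_sequence,
    smooth_value_grad,
    solve_path,
)
from tests.conftest import make_datasets

TIGHT = SolverOptions(tol=1e-15, max_iter=20000)


def session_for(T=1, p=5, n=30, seed=0, loss="ls"):
    return fm.create_session(make_datasets(T=T, p=p, n=n, seed=seed, loss=loss))


class TestSmoothValueGrad:
    def test_multi_task_metering(self):
        s = session_for(T=3, p=4)
        prob = ProblemSpec(session=s, penalty="l21")
        before = fm.comm_summary(s)
        smooth_value_grad(prob, np.zeros((4, 3)), np.zeros(3))
        after = fm.comm_summary(s)
        assert after["rounds"] - before["rounds"] == 1
        assert after["total_accesses"] - before["total_accesses"] == 3

    def test_pooled_equals_centralized_union(self, rng):
        X = rng.standard_normal((40, 6))
        w_true = rng.standard_normal(6)
        y = X @ w_true + 0.1 * rng.standard_normal(40)
        names = [f"g{i}" for i in range(6)]
        # unequal split to exercise the sample-size weighting
        d1 = fm.TaskDataset(X[:13], y[:13], names, "a")
        d2 = fm.TaskDataset(X[13:], y[13:], names, "b")
        s = fm.create_session([d1, d2])
        prob = ProblemSpec(session=s, penalty="l1", coupling="pooled")
        W = rng.standard_normal((6, 1))
        c = np.array([0.2])
        v, gW, gc = smooth_value_grad(prob, W, c)
        r = X @ W[:, 0] + c[0] - y
        assert v == pytest.approx(r @ r / (2 * 40), rel=1e-12)
        assert np.allclose(gW[:, 0], X.T @ r / 40, atol=1e-12)
        assert gc[0] == pytest.approx(r.mean(), rel=1e-12)

    def test_zero_C_is_loss_alone(self, rng):
        s = session_for(T=2, p=3)
        prob_plain = ProblemSpec(session=s, penalty="l1")
        prob_ridge = ProblemSpec(session=s, penalty="l1", smooth="ridge", C=0.0)
        W = rng.standard_normal((3, 2))
        c = np.zeros(2)
        va, _, _ = smooth_value_grad(prob_plain, W, c)
        vb, _, _ = smooth_value_grad(prob_ridge, W, c)
        assert va == pytest.approx(vb)


class TestFistaSolve:
    def test_unpenalized_matches_normal_equations(self, rng):
        s = session_for(T=1, p=5, n=40, seed=1)
        d = s.servers[s.server_ids[0]]._dataset
        prob = ProblemSpec(session=s, penalty="l1", lam=0.0, fit_intercept=False)
        res = fista_solve(prob, TIGHT)
        w_ref = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        assert np.allclose(res.model.W[:, 0], w_ref, atol=1e-6)

    @pytest.mark.parametrize("penalty", ["l1", "l21", "trace"])
    def test_above_lambda_max_zero_below_nonzero(self, penalty):
        s = session_for(T=3, p=6, n=25, seed=4)
        coupling = "pooled" if penalty == "l1" else "multi_task"
        prob = ProblemSpec(session=s, penalty=penalty, coupling=coupling)
        lm = lambda_max(prob)
        hi = fista_solve(ProblemSpec(session=s, penalty=penalty, coupling=coupling,
                                     lam=1.01 * lm), TIGHT)
        lo = fista_solve(ProblemSpec(session=s, penalty=penalty, coupling=coupling,
                                     lam=0.9 * lm), TIGHT)
        assert np.count_nonzero(hi.model.W) == 0
        assert np.count_nonzero(lo.model.W) > 0

    def test_objective_history_non_increasing_random_problems(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            T = int(rng.integers(1, 4))
            s = session_for(T=T, p=int(rng.integers(2, 9)), n=15, seed=seed)
            penalty = ["l1", "l21", "trace"][seed % 3]
            prob = ProblemSpec(session=s, penalty=penalty,
                               coupling="multi_task", lam=float(rng.uniform(0, 0.5)))
            res = fista_solve(prob, SolverOptions(max_iter=150))
            diffs = np.diff(res.objective)
            assert np.all(diffs <= 1e-12), f"seed {seed}: objective increased"

    def test_metering_matches_recorded_counters(self):
        """Session log and the solver's own accounting agree: a converged
        fit costs 1 intercept round + 2 rounds per iteration (gradient +
        accepted candidate) + 1 round per line-search retry."""
        s = session_for(T=2, p=6, n=30, seed=2)
        prob = ProblemSpec(session=s, penalty="l1", coupling="pooled", lam=0.1)
        res = fista_solve(prob, SolverOptions(tol=1e-8, max_iter=500))
        assert res.converged
        assert res.comm["rounds"] == 1 + 2 * res.n_iter + res.retries
        assert res.comm["total_accesses"] == res.comm["rounds"] * s.n_servers

    def test_quantization_deviation_shrinks_with_digits(self):
        results = {}
        for digits in (3, 6, None):
            ds = make_datasets(T=2, p=5, n=30, seed=9)
            s = fm.create_session(ds, PrivacyPolicy(digits=digits))
            prob = ProblemSpec(session=s, penalty="l21", lam=0.1)
            results[digits] = fista_solve(prob, SolverOptions(tol=1e-9)).model.W
        err3 = np.abs(results[3] - results[None]).max()
        err6 = np.abs(results[6] - results[None]).max()
        assert err6 <= err3 + 1e-12
        assert err6 < 1e-3


class TestLambdaMax:
    def test_pooled_lasso_hand_case(self):
        d = fm.TaskDataset(np.array([[1.0], [-1.0]]), np.array([1.0, -1.0]), ["g0"], "a")
        s = fm.create_session([d])
        prob = ProblemSpec(session=s, penalty="l1", coupling="pooled",
                           fit_intercept=False)
        assert lambda_max(prob) == pytest.approx(1.0)
        # subgradient check: solving just above gives exactly zero
        res = fista_solve(ProblemSpec(session=s, penalty="l1", coupling="pooled",
                                      fit_intercept=False, lam=1.0 + 1e-9), TIGHT)
        assert np.count_nonzero(res.model.W) == 0

    def test_l21_two_singleton_tasks(self):
        ds = [
            fm.TaskDataset(np.array([[1.0]]), np.array([1.0]), ["g0"], t)
            for t in ("a", "b")
        ]
        s = fm.create_session(ds)
        prob = ProblemSpec(session=s, penalty="l21", fit_intercept=False)
        assert lambda_max(prob) == pytest.approx(np.sqrt(2.0))

    def test_solver_self_consistency(self):
        s = session_for(T=2, p=8, n=30, seed=6)
        prob = ProblemSpec(session=s, penalty="trace")
        lm = lambda_max(prob)
        hi = fista_solve(ProblemSpec(session=s, penalty="trace", lam=1.01 * lm), TIGHT)
        lo = fista_solve(ProblemSpec(session=s, penalty="trace", lam=0.9 * lm), TIGHT)
        assert np.allclose(hi.model.W, 0.0, atol=1e-12)
        assert np.count_nonzero(np.abs(lo.model.W) > 1e-10) > 0


class TestLambdaSequence:
    def test_log_interpolation(self):
        assert lambda_sequence(1.0, 0.01, 3) == pytest.approx([1.0, 0.1, 0.01])

    def test_depth_two_endpoints(self):
        assert lambda_sequence(2.0, 0.5, 2) == pytest.approx([2.0, 1.0])

    def test_constant_ratio(self):
        seq = lambda_sequence(3.0, 0.001, 10)
        ratios = seq[1:] / seq[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            lambda_sequence(1.0, 1.5, 5)
        with pytest.raises(ValueError):
            lambda_sequence(1.0, 0.1, 1)


class TestSolvePath:
    def test_first_entry_all_zero_and_warm_matches_cold(self):
        s = session_for(T=2, p=6, n=30, seed=3)
        prob = ProblemSpec(session=s, penalty="l21")
        seq = lambda_sequence(lambda_max(prob), 0.05, 6)
        path = solve_path(prob, seq, TIGHT)
        assert np.count_nonzero(path.results[0].model.W) == 0
        for lam, warm in zip(seq, path.results):
            cold = fista_solve(ProblemSpec(session=s, penalty="l21", lam=float(lam)),
                               TIGHT)
            assert np.allclose(warm.model.W, cold.model.W, atol=1e-5)

    def test_sparsity_grows_down_the_path_on_average(self):
        total_diff = 0
        for seed in range(5):
            s = session_for(T=2, p=10, n=25, seed=seed + 20)
            prob = ProblemSpec(session=s, penalty="l1", coupling="multi_task")
            seq = lambda_sequence(lambda_max(prob), 0.01, 8)
            path = solve_path(prob, seq, SolverOptions(tol=1e-8))
            nnz = [np.count_nonzero(r.model.W) for r in path.results]
            total_diff += nnz[-1] - nnz[0]
        assert total_diff > 0

    def test_rejects_non_descending(self):
        s = session_for()
        prob = ProblemSpec(session=s, penalty="l1")
        with pytest.raises(ValueError):
            solve_path(prob, [0.1, 0.2], TIGHT)


class TestCheckTermination:
    def test_identical_objectives_terminate(self):
        assert check_termination([1.0, 1.0], "objective_rel", 1e-5) is True

    def test_single_point_never(self):
        assert check_termination([1.0], "objective_rel", 1e-5) is False

    def test_zero_tol_exact_only(self):
        assert check_termination([1.0, 1.0], "objective_rel", 0.0) is True
        assert check_termination([1.0, 1.0 - 1e-9], "objective_rel", 0.0) is False

    def test_param_rel(self):
        A = np.ones((2, 2))
        assert check_termination([A, A], "param_rel", 0.0) is True
        assert check_termination([A, A * 1.5], "param_rel", 1e-3) is False

    def test_iter_only_never(self):
        assert check_termination([1.0, 1.0], "iter_only", 1.0) is False
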