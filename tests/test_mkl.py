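"""The MKL epsilon-SVR solver: dual correctness, simplex search, predictions."""

import itertools

import numpy as np
import pytest

from roimkl import (
    LeakageError,
    MKLModel,
    center_and_normalize,
    decision_function,
    mkl_fit,
    mkl_predict,
    solve_svr_dual,
)
from roimkl.kernels import KernelSet


def _kernelset(n, M, p=20, seed=0, center=True):
    rng = np.random.default_rng(seed)
    Xs = [rng.standard_normal((n, p)) for _ in range(M)]
    ks = KernelSet(
        stack=np.stack([X @ X.T for X in Xs]),
        block_index=[(f"R{m:02d}", "harmful") for m in range(M)],
        subjects=[f"s{i}" for i in range(n)],
        block_sizes=[p] * M,
    )
    if center:
        ks = center_and_normalize(ks, range(n))
    return ks, Xs


def svr_dual_active_set_oracle(K, y, C, eps):
    """Exhaustive active-set enumeration of the epsilon-SVR dual (tiny n).

    Each point is in one of five KKT states; for every assignment the free
    coefficients and offset solve a linear system, feasibility is checked,
    and the best feasible dual value is kept.
    """
    n = len(y)
    best = -np.inf
    best_beta = None
    states = ["zero", "up_free", "up_bound", "low_free", "low_bound"]
    for assign in itertools.product(states, repeat=n):
        beta = np.zeros(n)
        for i, st in enumerate(assign):
            beta[i] = C if st == "up_bound" else (-C if st == "low_bound" else 0.0)
        free = [i for i, st in enumerate(assign) if st in ("up_free", "low_free")]
        k = len(free)
        # unknowns: free betas + b; equations: tube equalities + sum(beta)=0
        A = np.zeros((k + 1, k + 1))
        rhs = np.zeros(k + 1)
        for r, i in enumerate(free):
            target = y[i] - eps if assign[i] == "up_free" else y[i] + eps
            A[r, :k] = K[i, free]
            A[r, k] = 1.0
            rhs[r] = target - sum(K[i, j] * beta[j] for j in range(n) if j not in free)
        A[k, :k] = 1.0
        rhs[k] = -beta.sum()
        try:
            sol, res, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
        except np.linalg.LinAlgError:
            continue
        if np.abs(A @ sol - rhs).max() > 1e-8:
            continue
        for r, i in enumerate(free):
            beta[i] = sol[r]
        b = sol[k]
        tol = 1e-8
        ok = abs(beta.sum()) < 1e-6
        f = K @ beta + b
        for i, st in enumerate(assign):
            resid = y[i] - f[i]
            if st == "zero":
                ok &= abs(resid) <= eps + tol
            elif st == "up_free":
                ok &= tol < beta[i] < C - tol
            elif st == "low_free":
                ok &= -C + tol < beta[i] < -tol
            elif st == "up_bound":
                ok &= resid >= eps - tol
            else:
                ok &= resid <= -eps + tol
        if not ok:
            continue
        W = y @ beta - 0.5 * beta @ K @ beta - eps * np.abs(beta).sum()
        if W > best:
            best = W
            best_beta = beta.copy()
    return best, best_beta


class TestSolveSVRDual:
    def test_matches_active_set_enumeration_on_4_points(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((4, 6))
        K = X @ X.T
        y = rng.standard_normal(4)
        beta, b, obj = solve_svr_dual(K, y, C=1.0, epsilon=0.1, tol=1e-10)
        best, _ = svr_dual_active_set_oracle(K, y, 1.0, 0.1)
        assert abs(obj - best) <= 1e-6 * max(1.0, abs(best))

    def test_interpolable_labels_stay_inside_tube(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 8))
        K = X @ X.T
        y = K @ (0.01 * rng.standard_normal(6))  # small-norm interpolant
        beta, b, _ = solve_svr_dual(K, y, C=10.0, epsilon=0.1)
        assert np.abs(beta).max() < 10.0 - 1e-9
        assert np.abs(K @ beta + b - y).max() <= 0.1 + 1e-8

    def test_tiny_C_collapses_to_constant_offset(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((8, 10))
        K = X @ X.T
        y = rng.standard_normal(8)
        beta, b, _ = solve_svr_dual(K, y, C=1e-6, epsilon=0.1)
        pred = K @ beta + b
        assert np.ptp(pred) < 1e-3
        assert y.min() <= b <= y.max()

    def test_matches_reference_svr_implementation(self):
        # one-kernel cross-check against an established solver
        sklearn = pytest.importorskip("sklearn.svm")
        rng = np.random.default_rng(7)
        for C in (0.1, 1.0, 100.0):
            X = rng.standard_normal((12, 30))
            K = X @ X.T
            y = rng.standard_normal(12)
            beta, b, _ = solve_svr_dual(K, y, C=C, epsilon=0.1, tol=1e-10)
            ref = sklearn.SVR(kernel="precomputed", C=C, epsilon=0.1, tol=1e-10)
            ref.fit(K, y)
            assert np.abs(K @ beta + b - ref.predict(K)).max() <= 1e-5


def _grid_search_objective(ks, y, C, eps, step=0.02):
    """Exact SVR solve at every simplex grid point; the brute-force oracle."""
    M = len(ks)
    N = int(round(1.0 / step))
    best = np.inf
    if M == 2:
        combos = [(a, N - a) for a in range(N + 1)]
    else:
        combos = [(a, b, N - a - b) for a in range(N + 1) for b in range(N + 1 - a)]
    for combo in combos:
        d = np.array(combo, dtype=float) / N
        K = np.einsum("m,mij->ij", d, ks.stack)
        _, _, obj = solve_svr_dual(K, y, C, eps, tol=1e-9)
        best = min(best, obj)
    return best


class TestMKLFit:
    def test_single_kernel_reduces_to_plain_svr(self):
        ks, _ = _kernelset(10, 1, seed=3)
        y = np.random.default_rng(3).standard_normal(10)
        model = mkl_fit(ks, y, range(10), C=10.0)
        assert model.d.shape == (1,) and model.d[0] == 1.0
        beta, b, _ = solve_svr_dual(ks[0], y, C=10.0, epsilon=0.1)
        assert np.allclose(model.dual_coef, beta, atol=1e-8)
        assert abs(model.offset - b) < 1e-8

    def test_signal_kernel_dominates_weights(self):
        # kernel 1 carries a label-coupled pattern (the generator's model),
        # kernel 2 is pure noise; nearly noiseless labels
        rng = np.random.default_rng(8)
        n, p = 14, 25
        y = rng.standard_normal(n)
        y = (y - y.mean()) / y.std()
        v = rng.standard_normal(p)
        v /= np.linalg.norm(v)
        X1 = np.outer(y, v) + 1e-3 * rng.standard_normal((n, p))
        X2 = rng.standard_normal((n, p))
        ks = KernelSet(stack=np.stack([X1 @ X1.T, X2 @ X2.T]),
                       block_index=[("sig", "harmful"), ("noise", "harmful")],
                       subjects=[f"s{i}" for i in range(n)], block_sizes=[p, p])
        ks = center_and_normalize(ks, range(n))
        model = mkl_fit(ks, y, range(n), C=10.0)
        assert model.d[0] >= 0.95

    @pytest.mark.parametrize("seed", range(6))
    def test_objective_matches_simplex_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 13))
        M = int(rng.integers(2, 4))
        ks, _ = _kernelset(n, M, seed=seed + 50)
        y = rng.standard_normal(n)
        y = (y - y.mean()) / y.std()
        C = float(rng.choice([0.1, 1.0, 10.0]))
        model = mkl_fit(ks, y, range(n), C=C, tol=1e-5, max_iter=500)
        J = model.objective_trace[-1]
        J_grid = _grid_search_objective(ks, y, C, 0.1)
        assert J <= J_grid + 1e-3 * abs(J_grid)

    def test_objective_trace_monotone_and_simplex_feasible(self):
        ks, _ = _kernelset(12, 3, seed=9)
        y = np.random.default_rng(9).standard_normal(12)
        model = mkl_fit(ks, y, range(12), C=10.0)
        trace = np.asarray(model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9)
        assert np.all(model.d >= 0.0)
        assert abs(model.d.sum() - 1.0) < 1e-8

    def test_kernel_permutation_permutes_weights(self):
        ks, _ = _kernelset(10, 3, seed=10)
        y = np.random.default_rng(10).standard_normal(10)
        model = mkl_fit(ks, y, range(10), C=10.0, tol=1e-6)
        perm = [2, 0, 1]
        ks_p = KernelSet(stack=ks.stack[perm],
                         block_index=[ks.block_index[i] for i in perm],
                         subjects=list(ks.subjects),
                         block_sizes=[ks.block_sizes[i] for i in perm])
        model_p = mkl_fit(ks_p, y, range(10), C=10.0, tol=1e-6)
        assert np.allclose(model_p.d, model.d[perm], atol=1e-6)


class TestMKLPredict:
    def _fitted(self, seed=11):
        ks, _ = _kernelset(10, 2, seed=seed, center=False)
        train = list(range(8))
        ksc = center_and_normalize(ks, train)
        y = np.random.default_rng(seed).standard_normal(10)
        model = mkl_fit(ksc, y, train, C=10.0)
        return ks, ksc, y, model

    def test_training_predictions_within_tube_for_interpolating_model(self):
        ks, _ = _kernelset(8, 1, seed=12)
        rng = np.random.default_rng(12)
        y = ks[0] @ (0.01 * rng.standard_normal(8))
        model = mkl_fit(ks, y, range(8), C=100.0)
        pred = decision_function(model, ks, range(8))
        assert np.abs(pred - y).max() <= 0.1 + 1e-6

    def test_overlap_raises_leakage_error(self):
        _, ksc, _, model = self._fitted()
        with pytest.raises(LeakageError):
            mkl_predict(model, ksc, [7, 8])
        # disjoint indices pass
        assert mkl_predict(model, ksc, [8, 9]).shape == (2,)

    def test_sparse_model_ignores_corrupted_dead_kernel(self):
        ks, ksc, y, model = self._fitted()
        forced = MKLModel(d=np.array([1.0, 0.0]), dual_coef=model.dual_coef,
                          offset=model.offset, C=model.C, epsilon=model.epsilon,
                          train_idx=model.train_idx)
        base = mkl_predict(forced, ksc, [8, 9])
        corrupted = KernelSet(stack=ksc.stack.copy(),
                              block_index=list(ksc.block_index),
                              subjects=list(ksc.subjects),
                              block_sizes=list(ksc.block_sizes))
        corrupted.stack[1, 8:, :] = 1e6
        corrupted.stack[1, :, 8:] = 1e6
        assert np.array_equal(base, mkl_predict(forced, corrupted, [8, 9]))

    def test_rebuilt_kernels_give_identical_predictions(self):
        from roimkl import build_kernels
        from conftest import make_study

        _, _, data, ks1 = make_study(n_subjects=8, seed=13)
        ks2 = build_kernels(data)
        train = list(range(6))
        y = np.random.default_rng(13).standard_normal(8)
        m1 = mkl_fit(center_and_normalize(ks1, train), y, train, C=10.0)
        p1 = mkl_predict(m1, center_and_normalize(ks1, train), [6, 7])
        p2 = mkl_predict(m1, center_and_normalize(ks2, train), [6, 7])
        assert np.abs(p1 - p2).max() <= 1e-10

    def test_model_json_round_trip_repredicts_exactly(self, tmp_path):
        ks, ksc, y, model = self._fitted()
        path = tmp_path / "model.json"
        model.to_json(path)
        back = MKLModel.from_json(path)
        assert np.array_equal(back.d, model.d)
        assert np.array_equal(
            mkl_predict(model, ksc, [8, 9]), mkl_predict(back, ksc, [8, 9])
        )
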