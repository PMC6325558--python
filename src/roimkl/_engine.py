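"""Compiled numerical core.

Every hot loop of the pipeline lives here as a numba kernel over plain
float64 arrays: the SMO solver for the epsilon-SVR dual, leakage-free
kernel centering/normalization, the reduced-gradient search for simplex
kernel weights, and the nested leave-one-subject-out cross-validation.
The public modules (`kernels`, `mkl`, `inference`) wrap these with
validated, documented types; nothing in here knows about names, regions
or files.

Conventions
-----------
* Kernel stacks are ``(M, n, n)`` float64 arrays, one Gram matrix per
  region x condition block, subjects in rows/columns.
* The SVR dual is posed in the 2n libsvm form: variables
  ``z = (alpha, alpha*)``, minimize ``1/2 z'Qz + p'z`` with
  ``Q = [[K, -K], [-K, K]]``, ``p = (eps - y, eps + y)``, subject to
  ``0 <= z <= C`` and ``s'z = 0`` where ``s = (+1...,-1...)``.  Signed
  dual coefficients are ``beta = alpha - alpha*``.
* The MKL objective is ``J(d) = max_z dual(z; K(d))``; it is convex in
  ``d`` and minimized over the probability simplex.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BIG = 1e300


@njit(cache=True)
def smo_epsilon_svr(K, y, C, epsilon, tol, max_iter):
    """Solve the epsilon-SVR dual by SMO with maximal-violating-pair selection.

    Returns ``(beta, b, objective, n_iter, gap)`` where ``objective`` is the
    dual maximum (the value J(d) used by the MKL outer loop) and ``gap`` is
    the final KKT violation.  Deterministic: ties in working-set selection
    go to the lowest index.
    """
    n = K.shape[0]
    z = np.zeros(2 * n)
    G = np.empty(2 * n)
    for i in range(n):
        G[i] = epsilon - y[i]
        G[n + i] = epsilon + y[i]

    it = 0
    gmax = 0.0
    gmin = 0.0
    for it in range(max_iter):
        # first-order pick of i; second-order (largest decrease) pick of j
        gmax = -BIG
        gmin = BIG
        i_sel = -1
        for t in range(2 * n):
            s = 1.0 if t < n else -1.0
            v = -s * G[t]
            if (s > 0.0 and z[t] < C) or (s < 0.0 and z[t] > 0.0):
                if v > gmax:
                    gmax = v
                    i_sel = t
            if (s > 0.0 and z[t] > 0.0) or (s < 0.0 and z[t] < C):
                if v < gmin:
                    gmin = v
        if i_sel < 0 or gmax - gmin < tol:
            break
        i = i_sel
        ii0 = i % n
        Kii = K[ii0, ii0]
        j_sel = -1
        best = BIG
        for t in range(2 * n):
            s = 1.0 if t < n else -1.0
            if (s > 0.0 and z[t] > 0.0) or (s < 0.0 and z[t] < C):
                diff = gmax - (-s * G[t])
                if diff > 0.0:
                    tt = t % n
                    a = Kii + K[tt, tt] - 2.0 * K[ii0, tt]
                    if a < 1e-12:
                        a = 1e-12
                    score = -(diff * diff) / a
                    if score < best:
                        best = score
                        j_sel = t
        if j_sel < 0:
            break

        j = j_sel
        si = 1.0 if i < n else -1.0
        sj = 1.0 if j < n else -1.0
        ii = i % n
        jj = j % n

        a = K[ii, ii] + K[jj, jj] - 2.0 * K[ii, jj]
        if a < 1e-12:
            a = 1e-12
        delta = (gmax - (-sj * G[j])) / a

        # box limits on the step (z_i moves by si*delta, z_j by -sj*delta)
        if si > 0.0:
            lim = C - z[i]
        else:
            lim = z[i]
        if lim < delta:
            delta = lim
        if sj > 0.0:
            lim = z[j]
        else:
            lim = C - z[j]
        if lim < delta:
            delta = lim
        if delta <= 0.0:
            break

        z[i] += si * delta
        z[j] -= sj * delta
        for t in range(n):
            upd = delta * (K[t, ii] - K[t, jj])
            G[t] += upd
            G[n + t] -= upd

    beta = np.empty(n)
    for i in range(n):
        beta[i] = z[i] - z[n + i]

    # offset from KKT: b = -s_t G_t averaged over free variables
    b_sum = 0.0
    n_free = 0
    for t in range(2 * n):
        if 1e-12 * C < z[t] < C * (1.0 - 1e-12):
            s = 1.0 if t < n else -1.0
            b_sum += -s * G[t]
            n_free += 1
    if n_free > 0:
        b = b_sum / n_free
    else:
        b = 0.5 * (gmax + gmin) if gmax > -BIG and gmin < BIG else 0.0

    # dual maximum: -(1/2 z'Qz + p'z) = y'beta - 1/2 beta'K beta - eps*sum(z)
    quad = 0.0
    lin = 0.0
    ssum = 0.0
    for i in range(n):
        acc = 0.0
        for j in range(n):
            acc += K[i, j] * beta[j]
        quad += beta[i] * acc
        lin += y[i] * beta[i]
        ssum += z[i] + z[n + i]
    objective = lin - 0.5 * quad - epsilon * ssum
    return beta, b, objective, it, gmax - gmin


@njit(cache=True)
def combine_kernels(Kstack, d):
    M, n, _ = Kstack.shape
    out = np.zeros((n, n))
    for m in range(M):
        w = d[m]
        if w != 0.0:
            for i in range(n):
                for j in range(n):
                    out[i, j] += w * Kstack[m, i, j]
    return out


@njit(cache=True)
def center_normalize_stack(Kstack, train_idx, normalize):
    """Feature-space centering and trace normalization using training rows only.

    Centering uses the kernel identity with means over ``train_idx``; each
    kernel is then divided by the mean of its training-block diagonal so the
    training-block trace equals ``len(train_idx)``.  All-zero kernels are left
    untouched (flagged in the returned scale array as 0).
    """
    M, n, _ = Kstack.shape
    nt = train_idx.shape[0]
    out = np.empty_like(Kstack)
    scales = np.empty(M)
    for m in range(M):
        K = Kstack[m]
        col_mean = np.zeros(n)
        for i in range(n):
            acc = 0.0
            for tt in range(nt):
                acc += K[i, train_idx[tt]]
            col_mean[i] = acc / nt
        grand = 0.0
        for tt in range(nt):
            grand += col_mean[train_idx[tt]]
        grand /= nt
        for i in range(n):
            for j in range(n):
                out[m, i, j] = K[i, j] - col_mean[i] - col_mean[j] + grand
        tr = 0.0
        for tt in range(nt):
            tr += out[m, train_idx[tt], train_idx[tt]]
        scale = tr / nt
        if normalize and scale > 1e-300:
            inv = 1.0 / scale
            for i in range(n):
                for j in range(n):
                    out[m, i, j] *= inv
            scales[m] = scale
        else:
            scales[m] = scale if scale > 1e-300 else 0.0
    return out, scales


@njit(cache=True)
def mkl_fit_core(Kstack, y, C, epsilon, tol, max_iter, smo_tol, smo_max_iter):
    """Reduced-gradient descent of J(d) over the probability simplex.

    Alternates (a) exact SVR dual solve at fixed d with (b) a descent step
    along the reduced gradient with backtracking line search that only
    accepts objective decrease.  Returns
    ``(d, beta, b, trace, trace_len, converged)``; ``trace`` holds the
    non-increasing objective values after each accepted outer step.
    """
    M = Kstack.shape[0]
    d = np.full(M, 1.0 / M)
    trace = np.empty(max_iter + 1)

    if M == 1:
        Kc = combine_kernels(Kstack, d)
        beta, b, J, _, _ = smo_epsilon_svr(Kc, y, C, epsilon, smo_tol, smo_max_iter)
        trace[0] = J
        return d, beta, b, trace, 1, True

    Kc = combine_kernels(Kstack, d)
    beta, b, J, _, _ = smo_epsilon_svr(Kc, y, C, epsilon, smo_tol, smo_max_iter)
    trace[0] = J
    trace_len = 1
    converged = False

    grad = np.empty(M)
    D = np.empty(M)
    d_new = np.empty(M)

    for _ in range(max_iter):
        # gradient of the dual optimum wrt d_m at fixed optimal beta
        for m in range(M):
            acc = 0.0
            for i in range(Kstack.shape[1]):
                bi = beta[i]
                if bi != 0.0:
                    row = 0.0
                    for j in range(Kstack.shape[1]):
                        row += Kstack[m, i, j] * beta[j]
                    acc += bi * row
            grad[m] = -0.5 * acc

        # reference kernel: heaviest d, ties to steepest gradient, then lowest index
        mu = 0
        for m in range(1, M):
            if d[m] > d[mu] or (d[m] == d[mu] and grad[m] < grad[mu]):
                mu = m

        dsum = 0.0
        for m in range(M):
            if m == mu:
                D[m] = 0.0
                continue
            red = grad[m] - grad[mu]
            if d[m] > 1e-12 or red < 0.0:
                D[m] = -red
                dsum += D[m]
            else:
                D[m] = 0.0
        D[mu] = -dsum

        nD = 0.0
        for m in range(M):
            if abs(D[m]) > nD:
                nD = abs(D[m])
        if nD < 1e-12:
            converged = True
            break

        gamma_max = BIG
        for m in range(M):
            if D[m] < -1e-16:
                g = -d[m] / D[m]
                if g < gamma_max:
                    gamma_max = g
        if gamma_max <= 0.0 or gamma_max >= BIG:
            converged = True
            break

        # backtracking from the maximal feasible step; accept first decrease
        gamma = gamma_max
        accepted = False
        beta_n = beta
        b_n = b
        J_n = J
        for _k in range(30):
            ssum = 0.0
            for m in range(M):
                v = d[m] + gamma * D[m]
                if v < 0.0:
                    v = 0.0
                d_new[m] = v
                ssum += v
            for m in range(M):
                d_new[m] /= ssum
            Kc = combine_kernels(Kstack, d_new)
            beta_t, b_t, J_t, _, _ = smo_epsilon_svr(
                Kc, y, C, epsilon, smo_tol, smo_max_iter
            )
            if J_t < J - 1e-12 * (1.0 + abs(J)):
                accepted = True
                beta_n = beta_t
                b_n = b_t
                J_n = J_t
                break
            gamma *= 0.5
        if not accepted:
            converged = True
            break

        step = 0.0
        for m in range(M):
            diff = abs(d_new[m] - d[m])
            if diff > step:
                step = diff
            d[m] = d_new[m]
        beta = beta_n
        b = b_n
        J = J_n
        trace[trace_len] = J
        trace_len += 1
        if step < tol:
            converged = True
            break

    return d, beta, b, trace, trace_len, converged


@njit(cache=True)
def predict_from_fit(Kstack, d, beta, b, train_idx, test_idx):
    """Decision values f(x) = sum_i beta_i K(d)(x, i) + b for test subjects."""
    out = np.empty(test_idx.shape[0])
    M = Kstack.shape[0]
    for a in range(test_idx.shape[0]):
        t = test_idx[a]
        acc = 0.0
        for m in range(M):
            w = d[m]
            if w != 0.0:
                row = 0.0
                for c in range(train_idx.shape[0]):
                    row += Kstack[m, t, train_idx[c]] * beta[c]
                acc += w * row
        out[a] = acc + b
    return out


@njit(cache=True)
def _subset_stack(Kstack, idx):
    M = Kstack.shape[0]
    k = idx.shape[0]
    out = np.empty((M, k, k))
    for m in range(M):
        for a in range(k):
            for b in range(k):
                out[m, a, b] = Kstack[m, idx[a], idx[b]]
    return out


@njit(cache=True)
def _fit_and_predict(Kstack, y, train_idx, test_idx, C, epsilon,
                     mkl_tol, mkl_max_iter, smo_tol, smo_max_iter):
    """Center/normalize on train, standardize train labels, fit, predict test.

    Returns (pred, d, beta, b, y_mu, y_sd): predictions are de-standardized;
    beta/b live on the standardized-label scale.
    """
    Kc, _ = center_normalize_stack(Kstack, train_idx, True)
    nt = train_idx.shape[0]
    y_mu = 0.0
    for c in range(nt):
        y_mu += y[train_idx[c]]
    y_mu /= nt
    var = 0.0
    for c in range(nt):
        dv = y[train_idx[c]] - y_mu
        var += dv * dv
    y_sd = np.sqrt(var / nt) if nt > 1 else 0.0
    if y_sd <= 0.0:
        y_sd = 1.0
    y_tr = np.empty(nt)
    for c in range(nt):
        y_tr[c] = (y[train_idx[c]] - y_mu) / y_sd

    Ktr = _subset_stack(Kc, train_idx)
    d, beta, b, _, _, _ = mkl_fit_core(
        Ktr, y_tr, C, epsilon, mkl_tol, mkl_max_iter, smo_tol, smo_max_iter
    )
    raw = predict_from_fit(Kc, d, beta, b, train_idx, test_idx)
    pred = np.empty(test_idx.shape[0])
    for a in range(test_idx.shape[0]):
        pred[a] = raw[a] * y_sd + y_mu
    return pred, d, beta, b, y_mu, y_sd


@njit(cache=True)
def nested_cv(Kstack, y, C_grid, epsilon, mkl_tol, mkl_max_iter,
              smo_tol, smo_max_iter):
    """Nested leave-one-subject-out CV with inner leave-one-out C selection.

    Outer loop holds out one subject; the inner loop is leave-one-out over
    the remaining n-1 subjects, choosing C from ``C_grid`` by minimal inner
    MSE (ties to the smallest C, i.e. the earliest grid entry given an
    ascending grid).  Kernels are re-centered/normalized on every training
    set; labels are standardized inside every training fold.  The held-out
    subject's label and features never enter selection or fitting.

    Returns ``(y_pred, chosen_idx, d_all, beta_all, b_all, mu_all, sd_all)``.
    """
    n = Kstack.shape[1]
    M = Kstack.shape[0]
    nC = C_grid.shape[0]
    y_pred = np.empty(n)
    chosen = np.empty(n, dtype=np.int64)
    d_all = np.empty((n, M))
    beta_all = np.zeros((n, n - 1))
    b_all = np.empty(n)
    mu_all = np.empty(n)
    sd_all = np.empty(n)

    train = np.empty(n - 1, dtype=np.int64)
    inner_train = np.empty(n - 2, dtype=np.int64)
    test1 = np.empty(1, dtype=np.int64)

    for f in range(n):
        pos = 0
        for s in range(n):
            if s != f:
                train[pos] = s
                pos += 1

        best_ci = 0
        if nC > 1 and n - 1 >= 2:
            best_mse = BIG
            for ci in range(nC):
                sse = 0.0
                for vpos in range(n - 1):
                    v = train[vpos]
                    q = 0
                    for c in range(n - 1):
                        if c != vpos:
                            inner_train[q] = train[c]
                            q += 1
                    test1[0] = v
                    pred, _, _, _, _, _ = _fit_and_predict(
                        Kstack, y, inner_train, test1, C_grid[ci], epsilon,
                        mkl_tol, mkl_max_iter, smo_tol, smo_max_iter
                    )
                    dv = pred[0] - y[v]
                    sse += dv * dv
                mse = sse / (n - 1)
                if mse < best_mse:
                    best_mse = mse
                    best_ci = ci

        test1[0] = f
        pred, d, beta, b, y_mu, y_sd = _fit_and_predict(
            Kstack, y, train, test1, C_grid[best_ci], epsilon,
            mkl_tol, mkl_max_iter, smo_tol, smo_max_iter
        )
        y_pred[f] = pred[0]
        chosen[f] = best_ci
        for m in range(M):
            d_all[f, m] = d[m]
        for c in range(n - 1):
            beta_all[f, c] = beta[c]
        b_all[f] = b
        mu_all[f] = y_mu
        sd_all[f] = y_sd

    return y_pred, chosen, d_all, beta_all, b_all, mu_all, sd_all
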