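"""Multiple-kernel epsilon-SVR with simplex-constrained kernel weights.

The model is f(x) = sum_i beta_i K_d(x, x_i) + b with the combined kernel
K_d = sum_m d_m K_m, d on the probability simplex (d_m >= 0, sum d_m = 1).
Fitting alternates an exact epsilon-SVR dual solve at fixed d with a
reduced-gradient descent step on d (SimpleMKL family); the L1 simplex
constraint drives most kernel weights to exactly zero, which is what
makes the per-region weights interpretable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .kernels import KernelSet


class SolverError(RuntimeError):
    pass


class LeakageError(RuntimeError):
    """Train/test contamination detected."""


def _psd_clip(K: np.ndarray, rel_tol: float = 1e-8) -> np.ndarray:
    """Clip slightly negative eigenvalues arising from centered kernels."""
    K = 0.5 * (K + K.T)
    w, V = np.linalg.eigh(K)
    floor = -rel_tol * max(w.max(), 1.0)
    if w.min() < floor:
        raise SolverError(
            f"kernel is not positive semidefinite (min eigenvalue {w.min():g})"
        )
    if w.min() < 0.0:
        w = np.clip(w, 0.0, None)
        K = (V * w) @ V.T
    return K


def solve_svr_dual(K: np.ndarray, y: np.ndarray, C: float, epsilon: float,
                   tol: float = 1e-8, max_iter: int = 1_000_000):
    """Solve the epsilon-SVR dual QP on one Gram matrix.

    Returns ``(dual_coef, offset, objective)``: signed coefficients with
    box constraint |beta_i| <= C and sum(beta) = 0, the KKT offset averaged
    over free support vectors, and the dual optimum.
    """
    K = _psd_clip(np.asarray(K, dtype=float))
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("labels must be finite")
    if K.shape[0] != y.size:
        raise ValueError("kernel size must match label count")
    beta, b, obj, n_iter, gap = _engine.smo_epsilon_svr(
        K, y, float(C), float(epsilon), float(tol), int(max_iter)
    )
    if gap > max(tol * 10, 1e-6) and n_iter >= max_iter - 1:
        raise SolverError(
            f"SMO did not converge: KKT gap {gap:g} after {n_iter} iterations"
        )
    return beta, b, obj


@dataclass
class MKLModel:
    """Fitted simplex-weighted kernel machine.

    ``dual_coef`` and ``offset`` live on the label scale the model was fit
    on (callers that standardize labels de-standardize predictions).
    """

    d: np.ndarray
    dual_coef: np.ndarray
    offset: float
    C: float
    epsilon: float
    train_idx: np.ndarray
    objective_trace: list[float] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.dual_coef = np.asarray(self.dual_coef, dtype=float)
        self.train_idx = np.asarray(self.train_idx, dtype=np.int64)
        if np.any(self.d < -1e-12) or abs(self.d.sum() - 1.0) > 1e-8:
            raise ValueError("kernel weights must lie on the probability simplex")
        if np.any(np.abs(self.dual_coef) > self.C * (1 + 1e-8)):
            raise ValueError("dual coefficients violate the box constraint")

    def to_json(self, path=None) -> str:
        payload = {
            "d": self.d.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "offset": self.offset,
            "C": self.C,
            "epsilon": self.epsilon,
            "train_idx": self.train_idx.tolist(),
            "objective_trace": list(map(float, self.objective_trace)),
            "converged": self.converged,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, src) -> "MKLModel":
        if isinstance(src, str) and src.lstrip().startswith("{"):
            payload = json.loads(src)
        else:
            with open(src) as fh:
                payload = json.load(fh)
        return cls(
            d=np.array(payload["d"]), dual_coef=np.array(payload["dual_coef"]),
            offset=payload["offset"], C=payload["C"], epsilon=payload["epsilon"],
            train_idx=np.array(payload["train_idx"], dtype=np.int64),
            objective_trace=payload["objective_trace"],
            converged=payload["converged"],
        )


def mkl_fit(ks: KernelSet, y: np.ndarray, train_idx, C: float,
            epsilon: float = 0.1, tol: float = 1e-4, max_iter: int = 200,
            smo_tol: float = 1e-6, smo_max_iter: int = 1_000_000) -> MKLModel:
    """Fit the simplex-weighted SVR on the training block of ``ks``.

    ``ks`` must already be centered/normalized on ``train_idx``; ``y`` is
    the full-length label array (only training entries are read).  Weights
    start uniform; reaching ``max_iter`` without meeting the step criterion
    is recorded as ``converged=False``, not an error.
    """
    train_idx = np.asarray(sorted(set(int(i) for i in train_idx)), dtype=np.int64)
    y = np.asarray(y, dtype=float)
    Ktr = ks.stack[:, train_idx[:, None], train_idx[None, :]]
    Ktr = np.ascontiguousarray(Ktr)
    y_tr = y[train_idx]
    d, beta, b, trace, trace_len, converged = _engine.mkl_fit_core(
        Ktr, y_tr, float(C), float(epsilon), float(tol), int(max_iter),
        float(smo_tol), int(smo_max_iter),
    )
    return MKLModel(
        d=d, dual_coef=beta, offset=float(b), C=float(C),
        epsilon=float(epsilon), train_idx=train_idx,
        objective_trace=list(trace[:trace_len]), converged=bool(converged),
    )


def decision_function(model: MKLModel, ks: KernelSet, idx) -> np.ndarray:
    """Model predictions for arbitrary subjects (no overlap guard).

    ``ks`` must be centered/normalized with the model's ``train_idx``.
    """
    idx = np.asarray(list(idx), dtype=np.int64)
    return _engine.predict_from_fit(
        ks.stack, model.d, model.dual_coef, model.offset, model.train_idx, idx
    )


def mkl_predict(model: MKLModel, ks: KernelSet, test_idx) -> np.ndarray:
    """Predict labels for held-out subjects.

    Raises :class:`LeakageError` if ``test_idx`` overlaps the model's
    training subjects; use :func:`decision_function` for training-fit
    diagnostics.
    """
    test_idx = np.asarray(list(test_idx), dtype=np.int64)
    overlap = set(test_idx.tolist()) & set(model.train_idx.tolist())
    if overlap:
        raise LeakageError(f"test subjects {sorted(overlap)} are in the training set")
    return decision_function(model, ks, test_idx)
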