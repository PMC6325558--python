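"""Nested leave-one-subject-out CV, performance metrics, and permutation inference.

The outer loop holds out one subject at a time; the inner loop is
leave-one-out within the remaining training subjects and selects the SVR
box constraint C from a grid by minimal inner MSE (ties go to the
smallest C).  Kernels are re-centered and re-normalized on every training
set and labels are standardized within every training fold, so the
held-out subject's data never influences selection or fitting.

Significance comes from a full-pipeline permutation scheme: each
permutation shuffles the label-to-subject assignment *before* the outer
split and reruns the entire nested CV, so inner C selection also sees
permuted labels.  p-values use the add-one correction.  Across a family
of models, Benjamini-Hochberg FDR is applied separately to the r-based
and nMSE-based p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from . import _engine
from .io import DegenerateLabelsError, LabelVector, RunConfig
from .kernels import KernelSet
from .mkl import MKLModel


def pearson_r(y_true, y_pred) -> float:
    """Product-moment correlation of true and predicted labels.

    The sign is preserved — a negative value indicates poor decoding, it
    is never rectified.  Constant input raises, as the correlation is then
    undefined.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.std() == 0.0 or y_pred.std() == 0.0:
        raise DegenerateLabelsError("correlation undefined for constant input")
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def _safe_r(y_true, y_pred) -> float:
    """Correlation for pipeline summaries: zero-variance predictions carry
    no linear association and are scored 0 rather than raising."""
    if np.std(y_pred) == 0.0 or np.std(y_true) == 0.0:
        return 0.0
    return float(np.corrcoef(y_true, y_pred)[0, 1])


def nmse(y_true, y_pred, divisor: float | None = None) -> float:
    """MSE normalized by the range of the true labels.

    Range normalization makes questionnaires with different score ranges
    comparable; ``divisor`` overrides the default whole-sample range
    (used so permutation nulls share the observed divisor).
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if divisor is None:
        divisor = float(np.ptp(y_true))
    if divisor <= 0:
        raise DegenerateLabelsError("label range is zero; nMSE undefined")
    return float(np.mean((y_true - y_pred) ** 2) / divisor)


@dataclass
class FoldModel:
    """Outer-fold record: held-out subject, chosen C, fitted model."""

    held_out: int
    C: float
    model: MKLModel


@dataclass
class CVResult:
    """Out-of-fold predictions and summary metrics of one decoding model."""

    y_true: np.ndarray
    y_pred: np.ndarray
    r: float
    mse: float
    nmse: float
    nmse_divisor: float
    per_fold: list[FoldModel]
    block_index: list[tuple[str, str]]
    block_sizes: list[int] = field(default_factory=list)
    label_name: str = "score"
    p_r: float | None = None
    p_nmse: float | None = None

    def summary(self) -> dict:
        out = {
            "label_name": self.label_name,
            "r": self.r,
            "mse": self.mse,
            "nmse": self.nmse,
            "nmse_divisor": self.nmse_divisor,
            "chosen_C": [fm.C for fm in self.per_fold],
        }
        if self.p_r is not None:
            out["p_r"] = self.p_r
            out["p_nmse"] = self.p_nmse
        return out


def _as_values(y, ks: KernelSet) -> tuple[np.ndarray, str]:
    if isinstance(y, LabelVector):
        if list(y.subjects) != list(ks.subjects):
            raise ValueError("label subject order does not match kernel set")
        return y.values, y.name
    y = np.asarray(y, dtype=float)
    if y.size != ks.n_subjects:
        raise ValueError("label length does not match subject count")
    return y, "score"


def run_nested_cv(ks: KernelSet, y, cfg: RunConfig) -> CVResult:
    """Nested LOSO CV of the MKL regression on a raw (uncentered) kernel set."""
    y_vals, name = _as_values(y, ks)
    n = ks.n_subjects
    if n < 3:
        raise ValueError("nested CV needs at least 3 subjects")
    if np.ptp(y_vals) == 0.0:
        raise DegenerateLabelsError("labels are constant")

    C_grid = np.asarray(cfg.C_grid, dtype=float)
    y_pred, chosen, d_all, beta_all, b_all, _, _ = _engine.nested_cv(
        ks.stack, y_vals, C_grid, cfg.epsilon, cfg.mkl_tol, cfg.mkl_max_iter,
        cfg.smo_tol, cfg.smo_max_iter,
    )
    per_fold = []
    all_idx = np.arange(n, dtype=np.int64)
    for f in range(n):
        train_idx = all_idx[all_idx != f]
        per_fold.append(FoldModel(
            held_out=f,
            C=float(C_grid[chosen[f]]),
            model=MKLModel(
                d=d_all[f], dual_coef=beta_all[f], offset=float(b_all[f]),
                C=float(C_grid[chosen[f]]), epsilon=cfg.epsilon,
                train_idx=train_idx,
            ),
        ))
    divisor = float(np.ptp(y_vals))
    return CVResult(
        y_true=y_vals.copy(), y_pred=y_pred, r=_safe_r(y_vals, y_pred),
        mse=float(np.mean((y_vals - y_pred) ** 2)),
        nmse=nmse(y_vals, y_pred, divisor), nmse_divisor=divisor,
        per_fold=per_fold, block_index=list(ks.block_index),
        block_sizes=list(ks.block_sizes), label_name=name,
    )


@dataclass
class PermutationResult:
    p_r: float
    p_nmse: float
    null_r: np.ndarray = field(repr=False, default=None)
    null_nmse: np.ndarray = field(repr=False, default=None)


def permutation_test(ks: KernelSet, y, cfg: RunConfig,
                     observed: CVResult) -> PermutationResult:
    """Full-pipeline permutation null for one model.

    Each of ``cfg.n_permutations`` draws shuffles the label-to-subject
    assignment and reruns the complete nested CV (including inner C
    selection).  ``p_r = (1 + #{null r >= observed r}) / (1 + n_perm)``;
    the nMSE p-value counts nulls with *smaller or equal* error.  The
    observed result is annotated in place and also returned.
    """
    y_vals, _ = _as_values(y, ks)
    if cfg.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    C_grid = np.asarray(cfg.C_grid, dtype=float)
    null_r = np.empty(cfg.n_permutations)
    null_nmse = np.empty(cfg.n_permutations)
    for k in range(cfg.n_permutations):
        y_perm = y_vals[rng.permutation(y_vals.size)]
        y_pred, *_ = _engine.nested_cv(
            ks.stack, y_perm, C_grid, cfg.epsilon, cfg.mkl_tol,
            cfg.mkl_max_iter, cfg.smo_tol, cfg.smo_max_iter,
        )
        null_r[k] = _safe_r(y_perm, y_pred)
        null_nmse[k] = nmse(y_perm, y_pred, observed.nmse_divisor)
    p_r = (1.0 + np.sum(null_r >= observed.r)) / (1.0 + cfg.n_permutations)
    p_nmse = (1.0 + np.sum(null_nmse <= observed.nmse)) / (1.0 + cfg.n_permutations)
    observed.p_r = float(p_r)
    observed.p_nmse = float(p_nmse)
    return PermutationResult(float(p_r), float(p_nmse), null_r, null_nmse)


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up across a family of models.

    Returns ``(reject_flags, adjusted_p)``.  The r-based and nMSE-based
    families are corrected separately by calling this once per family.
    """
    p_values = np.asarray(list(p_values), dtype=float)
    if p_values.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p_values <= 0) | (p_values > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject, p_adj
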