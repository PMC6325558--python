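"""Weight aggregation, feature-set selection, transfer CV, and report writing.

Per-fold simplex weights d are averaged across the outer folds into
region/condition weight percentages (they sum to 100 because every fold's
d sums to 1).  Within each condition, regions are ranked by aggregated
weight; the expected ranking (ER) is the mean of a region's 1-based
within-condition rank across folds — a stability summary: the closer the
ER to the final rank, the more consistent the region's selection.
A model's predictive feature set is the blocks contributing more than a
threshold (default 10%); transferring one model's feature set to another
model's labels (between-model CV) probes whether two questionnaires draw
on the same neural sources.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .inference import CVResult, run_nested_cv
from .io import RunConfig, write_run_summary
from .kernels import KernelSet


@dataclass
class WeightTable:
    """Aggregated region/condition weights of one decoding model.

    ``table`` has one row per (region, condition) kernel with columns
    ``condition, region, n_voxels, weight_pct, rank, er``;
    ``condition_weight_pct`` maps condition -> summed weight percentage.
    """

    table: pd.DataFrame
    condition_weight_pct: dict[str, float]
    label_name: str = "score"

    def rows(self, condition: str) -> pd.DataFrame:
        sel = self.table[self.table.condition == condition]
        return sel.sort_values("rank").reset_index(drop=True)


def aggregate_weights(cv: CVResult) -> WeightTable:
    """Fold-mean simplex weights -> per-block percentages, ranks and ER."""
    if not cv.per_fold:
        raise ValueError("CVResult carries no per-fold models")
    D = np.vstack([fm.model.d for fm in cv.per_fold])  # (folds, M)
    weight_pct = D.mean(axis=0) * 100.0
    conditions = []
    for _, c in cv.block_index:
        if c not in conditions:
            conditions.append(c)

    records = []
    for cond in conditions:
        idx = [m for m, (_, c) in enumerate(cv.block_index) if c == cond]
        # per-fold within-condition ranks (descending weight, ties by atlas order)
        sub = D[:, idx]
        order = np.argsort(-sub, axis=1, kind="stable")
        fold_rank = np.empty_like(order)
        rows_ar = np.arange(sub.shape[0])[:, None]
        fold_rank[rows_ar, order] = np.arange(1, len(idx) + 1)[None, :]
        er = fold_rank.mean(axis=0)
        agg = weight_pct[idx]
        final_order = np.argsort(-agg, kind="stable")
        final_rank = np.empty(len(idx), dtype=int)
        final_rank[final_order] = np.arange(1, len(idx) + 1)
        for pos, m in enumerate(idx):
            records.append({
                "condition": cond,
                "region": cv.block_index[m][0],
                "n_voxels": cv.block_sizes[m] if cv.block_sizes else 0,
                "weight_pct": agg[pos],
                "rank": int(final_rank[pos]),
                "er": float(er[pos]),
            })
    table = pd.DataFrame.from_records(records)
    cond_w = {
        c: float(table.loc[table.condition == c, "weight_pct"].sum())
        for c in conditions
    }
    return WeightTable(table=table, condition_weight_pct=cond_w,
                       label_name=cv.label_name)


def select_feature_set(wt: WeightTable, threshold: float = 10.0) -> list[tuple[str, str]]:
    """Blocks with weight strictly above ``threshold`` percent.

    Returned in descending weight order.  An empty selection raises with
    advice to lower the threshold.
    """
    if not 0.0 < threshold < 100.0:
        raise ValueError("threshold must lie in (0, 100)")
    sel = wt.table[wt.table.weight_pct > threshold].sort_values(
        "weight_pct", ascending=False
    )
    if sel.empty:
        raise ValueError(
            f"no block exceeds {threshold}% weight; lower the threshold"
        )
    return [(row.region, row.condition) for row in sel.itertuples()]


def between_model_cv(ks: KernelSet, feature_set, y, cfg: RunConfig) -> CVResult:
    """Nested CV restricted to another model's predictive feature set.

    Self-pairing (a model's own feature set with its own labels) serves as
    the positive control; with the full kernel set this reduces exactly to
    the original run.
    """
    if not list(feature_set):
        raise ValueError("feature set is empty")
    return run_nested_cv(ks.subset(feature_set), y, cfg)


def write_report(run_dir, results: Mapping[str, CVResult],
                 weight_tables: Mapping[str, WeightTable] | None = None,
                 between: Mapping[tuple[str, str], CVResult] | None = None,
                 cfg: RunConfig | None = None) -> str:
    """Write per-model weight TSVs, a performance TSV, the transfer matrix,
    a JSON summary and a log into ``run_dir``.  Deterministic: identical
    inputs produce byte-identical files."""
    if not results:
        raise ValueError("no model results to report")
    run_dir = str(run_dir)
    os.makedirs(run_dir, exist_ok=True)
    if weight_tables is None:
        weight_tables = {name: aggregate_weights(cv) for name, cv in results.items()}

    log_lines = []
    for name, wt in weight_tables.items():
        out = wt.table[["rank", "region", "n_voxels", "weight_pct", "er",
                        "condition"]].sort_values(
            ["condition", "rank"], kind="stable"
        )
        path = os.path.join(run_dir, f"weights_{name}.tsv")
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")
        log_lines.append(f"weights for {name}: {path}")

    perf = pd.DataFrame([
        {
            "model": name,
            "r": cv.r,
            "p_r": cv.p_r if cv.p_r is not None else float("nan"),
            "mse": cv.mse,
            "nmse": cv.nmse,
            "p_nmse": cv.p_nmse if cv.p_nmse is not None else float("nan"),
        }
        for name, cv in results.items()
    ])
    perf.to_csv(os.path.join(run_dir, "model_performance.tsv"), sep="\t",
                index=False, float_format="%.6g")
    log_lines.append("performance table: model_performance.tsv")

    if between:
        rows = []
        for (fs_model, label_model), cv in between.items():
            rows.append({
                "feature_set": fs_model, "labels": label_model,
                "r": cv.r, "nmse": cv.nmse,
                "p_r": cv.p_r if cv.p_r is not None else float("nan"),
                "p_nmse": cv.p_nmse if cv.p_nmse is not None else float("nan"),
            })
        pd.DataFrame(rows).to_csv(
            os.path.join(run_dir, "between_model_cv.tsv"), sep="\t",
            index=False, float_format="%.6g",
        )
        log_lines.append("between-model matrix: between_model_cv.tsv")

    payload = {
        "models": {name: cv.summary() for name, cv in results.items()},
        "condition_weights": {
            name: wt.condition_weight_pct for name, wt in weight_tables.items()
        },
    }
    if cfg is not None:
        payload["config"] = {
            "C_grid": cfg.C_grid, "epsilon": cfg.epsilon,
            "n_permutations": cfg.n_permutations, "fdr_q": cfg.fdr_q,
            "seed": cfg.seed,
        }
    write_run_summary(run_dir, payload, log_lines)
    return run_dir


def plot_weights(wt: WeightTable, path=None):
    """Simple per-condition bar plot of region weights (optional matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    conds = list(wt.condition_weight_pct)
    fig, axes = plt.subplots(1, len(conds), figsize=(6 * len(conds), 4),
                             squeeze=False)
    for ax, cond in zip(axes[0], conds):
        rows = wt.rows(cond)
        ax.bar(rows.region, rows.weight_pct)
        ax.set_title(f"{wt.label_name}: {cond} "
                     f"({wt.condition_weight_pct[cond]:.0f}%)")
        ax.set_ylabel("region weight (%)")
        ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
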