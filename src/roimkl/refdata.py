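"""Published reference tables for arithmetic consistency checks.

``published_weight_tables.tsv`` reproduces, cell for cell, the region and
condition weight tables of a published application of this method: MKL
regression of pain-related-fear questionnaire scores (FABQ, FABQ-W,
TSK-13, TSK-11, trait anxiety) from 22 bilateral fear-circuit regions in
20 chronic-low-back-pain patients.  The printed voxel counts are kept
exactly as published, including the scrambled sizes in the TSK-11
harmless column of the original table.  These cells are *inputs*: the
package's aggregation rules (condition weight = within-condition sum of
region weights; feature set = blocks above 10%) must reproduce the
published condition-weight footnotes and starred feature sets from them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: condition-weight footnotes as printed (integer percent per condition)
PUBLISHED_CONDITION_WEIGHTS: dict[str, dict[str, float]] = {
    "FABQ": {"harmful": 88.0, "harmless": 12.0},
    "FABQ-W": {"harmful": 87.0, "harmless": 13.0},
    "TSK-13": {"harmful": 60.0, "harmless": 40.0},
    "TSK-11": {"harmful": 66.0, "harmless": 34.0},
    "T-Anxiety": {"harmful": 52.0, "harmless": 48.0},
}

#: questionnaire descriptive statistics of the published 20-patient sample
#: (minimum, maximum, mean, SD) — the label distributions the synthetic
#: generator emulates
PUBLISHED_LABEL_STATS: dict[str, tuple[float, float, float, float]] = {
    "FABQ": (3, 83, 35.45, 22.53),
    "FABQ-W": (0, 40, 15.50, 12.12),
    "TSK-13": (16, 43, 27.60, 5.96),
    "TSK-11": (13, 38, 23.20, 5.71),
    "T-Anxiety": (31, 59, 43.00, 6.05),
}


def load_published_weight_tables() -> pd.DataFrame:
    """Long-format table: model, condition, rank, region, size_vox,
    weight_pct, er, starred."""
    with resources.files("roimkl.data").joinpath(
        "published_weight_tables.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def condition_weight_sums(table: pd.DataFrame | None = None) -> dict[str, dict[str, float]]:
    """Within-condition sums of the printed region weights, per model."""
    if table is None:
        table = load_published_weight_tables()
    out: dict[str, dict[str, float]] = {}
    for (model, cond), grp in table.groupby(["model", "condition"]):
        out.setdefault(model, {})[cond] = float(grp.weight_pct.sum())
    return out


def top_k_sum(model: str, condition: str, k: int,
              table: pd.DataFrame | None = None) -> float:
    """Sum of the k largest printed region weights of one model x condition."""
    if table is None:
        table = load_published_weight_tables()
    sel = table[(table.model == model) & (table.condition == condition)]
    return float(sel.nlargest(k, "weight_pct").weight_pct.sum())


def published_feature_set(model: str,
                          table: pd.DataFrame | None = None) -> list[tuple[str, str]]:
    """Starred (region, condition) blocks of one model, descending weight."""
    if table is None:
        table = load_published_weight_tables()
    sel = table[(table.model == model) & (table.starred == 1)]
    sel = sel.sort_values("weight_pct", ascending=False)
    return [(r.region, r.condition) for r in sel.itertuples()]
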