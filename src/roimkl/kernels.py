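"""Per-region, per-condition linear Gram matrices with leakage-free scaling.

One linear kernel is built per (region, condition) block — 44 in the
full-scale configuration of 22 regions x 2 conditions.  Centering uses
the standard kernel-centering identity with feature means taken over the
*training* subjects only, applied to the full matrix; each kernel is then
divided by the mean of its training-block diagonal (trace normalization),
which equalizes average pattern energy across regions of very different
voxel counts.  Held-out rows therefore depend on held-out features only
through inner products with training features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .io import BetaDataset, DataError

log = logging.getLogger(__name__)


@dataclass
class KernelSet:
    """Ordered stack of subject-by-subject kernel matrices.

    ``stack`` is (M, n, n); ``block_index[m]`` names kernel m as a
    (region, condition) pair.  ``block_sizes`` records the feature
    dimension (voxel count) behind each kernel.
    """

    stack: np.ndarray
    block_index: list[tuple[str, str]]
    subjects: list[str]
    block_sizes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.stack = np.ascontiguousarray(self.stack, dtype=float)
        if self.stack.ndim != 3 or self.stack.shape[1] != self.stack.shape[2]:
            raise ValueError("stack must be (M, n, n)")
        if self.stack.shape[0] != len(self.block_index):
            raise ValueError("block_index must name every kernel")
        if self.stack.shape[1] != len(self.subjects):
            raise ValueError("kernel size must match subject count")
        asym = np.abs(self.stack - self.stack.transpose(0, 2, 1)).max() if len(self) else 0.0
        if asym > 1e-10:
            raise ValueError(f"kernels must be symmetric (max asymmetry {asym:g})")

    def __len__(self) -> int:
        return self.stack.shape[0]

    def __getitem__(self, m: int) -> np.ndarray:
        return self.stack[m]

    @property
    def n_subjects(self) -> int:
        return self.stack.shape[1]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for _, c in self.block_index:
            if c not in seen:
                seen.append(c)
        return seen

    def subset(self, blocks) -> "KernelSet":
        """Restrict to the given (region, condition) blocks, keeping order."""
        blocks = list(blocks)
        missing = [b for b in blocks if b not in self.block_index]
        if missing:
            raise KeyError(f"blocks not in kernel set: {missing}")
        idx = [self.block_index.index(b) for b in blocks]
        return KernelSet(
            stack=self.stack[idx].copy(),
            block_index=[self.block_index[i] for i in idx],
            subjects=list(self.subjects),
            block_sizes=[self.block_sizes[i] for i in idx] if self.block_sizes else [],
        )


def build_kernels(data: BetaDataset) -> KernelSet:
    """Linear Gram matrix per (region, condition) block, condition-major order."""
    mats = []
    index = []
    sizes = []
    for cond in data.conditions:
        for region in data.regions:
            X = data.region_matrix(region, cond)
            if not np.all(np.isfinite(X)):
                raise DataError(f"non-finite features in block {(region, cond)}")
            mats.append(X @ X.T)
            index.append((region, cond))
            sizes.append(X.shape[1])
    return KernelSet(
        stack=np.stack(mats), block_index=index,
        subjects=list(data.subjects), block_sizes=sizes,
    )


def center_and_normalize(ks: KernelSet, train_idx,
                         normalization: str = "trace") -> KernelSet:
    """Center (training-mean identity) then scale each kernel.

    ``normalization="trace"`` divides by the mean training-block diagonal so
    the training-block trace equals ``len(train_idx)``; ``"dim"`` divides by
    the feature dimension (voxel count) instead.  All-zero kernels are left
    at zero with a logged warning — they simply receive zero MKL weight
    downstream.
    """
    train_idx = np.asarray(sorted(set(int(i) for i in train_idx)), dtype=np.int64)
    if train_idx.size == 0:
        raise ValueError("train_idx must be nonempty")
    if train_idx.min() < 0 or train_idx.max() >= ks.n_subjects:
        raise ValueError("train_idx out of range")
    if normalization not in ("trace", "dim"):
        raise ValueError("normalization must be 'trace' or 'dim'")

    out, scales = _engine.center_normalize_stack(
        ks.stack, train_idx, normalization == "trace"
    )
    if normalization == "dim":
        if not ks.block_sizes:
            raise ValueError("'dim' normalization needs block_sizes")
        out = out / np.asarray(ks.block_sizes, dtype=float)[:, None, None]
    for m, s in enumerate(scales):
        if s == 0.0:
            log.warning(
                "kernel %s is zero after centering; left unscaled",
                ks.block_index[m],
            )
    return KernelSet(
        stack=out, block_index=list(ks.block_index),
        subjects=list(ks.subjects), block_sizes=list(ks.block_sizes),
    )
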