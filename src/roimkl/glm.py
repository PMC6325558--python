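"""First-level GLM: BOLD time series -> one beta map per condition.

The model mirrors a standard event-related first-level analysis: each
condition's events become a boxcar convolved with the canonical
double-gamma HRF, nuisance columns come from a ready-made confound table,
low-frequency drift is absorbed by a DCT basis (all cosines with period
above the high-pass cutoff) inside the design matrix, and ordinary least
squares is run per voxel.  No temporal autocorrelation model is applied;
estimates are plain OLS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError, FormatError, GeometryError, Parcellation

#: fine time grid (s) for oversampled boxcar-HRF convolution; onsets are
#: specified to 2 decimals, so 10 ms aligns events exactly.
MICROTIME_DT = 0.01


def hrf_continuous(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF evaluated on an arbitrary time grid (s).

    Peak delay 6 s, undershoot delay 16 s, both with dispersion 1 s,
    peak:undershoot amplitude ratio 6, support [0, 32] s, and unit peak
    amplitude.
    """
    t = np.asarray(t, dtype=float)
    peak = stats.gamma.pdf(t, a=6.0, scale=1.0)
    under = stats.gamma.pdf(t, a=16.0, scale=1.0)
    h = peak - under / 6.0
    h[(t < 0) | (t > 32.0)] = 0.0
    fine = np.arange(0.0, 32.0, 1e-3)
    ref = stats.gamma.pdf(fine, a=6.0, scale=1.0) - stats.gamma.pdf(
        fine, a=16.0, scale=1.0) / 6.0
    return h / ref.max()


def canonical_hrf(TR: float) -> np.ndarray:
    """Canonical HRF sampled at the repetition time; length ceil(32 / TR)."""
    if TR <= 0:
        raise ValueError("TR must be > 0")
    return hrf_continuous(np.arange(0.0, 32.0, TR))


def task_regressor(onsets, durations, n_volumes: int, TR: float,
                   dt: float = MICROTIME_DT) -> np.ndarray:
    """Boxcar-convolved-with-HRF regressor sampled at volume times k*TR.

    Built on an oversampled grid so sub-TR onsets are honored, then read
    out at the volume acquisition times.  The same code path is used by
    the synthetic session generator, so a noiseless simulation is exactly
    within the design's column space.
    """
    onsets = np.asarray(onsets, dtype=float)
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    t_end = n_volumes * TR
    grid = np.arange(0.0, t_end + 32.0, dt)
    box = np.zeros_like(grid)
    for on, du in zip(onsets, durations):
        box[(grid >= on) & (grid < on + du)] = 1.0
    h = hrf_continuous(np.arange(0.0, 32.0, dt))
    conv = np.convolve(box, h)[: grid.size] * dt
    vol_idx = np.round(np.arange(n_volumes) * TR / dt).astype(int)
    return conv[vol_idx]


def dct_highpass_basis(n_volumes: int, TR: float, cutoff: float = 128.0) -> np.ndarray:
    """DCT-II drift regressors: all cosines with period > cutoff seconds.

    The k-th basis function has period 2*n_volumes*TR / k, so the count is
    floor(2 * n_volumes * TR / cutoff).
    """
    n_basis = int(np.floor(2.0 * n_volumes * TR / cutoff))
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_volumes)) for k in range(1, n_basis + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


@dataclass
class DesignMatrix:
    """Assembled first-level design: task + confounds + DCT drift + intercept."""

    matrix: np.ndarray
    column_names: list[str]
    condition_columns: list[int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.column_names):
            raise FormatError("column_names must match matrix width")
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < self.matrix.shape[1]:
            # name the columns spanning the null space
            _, _, vt = np.linalg.svd(self.matrix, full_matrices=True)
            null = vt[rank:]
            bad = sorted(
                {
                    self.column_names[j]
                    for row in null
                    for j in np.flatnonzero(np.abs(row) > 1e-8)
                }
            )
            raise FormatError(f"design matrix is rank deficient; collinear columns: {bad}")


def build_design(events: pd.DataFrame, confounds: pd.DataFrame | None,
                 n_volumes: int, TR: float, hpf_cutoff: float = 128.0,
                 conditions: tuple[str, str] = ("harmful", "harmless")) -> DesignMatrix:
    """Assemble the first-level design matrix.

    ``events`` needs columns onset/duration/trial_type (seconds); each of
    the two task ``conditions`` must have at least one event, all within
    the scan.  Construction groups events by type, so it is independent of
    the row order of the table.
    """
    req = {"onset", "duration", "trial_type"}
    if not req <= set(events.columns):
        raise FormatError(f"events table needs columns {sorted(req)}")
    if np.any(events["onset"].to_numpy(float) + events["duration"].to_numpy(float)
              > n_volumes * TR + 1e-9):
        raise FormatError("events extend beyond the scan")
    cols = []
    names = []
    for cond in conditions:
        sel = events[events["trial_type"] == cond].sort_values("onset")
        if sel.empty:
            raise FormatError(f"no events for condition {cond!r}; both task "
                              "regressors are required")
        cols.append(task_regressor(sel["onset"].to_numpy(float),
                                   sel["duration"].to_numpy(float), n_volumes, TR))
        names.append(cond)
    condition_columns = list(range(len(conditions)))

    if confounds is not None and len(confounds.columns):
        if len(confounds) != n_volumes:
            raise FormatError("confound table must have one row per volume")
        for c in confounds.columns:
            cols.append(confounds[c].to_numpy(float))
            names.append(str(c))

    dct = dct_highpass_basis(n_volumes, TR, hpf_cutoff)
    for k in range(dct.shape[1]):
        cols.append(dct[:, k])
        names.append(f"dct{k + 1:02d}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    return DesignMatrix(np.column_stack(cols), names, condition_columns)


def fit_glm(bold: np.ndarray, design: DesignMatrix,
            mask: Parcellation) -> dict[str, np.ndarray]:
    """Voxelwise OLS inside the atlas regions; returns per-condition beta maps.

    Voxels outside every region are NaN in the output.  A non-finite time
    series inside the mask raises :class:`DataError`.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 4:
        raise GeometryError("bold must be a 4D (x, y, z, t) array")
    if bold.shape[:3] != mask.label_volume.shape:
        raise GeometryError("bold grid does not match the atlas grid")
    n_volumes = design.matrix.shape[0]
    if bold.shape[3] != n_volumes:
        raise GeometryError("bold time dimension does not match the design")

    in_mask = (mask.label_volume > 0).ravel(order="F")
    Y = bold.reshape(-1, n_volumes, order="F")[in_mask].T  # (t, voxels)
    if not np.all(np.isfinite(Y)):
        raise DataError("non-finite time series inside the atlas mask")

    coef, *_ = np.linalg.lstsq(design.matrix, Y, rcond=None)
    out: dict[str, np.ndarray] = {}
    for j in design.condition_columns:
        flat = np.full(in_mask.size, np.nan)
        flat[in_mask] = coef[j]
        out[design.column_names[j]] = flat.reshape(mask.label_volume.shape, order="F")
    return out
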