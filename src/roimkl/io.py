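"""Domain types and readers/writers shared by all pipeline stages.

The pipeline works on four objects: a :class:`Parcellation` (integer-labeled
atlas volume defining the region feature space), a :class:`BetaDataset`
(per-subject, per-condition voxel vectors extracted from beta maps), a
:class:`LabelVector` (one questionnaire score per subject), and a
:class:`RunConfig` (solver and inference settings).

Conventions: NIfTI voxel indices are 0-based and the affine maps voxel to
world mm; no resampling is performed — all volumes entering a run must
share grid and affine.  Voxel order within a region is ascending linear
index with x fastest (Fortran ravel order), which is deterministic and
independent of the file layout on disk.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """Input file does not have the expected form."""


class ConsistencyError(ValueError):
    """Two inputs that must agree do not."""


class GeometryError(ValueError):
    """Volumes do not share grid shape or affine."""


class DataError(ValueError):
    """Non-finite or missing values where finite data is required."""


class DegenerateLabelsError(ValueError):
    """Labels carry no variance; regression is undefined."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Parcellation:
    """Integer-labeled 3D atlas volume.

    Labels are positive integers; background is 0.  ``region_table`` maps
    each nonzero label present in the volume to a region name.
    """

    label_volume: np.ndarray
    voxel_size: tuple[float, float, float]
    region_table: dict[int, str]
    affine: np.ndarray

    def __post_init__(self) -> None:
        vol = np.asarray(self.label_volume)
        if vol.ndim != 3:
            raise FormatError("label volume must be 3D")
        if not np.issubdtype(vol.dtype, np.integer):
            if not np.all(np.isfinite(vol)) or not np.all(vol == np.round(vol)):
                raise FormatError("label volume must be integer-valued")
            vol = vol.astype(np.int32)
        if vol.min() < 0:
            raise FormatError("labels must be positive integers (background 0)")
        self.label_volume = vol
        present = set(int(v) for v in np.unique(vol)) - {0}
        table_labels = set(self.region_table)
        if table_labels != present:
            raise ConsistencyError(
                f"region_table labels {sorted(table_labels)} do not match "
                f"labels present in the volume {sorted(present)}"
            )
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)

    @property
    def labels(self) -> list[int]:
        """Sorted nonzero labels."""
        return sorted(self.region_table)

    @property
    def region_names(self) -> list[str]:
        """Region names in ascending label order (the atlas order)."""
        return [self.region_table[k] for k in self.labels]

    def region_indices(self, label: int) -> np.ndarray:
        """Flat voxel indices of a region, ascending, x-fastest order."""
        mask = (self.label_volume == label).ravel(order="F")
        return np.flatnonzero(mask)

    def voxel_counts(self) -> dict[int, int]:
        return {k: int((self.label_volume == k).sum()) for k in self.labels}


@dataclass
class BetaDataset:
    """Per-subject, per-condition, per-region voxel feature vectors."""

    subjects: list[str]
    conditions: list[str]
    regions: list[str]
    features: dict[tuple[str, str, str], np.ndarray]
    provenance: str = ""

    def __post_init__(self) -> None:
        lengths: dict[str, int] = {}
        for s in self.subjects:
            for c in self.conditions:
                for r in self.regions:
                    key = (s, c, r)
                    if key not in self.features:
                        raise ConsistencyError(f"missing feature vector for {key}")
                    v = np.asarray(self.features[key], dtype=float)
                    if not np.all(np.isfinite(v)):
                        raise DataError(f"non-finite features for {key}")
                    if r in lengths and lengths[r] != v.size:
                        raise ConsistencyError(
                            f"region {r!r} vector length varies across "
                            "subjects/conditions"
                        )
                    lengths[r] = v.size
                    self.features[key] = v
        self.region_sizes = lengths

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def region_matrix(self, region: str, condition: str) -> np.ndarray:
        """(n_subjects, n_voxels) feature matrix for one region x condition."""
        return np.vstack(
            [self.features[(s, condition, region)] for s in self.subjects]
        )


@dataclass
class LabelVector:
    """One continuous score per subject, aligned to a dataset's subject order."""

    subjects: list[str]
    values: np.ndarray
    name: str = "score"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.subjects):
            raise ConsistencyError("values must be 1D with one entry per subject")
        if not np.all(np.isfinite(self.values)):
            raise DataError(f"non-finite label in {self.name!r}")
        if self.values.size and np.ptp(self.values) == 0.0:
            raise DegenerateLabelsError(
                f"labels {self.name!r} are constant; regression is undefined"
            )


@dataclass
class RunConfig:
    """Settings of one decoding run.

    ``epsilon`` is the SVR tube width on labels standardized to unit
    variance within each training fold.  ``n_permutations`` defaults to a
    desk-scale 1000; the full-scale analysis this package models used
    16000.
    """

    C_grid: list[float] = field(default_factory=lambda: [0.1, 1.0, 10.0, 100.0, 1000.0])
    epsilon: float = 0.1
    n_permutations: int = 1000
    fdr_q: float = 0.05
    seed: int = 0
    mkl_tol: float = 1e-4
    mkl_max_iter: int = 200
    smo_tol: float = 1e-6
    smo_max_iter: int = 5_000

    def __post_init__(self) -> None:
        if not self.C_grid:
            raise ValueError("C_grid must be nonempty")
        if any(c <= 0 for c in self.C_grid):
            raise ValueError("all C_grid entries must be > 0")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must lie in (0, 1)")
        self.C_grid = sorted(float(c) for c in self.C_grid)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# operations


def _load_volume(src) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine) from a path, a nibabel image, or an array."""
    if isinstance(src, (str, os.PathLike)):
        img = nib.load(str(src))
        return np.asanyarray(img.dataobj), np.asarray(img.affine)
    if isinstance(src, nib.spatialimages.SpatialImage):
        return np.asanyarray(src.dataobj), np.asarray(src.affine)
    return np.asarray(src), np.eye(4)


def load_parcellation(path, names) -> Parcellation:
    """Load an integer-labeled NIfTI atlas.

    Parameters
    ----------
    path:
        NIfTI file (or nibabel image) with positive-integer region labels,
        background 0.
    names:
        Mapping label -> region name, or a TSV path with columns
        ``label`` and ``name``.  Must cover exactly the nonzero labels
        present in the volume.
    """
    data, affine = _load_volume(path)
    if isinstance(names, (str, os.PathLike)):
        tbl = pd.read_csv(names, sep="\t")
        if not {"label", "name"} <= set(tbl.columns):
            raise FormatError("names table needs 'label' and 'name' columns")
        names = {int(row.label): str(row.name) for row in tbl.itertuples()}
    names = {int(k): str(v) for k, v in dict(names).items()}
    if np.issubdtype(data.dtype, np.floating):
        if not np.all(np.isfinite(data)) or not np.all(data == np.round(data)):
            raise FormatError("parcellation volume is not integer-valued")
        data = data.astype(np.int32)
    voxel_size = tuple(float(v) for v in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))
    return Parcellation(
        label_volume=data, voxel_size=voxel_size, region_table=names, affine=affine
    )


def extract_features(beta_maps: Mapping, parc: Parcellation) -> BetaDataset:
    """Gather region-wise voxel vectors from per-subject/condition beta maps.

    ``beta_maps`` maps ``(subject, condition)`` to a NIfTI path, nibabel
    image or 3D array sharing the parcellation grid.  Voxels inside each
    region are read in ascending x-fastest linear-index order, identical
    across subjects and conditions.  NaN voxels inside a region are a
    :class:`DataError`; an all-zero region is kept as a zero vector.
    """
    subjects: list[str] = []
    conditions: list[str] = []
    for s, c in beta_maps:
        if s not in subjects:
            subjects.append(s)
        if c not in conditions:
            conditions.append(c)
    for s in subjects:
        for c in conditions:
            if (s, c) not in beta_maps:
                raise ConsistencyError(f"missing beta map for {(s, c)}")

    region_idx = {
        parc.region_table[lab]: parc.region_indices(lab) for lab in parc.labels
    }
    features: dict[tuple[str, str, str], np.ndarray] = {}
    for (s, c), src in beta_maps.items():
        data, affine = _load_volume(src)
        if data.shape != parc.label_volume.shape:
            raise GeometryError(
                f"beta map {(s, c)} grid {data.shape} != atlas grid "
                f"{parc.label_volume.shape}"
            )
        if isinstance(src, (str, os.PathLike, nib.spatialimages.SpatialImage)):
            if not np.allclose(affine, parc.affine, atol=1e-4):
                raise GeometryError(f"beta map {(s, c)} affine differs from atlas")
        flat = np.asarray(data, dtype=float).ravel(order="F")
        for rname, idx in region_idx.items():
            vec = flat[idx]
            if not np.all(np.isfinite(vec)):
                raise DataError(f"non-finite voxels in region {rname} of {(s, c)}")
            features[(s, c, rname)] = vec
    return BetaDataset(
        subjects=subjects,
        conditions=conditions,
        regions=parc.region_names,
        features=features,
        provenance="extract_features",
    )


def load_labels(table, column: str, subjects: Sequence[str] | None = None) -> LabelVector:
    """Read one questionnaire column from a participants TSV.

    Rows are joined to ``subjects`` by ``participant_id`` (order in the
    file is irrelevant).  Missing values raise — no imputation at n this
    small — and a constant column raises a :class:`DegenerateLabelsError`.
    """
    if isinstance(table, (str, os.PathLike)):
        table = pd.read_csv(table, sep="\t")
    if "participant_id" not in table.columns:
        raise FormatError("participants table needs a 'participant_id' column")
    if column not in table.columns:
        raise FormatError(f"column {column!r} not in participants table")
    tbl = table.set_index("participant_id")
    if tbl.index.has_duplicates:
        raise ConsistencyError("duplicate participant_id rows")
    order = list(tbl.index) if subjects is None else list(subjects)
    missing = [s for s in order if s not in tbl.index]
    if missing:
        raise ConsistencyError(f"subjects absent from participants table: {missing}")
    values = pd.to_numeric(tbl.loc[order, column], errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(values)):
        bad = [order[i] for i in np.flatnonzero(~np.isfinite(values))]
        raise DataError(f"missing/non-numeric {column!r} for {bad}; not imputed")
    return LabelVector(subjects=order, values=values, name=column)


# ---------------------------------------------------------------------------
# beta-dataset round trip (NIfTI volumes + TSV manifest)


def write_beta_dataset(dataset: BetaDataset, parc: Parcellation, out_dir) -> str:
    """Write one float64 NIfTI per (subject, condition) plus a manifest TSV.

    Voxels outside all regions are NaN.  Reading the manifest back with
    :func:`read_beta_dataset` reproduces every feature vector bit for bit.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    name_to_label = {v: k for k, v in parc.region_table.items()}
    rows = []
    for s in dataset.subjects:
        for c in dataset.conditions:
            flat = np.full(parc.label_volume.size, np.nan)
            for r in dataset.regions:
                flat[parc.region_indices(name_to_label[r])] = dataset.features[(s, c, r)]
            vol = flat.reshape(parc.label_volume.shape, order="F")
            path = os.path.join(out_dir, f"{s}_{c}_beta.nii")
            nib.save(nib.Nifti1Image(vol, parc.affine), path)
            rows.append({"participant_id": s, "condition": c, "path": path})
    manifest = os.path.join(out_dir, "beta_manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_beta_dataset(manifest, parc: Parcellation) -> BetaDataset:
    tbl = pd.read_csv(manifest, sep="\t")
    beta_maps = {
        (row.participant_id, row.condition): row.path for row in tbl.itertuples()
    }
    return extract_features(beta_maps, parc)


def write_run_summary(run_dir, payload: dict, log_lines: Sequence[str] = ()) -> None:
    """Machine-readable JSON summary plus plain-text log in a run directory."""
    run_dir = str(run_dir)
    os.makedirs(run_dir, exist_ok=True)
    with open(os.path.join(run_dir, "summary.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)
    with open(os.path.join(run_dir, "run.log"), "w") as fh:
        fh.write("\n".join(log_lines) + ("\n" if log_lines else ""))
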