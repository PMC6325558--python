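"""Synthetic studies with the statistical structure the analysis assumes.

The generator emulates the study design this pipeline targets: ~20
subjects with continuous questionnaire scores, a small atlas of
fear-circuit regions, two video conditions (harmful / harmless) with 15
trials each in a pseudorandomized event-related session (365 volumes,
TR 2.1 s, 4 s stimuli, 6-8 s jittered ITIs, no more than two identical
consecutive trials), and label-coupled multivoxel signal confined to
designated region x condition blocks.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm
from .io import BetaDataset, LabelVector, Parcellation

#: The 22 bilateral fear-circuit atlas labels (AAL nomenclature) used when
#: a full-scale atlas is requested: thalamus, amygdala, hippocampus,
#: insula, anterior cingulate, medial and lateral orbitofrontal and medial
#: prefrontal regions, left and right.
AAL22_REGIONS = [
    "Thalamus_L", "Thalamus_R",
    "Amygdala_L", "Amygdala_R",
    "Hippocampus_L", "Hippocampus_R",
    "Insula_L", "Insula_R",
    "Cingulum_Ant_L", "Cingulum_Ant_R",
    "Frontal_Med_Orb_L", "Frontal_Med_Orb_R",
    "Frontal_Sup_Orb_L", "Frontal_Sup_Orb_R",
    "Frontal_Mid_Orb_L", "Frontal_Mid_Orb_R",
    "Frontal_Inf_Orb_L", "Frontal_Inf_Orb_R",
    "Frontal_Sup_Medial_L", "Frontal_Sup_Medial_R",
    "Rectus_L", "Rectus_R",
]

DEFAULT_CONDITIONS = ("harmful", "harmless")


@dataclass
class SignalSpec:
    """Where and how strongly labels couple to multivoxel patterns.

    For every ``(region, condition)`` in ``informative_blocks`` the beta
    pattern of subject i is ``effect_size * z(y_i) * v + noise`` with ``v``
    a fixed unit-norm random pattern over the region's voxels and ``z``
    label standardization; all other blocks are pure noise.  An empty
    block list is the null model.  ``noise_sd = 0`` is the exact noiseless
    oracle mode.
    """

    informative_blocks: list[tuple[str, str]] = field(default_factory=list)
    effect_size: float = 1.0
    pattern_seed: int = 0
    noise_sd: float = 1.0
    label_mean: float = 35.45
    label_sd: float = 22.53

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class DesignSpec:
    """Session timing of the event-related design.

    ``rating_duration`` (the unmodeled VAS screen after each clip) defaults
    to 11 s so 30 trials with 4 s stimuli and ~7 s mean ITI fit comfortably
    inside 365 volumes at TR 2.1 s; the rating screen is left as unmodeled
    baseline.
    """

    n_volumes: int = 365
    TR: float = 2.1
    n_trials_per_condition: int = 15
    stimulus_duration: float = 4.0
    iti_range: tuple[float, float] = (6.0, 8.0)
    rating_duration: float = 11.0
    lead_in: float = 10.0
    max_consecutive: int = 2

    def __post_init__(self) -> None:
        n_trials = 2 * self.n_trials_per_condition
        span = self.lead_in + n_trials * (
            self.stimulus_duration + self.rating_duration + self.iti_range[1]
        )
        if span > self.n_volumes * self.TR:
            raise ValueError(
                "event span exceeds the session even at maximal ITI; "
                "shorten the design or add volumes"
            )


def make_atlas(grid_shape=(12, 12, 12), n_regions: int = 4, seed: int = 0,
               voxel_size=(2.5, 2.5, 2.8)) -> Parcellation:
    """Deterministic synthetic atlas of disjoint box-shaped regions.

    The grid is partitioned into cells and each region occupies a random
    box of at least 2 voxels per axis inside its own cell.  Regions are
    named ``R01``... except at ``n_regions = 22`` where the bilateral
    fear-circuit labels are used.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    grid_shape = tuple(int(g) for g in grid_shape)
    k = int(np.ceil(n_regions ** (1.0 / 3.0)))
    while k ** 3 < n_regions:
        k += 1
    cell = tuple(g // k for g in grid_shape)
    if min(cell) < 2:
        raise ValueError(
            f"cannot pack {n_regions} regions of >=4 voxels into grid "
            f"{grid_shape}; enlarge the grid"
        )
    rng = np.random.default_rng(seed)
    vol = np.zeros(grid_shape, dtype=np.int32)
    cells = [(i, j, l) for i in range(k) for j in range(k) for l in range(k)]
    for label, (ci, cj, cl) in enumerate(cells[:n_regions], start=1):
        origin = (ci * cell[0], cj * cell[1], cl * cell[2])
        size = [int(rng.integers(max(2, c // 2), c + 1)) for c in cell]
        off = [int(rng.integers(0, c - s + 1)) for c, s in zip(cell, size)]
        sl = tuple(
            slice(o + f, o + f + s) for o, f, s in zip(origin, off, size)
        )
        vol[sl] = label
    if n_regions == 22:
        names = {i + 1: AAL22_REGIONS[i] for i in range(22)}
    else:
        names = {i: f"R{i:02d}" for i in range(1, n_regions + 1)}
    affine = np.diag(list(voxel_size) + [1.0])
    return Parcellation(
        label_volume=vol, voxel_size=tuple(voxel_size),
        region_table=names, affine=affine,
    )


def simulate_labels(n_subjects: int, label_mean: float = 35.45,
                    label_sd: float = 22.53, seed: int = 0,
                    clip_range: tuple[float, float] | None = None,
                    name: str = "score") -> LabelVector:
    """Gaussian questionnaire scores, optionally clipped to a scale range."""
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for leave-one-out CV")
    if label_sd <= 0:
        raise ValueError("label_sd must be > 0")
    rng = np.random.default_rng(seed)
    values = rng.normal(label_mean, label_sd, size=n_subjects)
    if clip_range is not None:
        values = np.clip(values, *clip_range)
    subjects = [f"sub-{i + 1:02d}" for i in range(n_subjects)]
    return LabelVector(subjects=subjects, values=values, name=name)


def _region_patterns(parc: Parcellation, spec: SignalSpec) -> dict[str, np.ndarray]:
    """Fixed unit-norm pattern per region, deterministic in pattern_seed."""
    rng = np.random.default_rng(spec.pattern_seed)
    patterns = {}
    counts = parc.voxel_counts()
    for lab in parc.labels:
        v = rng.standard_normal(counts[lab])
        patterns[parc.region_table[lab]] = v / np.linalg.norm(v)
    return patterns


def simulate_betas(parc: Parcellation, labels: LabelVector, spec: SignalSpec,
                   seed: int | None = None,
                   conditions=DEFAULT_CONDITIONS) -> BetaDataset:
    """Per-subject, per-condition beta patterns with planted signal blocks."""
    region_names = parc.region_names
    for region, cond in spec.informative_blocks:
        if region not in region_names:
            raise ValueError(f"informative region {region!r} absent from atlas")
        if cond not in conditions:
            raise ValueError(f"informative condition {cond!r} unknown")
    noise_rng = np.random.default_rng(
        spec.pattern_seed + 1 if seed is None else seed
    )
    patterns = _region_patterns(parc, spec)
    y = labels.values
    sd = y.std()
    z = (y - y.mean()) / (sd if sd > 0 else 1.0)
    counts = {parc.region_table[k]: v for k, v in parc.voxel_counts().items()}

    informative = set(spec.informative_blocks)
    features: dict[tuple[str, str, str], np.ndarray] = {}
    for si, subj in enumerate(labels.subjects):
        for cond in conditions:
            for region in region_names:
                eps = (
                    noise_rng.standard_normal(counts[region]) * spec.noise_sd
                    if spec.noise_sd > 0 else np.zeros(counts[region])
                )
                vec = eps
                if (region, cond) in informative:
                    vec = spec.effect_size * z[si] * patterns[region] + eps
                features[(subj, cond, region)] = vec
    return BetaDataset(
        subjects=list(labels.subjects), conditions=list(conditions),
        regions=list(region_names), features=features,
        provenance=f"simulate_betas(pattern_seed={spec.pattern_seed})",
    )


def make_event_table(design: DesignSpec, seed: int = 0,
                     conditions=DEFAULT_CONDITIONS) -> pd.DataFrame:
    """Pseudorandomized event table honoring the consecutive-trial cap.

    Orders are drawn by rejection sampling (cap 1000 draws, then error):
    a random interleaving of the two conditions is accepted only if no
    more than ``design.max_consecutive`` identical trial types follow one
    another.  Onsets are lead-in + stimulus + rating + jittered ITI,
    rounded to 2 decimals.
    """
    rng = np.random.default_rng(seed)
    base = [conditions[0]] * design.n_trials_per_condition + \
           [conditions[1]] * design.n_trials_per_condition
    order = None
    for _ in range(1000):
        cand = list(rng.permutation(base))
        run, longest = 1, 1
        for a, b in zip(cand, cand[1:]):
            run = run + 1 if a == b else 1
            longest = max(longest, run)
        if longest <= design.max_consecutive:
            order = cand
            break
    if order is None:
        raise RuntimeError("could not find an admissible trial order in "
                           "1000 draws; relax the ordering constraint")
    onsets = []
    t = design.lead_in
    for _ in order:
        onsets.append(round(t, 2))
        iti = rng.uniform(*design.iti_range)
        t += design.stimulus_duration + design.rating_duration + iti
    return pd.DataFrame({
        "onset": onsets,
        "duration": [design.stimulus_duration] * len(order),
        "trial_type": order,
    })


@dataclass
class SimulatedSession:
    """One subject's simulated run: BOLD, tables, and the generative truth."""

    bold: np.ndarray
    events: pd.DataFrame
    confounds: pd.DataFrame
    amplitudes: dict[str, np.ndarray]  # condition -> true 3D amplitude map
    parc: Parcellation


def simulate_session(parc: Parcellation, label_value: float,
                     design: DesignSpec, spec: SignalSpec, seed: int = 0,
                     drift_amplitude: float = 0.0,
                     conditions=DEFAULT_CONDITIONS) -> SimulatedSession:
    """Full BOLD session for one subject.

    ``label_value`` is the subject's standardized score; informative blocks
    receive condition amplitudes ``effect_size * label_value * v`` per
    voxel.  Voxel time series are the HRF-convolved boxcars scaled by
    those amplitudes, plus an optional linear drift (also written to the
    confound table) and white noise of ``spec.noise_sd``.
    """
    events = make_event_table(design, seed=seed, conditions=conditions)
    regs = {
        cond: glm.task_regressor(
            events.loc[events.trial_type == cond, "onset"].to_numpy(float),
            design.stimulus_duration, design.n_volumes, design.TR,
        )
        for cond in conditions
    }
    patterns = _region_patterns(parc, spec)
    name_to_label = {v: k for k, v in parc.region_table.items()}
    shape = parc.label_volume.shape
    nvox = parc.label_volume.size

    amplitudes = {}
    for cond in conditions:
        flat = np.zeros(nvox)
        for region, bcond in spec.informative_blocks:
            if bcond != cond:
                continue
            idx = parc.region_indices(name_to_label[region])
            flat[idx] = spec.effect_size * label_value * patterns[region]
        amplitudes[cond] = flat.reshape(shape, order="F")

    drift = np.linspace(-0.5, 0.5, design.n_volumes)
    series = np.zeros((nvox, design.n_volumes))
    for cond in conditions:
        series += np.outer(amplitudes[cond].ravel(order="F"), regs[cond])
    series += drift_amplitude * drift[None, :]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed + 1)
        series += rng.standard_normal(series.shape) * spec.noise_sd
    bold = series.reshape(shape + (design.n_volumes,), order="F")
    confounds = pd.DataFrame({"drift_linear": drift})
    return SimulatedSession(
        bold=bold, events=events, confounds=confounds,
        amplitudes=amplitudes, parc=parc,
    )


def write_study(out_dir, parc: Parcellation, labels: LabelVector,
                dataset: BetaDataset) -> dict:
    """Write a simulated study as NIfTI + BIDS-style TSVs + manifest JSON."""
    import json
    import os

    import nibabel as nib

    from .io import write_beta_dataset

    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    nib.save(nib.Nifti1Image(parc.label_volume.astype(np.int16), parc.affine),
             os.path.join(out_dir, "atlas.nii"))
    pd.DataFrame(
        {"label": parc.labels, "name": parc.region_names}
    ).to_csv(os.path.join(out_dir, "atlas_labels.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {"participant_id": labels.subjects, labels.name: labels.values}
    ).to_csv(os.path.join(out_dir, "participants.tsv"), sep="\t", index=False)
    manifest = write_beta_dataset(dataset, parc, os.path.join(out_dir, "betas"))
    payload = {
        "n_subjects": len(labels.subjects),
        "conditions": dataset.conditions,
        "regions": dataset.regions,
        "label_name": labels.name,
        "beta_manifest": manifest,
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload
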