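import numpy as np
import pytest

from roimkl import (
    RunConfig,
    SignalSpec,
    build_kernels,
    make_atlas,
    simulate_betas,
    simulate_labels,
)


@pytest.fixture(scope="session")
def toy_atlas():
    """Four box regions on a 12^3 grid (27-216 voxels each)."""
    return make_atlas(grid_shape=(12, 12, 12), n_regions=4, seed=7)


def make_study(n_subjects=20, blocks=(("R02", "harmful"),), effect_size=5.0,
               noise_sd=1.0, seed=0, atlas=None, n_regions=4,
               grid_shape=(12, 12, 12)):
    """Synthetic decoding study: atlas, labels, betas, raw kernels.

    Defaults give a clearly decodable single-block signal at the target
    sample size of 20 subjects.
    """
    parc = atlas if atlas is not None else make_atlas(
        grid_shape=grid_shape, n_regions=n_regions, seed=7
    )
    labels = simulate_labels(n_subjects, seed=seed + 1)
    spec = SignalSpec(
        informative_blocks=list(blocks), effect_size=effect_size,
        noise_sd=noise_sd, pattern_seed=seed + 2,
    )
    data = simulate_betas(parc, labels, spec, seed=seed + 3)
    return parc, labels, data, build_kernels(data)


@pytest.fixture
def strong_study():
    """Near-noiseless single-block study; the pipeline should decode it."""
    return make_study(noise_sd=1e-8, effect_size=1.0, seed=11)


@pytest.fixture
def fast_cfg():
    return RunConfig(C_grid=[1.0, 100.0], n_permutations=99, seed=1234)
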