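import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import soundmvpa as sm


@pytest.fixture(scope="session")
def small_grid():
    return sm.ellipsoid_grid((8, 8, 4), voxel_mm=(2.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def full_design():
    """The study design: 7 runs x 7 categories x 6 items."""
    return sm.make_design(7, 7, 6, seed=11)


def make_clean_dataset(
    grid,
    n_runs=4,
    n_categories=3,
    items=2,
    n_subjects=1,
    n_informative=5,
    effect=2.0,
    sigma_item=0.0,
    sigma_run=0.0,
    sigma_noise=0.5,
    jitter=0,
    gain_sd=0.0,
    offset_sd=0.0,
    seed=7,
):
    """Small synthetic dataset with an unperturbed-by-default subject model."""
    design = sm.make_design(n_runs, n_categories, items, seed=seed)
    truth = sm.make_ground_truth(
        grid, n_informative, effect_size=effect, seed=seed,
        categories=design.categories,
    )
    subjects = sm.make_subjects(
        grid, n_subjects, categories=design.categories,
        spatial_jitter_voxels=jitter, gain_sd=gain_sd, offset_sd=offset_sd,
        seed=seed,
    )
    ds = sm.simulate_betas(
        design, truth, subjects,
        sigma_item=sigma_item, sigma_run=sigma_run, sigma_noise=sigma_noise,
        seed=seed, grid=grid,
    )
    return ds, design, truth, subjects


@pytest.fixture()
def small_dataset(small_grid):
    ds, *_ = make_clean_dataset(small_grid)
    return ds
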