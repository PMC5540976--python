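"""Shared fixtures: small, fast synthetic scenarios.

The reduced sheet (32x32 columns -> 4x4 voxels per patch, 64 voxels total)
keeps unit tests fast while preserving every structural property of the
full-size default (64x64 columns -> 8x8 voxels per patch).
"""

import numpy as np
import pandas as pd
import pytest

import voxelgrain as vg
from voxelgrain.datasets import PatternDataset
from voxelgrain.geometry import PatchSpec


SMALL_MAP = dict(columns_per_patch=32)


@pytest.fixture(scope="session")
def small_mixed():
    """Mixed scenario, 4 subjects, reduced sheet."""
    sc = vg.mixed_scenario(
        seed=11, n_subjects=4, map=vg.NeuralMapParams(**SMALL_MAP)
    )
    return vg.generate_dataset(sc)


@pytest.fixture(scope="session")
def small_coarse_noisefree():
    """Coarse-only scenario without any noise, 2 subjects, reduced sheet."""
    sc = vg.coarse_only_scenario(
        seed=21,
        n_subjects=2,
        map=vg.NeuralMapParams(**SMALL_MAP),
        noise=vg.NoiseParams(sigma_pattern=0.0, sigma_subject=0.0),
    )
    return vg.generate_dataset(sc)


@pytest.fixture(scope="session")
def small_mixed_noisefree():
    """Mixed scenario without noise: train and test contrasts are identical."""
    sc = vg.mixed_scenario(
        seed=31,
        n_subjects=2,
        map=vg.NeuralMapParams(**SMALL_MAP),
        noise=vg.NoiseParams(sigma_pattern=0.0, sigma_subject=0.0),
    )
    return vg.generate_dataset(sc)


def manual_dataset(t, grid_shape=(2, 2), patch_ids=(1,), kinds=("grating",)):
    """Hand-built PatternDataset over square per-patch grids at the four
    diagonal quarterfield centers; ``t`` has the full 6-d shape."""
    ny, nx = grid_shape
    centers = {1: 45.0, 2: 135.0, 3: 225.0, 4: 315.0}
    patches = [PatchSpec(pid, centers[pid], (1.5, 7.04)) for pid in patch_ids]
    rows = []
    for pid in patch_ids:
        for y in range(ny):
            for x in range(nx):
                rows.append(dict(patch_id=pid, ecc_band=min(y, 2), x=x, y=y,
                                 polar=centers[pid], ecc=3.0))
    voxels = pd.DataFrame(rows)
    return PatternDataset(
        t=np.asarray(t, dtype=float),
        voxels=voxels,
        kinds=tuple(kinds),
        grid_shape=grid_shape,
        patches=patches,
    )
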