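"""Shared fixtures: small random lesion cohorts built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from psdlsm.lesion_io import LesionMask


def random_blob_mask(
    rng: np.random.Generator,
    shape=(8, 8, 8),
    n_voxels: int = 6,
    voxel_mm: float = 1.0,
    patient_id: str = "",
) -> LesionMask:
    """A random connected blob grown by dilation from a random seed voxel."""
    grid = np.zeros(shape, dtype=np.uint8)
    pos = tuple(rng.integers(0, s) for s in shape)
    grid[pos] = 1
    cells = [pos]
    steps = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while grid.sum() < n_voxels:
        base = cells[rng.integers(len(cells))]
        d = steps[rng.integers(6)]
        nb = tuple(np.clip(np.add(base, d), 0, np.array(shape) - 1))
        if not grid[nb]:
            grid[nb] = 1
            cells.append(nb)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    return LesionMask(grid=grid, affine=affine, voxel_size_mm=(voxel_mm,) * 3, patient_id=patient_id)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_masks(rng) -> list[LesionMask]:
    """Twenty overlapping random blob masks on an 8^3 grid."""
    return [
        random_blob_mask(rng, n_voxels=int(rng.integers(4, 30)), patient_id=f"p{i:02d}")
        for i in range(20)
    ]
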