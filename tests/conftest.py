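"""Shared fixtures and geometry builders for the test suite."""

import numpy as np
import pytest

from strokemark.imaging import BinaryMask, ScalarVolume, VoxelGrid


def make_grid(shape, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> VoxelGrid:
    affine = np.diag([*spacing, 1.0])
    affine[:3, 3] = origin
    return VoxelGrid(tuple(shape), affine)


def ball_mask(radius: int, spacing=1.0, margin: int = 3) -> BinaryMask:
    """Digital sphere: voxels whose index distance to the centre is <= radius."""
    n = 2 * radius + 2 * margin + 1
    grid = make_grid((n, n, n), (spacing,) * 3)
    c = (n - 1) / 2
    ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    m = (ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2 <= radius**2
    return BinaryMask(grid, m.astype(np.uint8))


def box_mask(shape, lo, hi, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    """Axis-aligned filled box with voxel indices lo (incl) .. hi (excl)."""
    grid = make_grid(shape, spacing)
    m = np.zeros(shape, dtype=np.uint8)
    m[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = 1
    return BinaryMask(grid, m)


def random_mask(shape, rng, p=0.3, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    grid = make_grid(shape, spacing)
    return BinaryMask(grid, (rng.random(shape) < p).astype(np.uint8))


def random_volume(shape, rng, spacing=(1.0, 1.0, 1.0)) -> ScalarVolume:
    grid = make_grid(shape, spacing)
    return ScalarVolume(grid, rng.normal(500.0, 100.0, size=shape))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
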