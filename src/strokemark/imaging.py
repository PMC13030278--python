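"""Image data model and NIfTI I/O.

All downstream stages operate on three small in-memory types:

* :class:`VoxelGrid` — shape, voxel spacing (mm) and the 4x4 world
  transform mapping 0-based voxel indices to world mm coordinates.
* :class:`ScalarVolume` — a 3D scalar field (e.g. an ADC map) on a grid.
* :class:`BinaryMask` — a {0,1} field (lesion or tract mask) on a grid.

Volumes are reoriented to the closest-to-RAS canonical axis order at load
time so that axis indices mean the same thing for every input. Nearest-
neighbour resampling moves a mask onto another grid without leaving {0,1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import DimensionalityError, GeometryError, GridMismatchError

logger = logging.getLogger(__name__)

#: World-coordinate tolerance (mm) when comparing grids.
GRID_ATOL_MM = 1e-4


@dataclass(frozen=True)
class VoxelGrid:
    """Voxel lattice geometry: shape, mm spacing and world transform.

    ``world_transform`` maps homogeneous 0-based voxel indices to world mm
    coordinates (NIfTI affine convention). ``spacing`` is derived from the
    column norms of its linear part.
    """

    shape: tuple[int, int, int]
    world_transform: np.ndarray  # 4x4, voxel index -> world mm
    orientation_label: str = "RAS"

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        A = np.asarray(self.world_transform, dtype=float)
        if A.shape != (4, 4):
            raise GeometryError(f"world transform must be 4x4, got {A.shape}")
        object.__setattr__(self, "world_transform", A)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise GeometryError(f"invalid grid shape {shape}")
        if abs(np.linalg.det(A[:3, :3])) < 1e-12:
            raise GeometryError("world transform is singular")
        if np.any(self.spacing <= 0):
            raise GeometryError(f"non-positive voxel spacing {self.spacing}")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm per axis (column norms of the linear part)."""
        return np.linalg.norm(self.world_transform[:3, :3], axis=0)

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (N,3) voxel indices to (N,3) world mm coordinates."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.world_transform[:3, :3].T + self.world_transform[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (N,3) world mm coordinates to continuous voxel indices."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        inv = np.linalg.inv(self.world_transform)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class ScalarVolume:
    """A 3D scalar field (typically an ADC map) on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GridMismatchError(
                f"value array shape {self.values.shape} != grid shape {self.grid.shape}"
            )


@dataclass
class BinaryMask:
    """A {0,1} voxel field (lesion or tract mask) on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.shape != self.grid.shape:
            raise GridMismatchError(
                f"mask array shape {arr.shape} != grid shape {self.grid.shape}"
            )
        if arr.dtype != np.uint8:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask values must be in {{0,1}}, got {uniq[:10]}")
            arr = arr.astype(np.uint8)
        self.values = arr

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


def voxel_volume_mm3(grid: VoxelGrid) -> float:
    """Volume of one voxel in mm^3 (product of the spacings)."""
    return float(np.prod(grid.spacing))


def _load_canonical(path, take_first_of_4d: bool) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    ndim = len(img.shape)
    if ndim == 4:
        if not take_first_of_4d:
            raise DimensionalityError(
                f"{path}: 4D input; pass take_first_of_4d=True to extract volume 0"
            )
        data = np.asanyarray(img.dataobj)[..., 0]
    elif ndim == 3:
        data = np.asanyarray(img.dataobj)
    else:
        raise DimensionalityError(f"{path}: unsupported dimensionality {ndim}")
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        n_bad = int(np.size(data) - np.isfinite(data).sum())
        logger.warning("%s: %d non-finite voxels replaced with 0", path, n_bad)
        data = np.nan_to_num(data, nan=0.0, posinf=0.0, neginf=0.0)
    label = "".join(nib.aff2axcodes(img.affine))
    grid = VoxelGrid(tuple(data.shape), np.asarray(img.affine, float), label)
    return data, grid


def load_volume(path, take_first_of_4d: bool = False) -> ScalarVolume:
    """Read a 3D (or 4D, first timepoint) NIfTI scalar volume.

    The image is reoriented to the canonical closest-to-RAS axis order; 4D
    acquisitions collapse to their first volume only when
    ``take_first_of_4d`` is set, mirroring the handling of multi-timepoint
    diffusion series.
    """
    data, grid = _load_canonical(path, take_first_of_4d)
    return ScalarVolume(grid, data)


def load_mask(path, threshold: float = 0.5, take_first_of_4d: bool = False) -> BinaryMask:
    """Read a NIfTI mask, binarizing as ``value > threshold``."""
    data, grid = _load_canonical(path, take_first_of_4d)
    return BinaryMask(grid, (data > threshold).astype(np.uint8))


def save_volume(obj: ScalarVolume | BinaryMask, path) -> None:
    """Write a volume or mask back to NIfTI (float64 / uint8)."""
    nib.save(nib.Nifti1Image(obj.values, obj.grid.world_transform), str(path))


def assert_same_grid(a, b) -> None:
    """Raise :class:`GridMismatchError` unless two gridded objects share a grid.

    Shapes must be identical; world transforms must agree within
    ``GRID_ATOL_MM`` millimetres.
    """
    ga, gb = a.grid if hasattr(a, "grid") else a, b.grid if hasattr(b, "grid") else b
    if ga.shape != gb.shape:
        raise GridMismatchError(f"shape mismatch: {ga.shape} vs {gb.shape}")
    if not np.allclose(ga.world_transform, gb.world_transform, atol=GRID_ATOL_MM):
        raise GridMismatchError("world transform mismatch beyond tolerance")


def same_grid(a, b) -> bool:
    """Boolean form of :func:`assert_same_grid`."""
    try:
        assert_same_grid(a, b)
    except GridMismatchError:
        return False
    return True


def resample_nearest(mask: BinaryMask, target: VoxelGrid) -> BinaryMask:
    """Resample a binary mask onto ``target`` by nearest-neighbour lookup.

    Each target voxel takes the value of the source voxel whose centre is
    nearest in world coordinates; values stay strictly in {0,1}. Target
    voxels falling outside the source field of view become 0.
    """
    if same_grid(mask.grid, target):
        return BinaryMask(target, mask.values.copy())
    # compose target-index -> world -> source-index
    try:
        T = np.linalg.inv(mask.grid.world_transform) @ target.world_transform
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in VoxelGrid
        raise GeometryError("singular world transform") from exc
    nx, ny, nz = target.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    src = idx @ T[:3, :3].T + T[:3, 3]
    src = np.rint(src).astype(np.int64)
    inb = np.all((src >= 0) & (src < np.array(mask.grid.shape)), axis=1)
    out = np.zeros(len(src), dtype=np.uint8)
    s = src[inb]
    out[inb] = mask.values[s[:, 0], s[:, 1], s[:, 2]]
    return BinaryMask(target, out.reshape(target.shape))
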