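"""Slice-wise grey-level co-occurrence (GLCM) texture of the lesion interior.

Protocol
--------
ADC intensities inside the lesion are min-max normalised to 8-bit levels
(0-255) over the whole 3D lesion, then analysed slice by slice along the
axial axis. For every slice containing lesion voxels a co-occurrence matrix
is built for each pixel distance d in {1,2,3} and direction in
{0, 45, 90, 135} degrees, counting only pixel pairs with BOTH ends inside
the lesion mask; matrices are symmetrised and normalised to probabilities.
Six Haralick statistics (contrast, dissimilarity, homogeneity, angular
second moment, energy, correlation) are averaged over directions and
distances per slice; Shannon entropy comes from the slice's 256-bin
intensity histogram. The subject-level descriptor is the arithmetic mean
over contributing slices — seven numbers per subject.

Conventions for degenerate inputs: a constant lesion maps to level 0
everywhere; a zero-variance GLCM has correlation 1 (the limit convention);
offsets or slices with no valid pair are excluded from averages rather than
contributing zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyLesionError, UndefinedFeatureError
from .imaging import BinaryMask, ScalarVolume, assert_same_grid

#: (row, col) unit offsets per direction, matching the usual 2D GLCM
#: convention on array axes (axis 0 = rows).
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

#: sigma_i * sigma_j below this is treated as zero variance.
ZERO_VARIANCE_EPS = 1e-12


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 256
    distances: tuple[int, ...] = (1, 2, 3)
    angles_deg: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    normalized: bool = True
    slice_axis: int = 2
    #: normalise intensities over the whole 3D lesion (default) or per slice
    normalize_per_slice: bool = False

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if any(d < 1 for d in self.distances):
            raise ValueError("distances must be >= 1")
        if any(a not in _ANGLE_OFFSETS for a in self.angles_deg):
            raise ValueError(f"angles must be among {sorted(_ANGLE_OFFSETS)}")


@dataclass
class GLCMatrix:
    """Normalised symmetric co-occurrence probability matrix p(i,j)."""

    p: np.ndarray  # levels x levels
    mu_i: float
    mu_j: float
    sigma_i: float
    sigma_j: float
    valid_pair_count: int


@dataclass(frozen=True)
class TextureFeatures:
    contrast: float
    dissimilarity: float
    homogeneity: float
    asm: float
    energy: float
    correlation: float
    entropy: float

    def as_tuple(self) -> tuple[float, ...]:
        return (
            self.contrast,
            self.dissimilarity,
            self.homogeneity,
            self.asm,
            self.energy,
            self.correlation,
            self.entropy,
        )


def normalize_to_8bit(volume: ScalarVolume, mask: BinaryMask, levels: int = 256) -> np.ndarray:
    """Min-max scale in-mask intensities to integer levels 0..levels-1.

    Scaling uses the global 3D in-mask min/max (floor rounding, the maximum
    mapping exactly to the top level). A constant lesion maps to level 0.
    Voxels outside the mask are set to 0 and must be ignored via the mask.
    """
    assert_same_grid(volume, mask)
    if mask.voxel_count == 0:
        raise EmptyLesionError("cannot normalise an empty lesion")
    inmask = mask.values > 0
    vals = volume.values[inmask]
    lo, hi = float(vals.min()), float(vals.max())
    out = np.zeros(volume.values.shape, dtype=np.int64)
    if hi > lo:
        scaled = np.floor((volume.values[inmask] - lo) / (hi - lo) * (levels - 1))
        out[inmask] = np.clip(scaled, 0, levels - 1).astype(np.int64)
    return out


def _pair_values(
    levels2d: np.ndarray, mask2d: np.ndarray, distance: int, angle_deg: int
) -> tuple[np.ndarray, np.ndarray]:
    """Level values (a, b) of all ordered in-mask pixel pairs at the offset."""
    dr, dc = _ANGLE_OFFSETS[angle_deg]
    dr, dc = dr * distance, dc * distance
    nr, nc = levels2d.shape
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    if r0 >= r1 or c0 >= c1:
        z = np.empty(0, dtype=np.int64)
        return z, z
    m = mask2d[r0:r1, c0:c1] & mask2d[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    a = levels2d[r0:r1, c0:c1][m]
    b = levels2d[r0 + dr : r1 + dr, c0 + dc : c1 + dc][m]
    return a.astype(np.int64), b.astype(np.int64)


def _marginal_stats(p: np.ndarray) -> tuple[float, float, float, float]:
    lv = np.arange(p.shape[0], dtype=float)
    p_i = p.sum(axis=1)
    p_j = p.sum(axis=0)
    mu_i = float(lv @ p_i)
    mu_j = float(lv @ p_j)
    sigma_i = float(np.sqrt(((lv - mu_i) ** 2) @ p_i))
    sigma_j = float(np.sqrt(((lv - mu_j) ** 2) @ p_j))
    return mu_i, mu_j, sigma_i, sigma_j


def glcm_slice(
    levels2d: np.ndarray,
    mask2d: np.ndarray,
    distance: int,
    angle_deg: int,
    levels: int = 256,
) -> GLCMatrix:
    """Symmetric, normalised GLCM of one slice at one (distance, angle).

    Ordered pixel pairs are counted only when both ends lie inside the
    slice mask; the transpose is added (symmetry) and the matrix divided by
    the total count. With zero valid pairs the matrix is all-zero and
    ``valid_pair_count`` is 0 — callers must skip such offsets.
    """
    mask2d = np.asarray(mask2d, dtype=bool)
    a, b = _pair_values(np.asarray(levels2d), mask2d, distance, angle_deg)
    counts = np.zeros((levels, levels), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    counts = counts + counts.T
    total = counts.sum()
    n_pairs = len(a)
    if total > 0:
        p = counts / total
        mu_i, mu_j, sigma_i, sigma_j = _marginal_stats(p)
    else:
        p = counts
        mu_i = mu_j = sigma_i = sigma_j = 0.0
    return GLCMatrix(p, mu_i, mu_j, sigma_i, sigma_j, n_pairs)


def haralick_features(g: GLCMatrix) -> tuple[float, float, float, float, float, float]:
    """(contrast, dissimilarity, homogeneity, ASM, energy, correlation).

    Homogeneity uses the absolute-difference kernel 1/(1+|i-j|).
    Correlation is 1 by convention when either marginal variance vanishes.
    """
    if g.valid_pair_count == 0:
        raise UndefinedFeatureError("no valid pixel pairs: features undefined")
    nz = np.nonzero(g.p)
    pv = g.p[nz]
    i = nz[0].astype(float)
    j = nz[1].astype(float)
    d = i - j
    contrast = float((d**2 * pv).sum())
    dissimilarity = float((np.abs(d) * pv).sum())
    homogeneity = float((pv / (1.0 + np.abs(d))).sum())
    asm = float((pv**2).sum())
    energy = float(np.sqrt(asm))
    if g.sigma_i * g.sigma_j < ZERO_VARIANCE_EPS:
        correlation = 1.0
    else:
        correlation = float(
            (((i - g.mu_i) * (j - g.mu_j) * pv).sum()) / (g.sigma_i * g.sigma_j)
        )
    return contrast, dissimilarity, homogeneity, asm, energy, correlation


def slice_entropy(levels2d: np.ndarray, mask2d: np.ndarray, levels: int = 256) -> float:
    """Shannon entropy (bits) of the slice's in-mask level histogram."""
    mask2d = np.asarray(mask2d, dtype=bool)
    vals = np.asarray(levels2d)[mask2d]
    if vals.size == 0:
        raise EmptyLesionError("empty slice mask")
    counts = np.bincount(vals.astype(np.int64), minlength=levels)
    p = counts[counts > 0] / vals.size
    return float(-(p * np.log2(p)).sum())


def _haralick_from_pairs(a: np.ndarray, b: np.ndarray) -> tuple[float, ...]:
    """Haralick statistics straight from ordered pair values.

    Equivalent to building the dense symmetric normalised GLCM and applying
    :func:`haralick_features`, but O(#pairs): the symmetrised matrix puts
    probability 1/(2N) on (a,b) and (b,a) for each of the N ordered pairs,
    so every Eq.-style sum collapses to a mean over the pair list. Used by
    :func:`lesion_texture` on cohort-scale runs; equality with the dense
    route is asserted in the test suite.
    """
    n = len(a)
    af = a.astype(float)
    bf = b.astype(float)
    d = af - bf
    contrast = float((d**2).mean())
    dissimilarity = float(np.abs(d).mean())
    homogeneity = float((1.0 / (1.0 + np.abs(d))).mean())
    # ASM needs cell probabilities: count multiplicity of each symmetric cell.
    both = np.concatenate([a * 65536 + b, b * 65536 + a])
    _, cell_counts = np.unique(both, return_counts=True)
    total = 2.0 * n
    asm = float(((cell_counts / total) ** 2).sum())
    energy = float(np.sqrt(asm))
    # marginals of the symmetric matrix = pooled distribution of both ends
    pooled = np.concatenate([af, bf])
    mu = float(pooled.mean())
    var = float(pooled.var())
    if var < ZERO_VARIANCE_EPS:
        correlation = 1.0
    else:
        correlation = float(((af - mu) * (bf - mu)).mean() / var)
    return contrast, dissimilarity, homogeneity, asm, energy, correlation


def lesion_texture(
    volume: ScalarVolume, mask: BinaryMask, config: GLCMConfig | None = None
) -> TextureFeatures:
    """Subject-level 7-vector of texture features (see module docstring).

    Per slice containing lesion voxels, each Haralick statistic is averaged
    with uniform weights over every (distance, angle) offset that yields at
    least one valid pair; slice entropy comes from the intensity histogram.
    Subject values are arithmetic means across contributing slices.

    Raises
    ------
    UndefinedFeatureError
        If no slice yields a single valid pixel pair (e.g. a lesion of
        scattered isolated voxels) — entropy alone would be defined, but the
        record is treated as degenerate by the caller.
    """
    config = config or GLCMConfig()
    if mask.voxel_count == 0:
        raise EmptyLesionError("texture undefined for an empty lesion")
    levels3d = None
    if not config.normalize_per_slice:
        levels3d = normalize_to_8bit(volume, mask, config.levels)

    axis = config.slice_axis
    inmask = mask.values > 0
    slice_has_lesion = np.any(inmask, axis=tuple(i for i in range(3) if i != axis))

    haralick_slices: list[np.ndarray] = []
    entropy_slices: list[float] = []
    for s in np.nonzero(slice_has_lesion)[0]:
        sl = [slice(None)] * 3
        sl[axis] = s
        sl = tuple(sl)
        m2 = inmask[sl]
        if config.normalize_per_slice:
            v2 = volume.values[sl]
            vals = v2[m2]
            lo, hi = vals.min(), vals.max()
            l2 = np.zeros(v2.shape, dtype=np.int64)
            if hi > lo:
                l2[m2] = np.clip(
                    np.floor((v2[m2] - lo) / (hi - lo) * (config.levels - 1)),
                    0,
                    config.levels - 1,
                ).astype(np.int64)
        else:
            l2 = levels3d[sl]
        entropy_slices.append(slice_entropy(l2, m2, config.levels))
        per_offset = []
        for dist in config.distances:
            for ang in config.angles_deg:
                a, b = _pair_values(l2, m2, dist, ang)
                if len(a) == 0:
                    continue
                per_offset.append(_haralick_from_pairs(a, b))
        if per_offset:
            haralick_slices.append(np.mean(np.array(per_offset), axis=0))

    if not haralick_slices:
        raise UndefinedFeatureError("no slice produced a valid pixel pair")
    har = np.mean(np.array(haralick_slices), axis=0)
    ent = float(np.mean(entropy_slices))
    return TextureFeatures(*(float(x) for x in har), ent)
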