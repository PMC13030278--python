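"""Seeded synthetic phantoms for every pipeline stage.

Each phantom subject is a scaled-down head-like volume containing:

* two tract-shaped masks — curved vertical tubes placed symmetrically
  about the left/right midplane (stand-ins for TractSeg corticospinal
  tract output);
* a ground-truth ellipsoidal lesion of random size/orientation, optionally
  biased toward a tract so lesion-tract overlap varies across subjects;
* one or more noisy candidate lesion masks emulating imperfect
  segmentation models (random boundary erosion/dilation plus boundary
  voxel flips), for exercising majority-vote fusion;
* an ADC-like volume: spatially correlated background texture with a
  reduced mean inside the lesion (acute infarcts are ADC-dark);
* a binary outcome drawn from a stated logistic model,
  logit P(unfavourable) = b0 + b_vol * volume_mL + b_ov * mean_overlap_%.

Everything is deterministic given (spec, seed). Generated cohorts can be
kept in memory or written to disk in exactly the layout the CLI consumes
(NIfTI volumes + manifest/labels/truth CSVs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, binary_erosion, gaussian_filter
from scipy.spatial import cKDTree

from .errors import StrokemarkError
from .imaging import BinaryMask, ScalarVolume, VoxelGrid, save_volume, voxel_volume_mm3


@dataclass(frozen=True)
class PhantomSpec:
    """Generator settings; defaults define the standard study conditions."""

    shape: tuple[int, int, int] = (40, 48, 24)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)

    # tract tubes: lateral offset from the midplane, curvature and radius
    tract_offset_frac: float = 0.25      # of the LR field of view, per side
    tract_curve_mm: float = 6.0          # AP bowing of the centreline
    tract_radius_mm: float = 5.0

    # lesion: ellipsoid semi-axes (mm) and placement
    lesion_axes_mm: tuple[float, float] = (4.0, 12.0)
    tract_bias: float = 0.7              # P(center near a tract centreline)
    center_jitter_mm: float = 6.0

    # ADC model (units of 1e-6 mm^2/s, typical clinical scale)
    adc_background: float = 800.0
    adc_lesion_drop: float = 350.0
    adc_noise_sd: float = 60.0
    adc_noise_length_mm: float = 4.0

    # segmentation-noise model for candidate masks
    n_models: int = 3
    boundary_flip_rate: float = 0.10
    morph_radius: int = 1                # max erosion/dilation radius (voxels)

    # outcome model; defaults emulate an acute-stroke cohort with roughly
    # balanced outcomes (~53% unfavourable) and moderate imaging-outcome
    # association (oracle ROC-AUC ~0.83 for the true probability)
    beta0: float = -2.0
    beta_volume: float = 0.5             # per mL
    beta_overlap: float = 0.35           # per mean overlap %

    def __post_init__(self) -> None:
        if not 0 <= self.boundary_flip_rate < 0.5:
            raise StrokemarkError("boundary_flip_rate must be in [0, 0.5)")
        if self.tract_radius_mm <= 0 or self.lesion_axes_mm[0] <= 0:
            raise StrokemarkError("radii must be positive")
        if self.lesion_axes_mm[0] > self.lesion_axes_mm[1]:
            raise StrokemarkError("lesion axis range must be (lo, hi)")

    @property
    def grid(self) -> VoxelGrid:
        affine = np.diag([*self.spacing, 1.0])
        return VoxelGrid(self.shape, affine, "RAS")

    @classmethod
    def overlap_dominated(cls) -> "PhantomSpec":
        """Outcome driven by tract overlap alone (strong-signal condition).

        The slope makes the outcome nearly deterministic in overlap (the
        oracle that knows the true probability reaches ROC-AUC ~0.96) at
        roughly balanced prevalence, so overlap genuinely dominates.
        """
        return cls(beta0=-3.0, beta_volume=0.0, beta_overlap=1.2,
                   n_models=1, boundary_flip_rate=0.0, morph_radius=0)

    @classmethod
    def null(cls) -> "PhantomSpec":
        """Labels independent of every feature (null condition)."""
        return cls(beta0=0.0, beta_volume=0.0, beta_overlap=0.0,
                   n_models=1, boundary_flip_rate=0.0, morph_radius=0)


@dataclass
class PhantomSubject:
    subject_id: str
    adc: ScalarVolume
    lesion_truth: BinaryMask
    lesion_candidates: list[BinaryMask]
    cst_left: BinaryMask
    cst_right: BinaryMask
    truth: dict  # volume_ml, left/right overlap %, p_unfavourable, label, mrs


# ------------------------------------------------------------------- tracts


def _voxel_centers_mm(grid: VoxelGrid) -> np.ndarray:
    nx, ny, nz = grid.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    return grid.voxel_to_world(idx)


def _tract_centerline(spec: PhantomSpec, side: int) -> np.ndarray:
    """(T,3) world-mm centreline of one tube; side is -1 (left) or +1 (right)."""
    fov = np.array(spec.shape) * np.array(spec.spacing)
    t = np.linspace(0.0, 1.0, 200)
    x = fov[0] / 2.0 + side * spec.tract_offset_frac * fov[0]
    y = fov[1] / 2.0 + spec.tract_curve_mm * np.sin(math.pi * t)
    z = t * (fov[2] - spec.spacing[2])
    return np.stack([np.full_like(t, x), y, z], axis=1)


@lru_cache(maxsize=8)
def _tract_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic left/right tube masks (uint8 arrays), cached per spec."""
    centers = _voxel_centers_mm(spec.grid)
    out = []
    for side in (-1, +1):
        line = _tract_centerline(spec, side)
        d, _ = cKDTree(line).query(centers, k=1)
        out.append((d < spec.tract_radius_mm).astype(np.uint8).reshape(spec.shape))
    left, right = out
    if left.sum() == 0 or right.sum() == 0:
        raise StrokemarkError("tract tube does not fit the phantom volume")
    return left, right


def make_tracts(spec: PhantomSpec) -> tuple[BinaryMask, BinaryMask]:
    left, right = _tract_masks(spec)
    return BinaryMask(spec.grid, left.copy()), BinaryMask(spec.grid, right.copy())


# ------------------------------------------------------------------- lesion


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def _lesion_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    fov = np.array(spec.shape) * np.array(spec.spacing)
    axes = rng.uniform(*spec.lesion_axes_mm, size=3)
    if np.any(2 * axes.max() > fov):
        raise StrokemarkError("lesion cannot fit the phantom volume")
    centers = _voxel_centers_mm(spec.grid)
    for _ in range(20):
        if rng.random() < spec.tract_bias:
            side = -1 if rng.random() < 0.5 else +1
            line = _tract_centerline(spec, side)
            c = line[rng.integers(0, len(line))] + rng.normal(0, spec.center_jitter_mm, 3)
        else:
            c = rng.uniform(0.15, 0.85, size=3) * fov
        c = np.clip(c, axes.max() * 0.5, fov - axes.max() * 0.5)
        rot = _random_rotation(rng)
        u = (centers - c) @ rot / axes
        mask = (np.sum(u**2, axis=1) <= 1.0).reshape(spec.shape)
        if mask.sum() >= 4:
            return mask.astype(np.uint8)
    raise StrokemarkError("could not place a non-degenerate lesion")


def _noisy_candidate(
    truth: np.ndarray, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """Segmentation-model emulation: random morphology change + boundary flips."""
    cand = truth.astype(bool)
    if spec.morph_radius > 0:
        r = int(rng.integers(-spec.morph_radius, spec.morph_radius + 1))
        if r > 0:
            cand = binary_dilation(cand, iterations=r)
        elif r < 0:
            eroded = binary_erosion(cand, iterations=-r)
            if eroded.any():
                cand = eroded
    if spec.boundary_flip_rate > 0:
        shell = binary_dilation(cand, iterations=1) ^ binary_erosion(cand, iterations=1)
        flips = shell & (rng.random(cand.shape) < spec.boundary_flip_rate)
        cand = cand ^ flips
    return cand.astype(np.uint8)


# ------------------------------------------------------------------ subject


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def make_subject(
    spec: PhantomSpec, rng: np.random.Generator, subject_id: str = "phantom"
) -> PhantomSubject:
    """One fully deterministic phantom subject (see module docstring)."""
    grid = spec.grid
    left_arr, right_arr = _tract_masks(spec)
    lesion_arr = _lesion_mask(spec, rng)

    # ADC: correlated background texture, mean drop inside the lesion
    noise = rng.standard_normal(spec.shape)
    sigma = spec.adc_noise_length_mm / np.array(spec.spacing)
    smooth = gaussian_filter(noise, sigma=sigma)
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd * spec.adc_noise_sd
    adc_arr = spec.adc_background + smooth
    adc_arr[lesion_arr > 0] -= spec.adc_lesion_drop
    adc_arr = np.clip(adc_arr, 50.0, None)

    candidates = [
        _noisy_candidate(lesion_arr, spec, rng) for _ in range(spec.n_models)
    ]

    vv = voxel_volume_mm3(grid)
    volume_ml = float(lesion_arr.sum()) * vv / 1000.0
    n_left, n_right = float(left_arr.sum()), float(right_arr.sum())
    ov_left = 100.0 * float(np.sum((lesion_arr > 0) & (left_arr > 0))) / n_left
    ov_right = 100.0 * float(np.sum((lesion_arr > 0) & (right_arr > 0))) / n_right
    mean_ov = 0.5 * (ov_left + ov_right)
    logit = spec.beta0 + spec.beta_volume * volume_ml + spec.beta_overlap * mean_ov
    p = _sigmoid(logit)
    label = int(rng.random() < p)
    mrs = int(rng.integers(3, 7)) if label else int(rng.integers(0, 3))

    return PhantomSubject(
        subject_id=subject_id,
        adc=ScalarVolume(grid, adc_arr),
        lesion_truth=BinaryMask(grid, lesion_arr),
        lesion_candidates=[BinaryMask(grid, c) for c in candidates],
        cst_left=BinaryMask(grid, left_arr.copy()),
        cst_right=BinaryMask(grid, right_arr.copy()),
        truth={
            "volume_ml": volume_ml,
            "left_overlap_pct": ov_left,
            "right_overlap_pct": ov_right,
            "p_unfavourable": p,
            "label": label,
            "mrs": mrs,
        },
    )


def make_cohort(
    spec: PhantomSpec,
    n: int,
    seed: int,
    missing_label_rate: float = 0.0,
    out_dir: str | Path | None = None,
) -> tuple[list[PhantomSubject], pd.DataFrame]:
    """Generate ``n`` subjects from per-subject seeds derived from ``seed``.

    Returns the subjects and a truth table. With ``out_dir`` set, also
    writes the on-disk layout the ``cohort`` CLI consumes: per-subject
    NIfTI volumes, ``manifest.csv``, ``labels.csv`` and ``truth.csv``.
    """
    if n < 1:
        raise StrokemarkError("cohort size must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n + 1)
    label_rng = np.random.default_rng(children[-1])
    subjects = []
    rows = []
    for i in range(n):
        sid = f"sub-{i:04d}"
        subj = make_subject(spec, np.random.default_rng(children[i]), sid)
        labeled = label_rng.random() >= missing_label_rate
        subjects.append(subj)
        rows.append(
            {
                "subject_id": sid,
                **subj.truth,
                "mrs": subj.truth["mrs"] if labeled else np.nan,
            }
        )
    truth = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest_rows = []
        for subj in subjects:
            sdir = out / subj.subject_id
            sdir.mkdir(exist_ok=True)
            save_volume(subj.adc, sdir / "adc.nii.gz")
            save_volume(subj.cst_left, sdir / "cst_left.nii.gz")
            save_volume(subj.cst_right, sdir / "cst_right.nii.gz")
            cand_paths = []
            for m, cand in enumerate(subj.lesion_candidates):
                p = sdir / f"lesion_model{m}.nii.gz"
                save_volume(cand, p)
                cand_paths.append(str(p))
            manifest_rows.append(
                {
                    "subject_id": subj.subject_id,
                    "adc": str(sdir / "adc.nii.gz"),
                    "lesion_masks": ";".join(cand_paths),
                    "cst_left": str(sdir / "cst_left.nii.gz"),
                    "cst_right": str(sdir / "cst_right.nii.gz"),
                }
            )
        pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
        truth[["subject_id", "mrs"]].dropna().to_csv(out / "labels.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
    return subjects, truth


__all__ = [
    "PhantomSpec",
    "PhantomSubject",
    "make_subject",
    "make_cohort",
    "make_tracts",
    "replace",
]
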