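"""Per-subject feature extraction into the 19-feature record and cohort
table assembly.

The registry lists the 19 named imaging biomarkers grouped as:

* morphological (6): volume, surface area, sphericity, solidity,
  elongation, compactness
* intensity-based (4): max intensity, average intensity, centroid,
  quadrant distribution
* texture (7): contrast, dissimilarity, homogeneity, ASM, energy,
  correlation, entropy
* anatomical/tract (2): CST left/right volume, CST left/right overlap %

Some named features are multi-component (centroid is 3 scalars, quadrant
distribution 4, each CST feature 2), so the fixed vectorised design matrix
has 26 columns; both views are exposed.

Extraction never aborts a cohort run: degenerate subjects (e.g. an empty
fused lesion) yield a record with documented nulls and a log entry.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .errors import StrokemarkError, UndefinedFeatureError
from .features import (
    QuadrantConfig,
    morphology_features,
    spatial_intensity_features,
)
from .fusion import majority_vote
from .imaging import BinaryMask, ScalarVolume
from .overlap import overlap_metrics
from .texture import GLCMConfig, lesion_texture

logger = logging.getLogger(__name__)

#: The 19 named features and the width of each in the vectorised design
#: matrix (in fixed registry order).
FEATURE_REGISTRY: dict[str, int] = {
    "lesion_volume": 1,
    "surface_area": 1,
    "sphericity": 1,
    "solidity": 1,
    "elongation": 1,
    "compactness": 1,
    "max_intensity": 1,
    "avg_intensity": 1,
    "lesion_centroid": 3,
    "quadrant_distribution": 4,
    "contrast": 1,
    "dissimilarity": 1,
    "homogeneity": 1,
    "asm": 1,
    "energy": 1,
    "correlation": 1,
    "entropy": 1,
    "cst_volume": 2,
    "cst_overlap": 2,
}

#: Column names of the vectorised design matrix, in fixed order.
FEATURE_COLUMNS: tuple[str, ...] = (
    "lesion_volume_ml",
    "surface_area_mm2",
    "sphericity",
    "solidity",
    "elongation",
    "compactness",
    "max_intensity",
    "avg_intensity",
    "centroid_x_mm",
    "centroid_y_mm",
    "centroid_z_mm",
    "quadrant_la",
    "quadrant_lp",
    "quadrant_ra",
    "quadrant_rp",
    "contrast",
    "dissimilarity",
    "homogeneity",
    "asm",
    "energy",
    "correlation",
    "entropy",
    "cst_left_volume_ml",
    "cst_right_volume_ml",
    "cst_left_overlap_pct",
    "cst_right_overlap_pct",
)

assert sum(FEATURE_REGISTRY.values()) == len(FEATURE_COLUMNS)

_META_COLUMNS = ("subject_id", "config_hash", "version")
_LABEL_COLUMNS = ("mrs", "outcome_unfavourable")


@dataclass(frozen=True)
class PipelineConfig:
    """Extraction settings hashed into every record's provenance field."""

    quadrants: QuadrantConfig = field(default_factory=QuadrantConfig)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    mask_threshold: float = 0.5

    @property
    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "quadrants": [self.quadrants.lr_axis, self.quadrants.ap_axis],
                "glcm": [
                    self.glcm.levels,
                    list(self.glcm.distances),
                    list(self.glcm.angles_deg),
                    self.glcm.slice_axis,
                    self.glcm.normalize_per_slice,
                ],
                "mask_threshold": self.mask_threshold,
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class FeatureRecord:
    """One subject's vectorised feature row plus provenance."""

    subject_id: str
    values: dict[str, float | None]
    config_hash: str
    version: str = __version__

    def __post_init__(self) -> None:
        missing = set(FEATURE_COLUMNS) - set(self.values)
        if missing:
            raise StrokemarkError(f"record missing feature columns: {sorted(missing)}")

    @property
    def null_features(self) -> tuple[str, ...]:
        return tuple(k for k in FEATURE_COLUMNS if self.values[k] is None)

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id}
        row.update({k: self.values[k] for k in FEATURE_COLUMNS})
        row["config_hash"] = self.config_hash
        row["version"] = self.version
        return row


def extract_subject(
    adc: ScalarVolume,
    lesion_candidates: list[BinaryMask],
    cst_left: BinaryMask,
    cst_right: BinaryMask,
    subject_id: str = "subject",
    config: PipelineConfig | None = None,
) -> FeatureRecord:
    """Fuse candidate masks and compute the full 19-feature record.

    An empty fused lesion yields volume 0, null shape/intensity/texture
    features and 0% overlaps (tract volumes are still reported); any
    stage-level degeneracy nulls only its own features.
    """
    config = config or PipelineConfig()
    vals: dict[str, float | None] = {k: None for k in FEATURE_COLUMNS}

    lesion = majority_vote(lesion_candidates)
    ov = overlap_metrics(lesion, cst_left, cst_right)
    vals["cst_left_volume_ml"] = ov.left_cst_volume_ml
    vals["cst_right_volume_ml"] = ov.right_cst_volume_ml
    vals["cst_left_overlap_pct"] = ov.left_overlap_pct
    vals["cst_right_overlap_pct"] = ov.right_overlap_pct

    if lesion.voxel_count == 0:
        logger.warning("%s: empty fused lesion; shape/intensity/texture nulled", subject_id)
        vals["lesion_volume_ml"] = 0.0
        return FeatureRecord(subject_id, vals, config.config_hash)

    morph = morphology_features(lesion)
    vals["lesion_volume_ml"] = morph.volume_ml
    vals["surface_area_mm2"] = morph.surface_area_mm2
    vals["sphericity"] = morph.sphericity
    vals["solidity"] = None if np.isnan(morph.solidity) else morph.solidity
    vals["elongation"] = morph.elongation
    vals["compactness"] = morph.compactness

    spatial = spatial_intensity_features(adc, lesion, config.quadrants)
    vals["max_intensity"] = spatial.max_intensity
    vals["avg_intensity"] = spatial.avg_intensity
    cx, cy, cz = spatial.centroid_world_mm
    vals["centroid_x_mm"], vals["centroid_y_mm"], vals["centroid_z_mm"] = cx, cy, cz
    la, lp, ra, rp = spatial.quadrants.as_tuple()
    vals["quadrant_la"], vals["quadrant_lp"] = la, lp
    vals["quadrant_ra"], vals["quadrant_rp"] = ra, rp

    try:
        tex = lesion_texture(adc, lesion, config.glcm)
        for name, value in zip(
            ("contrast", "dissimilarity", "homogeneity", "asm", "energy", "correlation", "entropy"),
            tex.as_tuple(),
        ):
            vals[name] = value
    except UndefinedFeatureError:
        logger.warning("%s: texture undefined (no valid pixel pairs); nulled", subject_id)

    return FeatureRecord(subject_id, vals, config.config_hash)


@dataclass
class CohortTable:
    """Feature rows for a cohort, optionally with mRS outcome labels.

    ``frame`` holds one row per subject: id, the 26 feature columns,
    provenance, and (after :func:`attach_labels`) the raw mRS score and the
    derived binary outcome (1 = unfavourable, mRS > 2).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        needed = set(_META_COLUMNS) | set(FEATURE_COLUMNS)
        missing = needed - set(self.frame.columns)
        if missing:
            raise StrokemarkError(f"cohort frame missing columns: {sorted(missing)}")
        if self.frame["subject_id"].duplicated().any():
            raise StrokemarkError("duplicate subject_ids in cohort")
        hashes = self.frame["config_hash"].unique()
        if len(hashes) > 1:
            raise StrokemarkError(
                f"records from different configs refuse to concatenate: {hashes}"
            )

    @classmethod
    def from_records(cls, records: list[FeatureRecord]) -> "CohortTable":
        frame = pd.DataFrame([r.to_row() for r in records])
        return cls(frame)

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    @property
    def labeled(self) -> pd.DataFrame:
        """Rows retained for outcome modelling (mRS present)."""
        if "mrs" not in self.frame.columns:
            return self.frame.iloc[0:0]
        return self.frame[self.frame["mrs"].notna()]

    def design_matrix(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(X, y, column names) over labeled rows; nulls appear as NaN."""
        lab = self.labeled
        X = lab[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        y = lab["outcome_unfavourable"].to_numpy(dtype=int)
        return X, y, list(FEATURE_COLUMNS)


def attach_labels(table: CohortTable, labels: pd.DataFrame | str) -> CohortTable:
    """Join an mRS label table (columns subject_id, mrs) onto the cohort.

    Rows without a label keep NaN mRS and are excluded from outcome
    modelling; label rows for unknown subjects are ignored with a warning.
    The binary outcome is 1 for unfavourable (mRS > 2), 0 for favourable
    (mRS <= 2).
    """
    if isinstance(labels, str):
        labels = pd.read_csv(labels)
    labels = labels[["subject_id", "mrs"]].copy()
    labels["subject_id"] = labels["subject_id"].astype(str)
    unknown = set(labels["subject_id"]) - set(table.frame["subject_id"].astype(str))
    if unknown:
        logger.warning("%d label rows for unknown subjects ignored", len(unknown))
        labels = labels[~labels["subject_id"].isin(unknown)]
    frame = table.frame.drop(columns=[c for c in _LABEL_COLUMNS if c in table.frame], errors="ignore")
    frame = frame.merge(labels, on="subject_id", how="left")
    frame["outcome_unfavourable"] = (frame["mrs"] > 2).astype(float)
    frame.loc[frame["mrs"].isna(), "outcome_unfavourable"] = np.nan
    n_excluded = int(frame["mrs"].isna().sum())
    logger.info(
        "labels attached: %d subjects, %d unlabeled (excluded from outcome modelling)",
        len(frame),
        n_excluded,
    )
    return CohortTable(frame)


def write_cohort(table: CohortTable, path) -> None:
    """Serialise the cohort as CSV with a fixed column order.

    Nulls serialise as empty fields and read back as NaN; the round trip is
    lossless for finite values and nulls.
    """
    cols = ["subject_id", *FEATURE_COLUMNS, "config_hash", "version"]
    cols += [c for c in _LABEL_COLUMNS if c in table.frame.columns]
    table.frame[cols].to_csv(path, index=False)


def read_cohort(path) -> CohortTable:
    """Read a cohort CSV written by :func:`write_cohort`."""
    try:
        frame = pd.read_csv(path, dtype={"subject_id": str, "config_hash": str})
    except pd.errors.ParserError as exc:
        raise StrokemarkError(f"malformed cohort file {path}: {exc}") from exc
    return CohortTable(frame)
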