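"""Lesion-corticospinal-tract overlap metrics.

For each hemisphere the tract mask is (if needed) resampled onto the lesion
grid with nearest-neighbour interpolation, then three quantities are
reported per side: tract volume (mL), lesion-tract intersection volume
(mL), and the overlap percentage

    overlap% = 100 * V(lesion AND tract) / V(tract)

i.e. the share of the tract invaded by the lesion — the denominator is the
tract, not the lesion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EmptyTractError
from .imaging import BinaryMask, resample_nearest, same_grid, voxel_volume_mm3

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapMetrics:
    """Per-side tract volumes, intersection volumes and percentages.

    A side whose tract mask is empty after resampling carries ``None`` for
    all three of its fields.
    """

    left_cst_volume_ml: float | None
    right_cst_volume_ml: float | None
    left_overlap_volume_ml: float | None
    right_overlap_volume_ml: float | None
    left_overlap_pct: float | None
    right_overlap_pct: float | None


def _side_metrics(
    lesion: BinaryMask, tract: BinaryMask, side: str
) -> tuple[float | None, float | None, float | None]:
    if not same_grid(lesion, tract):
        tract = resample_nearest(tract, lesion.grid)
    vv = voxel_volume_mm3(lesion.grid)
    n_tract = tract.voxel_count
    if n_tract == 0:
        logger.warning("%s tract empty after resampling; side reported as null", side)
        return None, None, None
    n_overlap = int(np.sum((lesion.values > 0) & (tract.values > 0)))
    return (
        n_tract * vv / 1000.0,
        n_overlap * vv / 1000.0,
        100.0 * n_overlap / n_tract,
    )


def overlap_metrics(
    lesion: BinaryMask,
    cst_left: BinaryMask,
    cst_right: BinaryMask,
    strict: bool = False,
) -> OverlapMetrics:
    """Compute per-side lesion-tract overlap (see module docstring).

    Tract masks on a different grid are moved onto the lesion grid; the
    lesion mask itself is never resampled. With ``strict`` set, an empty
    tract raises :class:`~strokemark.errors.EmptyTractError` instead of
    reporting nulls for that side.
    """
    lv, lo, lp = _side_metrics(lesion, cst_left, "left")
    rv, ro, rp = _side_metrics(lesion, cst_right, "right")
    if strict and (lv is None or rv is None):
        raise EmptyTractError("empty tract mask after resampling")
    return OverlapMetrics(lv, rv, lo, ro, lp, rp)
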