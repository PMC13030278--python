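"""Voxel-wise majority voting over candidate lesion masks.

Several segmentation models may each propose a binary lesion mask for the
same subject. The consensus mask marks a voxel as lesion only when a strict
majority of the models agree; voxels without majority agreement are treated
as non-lesion. For the canonical three-model ensemble this is the
"at least two of three agree" rule; a single mask passes through unchanged.
"""

from __future__ import annotations

from .errors import StrokemarkError
from .imaging import BinaryMask, assert_same_grid

import numpy as np


def majority_vote(masks: list[BinaryMask]) -> BinaryMask:
    """Fuse candidate masks by strict voxel-wise majority.

    A voxel is lesion iff at least ``floor(n/2) + 1`` of the ``n`` input
    masks mark it. Ties at even ``n`` therefore resolve to non-lesion, the
    conservative default. All masks must share one grid.

    Raises
    ------
    StrokemarkError
        If the list is empty.
    GridMismatchError
        If any two masks disagree in grid.
    """
    if not masks:
        raise StrokemarkError("majority_vote requires at least one mask")
    first = masks[0]
    for other in masks[1:]:
        assert_same_grid(first, other)
    if len(masks) == 1:
        return BinaryMask(first.grid, first.values.copy())
    votes = np.zeros(first.grid.shape, dtype=np.int64)
    for m in masks:
        votes += m.values
    need = len(masks) // 2 + 1
    return BinaryMask(first.grid, (votes >= need).astype(np.uint8))
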