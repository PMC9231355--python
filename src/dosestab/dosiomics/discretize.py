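"""Fixed-range gray-level discretization of a dose distribution inside a ROI."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..grids import DoseGrid, RoiMask


@dataclass
class DiscretizedRoi:
    """Integer gray levels 1..n_levels inside a mask; 0 outside.

    The mapping is fixed-range: level(d) = floor((d - lo) / w) + 1 with
    w = (hi - lo) / n_levels, clipped so doses at or above ``hi`` land in the
    top level and doses at or below ``lo`` in level 1.  With the defaults
    (0-70 Gy, 70 levels) the bin width is exactly 1 Gy.
    """

    levels: np.ndarray  # int32, 0 outside the mask
    mask: np.ndarray  # bool
    n_levels: int
    spacing: tuple[float, float, float]

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(
    grid: DoseGrid,
    mask: RoiMask,
    lo: float = 0.0,
    hi: float = 70.0,
    n_levels: int = 70,
) -> DiscretizedRoi:
    """Bin the in-mask dose values into ``n_levels`` levels over [lo, hi] Gy."""
    if not mask.values.any():
        raise ValueError("cannot discretize an empty mask")
    if not lo < hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    if n_levels < 2:
        raise ValueError("need at least 2 gray levels")
    if grid.values.shape != mask.values.shape:
        raise ValueError("dose grid and mask shapes differ")
    w = (hi - lo) / n_levels
    lv = np.floor((grid.values - lo) / w).astype(np.int64) + 1
    np.clip(lv, 1, n_levels, out=lv)
    lv[~mask.values] = 0
    return DiscretizedRoi(
        levels=lv.astype(np.int32),
        mask=mask.values,
        n_levels=int(n_levels),
        spacing=grid.spacing,
    )
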