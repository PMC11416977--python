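"""Fixed-bin-width gray-level discretization of an ROI.

Texture matrices operate on integer gray levels.  Discretization uses a
fixed bin width anchored at the ROI minimum:

    level(v) = floor((HU(v) - min ROI HU) / bin_width) + 1

which is shift-invariant in HU and keeps the number of levels adaptive to
the ROI's dynamic range (the de-facto CT convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..imaging import EmptyRoiError, ImageVolume, RoiMask

__all__ = ["DiscretizedRoi", "discretize"]


@dataclass(frozen=True)
class DiscretizedRoi:
    """Integer gray-level grid over an ROI.

    ``levels`` holds values 1..ng inside the ROI and 0 outside.  ``ng`` is
    the highest assigned level (the number of bins spanned by the ROI's
    intensity range); intermediate levels may be unoccupied.
    """

    levels: np.ndarray
    mask: np.ndarray
    bin_width: float
    ng: int

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def roi_levels(self) -> np.ndarray:
        """Gray levels of the ROI voxels as a flat integer array."""
        return self.levels[self.mask]


def discretize(volume: ImageVolume, mask: RoiMask, bin_width: float) -> DiscretizedRoi:
    """Quantize ROI intensities into fixed-width gray-level bins."""
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    m = mask.voxels
    if not m.any():
        raise EmptyRoiError("cannot discretize an empty ROI")
    vals = volume.voxels[m]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite voxel values inside the ROI")
    lo = vals.min()
    levels = np.zeros(volume.shape, dtype=np.int64)
    levels[m] = np.floor((vals - lo) / bin_width).astype(np.int64) + 1
    return DiscretizedRoi(levels=levels, mask=m, bin_width=float(bin_width),
                          ng=int(levels.max()))
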