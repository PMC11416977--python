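"""First-order (intensity histogram) features, 18 per image.

Definitions follow the standard image-biomarker formulations.  Entropy and
Uniformity are computed on the fixed-bin-width discretized histogram; all
other statistics are computed on the raw intensities.  Moments use the
population (1/n) convention.  Degenerate inputs (constant or single-voxel
ROIs) map every 0/0 to a documented constant — Skewness 0, Kurtosis 0,
Entropy 0, Uniformity 1 — never NaN.
"""

from __future__ import annotations

import numpy as np

from ..imaging import EmptyRoiError, ImageVolume, RoiMask
from .discretize import discretize

__all__ = ["FIRSTORDER_NAMES", "firstorder_features"]

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    volume: ImageVolume, mask: RoiMask, bin_width: float = 25.0
) -> dict[str, float]:
    """Compute the 18 first-order features over the ROI voxels."""
    m = mask.voxels
    if not m.any():
        raise EmptyRoiError("first-order features require a nonempty ROI")
    x = volume.voxels[m].astype(np.float64)
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    if var > 0:
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2)
    else:
        skew, kurt = 0.0, 0.0

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    droi = discretize(volume, mask, bin_width)
    counts = np.bincount(droi.roi_levels())[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    energy = float(np.sum(x**2))
    return {
        "Energy": energy,
        "TotalEnergy": float(np.prod(volume.spacing)) * energy,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
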