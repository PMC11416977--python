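"""Full feature extraction: 9 images x 7 families = 851 named features.

Feature ids follow the ``<image>_<family>_<name>`` convention, with image
in {original, wavelet-LLL .. wavelet-HHH}.  Shape features are geometric
properties of the mask and appear only under the original image, giving

    18 x 9 first-order + 14 shape + 24 x 9 GLCM + 16 x 9 GLRLM
    + 16 x 9 GLSZM + 5 x 9 NGTDM + 14 x 9 GLDM  =  851.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..imaging import ImageVolume, RoiMask
from .discretize import discretize
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from .wavelet import WAVELET_KEYS, wavelet_decompose

__all__ = ["ExtractionConfig", "FAMILY_SIZES", "feature_manifest", "extract_all", "extract_cases"]

DEFAULT_IMAGES = ("original",) + tuple(f"wavelet-{k}" for k in WAVELET_KEYS)
DEFAULT_FAMILIES = ("shape", "firstorder", "glcm", "glrlm", "glszm", "ngtdm", "gldm")

_FAMILY_NAMES = {
    "shape": SHAPE_NAMES,
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}

FAMILY_SIZES = {fam: len(names) for fam, names in _FAMILY_NAMES.items()}


@dataclass(frozen=True)
class ExtractionConfig:
    """Which images and families to extract, and the discretization knobs.

    ``bin_width`` is the fixed gray-level bin width in HU (25 HU default,
    the common CT choice).  ``gldm_alpha`` is the dependence tolerance in
    gray levels.  ``window`` optionally clips intensities to a CT display
    window (level, width) before extraction; off by default so first-order
    statistics are computed on unsaturated HU.
    """

    images: tuple[str, ...] = DEFAULT_IMAGES
    families: tuple[str, ...] = DEFAULT_FAMILIES
    bin_width: float = 25.0
    wavelet: str = "coif1"
    gldm_alpha: int = 0
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for img in self.images:
            if img != "original" and not (
                img.startswith("wavelet-") and img[8:] in WAVELET_KEYS
            ):
                raise ValueError(f"unknown image key {img!r}")
        for fam in self.families:
            if fam not in _FAMILY_NAMES:
                raise ValueError(f"unknown feature family {fam!r}")


def feature_manifest(config: ExtractionConfig | None = None) -> list[str]:
    """The canonical ordered list of feature ids for a configuration."""
    cfg = config or ExtractionConfig()
    ids = []
    for img in cfg.images:
        for fam in cfg.families:
            if fam == "shape" and img != "original":
                continue
            for name in _FAMILY_NAMES[fam]:
                ids.append(f"{img}_{fam}_{name}")
    return ids


def extract_all(
    volume: ImageVolume, mask: RoiMask, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Extract every configured feature from one volume/mask pair.

    Returns an ordered mapping feature_id -> finite value following the
    manifest order; any non-finite result raises, naming the feature.
    """
    cfg = config or ExtractionConfig()
    data = volume.voxels
    if cfg.window is not None:
        level, width = cfg.window
        data = np.clip(data, level - width / 2.0, level + width / 2.0)

    bank = {"original": data}
    if any(img.startswith("wavelet-") for img in cfg.images):
        sub = wavelet_decompose(data, cfg.wavelet)
        bank.update({f"wavelet-{k}": v for k, v in sub.items()})

    out: dict[str, float] = {}
    for img in cfg.images:
        vol_img = ImageVolume(bank[img], volume.spacing, volume.origin)
        droi = None
        for fam in cfg.families:
            if fam == "shape":
                if img != "original":
                    continue
                vals = shape_features(mask)
            elif fam == "firstorder":
                vals = firstorder_features(vol_img, mask, cfg.bin_width)
            else:
                if droi is None:
                    droi = discretize(vol_img, mask, cfg.bin_width)
                if fam == "glcm":
                    vals = glcm_features(droi)
                elif fam == "glrlm":
                    vals = glrlm_features(droi)
                elif fam == "glszm":
                    vals = glszm_features(droi)
                elif fam == "ngtdm":
                    vals = ngtdm_features(droi)
                else:
                    vals = gldm_features(droi, cfg.gldm_alpha)
            for name in _FAMILY_NAMES[fam]:
                fid = f"{img}_{fam}_{name}"
                v = float(vals[name])
                if not np.isfinite(v):
                    raise ValueError(f"feature {fid} evaluated to a non-finite value")
                out[fid] = v
    return out


def extract_cases(cases, config: ExtractionConfig | None = None, margin: int = 3) -> pd.DataFrame:
    """Extract features for a list of cases (objects with volume/mask/case_id).

    Each case is cropped to its ROI bounding box plus ``margin`` voxels
    before extraction.  Returns a cases x features DataFrame indexed by
    case_id, columns in manifest order.
    """
    from ..imaging import crop_to_roi

    cfg = config or ExtractionConfig()
    rows = {}
    for case in cases:
        vol, msk = crop_to_roi(case.volume, case.mask, margin)
        rows[case.case_id] = extract_all(vol, msk, cfg)
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df[feature_manifest(cfg)]
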