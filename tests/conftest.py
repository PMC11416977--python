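"""Shared fixtures: tiny phantoms, discretized fuzz grids, small cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from timeradiomics.features.discretize import DiscretizedRoi
from timeradiomics.imaging import ImageVolume, RoiMask
from timeradiomics.phantom import PhantomSpec, generate_phantom


def make_droi(levels: np.ndarray, mask: np.ndarray | None = None) -> DiscretizedRoi:
    """Wrap an integer level grid (0 = outside ROI) as a DiscretizedRoi."""
    levels = np.asarray(levels, dtype=np.int64)
    if levels.ndim == 2:
        levels = levels[None]
    if levels.ndim == 1:
        levels = levels[None, None]
    if mask is None:
        mask = levels > 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim < 3:
            mask = mask.reshape(levels.shape)
    return DiscretizedRoi(levels=levels * mask, mask=mask,
                          bin_width=1.0, ng=int(levels.max()))


def make_volume(values, spacing=(1.0, 1.0, 1.0)) -> tuple[ImageVolume, RoiMask]:
    """Wrap an array as a volume with an all-foreground mask."""
    arr = np.asarray(values, dtype=float)
    while arr.ndim < 3:
        arr = arr[None]
    return ImageVolume(arr, spacing), RoiMask(np.ones(arr.shape, bool), spacing)


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic 32^3 phantom with default texture."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def fuzz_droi_suite():
    """Random discretized grids at <= 5x5x5 for oracle-equivalence fuzzing."""
    rng = np.random.default_rng(20240901)
    suite = []
    for shape in [(1, 1, 4), (1, 3, 3), (2, 3, 4), (4, 4, 4), (5, 5, 5)]:
        for ng in (1, 2, 4):
            levels = rng.integers(1, ng + 1, size=shape)
            mask = rng.random(shape) < 0.8
            if mask.sum() < 2:
                mask.flat[:2] = True
            suite.append(make_droi(levels, mask=mask))
    # plus fully dense grids
    for shape in [(3, 3, 3), (5, 4, 3)]:
        levels = rng.integers(1, 5, size=shape)
        suite.append(make_droi(levels))
    return suite
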