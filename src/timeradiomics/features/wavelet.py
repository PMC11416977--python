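"""Single-level undecimated 3-D wavelet filter bank.

The decomposition applies the decomposition low-pass (L) / high-pass (H)
filter of a discrete wavelet separably along each axis, with symmetric
boundary extension and no downsampling, producing eight sub-bands with the
same grid shape as the input.  Keys are three-letter strings whose letters
apply to the array axes in (z, y, x) order, e.g. ``HLL`` = high-pass along
z, low-pass along y and x.

The default wavelet is Coiflet-1, the convention of the CT radiomics
toolchain whose feature set this package reproduces.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pywt
from scipy import ndimage

from ..imaging import ImageVolume

__all__ = ["WAVELET_KEYS", "wavelet_decompose", "wavelet_kernel"]

WAVELET_KEYS = tuple("".join(p) for p in product("LH", repeat=3))
# ('LLL', 'LLH', 'LHL', 'LHH', 'HLL', 'HLH', 'HHL', 'HHH')


def _filters(wavelet: str) -> dict[str, np.ndarray]:
    w = pywt.Wavelet(wavelet)
    return {"L": np.asarray(w.dec_lo), "H": np.asarray(w.dec_hi)}


def wavelet_kernel(key: str, wavelet: str = "coif1") -> np.ndarray:
    """The separable 3-D impulse-response kernel of one sub-band.

    The kernel is the tensor product of the per-axis filters, each flipped
    to convolution orientation (the transform correlates the signal with
    the decomposition filter).
    """
    filt = _filters(wavelet)
    k = np.ones((1, 1, 1))
    for axis, letter in enumerate(key):
        shape = [1, 1, 1]
        f = filt[letter][::-1]
        shape[axis] = len(f)
        k = k * f.reshape(shape)
    return k


def wavelet_decompose(
    volume: ImageVolume | np.ndarray, wavelet: str = "coif1"
) -> dict[str, np.ndarray]:
    """Decompose a volume into the eight stationary wavelet sub-bands.

    Returns a dict keyed ``LLL`` .. ``HHH``; every sub-band has the input's
    grid shape.  Symmetric (half-sample mirror) boundary extension is used.
    """
    data = volume.voxels if isinstance(volume, ImageVolume) else np.asarray(volume, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    filt = _filters(wavelet)
    flen = len(filt["L"])
    for axis, n in enumerate(data.shape):
        if n < flen:
            raise ValueError(
                f"axis {axis} has length {n}, shorter than the {wavelet} "
                f"filter length {flen}; cannot decompose a degenerate axis"
            )
    # pass 0: filter along z with L and H, then fan out along y and x
    partial = {"": data}
    for axis in range(3):
        nxt: dict[str, np.ndarray] = {}
        for key, arr in partial.items():
            for letter in "LH":
                nxt[key + letter] = ndimage.correlate1d(
                    arr, filt[letter], axis=axis, mode="reflect"
                )
        partial = nxt
    return {k: partial[k] for k in WAVELET_KEYS}
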