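"""Image volumes, ROI masks, CT windowing and ROI cropping.

Volumes are 3-D scalar grids in Hounsfield units (HU) stored in ``(z, y, x)``
index order with per-axis voxel spacing in millimetres.  Masks are binary
grids aligned voxel-for-voxel with their volume.  NIfTI is the on-disk
format; a DICOM series can optionally be ingested read-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "RoiMask",
    "AlignmentError",
    "EmptyRoiError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_dicom_series",
    "apply_window",
    "crop_to_roi",
]


class AlignmentError(ValueError):
    """Raised when a mask grid does not align with its volume grid."""


class EmptyRoiError(ValueError):
    """Raised when an operation requires at least one foreground voxel."""


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D HU image with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Scalar intensities in HU; must be finite.
    spacing : tuple of float
        Voxel edge length in mm per array axis ``(z, y, x)``.
    origin : tuple of float
        Physical offset of voxel (0, 0, 0) in mm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float64)
        if vox.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("volume contains non-finite voxel values")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class RoiMask:
    """A binary tumor mask aligned with an :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {vox.shape}")
        object.__setattr__(self, "voxels", vox != 0)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())


def _affine(spacing: tuple[float, float, float], origin: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI (.nii or .nii.gz)."""
    img = nib.Nifti1Image(volume.voxels.astype(np.float64), _affine(volume.spacing, volume.origin))
    nib.save(img, str(path))


def read_volume(path) -> ImageVolume:
    """Read a NIfTI volume, preserving spacing and origin metadata."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    aff = img.affine
    spacing = tuple(float(abs(aff[i, i])) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return ImageVolume(data, spacing, origin)


def write_mask(mask: RoiMask, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing, (0.0, 0.0, 0.0)))
    nib.save(img, str(path))


def read_mask(path, volume: ImageVolume) -> RoiMask:
    """Read a mask and check alignment with ``volume``.

    Any nonzero label is treated as foreground.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.shape != volume.shape:
        raise AlignmentError(
            f"mask grid {data.shape} does not match volume grid {volume.shape}"
        )
    spacing = tuple(float(abs(img.affine[i, i])) for i in range(3))
    if not np.allclose(spacing, volume.spacing, rtol=1e-4):
        raise AlignmentError(
            f"mask spacing {spacing} does not match volume spacing {volume.spacing}"
        )
    return RoiMask(data != 0, volume.spacing)


def read_dicom_series(directory) -> ImageVolume:
    """Ingest a DICOM series directory (read-only) as an ImageVolume.

    Requires SimpleITK.  Axes are reordered to the package's (z, y, x)
    convention.
    """
    import SimpleITK as sitk  # deferred: optional dependency

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise FileNotFoundError(f"no DICOM series found under {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    data = sitk.GetArrayFromImage(img)  # already (z, y, x)
    sx, sy, sz = img.GetSpacing()
    ox, oy, oz = img.GetOrigin()
    return ImageVolume(np.asarray(data, dtype=np.float64), (sz, sy, sx), (oz, oy, ox))


def apply_window(volume: ImageVolume, level: float, width: float) -> ImageVolume:
    """Clip intensities to a CT display window.

    ``level`` is the window centre and ``width`` the full window width, both
    in HU; voxels are clipped to ``[level - width/2, level + width/2]``.  The
    mediastinal window used for tumor delineation in this pipeline is level
    50 HU, width 2000 HU, i.e. bounds [-950, 1050].
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    lo, hi = level - width / 2.0, level + width / 2.0
    return ImageVolume(np.clip(volume.voxels, lo, hi), volume.spacing, volume.origin)


def crop_to_roi(
    volume: ImageVolume, mask: RoiMask, margin_voxels: int = 0
) -> tuple[ImageVolume, RoiMask]:
    """Crop volume and mask to the mask's bounding box plus a voxel margin.

    The margin is clipped at the grid borders; the number of foreground
    voxels is preserved exactly.
    """
    if mask.shape != volume.shape:
        raise AlignmentError(
            f"mask grid {mask.shape} does not match volume grid {volume.shape}"
        )
    if mask.n_foreground == 0:
        raise EmptyRoiError("cannot crop to an empty ROI")
    slices = []
    for axis in range(3):
        proj = np.any(mask.voxels, axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        lo = max(int(idx[0]) - margin_voxels, 0)
        hi = min(int(idx[-1]) + margin_voxels + 1, mask.shape[axis])
        slices.append(slice(lo, hi))
    slices = tuple(slices)
    new_origin = tuple(
        volume.origin[a] + slices[a].start * volume.spacing[a] for a in range(3)
    )
    return (
        ImageVolume(volume.voxels[slices], volume.spacing, new_origin),
        RoiMask(mask.voxels[slices], mask.spacing),
    )
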