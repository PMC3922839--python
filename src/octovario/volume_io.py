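"""Reading, writing, and canonicalizing 3D intensity volumes.

The analysis downstream (octree decomposition, variogram estimation) assumes an
isotropic cube whose edge length is a power of two, with non-lung voxels set to
a background sentinel.  This module provides the :class:`VolumeImage` container
and the I/O needed to get arbitrary 3D scans into that canonical form.

Supported formats: NIfTI-1 (``.nii``/``.nii.gz``), MetaImage (``.mha``/``.mhd``)
and multi-page TIFF stacks.  DICOM series and resampling are out of scope;
anisotropic inputs are rejected rather than silently resampled, because
resampling would change every pair distance entering the variogram.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import DimensionalityError, ShapeError, SpacingError, VolumeIOError

__all__ = ["VolumeImage", "read_volume", "write_volume", "pad_to_cube"]

#: relative tolerance when deciding whether header spacing is isotropic
_ISO_RTOL = 0.01


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with isotropic voxel spacing.

    Parameters
    ----------
    data
        3D array of intensities; Hounsfield Units for CT.  Stored as float32.
    voxel_size_mm
        Isotropic voxel edge length in millimetres (e.g. 0.150 for a 150 um
        micro-CT reconstruction).
    background_value
        Sentinel carried by non-lung voxels.  Defaults to 0, the convention
        for masked CT; configurable because genuine tissue at exactly 0 HU
        would otherwise be indistinguishable from background.
    """

    data: np.ndarray
    voxel_size_mm: float = 1.0
    background_value: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if any(s < 1 for s in self.data.shape):
            raise ShapeError(f"degenerate volume shape {self.data.shape}")
        if not self.voxel_size_mm > 0:
            raise SpacingError(f"voxel_size_mm must be > 0, got {self.voxel_size_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def background_mask(self) -> np.ndarray:
        """Boolean grid, True where the voxel carries the background sentinel."""
        return self.data == self.background_value

    def foreground(self) -> np.ndarray:
        """1D array of all non-background intensities."""
        return self.data[self.data != self.background_value]

    def copy(self) -> "VolumeImage":
        return replace(self, data=self.data.copy())


def _sniff_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    raise VolumeIOError(f"cannot infer volume format from file name {path.name!r}")


def _check_isotropic(spacing: np.ndarray) -> float:
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise SpacingError(f"non-positive voxel spacing {tuple(spacing)}")
    mean = float(spacing.mean())
    if np.any(np.abs(spacing - mean) > _ISO_RTOL * mean):
        raise SpacingError(
            f"anisotropic voxel spacing {tuple(spacing)} exceeds "
            f"{100 * _ISO_RTOL:.0f}% tolerance; resample upstream"
        )
    return mean


def read_volume(
    path: str | os.PathLike,
    format: str = "auto",
    voxel_size_mm: float | None = None,
    background_value: float = 0.0,
) -> VolumeImage:
    """Read a 3D scalar volume from disk.

    ``voxel_size_mm`` overrides the header spacing and is required for TIFF
    stacks, which carry no reliable 3D spacing.  Anisotropic header spacing
    (beyond 1%) raises :class:`~octovario.errors.SpacingError`.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    if format == "auto":
        format = _sniff_format(path)

    if format == "nifti":
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:  # pragma: no cover - nibabel error variety
            raise VolumeIOError(f"failed to read NIfTI {path}: {exc}") from exc
        data = np.asanyarray(img.dataobj)
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    elif format == "metaimage":
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:
            raise VolumeIOError(f"failed to read MetaImage {path}: {exc}") from exc
        # SimpleITK arrays come back (z, y, x); transpose to (x, y, z)
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = np.asarray(img.GetSpacing(), dtype=float)
    elif format == "tiff_stack":
        import tifffile

        try:
            data = tifffile.imread(str(path))
        except Exception as exc:
            raise VolumeIOError(f"failed to read TIFF {path}: {exc}") from exc
        data = np.asarray(data)
        if data.ndim != 3:
            raise DimensionalityError(
                f"TIFF stack has {data.ndim} dimensions, expected 3"
            )
        data = data.transpose(2, 1, 0)  # pages are the slowest axis
        spacing = None
    else:
        raise VolumeIOError(f"unknown format {format!r}")

    data = np.asarray(data)
    if data.ndim != 3:
        raise DimensionalityError(f"{path} holds {data.ndim}D data, expected 3D")

    if voxel_size_mm is not None:
        size = float(voxel_size_mm)
        if size <= 0:
            raise SpacingError(f"voxel_size_mm must be > 0, got {size}")
    elif spacing is not None:
        size = _check_isotropic(spacing)
    else:
        raise SpacingError(
            f"{path} carries no voxel spacing; pass voxel_size_mm explicitly"
        )
    return VolumeImage(data, voxel_size_mm=size, background_value=background_value)


def write_volume(vol: VolumeImage, path: str | os.PathLike, format: str = "auto") -> None:
    """Write a volume to disk; ``read_volume`` of the result round-trips the
    voxel payload bit-exactly and the spacing to float precision."""
    path = Path(path)
    if format == "auto":
        format = _sniff_format(path)

    try:
        if format == "nifti":
            import nibabel as nib

            affine = np.diag([vol.voxel_size_mm] * 3 + [1.0])
            img = nib.Nifti1Image(vol.data, affine)
            img.header.set_zooms((vol.voxel_size_mm,) * 3)
            nib.save(img, str(path))
        elif format == "metaimage":
            import SimpleITK as sitk

            img = sitk.GetImageFromArray(vol.data.transpose(2, 1, 0))
            img.SetSpacing((vol.voxel_size_mm,) * 3)
            sitk.WriteImage(img, str(path))
        elif format == "tiff_stack":
            import tifffile

            tifffile.imwrite(
                str(path), vol.data.transpose(2, 1, 0), photometric="minisblack"
            )
        else:
            raise VolumeIOError(f"unknown format {format!r}")
    except OSError as exc:
        raise VolumeIOError(f"failed to write {path}: {exc}") from exc


def _next_power_of_two(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


def pad_to_cube(vol: VolumeImage) -> VolumeImage:
    """Zero-fill a volume to a power-of-two cube.

    The target edge is the smallest power of two not below the largest input
    dimension (a 400 x 380 x 512 scan becomes 512 cubed).  Original data sits
    at the low-index corner; added voxels carry the background sentinel.
    Corner placement is a convention, not a requirement: the variogram is
    invariant under whole-unit-block translations, so the offset does not
    matter as long as it is reproducible.
    """
    edge = _next_power_of_two(max(vol.shape))
    if vol.shape == (edge, edge, edge):
        return vol
    out = np.full((edge, edge, edge), vol.background_value, dtype=np.float32)
    sx, sy, sz = vol.shape
    out[:sx, :sy, :sz] = vol.data
    return VolumeImage(out, vol.voxel_size_mm, vol.background_value)
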