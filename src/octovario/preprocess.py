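"""Lung masking, noise filtering, and the geometric transforms used in
robustness testing.

The preparation chain for a CT scan is: grow a connected-threshold region from
a user-picked seed inside the lung, smooth the mask by morphological closing,
apply it (non-lung voxels -> background sentinel), median-filter, then pad to
a power-of-two cube.  The transforms (translate / rotate / downsample) exist
so that the insensitivity of the final variogram to patient positioning and to
resolution reduction can be demonstrated on any input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError, SeedError, ShapeError
from .volume_io import VolumeImage

__all__ = [
    "BinaryMask",
    "connected_threshold_mask",
    "smooth_mask",
    "apply_mask",
    "filter_volume",
    "transform_volume",
    "translate_volume",
    "rotate_volume",
    "downsample_volume",
]


@dataclass
class BinaryMask:
    """A boolean lung mask tied to the volume it was grown from."""

    data: np.ndarray
    seed: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ShapeError(f"mask must be 3D, got {self.data.ndim}D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_count(self) -> int:
        return int(self.data.sum())


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ParameterError(f"connectivity must be 6 or 26, got {connectivity}")


def connected_threshold_mask(
    vol: VolumeImage,
    seed: tuple[int, int, int],
    lower: float,
    upper: float,
    connectivity: int = 6,
) -> BinaryMask:
    """Region-grow the connected component of {lower <= I <= upper} containing
    ``seed``.

    The HU window is chosen per image to exclude major vasculature and all
    external tissue; it is deliberately an explicit parameter rather than an
    automatic estimate.
    """
    seed = tuple(int(c) for c in seed)  # type: ignore[assignment]
    if len(seed) != 3:
        raise SeedError(f"seed must be a voxel triple, got {seed}")
    if any(c < 0 or c >= s for c, s in zip(seed, vol.shape)):
        raise SeedError(f"seed {seed} outside volume of shape {vol.shape}")
    value = float(vol.data[seed])
    if not (lower <= value <= upper):
        raise SeedError(
            f"seed intensity {value} outside threshold window [{lower}, {upper}]"
        )
    in_window = (vol.data >= lower) & (vol.data <= upper)
    labels, _ = ndimage.label(in_window, structure=_connectivity_structure(connectivity))
    return BinaryMask(labels == labels[seed], seed=seed)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    zyx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (zyx**2).sum(axis=0) <= r * r


def smooth_mask(mask: BinaryMask, radius: int = 2) -> BinaryMask:
    """Morphological closing (dilate then erode) with a digital ball.

    Closing is extensive: the output always contains the input, and interior
    holes or notches up to the structuring-element scale are filled.
    """
    if radius < 1:
        raise ParameterError(f"smoothing radius must be >= 1, got {radius}")
    r = int(radius)
    ball = _ball(r)
    # pad by the radius so the closing is computed on an unbounded canvas;
    # otherwise mask regions touching the array edge erode incorrectly
    padded = np.pad(mask.data, r, mode="constant", constant_values=False)
    dilated = ndimage.binary_dilation(padded, structure=ball)
    closed = ndimage.binary_erosion(dilated, structure=ball)
    closed = closed[r:-r, r:-r, r:-r]
    return BinaryMask(closed | mask.data, seed=mask.seed)


def apply_mask(vol: VolumeImage, mask: BinaryMask) -> VolumeImage:
    """Set every voxel outside the mask to the background sentinel."""
    if mask.shape != vol.shape:
        raise ShapeError(f"mask shape {mask.shape} != volume shape {vol.shape}")
    data = np.where(mask.data, vol.data, np.float32(vol.background_value))
    return VolumeImage(data, vol.voxel_size_mm, vol.background_value)


def _median_footprint(diameter: float) -> np.ndarray:
    # digital ball of the stated diameter: offsets with Euclidean norm <= d/2
    r = int(np.floor(diameter / 2.0))
    zyx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (zyx**2).sum(axis=0) <= (diameter / 2.0) ** 2


def filter_volume(vol: VolumeImage, method: str = "median", param: float = 5) -> VolumeImage:
    """Noise-reduce a volume.

    ``median`` uses a spherical neighborhood of the given *diameter* in voxels
    (default 5, i.e. offsets within Euclidean radius 2.5) — an edge-preserving
    filter suited to CT speckle.  ``gaussian`` interprets ``param`` as the
    kernel standard deviation in voxels (the "radius" convention of the usual
    image toolkits).  ``none`` is the identity.
    """
    if method == "none":
        return vol.copy()
    if param <= 0:
        raise ParameterError(f"filter parameter must be > 0, got {param}")
    if method == "median":
        out = ndimage.median_filter(vol.data, footprint=_median_footprint(param))
    elif method == "gaussian":
        out = ndimage.gaussian_filter(vol.data, sigma=float(param)).astype(np.float32)
    else:
        raise ParameterError(f"unknown filter method {method!r}")
    return VolumeImage(out, vol.voxel_size_mm, vol.background_value)


def translate_volume(vol: VolumeImage, shift: tuple[int, int, int]) -> VolumeImage:
    """Shift volume content by an integer voxel triple, filling exposed space
    with the background sentinel.  Content pushed past the far edge is lost
    (no circular wrap)."""
    shift = tuple(shift)  # type: ignore[assignment]
    if len(shift) != 3 or any(s != int(s) for s in shift):
        raise ParameterError(f"translation must be an integer triple, got {shift}")
    shift = tuple(int(s) for s in shift)  # type: ignore[assignment]
    out = np.full_like(vol.data, vol.background_value)
    src = []
    dst = []
    for s, n in zip(shift, vol.shape):
        src.append(slice(max(0, -s), min(n, n - s)))
        dst.append(slice(max(0, s), min(n, n + s)))
    out[tuple(dst)] = vol.data[tuple(src)]
    return VolumeImage(out, vol.voxel_size_mm, vol.background_value)


def rotate_volume(vol: VolumeImage, angles_rad: tuple[float, float, float]) -> VolumeImage:
    """Rotate about the x, then y, then z axis through the volume center,
    with trilinear interpolation and background fill."""
    if len(angles_rad) != 3:
        raise ParameterError("rotation needs three angles (about x, y, z)")
    data = vol.data
    planes = [(1, 2), (0, 2), (0, 1)]  # rotation planes for the x, y, z axes
    for angle, axes in zip(angles_rad, planes):
        if angle == 0:
            continue
        data = ndimage.rotate(
            data,
            np.degrees(angle),
            axes=axes,
            reshape=False,
            order=1,
            mode="constant",
            cval=vol.background_value,
        )
    return VolumeImage(data, vol.voxel_size_mm, vol.background_value)


def downsample_volume(vol: VolumeImage, factor: int) -> VolumeImage:
    """Reduce resolution by averaging each factor^3 block (trilinear
    reduction); a 512-cube at factor 8 becomes a 64-cube whose voxels match
    the size of an 8x8x8 octree box."""
    factor = int(factor)
    if factor < 1:
        raise ParameterError(f"downsampling factor must be >= 1, got {factor}")
    if any(s % factor for s in vol.shape):
        raise ParameterError(
            f"factor {factor} does not divide volume shape {vol.shape}"
        )
    sx, sy, sz = (s // factor for s in vol.shape)
    blocks = vol.data.reshape(sx, factor, sy, factor, sz, factor)
    out = blocks.mean(axis=(1, 3, 5), dtype=np.float64).astype(np.float32)
    return VolumeImage(out, vol.voxel_size_mm * factor, vol.background_value)


def transform_volume(vol: VolumeImage, kind: str, params) -> VolumeImage:
    """Dispatch to :func:`translate_volume`, :func:`rotate_volume`, or
    :func:`downsample_volume`."""
    if kind == "translate":
        return translate_volume(vol, params)
    if kind == "rotate":
        return rotate_volume(vol, params)
    if kind == "downsample":
        return downsample_volume(vol, params)
    raise ParameterError(f"unknown transform kind {kind!r}")
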