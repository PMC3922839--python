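"""Octree decomposition of a power-of-two CT cube into homogeneous blocks.

A region is subdivided into its eight octants whenever its intensity standard
deviation exceeds a user-set threshold (in HU), or it contains a mixture of
background and lung voxels.  Subdivision stops at a minimum edge (default
2 voxels).  The surviving leaves therefore tile the cube with regions that are
each either (a) homogeneous lung at the threshold scale, (b) pure background,
or (c) minimum-size mixed blocks tracing boundaries, vessels and airways.

For the variogram stage only the larger leaves matter: every leaf at or above
the unit edge (default 8) is reduced to unit-size "super-voxels" carrying the
local mean HU, and the small boundary-tracing leaves are dropped.  This is
what lets spatial variance be estimated over parenchyma alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ParameterError, ShapeError
from .volume_io import VolumeImage

__all__ = [
    "OctreeBlock",
    "OctreeDecomposition",
    "UnitBlock",
    "UnitBlockSet",
    "decompose",
    "select_unit_blocks",
    "octree_histogram",
]


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class OctreeBlock:
    """One leaf of the decomposition, with its intensity statistics."""

    origin: tuple[int, int, int]
    size: int
    min: float
    max: float
    mean: float
    std: float
    n_background: int

    @property
    def all_background(self) -> bool:
        return self.n_background == self.size**3

    @property
    def contains_background(self) -> bool:
        return self.n_background > 0


@dataclass
class OctreeDecomposition:
    """The complete leaf set of an octree decomposition.

    Leaves are stored column-wise in numpy arrays; use :meth:`to_frame` for a
    tabular view or :meth:`blocks` to iterate :class:`OctreeBlock` objects.
    The leaves are disjoint and tile the source cube exactly, so
    ``sum(size**3) == prod(source_dims)`` always holds.
    """

    origins: np.ndarray  # (n, 3) int
    sizes: np.ndarray  # (n,) int
    mins: np.ndarray
    maxs: np.ndarray
    means: np.ndarray
    stds: np.ndarray
    n_background: np.ndarray  # (n,) int
    threshold_hu: float
    min_size: int
    source_dims: tuple[int, int, int]
    background_value: float = 0.0

    @property
    def n_blocks(self) -> int:
        return int(self.sizes.size)

    @property
    def all_background(self) -> np.ndarray:
        return self.n_background == self.sizes.astype(np.int64) ** 3

    @property
    def contains_background(self) -> np.ndarray:
        return self.n_background > 0

    def size_counts(self) -> dict[int, int]:
        """Number of leaves of each edge length (boundary/vessel load shows
        up as many small blocks; parenchyma as 8s and 16s)."""
        sizes, counts = np.unique(self.sizes, return_counts=True)
        return {int(s): int(c) for s, c in zip(sizes, counts)}

    def blocks(self) -> Iterator[OctreeBlock]:
        for i in range(self.n_blocks):
            yield OctreeBlock(
                origin=tuple(int(c) for c in self.origins[i]),
                size=int(self.sizes[i]),
                min=float(self.mins[i]),
                max=float(self.maxs[i]),
                mean=float(self.means[i]),
                std=float(self.stds[i]),
                n_background=int(self.n_background[i]),
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "origin_x": self.origins[:, 0],
                "origin_y": self.origins[:, 1],
                "origin_z": self.origins[:, 2],
                "size": self.sizes,
                "min": self.mins,
                "max": self.maxs,
                "mean": self.means,
                "std": self.stds,
                "n_background": self.n_background,
            }
        )


def decompose(
    vol: VolumeImage, threshold_hu: float = 40.0, min_size: int = 2
) -> OctreeDecomposition:
    """Decompose a power-of-two cube into homogeneous octree leaves.

    Starting from the full cube, a region splits into its eight octants iff
    its (population) standard deviation exceeds ``threshold_hu`` or it holds
    some but not all background voxels; regions of edge ``min_size`` never
    split.  Statistics are computed over all voxels of a region, background
    included — the mixed-background rule forces such regions apart above
    ``min_size``, so only min-size boundary blocks are affected, and those
    never enter the variogram.
    """
    n = vol.shape[0]
    if vol.shape != (n, n, n) or not _is_power_of_two(n):
        raise ShapeError(f"decompose needs a power-of-two cube, got {vol.shape}")
    if not threshold_hu > 0:
        raise ParameterError(f"threshold_hu must be > 0, got {threshold_hu}")
    if not (_is_power_of_two(min_size) and min_size >= 2):
        raise ParameterError(f"min_size must be a power of two >= 2, got {min_size}")
    if min_size > n:
        raise ParameterError(f"min_size {min_size} exceeds cube edge {n}")

    data = vol.data
    bg = np.float32(vol.background_value)

    origins: list[np.ndarray] = []
    sizes: list[np.ndarray] = []
    mins: list[np.ndarray] = []
    maxs: list[np.ndarray] = []
    means: list[np.ndarray] = []
    stds: list[np.ndarray] = []
    nbgs: list[np.ndarray] = []

    size = n
    # boolean grid over the (n/size)^3 blocks of the current level
    active = np.ones((1, 1, 1), dtype=bool)
    while True:
        nb = n // size
        view = data.reshape(nb, size, nb, size, nb, size).transpose(0, 2, 4, 1, 3, 5)
        bi, bj, bk = np.nonzero(active)
        vox = view[bi, bj, bk].reshape(len(bi), -1)  # gather active blocks only
        blk_mean = vox.mean(axis=1, dtype=np.float64)
        blk_std = vox.std(axis=1, dtype=np.float64)  # population form (ddof=0)
        blk_min = vox.min(axis=1).astype(np.float64)
        blk_max = vox.max(axis=1).astype(np.float64)
        blk_nbg = (vox == bg).sum(axis=1)
        total = size**3

        mixed = (blk_nbg > 0) & (blk_nbg < total)
        homogeneous = (blk_std <= threshold_hu) & ~mixed
        is_leaf = homogeneous if size > min_size else np.ones_like(homogeneous)

        origins.append(np.column_stack([bi, bj, bk])[is_leaf] * size)
        sizes.append(np.full(int(is_leaf.sum()), size, dtype=np.int64))
        mins.append(blk_min[is_leaf])
        maxs.append(blk_max[is_leaf])
        means.append(blk_mean[is_leaf])
        stds.append(blk_std[is_leaf])
        nbgs.append(blk_nbg[is_leaf].astype(np.int64))

        if size <= min_size:
            break
        split = np.zeros((nb, nb, nb), dtype=bool)
        split[bi[~is_leaf], bj[~is_leaf], bk[~is_leaf]] = True
        if not split.any():
            break
        active = (
            split.repeat(2, axis=0).repeat(2, axis=1).repeat(2, axis=2)
        )
        size //= 2

    return OctreeDecomposition(
        origins=np.concatenate(origins, axis=0),
        sizes=np.concatenate(sizes),
        mins=np.concatenate(mins),
        maxs=np.concatenate(maxs),
        means=np.concatenate(means),
        stds=np.concatenate(stds),
        n_background=np.concatenate(nbgs),
        threshold_hu=float(threshold_hu),
        min_size=int(min_size),
        source_dims=vol.shape,
        background_value=float(vol.background_value),
    )


@dataclass(frozen=True)
class UnitBlock:
    """A unit-size homogeneous block: the variogram's super-voxel."""

    centroid: tuple[float, float, float]
    mean_hu: float
    source_size: int


@dataclass
class UnitBlockSet:
    """Vectorized collection of unit blocks, sorted by centroid.

    ``centroids`` are voxel coordinates of block centers (for 8-cubes these
    sit at origin + 3.5 on each axis, on an 8-spaced lattice); ``mean_hu`` is
    the per-block mean intensity; ``source_size`` records the edge of the
    octree leaf each unit block came from.
    """

    centroids: np.ndarray  # (k, 3) float64
    mean_hu: np.ndarray  # (k,) float64
    source_size: np.ndarray  # (k,) int
    unit: int = 8

    def __len__(self) -> int:
        return int(self.mean_hu.size)

    def __iter__(self) -> Iterator[UnitBlock]:
        for i in range(len(self)):
            yield UnitBlock(
                centroid=tuple(float(c) for c in self.centroids[i]),
                mean_hu=float(self.mean_hu[i]),
                source_size=int(self.source_size[i]),
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "centroid_x": self.centroids[:, 0],
                "centroid_y": self.centroids[:, 1],
                "centroid_z": self.centroids[:, 2],
                "mean_hu": self.mean_hu,
                "source_size": self.source_size,
            }
        )


def select_unit_blocks(
    decomp: OctreeDecomposition, vol: VolumeImage, unit: int = 8
) -> UnitBlockSet:
    """Reduce a decomposition to background-free, homogeneous unit blocks.

    Every unit-size cell covered by a leaf of edge >= ``unit`` is a candidate:
    leaves of the unit edge contribute themselves, larger leaves are cut into
    unit-size sub-cells.  Each candidate's statistics are recomputed from the
    voxel data through a single code path, and a cell is retained only if it
    is background-free and its standard deviation is within the
    decomposition threshold — the same homogeneity test the octree applies.
    Testing every cell individually (rather than trusting the parent leaf)
    makes the selection a purely local function of the 8-aligned cell
    contents, which is what guarantees that translating a volume by whole
    unit blocks leaves the variogram bit-identical.  Leaves smaller than the
    unit — the vessel/boundary tracers — are dropped.  The result is sorted
    by centroid so identical block sets always enumerate identically.
    """
    if not (_is_power_of_two(unit) and unit >= 2):
        raise ParameterError(f"unit must be a power of two >= 2, got {unit}")
    n = vol.shape[0]
    if vol.shape != (n, n, n) or n % unit:
        raise ShapeError(f"volume shape {vol.shape} incompatible with unit {unit}")

    # origins of all candidate unit cells, in units of `unit`
    cells: list[np.ndarray] = []
    eligible = np.nonzero(decomp.sizes >= unit)[0]
    for i in eligible:
        s = int(decomp.sizes[i])
        o = decomp.origins[i] // unit
        m = s // unit
        if m == 1:
            cells.append(o.reshape(1, 3))
        else:
            gx, gy, gz = np.meshgrid(*([np.arange(m)] * 3), indexing="ij")
            cells.append(
                np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + o
            )
    if not cells:
        return UnitBlockSet(
            centroids=np.empty((0, 3)),
            mean_hu=np.empty(0),
            source_size=np.empty(0, dtype=np.int64),
            unit=unit,
        )
    cell_idx = np.concatenate(cells, axis=0)
    src = np.concatenate(
        [
            np.full(len(c), int(decomp.sizes[i]), dtype=np.int64)
            for c, i in zip(cells, eligible)
        ]
    )

    nb = n // unit
    view = vol.data.reshape(nb, unit, nb, unit, nb, unit).transpose(0, 2, 4, 1, 3, 5)
    vox = view[cell_idx[:, 0], cell_idx[:, 1], cell_idx[:, 2]].reshape(len(cell_idx), -1)
    means = vox.mean(axis=1, dtype=np.float64)
    stds = vox.std(axis=1, dtype=np.float64)
    n_bg = (vox == np.float32(decomp.background_value)).sum(axis=1)

    keep = (n_bg == 0) & (stds <= decomp.threshold_hu)
    centroids = cell_idx[keep].astype(np.float64) * unit + (unit - 1) / 2.0
    mean_hu = means[keep]
    source_size = src[keep]
    order = np.lexsort((centroids[:, 2], centroids[:, 1], centroids[:, 0]))
    return UnitBlockSet(
        centroids=centroids[order],
        mean_hu=mean_hu[order],
        source_size=source_size[order],
        unit=unit,
    )


def octree_histogram(
    decomp: OctreeDecomposition, bin_width_hu: float = 10.0
) -> pd.DataFrame:
    """Tabulate percent of lung volume per (box size, HU bin) cell.

    Only background-free leaves are counted.  Each leaf contributes its voxel
    count to the bin holding its mean HU; values are percentages of the total
    retained lung volume, so all cells sum to 100.  Rows are box sizes,
    columns are the left edges of the HU bins.
    """
    if not bin_width_hu > 0:
        raise ParameterError(f"bin_width_hu must be > 0, got {bin_width_hu}")
    keep = decomp.n_background == 0
    if not keep.any():
        return pd.DataFrame()
    sizes = decomp.sizes[keep]
    means = decomp.means[keep]
    voxels = sizes.astype(np.float64) ** 3
    bins = np.floor(means / bin_width_hu) * bin_width_hu
    frame = pd.DataFrame({"size": sizes, "hu_bin": bins, "voxels": voxels})
    table = frame.pivot_table(
        index="size", columns="hu_bin", values="voxels", aggfunc="sum", fill_value=0.0
    )
    return table * (100.0 / voxels.sum())
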