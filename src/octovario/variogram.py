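"""Empirical semi-variogram estimation over unit-block centroids.

The semi-variance at separation d is

    gamma(d) = 1 / (2 N(d)) * sum over the N(d) pairs at distance d of
               (I_i - I_j)^2

where I is the block mean intensity and distances are straight-line
(Euclidean) separations of block centroids.  With n blocks the total pair
count over all distances is n (n - 1) / 2.  Because unit blocks sit on an
8-spaced lattice, the attainable distances are exactly 8 * sqrt(i^2+j^2+k^2)
for integer triples, and pairs are grouped by exact distance value (rounded
to 6 decimals to absorb floating-point noise) rather than binned.

The variogram is only considered reliable out to d_max — half the diameter of
the largest approximately-independent region (for rat lungs, half the left
lobe, about 8 mm).  Beyond that, lobar independence and holes in the lung
geometry make the distance-variance relationship essentially random, so all
downstream statistics use the d <= d_max part; the full curve is retained for
diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .errors import AlignmentError, InsufficientDataError, ParameterError
from .octree import UnitBlockSet

__all__ = [
    "Variogram",
    "PowerLawFit",
    "pair_count",
    "empirical_variogram",
    "dmax_pixels",
    "average_variograms",
    "common_grid",
    "fit_power_law",
    "plot_variogram",
]

#: decimals used when grouping centroid distances
_DIST_DECIMALS = 6


@dataclass
class Variogram:
    """Per-distance pair counts and average semi-variance, truncated at d_max.

    ``distances``/``gamma``/``pair_counts`` cover d <= d_max; the ``full_*``
    arrays keep the untruncated curve so that ``full_pair_counts.sum()``
    equals ``pair_count(n_blocks)`` exactly.
    """

    distances: np.ndarray  # voxel units, strictly increasing
    gamma: np.ndarray  # HU^2
    pair_counts: np.ndarray
    d_max_vox: float
    n_blocks: int
    voxel_size_mm: float = 1.0
    full_distances: np.ndarray | None = None
    full_gamma: np.ndarray | None = None
    full_pair_counts: np.ndarray | None = None

    @property
    def distances_mm(self) -> np.ndarray:
        return self.distances * self.voxel_size_mm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_vox": self.distances,
                "distance_mm": self.distances_mm,
                "gamma_hu2": self.gamma,
                "n_pairs": self.pair_counts,
            }
        )

    def restrict(self, distances: np.ndarray) -> "Variogram":
        """Return a copy keeping only the given distance values (which must
        all be present); used to put several variograms on a common grid."""
        distances = np.asarray(distances, dtype=float)
        idx = np.searchsorted(self.distances, distances)
        idx_safe = np.minimum(idx, max(self.distances.size - 1, 0))
        if distances.size and (
            self.distances.size == 0
            or np.any(idx >= self.distances.size)
            or not np.allclose(self.distances[idx_safe], distances)
        ):
            raise AlignmentError("requested distances not all present in variogram")
        idx = idx_safe
        return Variogram(
            distances=self.distances[idx],
            gamma=self.gamma[idx],
            pair_counts=self.pair_counts[idx],
            d_max_vox=self.d_max_vox,
            n_blocks=self.n_blocks,
            voxel_size_mm=self.voxel_size_mm,
            full_distances=self.full_distances,
            full_gamma=self.full_gamma,
            full_pair_counts=self.full_pair_counts,
        )


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares power-law model gamma_hat(d) = coefficient * d**exponent."""

    coefficient: float
    exponent: float
    residual: float  # sum of squared log-residuals

    def predict(self, d: np.ndarray) -> np.ndarray:
        return self.coefficient * np.asarray(d, dtype=float) ** self.exponent


def pair_count(n: int) -> int:
    """Number of unordered pairs among n items: n (n - 1) / 2."""
    n = int(n)
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    return n * (n - 1) // 2


def dmax_pixels(d_max_mm: float, voxel_size_mm: float, unit_vox: int = 8) -> int:
    """Convert a d_max estimate in mm to whole unit blocks in voxels.

    The mm value (half the diameter of the largest lobe) is truncated to whole
    voxels, then rounded *up* to the nearest multiple of the unit-block edge —
    8 mm at 0.15 mm/voxel gives 53 voxels, rounded up to 7 face-bordering
    8-blocks, i.e. 56 voxels.
    """
    if not (d_max_mm > 0 and voxel_size_mm > 0 and unit_vox > 0):
        raise ParameterError("d_max_mm, voxel_size_mm and unit_vox must be positive")
    voxels = int(d_max_mm / voxel_size_mm)  # truncate toward zero
    return int(np.ceil(voxels / unit_vox)) * int(unit_vox)


def empirical_variogram(
    blocks: UnitBlockSet,
    d_max_vox: float,
    voxel_size_mm: float = 1.0,
) -> Variogram:
    """Estimate the semi-variogram from every unordered pair of unit blocks.

    Pairs are grouped by exact centroid distance; gamma(d) is half the mean
    squared intensity difference within each group.  The returned object is
    truncated at ``d_max_vox`` but keeps the untruncated curve for
    diagnostics.
    """
    if not isinstance(blocks, UnitBlockSet):
        blocks = _as_block_set(blocks)
    n = len(blocks)
    if n < 2:
        raise InsufficientDataError(f"need at least 2 unit blocks, got {n}")
    if not d_max_vox > 0:
        raise ParameterError(f"d_max_vox must be > 0, got {d_max_vox}")

    dists = pdist(blocks.centroids)
    if np.any(dists == 0):
        raise ParameterError("unit-block centroids are not distinct")
    sq_diff = pdist(blocks.mean_hu[:, None], metric="sqeuclidean")

    rounded = np.round(dists, _DIST_DECIMALS)
    uniq, inverse = np.unique(rounded, return_inverse=True)
    counts = np.bincount(inverse)
    sums = np.bincount(inverse, weights=sq_diff)
    gamma = sums / (2.0 * counts)

    keep = uniq <= d_max_vox + 10.0**-_DIST_DECIMALS
    return Variogram(
        distances=uniq[keep],
        gamma=gamma[keep],
        pair_counts=counts[keep],
        d_max_vox=float(d_max_vox),
        n_blocks=n,
        voxel_size_mm=float(voxel_size_mm),
        full_distances=uniq,
        full_gamma=gamma,
        full_pair_counts=counts,
    )


def _as_block_set(blocks) -> UnitBlockSet:
    """Accept any iterable of objects with .centroid and .mean_hu."""
    items = list(blocks)
    cents = np.array([b.centroid for b in items], dtype=np.float64)
    means = np.array([b.mean_hu for b in items], dtype=np.float64)
    sizes = np.array([getattr(b, "source_size", 8) for b in items], dtype=np.int64)
    order = np.lexsort((cents[:, 2], cents[:, 1], cents[:, 0])) if len(items) else []
    return UnitBlockSet(cents[order], means[order], sizes[order])


def average_variograms(variograms: list[Variogram]) -> Variogram:
    """Unweighted per-distance mean of several variograms on one grid.

    All inputs must share the same distance grid (guaranteed when unit size
    and d_max agree and the lungs are large enough to realize every lattice
    offset); mismatched grids raise rather than interpolate.  Pair counts are
    summed for bookkeeping only.
    """
    if not variograms:
        raise ParameterError("need at least one variogram to average")
    ref = variograms[0]
    for v in variograms[1:]:
        if not np.array_equal(v.distances, ref.distances):
            raise AlignmentError(
                "variogram distance grids differ; restrict to a common grid first"
            )
    gamma = np.mean([v.gamma for v in variograms], axis=0)
    pair_counts = np.sum([v.pair_counts for v in variograms], axis=0)
    return Variogram(
        distances=ref.distances.copy(),
        gamma=gamma,
        pair_counts=pair_counts,
        d_max_vox=ref.d_max_vox,
        n_blocks=int(sum(v.n_blocks for v in variograms)),
        voxel_size_mm=ref.voxel_size_mm,
    )


def common_grid(variograms: list[Variogram]) -> list[Variogram]:
    """Restrict several variograms to the intersection of their distance
    grids (no interpolation), so they can be averaged and differenced."""
    if not variograms:
        return []
    shared = variograms[0].distances
    for v in variograms[1:]:
        shared = np.intersect1d(shared, v.distances)
    if shared.size == 0:
        raise AlignmentError("variograms share no common distances")
    return [v.restrict(shared) for v in variograms]


def fit_power_law(v: Variogram) -> PowerLawFit:
    """Ordinary least squares of log gamma on log d over d <= d_max.

    A closed-form log-log fit is used rather than nonlinear iteration; zero
    (or negative) gamma entries cannot be log-transformed and are dropped
    with a warning.
    """
    d = np.asarray(v.distances, dtype=float)
    g = np.asarray(v.gamma, dtype=float)
    usable = g > 0
    if not usable.all():
        warnings.warn(
            f"dropping {int((~usable).sum())} non-positive gamma value(s) "
            "from power-law fit",
            stacklevel=2,
        )
    d, g = d[usable], g[usable]
    if d.size < 3:
        raise InsufficientDataError(
            f"power-law fit needs >= 3 positive-gamma points, got {d.size}"
        )
    log_d, log_g = np.log(d), np.log(g)
    slope, intercept = np.polyfit(log_d, log_g, 1)
    resid = float(np.sum((log_g - (slope * log_d + intercept)) ** 2))
    return PowerLawFit(coefficient=float(np.exp(intercept)), exponent=float(slope), residual=resid)


def plot_variogram(
    variograms,
    labels=None,
    path=None,
    ax=None,
    show_dmax: bool = True,
):
    """Plot distance vs. semi-variance with a d_max marker.

    ``variograms`` may be a single :class:`Variogram` or a list; returns the
    matplotlib axes.  If ``path`` is given the figure is saved there.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if isinstance(variograms, Variogram):
        variograms = [variograms]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for i, v in enumerate(variograms):
        label = labels[i] if labels else None
        d = v.full_distances if v.full_distances is not None else v.distances
        g = v.full_gamma if v.full_gamma is not None else v.gamma
        ax.plot(d, g, ".-", ms=3, lw=0.8, label=label)
    if show_dmax:
        ax.axvline(
            variograms[0].d_max_vox, ls="--", color="gray", lw=1, label="$d_{max}$"
        )
    ax.set_xlabel("distance (voxels)")
    ax.set_ylabel(r"semi-variance $\gamma(d)$ (HU$^2$)")
    if labels or show_dmax:
        ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
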