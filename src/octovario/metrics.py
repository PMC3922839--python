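"""Scalar disease metrics and the nonparametric group statistics.

Three per-subject metrics are computed from a masked lung volume and its
variogram:

* heterogeneity score Delta — mean absolute difference, over d <= d_max,
  between the subject's semi-variogram and the control-group mean variogram;
  shift-invariant by construction, it responds to *spatial* signal structure
  rather than absolute HU level;
* emphysema index (EI) — percent of lung voxels below an HU cutoff, here the
  control-group Gaussian-fit mean minus two control sigmas;
* coefficient of variation (CoV) — Gaussian-fit sigma over |mean| of the main
  lung histogram peak.

The octree threshold is calibrated from the control subjects: fit the main
lung peak of each control histogram with a Gaussian, average the sigmas, and
sweep thresholds at 1/3, 2/3, 1, 4/3 and 2 times that value, choosing the
level at which a Kruskal-Wallis test shows the control variograms most alike.

Group comparisons use rank statistics (Kruskal-Wallis across groups,
Mann-Whitney-Wilcoxon pairwise) at alpha = 0.05, taking each subject's
per-distance gamma values (d <= d_max) as the observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import (
    AlignmentError,
    EmptyMaskError,
    FitError,
    InsufficientDataError,
    ParameterError,
)
from .variogram import Variogram
from .volume_io import VolumeImage

__all__ = [
    "GaussianFit",
    "ThresholdCalibration",
    "HeterogeneityResult",
    "RankTestResult",
    "fit_lung_peak_gaussian",
    "calibrate_threshold",
    "emphysema_threshold",
    "emphysema_index",
    "coefficient_of_variation",
    "heterogeneity_score",
    "kruskal_wallis_test",
    "mann_whitney_test",
]

#: fractions of the mean control sigma swept when calibrating the threshold
SWEEP_FRACTIONS = (1 / 3, 2 / 3, 1.0, 4 / 3, 2.0)

#: half-width (HU) of the window around the histogram mode used for the fit
_FIT_WINDOW_HU = 150.0


@dataclass(frozen=True)
class GaussianFit:
    """Gaussian fitted to the main peak of a masked lung HU histogram."""

    mean_hu: float
    sigma_hu: float
    bin_width_hu: float
    fit_range: tuple[float, float]


@dataclass(frozen=True)
class ThresholdCalibration:
    """Octree-threshold sweep derived from control-group peak sigmas."""

    sigma_bar_hu: float
    sweep_hu: tuple[float, float, float, float, float]
    chosen_hu: float | None = None


@dataclass(frozen=True)
class HeterogeneityResult:
    """Per-subject metric bundle."""

    subject_id: str
    group: str
    delta: float
    emphysema_index_pct: float
    cov: float


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    test: str  # "kruskal_wallis" | "mann_whitney"
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _gaussian(x, amplitude, mean, sigma):
    return amplitude * np.exp(-((x - mean) ** 2) / (2.0 * sigma**2))


def fit_lung_peak_gaussian(vol: VolumeImage, bin_width_hu: float = 10.0) -> GaussianFit:
    """Fit the dominant mode of the lung HU histogram with a Gaussian.

    The histogram of non-background voxels is binned at ``bin_width_hu``; a
    Gaussian is least-squares fitted over a window of +/-150 HU around the
    modal bin, then refitted once after re-centering the window on the fitted
    mean.  Windowing keeps a secondary low-HU mode (severe focal disease) from
    corrupting the main-peak parameters.
    """
    if not bin_width_hu > 0:
        raise ParameterError(f"bin_width_hu must be > 0, got {bin_width_hu}")
    values = vol.foreground()
    if values.size == 0:
        raise EmptyMaskError("volume holds no non-background voxels")
    if float(values.std()) == 0.0:
        # a constant lung has no peak width; report the histogram-bin
        # quantization sigma so degenerate inputs flow through the pipeline
        mean = float(values[0])
        return GaussianFit(
            mean_hu=mean,
            sigma_hu=float(bin_width_hu) / np.sqrt(12.0),
            bin_width_hu=float(bin_width_hu),
            fit_range=(mean, mean),
        )

    lo = np.floor(values.min() / bin_width_hu) * bin_width_hu
    hi = np.ceil(values.max() / bin_width_hu) * bin_width_hu + bin_width_hu
    edges = np.arange(lo, hi + bin_width_hu / 2, bin_width_hu)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    center = centers[np.argmax(counts)]
    fit_lo = fit_hi = (0.0, 0.0)
    params = None
    for _ in range(2):  # fit, re-center once, refit
        window = np.abs(centers - center) <= _FIT_WINDOW_HU
        x, y = centers[window], counts[window].astype(float)
        if x.size < 4:
            raise FitError("too few histogram bins in the fit window")
        p0 = (float(y.max()), float(center), max(3 * bin_width_hu, 1.0))
        try:
            params, _ = optimize.curve_fit(_gaussian, x, y, p0=p0, maxfev=10000)
        except RuntimeError as exc:
            raise FitError(f"Gaussian peak fit did not converge: {exc}") from exc
        center = params[1]
        fit_lo, fit_hi = float(x.min()), float(x.max())
    return GaussianFit(
        mean_hu=float(params[1]),
        sigma_hu=float(abs(params[2])),
        bin_width_hu=float(bin_width_hu),
        fit_range=(fit_lo, fit_hi),
    )


def calibrate_threshold(control_fits: list[GaussianFit]) -> ThresholdCalibration:
    """Build the five-level threshold sweep from control peak sigmas.

    The mean control sigma is rounded to the nearest whole HU (sweeps are
    communicated in round numbers) and the sweep covers sigma_bar times
    {1/3, 2/3, 1, 4/3, 2}: a mean sigma of 60 gives 20, 40, 60, 80, 120 HU.
    The final choice among the levels is made by the user after judging
    which level groups the controls most tightly.
    """
    if not control_fits:
        raise ParameterError("need at least one control fit")
    sigma_bar = float(np.round(np.mean([f.sigma_hu for f in control_fits])))
    sweep = tuple(sigma_bar * f for f in SWEEP_FRACTIONS)
    return ThresholdCalibration(sigma_bar_hu=sigma_bar, sweep_hu=sweep)  # type: ignore[arg-type]


def emphysema_threshold(control_fits: list[GaussianFit]) -> float:
    """HU cutoff for the emphysema index: control mean minus two sigmas,
    both taken from the Gaussian peak fits (not raw moments, which a bimodal
    severe-disease histogram would distort)."""
    if not control_fits:
        raise ParameterError("need at least one control fit")
    mean = float(np.mean([f.mean_hu for f in control_fits]))
    sigma = float(np.mean([f.sigma_hu for f in control_fits]))
    return mean - 2.0 * sigma


def emphysema_index(vol: VolumeImage, hu_threshold: float) -> float:
    """Percent of non-background voxels strictly below ``hu_threshold``."""
    values = vol.foreground()
    if values.size == 0:
        raise EmptyMaskError("volume holds no non-background voxels")
    return 100.0 * float(np.count_nonzero(values < hu_threshold)) / values.size


def coefficient_of_variation(fit: GaussianFit) -> float:
    """sigma / |mean| of the fitted lung peak (reported as a magnitude, since
    lung HU means are negative)."""
    if fit.mean_hu == 0:
        raise ParameterError("CoV undefined for zero mean")
    return abs(fit.sigma_hu / fit.mean_hu)


def heterogeneity_score(
    subject: Variogram, control_mean: Variogram, signed: bool = False
) -> float:
    """Heterogeneity score Delta: mean per-distance deviation of a subject's
    variogram from the control-group mean, over d <= d_max.

    By default the absolute difference is averaged (Delta is a distance, so
    controls sit near but not at zero); ``signed=True`` averages the raw
    differences instead.
    """
    if not np.array_equal(subject.distances, control_mean.distances):
        raise AlignmentError("subject and control variograms are on different grids")
    if subject.distances.size == 0:
        raise InsufficientDataError("empty variogram")
    diff = subject.gamma - control_mean.gamma
    return float(np.mean(diff if signed else np.abs(diff)))


def _validate_groups(groups, minimum: int) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    for i, g in enumerate(arrays):
        if g.size < minimum:
            raise ParameterError(
                f"group {i} has {g.size} observation(s); need >= {minimum}"
            )
    return arrays


def kruskal_wallis_test(groups: list, alpha: float = 0.05) -> RankTestResult:
    """Kruskal-Wallis rank sum test across two or more groups.

    The H statistic uses the standard tie correction and the p-value comes
    from the chi-squared approximation with k - 1 degrees of freedom.  A
    degenerate sample in which every observation is identical carries no rank
    information; it is reported as H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ParameterError("Kruskal-Wallis needs at least two groups")
    arrays = _validate_groups(groups, minimum=2)
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return RankTestResult(0.0, 1.0, "kruskal_wallis", alpha)
    stat, p = stats.kruskal(*arrays)
    return RankTestResult(float(stat), float(p), "kruskal_wallis", alpha)


def mann_whitney_test(a, b, alpha: float = 0.05) -> RankTestResult:
    """Two-sided Mann-Whitney-Wilcoxon rank sum test.

    Uses the exact null distribution for small tie-free samples and otherwise
    the tie-corrected normal approximation with continuity correction
    (scipy's automatic policy).
    """
    a, b = _validate_groups([a, b], minimum=1)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return RankTestResult(float(res.statistic), float(res.pvalue), "mann_whitney", alpha)
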