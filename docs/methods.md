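# Methods

## The measurement model

The pipeline treats a masked, isotropic CT lung volume as a realization of a
spatial random field I(x) and asks how its variance is organized over
distance.  Two assumptions drive every design choice:

* disease alters homogeneity at scales **above** the unit-block edge
  (8 voxels = 1.2 mm at 150 µm) but **below** the lobe scale, so blocks can
  stand in for voxels and the variogram need only be trusted out to
  d_max ≈ half the largest lobe's diameter;
* the fine scales (2–4 voxel blocks) are dominated by vessels, airways and
  boundaries — structure, not disease — and are best discarded outright
  rather than modeled.

### Octree decomposition

A region splits into its eight octants iff its population standard deviation
(ddof = 0; the convention matters only for consistency since the threshold is
calibrated on the same footing) exceeds `threshold_hu`, or it contains some
but not all background voxels.  Regions of edge 2 never split.  Region
statistics include background voxels; the mixed-background rule forces such
regions apart above the minimum size, so the choice only affects minimum-size
boundary blocks, which never reach the variogram.  Decomposition is exact
tiling: leaf volumes always sum to the cube volume.

The threshold is calibrated from the control group: fit the main lung
histogram peak with a Gaussian (10 HU bins, window = mode ± 150 HU, refit
once after re-centering — the window keeps a secondary low-HU disease mode
from corrupting the fit), average the control sigmas, round to whole HU, and
sweep {σ̄/3, 2σ̄/3, σ̄, 4σ̄/3, 2σ̄}.  For σ̄ = 60 that is 20/40/60/80/120 HU.
The level at which a Kruskal–Wallis test finds the control variograms most
alike is selected (`threshold_hu="calibrate"`); 40 HU is the package default.

### Unit-block selection

Every unit-size (8³) cell covered by a leaf of edge ≥ 8 is re-tested
individually — background-free and std ≤ threshold — and its mean is
recomputed from the voxels through a single code path.  This differs from
the simpler "keep 8-leaves, split larger leaves unconditionally" rule on
purpose: with that rule an 8-cell whose own std exceeds the threshold can
hide under a homogeneous 16-leaf in one grid alignment yet be subdivided and
discarded in an alignment shifted by one block, so the variogram would *not*
be exactly translation invariant.  With the per-cell rule, inclusion and
statistics are purely local functions of 8-aligned cell contents, and
shifting a volume by whole unit blocks leaves the variogram bit-identical
(asserted in the tests for all three disease modes).

### Variogram

Pairs are grouped by exact centroid distance (8·√(i²+j²+k²); distances are
rounded to 6 decimals only to absorb floating-point noise), not binned —
the lattice makes exact grouping natural.  γ(d) is half the mean squared
intensity difference per group.  The truncated (d ≤ d_max) and full curves
are both kept; Σ N(d) over the full curve equals n(n−1)/2 exactly.
d_max conversion truncates mm → voxels toward zero, then rounds **up** to a
whole number of unit blocks (8 mm at 0.15 mm → 53 → 56 voxels).
Averaging variograms requires identical distance grids (no interpolation);
`common_grid` restricts a set of variograms to their shared distances first.
The power-law fit is ordinary least squares of log γ on log d — closed-form
and reproducible; non-positive γ entries are dropped with a warning.

### Metrics and tests

* Δ = mean |γ_subject(d) − γ̄_control(d)| over d ≤ d_max.  The absolute value
  makes Δ a distance (a signed mean is available via `signed=True`); the
  control mean includes the subject itself by default, so controls score
  small but nonzero (leave-one-out available via config).
* Emphysema index: percent of lung voxels below (control fit mean − 2·fit σ).
  Gaussian-fit moments are used rather than raw moments because a bimodal
  severe-disease histogram corrupts raw moments.
* CoV: fit σ / |fit mean|, reported as a magnitude (lung means are negative).
* Rank tests take each subject's per-distance γ values (d ≤ d_max) as
  observations — the only reading on which a within-control-group test with
  one variogram per subject is possible.  Kruskal–Wallis uses the
  tie-corrected H and the χ² approximation; an all-identical sample is
  reported as H = 0, p = 1.  Mann–Whitney uses the exact null distribution
  for small tie-free samples and the tie-corrected normal approximation with
  continuity correction otherwise.

## The phantom generator

Phantoms emulate a three-group rodent emphysema study at desk scale:
two ellipsoidal "lungs" (≈24% of a 128³ canvas at 0.15 mm voxels, clear of
the canvas edges), parenchyma −550 HU with 60 HU texture at correlation
length 12 voxels, vessel-like bright paths (+400 HU, ≈1% of lung volume,
inserted after the field so the octree's small-box behavior is exercised),
and background 0 outside the mask.

**Field synthesis.**  The correlated texture is built spectrally: seeded
white noise supplies random Fourier phases, and the per-axis amplitude
spectrum is optimized (a small linear program over nonnegative weights with
unit variance) so that the field's circular variogram matches the Gaussian
target γ(d) = σ²(1 − exp(−d²/4ℓ²)) as closely as the torus allows —
deterministically within 7.4% for all lags on a 64-grid with ℓ = 12, and
within 0.02% on a 128-grid.  Plain smoothed white noise was rejected: a lung
this size holds only a handful of correlation volumes, so its empirical
variogram wanders ±50–75% realization to realization, which would make every
spatial quantity downstream a lottery.  The price of pinning the spectrum is
a slightly non-Gaussian marginal on very small grids (skew ≈ 1 at 64³,
vanishing by 128³) and a pointwise standard deviation that reaches σ only as
the grid grows beyond ℓ (0.88 σ at 64³, 0.98 σ at 128³) — the phantom then
re-standardizes the field inside the lung, so each subject's lung mean and σ
are exactly their stated parameter values (matching the tight control-group σ spread of
about ±1 HU that motivates threshold calibration in the first place).

**Disease modes.**  `global_mild` subtracts 50 HU everywhere and adds a
second correlated component (σ 40 HU, ℓ 12 voxels) that is first
orthogonalized against the existing lung signal: over ~6 effective texture
blobs, the sample covariance of two independent fields is large enough to
swing the realized variance increment by ±1900 HU², occasionally erasing
the disease signature entirely; after projection the lung variance rises by
exactly σ².  `focal_severe` selects the contiguous 15% of lung voxels
nearest a fixed interior point, damps their texture by 0.5 (destroyed tissue
reads homogeneously dark) and pins the lesion mean exactly 200 HU below the
healthy remainder — the realized contrast, not merely the nominal shift, is
the effect size.

**Cohorts.**  The factory draws each subject's baseline lung mean from
Normal(−550, 45 HU) — the animal-to-animal variation without which the
emphysema index and CoV would trivially separate a 50 HU shift, contrary to
the biology the phantoms emulate — and gives each subject independent
texture, vessel and disease realizations via spawned seed streams.  Subject
ids use a 100s/200s/300s convention for control/mild/severe.

**What the phantoms do not emulate.**  Scanner noise and reconstruction
artifacts (so the median filter has nothing to remove — cohort runs default
to `filter_method="none"`, and the filter's statistical neutrality is tested
separately), airway trees and lobar fissures, respiratory motion, and
anatomically realistic vessel branching.  Passing tests therefore show the
*method* behaves as designed on fields with known statistics, not that any
particular animal study would reproduce these numbers.

## What to expect from the group comparison

With three subjects per group, strict Δ ordering (every control below every
mild, every mild below every severe) held in 15 of 16 scanned cohort seeds;
the margin is set by the mild group's added-component realization against
the controls' own γ spread.  A real pilot study of this size has the same
character.  The Kruskal–Wallis test *within* phantom controls is often
significant (unlike a typical animal study): with ~500 blocks per subject on
a shared mask geometry, even sub-percent systematic γ offsets are
detectable.  Neither behavior is a defect of the estimator — both are
consequences of n = 3 and of how much cleaner phantoms are than animals.

## Numerical choices and degenerate inputs

* Intensities are stored as float32; statistics accumulate in float64.
* Zero-filling places the original data at the low-index corner — the
  variogram's exact invariance to whole-block shifts makes the placement a
  reproducible convention rather than a modeling decision.
* Voxel coordinates are 0-based; unit-block centroids sit at origin + 3.5.
* Median filtering uses a digital ball of the stated diameter (5 → offsets
  with Euclidean norm ≤ 2.5); Gaussian "radius" means the kernel σ in
  voxels; rotation interpolates trilinearly with background fill.
* Morphological closing pads by the radius first, so masks touching the
  array edge close as on an unbounded canvas.
* A constant lung volume yields a degenerate Gaussian fit; it is reported
  with the histogram-bin quantization σ (bin width/√12) so trivial inputs
  flow through the pipeline rather than erroring.
* Anisotropic input volumes are rejected (resampling would silently change
  every pair distance); the tolerance is 1% about the mean spacing.
* Genuine lung tissue at exactly 0 HU would be misread as background under
  the CT sentinel convention; the sentinel is configurable for non-CT data.

## Problem sizes

Tests and the acceptance script run the full study at 128³ with 3 subjects
per group (~500 unit blocks, ~10⁵ pairs per subject), oracle comparisons on
volumes up to 32³ and block sets up to n = 200, field recovery at 64³, and
1000-replicate null simulations for the rank tests — sizes chosen so the
whole suite completes in about a minute on one CPU while every qualitative
claim is still exercised at the scale it concerns.
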