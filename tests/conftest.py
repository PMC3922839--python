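"""Shared fixtures and independent reference implementations (oracles).

The oracles here are deliberately naive — breadth-first flood fill, explicit
structuring-element sweeps, plain-recursive octree subdivision, double-loop
variogram — so they share no code path with the package implementations they
check.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from octovario import StudyConfig, VolumeImage, generate_cohort, run_study


# --------------------------------------------------------------------------
# fixtures


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_volume(data, voxel_size_mm=0.15, background=0.0):
    return VolumeImage(np.asarray(data, dtype=np.float32), voxel_size_mm, background)


@pytest.fixture(scope="session")
def default_cohort_study():
    """The full 3/3/3 phantom study at the generator defaults (128-cube,
    seed 0); session-scoped because several group-level checks share it."""
    cohort = generate_cohort(seed=0, dims=128)
    cfg = StudyConfig(threshold_hu=40.0, filter_method="none")
    return run_study(cohort, cfg)


# --------------------------------------------------------------------------
# oracles


def flood_fill_oracle(data, seed, lower, upper, connectivity=6):
    """Breadth-first flood fill over {lower <= I <= upper} from seed."""
    if connectivity == 6:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        offsets = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
    shape = data.shape
    inside = np.zeros(shape, dtype=bool)
    seen = np.zeros(shape, dtype=bool)
    queue = deque([tuple(seed)])
    seen[tuple(seed)] = True
    while queue:
        x, y, z = queue.popleft()
        if not (lower <= data[x, y, z] <= upper):
            continue
        inside[x, y, z] = True
        for dx, dy, dz in offsets:
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                if not seen[nx, ny, nz]:
                    seen[nx, ny, nz] = True
                    queue.append((nx, ny, nz))
    return inside


def ball_offsets(radius):
    r = int(np.ceil(radius))
    return [
        (i, j, k)
        for i in range(-r, r + 1)
        for j in range(-r, r + 1)
        for k in range(-r, r + 1)
        if i * i + j * j + k * k <= radius * radius
    ]


def closing_oracle(mask, radius):
    """Dilate-then-erode by an explicit per-voxel structuring-element sweep
    on an unbounded canvas (the mask is padded by the radius)."""
    offs = ball_offsets(radius)
    r = int(radius)
    padded = np.pad(mask, r, mode="constant", constant_values=False)
    shape = padded.shape
    dilated = np.zeros(shape, dtype=bool)
    for x, y, z in np.argwhere(padded):
        for dx, dy, dz in offs:
            nx, ny, nz = x + dx, y + dy, z + dz
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                dilated[nx, ny, nz] = True
    eroded = np.zeros(shape, dtype=bool)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                ok = True
                for dx, dy, dz in offs:
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if not (
                        0 <= nx < shape[0]
                        and 0 <= ny < shape[1]
                        and 0 <= nz < shape[2]
                        and dilated[nx, ny, nz]
                    ):
                        ok = False
                        break
                eroded[x, y, z] = ok
    return eroded[r:-r, r:-r, r:-r]


def median_filter_oracle(data, diameter):
    """Per-voxel neighborhood median with a spherical footprint; out-of-bounds
    neighbors are taken from the nearest edge voxel (scipy's default)."""
    offs = ball_offsets(diameter / 2.0)
    shape = data.shape
    out = np.empty_like(data)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                vals = [
                    data[
                        min(max(x + dx, 0), shape[0] - 1),
                        min(max(y + dy, 0), shape[1] - 1),
                        min(max(z + dz, 0), shape[2] - 1),
                    ]
                    for dx, dy, dz in offs
                ]
                out[x, y, z] = np.median(vals)
    return out


def recursive_octree_oracle(data, threshold, min_size, background=0.0):
    """Plain-recursive octree decomposer; returns {(origin, size)} leaf keys
    with (mean, std) for cross-checking."""
    leaves = {}

    def visit(ox, oy, oz, size):
        region = data[ox : ox + size, oy : oy + size, oz : oz + size]
        flat = region.astype(np.float64).ravel()
        std = flat.std()
        n_bg = int((region == np.float32(background)).sum())
        mixed = 0 < n_bg < size**3
        if size > min_size and (std > threshold or mixed):
            h = size // 2
            for dx in (0, h):
                for dy in (0, h):
                    for dz in (0, h):
                        visit(ox + dx, oy + dy, oz + dz, h)
        else:
            leaves[(ox, oy, oz, size)] = (flat.mean(), std, n_bg)

    visit(0, 0, 0, data.shape[0])
    return leaves


def brute_force_variogram(centroids, values, decimals=6):
    """Double loop over all unordered pairs; groups by rounded distance."""
    groups: dict[float, list[float]] = {}
    n = len(values)
    for i in range(n):
        for j in range(i + 1, n):
            d = round(float(np.linalg.norm(centroids[i] - centroids[j])), decimals)
            groups.setdefault(d, []).append(float(values[i] - values[j]) ** 2)
    dists = sorted(groups)
    gamma = np.array([sum(groups[d]) / (2.0 * len(groups[d])) for d in dists])
    counts = np.array([len(groups[d]) for d in dists])
    return np.array(dists), gamma, counts


def random_block_volume(rng, size, background=0.0):
    """Random test volume with planted structure: smooth-ish base, a
    high-variance octant, and a background slab, so all octree rules fire."""
    data = rng.normal(-500, 30, (size, size, size)).astype(np.float32)
    h = size // 2
    data[:h, :h, :h] += rng.normal(0, 150, (h, h, h))  # heterogeneous octant
    if rng.random() < 0.7:
        k = int(rng.integers(1, max(size // 4, 2)))
        data[:, :, :k] = background  # background slab
    if rng.random() < 0.3:
        data[h:, h:, h:] = -400.0  # perfectly homogeneous octant
    return data
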