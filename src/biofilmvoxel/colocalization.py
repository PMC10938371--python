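"""3D co-localization profiles: target occupancy vs distance from focal voxels.

The statistic asks how densely a *target* species occupies space at a given
physical distance from a *focal* species. Per run, ``n_focal`` focal voxels
are sampled uniformly without replacement; every voxel within ``max_dist_um``
(physical Euclidean distance, per-axis spacing respected) of a sampled focal
voxel is assigned to the distance bin whose odd-integer center (1, 3, 5, ...)
is nearest; per bin, target-occupied and total voxel tallies are pooled over
all sampled focal voxels and their ratio is the occupancy proportion. The
analysis is repeated ``n_runs`` times (run r reseeded with seed + r) and the
profile is the mean over runs; variability across biological replicates is
summarized separately with SEM.

Near image edges the out-of-bounds voxels simply do not exist, so bin totals
shrink — no mirroring or padding. When the focal population does not exceed
``n_focal`` every focal voxel is used once, which makes the sampled statistic
coincide exactly with the exhaustive all-pairs computation.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .image_io import BinaryMask

__all__ = [
    "ColocalizationProfile",
    "ReplicateProfileSummary",
    "colocalization_profile",
    "summarize_replicates",
]


def odd_bin_centers(max_dist_um: float) -> np.ndarray:
    """The odd-integer bin centers 1, 3, ..., <= max_dist_um."""
    if max_dist_um < 1:
        raise ValueError(f"max_dist_um must be >= 1, got {max_dist_um}")
    last = int(max_dist_um) if int(max_dist_um) % 2 == 1 else int(max_dist_um) - 1
    return np.arange(1, last + 1, 2)


def nearest_odd_bin(distances: np.ndarray) -> np.ndarray:
    """Nearest odd integer to each distance; exact-even ties resolve upward.

    d = 0 maps to bin 1. Derivation: the odd integer nearest to d is
    2*floor(d/2) + 1, which for even d (tie) picks d + 1.
    """
    d = np.asarray(distances, dtype=float)
    return (2 * np.floor(d / 2) + 1).astype(int)


@dataclasses.dataclass(frozen=True)
class ColocalizationProfile:
    """Per-distance-bin occupancy of a target species around focal voxels.

    ``per_run_proportions`` is an (n_runs, n_bins) matrix; entries are NaN
    where a run accumulated no voxels in a bin. ``counts`` holds the pooled
    (target_voxels, total_voxels) per bin accumulated over all runs.
    """

    focal: str
    target: str
    bin_centers_um: np.ndarray
    per_run_proportions: np.ndarray
    mean_proportion: np.ndarray
    n_focal_sampled: int
    n_runs: int
    seed: int
    counts: np.ndarray  # (n_bins, 2): target, total


@dataclasses.dataclass(frozen=True)
class ReplicateProfileSummary:
    focal: str
    target: str
    bin_centers_um: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_replicates: int


def _distance_kernel(spacing_um, max_dist_um, n_bins):
    """Relative-offset kernel: per offset, the 0-based bin index or -1 (discard).

    An offset is kept iff its nearest odd integer center is an actual bin,
    i.e. nearest-odd(d) <= last bin center. The center offset (d = 0) maps to
    bin 1 (index 0).
    """
    dz, dy, dx = spacing_um
    # a distance d belongs to the last (odd) bin center L iff d < L + 1,
    # so the kernel box must reach L + 1 along each axis
    reach = 2.0 * n_bins  # = last center + 1
    rz = int(np.floor(reach / dz))
    ry = int(np.floor(reach / dy))
    rx = int(np.floor(reach / dx))
    oz = np.arange(-rz, rz + 1)[:, None, None] * dz
    oy = np.arange(-ry, ry + 1)[None, :, None] * dy
    ox = np.arange(-rx, rx + 1)[None, None, :] * dx
    d = np.sqrt(oz**2 + oy**2 + ox**2)
    centers = nearest_odd_bin(d)
    kernel = (centers - 1) // 2  # odd center 2k+1 -> index k
    kernel[kernel >= n_bins] = -1
    return kernel.astype(np.int64), (rz, ry, rx)


def _accumulate(focal_idx, target_values, kernel, radii, n_bins):
    """Pool per-bin (target, total) tallies over the given focal voxels."""
    nz, ny, nx = target_values.shape
    rz, ry, rx = radii
    tgt = np.zeros(n_bins, dtype=np.int64)
    tot = np.zeros(n_bins, dtype=np.int64)
    target_f = target_values.astype(np.float64)
    for z, y, x in focal_idx:
        z0, z1 = max(z - rz, 0), min(z + rz + 1, nz)
        y0, y1 = max(y - ry, 0), min(y + ry + 1, ny)
        x0, x1 = max(x - rx, 0), min(x + rx + 1, nx)
        kwin = kernel[
            z0 - z + rz : z1 - z + rz,
            y0 - y + ry : y1 - y + ry,
            x0 - x + rx : x1 - x + rx,
        ].ravel()
        keep = kwin >= 0
        bins = kwin[keep]
        tot += np.bincount(bins, minlength=n_bins)
        tgt += np.bincount(
            bins, weights=target_f[z0:z1, y0:y1, x0:x1].ravel()[keep], minlength=n_bins
        ).astype(np.int64)
    return tgt, tot


def colocalization_profile(
    focal: BinaryMask,
    target: BinaryMask,
    n_focal: int = 1000,
    max_dist_um: float = 51.0,
    n_runs: int = 5,
    seed: int = 0,
) -> ColocalizationProfile:
    """Compute the target-around-focal occupancy profile.

    Deterministic given ``seed``; run r draws its focal sample with seed + r
    so runs are independent but jointly reproducible.
    """
    if focal.shape != target.shape or focal.spacing_um != target.spacing_um:
        raise ValueError("focal and target masks must be congruent in shape and spacing")
    if n_focal < 1:
        raise ValueError(f"n_focal must be >= 1, got {n_focal}")
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    focal_voxels = np.argwhere(focal.values)
    if focal_voxels.shape[0] == 0:
        raise ValueError("focal mask has no foreground voxels")

    centers = odd_bin_centers(max_dist_um)
    n_bins = centers.size
    kernel, radii = _distance_kernel(focal.spacing_um, max_dist_um, n_bins)

    n_population = focal_voxels.shape[0]
    use_all = n_population <= n_focal
    if use_all and n_population < n_focal:
        warnings.warn(
            f"focal population ({n_population}) smaller than n_focal ({n_focal}); "
            "using every focal voxel once",
            stacklevel=2,
        )

    per_run = np.full((n_runs, n_bins), np.nan)
    counts = np.zeros((n_bins, 2), dtype=np.int64)
    for run in range(n_runs):
        if use_all:
            sampled = focal_voxels
        else:
            rng = np.random.default_rng(seed + run)
            pick = rng.choice(n_population, size=n_focal, replace=False)
            sampled = focal_voxels[pick]
        tgt, tot = _accumulate(sampled, target.values, kernel, radii, n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_run[run] = np.where(tot > 0, tgt / np.maximum(tot, 1), np.nan)
        counts[:, 0] += tgt
        counts[:, 1] += tot

    return ColocalizationProfile(
        focal=focal.name,
        target=target.name,
        bin_centers_um=centers,
        per_run_proportions=per_run,
        mean_proportion=per_run.mean(axis=0),
        n_focal_sampled=int(min(n_focal, n_population)),
        n_runs=n_runs,
        seed=seed,
        counts=counts,
    )


def summarize_replicates(profiles: list) -> ReplicateProfileSummary:
    """Mean and SEM (sd / sqrt(n)) per bin across biological replicates.

    Each replicate contributes its run-averaged profile. All profiles must
    share bins and species labels; at least two replicates are required for a
    standard error.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 replicate profiles to estimate SEM")
    ref = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.bin_centers_um, ref.bin_centers_um):
            raise ValueError("replicate profiles have heterogeneous distance bins")
        if p.focal != ref.focal or p.target != ref.target:
            raise ValueError("replicate profiles mix species pairs")
    stackd = np.vstack([p.mean_proportion for p in profiles])
    n = stackd.shape[0]
    return ReplicateProfileSummary(
        focal=ref.focal,
        target=ref.target,
        bin_centers_um=ref.bin_centers_um,
        mean=stackd.mean(axis=0),
        sem=stackd.std(axis=0, ddof=1) / np.sqrt(n),
        n_replicates=n,
    )
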