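"""3D cell-aggregate detection: adjacency grouping and volume filtering.

An aggregate is a connected component of a species' foreground voxels under
an odd adjacency window: with the default (3, 3, 3) window two voxels are
neighbors when they differ by at most one index along every axis
(26-connectivity), and an aggregate is a maximal chain-connected set. The
size of an aggregate is the total physical volume of its voxels; downstream
counting retains only aggregates strictly larger than a volume threshold
(10 μm³ by default).
"""

from __future__ import annotations

import dataclasses
from collections import deque
from typing import Optional

import numpy as np
from scipy import ndimage

from .image_io import BinaryMask

__all__ = ["Aggregate", "AggregateSummary", "label_aggregates", "summarize_aggregates"]


@dataclasses.dataclass(frozen=True)
class Aggregate:
    id: int
    voxel_count: int
    volume_um3: float
    centroid_um: tuple  # (z, y, x) physical coordinates
    bbox: tuple  # ((z0, z1), (y0, y1), (x0, x1)) inclusive voxel index ranges


@dataclasses.dataclass(frozen=True)
class AggregateSummary:
    species: str
    n_total: int
    n_above_threshold: int
    threshold_um3: float
    mean_volume_um3: Optional[float]  # None when no aggregate is retained
    total_volume_um3: float
    image_id: str = ""
    day: Optional[int] = None
    replicate: Optional[str] = None


def _window_structure(adjacency: tuple) -> np.ndarray:
    """3x3x3 binary structure for adjacency components in {1, 3}."""
    struct = np.zeros((3, 3, 3), dtype=bool)
    kz, ky, kx = [(a - 1) // 2 for a in adjacency]
    struct[1 - kz : 2 + kz, 1 - ky : 2 + ky, 1 - kx : 2 + kx] = True
    return struct


def _label_bfs(values: np.ndarray, adjacency: tuple) -> np.ndarray:
    """Generic labeling for windows wider than 3: BFS with the full offset set."""
    kz, ky, kx = [(a - 1) // 2 for a in adjacency]
    offsets = [
        (dz, dy, dx)
        for dz in range(-kz, kz + 1)
        for dy in range(-ky, ky + 1)
        for dx in range(-kx, kx + 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    labels = np.zeros(values.shape, dtype=np.int32)
    nz, ny, nx = values.shape
    next_id = 0
    for z, y, x in np.argwhere(values):
        if labels[z, y, x]:
            continue
        next_id += 1
        labels[z, y, x] = next_id
        queue = deque([(int(z), int(y), int(x))])
        while queue:
            cz, cy, cx = queue.popleft()
            for dz, dy, dx in offsets:
                wz, wy, wx = cz + dz, cy + dy, cx + dx
                if 0 <= wz < nz and 0 <= wy < ny and 0 <= wx < nx:
                    if values[wz, wy, wx] and not labels[wz, wy, wx]:
                        labels[wz, wy, wx] = next_id
                        queue.append((wz, wy, wx))
    return labels


def label_aggregates(mask: BinaryMask, adjacency: tuple = (3, 3, 3)) -> list:
    """Group foreground voxels into aggregates under the adjacency window.

    Ids are assigned in raster-scan (z, y, x) order of each aggregate's first
    voxel, starting at 1. Every foreground voxel belongs to exactly one
    aggregate.
    """
    adjacency = tuple(int(a) for a in adjacency)
    if len(adjacency) != 3:
        raise ValueError("adjacency must have three components")
    if any(a < 1 or a % 2 == 0 for a in adjacency):
        raise ValueError(f"adjacency components must be odd and >= 1, got {adjacency}")

    if all(a <= 3 for a in adjacency):
        labels, n = ndimage.label(mask.values, structure=_window_structure(adjacency))
    else:
        labels = _label_bfs(mask.values, adjacency)
        n = labels.max()
    if n == 0:
        return []

    # reorder ids by raster-scan order of each component's first voxel
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nonzero = np.flatnonzero(flat)
    # reversed so earlier indices overwrite later ones
    first[flat[nonzero[::-1]]] = nonzero[::-1]
    order = np.argsort(first[1:], kind="stable")  # old label - 1, by first voxel
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(1, n + 1)

    counts = np.bincount(flat, minlength=n + 1)[1:]
    vol = mask.voxel_volume_um3
    spacing = np.asarray(mask.spacing_um)
    centroids = ndimage.center_of_mass(mask.values, labels, index=np.arange(1, n + 1))
    slices = ndimage.find_objects(labels)

    aggs = []
    for old in range(1, n + 1):
        sl = slices[old - 1]
        bbox = tuple((s.start, s.stop - 1) for s in sl)
        centroid = tuple(np.asarray(centroids[old - 1]) * spacing)
        aggs.append(
            Aggregate(
                id=int(rank[old - 1]),
                voxel_count=int(counts[old - 1]),
                volume_um3=float(counts[old - 1] * vol),
                centroid_um=centroid,
                bbox=bbox,
            )
        )
    aggs.sort(key=lambda a: a.id)
    return aggs


def summarize_aggregates(
    aggs: list,
    threshold_um3: float = 10.0,
    species: str = "",
    image_id: str = "",
    day=None,
    replicate=None,
) -> AggregateSummary:
    """Count and summarize aggregates strictly larger than ``threshold_um3``.

    An empty retained set yields count 0 with ``mean_volume_um3 = None``
    (undefined mean flagged, not an error).
    """
    if threshold_um3 < 0:
        raise ValueError(f"threshold_um3 must be nonnegative, got {threshold_um3}")
    retained = [a for a in aggs if a.volume_um3 > threshold_um3]
    total = sum(a.volume_um3 for a in retained)
    return AggregateSummary(
        species=species,
        n_total=len(aggs),
        n_above_threshold=len(retained),
        threshold_um3=float(threshold_um3),
        mean_volume_um3=(total / len(retained)) if retained else None,
        total_volume_um3=total,
        image_id=image_id,
        day=day,
        replicate=replicate,
    )
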