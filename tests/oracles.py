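"""Independent brute-force reference implementations used only by the tests.

Each oracle recomputes a statistic by the most literal method available —
triple loops, explicit enumeration, textbook formulas — deliberately sharing
no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def coloc_bruteforce(focal, target, spacing, max_dist_um):
    """All-pairs co-localization tallies by explicit iteration.

    Returns (bin_centers, target_counts, total_counts) pooling every focal
    voxel. Binning: a distance d joins the odd-integer center minimizing
    |d - center|, ties going to the larger center; distances whose nearest
    odd integer exceeds the last center are discarded.
    """
    last = int(max_dist_um) if int(max_dist_um) % 2 == 1 else int(max_dist_um) - 1
    centers = list(range(1, last + 1, 2))
    candidates = centers + [last + 2]  # sentinel: nearest odd beyond range
    tgt = {c: 0 for c in centers}
    tot = {c: 0 for c in centers}
    dz, dy, dx = spacing
    nz, ny, nx = focal.shape
    focal_voxels = [tuple(v) for v in np.argwhere(focal)]
    for fz, fy, fx in focal_voxels:
        for z in range(nz):
            for y in range(ny):
                for x in range(nx):
                    d = math.sqrt(
                        ((z - fz) * dz) ** 2 + ((y - fy) * dy) ** 2 + ((x - fx) * dx) ** 2
                    )
                    # nearest odd candidate, ties upward
                    best = min(candidates, key=lambda c: (abs(d - c), -c))
                    if best > last:
                        continue
                    tot[best] += 1
                    tgt[best] += int(target[z, y, x])
    return (
        np.array(centers),
        np.array([tgt[c] for c in centers]),
        np.array([tot[c] for c in centers]),
    )


def flood_fill_labels(values, adjacency=(3, 3, 3)):
    """Connected components by recursive-style flood fill over an offset list."""
    kz, ky, kx = [(a - 1) // 2 for a in adjacency]
    offsets = [
        (dz, dy, dx)
        for dz in range(-kz, kz + 1)
        for dy in range(-ky, ky + 1)
        for dx in range(-kx, kx + 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    nz, ny, nx = values.shape
    labels = np.zeros(values.shape, dtype=int)
    current = 0
    for start in map(tuple, np.argwhere(values)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                w = (z + dz, y + dy, x + dx)
                if 0 <= w[0] < nz and 0 <= w[1] < ny and 0 <= w[2] < nx:
                    if values[w] and not labels[w]:
                        labels[w] = current
                        stack.append(w)
    return labels, current


def kapur_scan(values, n_bins):
    """Maximum-entropy threshold by literal per-candidate entropy evaluation."""
    lo, hi = float(np.min(values)), float(np.max(values))
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    p = counts / counts.sum()
    best_obj, best_edge = -np.inf, None
    for k in range(n_bins - 1):  # split after bin k
        w_bg = p[: k + 1].sum()
        w_fg = p[k + 1 :].sum()
        if w_bg == 0 or w_fg == 0:
            continue
        h_bg = -sum(q / w_bg * math.log(q / w_bg) for q in p[: k + 1] if q > 0)
        h_fg = -sum(q / w_fg * math.log(q / w_fg) for q in p[k + 1 :] if q > 0)
        if h_bg + h_fg > best_obj + 1e-12:
            best_obj = h_bg + h_fg
            best_edge = edges[k + 1]
    return best_edge, best_obj


def permanova_f(dist, groups):
    """Anderson pseudo-F from pairwise distances by explicit double loops."""
    n = len(groups)
    labels = sorted(set(groups))
    a = len(labels)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += dist[i][j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in labels:
        members = [i for i in range(n) if groups[i] == g]
        s = 0.0
        for i, j in itertools.combinations(members, 2):
            s += dist[i][j] ** 2
        ss_within += s / len(members)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova_exhaustive_p(dist, groups):
    """Exact PERMANOVA tail probability over all distinct label arrangements."""
    f_obs = permanova_f(dist, groups)
    arrangements = sorted(set(itertools.permutations(groups)))
    exceed = sum(1 for g in arrangements if permanova_f(dist, list(g)) >= f_obs - 1e-12)
    return exceed / len(arrangements), len(arrangements)
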