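"""Community composition statistics for the four-species consortium.

Covers the post-ASV analysis chain: 16S copy-number correction and relative
abundance, Bray-Curtis dissimilarity, PERMANOVA (distance-based pseudo-F with
label permutation), PCoA ordination, and the group-comparison tests
(Kruskal-Wallis with Benjamini-Hochberg FDR across the taxon family, and the
Wilcoxon rank-sum test for two-group phenotype contrasts).

PERMANOVA follows the distance-based decomposition: with squared pairwise
distances d²ᵢⱼ, SS_total = Σᵢ<ⱼ d²ᵢⱼ / n and SS_within = Σ groups
Σᵢ<ⱼ∈group d²ᵢⱼ / n_group; pseudo-F = (SS_between/(a−1)) / (SS_within/(n−a)).
Significance uses the (1 + exceedances) / (1 + permutations) convention so a
Monte-Carlo p is never 0; when the number of distinct label arrangements is
no larger than the requested permutation count, the full arrangement set is
enumerated instead and the p-value is the exact tail probability.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "PermanovaResult",
    "PcoaResult",
    "GroupComparison",
    "copy_number_correct",
    "bray_curtis",
    "permanova",
    "pcoa",
    "kruskal_wallis_bh",
    "wilcoxon_rank_sum",
]


@dataclasses.dataclass(frozen=True)
class AbundanceTable:
    """Samples × taxa counts with per-taxon 16S copy numbers and metadata.

    ``counts`` rows are samples, columns taxa; ``metadata`` is indexed like
    ``counts`` and typically carries ``day`` and ``replicate`` columns.
    ``copy_numbers`` maps each taxon to its 16S rRNA gene copy number (> 0);
    it has no default — it is strain-specific knowledge the user supplies.
    """

    counts: pd.DataFrame
    copy_numbers: Mapping[str, float]
    metadata: Optional[pd.DataFrame] = None
    is_relative: bool = False

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.columns.duplicated().any():
            raise ValueError("taxa labels must be unique")
        missing = [t for t in self.counts.columns if t not in self.copy_numbers]
        if missing:
            raise ValueError(f"missing 16S copy numbers for taxa: {missing}")
        if any(self.copy_numbers[t] <= 0 for t in self.counts.columns):
            raise ValueError("copy numbers must be positive")
        if self.metadata is not None and not self.metadata.index.equals(self.counts.index):
            raise ValueError("metadata index must match counts index")

    @property
    def taxa(self) -> list:
        return list(self.counts.columns)

    @property
    def samples(self) -> list:
        return list(self.counts.index)


def copy_number_correct(table: AbundanceTable, correct: bool = True) -> AbundanceTable:
    """Divide counts by per-taxon 16S copy numbers and renormalize to relative abundance.

    Samples whose corrected total is zero cannot be renormalized; they are
    logged and dropped. Set ``correct=False`` to renormalize without the
    copy-number division.
    """
    corrected = table.counts.astype(float).copy()
    if correct:
        for taxon in corrected.columns:
            corrected[taxon] = corrected[taxon] / table.copy_numbers[taxon]
    totals = corrected.sum(axis=1)
    zero = totals == 0
    if zero.any():
        dropped = list(corrected.index[zero])
        logger.warning("dropping zero-total samples: %s", dropped)
        corrected = corrected.loc[~zero]
        totals = totals.loc[~zero]
    relative = corrected.div(totals, axis=0)
    meta = table.metadata.loc[relative.index] if table.metadata is not None else None
    return AbundanceTable(
        counts=relative,
        copy_numbers=dict(table.copy_numbers),
        metadata=meta,
        is_relative=True,
    )


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(i,j) = Σ|xᵢ−xⱼ| / Σ(xᵢ+xⱼ) between samples."""
    x = table.counts.values.astype(float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    if zero_rows.size >= 2:
        names = [table.samples[i] for i in zero_rows]
        raise ValueError(f"Bray-Curtis undefined between all-zero samples: {names}")
    condensed = pdist(x, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(s) for s in table.samples])


@dataclasses.dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int
    seed: Optional[int]
    exhaustive: bool = False


def _distinct_arrangements(counts: Sequence[int]) -> int:
    n = sum(counts)
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(c)
    return total


def _multiset_permutations(items: list):
    """Yield the distinct permutations of a label multiset, lexicographically."""
    items = sorted(items)
    n = len(items)
    yield tuple(items)
    while True:
        i = n - 2
        while i >= 0 and items[i] >= items[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while items[j] <= items[i]:
            j -= 1
        items[i], items[j] = items[j], items[i]
        items[i + 1 :] = reversed(items[i + 1 :])
        yield tuple(items)


def _pseudo_f_batch(d2: np.ndarray, label_matrix: np.ndarray, group_ids: np.ndarray):
    """Pseudo-F and R² for each row of labels in ``label_matrix`` (m, n)."""
    n = d2.shape[0]
    a = group_ids.size
    ss_total = d2.sum() / (2 * n)
    ss_within = np.zeros(label_matrix.shape[0])
    for g in group_ids:
        ind = (label_matrix == g).astype(float)  # (m, n)
        n_g = ind.sum(axis=1)
        pair_sums = np.einsum("mi,ij,mj->m", ind, d2, ind) / 2.0
        ss_within += pair_sums / n_g
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / (a - 1)) / (ss_within / (n - a))
        r2 = np.where(ss_total > 0, ss_between / ss_total, 0.0)
    return f, r2, ss_total


def permanova(
    dm: DistanceMatrix,
    groups: Sequence,
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with free label permutation.

    When the number of distinct label arrangements is <= ``n_permutations``
    the arrangement set is enumerated exhaustively (the identity included)
    and p is the exact tail probability #(F_perm >= F_obs)/#arrangements;
    otherwise ``n_permutations`` random permutations are drawn with ``seed``
    and p = (1 + #(F_perm >= F_obs)) / (1 + n_permutations).
    """
    d = np.asarray(dm.data, dtype=float)
    groups = np.asarray(groups)
    n = d.shape[0]
    if groups.shape[0] != n:
        raise ValueError("group labels must match the distance matrix size")
    uniq, inv = np.unique(groups, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    d2 = d**2
    group_ids = np.arange(uniq.size)
    f_obs, r2_obs, ss_total = _pseudo_f_batch(d2, inv[None, :], group_ids)
    f_obs, r2_obs = float(f_obs[0]), float(r2_obs[0])

    if ss_total == 0:
        # all samples coincide: no variance to partition
        return PermanovaResult(0.0, 0.0, 1.0, 0, seed, exhaustive=True)

    counts = np.bincount(inv)
    n_distinct = _distinct_arrangements(counts)
    if n_distinct <= n_permutations:
        logger.info(
            "fewer distinct permutations (%d) than requested (%d): exhaustive enumeration",
            n_distinct,
            n_permutations,
        )
        perms = np.array(list(_multiset_permutations(list(inv))))
        f_perm, _, _ = _pseudo_f_batch(d2, perms, group_ids)
        p = float(np.count_nonzero(f_perm >= f_obs - 1e-12)) / n_distinct
        return PermanovaResult(f_obs, r2_obs, p, n_distinct, seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(inv) for _ in range(n_permutations)])
    f_perm, _, _ = _pseudo_f_batch(d2, perms, group_ids)
    exceed = int(np.count_nonzero(f_perm >= f_obs - 1e-12))
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(f_obs, r2_obs, p, n_permutations, seed, exhaustive=False)


@dataclasses.dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame  # samples × axes
    eigenvalues: np.ndarray  # all eigenvalues, decreasing (negatives reported)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Classical scaling of a distance matrix (double-centered Gower eigendecomposition).

    Coordinates come from the positive eigenvalues; negative eigenvalues are
    reported, not silently dropped. Sign convention: the first nonzero
    loading of every axis is made positive so plots are reproducible.
    """
    res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    eigvals = np.asarray(res.eigvals, dtype=float)
    coords = res.samples.to_numpy(copy=True)
    positive = eigvals > 1e-10 * max(1.0, np.abs(eigvals).max())
    n_pos = int(np.count_nonzero(positive))
    coords = coords[:, :n_pos]
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    pos_sum = eigvals[positive].sum()
    proportion = eigvals[:n_pos] / pos_sum if pos_sum > 0 else np.zeros(n_pos)
    frame = pd.DataFrame(
        coords,
        index=list(dm.ids),
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return PcoaResult(coordinates=frame, eigenvalues=eigvals, proportion_explained=proportion)


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    test: str  # "wilcoxon" | "kruskal_wallis"
    feature: str
    statistic: float
    p_value: float
    p_adjusted: Optional[float]
    group_labels: tuple
    n_per_group: tuple
    method: str = ""
    flagged: bool = False


def kruskal_wallis_bh(groups_per_feature: Mapping[str, Sequence[Sequence[float]]],
                      group_labels: Optional[Sequence[str]] = None) -> list:
    """Kruskal-Wallis H per feature with BH FDR adjustment across the family.

    ``groups_per_feature`` maps a feature (taxon) to its per-group value
    sequences; the family for the BH correction is exactly the set of
    features passed in one call. Features whose values are identical across
    all groups get H = 0, p = 1 and are flagged.
    """
    results = []
    pvals = []
    for feature, groups in groups_per_feature.items():
        groups = [np.asarray(g, dtype=float) for g in groups]
        if len(groups) < 2:
            raise ValueError(f"feature {feature!r}: need >= 2 groups")
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            stat, p, flagged = 0.0, 1.0, True
        else:
            stat, p = stats.kruskal(*groups)
            flagged = False
        labels = tuple(group_labels) if group_labels is not None else tuple(
            f"group{i + 1}" for i in range(len(groups))
        )
        results.append(
            GroupComparison(
                test="kruskal_wallis",
                feature=feature,
                statistic=float(stat),
                p_value=float(p),
                p_adjusted=None,
                group_labels=labels,
                n_per_group=tuple(len(g) for g in groups),
                method="rank H with tie correction",
                flagged=flagged,
            )
        )
        pvals.append(float(p))
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    return [
        dataclasses.replace(r, p_adjusted=float(q)) for r, q in zip(results, adjusted)
    ]


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    labels: tuple = ("a", "b"),
) -> GroupComparison:
    """Wilcoxon rank-sum (Mann-Whitney) test between two groups.

    Uses the exact null distribution for small samples without ties and the
    normal approximation with tie and continuity correction otherwise; the
    method used is recorded on the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and a.size + b.size <= 25:
        method = "exact"
    else:
        method = "asymptotic"
    stat, p = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return GroupComparison(
        test="wilcoxon",
        feature="",
        statistic=float(stat),
        p_value=float(p),
        p_adjusted=None,
        group_labels=tuple(labels),
        n_per_group=(a.size, b.size),
        method=method,
    )
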