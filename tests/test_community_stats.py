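import numpy as np
import pandas as pd
import pytest
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from biofilmvoxel import (
    AbundanceTable,
    bray_curtis,
    copy_number_correct,
    kruskal_wallis_bh,
    pcoa,
    permanova,
    wilcoxon_rank_sum,
)
from oracles import permanova_exhaustive_p, permanova_f

TAXA = ["Sr", "Pa", "Mo", "Xr"]
COPIES = {"Sr": 1.0, "Pa": 1.0, "Mo": 1.0, "Xr": 1.0}


def table_of(rows, copy_numbers=None, days=None):
    counts = pd.DataFrame(rows, columns=TAXA[: len(rows[0])],
                          index=[f"s{i}" for i in range(len(rows))])
    meta = None
    if days is not None:
        meta = pd.DataFrame({"day": days}, index=counts.index)
    cn = copy_numbers or {t: 1.0 for t in counts.columns}
    return AbundanceTable(counts=counts, copy_numbers=cn, metadata=meta)


class TestCopyNumberCorrect:
    def test_hand_arithmetic(self):
        table = table_of([[100, 100]], copy_numbers={"Sr": 1.0, "Pa": 2.0})
        rel = copy_number_correct(table)
        np.testing.assert_allclose(rel.counts.iloc[0].values, [2 / 3, 1 / 3])

    def test_unit_copy_numbers_are_plain_relative_abundance(self):
        table = table_of([[30, 10, 40, 20]])
        rel = copy_number_correct(table)
        np.testing.assert_allclose(rel.counts.iloc[0].values, [0.3, 0.1, 0.4, 0.2])

    def test_zero_total_sample_dropped(self):
        table = table_of([[10, 10], [0, 0]], copy_numbers={"Sr": 1.0, "Pa": 1.0})
        rel = copy_number_correct(table)
        assert list(rel.counts.index) == ["s0"]

    def test_idempotent_on_relative_tables(self):
        table = table_of([[0.25, 0.75], [0.5, 0.5]], copy_numbers={"Sr": 1, "Pa": 1})
        once = copy_number_correct(table)
        twice = copy_number_correct(once)
        np.testing.assert_allclose(once.counts.values, twice.counts.values)

    def test_missing_copy_number_errors(self):
        with pytest.raises(ValueError, match="copy numbers"):
            table_of([[1, 2]], copy_numbers={"Sr": 1.0})


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        dm = bray_curtis(table_of([[1, 2, 3], [1, 2, 3]]))
        assert dm[0, 1] == 0.0

    def test_disjoint_samples_one(self):
        dm = bray_curtis(table_of([[1, 0], [0, 1]]))
        assert dm[0, 1] == pytest.approx(1.0)

    def test_hand_value(self):
        dm = bray_curtis(table_of([[2, 1, 0], [1, 1, 1]]))
        assert dm[0, 1] == pytest.approx(1 / 3)

    def test_bounded_symmetric(self, rng):
        counts = rng.integers(0, 50, size=(6, 4)) + 1
        dm = bray_curtis(table_of(counts.tolist()))
        d = np.asarray(dm.data)
        assert np.all(d >= 0) and np.all(d <= 1)
        np.testing.assert_allclose(d, d.T)

    def test_two_all_zero_samples_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(table_of([[0, 0], [0, 0], [1, 2]]))


class TestPermanova:
    def small_dm(self, rng, effect=0.5):
        x = rng.random((6, 3))
        x[3:] += effect
        from scipy.spatial.distance import pdist, squareform
        return DistanceMatrix(squareform(pdist(x, "braycurtis")),
                              ids=[str(i) for i in range(6)])

    def test_exhaustive_p_matches_enumeration_oracle(self, rng):
        dm = self.small_dm(rng)
        groups = ["a", "a", "a", "b", "b", "b"]
        res = permanova(dm, groups, n_permutations=999)
        assert res.exhaustive
        p_oracle, n_arr = permanova_exhaustive_p(np.asarray(dm.data), groups)
        assert n_arr == 20
        assert res.p_value == pytest.approx(p_oracle)
        assert res.pseudo_f == pytest.approx(permanova_f(np.asarray(dm.data), groups))

    def test_r2_decomposition(self, rng):
        dm = self.small_dm(rng, effect=1.0)
        res = permanova(dm, ["a", "a", "a", "b", "b", "b"])
        assert 0 <= res.r2 <= 1
        # strong effect: most variance between groups
        assert res.r2 > 0.5

    def test_degenerate_all_identical(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = permanova(dm, ["x", "x", "y", "y"])
        assert res.r2 == 0.0 and res.p_value == 1.0

    def test_matches_skbio_pseudo_f(self, rng):
        """Independent cross-check of the observed statistic against scikit-bio."""
        x = rng.random((9, 4))
        x[3:6] += 0.3
        x[6:] += 0.6
        from scipy.spatial.distance import pdist, squareform
        dm = DistanceMatrix(squareform(pdist(x, "braycurtis")),
                            ids=[str(i) for i in range(9)])
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        mine = permanova(dm, groups, n_permutations=99, seed=0)
        ref = skbio_permanova(dm, grouping=groups, permutations=99)
        assert mine.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_single_group_errors(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(ValueError):
            permanova(dm, ["x", "x", "x"])


class TestPcoa:
    def test_points_on_a_line_recovered(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(d, ids=list("abc")))
        axis1 = res.coordinates.iloc[:, 0].values
        gaps = np.diff(np.sort(axis1))
        np.testing.assert_allclose(gaps, [1.0, 1.0], atol=1e-8)
        if res.eigenvalues.size > 1:
            assert abs(res.eigenvalues[1]) < 1e-8

    def test_euclidean_round_trip(self, rng):
        """Distances of recovered coordinates reproduce the input distances."""
        pts = rng.random((7, 2))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(7)]))
        d_rec = squareform(pdist(res.coordinates.values))
        np.testing.assert_allclose(d_rec, d, atol=1e-8)

    def test_identical_samples_zero_coordinates(self):
        dm = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        res = pcoa(dm)
        assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates.values, 0)

    def test_proportions_over_positive_eigenvalues(self, rng):
        counts = rng.integers(1, 50, size=(6, 4))
        dm = bray_curtis(table_of(counts.tolist()))
        res = pcoa(dm)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)  # decreasing
        assert res.proportion_explained.sum() <= 1 + 1e-9
        assert np.all(res.proportion_explained >= 0)

    def test_sign_convention_reproducible(self, rng):
        counts = rng.integers(1, 50, size=(5, 4))
        dm = bray_curtis(table_of(counts.tolist()))
        a = pcoa(dm).coordinates.values
        b = pcoa(dm).coordinates.values
        np.testing.assert_array_equal(a, b)
        for axis in range(a.shape[1]):
            nz = np.flatnonzero(np.abs(a[:, axis]) > 1e-12)
            if nz.size:
                assert a[nz[0], axis] > 0


class TestKruskalWallisBH:
    def test_maximal_separation_h(self):
        """Three fully separated groups of 3 attain the maximal H for n = 9.

        Rank means are 2, 5, 8, so H = 12/(9·10) · 3·[(2-5)² + 0 + (8-5)²] = 7.2.
        """
        res = kruskal_wallis_bh({"t": [[1, 2, 3], [10, 20, 30], [100, 200, 300]]})
        assert res[0].statistic == pytest.approx(7.2)

    def test_identical_groups_flagged_p1(self):
        res = kruskal_wallis_bh({"t": [[5, 5, 5], [5, 5, 5]]})
        assert res[0].p_value == 1.0 and res[0].flagged

    def test_bh_step_up_hand_case(self, monkeypatch):
        """p = (0.01, 0.02, 0.03, 0.04) all adjust to 0.04 under BH."""
        from biofilmvoxel import community_stats as cs
        raw = iter([0.01, 0.02, 0.03, 0.04])

        def fake_kruskal(*groups):
            return 1.0, next(raw)

        monkeypatch.setattr(cs.stats, "kruskal", fake_kruskal)
        res = kruskal_wallis_bh({t: [[1, 2], [3, 4]] for t in TAXA})
        assert [r.p_adjusted for r in res] == pytest.approx([0.04] * 4)

    def test_bh_monotone_never_decreases(self, rng):
        groups = {
            f"t{i}": [rng.normal(0, 1, 5), rng.normal(i * 0.4, 1, 5)] for i in range(6)
        }
        res = kruskal_wallis_bh(groups)
        for r in res:
            assert r.p_adjusted >= r.p_value - 1e-12
        order_p = np.argsort([r.p_value for r in res])
        adj_sorted = np.array([r.p_adjusted for r in res])[order_p]
        assert np.all(np.diff(adj_sorted) >= -1e-12)


class TestWilcoxonRankSum:
    def test_fully_separated_exact_one_sided(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.p_value == pytest.approx(1 / 20)
        assert res.method == "exact"

    def test_identical_groups_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_rank_invariance_under_monotone_transform(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.5, 1, 8)
        p1 = wilcoxon_rank_sum(a, b).p_value
        p2 = wilcoxon_rank_sum(np.exp(a), np.exp(b)).p_value
        assert p1 == pytest.approx(p2)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])
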