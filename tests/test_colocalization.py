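import numpy as np
import pytest

from biofilmvoxel import BinaryMask, colocalization_profile, summarize_replicates
from biofilmvoxel.colocalization import nearest_odd_bin, odd_bin_centers
from oracles import coloc_bruteforce

ISO = (1.0, 1.0, 1.0)


def mask_of(values, spacing=ISO, name="m"):
    return BinaryMask(np.asarray(values, dtype=bool), spacing, name)


class TestBinning:
    def test_51um_gives_26_odd_centers(self):
        centers = odd_bin_centers(51)
        assert centers.size == 26
        np.testing.assert_array_equal(centers, np.arange(1, 52, 2))

    def test_nearest_odd_ties_resolve_upward(self):
        # d = 0 -> 1; d = 2 (tie between 1 and 3) -> 3; d = 1.9 -> 1
        np.testing.assert_array_equal(
            nearest_odd_bin([0.0, 1.0, 1.9, 2.0, 2.1, 4.0, 51.9]),
            [1, 1, 1, 3, 3, 5, 51],
        )


class TestProfileAgainstBruteForce:
    @pytest.mark.parametrize("spacing", [ISO, (0.5, 0.25, 0.25)])
    def test_exhaustive_equals_all_pairs_oracle(self, rng, spacing):
        """Using every focal voxel, tallies equal the literal all-pairs scan."""
        focal = rng.random((8, 9, 10)) < 0.1
        target = rng.random((8, 9, 10)) < 0.25
        focal.ravel()[0] = True  # ensure non-empty
        max_dist = 5
        prof = colocalization_profile(
            mask_of(focal, spacing), mask_of(target, spacing),
            n_focal=10**9, max_dist_um=max_dist, n_runs=1, seed=0,
        )
        centers, tgt, tot = coloc_bruteforce(focal, target, spacing, max_dist)
        np.testing.assert_array_equal(prof.bin_centers_um, centers)
        np.testing.assert_array_equal(prof.counts[:, 0], tgt)
        np.testing.assert_array_equal(prof.counts[:, 1], tot)

    def test_single_center_focal_known_scatter(self):
        """One focal voxel at the center of a 12³ grid, hand-planted targets."""
        focal = np.zeros((12, 12, 12), dtype=bool)
        focal[6, 6, 6] = True
        target = np.zeros_like(focal)
        for pos in [(6, 6, 7), (6, 8, 6), (6, 6, 2), (1, 6, 6), (9, 9, 9)]:
            target[pos] = True
        prof = colocalization_profile(
            mask_of(focal), mask_of(target), n_focal=1, max_dist_um=9, n_runs=1, seed=0
        )
        centers, tgt, tot = coloc_bruteforce(focal, target, ISO, 9)
        np.testing.assert_allclose(
            prof.mean_proportion, np.where(tot > 0, tgt / np.maximum(tot, 1), np.nan)
        )


class TestDegenerateTargets:
    def test_saturated_target_gives_proportion_one(self, rng):
        focal = rng.random((6, 6, 6)) < 0.2
        focal[3, 3, 3] = True
        prof = colocalization_profile(
            mask_of(focal), mask_of(np.ones((6, 6, 6))), n_focal=5, max_dist_um=5,
            n_runs=2, seed=1,
        )
        filled = prof.counts[:, 1] > 0
        np.testing.assert_allclose(prof.mean_proportion[filled], 1.0)

    def test_empty_target_gives_proportion_zero(self, rng):
        focal = rng.random((6, 6, 6)) < 0.2
        focal[0, 0, 0] = True
        prof = colocalization_profile(
            mask_of(focal), mask_of(np.zeros((6, 6, 6))), n_focal=5, max_dist_um=5,
            n_runs=2, seed=1,
        )
        filled = prof.counts[:, 1] > 0
        np.testing.assert_allclose(prof.mean_proportion[filled], 0.0)

    def test_empty_focal_errors(self):
        with pytest.raises(ValueError, match="no foreground"):
            colocalization_profile(
                mask_of(np.zeros((3, 3, 3))), mask_of(np.ones((3, 3, 3))), n_focal=1
            )

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="congruent"):
            colocalization_profile(
                mask_of(np.ones((3, 3, 3))), mask_of(np.ones((3, 3, 4))), n_focal=1
            )

    def test_self_profile_includes_d0_self_count(self):
        """focal = target: the focal voxel itself lands in bin 1."""
        values = np.zeros((5, 5, 5), dtype=bool)
        values[2, 2, 2] = True
        prof = colocalization_profile(
            mask_of(values), mask_of(values), n_focal=1, max_dist_um=3, n_runs=1, seed=0
        )
        assert prof.counts[0, 0] == 1  # exactly the self voxel


class TestSamplingBehavior:
    def test_deterministic_given_seed(self, rng):
        focal = rng.random((8, 10, 10)) < 0.3
        target = rng.random((8, 10, 10)) < 0.2
        kwargs = dict(n_focal=20, max_dist_um=5, n_runs=3, seed=42)
        p1 = colocalization_profile(mask_of(focal), mask_of(target), **kwargs)
        p2 = colocalization_profile(mask_of(focal), mask_of(target), **kwargs)
        np.testing.assert_array_equal(p1.per_run_proportions, p2.per_run_proportions)

    def test_sampled_estimate_unbiased_and_variance_shrinks(self, rng):
        """Monte-Carlo: the sampled proportion converges on the exhaustive value."""
        focal = rng.random((10, 12, 12)) < 0.4
        target = rng.random((10, 12, 12)) < 0.15
        f, t = mask_of(focal), mask_of(target)
        exact = colocalization_profile(f, t, n_focal=10**9, max_dist_um=5,
                                       n_runs=1, seed=0).mean_proportion
        runs = 24
        small = colocalization_profile(f, t, n_focal=25, max_dist_um=5,
                                       n_runs=runs, seed=7).per_run_proportions
        large = colocalization_profile(f, t, n_focal=400, max_dist_um=5,
                                       n_runs=runs, seed=7).per_run_proportions
        for per_run in (small, large):
            mean = per_run.mean(axis=0)
            sem = per_run.std(axis=0, ddof=1) / np.sqrt(runs)
            assert np.all(np.abs(mean - exact) <= 3 * sem + 1e-12)
        # 16x more focal samples: per-run scatter must shrink
        assert large.std(axis=0).mean() < small.std(axis=0).mean()

    def test_null_scene_profile_is_flat(self, rng):
        """Target independent of focal: interior bins share one proportion."""
        focal = rng.random((16, 24, 24)) < 0.05
        target = rng.random((16, 24, 24)) < 0.10
        prof = colocalization_profile(mask_of(focal), mask_of(target),
                                      n_focal=10**9, max_dist_um=7, n_runs=1, seed=0)
        interior = slice(0, 3)  # bins 1, 3, 5 — away from edge-depleted tails
        tgt, tot = prof.counts[interior, 0], prof.counts[interior, 1]
        p = tgt.sum() / tot.sum()
        sigma = np.sqrt(p * (1 - p) / tot)
        assert np.all(np.abs(tgt / tot - p) < 4 * sigma + 0.005)

    def test_isotropic_scene_axis_permutation_invariant(self, rng):
        focal = rng.random((9, 9, 9)) < 0.15
        target = rng.random((9, 9, 9)) < 0.2
        base = colocalization_profile(mask_of(focal), mask_of(target),
                                      n_focal=10**9, max_dist_um=5, n_runs=1, seed=0)
        for axes in [(1, 2, 0), (2, 0, 1), (0, 2, 1)]:
            perm = colocalization_profile(
                mask_of(np.transpose(focal, axes)), mask_of(np.transpose(target, axes)),
                n_focal=10**9, max_dist_um=5, n_runs=1, seed=0)
            np.testing.assert_array_equal(base.counts, perm.counts)


class TestReplicateSummary:
    def make_profile(self, means, seed=0):
        focal = np.zeros((4, 4, 4), dtype=bool)
        focal[0, 0, 0] = True
        prof = colocalization_profile(mask_of(focal), mask_of(focal),
                                      n_focal=1, max_dist_um=3, n_runs=1, seed=seed)
        import dataclasses
        return dataclasses.replace(prof, mean_proportion=np.asarray(means, dtype=float))

    def test_identical_replicates_zero_sem(self):
        profs = [self.make_profile([0.5, 0.5]) for _ in range(3)]
        summary = summarize_replicates(profs)
        np.testing.assert_allclose(summary.sem, 0.0)
        np.testing.assert_allclose(summary.mean, 0.5)

    def test_closed_form_sem(self):
        profs = [self.make_profile([m, 0.0]) for m in (0.2, 0.4, 0.6)]
        summary = summarize_replicates(profs)
        assert summary.mean[0] == pytest.approx(0.4)
        assert summary.sem[0] == pytest.approx(0.2 / np.sqrt(3), rel=1e-12)

    def test_single_profile_errors(self):
        with pytest.raises(ValueError):
            summarize_replicates([self.make_profile([0.1, 0.1])])

    def test_mixed_species_pairs_rejected(self):
        import dataclasses
        a = self.make_profile([0.1, 0.1])
        b = dataclasses.replace(a, target="other")
        with pytest.raises(ValueError, match="species"):
            summarize_replicates([a, b])
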