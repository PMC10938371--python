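"""Measure how densely a target species occupies space around a focal species.

Plants target cells within 4 μm of the focal species' aggregate surfaces and
computes the co-localization profile: the proportion of voxels occupied by
the target in odd-integer distance bins (1, 3, 5, ... μm) around sampled
focal voxels. Short-range enrichment shows as high occupancy in the first
bins that decays toward the flat background level.
"""

from biofilmvoxel import (
    BinaryMask,
    SpeciesPlan,
    SyntheticSceneSpec,
    colocalization_profile,
    generate_scene,
)

spec = SyntheticSceneSpec(
    shape=(24, 64, 64),
    spacing_um=(0.5, 0.25, 0.25),
    species=(
        SpeciesPlan("Pa", n_aggregates=5, radius_um=1.5, min_gap_um=3.0),
        SpeciesPlan("Xr", placement=("near", "Pa", 4.0), n_cells=200),
    ),
    seed=23,
)
_, truth = generate_scene(spec)
focal = BinaryMask(truth.masks["Pa"], spec.spacing_um, "Pa")
target = BinaryMask(truth.masks["Xr"], spec.spacing_um, "Xr")

profile = colocalization_profile(
    focal, target, n_focal=1000, max_dist_um=15, n_runs=5, seed=3
)
print("distance bin (um) -> mean target occupancy over 5 runs")
for center, prop in zip(profile.bin_centers_um, profile.mean_proportion):
    bar = "#" * int(prop * 400)
    print(f"  {center:2d}  {prop:.4f}  {bar}")
# Targets were planted within 4 um of the focal aggregates, so occupancy is
# highest in the 1-3 um bins and falls to near zero beyond ~10 um.
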