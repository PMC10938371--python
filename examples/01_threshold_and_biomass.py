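"""Binarize a fluorescence channel and quantify its bio-volume.

Builds a synthetic FISH-like scene, renders one species as a noisy intensity
channel, thresholds it with the maximum-entropy criterion, and reports the
bio-volume (foreground voxels x physical voxel volume, in μm³) next to the
planted ground truth.
"""

import numpy as np

from biofilmvoxel import (
    BinaryMask,
    SpeciesPlan,
    SyntheticSceneSpec,
    binarize,
    biomass_volume,
    generate_intensity,
    generate_scene,
    max_entropy_threshold,
)

spec = SyntheticSceneSpec(
    shape=(24, 64, 64),
    spacing_um=(0.5, 202.83 / 1024, 202.83 / 1024),  # FISH acquisition geometry
    species=(SpeciesPlan("Pa", n_aggregates=5, radius_um=1.2, min_gap_um=2.0),),
    seed=7,
)
_, truth = generate_scene(spec)
mask = BinaryMask(truth.masks["Pa"], spec.spacing_um, "Pa")
grid = generate_intensity(mask, seed=7)  # dark-background confocal noise model

result = max_entropy_threshold(grid, n_bins=256)
recovered = binarize(grid, result.threshold)
record = biomass_volume(recovered)
true_voxels = int(mask.values.sum())

print(f"max-entropy threshold: {result.threshold:.1f} (256-bin histogram)")
print(f"voxel volume: {record.voxel_volume_um3:.4f} um^3 (dz*dy*dx)")
print(f"bio-volume: {record.biomass_um3:.2f} um^3 from {record.voxel_count} voxels")
print(f"planted foreground: {true_voxels} voxels "
      f"({100 * np.mean(recovered.values != mask.values):.3f}% voxel error)")
# The bio-volume is the abundance measure used per species per image; with a
# well-separated intensity model the thresholding path recovers the planted
# voxel count to a fraction of a percent.
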