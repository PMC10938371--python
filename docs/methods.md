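# Methods

This note documents the models and procedures implemented in `biofilmvoxel`,
the parameters that matter, the numerical conventions, and what the synthetic
benchmarks do and do not demonstrate.

## Voxel geometry

All spatial data live on 3D lattices in (z, y, x) order with per-axis
physical edge lengths in μm, declared by the user (TIFF voxel-size metadata
dialects are too inconsistent to parse reliably). Anisotropy is the normal
case: confocal slice thickness (dz = 0.5 μm) differs from the in-plane pixel
pitch (field of view / pixel count; 404.63 μm / 1430 px ≈ 0.283 μm for
whole-community staining, 202.83 μm / 1024 px ≈ 0.198 μm for FISH). The voxel
volume dz·dy·dx (≈ 0.04 and ≈ 0.02 μm³ for those two geometries) is always
computed from spacing, never hard-coded. Multi-page TIFFs may interleave
channels fastest (page = z·C + c, default) or z fastest; both are supported.

## Maximum-entropy thresholding

Binarization uses Kapur's criterion on a 256-bin histogram spanning
[min, max] of the full 3D volume: choose the bin edge *t* maximizing
H_bg(t) + H_fg(t), the Shannon entropies of the renormalized histogram
partitions at/below and strictly above *t*. Empty bins contribute zero
entropy (0·log 0 := 0); ties break toward the lower threshold; foreground is
*strictly above* the threshold. Thresholding the whole volume (rather than
per slice, which is also provided) keeps derived bio-volumes independent of
slice ordering. The implementation is a vectorized cumulative-sum scan; the
test suite checks it bin-for-bin against a literal per-candidate entropy
evaluation.

A practical caveat that the synthetic noise model (below) respects: on a
histogram whose dominant class is a wide mid-range Gaussian, entropy
maximization places the cut ~2σ inside that class's tail — the mixing-entropy
gain of moving a little tail mass into the smaller partition outweighs the
loss — so a percent-scale voxel fraction is misclassified *no matter how far
apart the class means are*. Max-entropy thresholding is reliable when the
background is dark and narrow (a few gray levels of read noise above the
detector floor), which is the regime real confocal fluorescence images
occupy.

## Bio-volume

A species' biomass volume is foreground voxel count × voxel volume (μm³).
No connectivity or size filtering happens at this stage. Per-stack batch
quantification reports per-channel records plus (optionally) the union, which
equals the sum only when channels are disjoint.

## 3D co-localization profiles

The statistic asks: what proportion of the volume at distance *d* from the
focal species is occupied by the target species?

Per run, `n_focal` (default 1000) focal voxels are sampled uniformly
*without replacement* (when the focal population is smaller, every voxel is
used once — which makes the exhaustive all-pairs computation a special case
of the sampled one, and is why the oracle tests can demand exact equality).
Every voxel within `max_dist_um` (default 51) of a sampled focal voxel joins
the distance bin whose odd-integer center (1, 3, …) is nearest; distances are
physical Euclidean with per-axis spacing. Nearest-odd binning is
b(d) = 2·⌊d/2⌋ + 1: exact-even ties resolve upward, d = 0 (the focal voxel
itself) maps to bin 1 — inert when focal ≠ target, a documented constant
self-count when focal = target. A distance belongs to the profile iff its
nearest odd center is ≤ the last bin center (so the 51-centered bin collects
d < 52). Out-of-bounds voxels near image edges simply do not exist: totals
shrink, no padding or mirroring.

Counts pool over focal voxels *before* division (pooled proportion, not
per-focal averaging). The analysis repeats `n_runs` (default 5) times with
run r seeded seed + r; the profile is the mean over runs. Biological
replicates are summarized per bin by mean and SEM = sd/√n of the replicate
means. With the default 51 μm cap there are exactly 26 bins.

## Cell aggregates

Aggregates are maximal chain-connected sets of foreground voxels under an
odd adjacency window: (3, 3, 3) ⇒ 26-connectivity (the default and the only
window used in the benchmarks; wider odd windows are supported via a BFS
fallback). Labeling uses `scipy.ndimage.label`, relabeled so ids follow
raster-scan order of each component's first voxel. Sizes are physical
volumes; summaries count aggregates *strictly* larger than the threshold
(default 10 μm³ — at FISH geometry, 400 voxels ≈ 7.9 μm³ is dropped and
600 voxels ≈ 11.8 μm³ is kept), and the mean retained volume is computed
over the retained set only. An empty retained set is a flagged summary
(mean = None), not an error. No hole-filling or watershed splitting:
grouping is purely by adjacency.

## Community statistics

Counts are divided by per-taxon 16S rRNA gene copy numbers (a required user
input — copy numbers are strain-specific knowledge with no sensible default)
and renormalized to relative abundance; zero-total samples are logged and
dropped. Bray–Curtis dissimilarity comes from `scipy.spatial.distance`;
PCoA wraps `skbio.stats.ordination.pcoa` with a deterministic sign convention
(first nonzero loading of each axis positive) and explained proportions
computed over positive eigenvalues only, negatives reported.

PERMANOVA is implemented in-package because the contract requires exhaustive
enumeration on small designs: with squared distances d²ᵢⱼ,
SS_total = Σᵢ<ⱼ d²ᵢⱼ/n, SS_within = Σ_g (Σᵢ<ⱼ∈g d²ᵢⱼ)/n_g, and
pseudo-F = [SS_between/(a−1)]/[SS_within/(n−a)]. When the number of distinct
label arrangements is ≤ the requested permutation count the arrangement set
is enumerated and p is the exact tail probability (identity included);
otherwise p = (1 + #exceedances)/(1 + n_permutations), so a Monte-Carlo p is
never 0. Permutation F-statistics are evaluated in vectorized batches, which
makes the 1000-table null calibration run in seconds. `scikit-bio`'s
PERMANOVA serves as an independent cross-check in the tests, never as the
implementation. All-coincident samples are a degenerate case returning
R² = 0, p = 1.

Kruskal–Wallis (tie-corrected H, via `scipy.stats`) is adjusted with
Benjamini–Hochberg across exactly the family of taxa passed in one call —
family membership is explicit, never implicit. Features identical across all
groups return H = 0, p = 1, flagged. The Wilcoxon rank-sum test uses the
exact null for pooled n ≤ 25 without ties, otherwise the tie/continuity-
corrected normal approximation; the method used is recorded on the result.

## qPCR arithmetic

copies/μl = conc(ng/μl) · 6.022×10²³ / (length(bp) · 10⁹ · m_bp). The
default m_bp is 650 Da per bp — the constant used in the copy-number
equation of common qPCR calculators — while 660 Da is the other widely
quoted average; both are available and the choice travels with the constants
object. Standard curves are least-squares fits Ct = a + b·log₁₀(copies);
efficiency = 10^(−1/b) − 1 (b = −3.3219 ⇔ 100%); unknowns are interpolated
from the fitted line even when a Ct coincides with a standard, and
extrapolation beyond the standards' Ct range warns. Percent increases are
computed on group medians and reported to one decimal.

## Synthetic data: what it emulates, and what it does not

Scenes are flat slabs of anisotropic voxels with spherical aggregates
rasterized at physical radii — spheres because their voxelized volumes are
analytically checkable, and every rasterized sphere is (3,3,3)-connected.
Species channels are disjoint by construction (overlap candidates are
redrawn). Co-localization structure is planted by placing single-voxel
target cells at distances to the nearest focal aggregate *surface* drawn
uniformly from [0, r_max], so the expected profile shape — enriched in bins
≤ r_max, flat beyond — is known by construction. Ground truth equals the
emitted masks voxel for voxel.

Intensity images put Gaussian noise around a dark background mean
(default 3 ± 1.5 gray levels, emulating read noise above the detector
floor) and a bright foreground (180 ± 20, emulating photon noise), rounded
to integer gray levels: ~9σ mean separation relative to the wider class. In
this regime the thresholding path recovers planted masks to ≤ 0.1% voxel
error across foreground fractions from a few to tens of percent. This is a
deliberate modeling choice — see the thresholding caveat above for why a
wide mid-range background cannot meet that bound under entropy maximization.

Count tables are Dirichlet-multinomial draws around per-day expected
compositions (precision parameter `dispersion`; ∞ gives a pure multinomial);
phenotypes are drawn symmetrically about planted medians so sample medians
converge to the targets.

What passing these benchmarks does *not* show about real data: no optical
PSF, root autofluorescence, curved root geometry, stitching seams, chromatic
shift, or sequencing artifacts (chimeras, contamination) are simulated.
Recovery on planted spheres bounds algorithmic correctness, not robustness
to acquisition pathology.

## Benchmark problem sizes and numerical conventions

The shipped benchmarks use scenes of 24×64×64 voxels at FISH-like spacing
(0.5, 0.25, 0.25) μm with 5 planted aggregates of radius 1.5 μm and 200
planted target cells within 4 μm; co-localization oracle checks run on
≤ 12³-scale grids where the literal all-pairs scan is exact and fast; the
PERMANOVA null calibration uses 1000 tables of 9 samples (3 days × 3
replicates, depth 2000) with 199 permutations each, giving p-value
granularity 1/200 so the nominal 0.05 level is attainable exactly. Seeds
propagate explicitly: scene/table/phenotype generators take a seed, the
co-localization runs use seed + r, and PERMANOVA permutations use the
caller's seed.

Tie-breaks and degenerate inputs, collected: thresholding ties go to the
lower candidate and constant images are errors; nearest-odd distance ties go
upward; aggregates at exactly the volume threshold are excluded; empty
retained aggregate sets are flagged, not errors; zero-total community
samples are dropped with a warning; two all-zero samples make Bray–Curtis
undefined (error); PERMANOVA on coincident samples returns R² = 0, p = 1;
identical groups give p = 1 in both rank tests; zero-slope standard curves
cannot be interpolated.

## Known limitations

- Stitching of tiled acquisitions, OME/proprietary formats, and metadata
  parsing are out of scope; geometry is declared by the caller.
- The co-localization kernel holds all offsets within the distance cap in
  memory; at 51 μm on sub-0.2 μm pitch that is large — profiles at full
  printed geometry are batch jobs, not interactive calls.
- PERMANOVA supports one-way designs only (free permutation), matching
  single-factor use on sampling day.
- Aggregate counts are reported per image with the image footprint logged;
  no rescaling to a nominal reference area is applied.
- The max-entropy misclassification caveat above applies to any image whose
  background is wide and mid-range; inspect thresholds (they are logged and
  reported) before trusting bio-volumes on unusual data.
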