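# biofilmvoxel

Voxel-level quantification and spatial statistics for multispecies biofilms
on plant roots imaged by confocal laser scanning microscopy (CLSM), with or
without species-specific FISH labeling.

## Who this is for

Microbial ecologists studying synthetic communities on the rhizoplane — for
example a four-species consortium (*S. rhizophila*, *P. amylolyticus*,
*M. oxydans*, *X. retroflexus*) colonizing *Arabidopsis* roots — who need to
turn multi-channel 3D z-stacks and companion count/qPCR/phenotype tables into
per-species abundances, spatial interaction profiles, and community
statistics. All inputs are plain formats (multi-page TIFF, CSV, YAML), all
outputs are diffable CSV.

## What it computes

**Bio-volume.** Each channel is binarized with the maximum-entropy (Kapur)
criterion: the threshold *t* maximizing H_bg(t) + H_fg(t), the Shannon
entropies of the normalized histogram partitions at/below and strictly above
*t*. The species' bio-volume is then

&nbsp;&nbsp;&nbsp;&nbsp;V = N_fg · dz·dy·dx  (μm³),

with the voxel edge lengths taken from the acquisition geometry (e.g.
0.5 μm slices at 202.83 μm / 1024 px pitch ⇒ ≈ 0.02 μm³ per voxel).

**3D co-localization.** For a focal species F and target species T, sample
n = 1000 focal voxels uniformly; every voxel within 51 μm (physical Euclidean
distance, anisotropy respected) of a sampled focal voxel joins the distance
bin with the nearest odd-integer center (1, 3, …, 51 μm); per bin the pooled
proportion of target-occupied voxels is reported. The analysis is repeated
5 times (reseeded deterministically) and averaged; biological replicates are
summarized by mean ± SEM per bin.

**Cell aggregates.** Connected components of a species mask under a 3×3×3
adjacency window (26-connectivity), sized in μm³, counted after discarding
aggregates not strictly larger than 10 μm³.

**Community statistics.** 16S-copy-number-corrected relative abundances,
Bray–Curtis dissimilarity d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), PCoA (classical
scaling, negative eigenvalues reported), one-way PERMANOVA
(pseudo-F = [SS_between/(a−1)] / [SS_within/(n−a)], permutation p-value with
exhaustive enumeration on small designs), Kruskal–Wallis with
Benjamini–Hochberg FDR across the taxon family, and the Wilcoxon rank-sum
test (exact for small untied samples).

**qPCR arithmetic.** copies/μl = conc(ng/μl) · N_A / (length(bp) · 10⁹ · 650),
standard-curve fitting Ct = a + b·log₁₀(copies) with efficiency
10^(−1/b) − 1, Ct interpolation, per-root-length normalization, and
percent-increase effect sizes on group medians.

**Synthetic scenes.** Every input can be generated with planted ground truth
(spherical aggregates at physical radii, targets planted at controlled
distances from focal aggregate surfaces, Dirichlet-multinomial count tables,
phenotype samples with planted medians), so the whole chain is testable
without any acquired data.

## Worked example

```bash
python examples/02_colocalization.py
```

prints, for a scene with target cells planted within 4 μm of the focal
species' aggregate surfaces:

```
distance bin (um) -> mean target occupancy over 5 runs
   1  0.0045  #
   3  0.0040  #
   5  0.0022
   7  0.0017
   9  0.0018
  11  0.0021
  13  0.0021
  15  0.0014
```

Occupancy is highest in the 1–3 μm bins and decays to the background level
beyond ~5–10 μm: the short-range enrichment planted into the scene is
recovered as a peaked co-localization profile. The other examples cover
thresholding + bio-volume (`01`), aggregate detection (`03`), community
statistics (`04`, printing e.g. `PERMANOVA on day: pseudo-F = 46.92,
R2 = 0.940, p = 0.006`), qPCR (`05`), and the full YAML-driven pipeline
(`06`). A thin CLI wraps the same calls:

```bash
biofilmvoxel threshold --input stack.tif --spacing 0.5,0.198,0.198 \
    --channels Pa,Mo,Sr,Xr --bins 256 --out-dir masks/
biofilmvoxel coloc --focal masks/Pa_mask.tif --target masks/Xr_mask.tif \
    --spacing 0.5,0.198,0.198 --n-focal 1000 --max-dist 51 --runs 5 \
    --seed 17 --out profile.csv
biofilmvoxel run --config run.yaml
```

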