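"""Community composition dynamics: copy-number correction, Bray-Curtis,
PERMANOVA and per-taxon rank tests.

Simulates a four-taxon count table whose composition shifts across three
sampling days (one taxon rising from 16% to 35%, mirroring a keystone
species' trajectory), corrects counts by 16S copy numbers, and asks whether
time structures the community.
"""

from biofilmvoxel import (
    bray_curtis,
    copy_number_correct,
    generate_abundance_table,
    kruskal_wallis_bh,
    pcoa,
    permanova,
)

TAXA = ["Sr", "Pa", "Mo", "Xr"]
COPY_NUMBERS = {"Sr": 5.0, "Pa": 10.0, "Mo": 2.0, "Xr": 4.0}
DAY_PROFILES = {
    5: [0.55, 0.16, 0.17, 0.12],
    10: [0.40, 0.28, 0.17, 0.15],
    15: [0.25, 0.35, 0.22, 0.18],
}

table = generate_abundance_table(
    DAY_PROFILES, TAXA, COPY_NUMBERS, dispersion=500, depth=10_000,
    n_replicates=3, seed=11,
)
relative = copy_number_correct(table)
dm = bray_curtis(relative)
result = permanova(dm, relative.metadata["day"].values, n_permutations=999, seed=11)
ordination = pcoa(dm)

print("mean relative abundance per day (after copy-number correction):")
print(relative.counts.groupby(relative.metadata["day"]).mean().round(3))
print(f"\nPERMANOVA on day: pseudo-F = {result.pseudo_f:.2f}, "
      f"R2 = {result.r2:.3f}, p = {result.p_value:.3f} "
      f"({result.n_permutations} permutations)")
print(f"PCoA axis 1 explains {100 * ordination.proportion_explained[0]:.1f}% "
      "of the positive-eigenvalue variance")

grouped = {
    taxon: [relative.counts.loc[relative.metadata["day"] == d, taxon].values
            for d in (5, 10, 15)]
    for taxon in TAXA
}
print("\nKruskal-Wallis per taxon (BH-adjusted across the 4-taxon family):")
for r in kruskal_wallis_bh(grouped, group_labels=["D5", "D10", "D15"]):
    print(f"  {r.feature}: H = {r.statistic:.2f}, p = {r.p_value:.4f}, "
          f"q = {r.p_adjusted:.4f}")
# A large R2 with small p says sampling day explains most of the
# between-sample Bray-Curtis variance — the planted composition shift is
# recovered as a significant temporal succession.
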