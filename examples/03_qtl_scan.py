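"""Genome scan for a spot-density QTL with a permutation threshold.

Simulates a cohort carrying one QTL (20% of phenotypic variance on LG2 at
50 cM), reconstructs haplotypes, computes position-wise IBD matrices, and
compares the QTL model y = Xb + a + q + e against the polygenic model at
every grid position by restricted likelihood ratio.  Genome-wide
significance comes from within-family phenotype permutations
(Churchill-Doerge).  Finally the offspring of one informative parent are
split by inherited haplotype to show the allele contrast at the peak.
"""

from salmospot import (
    CohortSpec,
    allele_contrast,
    phase_offspring,
    scan_genome,
    simulate_cohort,
)

spec = CohortSpec(
    strains=("Mowi", "Figgjo"),
    n_families_per_cross=10,
    n_offspring_per_family=20,
    variance_fractions=(0.05, 0.15, 0.20, 0.60),
    qtl_group="LG2",
    qtl_position_cM=50.0,
    seed=11,
)
cohort, pedigree, genotypes, truth = simulate_cohort(spec)

result = scan_genome(
    cohort, pedigree, genotypes, trait="spot_density",
    step_cM=None, n_perm=200, alpha=0.05, seed=1,
)
print(result.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    f"\ntop hit: {result.top_linkage_group} @ {result.top_position_cM:g} cM, "
    f"LRT = {result.top_lrt:.2f}"
)
print(
    f"genome-wide 5% threshold = {result.threshold:.2f} "
    f"(200 permutations), p = {result.genomewide_p:.3f}, "
    f"significant: {result.significant}"
)

# allele contrast at the peak for the first parent informative there
assignment = phase_offspring(pedigree, genotypes)
parents = pedigree.table.loc[pedigree.table["sire"] != "", "sire"].unique()
contrast = sire = None
for candidate in parents:
    try:
        contrast = allele_contrast(
            assignment, cohort, pedigree, candidate,
            result.top_linkage_group, result.top_position_cM,
        )
        sire = candidate
        break
    except ValueError:  # parent homozygous / unresolved near the peak
        continue
print(f"\noffspring of {sire} split by inherited haplotype at the peak:")
print(contrast.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    "\nThe LRT profile peaks on the linkage group carrying the simulated "
    "QTL; the haplotype groups differ in mean spot density by roughly the "
    "planted allele effect."
)
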