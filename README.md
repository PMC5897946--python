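# salmospot

Quantitative analysis of skin-spot patterns in Atlantic salmon (*Salmo
salar*): standardized image-based spot counting, nearest-neighbour
clustering statistics, and pedigree-based variance-component QTL mapping
with permutation significance thresholds.

## Who this is for

Researchers studying pigmentation phenotypes in salmonids (or comparable
common-garden designs) who need to go from photographs and pedigrees to
heritability estimates and QTL scans, and anyone who wants a fully
simulatable, testable reference implementation of that analysis chain.
Every stage can run on synthetic data with known ground truth, so the whole
pipeline is verifiable without access to any original photographs.

## What it computes

**Spot quantification.** A standardized rectangular region of interest
(ROI) is anchored to anatomical landmarks: it spans from the gill crease to
the front of the dorsal fin, initially from the lateral line down to the top
of the pectoral fin, and is then re-centred vertically on the lateral line.
Spots are dark connected components (8-connectivity, Otsu or fixed
threshold) inside the ROI; counts are normalised by ROI area into spot
densities (spots/cm²). Fish with no spots are excluded from density
analyses, fish with fewer than 10 spots from clustering analyses, and
single-member families from family models.

**Spot clustering.** The Clark–Evans average-nearest-neighbour ratio

    R = mean_i min_{j≠i} d(i,j) / (0.5 / sqrt(n / A)),

the mean nearest-neighbour distance divided by its expectation under
complete spatial randomness in a window of area A. R < 1 indicates
clustering, R > 1 over-dispersion. No edge correction by default; a
Donnelly-corrected variant is available for sensitivity analysis.

**Genetics.** The QTL model at a genomic position is the Gaussian mixed
model

    y = Xβ + a + q + e,   a ~ N(0, σ²_a A),   q ~ N(0, σ²_q Π(pos)),

where A is the pedigree numerator relationship matrix and Π(pos) the
identity-by-descent matrix at the position, built from nuclear-family
haplotype reconstruction and a two-state Markov model of parental origin
under Haldane recombination. The scan statistic is the restricted
likelihood ratio against the polygenic model `y = Xβ + a + e`; genome-wide
significance comes from within-family phenotype permutations
(Churchill–Doerge). Heritability is `h² = σ²_a / (σ²_a + σ²_q + σ²_e)`, and
the QTL's contribution is reported as a fraction of the genetic and of the
total variance. All variance components are fitted by REML with a
block-factorised, batch-vectorised evaluator (see `docs/methods.md`).

**Group statistics.** Per-strain summaries, strain/family variance shares
(random-effects model), Welch t / Mann–Whitney / Kruskal–Wallis tests,
one-way ANOVA R², and fold-difference rendering ("sevenfold", "6.5-fold").

## Worked example

```python
from salmospot import (CohortSpec, simulate_cohort, scan_genome,
                       additive_relationship, fit_vc_model, heritability)
from salmospot.scan import design_matrix

spec = CohortSpec(strains=("Mowi", "Figgjo"), n_families_per_cross=10,
                  n_offspring_per_family=20,
                  variance_fractions=(0.05, 0.15, 0.20, 0.60),
                  qtl_group="LG2", qtl_position_cM=50.0, seed=11)
cohort, pedigree, genotypes, truth = simulate_cohort(spec)

result = scan_genome(cohort, pedigree, genotypes, step_cM=None,
                     n_perm=200, alpha=0.05, seed=1)
print(result.top_linkage_group, result.top_position_cM, result.top_lrt)
print(result.threshold, result.genomewide_p)
```

Output (seed 11):

```
LG2 25.0 7.04
6.68 0.040
```

The scan's peak restricted-likelihood-ratio (7.04) lands on the linkage
group carrying the simulated QTL and exceeds the genome-wide 5% permutation
threshold (6.68), i.e. the QTL is detected at genome-wide p = 0.040. The
`examples/` directory has one narrative script per capability: image
quantification and ANN clustering (`01`), heritability (`02`), the QTL scan
with allele contrasts (`03`) and group statistics (`04`); each prints the
numbers it computes with a line on what they mean.

A thin CLI mirrors the library for shell pipelines:

```bash
salmospot simulate cohort --out runs/demo --seed 7
salmospot scan-qtl --pheno runs/demo/cohort.csv --geno runs/demo/genotypes.csv \
    --map runs/demo/map.tsv --pedigree runs/demo/pedigree.csv \
    --trait spot_density --n-perm 200 --out runs/demo/scan
salmospot run --config config.yaml --out runs/full --seed 7
```

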