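# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the package. Everything stated here is computed by the test
suite or the example scripts; nothing is quoted from external data.

## Spot quantification

The ROI is a half-open pixel rectangle `[x0, x1) × [y0, y1)` built from four
landmarks: horizontally from the gill crease to the front of the dorsal
fin; vertically the landmark rectangle runs from the lateral line down to
the top of the pectoral fin, and the final ROI keeps that height but is
translated so its vertical midline is the lateral line (integer division
for the half-height; the renderer emits even ROI heights so the synthetic
round trip is exact). The lateral line is treated as horizontal within the
ROI span; body curvature is out of scope. No clipping is ever performed —
landmarks implying an out-of-bounds ROI are an error, because silently
shrinking the window would bias densities.

Spot detection converts to grayscale, binarises with Otsu's threshold
computed on the ROI histogram (spots are the dark phase; a fixed threshold
can be supplied when a study calibrates one), labels 8-connected
components, and discards components smaller than `min_area_cm2`
(default 0.005 cm², configurable — a particle filter against pixel noise).
Physical units come from one isotropic scale (cm/pixel) per image.
Touching spots merge into one component by construction; this matches
particle-analysis behaviour and slightly undercounts dense patterns.

Exclusion rules are applied per analysis, each drop logged with its reason:
zero-spot fish for density analyses (the measurement presupposes spots),
fewer than 10 spots for nearest-neighbour clustering (at low counts the
spacing of spots is dominated by chance), and single-member families for
family models (no within-family contrast).

## Average nearest neighbour (Clark–Evans) ratio

`R = mean nearest-neighbour distance / (0.5 / sqrt(n / A))` with A the ROI
window area (the measurement geometry), not the convex hull. The default
applies **no edge correction**: near-boundary points have censored
neighbours, which biases R upward by a few percent at n ≈ 50–100; this is
deliberate so that values are comparable with the common uncorrected usage,
and a Donnelly-corrected expectation is available behind a flag for
sensitivity analysis. Classification labels (clustered / random /
scattered) are descriptive, with the tolerance around 1 set to 0 — ratios
are reported raw and the labels carry no inferential weight.

## Synthetic data generators

**Point patterns.** Three processes span the observed regimes: homogeneous
Poisson (complete spatial randomness), Thomas cluster process (Poisson
parents on a window expanded by 4 cluster-sd to avoid edge thinning;
Poisson offspring counts; isotropic Gaussian dispersal) for the clustered,
river-type phenotype, and simple sequential inhibition (hard-core) for the
scattered, hatchery-type phenotype. Default intensities follow the two
regimes (≈1.5 spots/cm² scattered, lower effective density clustered). The
hard-core sampler retries placement up to 200× the target count and returns
the accepted points if the window saturates. These processes are test
fixtures spanning the observed clustering directions, not claims about the
biological mechanism of pattern formation.

**Images.** Spots render as dark disks (intensity 35 on a 210 background)
with optional Gaussian radius jitter and pixel noise; landmarks are
embedded so the standardized ROI reconstruction recovers exactly the
pattern window, tying detector output to simulation truth. Noise-free
images round-trip losslessly through PNG.

**Pedigree and genotypes.** Two-generation multi-strain crosses;
`half_sib=True` (default) mates each sire to two dams so adjacent families
share a father — the half-sib structure that powers variance-component
mapping. Founder SNP alleles are drawn from given frequencies (default
0.5, the most informative choice for a biallelic panel); transmission
follows a per-linkage-group Markov chain with Haldane recombination
`r = (1 − exp(−2d/100))/2` between adjacent markers (no interference — the
simplest model consistent with a sparse 20–30 cM map). Every meiosis's
parental origin is recorded as simulation truth. The default map is 3
linkage groups × 4 markers at 25 cM spacing, a desk-scale stand-in for a
sparse genome-wide panel.

**Phenotypes.** `y = mean + strain + u + q + e` with founder breeding
values N(0, σ²_a), offspring = parent average + Mendelian sampling
N(0, σ²_a/2) (exact for non-inbred parents), and iid residuals. Strain
effects are fixed shifts if supplied, otherwise drawn once per cohort from
N(0, v_strain). Variance fractions (strain, polygenic, QTL, residual) must
sum to 1; defaults put the trait on the hatchery spot-density scale
(mean 1.5, sd ≈ 0.83 spots/cm²) — all estimators are location/scale
equivariant, so this is cosmetic.

The QTL is a **hidden causal locus**: its founder alleles are drawn
independently of the marker panel and its meiotic origins are sampled
conditionally on the recorded origins at the colocated/flanking markers.
By default it sits exactly on a marker, so descent at the QTL is as
informative as the panel allows, but the causal alleles remain unobserved —
as for a real QTL tagged by markers. (Making the QTL *be* a genotyped
marker couples allele states across families beyond descent sharing and
inflates the estimated QTL variance; the hidden-locus design keeps the
IBD mixed model correctly specified.) The allelic effect is scaled so the
realized QTL variance matches the requested fraction. The true
narrow-sense heritability implied by a spec counts the QTL as additive
variance: `h² = (v_a + v_q)/(v_a + v_q + v_e)`, with strain a fixed effect
and hence outside the denominator.

## Haplotype reconstruction and IBD

For each meiosis and marker the transmitted allele of a parent is resolved
where genotypes permit: homozygous parents always transmit their allele
(but are uninformative about *which* haplotype travelled); a heterozygous
parent's transmission is resolved when the offspring is homozygous, or
heterozygous with a homozygous mate. Double-heterozygous matings with
heterozygous offspring are treated as uninformative (0.5) rather than
propagating the partial sire/dam anti-correlation — a standard
simplification that loses a little information. Mendelian inconsistencies
are flagged, logged, and the marker set uninformative for that meiosis.

With phased input the parent haplotypes are taken as given. With unphased
dosages each parent's haplotypes are reconstructed by majority linkage:
consecutive heterozygous markers are phased so that the parent's resolved
transmissions across all of its offspring imply the fewest recombinations.
Phase is arbitrary up to a flip per parent and linkage group, which cancels
in all IBD quantities.

Origin probabilities at any position follow the exact two-state Markov
posterior given the nearest informative flanking markers (products of
Haldane non-recombination probabilities, 0.5 when no informative marker
exists on the group). The IBD matrix at a position has unit diagonal,
parent–offspring entries of exactly 0.5, and, for each pair of offspring
and each shared parent, a contribution `0.5 × (p_i p_j + (1−p_i)(1−p_j))`
— the probability both inherited the same parental haplotype. Founders are
assumed unrelated and non-inbred; the construction is defined for
two-generation pedigrees and refuses deeper ones. Entries are **expected**
sharing given marker data, so the matrix is a posterior-mean (soft) IBD;
its calibration (E[realized share | expected share] = expected share) is
verified by simulation in the test suite.

## REML with arbitrary covariance structures

The mixed model `y = Xβ + Σ_k u_k + e`, `u_k ~ N(0, σ²_k S_k)`, is fitted by
restricted maximum likelihood. The residual variance is profiled out,
leaving the variance ratios λ_k = σ²_k/σ²_e, optimised on the log scale
over [e⁻¹⁸, e⁹] by Nelder–Mead; ratios landing on the lower clamp are
snapped to 0 (boundary estimates are expected and legitimate — e.g. a null
QTL). The profiled restricted log-likelihood is

    −½ [ log|K| + log|XᵀK⁻¹X| + (n−p)(1 + log 2πσ̂²) ],
    K = I + Σ_k λ_k S_k,   σ̂² = yᵀPy/(n−p).

Implementation choices that matter:

* The combined support of the structures is split into connected components
  (families and half-sib clusters), so each likelihood evaluation factors
  into many small Cholesky problems instead of one n×n factorisation.
* All linear algebra is batched over blocks **and** over phenotype columns,
  each column carrying its own parameters. A genome scan over hundreds of
  permutations advances every permutation with each optimiser step, and
  columns whose simplex has converged (spread < 1e-5 in the scan, 1e-7 in
  standalone fits) drop out of further evaluations.
* The per-block inner loop (assemble K, Cholesky, whiten [X|y], accumulate
  quadratic forms) is compiled with numba when available; a vectorised
  NumPy path computes identical quantities otherwise.
* Standalone fits start from an interior point (all λ = e⁻¹) and from the
  boundary, then polish. Scan fits use a warm-start simplex spanning the
  null-model optimum with a negligible QTL ratio, a stepped polygenic
  ratio, and a moderate QTL ratio; because the Nelder–Mead never discards
  its best vertex, the QTL model's likelihood cannot fall below the null
  solution, keeping every LRT ≥ 0 up to the 1e-6 floor applied afterwards.

Under the null the LRT at a position follows approximately the boundary
mixture ½χ²(0) + ½χ²(1); the suite checks stochastic dominance by χ²(1)
and a sizeable point mass at zero.

## Genome scan and permutation thresholds

The scan grid is every marker plus every `step_cM` step (default 5 cM;
`step_cM=None` scans markers only — used in the desk-scale studies where
the marker set already tiles the groups at 25 cM). Fixed effects default to
intercept + strain. Genome-wide significance uses the maximum-statistic
permutation approach: phenotypes are permuted **within full-sib families**.
Under the no-QTL null, sibs are exchangeable (identical fixed effects and
polygenic covariance), so within-family shuffling preserves the null
covariance exactly while severing the link between phenotypes and the
within-family IBD deviations that carry QTL signal. A global shuffle would
destroy the polygenic family covariance and badly understate the null
maxima (measured ~27% genome-wide rejection at nominal 5% on polygenic null
cohorts, versus ~5–6% for within-family permutation). The threshold at
level α is the smallest observed permutation maximum whose empirical
exceedance is ≤ α; the genome-wide p of an observed statistic is the
fraction of permutation maxima at or above it.

Because sibs are exchangeable under the null and the permutations are drawn
uniformly from the within-family permutation group, the resulting test is a
finite-sample exact randomisation test: its true rejection probability at
α = 0.05 with 200 permutations is 10/201 ≈ 4.97%. The suite verifies this
two ways: tie-randomised rank p-values are uniform over null replicates
(Kolmogorov–Smirnov), and an empirical rejection-rate study counts
rejections over 200 replicate null cohorts. The latter is itself one
binomial draw — even an exact procedure falls outside a 4–7% band in
roughly a third of such studies — so the uniformity test is the
statistically stronger check of calibration.

## Group statistics

Strain/family variance shares come from a REML fit with random strain and
random family-within-strain intercepts (families never cross strains in
these designs) and an intercept-only fixed part; shares are components over
their sum. Note the two distinct roles of strain: random in the variance
split, fixed in the QTL models. Group tests delegate to scipy (Welch t
with fractional df, Mann–Whitney, Kruskal–Wallis); ANOVA R² is the
between-group share of the total sum of squares. Fold differences render
as "k-fold" rounded to one decimal, collapsing to a spelled-out integer
("sevenfold") when rounding to zero decimals is requested.

## Study sizes used by the test suite

Chosen as desk-scale versions of the two experiments:

* Calibration of the permutation test: 200 replicate null cohorts of
  n = 200 offspring (2 strains × 10 families × 10, half-sib pairs), 3
  linkage groups × 4 markers, n_perm = 200, marker-only grid.
* Parameter recovery: 20 replicates per heritability grid point
  (h² ∈ {0.06, 0.30, 0.54}) of 42-family cohorts (6 crosses × 7
  families × 18 offspring = 756 fish, the scale of the hatchery design) with the QTL carrying 11% of the
  genetic variance; heritability is estimated from the polygenic animal
  model and the QTL fraction from the QTL model at the true position.
* Statistic directions: 200 patterns per regime in a 40 cm² window.

## Known limitations

* The QTL-variance *fraction* is statistically unidentifiable at very low
  heritability at these sample sizes (at h² = 0.06 the estimate is a ratio
  of two near-zero variance components; its replicate spread spans the
  whole unit interval). Recovery is demonstrated at h² = 0.30; the point
  estimate at low h² should be treated as qualitative.
* Expected (soft) IBD loses information relative to fully observed descent
  when markers are sparse or parents homozygous (~40–60% informative
  meioses at 25 cM with allele frequency 0.5); single-replicate scans can
  be weak when key parents happen to be uninformative near the QTL. This is
  a property of the design, not of the estimator.
* IBD matrices are defined for two-generation pedigrees with unrelated,
  non-inbred founders; the kinship matrix itself supports arbitrary
  pedigrees.
* The spot detector does not split touching spots; clustered patterns can
  merge, which mildly deflates counts and inflates per-spot areas.
* Synthetic images are idealised (uniform background, circular spots,
  Gaussian noise); passing tests demonstrate the measurement chain's
  correctness, not robustness to photographic artefacts, fin occlusion or
  landmark error in real photographs.
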