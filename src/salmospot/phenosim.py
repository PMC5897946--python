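"""Simulate quantitative phenotypes on a pedigree with known ground truth.

The generative model mirrors the mixed model used for the genetic analysis:

    y = strain effect + polygenic breeding value + QTL effect + residual

* breeding values follow the additive (numerator) relationship structure:
  founders draw N(0, sigma2_a); each offspring takes the parental average
  plus an independent Mendelian-sampling deviation N(0, sigma2_a / 2),
* the QTL effect is additive in the allele dosage at a (possibly hidden)
  biallelic locus, scaled so its realized variance matches the requested
  fraction of total variance,
* residuals are independent Gaussians.

Only offspring receive phenotypes (parents are broodstock, not measured).
Realized variance components are recorded in the simulation truth so
estimator-recovery tests can compare against what was actually generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genedrop import (
    GeneticMap,
    GenotypeMatrix,
    SimulationTruth,
    gen_genotypes,
    haldane_r,
)
from .pedigree import Pedigree, gen_pedigree

__all__ = ["CohortSpec", "gen_phenotypes", "qtl_genotype", "simulate_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated multi-strain half-sib cohort.

    ``variance_fractions`` gives (strain, polygenic, QTL, residual) as
    fractions of the total phenotypic variance; they must be non-negative
    and sum to 1.  The QTL sits at ``qtl_position_cM`` on ``qtl_group``; when
    that position coincides with a mapped marker the QTL locus is that
    marker, otherwise a hidden locus is simulated between the flanking
    markers.  Defaults reproduce the scale of a hatchery experiment: 6
    crosses x 6 families x 20 offspring = 720 fish on a sparse 25-cM map,
    with spot densities around 1.5 spots/cm2 (sd ~0.83); all estimators are
    scale-equivariant, so ``trait_mean``/``total_variance`` are cosmetic.
    """

    strains: tuple[str, ...] = ("Mowi", "FxM", "MxF", "Arna", "Figgjo", "Vosso")
    n_families_per_cross: int = 6
    n_offspring_per_family: int = 20
    gmap: GeneticMap = field(default_factory=GeneticMap.regular)
    founder_allele_freqs: float = 0.5
    qtl_group: str = "LG1"
    qtl_position_cM: float = 25.0
    qtl_allele_freq: float = 0.5
    variance_fractions: tuple[float, float, float, float] = (0.10, 0.27, 0.03, 0.60)
    strain_effects: dict[str, float] | None = None
    trait_mean: float = 1.5
    total_variance: float = 0.69
    half_sib: bool = True
    trait_name: str = "spot_density"
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.variance_fractions, dtype=float)
        if fr.shape != (4,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("variance fractions must be 4 non-negative values summing to 1")
        if not 0 < self.qtl_allele_freq < 1:
            raise ValueError("QTL allele frequency must lie in (0, 1)")
        self.gmap.locate(self.qtl_group, self.qtl_position_cM)  # validates position

    @property
    def qtl_fraction_of_genetic(self) -> float:
        """Share of the genetic (polygenic + QTL) variance carried by the QTL."""
        _, va, vq, _ = self.variance_fractions
        return 0.0 if va + vq == 0 else vq / (va + vq)

    @property
    def true_h2(self) -> float:
        """Narrow-sense heritability implied by the fractions, with strain
        treated as a fixed effect (excluded from the denominator).  The QTL
        contributes additive variance, so it belongs in the numerator."""
        _, va, vq, ve = self.variance_fractions
        return (va + vq) / (va + vq + ve)


def qtl_genotype(
    geno: GenotypeMatrix,
    truth: SimulationTruth,
    pedigree: Pedigree,
    lg: str,
    position_cM: float,
    allele_freq: float = 0.5,
    seed: int = 0,
) -> pd.Series:
    """Allele dosage at the QTL locus for every pedigree member.

    The QTL is always a *hidden* biallelic locus: founder alleles are drawn
    from ``allele_freq`` independently of the marker panel, and each meiotic
    origin is sampled conditionally on the recorded origins at the flanking
    markers under Haldane recombination.  On a mapped marker the origin is
    that marker's origin exactly (zero recombination distance), so the IBD
    machinery is fully informative there, but the causal alleles themselves
    remain unobserved — as they are for a real QTL, where the genotyped
    marker tags descent, not the causal variant's allelic state.
    """
    gmap = geno.gmap
    idx, pos = gmap.locate(lg, position_cM)
    rng = np.random.default_rng(seed)

    on = np.flatnonzero(np.isclose(pos, position_cM, atol=1e-6))
    if on.size:
        jl = jr = int(idx[on[0]])
        r1 = r2 = 0.0
    else:
        left = int(np.searchsorted(pos, position_cM) - 1)
        jl, jr = int(idx[left]), int(idx[left + 1])
        r1 = float(haldane_r(position_cM - pos[left]))
        r2 = float(haldane_r(pos[left + 1] - position_cM))

    tab = pedigree.table
    alleles: dict[str, np.ndarray] = {}
    for rec in tab.itertuples():
        if rec.sire == "":
            alleles[rec.id] = (rng.random(2) < allele_freq).astype(np.int8)
        else:
            k = truth.origin_row(rec.id)
            transmitted = []
            for parent, origin in ((rec.sire, truth.sire_origin), (rec.dam, truth.dam_origin)):
                a, b = int(origin[k, jl]), int(origin[k, jr])
                # P(origin at QTL = a | flanking origins a, b)
                if a == b:
                    p_keep = (1 - r1) * (1 - r2) / ((1 - r1) * (1 - r2) + r1 * r2)
                else:
                    p_keep = (1 - r1) * r2 / ((1 - r1) * r2 + r1 * (1 - r2))
                o = a if rng.random() < p_keep else 1 - a
                transmitted.append(alleles[parent][o])
            alleles[rec.id] = np.asarray(transmitted, dtype=np.int8)
    dosage = {ind: int(al.sum()) for ind, al in alleles.items()}
    return pd.Series(dosage, name="qtl_dosage").loc[geno.ids]


def gen_phenotypes(
    pedigree: Pedigree,
    truth: SimulationTruth,
    variance_fractions: tuple[float, float, float, float],
    strain_effects: dict[str, float] | None = None,
    qtl_dosage: pd.Series | None = None,
    trait_mean: float = 0.0,
    total_variance: float = 1.0,
    trait_name: str = "spot_density",
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw phenotypes for the pedigree's offspring; truth is updated in place.

    ``strain_effects`` supplies fixed per-strain shifts; when omitted, shifts
    are drawn once per cohort as N(0, v_strain * total_variance) so the
    requested strain fraction is honoured on average.  ``qtl_dosage`` is
    required whenever the QTL fraction is positive.
    """
    fr = np.asarray(variance_fractions, dtype=float)
    if fr.shape != (4,) or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("variance fractions must be 4 non-negative values summing to 1")
    v_strain, v_poly, v_qtl, v_res = fr * total_variance
    rng = np.random.default_rng(seed)

    tab = pedigree.table
    strains = list(dict.fromkeys(tab["strain"]))
    if strain_effects is None:
        shifts = rng.normal(0.0, np.sqrt(v_strain), size=len(strains)) if v_strain > 0 else np.zeros(len(strains))
        strain_effects = dict(zip(strains, shifts))

    # breeding values in topological order
    bv: dict[str, float] = {}
    sd_founder = np.sqrt(v_poly)
    sd_mendel = np.sqrt(v_poly / 2.0)
    for rec in tab.itertuples():
        if rec.sire == "":
            bv[rec.id] = rng.normal(0.0, sd_founder) if v_poly > 0 else 0.0
        else:
            ms = rng.normal(0.0, sd_mendel) if v_poly > 0 else 0.0
            bv[rec.id] = 0.5 * (bv[rec.sire] + bv[rec.dam]) + ms

    off = tab.loc[tab["sire"] != "", ["id", "strain"]].reset_index(drop=True)
    n = len(off)
    u = np.asarray([bv[i] for i in off["id"]])

    if v_qtl > 0:
        if qtl_dosage is None:
            raise ValueError("qtl_dosage required when the QTL variance fraction is positive")
        d = qtl_dosage.loc[off["id"]].to_numpy(dtype=float)
        var_d = d.var()
        if var_d <= 0:
            raise ValueError("QTL locus is monomorphic among offspring; cannot scale effect")
        q = np.sqrt(v_qtl / var_d) * (d - d.mean())
    else:
        q = np.zeros(n)
        d = (
            qtl_dosage.loc[off["id"]].to_numpy(dtype=float)
            if qtl_dosage is not None
            else np.zeros(n)
        )

    e = rng.normal(0.0, np.sqrt(v_res), size=n) if v_res > 0 else np.zeros(n)
    s = off["strain"].map(strain_effects).to_numpy(dtype=float)
    y = trait_mean + s + u + q + e

    fam = pedigree.family_of().loc[off["id"]].to_numpy()
    cohort = pd.DataFrame(
        {"id": off["id"], "strain": off["strain"], "family": fam, trait_name: y}
    )
    truth.breeding_values = pd.Series(u, index=off["id"], name="breeding_value")
    truth.qtl_dosage = pd.Series(d, index=off["id"], name="qtl_dosage")
    truth.realized_components = {
        "strain": float(np.var(s, ddof=1)),
        "polygenic": float(np.var(u, ddof=1)),
        "qtl": float(np.var(q, ddof=1)),
        "residual": float(np.var(e, ddof=1)),
        "sigma2_strain": float(v_strain),
        "sigma2_a": float(v_poly),
        "sigma2_q": float(v_qtl),
        "sigma2_e": float(v_res),
    }
    return cohort, truth


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, Pedigree, GenotypeMatrix, SimulationTruth]:
    """Generate a full cohort (pedigree, genotypes, phenotypes) from one seed.

    The single cohort seed is deterministically split into independent
    sub-seeds for gene-dropping, the hidden QTL locus and the phenotype draw.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_geno, s_qtl, s_pheno = (int(x) & 0x7FFFFFFF for x in ss.generate_state(3))

    ped = gen_pedigree(
        list(spec.strains),
        spec.n_families_per_cross,
        spec.n_offspring_per_family,
        half_sib=spec.half_sib,
    )
    geno, truth = gen_genotypes(ped, spec.gmap, spec.founder_allele_freqs, seed=s_geno)
    dosage = qtl_genotype(
        geno, truth, ped, spec.qtl_group, spec.qtl_position_cM,
        allele_freq=spec.qtl_allele_freq, seed=s_qtl,
    )
    cohort, truth = gen_phenotypes(
        ped,
        truth,
        spec.variance_fractions,
        strain_effects=spec.strain_effects,
        qtl_dosage=dosage,
        trait_mean=spec.trait_mean,
        total_variance=spec.total_variance,
        trait_name=spec.trait_name,
        seed=s_pheno,
    )
    return cohort, ped, geno, truth
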