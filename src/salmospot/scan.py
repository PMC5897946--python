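"""Variance-component QTL scan with permutation significance thresholds.

At each genomic position the QTL model

    y = X beta + a + q + e,   a ~ N(0, sigma2_a A),  q ~ N(0, sigma2_q Pi(pos))

is compared by restricted likelihood ratio with the polygenic-only model
``y = X beta + a + e``.  ``A`` is the pedigree numerator relationship matrix
and ``Pi(pos)`` the position-wise IBD matrix; the LRT profile along the map
is the QTL signal.  Genome-wide significance comes from a permutation test:
the phenotype vector is shuffled against the (pedigree, genotype) structure,
the maximum LRT over the whole grid is recorded per permutation, and the
threshold is the empirical (1 - alpha) quantile of those maxima.

Heritability and the QTL's share of the genetic / total variance are read
off the fitted variance components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genedrop import GenotypeMatrix
from .ibd import ibd_matrix
from .kinship import additive_relationship
from .pedigree import Pedigree
from .phasing import HaplotypeAssignment, phase_offspring
from .reml import BlockedREML, VarianceComponents, fit_vc_model

__all__ = [
    "ScanResult",
    "GenomeScanner",
    "lrt_at_position",
    "scan_genome",
    "permutation_threshold",
    "heritability",
    "qtl_variance_fractions",
    "allele_contrast",
    "design_matrix",
]

_LOG_LO = -18.0


@dataclass
class ScanResult:
    """Genome-scan output: per-position LRT plus permutation summaries."""

    table: pd.DataFrame  # linkage_group, position_cM, lrt [, genomewide_p]
    top_linkage_group: str
    top_position_cM: float
    top_lrt: float
    threshold: float | None = None
    alpha: float | None = None
    n_perm: int = 0
    genomewide_p: float | None = None
    null_fit: VarianceComponents | None = None

    @property
    def significant(self) -> bool | None:
        if self.genomewide_p is None or self.alpha is None:
            return None
        return self.genomewide_p < self.alpha


def design_matrix(
    cohort: pd.DataFrame, fixed_effects: tuple[str, ...] = ("strain",)
) -> tuple[np.ndarray, list[str]]:
    """Intercept plus treatment-coded dummies for each fixed-effect column."""
    cols = [np.ones(len(cohort))]
    names = ["intercept"]
    for eff in fixed_effects:
        levels = list(dict.fromkeys(cohort[eff]))
        for lev in levels[1:]:
            cols.append((cohort[eff] == lev).to_numpy(dtype=float))
            names.append(f"{eff}[{lev}]")
    return np.column_stack(cols), names


class GenomeScanner:
    """Reusable scan engine: aligns data once, then scans phenotype batches.

    Building the engine performs the expensive, phenotype-independent work
    (kinship, haplotype reconstruction, block decomposition); :meth:`scan`
    then evaluates any number of phenotype vectors in one batched pass, which
    is what makes Churchill-Doerge permutations tractable.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        pedigree: Pedigree,
        genotypes: GenotypeMatrix,
        trait: str = "spot_density",
        fixed_effects: tuple[str, ...] = ("strain",),
        step_cM: float | None = 5.0,
        assignment: HaplotypeAssignment | None = None,
    ):
        ids = cohort["id"].astype(str).tolist()
        missing = sorted(set(ids) - set(genotypes.ids))
        if missing:
            raise ValueError(f"phenotyped individuals missing genotypes: {missing}")
        missing_ped = sorted(set(ids) - set(pedigree.ids))
        if missing_ped:
            raise ValueError(f"phenotyped individuals missing from pedigree: {missing_ped}")

        self.cohort = cohort.reset_index(drop=True)
        self.ids = ids
        self.trait = trait
        self.pedigree = pedigree
        self.gmap = genotypes.gmap
        self.y = cohort[trait].to_numpy(dtype=float)
        self.X, self.fixed_names = design_matrix(cohort, fixed_effects)
        self.A = additive_relationship(pedigree, ids=ids).to_numpy()
        self.assignment = assignment if assignment is not None else phase_offspring(pedigree, genotypes)

        grid: list[tuple[str, float]] = []
        for lg in self.gmap.linkage_groups:
            pos = self.gmap.positions(lg)
            pts = set(np.round(pos, 6))
            if step_cM is not None:
                pts |= set(np.round(np.arange(pos[0], pos[-1] + 1e-9, step_cM), 6))
            grid.extend((lg, float(p)) for p in sorted(pts))
        self.positions = grid

        # IBD support never exceeds parent-sharing, which A already covers,
        # so one block decomposition serves every position.
        pi0 = self._ibd(*grid[0])
        self._engine = BlockedREML(self.X, [self.A, pi0])
        self._null_engine = BlockedREML(self.X, [self.A])

    def _ibd(self, lg: str, position: float) -> np.ndarray:
        return ibd_matrix(
            self.assignment, self.pedigree, lg, position, ids=self.ids
        ).to_numpy()

    def scan(self, Y: np.ndarray | None = None) -> dict:
        """LRT at every grid position for each phenotype column.

        ``Y``: (n, B) batch; defaults to the scanner's own trait vector.
        Returns dict with ``lrt`` (B, n_positions), ``null`` fit dict and the
        per-position fit dicts of the batched engine.
        """
        if Y is None:
            Y = self.y[:, None]
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        B = Y.shape[1]
        null = self._null_engine.fit(Y)
        # Warm-start simplex for the QTL model: one vertex at the null
        # optimum with a negligible QTL ratio (the likelihood can then only
        # improve, keeping every LRT >= 0), one stepping the polygenic ratio,
        # and one with a moderate QTL ratio.
        lam_a0 = np.log(np.maximum(null["lam"][:, 0], 1e-8))
        simplex = np.empty((B, 3, 2))
        simplex[:, 0] = np.column_stack([lam_a0, np.full(B, _LOG_LO)])
        simplex[:, 1] = np.column_stack([lam_a0 + 1.2, np.full(B, _LOG_LO)])
        simplex[:, 2] = np.column_stack([lam_a0, np.full(B, -1.5)])
        lrt = np.empty((B, len(self.positions)))
        fits = []
        for j, (lg, pos) in enumerate(self.positions):
            self._engine.set_structure(1, self._ibd(lg, pos))
            fit = self._engine.fit(
                Y, init_simplex=simplex, iters=60, polish_iters=0, tol=1e-5,
            )
            lrt[:, j] = np.maximum(2.0 * (fit["loglik"] - null["loglik"]), 0.0)
            fits.append(fit)
        return {"lrt": lrt, "null": null, "fits": fits}

    def permutation_maxima(self, n_perm: int, seed: int = 0) -> np.ndarray:
        """Maximum genome-wide LRT for each of ``n_perm`` phenotype shuffles.

        Phenotypes are permuted *within full-sib families*: under the
        no-QTL null the phenotypes of sibs are exchangeable (identical
        polygenic and fixed-effect structure), so within-family shuffling
        preserves the genetic covariance of the null while severing the link
        between phenotypes and the within-family IBD deviations that carry
        the QTL signal.  A global shuffle would instead destroy the
        polygenic structure and badly understate the null maxima.
        """
        rng = np.random.default_rng(seed)
        fam = self.pedigree.family_of().reindex(self.ids).to_numpy()
        groups = [np.flatnonzero(fam == f) for f in pd.unique(fam)]
        n = len(self.y)
        Y = np.empty((n, n_perm))
        for b in range(n_perm):
            perm = np.arange(n)
            for g in groups:
                perm[g] = g[rng.permutation(g.size)]
            Y[:, b] = self.y[perm]
        return self.scan(Y)["lrt"].max(axis=1)


def lrt_at_position(
    y: np.ndarray, X: np.ndarray, A: np.ndarray, ibd: np.ndarray
) -> float:
    """Restricted-likelihood ratio of the QTL model vs the polygenic model.

    ``LRT = 2 (loglik[y = Xb + a + q + e] - loglik[y = Xb + a + e])``,
    floored at 0 (the models are nested; small negative values can only be
    numerical noise).
    """
    m1 = fit_vc_model(y, X, {"additive": A, "qtl": ibd}, validate=False)
    m2 = fit_vc_model(y, X, {"additive": A}, validate=False)
    return max(
        2.0 * (m1.log_restricted_likelihood - m2.log_restricted_likelihood), 0.0
    )


def scan_genome(
    cohort: pd.DataFrame,
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    trait: str = "spot_density",
    fixed_effects: tuple[str, ...] = ("strain",),
    step_cM: float | None = 5.0,
    n_perm: int = 0,
    alpha: float = 0.05,
    seed: int = 0,
    scanner: GenomeScanner | None = None,
) -> ScanResult:
    """Full genome scan, optionally with a permutation threshold.

    The grid contains every marker plus every ``step_cM`` step within each
    linkage group (``step_cM=None`` scans markers only).
    """
    sc = scanner or GenomeScanner(
        cohort, pedigree, genotypes, trait=trait,
        fixed_effects=fixed_effects, step_cM=step_cM,
    )
    res = sc.scan()
    lrt = res["lrt"][0]
    table = pd.DataFrame(
        {
            "linkage_group": [lg for lg, _ in sc.positions],
            "position_cM": [p for _, p in sc.positions],
            "lrt": lrt,
        }
    )
    top = int(np.argmax(lrt))
    threshold = None
    gw_p = None
    if n_perm:
        maxima = sc.permutation_maxima(n_perm, seed=seed)
        threshold = _threshold_from_maxima(maxima, alpha)
        gw_p = float(np.mean(maxima >= lrt[top]))
        table["genomewide_p"] = [float(np.mean(maxima >= v)) for v in lrt]
    null_lam = res["null"]["lam"][0, 0]
    null_s2e = float(res["null"]["sigma2_e"][0])
    null_fit = VarianceComponents(
        beta=res["null"]["beta"][0],
        sigma2={"additive": float(null_lam * null_s2e)},
        sigma2_e=null_s2e,
        log_restricted_likelihood=float(res["null"]["loglik"][0]),
        converged=bool(res["null"]["converged"][0]),
        n=len(sc.y),
        n_fixed=sc.X.shape[1],
    )
    return ScanResult(
        table=table,
        top_linkage_group=sc.positions[top][0],
        top_position_cM=sc.positions[top][1],
        top_lrt=float(lrt[top]),
        threshold=threshold,
        alpha=alpha if n_perm else None,
        n_perm=n_perm,
        genomewide_p=gw_p,
        null_fit=null_fit,
    )


def _threshold_from_maxima(maxima: np.ndarray, alpha: float) -> float:
    """Smallest observed maximum whose empirical exceedance is <= alpha."""
    vals = np.sort(maxima)
    n = vals.size
    # exceedance of vals[i] (as a candidate threshold) = #(maxima >= vals[i]) / n
    exceed = (n - np.searchsorted(vals, vals, side="left")) / n
    ok = exceed <= alpha
    if not ok.any():
        raise ValueError(f"n_perm={n} too small for alpha={alpha}")
    return float(vals[ok][0])


def permutation_threshold(
    cohort: pd.DataFrame,
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    trait: str = "spot_density",
    fixed_effects: tuple[str, ...] = ("strain",),
    step_cM: float | None = 5.0,
    scanner: GenomeScanner | None = None,
) -> float:
    """Churchill-Doerge genome-wide LRT threshold at significance ``alpha``.

    Raises ``ValueError`` when ``n_perm`` cannot resolve the requested
    quantile (``n_perm * alpha < 1``) or is below the minimum of 100.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_perm * alpha < 1:
        raise ValueError(f"n_perm={n_perm} too small for alpha={alpha}")
    sc = scanner or GenomeScanner(
        cohort, pedigree, genotypes, trait=trait,
        fixed_effects=fixed_effects, step_cM=step_cM,
    )
    maxima = sc.permutation_maxima(n_perm, seed=seed)
    return _threshold_from_maxima(maxima, alpha)


def heritability(vc: VarianceComponents) -> float:
    """Narrow-sense heritability sigma2_a / (sigma2_a + sigma2_q + sigma2_e)."""
    total = vc.sigma2_a + vc.sigma2_q + vc.sigma2_e
    if total <= 0:
        raise ValueError("all variance components are zero; h2 undefined")
    return vc.sigma2_a / total


def qtl_variance_fractions(vc: VarianceComponents) -> tuple[float, float]:
    """QTL variance as a fraction of (genetic, total phenotypic) variance."""
    genetic = vc.sigma2_q + vc.sigma2_a
    total = genetic + vc.sigma2_e
    if total <= 0:
        raise ValueError("zero total variance")
    frac_gen = 0.0 if genetic == 0 else vc.sigma2_q / genetic
    return frac_gen, vc.sigma2_q / total


def allele_contrast(
    assignment: HaplotypeAssignment,
    cohort: pd.DataFrame,
    pedigree: Pedigree,
    parent: str,
    lg: str,
    position_cM: float,
    trait: str = "spot_density",
    stratify_by_mate_strain: bool = False,
    min_confidence: float = 0.8,
) -> pd.DataFrame:
    """Offspring trait means split by the haplotype inherited from ``parent``.

    Offspring are assigned to haplotype groups when their origin probability
    at the position is at least ``min_confidence`` (or at most its
    complement); ambiguous meioses are dropped.  Returns one row per group
    (optionally per mate-strain background) with n, mean, sd, and the Welch
    t statistic / p value of the two-group contrast.

    Raises ``ValueError`` when the parent is uninformative at the position.
    """
    tab = pedigree.table
    off = tab[(tab["sire"] == parent) | (tab["dam"] == parent)]
    if off.empty:
        raise ValueError(f"{parent!r} has no offspring")
    rows = []
    for rec in off.itertuples():
        which = "sire" if rec.sire == parent else "dam"
        k = assignment.offspring_ids.index(rec.id)
        p0 = assignment.origin_prob(which, lg, position_cM)[k]
        mate = rec.dam if which == "sire" else rec.sire
        mate_strain = tab.set_index("id").loc[mate, "strain"]
        rows.append((rec.id, p0, mate_strain))
    info = pd.DataFrame(rows, columns=["id", "p0", "mate_strain"])
    info["haplotype"] = np.where(info["p0"] >= min_confidence, 0,
                                 np.where(info["p0"] <= 1 - min_confidence, 1, -1))
    info = info[info["haplotype"] >= 0]
    if info.empty or info["haplotype"].nunique() < 2:
        raise ValueError(
            f"parent {parent!r} is uninformative at {lg}:{position_cM} cM"
        )
    merged = info.merge(cohort[["id", trait]], on="id", how="inner")

    def _contrast(df: pd.DataFrame) -> pd.DataFrame:
        g0 = df.loc[df["haplotype"] == 0, trait]
        g1 = df.loc[df["haplotype"] == 1, trait]
        if len(g0) and len(g1):
            t, p = stats.ttest_ind(g0, g1, equal_var=False)
        else:
            t, p = np.nan, np.nan
        out = (
            df.groupby("haplotype")[trait]
            .agg(n="size", mean="mean", sd="std")
            .reset_index()
        )
        out["t"] = t
        out["p"] = p
        return out

    if stratify_by_mate_strain:
        parts = []
        for strain, df in merged.groupby("mate_strain"):
            part = _contrast(df)
            part.insert(0, "mate_strain", strain)
            parts.append(part)
        return pd.concat(parts, ignore_index=True)
    return _contrast(merged)
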