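"""Nuclear-family haplotype reconstruction and parental-origin tracking.

For every meiosis (offspring x parent) and marker the goal is the
probability that the transmitted allele came from the parent's haplotype 0
versus haplotype 1.  The model is a two-state Markov chain along the
chromosome (states = parental haplotype of origin) with Haldane transition
probabilities between markers:

1. At each marker, the *transmitted allele* of a parent is resolved from the
   offspring genotype where possible (a homozygous parent always transmits
   its allele; a heterozygous parent's transmission is resolved when the
   offspring is homozygous, or heterozygous with a homozygous mate).
2. For unphased input, each parent's haplotypes are reconstructed by chaining
   heterozygous markers: the relative phase of adjacent heterozygous markers
   is chosen to minimise the implied number of recombinations across all of
   the parent's meioses (majority linkage).  Phase is arbitrary up to a flip
   per linkage group, which is irrelevant for IBD.
3. Origin probabilities at any genomic position follow from the nearest
   informative flanking markers; uninformative stretches fall back to 0.5.

Mendelian inconsistencies are flagged, logged, and the marker set
uninformative for that meiosis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genedrop import GeneticMap, GenotypeMatrix, SimulationTruth, haldane_r
from .pedigree import UNKNOWN, Pedigree

__all__ = ["HaplotypeAssignment", "phase_offspring", "assignment_from_truth"]

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeAssignment:
    """Per-meiosis parental-origin information along the genome.

    ``origins[s]`` (s in {"sire", "dam"}) holds, per offspring and marker,
    the transmitted-haplotype index where informative; ``informative[s]``
    masks those entries.  Probabilities at arbitrary positions come from
    :meth:`origin_prob`.
    """

    offspring_ids: list[str]
    gmap: GeneticMap
    origins: dict[str, np.ndarray]  # (n_off, n_markers) int8, valid where informative
    informative: dict[str, np.ndarray]  # (n_off, n_markers) bool
    mendel_errors: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "parent", "marker_id"])
    )

    def origin_prob_at_markers(self, parent: str) -> np.ndarray:
        """P(haplotype-0 origin) per meiosis at every marker, (n_off, m)."""
        m = self.gmap.n_markers
        out = np.empty((len(self.offspring_ids), m))
        for lg in self.gmap.linkage_groups:
            idx = self.gmap.group_indices(lg)
            pos = self.gmap.table["position_cM"].to_numpy()[idx]
            for j, p in zip(idx, pos):
                out[:, j] = self.origin_prob(parent, lg, p)
        return out

    def origin_prob(self, parent: str, lg: str, position_cM: float) -> np.ndarray:
        """P(transmitted allele came from haplotype 0) at a position.

        Exact two-state Markov posterior given the nearest informative
        flanking markers; 0.5 where a meiosis has no informative marker on
        the linkage group.
        """
        if parent not in ("sire", "dam"):
            raise ValueError("parent must be 'sire' or 'dam'")
        idx, pos = self.gmap.locate(lg, position_cM)
        info = self.informative[parent][:, idx]
        orig = self.origins[parent][:, idx]
        n_off, m = info.shape
        cols = np.arange(m)

        # Index of last informative marker at or left of the query, per meiosis.
        k = int(np.searchsorted(pos, position_cM, side="right")) - 1
        left_idx = np.where(info[:, : k + 1], cols[: k + 1], -1).max(axis=1) if k >= 0 else np.full(n_off, -1)
        right_slice = info[:, k + 1 :]
        right_idx = np.where(
            right_slice.any(axis=1),
            k + 1 + np.argmax(right_slice, axis=1),
            -1,
        ) if k + 1 < m else np.full(n_off, -1)
        # A marker exactly at the query belongs to the left flank (distance 0).

        p_left = np.full(n_off, 0.5)
        has_l = left_idx >= 0
        if has_l.any():
            d = position_cM - pos[left_idx[has_l]]
            r = haldane_r(d)
            a = orig[has_l, left_idx[has_l]]
            p_left[has_l] = np.where(a == 0, 1.0 - r, r)
        p_right = np.full(n_off, 0.5)
        has_r = right_idx >= 0
        if has_r.any():
            d = pos[right_idx[has_r]] - position_cM
            r = haldane_r(d)
            b = orig[has_r, right_idx[has_r]]
            p_right[has_r] = np.where(b == 0, 1.0 - r, r)

        num = p_left * p_right
        den = num + (1.0 - p_left) * (1.0 - p_right)
        return num / den


def _transmitted(
    g_par: np.ndarray, g_mate: np.ndarray, g_off: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resolve which allele (0/1) a parent transmitted, per marker.

    Returns (transmitted allele, resolved mask, Mendelian-error mask) for
    dosage vectors of one offspring against one parent/mate pair.
    """
    t = np.full(g_par.shape, -1, dtype=np.int8)
    err = np.zeros(g_par.shape, dtype=bool)

    # Mendelian checks against the focal parent alone.
    err |= (g_par == 0) & (g_off == 2)
    err |= (g_par == 2) & (g_off == 0)
    # And against the pair.
    err |= (g_par == 0) & (g_mate == 0) & (g_off != 0)
    err |= (g_par == 2) & (g_mate == 2) & (g_off != 2)
    err |= (g_par == 0) & (g_mate == 2) & (g_off != 1)
    err |= (g_par == 2) & (g_mate == 0) & (g_off != 1)

    t = np.where(g_par == 0, 0, t)
    t = np.where(g_par == 2, 1, t)
    het = g_par == 1
    t = np.where(het & (g_off == 0), 0, t)
    t = np.where(het & (g_off == 2), 1, t)
    # Offspring het: resolvable only when the mate is homozygous.
    t = np.where(het & (g_off == 1) & (g_mate == 0), 1, t)
    t = np.where(het & (g_off == 1) & (g_mate == 2), 0, t)

    resolved = (t >= 0) & ~err
    return t, resolved, err


def _phase_parent(
    gmap: GeneticMap,
    g_par: np.ndarray,
    t_mat: np.ndarray,
    resolved: np.ndarray,
) -> np.ndarray:
    """Reconstruct one parent's haplotype-0 allele per marker.

    ``t_mat``/``resolved``: (n_meioses, m) transmitted alleles across this
    parent's meioses.  At heterozygous markers the relative phase of
    consecutive heterozygous markers is set by majority vote over meioses
    resolving both (origin changes are rarer than not, so the phase that
    makes transmissions agree wins).  Homozygous markers are trivially
    phased.  Returns hap0 alleles, (m,) int8.
    """
    m = gmap.n_markers
    hap0 = np.where(g_par == 2, 1, 0).astype(np.int8)
    for lg in gmap.linkage_groups:
        idx = gmap.group_indices(lg)
        het = idx[g_par[idx] == 1]
        if het.size == 0:
            continue
        hap0[het[0]] = 0  # anchor; phase is arbitrary up to a flip per group
        for prev, cur in zip(het[:-1], het[1:]):
            both = resolved[:, prev] & resolved[:, cur]
            if not both.any():
                hap0[cur] = 0  # phase chain broken; start a new arbitrary segment
                continue
            same = int(np.sum(t_mat[both, prev] == t_mat[both, cur]))
            diff = int(both.sum()) - same
            # If transmissions mostly agree, the alleles sit on the same
            # haplotype as at the previous marker (relative to hap0 there).
            hap0[cur] = np.int8(hap0[prev] if same >= diff else 1 - hap0[prev])
    return hap0


def phase_offspring(
    pedigree: Pedigree, geno: GenotypeMatrix
) -> HaplotypeAssignment:
    """Reconstruct parental origins for every offspring x marker.

    With phased input genotypes the parents' haplotypes are taken as given;
    with unphased (dosage) input they are reconstructed from the offspring by
    majority linkage.  Only two-generation (nuclear-family) pedigrees are
    supported.
    """
    if pedigree.n_generations() > 2:
        raise ValueError("haplotype reconstruction supports two-generation pedigrees only")
    gmap = geno.gmap
    m = gmap.n_markers
    tab = pedigree.table
    off = tab.loc[tab["sire"] != UNKNOWN]
    off_ids = off["id"].tolist()
    n_off = len(off_ids)
    dose = geno.dosage()
    row = {ind: i for i, ind in enumerate(geno.ids)}

    # Resolve transmitted alleles per meiosis.
    t_all = {p: np.full((n_off, m), -1, dtype=np.int8) for p in ("sire", "dam")}
    res_all = {p: np.zeros((n_off, m), dtype=bool) for p in ("sire", "dam")}
    err_records: list[tuple[str, str, str]] = []
    marker_ids = np.asarray(gmap.marker_ids)
    for k, rec in enumerate(off.itertuples()):
        g_o = dose[row[rec.id]]
        for pkey, par, mate in (("sire", rec.sire, rec.dam), ("dam", rec.dam, rec.sire)):
            t, resolved, err = _transmitted(dose[row[par]], dose[row[mate]], g_o)
            t_all[pkey][k] = t
            res_all[pkey][k] = resolved
            if err.any():
                for mk in marker_ids[err]:
                    err_records.append((rec.id, par, mk))

    if err_records:
        logger.warning(
            "%d Mendelian inconsistencies flagged; affected markers set "
            "uninformative for those meioses",
            len(err_records),
        )

    # Parent haplotypes: given (phased input) or reconstructed.
    hap0: dict[str, np.ndarray] = {}
    parents = sorted(set(off["sire"]) | set(off["dam"]))
    for par in parents:
        g_par = dose[row[par]]
        if geno.phased:
            hap0[par] = geno.alleles[row[par], :, 0]
        else:
            meios_idx = []
            t_rows = []
            res_rows = []
            for k, rec in enumerate(off.itertuples()):
                for pkey, pid in (("sire", rec.sire), ("dam", rec.dam)):
                    if pid == par:
                        t_rows.append(t_all[pkey][k])
                        res_rows.append(res_all[pkey][k])
            hap0[par] = _phase_parent(
                gmap, g_par, np.asarray(t_rows), np.asarray(res_rows)
            )

    # Origins: informative iff parent heterozygous and transmission resolved.
    origins = {p: np.zeros((n_off, m), dtype=np.int8) for p in ("sire", "dam")}
    informative = {p: np.zeros((n_off, m), dtype=bool) for p in ("sire", "dam")}
    for k, rec in enumerate(off.itertuples()):
        for pkey, par in (("sire", rec.sire), ("dam", rec.dam)):
            g_par = dose[row[par]]
            h0 = hap0[par]
            t = t_all[pkey][k]
            info = res_all[pkey][k] & (g_par == 1)
            informative[pkey][k] = info
            origins[pkey][k][info] = np.where(t[info] == h0[info], 0, 1)

    errors = pd.DataFrame(err_records, columns=["id", "parent", "marker_id"])
    return HaplotypeAssignment(
        offspring_ids=off_ids,
        gmap=gmap,
        origins=origins,
        informative=informative,
        mendel_errors=errors,
    )


def assignment_from_truth(
    pedigree: Pedigree, gmap: GeneticMap, truth: SimulationTruth
) -> HaplotypeAssignment:
    """Fully informative assignment built from recorded simulation truth.

    Useful as an oracle: every marker is informative and origins are exact.
    """
    tab = pedigree.table
    off_ids = tab.loc[tab["sire"] != UNKNOWN, "id"].tolist()
    rows = [truth.origin_row(i) for i in off_ids]
    info = np.ones((len(off_ids), gmap.n_markers), dtype=bool)
    return HaplotypeAssignment(
        offspring_ids=off_ids,
        gmap=gmap,
        origins={
            "sire": truth.sire_origin[rows].astype(np.int8),
            "dam": truth.dam_origin[rows].astype(np.int8),
        },
        informative={"sire": info, "dam": info.copy()},
    )
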