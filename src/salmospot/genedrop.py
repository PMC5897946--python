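"""Gene-dropping simulation of SNP genotypes through a pedigree.

Founder alleles are drawn from stated allele frequencies; each meiosis
transmits one of the parent's two haplotypes per marker, with recombination
between adjacent markers following the Haldane map function (no
interference):

    r = (1 - exp(-2 d / 100)) / 2   for map distance d in cM.

The parental origin (which of the parent's two haplotypes was transmitted)
is recorded for every meiosis and marker, providing exact ground truth for
the haplotype-reconstruction and IBD machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "SimulationTruth",
    "haldane_r",
    "haldane_d",
    "gen_genotypes",
]


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def haldane_d(r: np.ndarray | float) -> np.ndarray | float:
    """Inverse Haldane map function: cM distance for a recombination fraction."""
    return -50.0 * np.log(1.0 - 2.0 * np.asarray(r, dtype=float))


@dataclass
class GeneticMap:
    """Linkage map: ordered markers with cM positions per linkage group."""

    table: pd.DataFrame  # columns: linkage_group, marker_id, position_cM

    def __post_init__(self) -> None:
        required = {"linkage_group", "marker_id", "position_cM"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"map lacks columns: {sorted(missing)}")
        tab = self.table.copy()
        tab["marker_id"] = tab["marker_id"].astype(str)
        tab["linkage_group"] = tab["linkage_group"].astype(str)
        tab["position_cM"] = tab["position_cM"].astype(float)
        if tab["marker_id"].duplicated().any():
            raise ValueError("duplicate marker ids in map")
        for lg, grp in tab.groupby("linkage_group", sort=False):
            if not np.all(np.diff(grp["position_cM"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on group {lg}")
        self.table = tab.reset_index(drop=True)

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def linkage_groups(self) -> list[str]:
        return list(dict.fromkeys(self.table["linkage_group"]))

    def group_indices(self, lg: str) -> np.ndarray:
        """Row indices (into the global marker order) of a linkage group."""
        idx = np.flatnonzero((self.table["linkage_group"] == lg).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown linkage group {lg!r}")
        return idx

    def positions(self, lg: str) -> np.ndarray:
        return self.table["position_cM"].to_numpy()[self.group_indices(lg)]

    def marker_index(self, marker_id: str) -> int:
        hits = np.flatnonzero((self.table["marker_id"] == marker_id).to_numpy())
        if hits.size == 0:
            raise KeyError(f"marker {marker_id!r} not on the map")
        return int(hits[0])

    def locate(self, lg: str, position_cM: float) -> tuple[np.ndarray, np.ndarray]:
        """Group marker indices and positions, validating the query position."""
        idx = self.group_indices(lg)
        pos = self.table["position_cM"].to_numpy()[idx]
        if position_cM < pos[0] - 1e-9 or position_cM > pos[-1] + 1e-9:
            raise ValueError(
                f"position {position_cM} cM off the mapped range "
                f"[{pos[0]}, {pos[-1]}] of group {lg}"
            )
        return idx, pos

    @staticmethod
    def regular(
        n_groups: int = 3, n_markers_per_group: int = 4, spacing_cM: float = 25.0
    ) -> "GeneticMap":
        """Evenly spaced map, e.g. markers at 0, 25, 50, 75 cM per group."""
        rows = [
            {
                "linkage_group": f"LG{g + 1}",
                "marker_id": f"LG{g + 1}_M{m + 1}",
                "position_cM": m * spacing_cM,
            }
            for g in range(n_groups)
            for m in range(n_markers_per_group)
        ]
        return GeneticMap(pd.DataFrame(rows))


@dataclass
class GenotypeMatrix:
    """Phased biallelic genotypes: alleles[i, m, k] in {0, 1}.

    ``k`` indexes the two gametes; for founders the order is arbitrary, for
    non-founders gamete 0 came from the sire and gamete 1 from the dam.
    """

    ids: list[str]
    alleles: np.ndarray  # (n, n_markers, 2) int8
    gmap: GeneticMap
    phased: bool = True

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.ids), self.gmap.n_markers, 2):
            raise ValueError("alleles shape must be (n_individuals, n_markers, 2)")

    def dosage(self) -> np.ndarray:
        """Allele-1 dosage matrix, values 0/1/2, shape (n, n_markers)."""
        return self.alleles.sum(axis=2).astype(np.int8)

    def index_of(self, ind: str) -> int:
        return self.ids.index(ind)

    def to_frame(self, dialect: str = "dosage") -> pd.DataFrame:
        """Tabular form: ``dosage`` (0/1/2) or ``phased`` ("A|B")."""
        cols = self.gmap.marker_ids
        if dialect == "dosage":
            data = self.dosage()
            return pd.DataFrame(data, index=self.ids, columns=cols).rename_axis("id")
        if dialect == "phased":
            a = self.alleles
            strs = np.char.add(
                np.char.add(a[:, :, 0].astype(str), "|"), a[:, :, 1].astype(str)
            )
            return pd.DataFrame(strs, index=self.ids, columns=cols).rename_axis("id")
        raise ValueError(f"unknown genotype dialect {dialect!r}")


@dataclass
class SimulationTruth:
    """Ground truth recorded by the generators for parameter-recovery tests.

    ``sire_origin``/``dam_origin`` hold, per non-founder and marker, which
    parental haplotype (0 or 1) was transmitted.  Phenotype-level fields are
    filled by the phenotype generator.
    """

    nonfounder_ids: list[str]
    sire_origin: np.ndarray  # (n_nonfounders, n_markers) int8
    dam_origin: np.ndarray
    breeding_values: pd.Series | None = None
    qtl_dosage: pd.Series | None = None
    realized_components: dict[str, float] = field(default_factory=dict)

    def origin_row(self, ind: str) -> int:
        return self.nonfounder_ids.index(ind)

    def to_frame(self, gmap: GeneticMap | None = None) -> pd.DataFrame:
        """Tabular ground truth: one row per non-founder with its breeding
        value, QTL dosage and (when a map is given) per-marker parental
        origins as ``sire_origin_<marker>`` / ``dam_origin_<marker>``."""
        out = pd.DataFrame({"id": self.nonfounder_ids})
        if self.breeding_values is not None:
            out["breeding_value"] = self.breeding_values.reindex(out["id"]).to_numpy()
        if self.qtl_dosage is not None:
            out["qtl_dosage"] = self.qtl_dosage.reindex(out["id"]).to_numpy()
        if gmap is not None:
            for j, m in enumerate(gmap.marker_ids):
                out[f"sire_origin_{m}"] = self.sire_origin[:, j]
                out[f"dam_origin_{m}"] = self.dam_origin[:, j]
        return out


def _meiosis_origins(
    rng: np.random.Generator, gmap: GeneticMap, n_meioses: int
) -> np.ndarray:
    """Simulate parental-origin vectors (n_meioses, n_markers) with Haldane
    switching between adjacent markers, independently per linkage group."""
    m = gmap.n_markers
    origins = np.zeros((n_meioses, m), dtype=np.int8)
    for lg in gmap.linkage_groups:
        idx = gmap.group_indices(lg)
        pos = gmap.table["position_cM"].to_numpy()[idx]
        r = haldane_r(np.diff(pos))
        cur = rng.integers(0, 2, size=n_meioses).astype(np.int8)
        origins[:, idx[0]] = cur
        for j, rj in enumerate(r):
            flip = rng.random(n_meioses) < rj
            cur = np.where(flip, 1 - cur, cur).astype(np.int8)
            origins[:, idx[j + 1]] = cur
    return origins


def gen_genotypes(
    pedigree: Pedigree,
    gmap: GeneticMap,
    founder_allele_freqs: np.ndarray | float,
    seed: int = 0,
) -> tuple[GenotypeMatrix, SimulationTruth]:
    """Drop genes through the pedigree and record every parental origin.

    Parameters
    ----------
    pedigree
        Validated pedigree (any depth; processed in topological order).
    gmap
        Linkage map defining marker order and recombination distances.
    founder_allele_freqs
        Allele-1 frequency per marker (scalar or length-n_markers array),
        each in (0, 1).
    seed
        Seed for founder alleles and meioses.
    """
    m = gmap.n_markers
    freqs = np.broadcast_to(np.asarray(founder_allele_freqs, dtype=float), (m,))
    if np.any(freqs <= 0) or np.any(freqs >= 1):
        raise ValueError("founder allele frequencies must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    ids = pedigree.ids
    row = {ind: i for i, ind in enumerate(ids)}
    alleles = np.zeros((len(ids), m, 2), dtype=np.int8)

    tab = pedigree.table
    founder_mask = (tab["sire"] == UNKNOWN).to_numpy()
    founder_rows = np.flatnonzero(founder_mask)
    alleles[founder_rows] = (
        rng.random((founder_rows.size, m, 2)) < freqs[None, :, None]
    ).astype(np.int8)

    nonfounders = tab.loc[~founder_mask]
    nf_ids = nonfounders["id"].tolist()
    sire_origin = _meiosis_origins(rng, gmap, len(nf_ids))
    dam_origin = _meiosis_origins(rng, gmap, len(nf_ids))

    cols = np.arange(m)
    for k, rec in enumerate(nonfounders.itertuples()):
        i = row[rec.id]
        alleles[i, :, 0] = alleles[row[rec.sire], cols, sire_origin[k]]
        alleles[i, :, 1] = alleles[row[rec.dam], cols, dam_origin[k]]

    geno = GenotypeMatrix(ids=ids, alleles=alleles, gmap=gmap)
    truth = SimulationTruth(
        nonfounder_ids=nf_ids, sire_origin=sire_origin, dam_origin=dam_origin
    )
    return geno, truth
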