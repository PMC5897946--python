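"""Pedigree container and two-generation half-sib cross designs.

The experimental design emulated here is a multi-strain common-garden cross:
each strain (or reciprocal hybrid cross) contributes several full-sibling
families, and with the half-sib option a sire is mated to two dams so that
adjacent families share a father.  Shared parents across families are what
give a variance-component QTL analysis its power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "gen_pedigree"]

UNKNOWN = ""  # parent code for founders


@dataclass
class Pedigree:
    """Validated pedigree table.

    ``table`` has columns id, sire, dam, strain, sex; founders carry the
    empty string for both parents.  Rows are stored in topological order
    (parents before offspring).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "sire", "dam", "strain"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree table lacks columns: {sorted(missing)}")
        if "sex" not in self.table.columns:
            self.table = self.table.assign(sex="U")
        tab = self.table.fillna({"sire": UNKNOWN, "dam": UNKNOWN})
        ids = tab["id"].astype(str)
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate individual ids: {dupes}")
        tab = tab.assign(id=ids, sire=tab["sire"].astype(str), dam=tab["dam"].astype(str))
        known = set(ids)
        for col in ("sire", "dam"):
            bad = tab.loc[(tab[col] != UNKNOWN) & ~tab[col].isin(known), col]
            if len(bad):
                raise ValueError(f"unknown {col} ids: {sorted(set(bad))}")
        one_parent = (tab["sire"] == UNKNOWN) != (tab["dam"] == UNKNOWN)
        if one_parent.any():
            raise ValueError(
                f"individuals with exactly one known parent: "
                f"{tab.loc[one_parent, 'id'].tolist()}"
            )
        self.table = self._toposort(tab)

    @staticmethod
    def _toposort(tab: pd.DataFrame) -> pd.DataFrame:
        """Kahn's algorithm; raises on parentage cycles."""
        parents = {
            row.id: {p for p in (row.sire, row.dam) if p != UNKNOWN}
            for row in tab.itertuples()
        }
        children: dict[str, list[str]] = {i: [] for i in parents}
        indeg = {i: len(ps) for i, ps in parents.items()}
        for child, ps in parents.items():
            for p in ps:
                children[p].append(child)
        queue = sorted(i for i, d in indeg.items() if d == 0)
        order: list[str] = []
        while queue:
            node = queue.pop(0)
            order.append(node)
            for ch in children[node]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(order) != len(parents):
            cyclic = sorted(set(parents) - set(order))
            raise ValueError(f"pedigree contains a parentage cycle involving: {cyclic}")
        return tab.set_index("id").loc[order].reset_index()

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    @property
    def founders(self) -> list[str]:
        t = self.table
        return t.loc[(t["sire"] == UNKNOWN), "id"].tolist()

    @property
    def offspring(self) -> list[str]:
        t = self.table
        return t.loc[(t["sire"] != UNKNOWN), "id"].tolist()

    def parents_of(self, ind: str) -> tuple[str, str]:
        row = self.table.set_index("id").loc[ind]
        return row["sire"], row["dam"]

    def n_generations(self) -> int:
        """Maximum pedigree depth (founders = 1)."""
        depth: dict[str, int] = {}
        for row in self.table.itertuples():
            if row.sire == UNKNOWN:
                depth[row.id] = 1
            else:
                depth[row.id] = 1 + max(depth[row.sire], depth[row.dam])
        return max(depth.values()) if depth else 0

    def family_of(self) -> pd.Series:
        """Family label (sire x dam pair) per offspring, indexed by id."""
        off = self.table[self.table["sire"] != UNKNOWN]
        return pd.Series(
            (off["sire"] + "x" + off["dam"]).to_numpy(), index=off["id"], name="family"
        )


def gen_pedigree(
    strains: list[str],
    n_families_per_cross: int,
    n_offspring_per_family: int,
    half_sib: bool = True,
    seed: int = 0,
) -> Pedigree:
    """Build a two-generation multi-strain cross design.

    Each strain label defines a cross with ``n_families_per_cross`` full-sib
    families of ``n_offspring_per_family`` offspring.  With ``half_sib=True``
    consecutive family pairs within a cross share their sire, so the design
    contains paternal half-sib links; dams are always unique.

    Founders have unknown parents; sexes are recorded as M/F for parents and
    U for offspring.
    """
    if len(strains) < 2:
        raise ValueError("need at least 2 strains")
    if n_families_per_cross < 1 or n_offspring_per_family < 1:
        raise ValueError("family and offspring counts must be >= 1")

    rows: list[dict] = []
    for strain in strains:
        n_sires = (
            (n_families_per_cross + 1) // 2 if half_sib and n_families_per_cross >= 2
            else n_families_per_cross
        )
        sires = [f"{strain}_S{i + 1}" for i in range(n_sires)]
        dams = [f"{strain}_D{i + 1}" for i in range(n_families_per_cross)]
        for s in sires:
            rows.append({"id": s, "sire": UNKNOWN, "dam": UNKNOWN, "strain": strain, "sex": "M"})
        for d in dams:
            rows.append({"id": d, "sire": UNKNOWN, "dam": UNKNOWN, "strain": strain, "sex": "F"})
        for fam_idx in range(n_families_per_cross):
            sire = sires[fam_idx // 2] if half_sib and n_families_per_cross >= 2 else sires[fam_idx]
            dam = dams[fam_idx]
            for k in range(n_offspring_per_family):
                rows.append(
                    {
                        "id": f"{strain}_F{fam_idx + 1}_O{k + 1}",
                        "sire": sire,
                        "dam": dam,
                        "strain": strain,
                        "sex": "U",
                    }
                )
    return Pedigree(pd.DataFrame(rows))
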