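"""Readers and writers for the pipeline's tabular formats.

All tables are plain CSV/TSV with a one-line header (delimiter chosen by
file extension).  Missing values are empty fields or "NA".  The formats:

* cohort / phenotype table: ``id`` plus trait columns (strain, family,
  weight, spot_count, spot_density, ...); unknown columns are preserved.
* pedigree: ``id, sire, dam, strain[, sex]`` with empty parents for founders.
* genetic map: ``linkage_group, marker_id, position_cM`` (TSV by convention).
* genotypes: one row per individual (``id`` column), one column per marker;
  values either dosages 0/1/2 or a phased ``A|B`` dialect (auto-detected).
* landmarks sidecar: ``image_id, landmark, x, y`` rows naming the anatomical
  points of each image.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genedrop import GeneticMap, GenotypeMatrix
from .pedigree import Pedigree
from .spots import Landmarks

__all__ = [
    "read_cohort",
    "write_table",
    "read_pedigree",
    "write_pedigree",
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "read_landmarks",
    "write_landmarks",
    "file_digest",
    "write_json",
]

_NA = ["", "NA"]


def _sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_cohort(
    path: str | Path, required: tuple[str, ...] = ("id",)
) -> pd.DataFrame:
    """Load a per-fish table, enforcing mandatory columns and unique ids."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep(path), na_values=_NA, keep_default_na=False)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise KeyError(f"{path.name}: missing mandatory column(s) {missing}")
    if "id" in table.columns:
        table["id"] = table["id"].astype(str)
        if table["id"].duplicated().any():
            dupes = table.loc[table["id"].duplicated(), "id"].tolist()
            raise ValueError(f"{path.name}: duplicate fish id(s) {dupes}")
    return table


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep=_sep(path), index=False)
    return path


def read_pedigree(path: str | Path) -> Pedigree:
    path = Path(path)
    tab = pd.read_csv(path, sep=_sep(path), na_values=_NA, keep_default_na=False, dtype=str)
    return Pedigree(tab)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> Path:
    return write_table(pedigree.table, path)


def read_map(path: str | Path) -> GeneticMap:
    path = Path(path)
    return GeneticMap(pd.read_csv(path, sep=_sep(path)))


def write_map(gmap: GeneticMap, path: str | Path) -> Path:
    return write_table(gmap.table, path)


def read_genotypes(path: str | Path, gmap: GeneticMap) -> GenotypeMatrix:
    """Load genotypes in either the dosage (0/1/2) or phased ("A|B") dialect."""
    path = Path(path)
    tab = pd.read_csv(path, sep=_sep(path), dtype=str).set_index("id")
    missing = [m for m in gmap.marker_ids if m not in tab.columns]
    if missing:
        raise KeyError(f"{path.name}: genotype file lacks mapped marker(s) {missing}")
    tab = tab[gmap.marker_ids]
    ids = tab.index.astype(str).tolist()
    sample = str(tab.iloc[0, 0])
    phased = "|" in sample
    n, m = tab.shape
    alleles = np.zeros((n, m, 2), dtype=np.int8)
    if phased:
        vals = tab.to_numpy(dtype=str)
        alleles[:, :, 0] = np.char.partition(vals, "|")[:, :, 0].astype(np.int8)
        alleles[:, :, 1] = np.char.rpartition(vals, "|")[:, :, 2].astype(np.int8)
    else:
        dose = tab.to_numpy(dtype=float).astype(np.int8)
        if dose.min() < 0 or dose.max() > 2:
            raise ValueError(f"{path.name}: dosages outside 0..2")
        alleles[:, :, 0] = (dose >= 1).astype(np.int8)
        alleles[:, :, 1] = (dose == 2).astype(np.int8)
    return GenotypeMatrix(ids=ids, alleles=alleles, gmap=gmap, phased=phased)


def write_genotypes(
    geno: GenotypeMatrix, path: str | Path, dialect: str = "dosage"
) -> Path:
    return write_table(geno.to_frame(dialect=dialect).reset_index(), path)


def read_landmarks(path: str | Path) -> dict[str, Landmarks]:
    """Landmark sidecar -> mapping image_id -> Landmarks."""
    path = Path(path)
    tab = pd.read_csv(path, sep=_sep(path))
    out: dict[str, Landmarks] = {}
    for image_id, grp in tab.groupby("image_id"):
        pts = {row.landmark: (int(row.x), int(row.y)) for row in grp.itertuples()}
        out[str(image_id)] = Landmarks(
            pectoral_fin_top=pts["pectoral_fin_top"],
            gill_crease_x=pts["gill_crease"][0],
            lateral_line_y=pts["lateral_line"][1],
            dorsal_fin_front_x=pts["dorsal_fin_front"][0],
            eye=pts.get("eye"),
        )
    return out


def write_landmarks(landmarks: dict[str, Landmarks], path: str | Path) -> Path:
    rows = []
    for image_id, lm in landmarks.items():
        rows.extend(
            [
                (image_id, "pectoral_fin_top", *lm.pectoral_fin_top),
                (image_id, "gill_crease", lm.gill_crease_x, 0),
                (image_id, "lateral_line", 0, lm.lateral_line_y),
                (image_id, "dorsal_fin_front", lm.dorsal_fin_front_x, 0),
            ]
        )
        if lm.eye is not None:
            rows.append((image_id, "eye", *lm.eye))
    return write_table(
        pd.DataFrame(rows, columns=["image_id", "landmark", "x", "y"]), path
    )


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
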