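"""Pedigree-based additive (numerator) relationship matrix.

The tabular method builds A row by row in topological order:

    a_ii = 1 + 0.5 * a_{sire(i), dam(i)}
    a_ij = 0.5 * (a_{j, sire(i)} + a_{j, dam(i)})   for j processed before i

with unknown parents contributing zero.  A is the expected additive genetic
covariance structure (twice the kinship coefficient) and is the G-side
covariance of the polygenic effect in the animal model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree

__all__ = ["additive_relationship"]


def additive_relationship(pedigree: Pedigree, ids: list[str] | None = None) -> pd.DataFrame:
    """Numerator relationship matrix A over the pedigree's individuals.

    Parameters
    ----------
    pedigree
        Validated (hence acyclic, topologically ordered) pedigree.
    ids
        Optional subset/order of individuals for the returned matrix; the
        full pedigree is always used for the recursion.

    Returns
    -------
    DataFrame indexed by individual id on both axes.
    """
    tab = pedigree.table
    order = tab["id"].tolist()
    row = {ind: i for i, ind in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for i, rec in enumerate(tab.itertuples()):
        if rec.sire == UNKNOWN:
            a[i, i] = 1.0
        else:
            s, d = row[rec.sire], row[rec.dam]
            a[i, i] = 1.0 + 0.5 * a[s, d]
            vals = 0.5 * (a[:i, s] + a[:i, d])
            a[i, :i] = vals
            a[:i, i] = vals
    out = pd.DataFrame(a, index=order, columns=order)
    if ids is not None:
        out = out.loc[ids, ids]
    return out
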