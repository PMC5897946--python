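"""Position-wise identity-by-descent matrices for two-generation pedigrees.

The IBD matrix at a genomic position holds, for every pair of individuals,
the expected proportion of alleles shared identical by descent (twice the
locus-specific kinship; diagonal 1 for non-inbred individuals).  For a pair
of offspring sharing a parent, each shared parent contributes

    0.5 * P(both inherited the same parental haplotype at the position),

computed from the per-meiosis origin probabilities of the haplotype
assignment.  Founders are assumed unrelated and non-inbred; a parent and its
offspring share exactly 0.5 at every locus.  ZZ' in the QTL model is this
matrix: it is the covariance structure of the random QTL effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree
from .phasing import HaplotypeAssignment

__all__ = ["ibd_matrix"]


def ibd_matrix(
    assignment: HaplotypeAssignment,
    pedigree: Pedigree,
    lg: str,
    position_cM: float,
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """IBD (pi) matrix at one genomic position.

    Parameters
    ----------
    assignment
        Parental-origin probabilities from :func:`phase_offspring` (or the
        truth-based oracle).
    pedigree
        Two-generation pedigree; deeper pedigrees raise ``ValueError``.
    lg, position_cM
        Query position; must lie on the mapped range of the linkage group.
    ids
        Optional subset/order for the returned matrix (e.g. phenotyped
        offspring only).

    Returns
    -------
    Symmetric DataFrame with entries in [0, 1] and unit diagonal.
    """
    if pedigree.n_generations() > 2:
        raise ValueError("IBD matrices are defined for two-generation pedigrees only")
    tab = pedigree.table
    all_ids = tab["id"].tolist()
    pos_of = {ind: i for i, ind in enumerate(all_ids)}
    n = len(all_ids)
    pi = np.eye(n)

    off = tab.loc[tab["sire"] != UNKNOWN]
    off_ids = off["id"].tolist()
    if off_ids != assignment.offspring_ids:
        raise ValueError("assignment offspring do not match the pedigree")

    p_sire = assignment.origin_prob("sire", lg, position_cM)
    p_dam = assignment.origin_prob("dam", lg, position_cM)

    # Parent-offspring sharing is 0.5 at every locus.
    for rec in off.itertuples():
        i = pos_of[rec.id]
        for par in (rec.sire, rec.dam):
            j = pos_of[par]
            pi[i, j] = pi[j, i] = 0.5

    # Offspring pairs: each shared parent contributes 0.5 * P(same haplotype).
    for parent_key, probs in (("sire", p_sire), ("dam", p_dam)):
        groups = off.groupby(parent_key, sort=False).indices
        for _, members in groups.items():
            if len(members) < 2:
                continue
            p = probs[members]
            same = np.outer(p, p) + np.outer(1.0 - p, 1.0 - p)
            rows = np.asarray([pos_of[off_ids[k]] for k in members])
            pi[np.ix_(rows, rows)] += 0.5 * same
            pi[rows, rows] -= 0.5 * same.diagonal()  # keep the unit diagonal

    out = pd.DataFrame(pi, index=all_ids, columns=all_ids)
    if ids is not None:
        out = out.loc[ids, ids]
    return out
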