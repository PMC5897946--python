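import numpy as np
import pandas as pd
import pytest

import salmospot as sp


@pytest.fixture(scope="session")
def small_pedigree() -> sp.Pedigree:
    """2 strains x 2 families x 5 offspring, half-sib sires."""
    return sp.gen_pedigree(["Mowi", "Figgjo"], 2, 5)


@pytest.fixture(scope="session")
def nuclear_cohort():
    """Mid-sized cohort with a planted QTL for genetics tests."""
    spec = sp.CohortSpec(
        strains=("Mowi", "Figgjo"),
        n_families_per_cross=6,
        n_offspring_per_family=12,
        variance_fractions=(0.05, 0.25, 0.10, 0.60),
        seed=42,
    )
    cohort, ped, geno, truth = sp.simulate_cohort(spec)
    return {"spec": spec, "cohort": cohort, "pedigree": ped, "geno": geno, "truth": truth}


def flood_fill_count(mask: np.ndarray) -> int:
    """Brute-force 8-connected component count by BFS flood fill.

    Independent oracle for the labelled-component spot counter; pure Python,
    no image-processing library involved.
    """
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count
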