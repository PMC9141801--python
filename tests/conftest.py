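import numpy as np
import pandas as pd
import pytest

from triotdt.core import MISSING, CohortGenotypes, Trio, TrioSet


def make_trioset(n_trios: int) -> TrioSet:
    return TrioSet([
        Trio(f"T{i:03d}", f"T{i:03d}_c", f"T{i:03d}_m", f"T{i:03d}_f")
        for i in range(n_trios)
    ])


def cohort_from_dosages(child, mother, father, chrom="1", start_pos=100,
                        dp=60, gq=99):
    """Build a clean biallelic cohort from (V, n_trios) dosage arrays.

    Payload is clean (high DP/GQ, allele balance consistent with dosage) so
    QC filters pass everything; -1 entries stay missing.
    """
    child, mother, father = (np.atleast_2d(np.asarray(x, dtype=np.int8))
                             for x in (child, mother, father))
    V, n_trios = child.shape
    trios = make_trioset(n_trios)
    S = trios.n_samples
    dos = np.empty((V, S), dtype=np.int8)
    dos[:, 0::3], dos[:, 1::3], dos[:, 2::3] = child, mother, father

    miss = dos == MISSING
    gt1 = np.where(miss, MISSING, (dos >= 1).astype(np.int8)).astype(np.int8)
    gt2 = np.where(miss, MISSING, (dos == 2).astype(np.int8)).astype(np.int8)

    variants = pd.DataFrame({
        "chrom": [chrom] * V,
        "pos": np.arange(start_pos, start_pos + V),
        "id": [f"v{i}" for i in range(V)],
        "ref": ["A"] * V,
        "alt": ["G"] * V,
    })
    ar = np.where(miss, np.nan, np.where(dos == 1, 0.5, np.where(dos == 2, 1.0, 0.0)))
    geno = CohortGenotypes(
        variants, trios.samples, gt1, gt2,
        np.full((V, S), dp, dtype=np.int32),
        np.full((V, S), gq, dtype=np.int32),
        ar,
    )
    return geno, trios


@pytest.fixture
def tiny_cohort():
    """3 trios, 2 variants: variant 0 forced transmissions, variant 1 mixed."""
    child = [[1, 1, 0], [2, 1, 0]]
    mother = [[1, 1, 0], [1, 1, 1]]
    father = [[0, 0, 0], [1, 1, 0]]
    return cohort_from_dosages(child, mother, father)
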