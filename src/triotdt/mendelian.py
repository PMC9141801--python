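"""Mendelian-consistency checking, error policy, and de novo calling.

A trio genotype triple (child, mother, father), coded as alternate-allele
dosages in {0, 1, 2}, is Mendelian-consistent when the child's dosage can
be assembled from one gamete of each parent (a homozygote contributes its
only allele, a heterozygote either). Of the 27 ordered triples, 12 are
inconsistent.

Inconsistencies split into two classes: the *de novo pattern* — the child
carries an alternate allele while both parents are homozygous reference —
and every *other* inconsistency (e.g. child 0 with a parent 2), which is
treated as a genotyping error and never reported as de novo.

Policy: a variant with >= 2 inconsistencies across trios is removed from
association analyses; a variant with exactly one has the offending trio's
three genotypes blanked at that variant. De novo calling runs *before* the
zero-out (which would otherwise erase the signal), on a copy of the cohort
held to a stricter variant missingness bound (default 2%).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, CohortGenotypes, TrioSet, VariantKey

__all__ = [
    "MendelVerdict",
    "MendelPolicy",
    "DeNovoCall",
    "mendelian_check",
    "scan_mendelian",
    "apply_mendel_policy",
    "call_de_novo",
]

_GAMETES = {0: (0,), 1: (0, 1), 2: (1,)}


def _build_tables() -> tuple[np.ndarray, np.ndarray]:
    consistent = np.zeros((3, 3, 3), dtype=bool)
    denovo = np.zeros((3, 3, 3), dtype=bool)
    for c, m, f in product(range(3), repeat=3):
        consistent[c, m, f] = any(
            a + b == c for a in _GAMETES[m] for b in _GAMETES[f]
        )
        denovo[c, m, f] = (not consistent[c, m, f]) and m == 0 and f == 0 and c >= 1
    return consistent, denovo


_CONSISTENT, _DENOVO_PATTERN = _build_tables()


@dataclass(frozen=True)
class MendelVerdict:
    consistent: bool
    error_class: str  # none | de_novo_pattern | other_inconsistency
    trio_id: str = ""
    variant: VariantKey | None = None

    def __post_init__(self) -> None:
        if (self.error_class == "none") != self.consistent:
            raise ValueError("error_class must be 'none' iff consistent")


@dataclass(frozen=True)
class MendelPolicy:
    """Error-handling policy for association analyses."""

    drop_threshold: int = 2       # variant removed at this many inconsistencies
    zero_out_single: bool = True  # blank the offending trio at single-error variants
    denovo_max_missing: float = 0.02  # stricter variant missingness for de novo calling

    def __post_init__(self) -> None:
        if self.drop_threshold < 1:
            raise ValueError("drop_threshold must be >= 1")


@dataclass(frozen=True)
class DeNovoCall:
    variant: VariantKey
    trio_id: str
    child_dosage: int
    mother_dosage: int
    father_dosage: int
    cohort_maf: float
    recurrence: int  # trios sharing the de novo pattern at this variant


def mendelian_check(
    child: int, mother: int, father: int,
    trio_id: str = "", variant: VariantKey | None = None,
) -> MendelVerdict:
    """Verdict for one dosage triple; a missing member is untestable
    (consistent by default)."""
    doses = (child, mother, father)
    if any(d == MISSING for d in doses):
        return MendelVerdict(True, "none", trio_id, variant)
    for d in doses:
        if d not in (0, 1, 2):
            raise ValueError(f"dosage must be in {{0,1,2}} or missing, got {d}")
    if _CONSISTENT[child, mother, father]:
        return MendelVerdict(True, "none", trio_id, variant)
    cls = "de_novo_pattern" if _DENOVO_PATTERN[child, mother, father] else "other_inconsistency"
    return MendelVerdict(False, cls, trio_id, variant)


def _triple_dosages(geno: CohortGenotypes, trios: TrioSet):
    dos = geno.dosage
    c, m, f = trios.member_columns()
    return dos[:, c], dos[:, m], dos[:, f]


def _inconsistency_mask(geno: CohortGenotypes, trios: TrioSet) -> np.ndarray:
    """(V, n_trios) boolean: testable and Mendelian-inconsistent."""
    dc, dm, df = _triple_dosages(geno, trios)
    testable = (dc != MISSING) & (dm != MISSING) & (df != MISSING)
    dc_, dm_, df_ = (np.where(testable, x, 0) for x in (dc, dm, df))
    return testable & ~_CONSISTENT[dc_, dm_, df_]


def scan_mendelian(
    geno: CohortGenotypes, trios: TrioSet
) -> tuple[pd.DataFrame, np.ndarray]:
    """Scan every (variant, trio) pair with all three members called.

    Returns the inconsistent verdicts as a table (variant key, trio,
    dosages, error class) — consistent pairs are implicit — and the
    per-variant inconsistency counts.
    """
    incons = _inconsistency_mask(geno, trios)
    counts = incons.sum(axis=1).astype(int)
    dc, dm, df = _triple_dosages(geno, trios)
    vi, ti = np.nonzero(incons)
    keys = geno.variant_keys()
    rows = []
    for v, t in zip(vi, ti):
        c, m, f = int(dc[v, t]), int(dm[v, t]), int(df[v, t])
        cls = "de_novo_pattern" if _DENOVO_PATTERN[c, m, f] else "other_inconsistency"
        k = keys[v]
        rows.append((k.chrom, k.pos, k.ref, k.alt, trios.trios[t].trio_id, c, m, f, cls))
    verdicts = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "trio_id",
                 "child", "mother", "father", "error_class"],
    )
    return verdicts, counts


def apply_mendel_policy(
    geno: CohortGenotypes, trios: TrioSet, counts: np.ndarray, policy: MendelPolicy
) -> CohortGenotypes:
    """Drop variants at >= drop_threshold errors; below the threshold,
    blank the offending trio's three genotypes at that variant only.

    Trios without errors are never altered.
    """
    out = geno.copy()
    if policy.zero_out_single:
        incons = _inconsistency_mask(out, trios)
        single = (counts >= 1) & (counts < policy.drop_threshold)
        if single.any():
            c, m, f = trios.member_columns()
            mask = np.zeros((out.n_variants, out.n_samples), dtype=bool)
            vi, ti = np.nonzero(incons & single[:, None])
            for cols in (c, m, f):
                mask[vi, cols[ti]] = True
            out.set_missing(mask)
    return out.subset_variants(counts < policy.drop_threshold)


def call_de_novo(
    geno: CohortGenotypes, trios: TrioSet, policy: MendelPolicy | None = None
) -> list[DeNovoCall]:
    """De novo candidates: child carries an alternate allele, both parents
    homozygous reference.

    Operates on a copy restricted to variants whose missing rate is at most
    ``policy.denovo_max_missing`` (strictly above is excluded), *before*
    any Mendelian zero-out. Each call carries the cohort minor-allele
    frequency and the variant's recurrence count across trios — recurrent
    "de novos" usually flag an alignment or calling artifact and are left
    to the user's judgement.
    """
    policy = policy if policy is not None else MendelPolicy()
    miss_rate = (geno.gt1 == MISSING).mean(axis=1)
    strict = geno.subset_variants(miss_rate <= policy.denovo_max_missing)

    dc, dm, df = _triple_dosages(strict, trios)
    testable = (dc != MISSING) & (dm != MISSING) & (df != MISSING)
    dc_, dm_, df_ = (np.where(testable, x, 0) for x in (dc, dm, df))
    pattern = testable & _DENOVO_PATTERN[dc_, dm_, df_]

    dos = strict.dosage
    called = dos != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(called, dos, 0).sum(axis=1) / (2.0 * called.sum(axis=1))
    maf = np.minimum(af, 1 - af)
    recurrence = pattern.sum(axis=1)

    keys = strict.variant_keys()
    calls = []
    for v, t in zip(*np.nonzero(pattern)):
        calls.append(DeNovoCall(
            variant=keys[v],
            trio_id=trios.trios[t].trio_id,
            child_dosage=int(dc[v, t]),
            mother_dosage=int(dm[v, t]),
            father_dosage=int(df[v, t]),
            cohort_maf=float(maf[v]),
            recurrence=int(recurrence[v]),
        ))
    return calls


def de_novo_table(calls: list[DeNovoCall]) -> pd.DataFrame:
    """Flat table of de novo calls (chrom, pos, ref, alt, trio, genotypes,
    cohort MAF, recurrence) for TSV export."""
    return pd.DataFrame(
        [
            (c.variant.chrom, c.variant.pos, c.variant.ref, c.variant.alt,
             c.trio_id, c.child_dosage, c.mother_dosage, c.father_dosage,
             c.cohort_maf, c.recurrence)
            for c in calls
        ],
        columns=["chrom", "pos", "ref", "alt", "trio_id",
                 "child", "mother", "father", "cohort_maf", "recurrence"],
    )
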