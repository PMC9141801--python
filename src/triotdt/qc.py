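"""Genotype-call and variant-level quality control.

The cascade mirrors a standard targeted-sequencing trio workflow: per-call
depth (DP >= 15), genotype quality (GQ >= 20) and genotype-class-specific
allele-balance windows, followed by variant-level missingness (drop if
> 20% missing) and monomorphism filters, and finally the Mendelian-error
policy. Boundary semantics are strict as stated: DP 15 passes, GQ 20
passes, a missing rate of exactly 0.20 passes, het alt-ratio exactly 0.3
or 0.7 passes, hom-ref alt-ratio exactly 0.15 fails, hom-alt exactly 0.85
fails.

DP/GQ/allele-balance failures blank the individual call (set it missing)
rather than dropping the whole variant; the subsequent missingness filter
then removes variants that lost too many calls. A call whose payload is
absent (no DP, no GQ, or no AD-derived alt-ratio) is exempt from the
corresponding filter: what is not measured cannot be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, CohortGenotypes, RegionSpec, TrioSet, split_multiallelic

__all__ = ["QCThresholds", "QCLog", "apply_call_filters", "filter_variants", "qc_pipeline"]


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults are the workflow's operating point.

    Allele-balance windows are per genotype class: hom-ref passes when
    alt_ratio < ``homref_ab_max``, hom-alt when alt_ratio >
    ``homalt_ab_min``, het when ``het_ab_low`` <= alt_ratio <=
    ``het_ab_high``.
    """

    min_depth: int = 15
    min_gq: int = 20
    homref_ab_max: float = 0.15
    homalt_ab_min: float = 0.85
    het_ab_low: float = 0.30
    het_ab_high: float = 0.70
    max_missing_rate: float = 0.20
    drop_monomorphic: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.homref_ab_max < self.het_ab_low <= self.het_ab_high
                < self.homalt_ab_min <= 1):
            raise ValueError("allele-balance windows must be ordered: "
                             "homref_ab_max < het_ab_low <= het_ab_high < homalt_ab_min")


@dataclass
class QCLog:
    """Ordered record of applied stages with survivor counts."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, geno: CohortGenotypes,
            calls_set_missing: int = 0, variants_dropped: int = 0) -> None:
        self.stages.append({
            "stage": stage,
            "calls_set_missing": int(calls_set_missing),
            "variants_dropped": int(variants_dropped),
            "variants_after": geno.n_variants,
            "nonmissing_calls_after": int((geno.gt1 != MISSING).sum()),
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __getitem__(self, stage: str) -> dict:
        for s in self.stages:
            if s["stage"] == stage:
                return s
        raise KeyError(stage)


def apply_call_filters(
    geno: CohortGenotypes, thr: QCThresholds, log: QCLog | None = None
) -> tuple[CohortGenotypes, QCLog]:
    """Blank calls failing DP, GQ, or the allele-balance window.

    Returns a new cohort; the input is not modified. Each failing call is
    set missing; surviving dosages are untouched.
    """
    log = log if log is not None else QCLog()
    out = geno.copy()
    called = out.gt1 != MISSING

    fail_dp = called & (out.dp != MISSING) & (out.dp < thr.min_depth)
    fail_gq = called & (out.gq != MISSING) & (out.gq < thr.min_gq)

    dos = out.dosage
    ar = out.alt_ratio
    has_ar = ~np.isnan(ar)
    with np.errstate(invalid="ignore"):
        fail_ab = called & has_ar & (
            ((dos == 0) & (ar >= thr.homref_ab_max))
            | ((dos == 2) & (ar <= thr.homalt_ab_min))
            | ((dos == 1) & ((ar < thr.het_ab_low) | (ar > thr.het_ab_high)))
        )

    out.set_missing(fail_dp)
    log.add("depth", out, calls_set_missing=int(fail_dp.sum()))
    out.set_missing(fail_gq & ~fail_dp)
    log.add("genotype_quality", out, calls_set_missing=int((fail_gq & ~fail_dp).sum()))
    new_ab = fail_ab & ~fail_dp & ~fail_gq
    out.set_missing(new_ab)
    log.add("allele_balance", out, calls_set_missing=int(new_ab.sum()))
    return out, log


def filter_variants(
    geno: CohortGenotypes, thr: QCThresholds, log: QCLog | None = None
) -> tuple[CohortGenotypes, QCLog]:
    """Drop variants by missingness (> max rate, strict) then monomorphism.

    Monomorphism is evaluated after call filtering: a variant whose
    surviving calls carry zero alternate alleles, or zero reference
    alleles, is uninformative for transmission and is removed.
    """
    log = log if log is not None else QCLog()
    miss_rate = (geno.gt1 == MISSING).mean(axis=1)
    keep = miss_rate <= thr.max_missing_rate
    out = geno.subset_variants(keep)
    log.add("missingness", out, variants_dropped=int((~keep).sum()))

    if thr.drop_monomorphic:
        dos = out.dosage
        called = dos != MISSING
        n_alt = np.where(called, dos, 0).sum(axis=1)
        n_ref = np.where(called, 2 - dos, 0).sum(axis=1)
        poly = (n_alt > 0) & (n_ref > 0) & called.any(axis=1)
        out = out.subset_variants(poly)
        log.add("monomorphism", out, variants_dropped=int((~poly).sum()))
    return out, log


def qc_pipeline(
    geno: CohortGenotypes,
    trios: TrioSet,
    thr: QCThresholds | None = None,
    mendel_policy=None,
    regions: RegionSpec | None = None,
):
    """Full QC cascade: regions -> multiallelic split -> call filters ->
    missingness/monomorphism -> Mendelian policy.

    De novo candidates are collected (under the stricter missingness regime)
    before the Mendelian zero-out erases their signal.

    Returns ``(clean_cohort, qc_log, de_novo_calls)``; ``de_novo_calls`` is
    None when ``mendel_policy`` is None.
    """
    from .mendelian import MendelPolicy, apply_mendel_policy, call_de_novo, scan_mendelian

    thr = thr if thr is not None else QCThresholds()
    log = QCLog()
    log.add("input", geno)

    if regions is not None:
        geno = geno.restrict_to_regions(regions)
        log.add("region_restriction", geno,
                variants_dropped=log["input"]["variants_after"] - geno.n_variants)
    before = geno.n_variants
    geno = split_multiallelic(geno)
    log.add("multiallelic_split", geno,
            variants_dropped=0 if geno.n_variants >= before else before - geno.n_variants)

    geno, log = apply_call_filters(geno, thr, log)
    geno, log = filter_variants(geno, thr, log)

    denovo = None
    if mendel_policy is not None:
        if not isinstance(mendel_policy, MendelPolicy):
            raise TypeError("mendel_policy must be a MendelPolicy")
        denovo = call_de_novo(geno, trios, mendel_policy)
        verdicts, counts = scan_mendelian(geno, trios)
        geno = apply_mendel_policy(geno, trios, counts, mendel_policy)
        n_drop = int((counts >= mendel_policy.drop_threshold).sum())
        log.add("mendelian_policy", geno, variants_dropped=n_drop)
    return geno, log, denovo
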