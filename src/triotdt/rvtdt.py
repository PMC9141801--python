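"""Rare-variant collapsing TDT (trio burden tests with a permutation null).

Single-variant TDT is underpowered for rare alleles, so rare variants
(founder minor-allele frequency <= 0.01 by default) in a gene or
intergenic region are collapsed into one region-level test. The atomic
unit is the :class:`TransmissionEvent`: one heterozygous parent at one
rare variant in a complete, Mendelian-consistent trio either transmitted
the rare allele (1) or did not (0).

Statistics over a region's events:

* **CMC** — carrier collapse, McNemar-style: (number of trios that
  transmitted >= 1 rare allele) - (number that un-transmitted >= 1);
* **BRV** — allele-count burden: T_rare - U_rare summed over events;
* **WSS** — frequency-weighted burden: sum_v w_v (T_v - U_v) with
  w_v = 1 / sqrt(n_v q_v (1 - q_v)), where q_v is the rare-allele
  frequency estimated from the *untransmitted* parental alleles (the
  within-family pseudo-control), with a +1/+2 pseudocount;
* **VT** — the BRV statistic maximized over the distinct founder-MAF
  thresholds present in the region (the maximization is repeated inside
  every permutation).

The null is generated by independently flipping each event's transmitted
status with probability 1/2 — valid under Mendel's law regardless of
population structure, since each heterozygous parent transmits either
allele equiprobably under no association. p-values carry the +1
correction, p = (1 + #{permuted >= observed}) / (1 + n_permutations), and
therefore never equal 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, CohortGenotypes, RegionSpec, TrioSet, VariantKey
from .mendelian import _CONSISTENT
from .tdt import founder_alt_freq

__all__ = [
    "TransmissionEvent",
    "RareVariantSet",
    "RvTdtResult",
    "collapse_region",
    "burden_statistic",
    "vt_statistic",
    "permutation_p",
    "run_rvtdt",
]

TESTS = ("CMC", "BRV", "WSS", "VT")


@dataclass(frozen=True)
class TransmissionEvent:
    trio_id: str
    variant: VariantKey
    transmitted_dose: int  # 1 if the rare allele was transmitted
    parent: str  # "mother" | "father"


@dataclass
class RareVariantSet:
    """Rare variants of one region plus their transmission events.

    Event arrays are parallel: ``event_variant[k]`` indexes ``variants``,
    ``event_trio[k]`` indexes the trio list, ``event_transmitted[k]`` is
    the transmitted rare-allele dose in {0, 1}.
    """

    region_label: str
    variants: list[VariantKey]
    founder_maf: np.ndarray  # per variant, minor-allele frequency in founders
    maf_threshold: float
    trio_ids: list[str]
    event_variant: np.ndarray
    event_trio: np.ndarray
    event_transmitted: np.ndarray
    event_parent: np.ndarray

    @property
    def n_events(self) -> int:
        return len(self.event_transmitted)

    @property
    def is_empty(self) -> bool:
        return len(self.variants) == 0 or self.n_events == 0

    def events(self) -> list[TransmissionEvent]:
        return [
            TransmissionEvent(
                self.trio_ids[t], self.variants[v], int(x), str(p)
            )
            for v, t, x, p in zip(
                self.event_variant, self.event_trio,
                self.event_transmitted, self.event_parent,
            )
        ]


def collapse_region(
    geno: CohortGenotypes,
    trios: TrioSet,
    region_label: str,
    maf_threshold: float = 0.01,
    region: RegionSpec | None = None,
) -> RareVariantSet:
    """Collect the region's rare variants and their transmission events.

    Rarity is judged on the *founder* (parental) minor-allele frequency
    estimated from the cohort itself; the threshold is inclusive
    (MAF exactly 0.01 is rare). The rare allele at each variant is its
    founder minor allele, so transmissions are oriented per variant.
    """
    if region is not None:
        geno = geno.subset_variants(
            region.contains_many(
                geno.variants["chrom"].astype(str).tolist(),
                geno.variants["pos"].to_numpy(),
            )
        )
    af = founder_alt_freq(geno, trios)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(af, 1 - af)
        rare = np.isfinite(maf) & (maf <= maf_threshold) & (maf > 0)
    sub = geno.subset_variants(rare)
    alt_is_rare = af[rare] <= 0.5

    dos = sub.dosage
    c, m, f = trios.member_columns()
    dc, dm, df = dos[:, c], dos[:, m], dos[:, f]
    # orient dosages so "1 allele" always means one copy of the rare allele
    flip = ~alt_is_rare
    dc, dm, df = (np.where((x != MISSING) & flip[:, None], 2 - x, x) for x in (dc, dm, df))

    testable = (dc != MISSING) & (dm != MISSING) & (df != MISSING)
    dc_, dm_, df_ = (np.where(testable, x, 0) for x in (dc, dm, df))
    ok = testable & _CONSISTENT[dc_, dm_, df_]

    ev_v, ev_t, ev_x, ev_p = [], [], [], []

    def _add(mask: np.ndarray, transmitted: np.ndarray, parent: str) -> None:
        vi, ti = np.nonzero(mask)
        ev_v.append(vi)
        ev_t.append(ti)
        ev_x.append(transmitted[mask].astype(np.int8))
        ev_p.append(np.full(mask.sum(), parent, dtype=object))

    het_m, het_f = (dm_ == 1), (df_ == 1)
    hom_m, hom_f = ~het_m, ~het_f
    # het mother x hom father
    _add(ok & het_m & hom_f, (dc_ - df_ // 2 == 1), "mother")
    # het father x hom mother
    _add(ok & het_f & hom_m, (dc_ - dm_ // 2 == 1), "father")
    # double het: two events; for child dosage 1 the transmitting parent is
    # unidentifiable without phase — the maternal event is scored as the
    # transmission (only aggregate counts enter every statistic)
    both = ok & het_m & het_f
    _add(both, (dc_ >= 1), "mother")
    _add(both, (dc_ == 2), "father")

    return RareVariantSet(
        region_label=region_label,
        variants=sub.variant_keys(),
        founder_maf=maf[rare],
        maf_threshold=maf_threshold,
        trio_ids=[t.trio_id for t in trios.trios],
        event_variant=np.concatenate(ev_v) if ev_v else np.array([], dtype=int),
        event_trio=np.concatenate(ev_t) if ev_t else np.array([], dtype=int),
        event_transmitted=np.concatenate(ev_x) if ev_x else np.array([], dtype=np.int8),
        event_parent=np.concatenate(ev_p) if ev_p else np.array([], dtype=object),
    )


# --------------------------------------------------------------------------
# Statistics (all accept an (n_perm, n_events) 0/1 matrix for vectorized use)
# --------------------------------------------------------------------------

def _check_nonempty(rvs: RareVariantSet) -> None:
    if rvs.is_empty:
        raise ValueError(
            f"region {rvs.region_label!r}: no rare variants / transmission events"
        )


def _per_variant_tu(rvs: RareVariantSet, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(P, E) transmitted matrix -> per-variant (T_v, U_v), shape (P, V)."""
    V = len(rvs.variants)
    inc = np.zeros((rvs.n_events, V))
    inc[np.arange(rvs.n_events), rvs.event_variant] = 1.0
    T = t @ inc
    U = (1 - t) @ inc
    return T, U


def _brv(rvs: RareVariantSet, t: np.ndarray) -> np.ndarray:
    return (2 * t - 1).sum(axis=1)


def _cmc(rvs: RareVariantSet, t: np.ndarray) -> np.ndarray:
    n_trio = len(rvs.trio_ids)
    inc = np.zeros((rvs.n_events, n_trio))
    inc[np.arange(rvs.n_events), rvs.event_trio] = 1.0
    any_t = (t @ inc) > 0
    any_u = ((1 - t) @ inc) > 0
    return any_t.sum(axis=1) - any_u.sum(axis=1)


def _wss(rvs: RareVariantSet, t: np.ndarray) -> np.ndarray:
    T, U = _per_variant_tu(rvs, t)
    n_v = np.bincount(rvs.event_variant, minlength=len(rvs.variants)).astype(float)
    q = (U + 1.0) / (n_v + 2.0)  # rare-allele freq from untransmitted alleles
    w = 1.0 / np.sqrt(np.maximum(n_v, 1.0) * q * (1.0 - q))
    w[:, n_v == 0] = 0.0
    return (w * (T - U)).sum(axis=1)


def _vt(rvs: RareVariantSet, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Max over distinct-MAF thresholds of the BRV statistic; returns
    (statistic, chosen threshold) per permutation row."""
    T, U = _per_variant_tu(rvs, t)
    order = np.argsort(rvs.founder_maf, kind="mergesort")
    maf_sorted = rvs.founder_maf[order]
    net = (T - U)[:, order].cumsum(axis=1)
    # evaluate only at the last variant of each distinct MAF value
    ends = np.r_[maf_sorted[1:] != maf_sorted[:-1], True]
    net_at = net[:, ends]
    best = net_at.argmax(axis=1)
    stats = net_at[np.arange(net_at.shape[0]), best]
    thresholds = maf_sorted[ends][best]
    return stats, thresholds


def burden_statistic(rvs: RareVariantSet, test_name: str) -> float:
    """Observed CMC / BRV / WSS statistic for the region."""
    _check_nonempty(rvs)
    t = rvs.event_transmitted.astype(float)[None, :]
    if test_name == "CMC":
        return float(_cmc(rvs, t)[0])
    if test_name == "BRV":
        return float(_brv(rvs, t)[0])
    if test_name == "WSS":
        return float(_wss(rvs, t)[0])
    if test_name == "VT":
        return float(_vt(rvs, t)[0][0])
    raise ValueError(f"unknown test {test_name!r}; expected one of {TESTS}")


def vt_statistic(rvs: RareVariantSet) -> tuple[float, float]:
    """Observed VT statistic and the founder-MAF threshold achieving it."""
    _check_nonempty(rvs)
    t = rvs.event_transmitted.astype(float)[None, :]
    stats, thr = _vt(rvs, t)
    return float(stats[0]), float(thr[0])


@dataclass(frozen=True)
class RvTdtResult:
    region_label: str
    test_name: str
    statistic: float
    p: float
    n_permutations: int
    seed: int | None
    chosen_threshold: float | None = None  # VT only


def permutation_p(
    rvs: RareVariantSet,
    test_name: str,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> RvTdtResult:
    """Permutation p-value: flip each event's transmission with prob 1/2.

    The flip preserves each trio's heterozygous-parent count exactly (only
    direction changes), so the null respects the family structure and any
    population stratification. The WSS weights and the VT maximization are
    recomputed inside every permutation.
    """
    _check_nonempty(rvs)
    if n_permutations < 100:
        warnings.warn(f"n_permutations = {n_permutations} < 100: p-value resolution is poor")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_repr = seed if isinstance(seed, (int, np.integer)) else None

    stat_fn = {"CMC": _cmc, "BRV": _brv, "WSS": _wss}.get(test_name)
    obs_thr: float | None = None
    t_obs = rvs.event_transmitted.astype(float)[None, :]
    t_perm = (rng.random((n_permutations, rvs.n_events)) < 0.5).astype(float)
    if test_name == "VT":
        obs_arr, thr_arr = _vt(rvs, t_obs)
        obs = float(obs_arr[0])
        obs_thr = float(thr_arr[0])
        null, _ = _vt(rvs, t_perm)
    elif stat_fn is not None:
        obs = float(stat_fn(rvs, t_obs)[0])
        null = stat_fn(rvs, t_perm)
    else:
        raise ValueError(f"unknown test {test_name!r}; expected one of {TESTS}")

    p = (1.0 + float((null >= obs).sum())) / (1.0 + n_permutations)
    return RvTdtResult(
        region_label=rvs.region_label,
        test_name=test_name,
        statistic=obs,
        p=p,
        n_permutations=n_permutations,
        seed=seed_repr,
        chosen_threshold=obs_thr,
    )


def run_rvtdt(
    geno: CohortGenotypes,
    trios: TrioSet,
    regions: dict[str, RegionSpec],
    tests: tuple[str, ...] = TESTS,
    maf_threshold: float = 0.01,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Collapse each labelled region and run the requested burden tests.

    Regions without rare variants are skipped. One independent permutation
    stream per (region, test), derived from ``seed``, keeps results
    reproducible and order-independent.
    """
    root = np.random.default_rng(seed)
    rows = []
    for label, region in regions.items():
        rvs = collapse_region(geno, trios, label, maf_threshold, region)
        if rvs.is_empty:
            continue
        for test in tests:
            res = permutation_p(rvs, test, n_permutations, seed=root.spawn(1)[0])
            rows.append((label, test, res.statistic, res.p,
                         res.n_permutations, res.chosen_threshold,
                         len(rvs.variants), rvs.n_events))
    return pd.DataFrame(
        rows,
        columns=["region", "test", "statistic", "p", "n_perm",
                 "vt_threshold", "n_rare_variants", "n_events"],
    )
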