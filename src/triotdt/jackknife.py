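"""Leave-one-out (jackknife) TDT and locus-heterogeneity partitioning.

When a cohort shows association peaks at several loci, different subsets
of families may drive different peaks (locus heterogeneity). The jackknife
scan re-runs the TDT at each locus's *index variant* — the top full-cohort
hit in the region, fixed before the scan — with one trio removed at a
time. A trio's *influence* on a locus is

    influence = [-log10 p (full cohort)] - [-log10 p (cohort minus trio)]

so positive influence means the trio strengthens the signal. Each trio is
then assigned to the locus where its influence is maximal, provided that
influence is positive (ties and all-non-positive rows stay unassigned),
and the TDT is re-run within each group.

The scan is deterministic: no randomness, and index variants are not
re-selected inside the loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CohortGenotypes, RegionSpec, TrioSet, VariantKey
from .tdt import SignificanceThresholds, _count_vectorized, run_tdt, tdt_statistic

__all__ = [
    "LocusSignal",
    "InfluenceMatrix",
    "TrioPartition",
    "select_index_variant",
    "leave_one_out_scan",
    "assign_trios",
    "per_group_tdt",
]


@dataclass(frozen=True)
class LocusSignal:
    locus_id: str
    region: RegionSpec
    index_variant: VariantKey

    def __post_init__(self) -> None:
        if not self.region.contains(self.index_variant.chrom, self.index_variant.pos):
            raise ValueError(
                f"index variant {self.index_variant} outside region of locus "
                f"{self.locus_id!r}"
            )


def select_index_variant(
    tdt_table: pd.DataFrame, region: RegionSpec, locus_id: str
) -> LocusSignal:
    """Locus anchored at the smallest-p full-cohort TDT hit inside a region."""
    inside = region.contains_many(
        tdt_table["chrom"].astype(str).tolist(), tdt_table["pos"].to_numpy()
    )
    sub = tdt_table[inside]
    if sub.empty:
        raise ValueError(f"no testable variant inside region for locus {locus_id!r}")
    top = sub.iloc[0]  # table is sorted by p ascending
    return LocusSignal(
        locus_id,
        region,
        VariantKey(str(top["chrom"]), int(top["pos"]), top["ref"], top["alt"]),
    )


@dataclass
class InfluenceMatrix:
    entries: np.ndarray  # (n_trios, n_loci), delta -log10 p
    trio_ids: list[str]
    locus_ids: list[str]
    full_neglogp: np.ndarray  # per locus, full-cohort -log10 p at the index variant

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.trio_ids, columns=self.locus_ids)


@dataclass
class TrioPartition:
    assignment: dict[str, str]  # trio_id -> locus_id or "unassigned"
    group_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.group_sizes:
            sizes: dict[str, int] = {}
            for locus in self.assignment.values():
                sizes[locus] = sizes.get(locus, 0) + 1
            self.group_sizes = sizes

    def group_indices(self, trios: TrioSet) -> dict[str, np.ndarray]:
        """Trio positions per locus (unassigned trios excluded)."""
        out: dict[str, list[int]] = {}
        for i, t in enumerate(trios.trios):
            locus = self.assignment.get(t.trio_id, "unassigned")
            if locus != "unassigned":
                out.setdefault(locus, []).append(i)
        return {k: np.array(v, dtype=int) for k, v in out.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trio_id": list(self.assignment), "locus": list(self.assignment.values())}
        )


def _variant_row(geno: CohortGenotypes, key: VariantKey) -> int:
    v = geno.variants
    hit = np.flatnonzero(
        (v["chrom"].astype(str) == key.chrom)
        & (v["pos"] == key.pos)
        & (v["ref"] == key.ref)
        & (v["alt"] == key.alt)
    )
    if len(hit) == 0:
        raise KeyError(f"index variant {key} not present in cohort")
    return int(hit[0])


def leave_one_out_scan(
    geno: CohortGenotypes, trios: TrioSet, loci: list[LocusSignal]
) -> InfluenceMatrix:
    """Influence of each trio on each locus's index-variant signal.

    Removing an uninformative trio (no scored transmission at the index
    variant) leaves the counts unchanged, so its influence is exactly 0.
    If removal makes the index variant untestable (T + U = 0), the trio is
    credited with the locus's full -log10 p (maximal influence).
    """
    dos = geno.dosage
    c, m, f = trios.member_columns()
    n_trios = len(trios)
    entries = np.zeros((n_trios, len(loci)))
    full_neglogp = np.zeros(len(loci))

    for j, locus in enumerate(loci):
        vi = _variant_row(geno, locus.index_variant)
        dc, dm, df = dos[vi, c], dos[vi, m], dos[vi, f]
        # each trio's own (t, u) contribution at the index variant
        t_i, u_i = _count_vectorized(dc[:, None], dm[:, None], df[:, None])
        T, U = int(t_i.sum()), int(u_i.sum())
        if T + U == 0:
            raise ValueError(
                f"index variant {locus.index_variant} has no informative "
                "transmissions in the full cohort"
            )
        full = -np.log10(tdt_statistic(T, U).p)
        full_neglogp[j] = full
        for i in range(n_trios):
            T_loo, U_loo = T - int(t_i[i]), U - int(u_i[i])
            if T_loo + U_loo == 0:
                entries[i, j] = full
            else:
                entries[i, j] = full + np.log10(tdt_statistic(T_loo, U_loo).p)

    return InfluenceMatrix(
        entries=entries,
        trio_ids=[t.trio_id for t in trios.trios],
        locus_ids=[l.locus_id for l in loci],
        full_neglogp=full_neglogp,
    )


def assign_trios(
    infl: InfluenceMatrix, min_influence: float = 0.0
) -> TrioPartition:
    """Argmax-positive assignment: each trio goes to the locus where its
    influence is maximal, provided that influence exceeds ``min_influence``;
    a tie for the maximum, or no positive influence, leaves it unassigned.
    """
    assignment: dict[str, str] = {}
    for i, trio_id in enumerate(infl.trio_ids):
        row = infl.entries[i]
        best = row.max()
        if best <= min_influence or (row == best).sum() > 1:
            assignment[trio_id] = "unassigned"
        else:
            assignment[trio_id] = infl.locus_ids[int(row.argmax())]
    return TrioPartition(assignment)


def per_group_tdt(
    geno: CohortGenotypes,
    trios: TrioSet,
    partition: TrioPartition,
    thresholds: SignificanceThresholds | None = None,
) -> dict[str, pd.DataFrame]:
    """Re-run the TDT within each locus's trio group.

    Unassigned trios take part in no group. An empty group yields an empty
    table with a warning.
    """
    groups = partition.group_indices(trios)
    out: dict[str, pd.DataFrame] = {}
    for locus_id in partition.group_sizes:
        if locus_id == "unassigned":
            continue
        idx = groups.get(locus_id, np.array([], dtype=int))
        if len(idx) == 0:
            warnings.warn(f"locus {locus_id!r}: empty trio group, no TDT run")
            out[locus_id] = pd.DataFrame()
            continue
        sub = trios.subset(idx)
        cols = np.array([trios.sample_index[s] for s in sub.samples], dtype=int)
        sub_geno = CohortGenotypes(
            geno.variants, sub.samples,
            geno.gt1[:, cols], geno.gt2[:, cols],
            geno.dp[:, cols], geno.gq[:, cols],
            geno.alt_ratio[:, cols], geno.region_set,
        )
        out[locus_id] = run_tdt(sub_geno, sub, thresholds)
    return out
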