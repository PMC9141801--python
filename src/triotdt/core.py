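"""Domain types and ingest for trio-cohort targeted sequencing data.

The sampling unit is the *trio* — an affected child plus both biological
parents. Genotypes live in a :class:`CohortGenotypes` matrix (variants x
samples) carrying per-call read depth (DP), genotype quality (GQ) and
alternate-allele read fraction, which the downstream QC cascade filters on.

Coordinate convention: user-facing positions are 1-based inclusive (VCF/BED
reporting style); all internal interval arithmetic is 0-based half-open.
The conversion happens exactly once, at ingest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trio",
    "TrioSet",
    "VariantKey",
    "RegionSpec",
    "CohortGenotypes",
    "read_pedigree",
    "read_genotypes",
    "split_multiallelic",
    "write_vcf",
]

MISSING = -1  # sentinel for integer genotype/DP/GQ payloads


@dataclass(frozen=True)
class Trio:
    """One child-parent trio; the design assumes an affected proband."""

    trio_id: str
    child_id: str
    mother_id: str
    father_id: str
    child_affected: bool = True

    def __post_init__(self) -> None:
        ids = {self.child_id, self.mother_id, self.father_id}
        if len(ids) != 3:
            raise ValueError(
                f"trio {self.trio_id!r}: child/mother/father IDs must be distinct"
            )

    @property
    def sample_ids(self) -> tuple[str, str, str]:
        return (self.child_id, self.mother_id, self.father_id)


class TrioSet:
    """Ordered collection of trios with a sample -> column index.

    Column order is (child, mother, father) per trio, in trio order.
    No sample may belong to two trios.
    """

    def __init__(self, trios: Sequence[Trio], exclusions: pd.DataFrame | None = None):
        self.trios: list[Trio] = list(trios)
        seen: dict[str, str] = {}
        for t in self.trios:
            for sid in t.sample_ids:
                if sid in seen:
                    raise ValueError(
                        f"sample {sid!r} appears in trios {seen[sid]!r} and {t.trio_id!r}"
                    )
                seen[sid] = t.trio_id
        self.samples: list[str] = [s for t in self.trios for s in t.sample_ids]
        self.sample_index: dict[str, int] = {s: i for i, s in enumerate(self.samples)}
        # samples/trios excluded at ingest, with reasons (may be empty)
        self.exclusions = (
            exclusions
            if exclusions is not None
            else pd.DataFrame(columns=["unit", "ids", "reason"])
        )

    def __len__(self) -> int:
        return len(self.trios)

    def __iter__(self):
        return iter(self.trios)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def member_columns(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Column indices of (children, mothers, fathers), each length n_trios."""
        c = np.array([self.sample_index[t.child_id] for t in self.trios], dtype=int)
        m = np.array([self.sample_index[t.mother_id] for t in self.trios], dtype=int)
        f = np.array([self.sample_index[t.father_id] for t in self.trios], dtype=int)
        return c, m, f

    def subset(self, keep: Iterable[int] | np.ndarray) -> "TrioSet":
        """New TrioSet restricted to trios at the given positions."""
        idx = np.asarray(list(keep), dtype=int)
        return TrioSet([self.trios[i] for i in idx])

    def write_exclusion_report(self, path: str | Path) -> None:
        self.exclusions.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True, order=True)
class VariantKey:
    """A biallelic variant site (post multiallelic split)."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if "," in self.alt:
            raise ValueError("VariantKey requires a single alternate allele")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


class RegionSpec:
    """A set of target intervals, stored 0-based half-open per chromosome.

    Construct from 1-based inclusive coordinates (as printed in papers and
    carried by VCF POS) with :meth:`from_1based`, or from BED (already
    0-based half-open) with :meth:`from_bed`. Overlapping or adjacent
    intervals on a chromosome are merged at construction.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]], label: str = ""):
        self.label = label
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if not start < end:
                raise ValueError(f"empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
        self._by_chrom: dict[str, np.ndarray] = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            merged: list[list[int]] = [list(ivals[0])]
            for s, e in ivals[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._by_chrom[chrom] = np.asarray(merged, dtype=np.int64)

    @classmethod
    def from_1based(
        cls, intervals: Iterable[tuple[str, int, int]], label: str = ""
    ) -> "RegionSpec":
        """Build from 1-based inclusive (chrom, start, end) triples."""
        return cls(((c, s - 1, e) for c, s, e in intervals), label=label)

    @classmethod
    def from_bed(cls, path: str | Path, label: str = "") -> "RegionSpec":
        bed = pd.read_csv(
            path, sep=r"\s+", header=None, usecols=[0, 1, 2], comment="#",
            names=["chrom", "start", "end"], dtype={"chrom": str},
        )
        return cls(bed.itertuples(index=False, name=None), label=label or str(path))

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        """Internal 0-based half-open intervals, sorted by chromosome."""
        return [
            (c, int(s), int(e))
            for c in sorted(self._by_chrom)
            for s, e in self._by_chrom[c]
        ]

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        ivals = self._by_chrom.get(str(chrom))
        if ivals is None:
            return False
        p = pos - 1  # to 0-based
        i = np.searchsorted(ivals[:, 0], p, side="right") - 1
        return i >= 0 and p < ivals[i, 1]

    def contains_many(self, chroms: Sequence[str], pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos)
        out = np.zeros(len(pos), dtype=bool)
        for i, (c, p) in enumerate(zip(chroms, pos)):
            out[i] = self.contains(c, int(p))
        return out

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{self.label}\n")


class CohortGenotypes:
    """Variant x sample genotype matrix with DP/GQ/allele-balance payload.

    Genotypes are stored as two allele-index arrays ``gt1``/``gt2`` (``-1``
    missing) so that multiallelic records survive ingest intact; after
    :func:`split_multiallelic` every record is biallelic and ``dosage``
    (alternate-allele count in {0,1,2}, -1 missing) is well defined.

    ``alt_ratio`` is alt reads / (ref reads + alt reads) from the AD field,
    NaN when AD is absent (such calls are exempt from allele-balance QC).
    """

    def __init__(
        self,
        variants: pd.DataFrame,
        samples: Sequence[str],
        gt1: np.ndarray,
        gt2: np.ndarray,
        dp: np.ndarray,
        gq: np.ndarray,
        alt_ratio: np.ndarray,
        region_set: RegionSpec | None = None,
        ad: list | None = None,
    ):
        self.variants = variants.reset_index(drop=True)
        self.samples = list(samples)
        V, S = len(self.variants), len(self.samples)
        for name, arr in (("gt1", gt1), ("gt2", gt2), ("dp", dp), ("gq", gq),
                          ("alt_ratio", alt_ratio)):
            if arr.shape != (V, S):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(V, S)}")
        self.gt1 = gt1
        self.gt2 = gt2
        self.dp = dp
        self.gq = gq
        self.alt_ratio = alt_ratio
        self.region_set = region_set
        self.ad = ad  # per-variant (S, n_alleles) read-depth matrices, pre-split only

    # -- basic geometry ----------------------------------------------------
    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def is_biallelic(self) -> bool:
        return not self.variants["alt"].str.contains(",").any()

    @property
    def dosage(self) -> np.ndarray:
        """Alternate-allele count per call, -1 missing. Biallelic records only."""
        if not self.is_biallelic:
            raise ValueError("dosage undefined before multiallelic split")
        miss = (self.gt1 == MISSING) | (self.gt2 == MISSING)
        d = (self.gt1 + self.gt2).astype(np.int8)
        d[miss] = MISSING
        return d

    def set_missing(self, mask: np.ndarray) -> None:
        """Blank calls (genotype and payload stay; dosage becomes missing)."""
        self.gt1 = np.where(mask, MISSING, self.gt1).astype(np.int8)
        self.gt2 = np.where(mask, MISSING, self.gt2).astype(np.int8)

    def variant_keys(self) -> list[VariantKey]:
        return [
            VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
            for r in self.variants.itertuples()
        ]

    def variant_labels(self) -> pd.Series:
        v = self.variants
        ids = v["id"] if "id" in v.columns else pd.Series(["."] * len(v))
        lab = v["chrom"].astype(str) + ":" + v["pos"].astype(str) + ":" + v["ref"] + ">" + v["alt"]
        return ids.where(ids.ne("."), lab)

    def subset_variants(self, keep: np.ndarray) -> "CohortGenotypes":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        ad = [self.ad[i] for i in keep] if self.ad is not None else None
        return CohortGenotypes(
            self.variants.iloc[keep], self.samples,
            self.gt1[keep].copy(), self.gt2[keep].copy(),
            self.dp[keep].copy(), self.gq[keep].copy(),
            self.alt_ratio[keep].copy(), self.region_set, ad,
        )

    def copy(self) -> "CohortGenotypes":
        return self.subset_variants(np.arange(self.n_variants))

    def restrict_to_regions(self, regions: RegionSpec) -> "CohortGenotypes":
        keep = regions.contains_many(
            self.variants["chrom"].tolist(), self.variants["pos"].to_numpy()
        )
        out = self.subset_variants(keep)
        out.region_set = regions
        return out


# --------------------------------------------------------------------------
# Ingest
# --------------------------------------------------------------------------

def read_pedigree(ped_source: str | Path) -> TrioSet:
    """Read a 6-column PED file into a :class:`TrioSet`.

    One trio is formed per affected child whose two parents both appear as
    rows in the file. Singletons, duos and unaffected children are excluded
    and listed in ``TrioSet.exclusions``; a duplicated child ID is a hard
    error.
    """
    ped = pd.read_csv(
        ped_source, sep=r"\s+", header=None, comment="#",
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    if ped["iid"].duplicated().any():
        dups = ped.loc[ped["iid"].duplicated(), "iid"].tolist()
        raise ValueError(f"duplicated individual ID(s) in PED: {dups}")
    present = set(ped["iid"])
    children = ped[(ped["father"] != "0") | (ped["mother"] != "0")]
    parent_ids = set(children["father"]) | set(children["mother"])

    trios: list[Trio] = []
    excl: list[dict] = []
    for row in children.itertuples():
        have_f = row.father != "0" and row.father in present
        have_m = row.mother != "0" and row.mother in present
        if not (have_f and have_m):
            kind = "duo" if (have_f or have_m) else "singleton"
            excl.append({"unit": kind, "ids": row.iid, "reason": "incomplete trio"})
            warnings.warn(f"child {row.iid}: incomplete trio ({kind}), excluded")
            continue
        affected = row.phenotype == "2"
        if not affected:
            excl.append({"unit": "trio", "ids": row.iid, "reason": "child not affected"})
            continue
        trios.append(Trio(row.fid, row.iid, row.mother, row.father))
    # founders with no child row are singletons
    for row in ped.itertuples():
        if row.father == "0" and row.mother == "0" and row.iid not in parent_ids:
            excl.append({"unit": "singleton", "ids": row.iid, "reason": "no trio membership"})
    return TrioSet(trios, pd.DataFrame(excl, columns=["unit", "ids", "reason"]))


def read_genotypes(
    vcf_source: str | Path, regions: RegionSpec | None, trios: TrioSet
) -> CohortGenotypes:
    """Load a multi-sample VCF into a :class:`CohortGenotypes`.

    Only records inside ``regions`` are retained (1-based POS membership);
    sample columns are reordered to the TrioSet's (child, mother, father)
    order. DP/GQ/AD are read when present, else recorded missing. A TrioSet
    sample absent from the VCF is a hard error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_source), gts012=False)
    vcf_index = {s: i for i, s in enumerate(vcf.samples)}
    for s in trios.samples:
        if s not in vcf_index:
            raise ValueError(f"sample {s!r} required by pedigree but absent from VCF")
    cols = np.array([vcf_index[s] for s in trios.samples], dtype=int)
    S = len(cols)

    rows, g1, g2, dps, gqs, ads = [], [], [], [], [], []
    for rec in vcf:
        if regions is not None and not regions.contains(rec.CHROM, rec.POS):
            continue
        alts = rec.ALT
        if not alts:
            continue
        gt = np.asarray(rec.genotype.array())[:, :2][cols]
        # half-called genotypes (one allele missing) are set fully missing
        gt[(gt < 0).any(axis=1)] = MISSING
        dp = rec.format("DP")
        dp = (np.full(S, MISSING, dtype=np.int32) if dp is None
              else np.where(dp[cols, 0] < 0, MISSING, dp[cols, 0]).astype(np.int32))
        gq = rec.format("GQ")
        gq = (np.full(S, MISSING, dtype=np.int32) if gq is None
              else np.where(gq[cols, 0] < 0, MISSING, gq[cols, 0]).astype(np.int32))
        ad = rec.format("AD")
        ad = None if ad is None else np.where(ad[cols] < 0, MISSING, ad[cols]).astype(np.int32)
        rows.append((rec.CHROM, rec.POS, rec.ID or ".", rec.REF, ",".join(alts)))
        g1.append(gt[:, 0].astype(np.int8))
        g2.append(gt[:, 1].astype(np.int8))
        dps.append(dp)
        gqs.append(gq)
        ads.append(ad)

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    V = len(variants)
    shape = (V, S)
    geno = CohortGenotypes(
        variants, trios.samples,
        np.array(g1, dtype=np.int8).reshape(shape),
        np.array(g2, dtype=np.int8).reshape(shape),
        np.array(dps, dtype=np.int32).reshape(shape),
        np.array(gqs, dtype=np.int32).reshape(shape),
        np.full(shape, np.nan),
        region_set=regions,
        ad=ads,
    )
    _fill_alt_ratio_biallelic(geno)
    return geno


def _fill_alt_ratio_biallelic(geno: CohortGenotypes) -> None:
    """alt_ratio = alt/(ref+alt) reads for records that are already biallelic."""
    if geno.ad is None:
        return
    multi = geno.variants["alt"].str.contains(",").to_numpy()
    for i in range(geno.n_variants):
        ad = geno.ad[i]
        if ad is None or multi[i] or ad.shape[1] < 2:
            continue
        ref, alt = ad[:, 0].astype(float), ad[:, 1].astype(float)
        ok = (ref >= 0) & (alt >= 0) & (ref + alt > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            geno.alt_ratio[i] = np.where(ok, alt / (ref + alt), np.nan)


def split_multiallelic(geno: CohortGenotypes) -> CohortGenotypes:
    """Expand every multiallelic record into one biallelic record per ALT.

    On a split record a sample's dosage counts only the focal alternate;
    genotypes carrying a *different* alternate allele are set missing on
    that record (recoding them as reference would inflate reference
    transmissions). Biallelic records pass through unchanged, so the
    operation is idempotent.
    """
    multi = geno.variants["alt"].str.contains(",").to_numpy()
    if not multi.any():
        out = geno.copy()
        _warn_non_normalized(out)
        return out

    rows, g1, g2, dps, gqs, ars = [], [], [], [], [], []
    for i, row in enumerate(geno.variants.itertuples()):
        alts = row.alt.split(",")
        a, b = geno.gt1[i], geno.gt2[i]
        ad = geno.ad[i] if geno.ad is not None else None
        for j, alt in enumerate(alts, start=1):
            if len(alts) == 1:
                na, nb, ar = a.copy(), b.copy(), geno.alt_ratio[i].copy()
            else:
                other = ((a > 0) & (a != j)) | ((b > 0) & (b != j))
                miss = (a == MISSING) | (b == MISSING) | other
                na = np.where(miss, MISSING, (a == j).astype(np.int8)).astype(np.int8)
                nb = np.where(miss, MISSING, (b == j).astype(np.int8)).astype(np.int8)
                ar = np.full(geno.n_samples, np.nan)
                if ad is not None and ad.shape[1] > j:
                    ref, alt_d = ad[:, 0].astype(float), ad[:, j].astype(float)
                    ok = (ref >= 0) & (alt_d >= 0) & (ref + alt_d > 0)
                    with np.errstate(invalid="ignore", divide="ignore"):
                        ar = np.where(ok, alt_d / (ref + alt_d), np.nan)
            rows.append((row.chrom, row.pos, row.id, row.ref, alt))
            g1.append(na)
            g2.append(nb)
            dps.append(geno.dp[i])
            gqs.append(geno.gq[i])
            ars.append(ar)

    out = CohortGenotypes(
        pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"]),
        geno.samples,
        np.vstack(g1).astype(np.int8), np.vstack(g2).astype(np.int8),
        np.vstack(dps).astype(np.int32), np.vstack(gqs).astype(np.int32),
        np.vstack(ars), geno.region_set, ad=None,
    )
    _warn_non_normalized(out)
    return out


def _warn_non_normalized(geno: CohortGenotypes) -> None:
    v = geno.variants
    shared = (v["ref"].str.len() > 1) & (v["alt"].str.len() > 1) & (
        v["ref"].str[-1] == v["alt"].str[-1]
    )
    if shared.any():
        n = int(shared.sum())
        warnings.warn(
            f"{n} indel record(s) look non-left-normalized (shared trailing base); "
            "no normalization is performed"
        )


# --------------------------------------------------------------------------
# VCF writing (plain text VCF 4.2, GT:DP:GQ:AD)
# --------------------------------------------------------------------------

def write_vcf(geno: CohortGenotypes, path: str | Path) -> None:
    """Write the cohort as a VCF 4.2 file (bgzipped + indexed if ``.gz``).

    Round-trip guarantee: re-reading with :func:`read_genotypes` reproduces
    the dosage/DP/GQ matrices exactly.
    """
    path = Path(path)
    plain = path.with_suffix("") if path.suffix == ".gz" else path
    chroms = sorted(set(geno.variants["chrom"].astype(str)))
    with open(plain, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        order = np.lexsort(
            (geno.variants["pos"].to_numpy(), geno.variants["chrom"].to_numpy())
        )
        ids = geno.variants["id"] if "id" in geno.variants.columns else None
        for i in order:
            row = geno.variants.iloc[i]
            vid = ids.iloc[i] if ids is not None else "."
            calls = []
            for s in range(geno.n_samples):
                a, b = geno.gt1[i, s], geno.gt2[i, s]
                gt = "./." if (a == MISSING or b == MISSING) else f"{a}/{b}"
                dp = "." if geno.dp[i, s] == MISSING else str(int(geno.dp[i, s]))
                gq = "." if geno.gq[i, s] == MISSING else str(int(geno.gq[i, s]))
                ad = _format_ad(geno, i, s)
                calls.append(f"{gt}:{dp}:{gq}:{ad}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t{vid}\t{row.ref}\t{row.alt}\t.\t.\t.\t"
                "GT:DP:GQ:AD\t" + "\t".join(calls) + "\n"
            )
    if path.suffix == ".gz":
        import pysam

        pysam.tabix_compress(str(plain), str(path), force=True)
        pysam.tabix_index(str(path), preset="vcf", force=True)
        plain.unlink()


def _format_ad(geno: CohortGenotypes, i: int, s: int) -> str:
    if geno.ad is not None and geno.ad[i] is not None:
        vals = geno.ad[i][s]
        if (vals >= 0).all():
            return ",".join(str(int(x)) for x in vals)
        return "."
    ar, dp = geno.alt_ratio[i, s], geno.dp[i, s]
    if np.isnan(ar) or dp == MISSING:
        return "."
    alt = int(round(ar * dp))
    return f"{dp - alt},{alt}"
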