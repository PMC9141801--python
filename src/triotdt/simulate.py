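"""Synthetic trio-cohort generator with LD, transmission distortion and noise.

Produces child-parent trio cohorts with the statistical structure the
analysis modules assume, plus a ground-truth table for scoring every
pipeline stage:

* **founder haplotypes** with blockwise linkage disequilibrium from a
  copying model: within a block every variant copies a shared block
  ancestor draw with probability ``ld_strength`` (else an independent
  Bernoulli of its own frequency), so the between-variant correlation is
  ``ld_strength**2`` times the comonotone-coupling correlation of the two
  marginals — an analytic r^2 that tests can check; blocks are
  independent, and parental transmission is per block (free recombination
  between blocks, none within);
* **risk loci** with distorted transmission: a heterozygous parent in the
  locus's trio subgroup transmits the haplotype carrying the risk allele
  with probability tau (tau = 0.5 is the null), giving the TDT the closed-
  form expected odds ratio tau / (1 - tau);
* **locus-heterogeneity subgroups**: disjoint trio subsets, each distorted
  at its own locus only;
* optional **ascertainment**: trios are redrawn until the child carries at
  least one risk allele at a designated index variant, mirroring
  proband-based selection;
* **injected de novos** (child heterozygous, both parents homozygous
  reference, placed on cleanly genotyped calls);
* **read-level noise**: Poisson depth, genotype quality, Beta-distributed
  allele balance with AD fields, random missingness, and deliberately
  planted QC failures (low DP / low GQ / aberrant allele balance) and
  Mendelian inconsistencies for bookkeeping tests.

All randomness flows from ``SimConfig.seed``; outputs are byte-identical
across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, CohortGenotypes, RegionSpec, Trio, TrioSet, write_vcf

__all__ = [
    "SimRegion",
    "RiskLocus",
    "SimConfig",
    "SimTruth",
    "simulate_founder_haplotypes",
    "simulate_trios",
    "write_cohort",
]


@dataclass(frozen=True)
class SimRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_variants: int


@dataclass(frozen=True)
class RiskLocus:
    """One transmission-distorted locus tied to a trio subgroup."""

    locus_id: str
    region: int          # index into SimConfig.regions
    tau: float = 0.8     # P(het parent transmits the risk allele); 0.5 = null
    subgroup: str = "all"
    risk_maf: float = 0.30  # founder frequency forced at the index variant
    index_pos: int | None = None  # defaults to the region's middle variant
    ascertained: bool = False  # subgroup's probands must carry the risk allele

    def __post_init__(self) -> None:
        if not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")


@dataclass
class SimConfig:
    """Generator settings; defaults emulate an ~80-trio targeted-sequencing
    cohort over two 2 Mb regions with blockwise LD and 30% rare variants."""

    n_trios: int = 80
    regions: list[SimRegion] = field(default_factory=lambda: [
        SimRegion("7", 32_652_669, 34_695_364, 400),
        SimRegion("20", 54_797_058, 56_797_057, 400),
    ])
    rare_fraction: float = 0.30        # mass of the founder-MAF spectrum at <= 0.01
    rare_maf_range: tuple = (0.002, 0.01)
    common_maf_range: tuple = (0.05, 0.5)
    ld_block_length: int = 10          # variants per LD block
    ld_strength: float = 0.9           # copying prob c; between-variant r ~ c^2
    risk_loci: list[RiskLocus] = field(default_factory=list)
    subgroup_sizes: dict | None = None  # label -> n_trios; None = all in "all"
    ascertainment_locus: str | None = None  # locus_id; child must carry a risk allele
    max_ascertainment_attempts: int = 200   # per trio
    n_denovo: int = 0
    mean_dp: float = 60.0
    gq_mean: float = 80.0
    gq_sd: float = 10.0
    ab_concentration: float = 50.0     # Beta concentration of het allele balance
    error_read_rate: float = 0.002     # alt reads on hom-ref calls (and mirrored)
    missing_rate: float = 0.02
    clean_payload: bool = False        # exact DP/GQ/AB (fixture mode, no noise)
    n_low_dp: int = 0                  # planted per-call QC failures
    n_low_gq: int = 0
    n_bad_ab: int = 0
    n_mendel_single: int = 0           # variants with exactly one planted inconsistency
    n_mendel_multi: int = 0            # variants with two planted inconsistencies
    seed: int = 0

    def region_spec(self) -> RegionSpec:
        return RegionSpec.from_1based(
            [(r.chrom, r.start, r.end) for r in self.regions], label="simulated targets"
        )


@dataclass
class SimTruth:
    """Everything needed to score recall/precision of every pipeline stage."""

    trio_subgroup: dict            # trio_id -> subgroup label
    risk_loci: pd.DataFrame        # locus_id, chrom, pos, ref, alt, tau, subgroup
    denovo: pd.DataFrame           # chrom, pos, ref, alt, trio_id
    founder_maf: pd.DataFrame      # chrom, pos, configured founder MAF
    planted: pd.DataFrame          # kind, chrom, pos, sample, detail
    counts: dict                   # planted-failure tallies by kind

    def to_frame(self) -> pd.DataFrame:
        rows = [("subgroup", "", 0, t, lab) for t, lab in self.trio_subgroup.items()]
        for r in self.risk_loci.itertuples():
            rows.append(("risk_locus", r.chrom, r.pos, r.locus_id,
                         f"tau={r.tau};subgroup={r.subgroup}"))
        for r in self.denovo.itertuples():
            rows.append(("de_novo", r.chrom, r.pos, r.trio_id, f"{r.ref}>{r.alt}"))
        for r in self.planted.itertuples():
            rows.append((r.kind, r.chrom, r.pos, r.sample, r.detail))
        return pd.DataFrame(rows, columns=["kind", "chrom", "pos", "unit", "detail"])


# --------------------------------------------------------------------------
# Variant layout and founder haplotypes
# --------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class _Layout:
    variants: pd.DataFrame   # chrom, pos, id, ref, alt
    p: np.ndarray            # founder alt-allele frequency per variant
    block: np.ndarray        # block id per variant
    region_of: np.ndarray    # region index per variant
    index_rows: dict         # locus_id -> variant row


def _build_layout(cfg: SimConfig, rng: np.random.Generator) -> _Layout:
    rows, ps, blocks, region_of = [], [], [], []
    block_id = 0
    index_rows: dict[str, int] = {}
    offset = 0
    for ri, reg in enumerate(cfg.regions):
        pos = np.sort(rng.choice(
            np.arange(reg.start, reg.end + 1), size=reg.n_variants, replace=False
        ))
        is_rare = rng.random(reg.n_variants) < cfg.rare_fraction
        p = np.where(
            is_rare,
            rng.uniform(*cfg.rare_maf_range, reg.n_variants),
            rng.uniform(*cfg.common_maf_range, reg.n_variants),
        )
        ref = _BASES[rng.integers(0, 4, reg.n_variants)]
        alt = np.array([
            rng.choice([b for b in "ACGT" if b != r]) for r in ref
        ])
        for k in range(reg.n_variants):
            rows.append((reg.chrom, int(pos[k]), f"sv{ri}_{k}", ref[k], alt[k]))
        ps.append(p)
        blocks.append(block_id + np.arange(reg.n_variants) // cfg.ld_block_length)
        block_id = int(blocks[-1][-1]) + 1
        region_of.append(np.full(reg.n_variants, ri))
        offset += reg.n_variants

    p = np.concatenate(ps)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])

    # pin each risk locus's index variant and force its founder frequency
    starts = np.cumsum([0] + [r.n_variants for r in cfg.regions])
    for locus in cfg.risk_loci:
        lo, hi = starts[locus.region], starts[locus.region + 1]
        region_pos = variants["pos"].to_numpy()[lo:hi]
        target = (locus.index_pos if locus.index_pos is not None
                  else int(np.median(region_pos)))
        row = lo + int(np.argmin(np.abs(region_pos - target)))
        p[row] = locus.risk_maf
        index_rows[locus.locus_id] = row

    return _Layout(variants, p, np.concatenate(blocks),
                   np.concatenate(region_of), index_rows)


def _draw_haplotypes(layout: _Layout, n: int, c: float,
                     rng: np.random.Generator) -> np.ndarray:
    """n haplotypes under the block-copying model, shape (n, V), int8."""
    V = len(layout.p)
    n_blocks = int(layout.block.max()) + 1 if V else 0
    u = rng.random((n, n_blocks))            # one ancestor draw per block
    ancestor = u[:, layout.block] < layout.p  # comonotone within block
    fresh = rng.random((n, V)) < layout.p
    copies = rng.random((n, V)) < c
    return np.where(copies, ancestor, fresh).astype(np.int8)


def simulate_founder_haplotypes(
    cfg: SimConfig, n_haplotypes: int, seed: int | np.random.Generator | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Founder haplotype matrix (n_haplotypes x n_variants) plus variant table.

    Marginal allele frequencies follow the configured MAF spectrum exactly;
    within-block LD follows the copying model described in the module
    docstring; across blocks variants are independent.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(cfg.seed if seed is None else seed))
    layout = _build_layout(cfg, rng)
    return _draw_haplotypes(layout, n_haplotypes, cfg.ld_strength, rng), layout.variants


# --------------------------------------------------------------------------
# Trio simulation
# --------------------------------------------------------------------------

def _subgroup_labels(cfg: SimConfig) -> list[str]:
    if cfg.subgroup_sizes is None:
        return ["all"] * cfg.n_trios
    if sum(cfg.subgroup_sizes.values()) != cfg.n_trios:
        raise ValueError("subgroup sizes must sum to n_trios")
    labels: list[str] = []
    for lab, n in cfg.subgroup_sizes.items():
        labels.extend([lab] * n)
    return labels


def _transmit(
    hap_a: np.ndarray, hap_b: np.ndarray, layout: _Layout,
    distortions: list[tuple[int, float]], rng: np.random.Generator,
) -> np.ndarray:
    """One gamete: per-block uniform choice between the parent's haplotypes,
    except risk blocks, where a heterozygous parent passes the haplotype
    carrying the risk allele with probability tau."""
    n_blocks = int(layout.block.max()) + 1
    take_b = rng.random(n_blocks) < 0.5
    for row, tau in distortions:
        if hap_a[row] != hap_b[row]:  # heterozygous at the index variant
            risk_on_b = hap_b[row] == 1
            transmit_risk = rng.random() < tau
            take_b[layout.block[row]] = risk_on_b == transmit_risk
    choice = take_b[layout.block]
    return np.where(choice, hap_b, hap_a)


def simulate_trios(cfg: SimConfig) -> tuple[CohortGenotypes, TrioSet, SimTruth]:
    """Generate a full trio cohort: genotypes + pedigree + ground truth."""
    rng = np.random.default_rng(cfg.seed)
    layout = _build_layout(cfg, rng)
    V = len(layout.p)
    labels = _subgroup_labels(cfg)

    asc_row = None
    if cfg.ascertainment_locus is not None:
        asc_row = layout.index_rows[cfg.ascertainment_locus]

    child_g = np.zeros((V, cfg.n_trios, 2), dtype=np.int8)
    mother_g = np.zeros_like(child_g)
    father_g = np.zeros_like(child_g)
    trios: list[Trio] = []
    subgroup_of: dict[str, str] = {}

    for i in range(cfg.n_trios):
        lab = labels[i]
        distortions = [
            (layout.index_rows[L.locus_id], L.tau)
            for L in cfg.risk_loci if L.subgroup == lab
        ]
        # proband-carrier ascertainment: global locus, plus any risk locus
        # of this trio's own subgroup flagged as ascertained
        asc_rows = [] if asc_row is None else [asc_row]
        asc_rows += [
            layout.index_rows[L.locus_id]
            for L in cfg.risk_loci if L.subgroup == lab and L.ascertained
        ]
        for attempt in range(cfg.max_ascertainment_attempts):
            haps = _draw_haplotypes(layout, 4, cfg.ld_strength, rng)
            m_a, m_b, f_a, f_b = haps
            from_m = _transmit(m_a, m_b, layout, distortions, rng)
            from_f = _transmit(f_a, f_b, layout, distortions, rng)
            if all(from_m[r] + from_f[r] >= 1 for r in asc_rows):
                break
        else:
            raise RuntimeError(
                f"ascertainment filter unsatisfied after "
                f"{cfg.max_ascertainment_attempts} attempts for trio {i}"
            )
        tid = f"T{i + 1:03d}"
        trios.append(Trio(tid, f"{tid}_c", f"{tid}_m", f"{tid}_f"))
        subgroup_of[tid] = lab
        child_g[:, i, 0], child_g[:, i, 1] = from_m, from_f
        mother_g[:, i, 0], mother_g[:, i, 1] = m_a, m_b
        father_g[:, i, 0], father_g[:, i, 1] = f_a, f_b

    trioset = TrioSet(trios)
    S = trioset.n_samples
    gt1 = np.empty((V, S), dtype=np.int8)
    gt2 = np.empty((V, S), dtype=np.int8)
    for i in range(cfg.n_trios):
        gt1[:, 3 * i], gt2[:, 3 * i] = child_g[:, i, 0], child_g[:, i, 1]
        gt1[:, 3 * i + 1], gt2[:, 3 * i + 1] = mother_g[:, i, 0], mother_g[:, i, 1]
        gt1[:, 3 * i + 2], gt2[:, 3 * i + 2] = father_g[:, i, 0], father_g[:, i, 1]

    planted: list[tuple] = []
    vpos = layout.variants["pos"].to_numpy()
    vchrom = layout.variants["chrom"].to_numpy()
    protected = set(layout.index_rows.values())

    # -- de novo injection (clean calls; both parents hom-ref, child het) --
    denovo_rows: list[tuple] = []
    if cfg.n_denovo > 0:
        hom_ref_trio = (child_g.sum(axis=2) == 0) & (mother_g.sum(axis=2) == 0) \
            & (father_g.sum(axis=2) == 0)
        candidates = [
            (v, t) for v, t in zip(*np.nonzero(hom_ref_trio))
            if v not in protected
        ]
        if len(candidates) < cfg.n_denovo:
            raise RuntimeError("not enough hom-ref trio sites for de novo injection")
        used_variants: set[int] = set()
        picks = []
        for k in rng.permutation(len(candidates)):
            v, t = candidates[k]
            if v in used_variants:
                continue
            picks.append((int(v), int(t)))
            used_variants.add(int(v))
            if len(picks) == cfg.n_denovo:
                break
        for v, t in picks:
            gt2[v, 3 * t] = 1  # child becomes 0/1
            row = layout.variants.iloc[v]
            denovo_rows.append((row.chrom, int(row.pos), row.ref, row.alt,
                                trios[t].trio_id))
            protected.add(v)

    # -- planted Mendelian inconsistencies (never the de novo pattern) -----
    poly = np.flatnonzero(
        (layout.p >= 0.05)
        & ~np.isin(np.arange(V), list(protected))
    )
    rng.shuffle(poly)
    mendel_iter = iter(poly)
    for n_errors, kind in ((1, "mendel_single"), (2, "mendel_multi")):
        n_variants = cfg.n_mendel_single if kind == "mendel_single" else cfg.n_mendel_multi
        for _ in range(n_variants):
            v = int(next(mendel_iter))
            protected.add(v)
            for t in rng.choice(cfg.n_trios, size=n_errors, replace=False):
                # mother 2/2, father 2/2, child 0/0: inconsistent, not de novo
                gt1[v, 3 * t] = gt2[v, 3 * t] = 0
                for col in (3 * t + 1, 3 * t + 2):
                    gt1[v, col] = gt2[v, col] = 1
                planted.append((kind, vchrom[v], int(vpos[v]),
                                trioset.samples[3 * t], f"trio={trios[t].trio_id}"))

    # -- read-level payload ------------------------------------------------
    dos = (gt1 + gt2).astype(np.int8)
    if cfg.clean_payload:
        dp = np.full((V, S), int(round(cfg.mean_dp)), dtype=np.int32)
        gq = np.full((V, S), 99, dtype=np.int32)
        ar = np.where(dos == 1, 0.5, np.where(dos == 2, 1.0, 0.0))
    else:
        dp = rng.poisson(cfg.mean_dp, size=(V, S)).astype(np.int32)
        gq = np.clip(np.round(rng.normal(cfg.gq_mean, cfg.gq_sd, size=(V, S))),
                     0, 99).astype(np.int32)
        a = cfg.ab_concentration
        het_ab = rng.beta(a / 2, a / 2, size=(V, S))
        e = cfg.error_read_rate
        hom_ref_ab = rng.beta(1, max(1.0 / e - 1.0, 1.0), size=(V, S))
        ar = np.where(dos == 1, het_ab, np.where(dos == 2, 1 - hom_ref_ab, hom_ref_ab))

    # planted per-call QC failures on otherwise clean calls
    flat = rng.permutation(V * S)
    flat = flat[~np.isin(flat // S, list(protected))]
    cursor = 0

    def _take(n: int) -> np.ndarray:
        nonlocal cursor
        out = flat[cursor:cursor + n]
        cursor += n
        return out

    for idx in _take(cfg.n_low_dp):
        v, s = divmod(int(idx), S)
        dp[v, s] = 10
        planted.append(("low_dp", vchrom[v], int(vpos[v]), trioset.samples[s], "DP=10"))
    for idx in _take(cfg.n_low_gq):
        v, s = divmod(int(idx), S)
        gq[v, s] = 10
        planted.append(("low_gq", vchrom[v], int(vpos[v]), trioset.samples[s], "GQ=10"))
    for idx in _take(cfg.n_bad_ab):
        v, s = divmod(int(idx), S)
        gt1[v, s], gt2[v, s] = 0, 1   # het with grossly skewed balance
        ar[v, s] = 0.10
        planted.append(("bad_ab", vchrom[v], int(vpos[v]), trioset.samples[s], "AB=0.10"))

    # random missingness (never on de novo trios' calls at their variant)
    if cfg.missing_rate > 0:
        miss = rng.random((V, S)) < cfg.missing_rate
        for row in denovo_rows:
            v = int(np.flatnonzero((vchrom == row[0]) & (vpos == row[1]))[0])
            t = next(i for i, tr in enumerate(trios) if tr.trio_id == row[4])
            miss[v, 3 * t:3 * t + 3] = False
        gt1 = np.where(miss, MISSING, gt1).astype(np.int8)
        gt2 = np.where(miss, MISSING, gt2).astype(np.int8)

    # AD from depth and allele balance; alt_ratio re-derived from AD
    alt_reads = np.round(ar * dp).astype(np.int32)
    ad = [np.stack([dp[v] - alt_reads[v], alt_reads[v]], axis=1) for v in range(V)]
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_ratio = np.where(dp > 0, alt_reads / dp, np.nan)

    geno = CohortGenotypes(
        layout.variants, trioset.samples, gt1, gt2, dp, gq, alt_ratio,
        region_set=cfg.region_spec(), ad=ad,
    )

    keys = layout.variants
    risk_rows = [
        (L.locus_id,
         keys.iloc[layout.index_rows[L.locus_id]].chrom,
         int(keys.iloc[layout.index_rows[L.locus_id]].pos),
         keys.iloc[layout.index_rows[L.locus_id]].ref,
         keys.iloc[layout.index_rows[L.locus_id]].alt,
         L.tau, L.subgroup)
        for L in cfg.risk_loci
    ]
    truth = SimTruth(
        trio_subgroup=subgroup_of,
        risk_loci=pd.DataFrame(
            risk_rows,
            columns=["locus_id", "chrom", "pos", "ref", "alt", "tau", "subgroup"],
        ),
        denovo=pd.DataFrame(
            denovo_rows, columns=["chrom", "pos", "ref", "alt", "trio_id"]
        ),
        founder_maf=pd.DataFrame({
            "chrom": vchrom, "pos": vpos,
            "founder_maf": np.minimum(layout.p, 1 - layout.p),
        }),
        planted=pd.DataFrame(
            planted, columns=["kind", "chrom", "pos", "sample", "detail"]
        ),
        counts={
            "low_dp": cfg.n_low_dp, "low_gq": cfg.n_low_gq, "bad_ab": cfg.n_bad_ab,
            "mendel_single": cfg.n_mendel_single, "mendel_multi": cfg.n_mendel_multi,
            "de_novo": cfg.n_denovo,
        },
    )
    return geno, trioset, truth


# --------------------------------------------------------------------------
# Writers
# --------------------------------------------------------------------------

def write_cohort(
    geno: CohortGenotypes, trios: TrioSet, truth: SimTruth, out_dir: str | Path,
    prefix: str = "cohort", bgzip: bool = False,
) -> dict[str, Path]:
    """Write VCF (optionally bgzipped + indexed), PED, regions BED and
    ground-truth TSV; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vcf_path = out / (f"{prefix}.vcf.gz" if bgzip else f"{prefix}.vcf")
    write_vcf(geno, vcf_path)

    ped_path = out / f"{prefix}.ped"
    with open(ped_path, "w") as fh:
        for t in trios:
            fh.write(f"{t.trio_id} {t.father_id} 0 0 1 1\n")
            fh.write(f"{t.trio_id} {t.mother_id} 0 0 2 1\n")
            fh.write(f"{t.trio_id} {t.child_id} {t.father_id} {t.mother_id} 1 "
                     f"{2 if t.child_affected else 1}\n")

    bed_path = out / f"{prefix}.bed"
    if geno.region_set is not None:
        geno.region_set.to_bed(bed_path)

    truth_path = out / f"{prefix}.truth.tsv"
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    return {"vcf": vcf_path, "ped": ped_path, "bed": bed_path, "truth": truth_path}
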