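"""Genotype-frequency profiles and over-transmission direction summaries.

For a chosen variant set (typically the significant hits at a locus),
compares the genotype spectrum of the children against that of the
parents: fractions of homozygous-major, heterozygous and homozygous-minor
genotypes pooled over the set. Under transmission distortion the children
are enriched for the over-transmitted allele's homozygote relative to
their parents, which these profiles make visible.

Major/minor orientation is taken from *parental* (founder) allele
frequencies so that distortion in the children cannot flip the reference
frame of the comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, CohortGenotypes, TrioSet
from .tdt import founder_alt_freq

__all__ = [
    "GenotypeProfile",
    "genotype_frequencies",
    "transmission_direction",
    "opposite_effect_scan",
]


@dataclass
class GenotypeProfile:
    role: str  # "children" | "parents"
    variant_set: str
    hom_major: float
    het: float
    hom_minor: float
    per_variant: pd.DataFrame  # per-variant fractions + call counts

    @property
    def pooled(self) -> tuple[float, float, float]:
        return (self.hom_major, self.het, self.hom_minor)


def _select_variants(
    geno: CohortGenotypes, variant_ids, exclude=()
) -> np.ndarray:
    v = geno.variants
    coords = v["chrom"].astype(str) + ":" + v["pos"].astype(str) + ":" + v["ref"] + ">" + v["alt"]
    ids = v["id"] if "id" in v.columns else coords
    wanted = set(variant_ids)
    drop = set(exclude)
    keep = (coords.isin(wanted) | ids.isin(wanted)) & ~coords.isin(drop) & ~ids.isin(drop)
    return keep.to_numpy()


def genotype_frequencies(
    geno: CohortGenotypes,
    trios: TrioSet,
    variant_ids,
    role: str,
    exclude=(),
) -> GenotypeProfile:
    """Pooled and per-variant genotype fractions for children or parents.

    ``variant_ids`` may hold VCF IDs or "chrom:pos:ref>alt" labels;
    ``exclude`` removes variants from the pooling (e.g. the variant the
    cohort was ascertained on). Fractions are over non-missing calls; the
    three pooled fractions sum to 1.
    """
    if role not in ("children", "parents"):
        raise ValueError("role must be 'children' or 'parents'")
    keep = _select_variants(geno, variant_ids, exclude)
    if not keep.any():
        raise ValueError("variant set selects no variants in the cohort")
    sub = geno.subset_variants(keep)

    af = founder_alt_freq(sub, trios)
    if np.any(af == 0.5):
        warnings.warn(
            "parental MAF exactly 0.5 at some variant(s); orienting by ref/alt"
        )
    minor_is_alt = af <= 0.5

    c, m, f = trios.member_columns()
    cols = c if role == "children" else np.concatenate([m, f])
    dos = sub.dosage[:, cols]
    called = dos != MISSING
    # minor-allele dosage: flip where the minor allele is the reference
    minor_dos = np.where(minor_is_alt[:, None], dos, 2 - dos)

    counts = np.stack([
        ((minor_dos == 0) & called).sum(axis=1),  # hom major
        ((minor_dos == 1) & called).sum(axis=1),  # het
        ((minor_dos == 2) & called).sum(axis=1),  # hom minor
    ], axis=1).astype(float)
    n_calls = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts / n_calls[:, None]

    per_variant = pd.DataFrame({
        "variant": sub.variant_labels().to_numpy(),
        "hom_major": frac[:, 0],
        "het": frac[:, 1],
        "hom_minor": frac[:, 2],
        "n_calls": n_calls.astype(int),
    })
    total = counts.sum(axis=0)
    pooled = total / total.sum()
    return GenotypeProfile(
        role=role,
        variant_set=",".join(map(str, variant_ids)) if len(list(variant_ids)) < 5
        else f"{len(list(variant_ids))} variants",
        hom_major=float(pooled[0]),
        het=float(pooled[1]),
        hom_minor=float(pooled[2]),
        per_variant=per_variant,
    )


def transmission_direction(results: pd.DataFrame, p_max: float = 1e-5) -> pd.DataFrame:
    """Label each significant variant by the over-transmitted allele.

    ``results`` is a :func:`triotdt.tdt.run_tdt` table (it already carries
    founder-oriented ``direction``); rows with p < ``p_max`` are returned
    with a locus (chromosome) cross-tabulation available via groupby.
    """
    sig = results[results["p"] < p_max].copy()
    return sig[["chrom", "pos", "id", "ref", "alt", "T", "U", "p",
                "founder_alt_freq", "direction"]].reset_index(drop=True)


def opposite_effect_scan(
    results_a: pd.DataFrame, results_b: pd.DataFrame, p_max: float
) -> pd.DataFrame:
    """Variants significant in two cohorts with opposite transmission.

    Matches variants by (chrom, pos, ref, alt) across two TDT tables (e.g.
    two suture phenotypes sequenced over a shared region) and reports those
    with p < ``p_max`` in *both* and a different over-transmitted allele
    (one cohort over-transmits the alternate, the other the reference).
    """
    key = ["chrom", "pos", "ref", "alt"]
    a = results_a[results_a["p"] < p_max]
    b = results_b[results_b["p"] < p_max]
    merged = a.merge(b, on=key, suffixes=("_a", "_b"))
    if merged.empty:
        return merged
    over_alt_a = merged["T_a"] > merged["U_a"]
    over_alt_b = merged["T_b"] > merged["U_b"]
    informative = (merged["T_a"] != merged["U_a"]) & (merged["T_b"] != merged["U_b"])
    out = merged[informative & (over_alt_a != over_alt_b)]
    cols = key + ["id_a", "T_a", "U_a", "p_a", "T_b", "U_b", "p_b"]
    return out[[c for c in cols if c in out.columns]].reset_index(drop=True)


def plot_profiles(children: GenotypeProfile, parents: GenotypeProfile, path=None):
    """Side-by-side histogram of the two pooled genotype spectra."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=True)
    for ax, prof in zip(axes, (children, parents)):
        ax.bar(["hom major", "het", "hom minor"], prof.pooled, color="steelblue")
        ax.set_title(prof.role)
        ax.set_ylim(0, 1)
    axes[0].set_ylabel("fraction of genotype calls")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
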