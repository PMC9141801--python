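"""Ingest, coordinate conventions, and multiallelic handling."""

import io
import textwrap

import numpy as np
import pandas as pd
import pytest

from triotdt.core import (
    MISSING,
    CohortGenotypes,
    RegionSpec,
    Trio,
    TrioSet,
    read_genotypes,
    read_pedigree,
    split_multiallelic,
    write_vcf,
)
from triotdt.simulate import SimConfig, SimRegion, simulate_trios, write_cohort


def _ped(text, tmp_path):
    p = tmp_path / "fam.ped"
    p.write_text(textwrap.dedent(text))
    return p


class TestPedigree:
    def test_minimal_trio(self, tmp_path):
        ts = read_pedigree(_ped(
            """\
            F1 dad 0 0 1 1
            F1 mom 0 0 2 1
            F1 kid dad mom 1 2
            """, tmp_path))
        assert len(ts) == 1
        t = ts.trios[0]
        assert (t.child_id, t.mother_id, t.father_id) == ("kid", "mom", "dad")
        assert t.child_affected

    def test_duo_excluded_and_reported(self, tmp_path):
        with pytest.warns(UserWarning, match="incomplete trio"):
            ts = read_pedigree(_ped(
                """\
                F1 mom 0 0 2 1
                F1 kid 0 mom 1 2
                """, tmp_path))
        assert len(ts) == 0
        assert (ts.exclusions["unit"] == "duo").sum() == 1

    def test_full_cohort_dimensions(self, tmp_path):
        lines = []
        for i in range(83):
            lines += [f"F{i} d{i} 0 0 1 1", f"F{i} m{i} 0 0 2 1",
                      f"F{i} c{i} d{i} m{i} 1 2"]
        ts = read_pedigree(_ped("\n".join(lines) + "\n", tmp_path))
        assert len(ts) == 83
        assert ts.n_samples == 249

    def test_duplicate_child_is_hard_error(self, tmp_path):
        with pytest.raises(ValueError, match="duplicated"):
            read_pedigree(_ped(
                """\
                F1 dad 0 0 1 1
                F1 dad 0 0 1 1
                """, tmp_path))

    def test_trio_ids_must_be_distinct(self):
        with pytest.raises(ValueError, match="distinct"):
            Trio("t", "x", "x", "y")

    def test_no_sample_in_two_trios(self):
        with pytest.raises(ValueError, match="appears in trios"):
            TrioSet([Trio("a", "c1", "m1", "f1"), Trio("b", "c2", "m1", "f2")])


class TestRegions:
    def test_one_based_inclusive_boundaries(self):
        r = RegionSpec.from_1based([("20", 7_065_143, 7_202_442)])
        assert r.contains("20", 7_117_108)  # interior
        assert r.contains("20", 7_065_143)  # left edge inclusive
        assert r.contains("20", 7_202_442)  # right edge inclusive
        assert not r.contains("20", 7_065_142)
        assert not r.contains("20", 7_202_443)
        assert not r.contains("7", 7_117_108)

    def test_overlapping_intervals_merge(self):
        r = RegionSpec([("1", 0, 100), ("1", 50, 150), ("1", 200, 300)])
        assert r.intervals == [("1", 0, 150), ("1", 200, 300)]

    def test_bed_round_trip(self, tmp_path):
        r = RegionSpec([("1", 10, 20), ("2", 0, 5)], label="t")
        p = tmp_path / "r.bed"
        r.to_bed(p)
        r2 = RegionSpec.from_bed(p)
        assert r2.intervals == r.intervals


def _vcf(text, tmp_path):
    p = tmp_path / "x.vcf"
    p.write_text(textwrap.dedent(text))
    return p


HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=20>
##FORMAT=<ID=GT,Number=1,Type=String,Description="g">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="a">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tT000_c\tT000_m\tT000_f
"""


class TestReadGenotypes:
    def _trios(self):
        return TrioSet([Trio("T000", "T000_c", "T000_m", "T000_f")])

    def test_region_retention_and_alt_ratio(self, tmp_path):
        vcf = _vcf(HEADER + (
            "20\t7117108\trs1\tA\tG\t.\t.\t.\tGT:DP:GQ:AD\t"
            "0/1:30:99:6,2\t0/0:25:99:25,0\t0/1:28:99:14,14\n"
            "20\t9000000\trs2\tA\tG\t.\t.\t.\tGT:DP:GQ:AD\t"
            "0/1:30:99:15,15\t0/0:25:99:25,0\t0/0:28:99:28,0\n"
        ), tmp_path)
        regions = RegionSpec.from_1based([("20", 7_065_143, 7_202_442)])
        g = read_genotypes(vcf, regions, self._trios())
        assert g.n_variants == 1  # rs2 outside all intervals is dropped
        assert g.variants.iloc[0]["pos"] == 7117108
        assert g.alt_ratio[0, 0] == pytest.approx(0.25)  # AD=(6,2) -> 2/8

    def test_missing_sample_is_hard_error(self, tmp_path):
        vcf = _vcf(HEADER.replace("T000_f", "other"), tmp_path)
        with pytest.raises(ValueError, match="T000_f"):
            read_genotypes(vcf, None, self._trios())

    def test_half_call_set_fully_missing(self, tmp_path):
        vcf = _vcf(HEADER + (
            "20\t7117108\t.\tA\tG\t.\t.\t.\tGT\t./1\t0/0\t0/1\n"
        ), tmp_path)
        g = read_genotypes(vcf, None, self._trios())
        assert g.dosage[0, 0] == MISSING


class TestSplitMultiallelic:
    def _multi(self, tmp_path):
        vcf = _vcf(HEADER + (
            "20\t100\t.\tA\tG,T\t.\t.\t.\tGT:DP:GQ:AD\t"
            "1/2:40:99:10,15,15\t0/1:40:99:20,20,0\t0/2:40:99:20,0,20\n"
        ), tmp_path)
        return read_genotypes(
            vcf, None, TrioSet([Trio("T000", "T000_c", "T000_m", "T000_f")])
        )

    def test_triallelic_splits_into_two(self, tmp_path):
        out = split_multiallelic(self._multi(tmp_path))
        assert out.n_variants == 2
        assert list(out.variants["alt"]) == ["G", "T"]

    def test_other_alt_genotypes_set_missing(self, tmp_path):
        out = split_multiallelic(self._multi(tmp_path))
        dos = out.dosage
        # child 1/2 carries both alts -> missing on each split record
        assert dos[0, 0] == MISSING and dos[1, 0] == MISSING
        # mother 0/1 -> dosage 1 on the G record, missing on the T record
        assert dos[0, 1] == 1 and dos[1, 1] == MISSING
        # father 0/2 -> missing on G, dosage 1 on T
        assert dos[0, 2] == MISSING and dos[1, 2] == 1

    def test_split_alt_ratio_uses_focal_ad(self, tmp_path):
        out = split_multiallelic(self._multi(tmp_path))
        # mother AD (20, 20, 0): G record alt_ratio 20/40, T record 0/20
        assert out.alt_ratio[0, 1] == pytest.approx(0.5)
        assert out.alt_ratio[1, 1] == pytest.approx(0.0)

    def test_idempotent_and_biallelic_identity(self, tmp_path):
        once = split_multiallelic(self._multi(tmp_path))
        twice = split_multiallelic(once)
        assert np.array_equal(once.dosage, twice.dosage)
        assert once.variants.equals(twice.variants)


class TestVcfRoundTrip:
    @pytest.mark.parametrize("bgzip", [False, True])
    def test_write_read_identity(self, tmp_path, bgzip):
        cfg = SimConfig(n_trios=10, regions=[SimRegion("20", 1000, 90_000, 40)],
                        missing_rate=0.05, seed=42)
        geno, trios, truth = simulate_trios(cfg)
        paths = write_cohort(geno, trios, truth, tmp_path, bgzip=bgzip)
        trios2 = read_pedigree(paths["ped"])
        geno2 = read_genotypes(paths["vcf"], geno.region_set, trios2)
        assert np.array_equal(geno.dosage, geno2.dosage)
        assert np.array_equal(geno.dp, geno2.dp)
        assert np.array_equal(geno.gq, geno2.gq)
        ok = ~np.isnan(geno.alt_ratio)
        assert np.allclose(geno.alt_ratio[ok], geno2.alt_ratio[ok])
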