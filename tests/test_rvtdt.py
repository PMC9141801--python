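"""Rare-variant collapsing: MAF boundary, statistic identities, permutation
null properties including stratification robustness."""

import numpy as np
import pytest

from triotdt.rvtdt import (
    burden_statistic,
    collapse_region,
    permutation_p,
    vt_statistic,
)
from triotdt.simulate import SimConfig, SimRegion, simulate_trios
from triotdt.tdt import transmission_counts

from conftest import cohort_from_dosages


def _rare_cohort(n_trios=40, n_carrier=3, V=5):
    """V rare variants; at each, n_carrier mothers are het, rest hom-ref."""
    child = np.zeros((V, n_trios), dtype=int)
    mother = np.zeros((V, n_trios), dtype=int)
    father = np.zeros((V, n_trios), dtype=int)
    for v in range(V):
        carriers = range(v, v + n_carrier)  # staggered so MAFs differ slightly
        for t in carriers:
            mother[v, t % n_trios] = 1
            child[v, t % n_trios] = 1  # always transmitted
    return cohort_from_dosages(child, mother, father)


class TestCollapse:
    def test_common_variants_excluded(self):
        rng = np.random.default_rng(0)
        mother = rng.integers(0, 3, size=(4, 40))
        father = rng.integers(0, 3, size=(4, 40))
        child = np.clip(mother // 2 + father // 2, 0, 2)  # consistent-ish
        geno, trios = cohort_from_dosages(child, mother, father)
        rvs = collapse_region(geno, trios, "r", maf_threshold=0.01)
        assert rvs.is_empty

    def test_maf_boundary_is_inclusive(self):
        # 50 trios -> 200 founder alleles; 2 alt alleles = MAF exactly 0.01
        n = 50
        mother = [[1, 1] + [0] * (n - 2)]
        father = [[0] * n]
        child = [[1, 0] + [0] * (n - 2)]
        geno, trios = cohort_from_dosages(child, mother, father)
        rvs = collapse_region(geno, trios, "r", maf_threshold=0.01)
        assert len(rvs.variants) == 1
        assert rvs.founder_maf[0] == pytest.approx(0.01)

    def test_planted_rare_variants_all_collected(self):
        cfg = SimConfig(n_trios=60, regions=[SimRegion("1", 1, 100_000, 30)],
                        rare_fraction=1.0, ld_strength=0.0, missing_rate=0.0,
                        clean_payload=True, seed=4)
        geno, trios, truth = simulate_trios(cfg)
        rvs = collapse_region(geno, trios, "r", maf_threshold=0.01)
        # every variant with in-sample founder MAF in (0, 0.01] is present
        from triotdt.tdt import founder_alt_freq
        af = founder_alt_freq(geno, trios)
        maf = np.minimum(af, 1 - af)
        expected = int(((maf > 0) & (maf <= 0.01)).sum())
        assert len(rvs.variants) == expected > 0


class TestStatistics:
    def test_brv_equals_summed_single_variant_counts(self):
        geno, trios = _rare_cohort()
        rvs = collapse_region(geno, trios, "r", maf_threshold=0.2)
        T, U = transmission_counts(geno, trios)
        assert burden_statistic(rvs, "BRV") == float((T - U).sum())

    def test_forced_transmissions_give_expected_brv_and_cmc(self):
        # 3 carrier mothers at one variant, all transmit
        geno, trios = _rare_cohort(V=1)
        rvs = collapse_region(geno, trios, "r", maf_threshold=0.2)
        assert burden_statistic(rvs, "BRV") == 3.0
        assert burden_statistic(rvs, "CMC") == 3.0

    def test_vt_dominates_brv_and_degenerates_with_single_maf(self):
        geno, trios = _rare_cohort()
        rvs = collapse_region(geno, trios, "r", maf_threshold=0.2)
        vt, thr = vt_statistic(rvs)
        assert vt >= burden_statistic(rvs, "BRV")
        # degenerate: one distinct MAF value -> VT == BRV
        single = collapse_region(*_rare_cohort(V=1), "s", maf_threshold=0.2)
        assert vt_statistic(single)[0] == burden_statistic(single, "BRV")

    def test_wss_with_constant_weights_matches_brv(self):
        geno, trios = _rare_cohort()
        rvs = collapse_region(geno, trios, "r", maf_threshold=0.2)
        from triotdt import rvtdt as rv
        t = rvs.event_transmitted.astype(float)[None, :]
        T, U = rv._per_variant_tu(rvs, t)
        constant = float((T - U).sum())
        assert constant == rv._brv(rvs, t)[0]

    def test_unknown_test_is_hard_error(self):
        geno, trios = _rare_cohort(V=1)
        rvs = collapse_region(geno, trios, "r", maf_threshold=0.2)
        with pytest.raises(ValueError, match="unknown test"):
            burden_statistic(rvs, "SKAT")


class TestPermutation:
    def test_reproducible_and_never_zero(self):
        geno, trios = _rare_cohort()
        rvs = collapse_region(geno, trios, "r", maf_threshold=0.2)
        a = permutation_p(rvs, "BRV", 500, seed=7)
        b = permutation_p(rvs, "BRV", 500, seed=7)
        assert a.p == b.p > 0

    def test_balanced_statistic_has_large_p(self):
        # two events, one transmitted one not -> statistic 0
        n = 50
        mother = [[1, 1] + [0] * (n - 2)]
        father = [[0] * n]
        child = [[1, 0] + [0] * (n - 2)]
        geno, trios = cohort_from_dosages(child, mother, father)
        rvs = collapse_region(geno, trios, "r", maf_threshold=0.05)
        res = permutation_p(rvs, "BRV", 1000, seed=3)
        assert res.statistic == 0.0 and res.p > 0.5

    def test_low_permutation_count_warns(self):
        geno, trios = _rare_cohort(V=1)
        rvs = collapse_region(geno, trios, "r", maf_threshold=0.2)
        with pytest.warns(UserWarning, match="resolution"):
            permutation_p(rvs, "BRV", 50, seed=1)

    def test_planted_rare_burden_detected(self):
        # region of 12 rare variants whose het parents transmit the rare
        # allele with probability 0.8: BRV p < 0.05 in >= 80% of replicates
        rng = np.random.default_rng(500)
        n, V = 80, 12
        hits = 0
        for rep in range(20):
            mother = np.zeros((V, n), dtype=int)
            child = np.zeros((V, n), dtype=int)
            for v in range(V):
                for t in rng.choice(n, size=3, replace=False):
                    mother[v, t] = 1
                    child[v, t] = rng.random() < 0.8
            geno, trios = cohort_from_dosages(child, mother,
                                              np.zeros((V, n), dtype=int))
            rvs = collapse_region(geno, trios, "signal", maf_threshold=0.05)
            if permutation_p(rvs, "BRV", 400, seed=rep).p < 0.05:
                hits += 1
        assert hits >= 16  # >= 80% power

    def test_stratification_does_not_inflate_type_one_error(self):
        # two founder subpopulations with different rare-allele burdens:
        # trios 0-39 carry rare alleles at set A, trios 40-79 at set B.
        rng = np.random.default_rng(42)
        n, V = 80, 30
        mother = np.zeros((V, n), dtype=int)
        father = np.zeros((V, n), dtype=int)
        child = np.zeros((V, n), dtype=int)
        for v in range(V):
            pool = range(0, 40) if v < V // 2 else range(40, 80)
            for t in rng.choice(list(pool), size=3, replace=False):
                mother[v, t] = 1
                child[v, t] = rng.integers(0, 2)  # fair transmission
        geno, trios = cohort_from_dosages(child, mother, father)
        rvs = collapse_region(geno, trios, "r", maf_threshold=0.05)
        ps = [permutation_p(rvs, test, 600, seed=9).p
              for test in ("CMC", "BRV", "WSS", "VT")]
        assert all(p > 0.05 for p in ps)
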