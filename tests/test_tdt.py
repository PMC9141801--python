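"""Transmission counting against exhaustive enumeration; statistic checks
against an independent McNemar implementation; relabeling invariance."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.contingency_tables import mcnemar

from triotdt.core import MISSING
from triotdt.simulate import SimConfig, SimRegion, simulate_trios
from triotdt.tdt import (
    SignificanceThresholds,
    count_transmissions,
    run_tdt,
    tdt_statistic,
    transmission_counts,
)

from conftest import cohort_from_dosages


def oracle_consistent(c, m, f):
    gam = {0: [0], 1: [0, 1], 2: [1]}
    return any(a + b == c for a in gam[m] for b in gam[f])


class TestCountTransmissions:
    @pytest.mark.parametrize(
        "c, m, f, expected",
        [
            (1, 1, 0, (1, 0)),  # forced transmission of alt from het mother
            (0, 1, 0, (0, 1)),
            (1, 1, 1, (1, 1)),  # double het, child het: one of each
            (2, 1, 1, (2, 0)),
            (0, 1, 1, (0, 2)),
            (1, 0, 2, (0, 0)),  # both parents homozygous: uninformative
            (2, 1, 2, (1, 0)),  # het mother with hom-alt father
        ],
    )
    def test_single_trio_patterns(self, c, m, f, expected):
        assert count_transmissions([c], [m], [f]) == expected

    def test_t_plus_u_equals_het_parents_over_all_consistent_triples(self):
        for c, m, f in product(range(3), repeat=3):
            if not oracle_consistent(c, m, f):
                continue
            T, U = count_transmissions([c], [m], [f])
            assert T + U == (m == 1) + (f == 1), (c, m, f)

    def test_inconsistent_trio_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="inconsistent"):
            assert count_transmissions([2], [0], [0]) == (0, 0)

    def test_missing_member_skipped(self):
        assert count_transmissions([1, 1], [1, MISSING], [0, 0]) == (1, 0)


class TestTdtStatistic:
    def test_balanced_counts_are_null(self):
        for k in (1, 5, 40):
            r = tdt_statistic(k, k)
            assert r.chi2 == 0 and r.p == 1 and r.odds_ratio == 1

    def test_zero_t_gives_zero_or(self):
        r = tdt_statistic(0, 24)
        assert r.odds_ratio == 0

    def test_zero_u_gives_infinite_or(self):
        r = tdt_statistic(24, 0)
        assert np.isinf(r.odds_ratio)

    def test_undefined_when_no_transmissions(self):
        with pytest.raises(ValueError):
            tdt_statistic(0, 0)

    def test_matches_independent_mcnemar_on_random_pairs(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            T, U = rng.integers(0, 120, size=2)
            if T + U == 0:
                continue
            ours = tdt_statistic(int(T), int(U))
            ref = mcnemar([[0, T], [U, 0]], exact=False, correction=False)
            assert ours.chi2 == pytest.approx(float(ref.statistic))
            assert ours.p == pytest.approx(float(ref.pvalue), rel=1e-10, abs=1e-300)

    def test_ref_alt_swap_symmetry_property(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(derandomize=True, max_examples=200)
        @given(st.integers(0, 500), st.integers(0, 500))
        def check(T, U):
            if T + U == 0:
                return
            a, b = tdt_statistic(T, U), tdt_statistic(U, T)
            assert a.chi2 == b.chi2 and a.p == b.p
            if T > 0 and U > 0:
                assert a.odds_ratio == pytest.approx(1 / b.odds_ratio)

        check()

    def test_deep_tail_precision(self):
        # chi-square survival must stay accurate far below double-epsilon
        # of the CDF: (T, U) = (100, 3) gives p ~ 1e-21
        r = tdt_statistic(100, 3)
        assert 0 < r.p < 1e-18


class TestRunTdt:
    def test_allele_relabeling_flips_or_keeps_p(self):
        cfg = SimConfig(n_trios=40, regions=[SimRegion("1", 1, 200_000, 60)],
                        missing_rate=0.02, seed=31)
        geno, trios, _ = simulate_trios(cfg)
        tab = run_tdt(geno, trios)
        flipped = geno.copy()
        # swap ref/alt labels: dosage d -> 2 - d
        called = flipped.gt1 != MISSING
        g1 = np.where(called, 1 - flipped.gt1, MISSING).astype(np.int8)
        g2 = np.where(called, 1 - flipped.gt2, MISSING).astype(np.int8)
        flipped.gt1, flipped.gt2 = g1, g2
        tab_f = run_tdt(flipped, trios)
        key = ["chrom", "pos"]
        m = tab.merge(tab_f, on=key, suffixes=("", "_f"))
        assert np.allclose(m["p"], m["p_f"])
        assert np.array_equal(m["T"].to_numpy(), m["U_f"].to_numpy())
        assert np.array_equal(m["U"].to_numpy(), m["T_f"].to_numpy())

    def test_uninformative_trios_are_transparent(self):
        child = [[1, 1]]
        mother = [[1, 1]]
        father = [[0, 0]]
        geno, trios = cohort_from_dosages(child, mother, father)
        t1 = transmission_counts(geno, trios)
        # append a trio with both parents homozygous
        child2 = [[1, 1, 0]]
        mother2 = [[1, 1, 0]]
        father2 = [[0, 0, 0]]
        geno2, trios2 = cohort_from_dosages(child2, mother2, father2)
        t2 = transmission_counts(geno2, trios2)
        assert (t1[0][0], t1[1][0]) == (t2[0][0], t2[1][0])

    def test_planted_aggregate_counts_top_the_table(self):
        # 58 trios transmit alt, 10 do not, 2 uninformative
        child = [[1] * 58 + [0] * 10 + [0] * 2]
        mother = [[1] * 68 + [0] * 2]
        father = [[0] * 68 + [0] * 2]
        geno, trios = cohort_from_dosages(child, mother, father)
        tab = run_tdt(geno, trios)
        row = tab.iloc[0]
        assert (row["T"], row["U"]) == (58, 10)
        assert row["OR"] == pytest.approx(5.8)

    def test_no_heterozygous_parents_yields_empty_table(self):
        geno, trios = cohort_from_dosages([[0, 1]], [[0, 0]], [[0, 2]])
        assert run_tdt(geno, trios).empty

    def test_significance_flags(self):
        assert SignificanceThresholds().genomewide < SignificanceThresholds().suggestive
        with pytest.raises(ValueError):
            SignificanceThresholds(suggestive=1e-9, genomewide=5e-8)
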