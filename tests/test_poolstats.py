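"""Nucleotide diversity and Karlsson F_ST estimators."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscan.pileup_io import PoolSpec, SiteCounts, SiteFilterConfig, SiteMatrix
from poolscan.poolstats import (
    fst_window_table,
    genome_mean_pi_percent,
    pairwise_summary,
    pi_window_table,
    site_fst_components,
    site_pi,
    sliding_windows,
    snp_table,
    window_fst,
)


def exact_fst_components(a1, b1, a2, b2):
    """Independent exact-fraction oracle for the Karlsson site components."""
    n1, n2 = a1 + b1, a2 + b2
    h1 = Fraction(a1 * b1, n1 * (n1 - 1))
    h2 = Fraction(a2 * b2, n2 * (n2 - 1))
    num = (Fraction(a1, n1) - Fraction(a2, n2)) ** 2 - h1 / n1 - h2 / n2
    den = num + h1 + h2
    return num, den


class TestSitePi:
    @pytest.mark.parametrize(
        "x,C,expected",
        [(0, 30, 0.0), (1, 2, 1.0), (5, 10, 50 / 90)],
    )
    def test_values(self, x, C, expected):
        assert site_pi(x, C) == pytest.approx(expected, abs=1e-12)

    def test_low_coverage_flagged_not_raised(self):
        assert np.isnan(site_pi(0, 1))

    @settings(max_examples=200, deadline=None)
    @given(st.integers(2, 500), st.data())
    def test_bounds(self, C, data):
        x = data.draw(st.integers(0, C))
        v = site_pi(x, C)
        assert 0.0 <= v <= 1.0


class TestSiteFst:
    def test_fixed_difference(self):
        comp = site_fst_components(20, 0, 0, 20)
        assert comp.h1 == comp.h2 == 0.0
        assert comp.num == comp.den == 1.0
        assert window_fst([comp]) == 1.0

    def test_identical_pools_give_small_negative(self):
        comp = site_fst_components(10, 10, 10, 10)
        # exact: num = -1/38, den = 1/2
        assert comp.num == pytest.approx(-1 / 38, abs=1e-15)
        assert comp.den == pytest.approx(0.5, abs=1e-15)
        assert window_fst([comp]) == pytest.approx(-1 / 19, abs=1e-12)

    def test_worked_example_against_fraction_oracle(self):
        num, den = exact_fst_components(18, 2, 5, 15)
        comp = site_fst_components(18, 2, 5, 15)
        assert comp.num == pytest.approx(float(num), rel=1e-12)
        assert comp.den == pytest.approx(float(den), rel=1e-12)
        assert window_fst([comp]) == pytest.approx(float(num / den), rel=1e-12)
        # frozen value from the oracle
        assert window_fst([comp]) == pytest.approx(0.5827067669172933, rel=1e-12)

    def test_low_depth_site_excluded(self):
        assert site_fst_components(1, 0, 10, 10) is None
        assert window_fst([None, site_fst_components(20, 0, 0, 20)]) == 1.0

    def test_undefined_when_denominator_zero(self):
        # both pools fixed for the same allele
        assert np.isnan(window_fst([site_fst_components(20, 0, 20, 0)]))

    @settings(max_examples=200, deadline=None)
    @given(
        st.tuples(st.integers(0, 50), st.integers(0, 50),
                  st.integers(0, 50), st.integers(0, 50))
    )
    def test_symmetry_and_relabeling(self, counts):
        a1, b1, a2, b2 = counts
        comp = site_fst_components(a1, b1, a2, b2)
        if comp is None:
            return
        swapped = site_fst_components(a2, b2, a1, b1)
        assert comp.num == pytest.approx(swapped.num, abs=1e-12)
        assert comp.den == pytest.approx(swapped.den, abs=1e-12)
        relabeled = site_fst_components(b1, a1, b2, a2)
        assert comp.h1 == pytest.approx(relabeled.h1)
        assert comp.num == pytest.approx(relabeled.num, abs=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 40), st.integers(0, 40),
                      st.integers(0, 40), st.integers(0, 40)),
            min_size=1, max_size=20,
        )
    )
    def test_window_never_exceeds_one(self, sites):
        comps = [site_fst_components(*s) for s in sites]
        v = window_fst(comps)
        if not np.isnan(v):
            assert v <= 1.0 + 1e-12

    def test_window_equals_one_iff_all_fixed_differences(self):
        fixed = [site_fst_components(30, 0, 0, 25) for _ in range(5)]
        assert window_fst(fixed) == 1.0
        mixed = fixed + [site_fst_components(15, 15, 14, 16)]
        assert window_fst(mixed) < 1.0


class TestSlidingWindows:
    def test_interior_site_in_two_windows(self):
        wins = sliding_windows(np.array([1250]), size=1000, step=500)
        assert [(s, e) for s, e, _ in wins] == [(500, 1500), (1000, 2000)]

    def test_left_edge_site_in_one_window(self):
        wins = sliding_windows(np.array([400]), size=1000, step=500)
        assert [(s, e) for s, e, _ in wins] == [(0, 1000)]

    def test_unsorted_raises(self):
        with pytest.raises(ValueError, match="sorted"):
            sliding_windows(np.array([500, 100]))

    def test_membership_matches_bruteforce(self, rng):
        positions = np.sort(rng.integers(1, 20_000, size=300))
        size, step = 1000, 500
        wins = sliding_windows(positions, size=size, step=step)
        brute = {}
        for start in range(0, 20_000, step):
            members = [
                i for i, p in enumerate(positions)
                if start <= p - 1 < start + size
            ]
            if members:
                brute[start] = members
        assert {s: list(m) for s, _, m in wins} == brute


class TestWindowTables:
    def _matrix(self, positions, counts_per_site, pool_names=("p1", "p2")):
        n = len(positions)
        return SiteMatrix(
            chrom=np.array(["c1"] * n, dtype=object),
            pos=np.asarray(positions, dtype=np.int64),
            ref=np.array(["A"] * n, dtype=object),
            counts=np.asarray(counts_per_site, dtype=np.int64),
            pool_names=pool_names,
        )

    def test_window_pi_single_snp_among_monomorphic(self):
        # 5,000 covered sites, one SNP with x=5, C=10 in pool 0
        positions = np.arange(1, 5001)
        counts = np.zeros((5000, 2, 4), dtype=np.int64)
        counts[:, :, 0] = 10  # all-ref coverage 10
        counts[2500, 0] = [5, 5, 0, 0]
        counts[2500, 1] = [5, 5, 0, 0]
        mat = self._matrix(positions, counts)
        cfg = SiteFilterConfig()
        tab = pi_window_table(mat, cfg, pool=0, size=5000)
        assert len(tab) == 1
        assert tab.iloc[0]["n_covered"] == 5000
        assert tab.iloc[0]["value"] == pytest.approx((50 / 90) / 5000, rel=1e-9)
        assert genome_mean_pi_percent(tab) == pytest.approx(
            100 * (50 / 90) / 5000, rel=1e-9
        )

    def test_all_monomorphic_gives_zero(self):
        positions = np.arange(1, 5001)
        counts = np.zeros((5000, 2, 4), dtype=np.int64)
        counts[:, :, 2] = 20
        tab = pi_window_table(self._matrix(positions, counts),
                              SiteFilterConfig(), pool=0)
        assert (tab["value"] == 0).all()

    def test_sparse_window_dropped(self):
        positions = np.array([1, 2, 3])
        counts = np.zeros((3, 2, 4), dtype=np.int64)
        counts[:, :, 0] = 20
        tab = pi_window_table(self._matrix(positions, counts),
                              SiteFilterConfig(), pool=0, size=5000,
                              chrom_lengths={"c1": 5000})
        assert len(tab) == 0

    def test_fst_table_matches_scalar_path(self, rng):
        # vectorised window table == sliding_windows + window_fst per window
        n = 400
        positions = np.sort(rng.choice(np.arange(1, 20_001), size=n, replace=False))
        counts = np.zeros((n, 2, 4), dtype=np.int64)
        for i in range(n):
            p = rng.uniform(0.1, 0.9)
            for pool in range(2):
                cov = int(rng.integers(20, 60))
                alt = rng.binomial(cov, p)
                counts[i, pool] = [cov - alt, alt, 0, 0]
        mat = self._matrix(positions, counts)
        cfg = SiteFilterConfig()
        tab = fst_window_table(mat, cfg, (0, 1), size=1000, step=500,
                               chrom_lengths={"c1": 20_000}, min_snps_window=1)
        snps = snp_table(mat, cfg)
        wins = sliding_windows(snps["pos"].to_numpy(), size=1000, step=500)
        expected = {}
        for start, end, members in wins:
            comps = [
                site_fst_components(
                    int(snps["a0"].iloc[i]), int(snps["b0"].iloc[i]),
                    int(snps["a1"].iloc[i]), int(snps["b1"].iloc[i]),
                )
                for i in members
            ]
            expected[start] = window_fst(comps)
        got = dict(zip(tab["start"], tab["value"]))
        for start, val in expected.items():
            if start not in got:
                # trailing window extending past the chromosome end: the
                # table's grid keeps only fully contained windows
                assert start + 1000 > 20_000
                continue
            assert got[start] == pytest.approx(val, rel=1e-9, abs=1e-12)
        # windows without SNPs are NaN
        for start, val in got.items():
            if start not in expected:
                assert np.isnan(val)

    def test_min_snps_window_undefines_sparse_windows(self, rng):
        positions = np.array([100, 200, 2100])
        counts = np.zeros((3, 2, 4), dtype=np.int64)
        counts[:, 0] = [30, 10, 0, 0]
        counts[:, 1] = [10, 30, 0, 0]
        mat = self._matrix(positions, counts)
        tab = fst_window_table(mat, SiteFilterConfig(), (0, 1), size=1000,
                               step=500, chrom_lengths={"c1": 4000},
                               min_snps_window=2)
        by_start = dict(zip(tab["start"], tab["value"]))
        assert not np.isnan(by_start[0])  # 2 SNPs
        assert np.isnan(by_start[2000])  # 1 SNP -> undefined


class TestPairwiseSummary:
    def test_mean_and_median(self):
        assert pairwise_summary([0.1, 0.2, 0.6]) == (
            pytest.approx(0.3), pytest.approx(0.2)
        )

    def test_constant(self):
        m, med = pairwise_summary([0.4, 0.4, 0.4])
        assert m == pytest.approx(0.4) and med == pytest.approx(0.4)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            pairwise_summary([np.nan])


def test_identical_frequency_pools_fst_near_zero(rng):
    """Windows over two pools sampled from the same frequencies: mean ~ 0."""
    n_windows, snps_per_window = 500, 10
    n = n_windows * snps_per_window
    p = rng.uniform(0.1, 0.9, size=n)
    vals = []
    for w in range(n_windows):
        comps = []
        for i in range(w * snps_per_window, (w + 1) * snps_per_window):
            c1, c2 = rng.poisson(45, size=2) + 2
            x1, x2 = rng.binomial(c1, p[i]), rng.binomial(c2, p[i])
            comps.append(site_fst_components(c1 - x1, x1, c2 - x2, x2))
        vals.append(window_fst(comps))
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean()) < 3 * se + 1e-3
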