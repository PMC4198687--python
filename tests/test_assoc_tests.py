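"""Association tests, exact fallback, adjustment and the genome scan."""

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from rarefx import (
    AlleleCounts2x2,
    ScanConfig,
    adjust_pvalues,
    fisher_exact_allelic,
    genome_scan,
    h_test,
    or_wald_test,
    rd_score_test,
)
from rarefx import test_variant as run_variant_tests

RS17042882 = AlleleCounts2x2(235, 3852, 165, 5876)


def fisher_enumeration_oracle(x1, n1, x2, n2):
    """Exact two-sided Fisher p by integer enumeration of the support."""
    s = x1 + x2
    lo, hi = max(0, s - n2), min(n1, s)
    num = {k: math.comb(n1, k) * math.comb(n2, s - k) for k in range(lo, hi + 1)}
    # point-probability rule with the 1e-7 relative tie tolerance,
    # evaluated in exact integer arithmetic
    obs = num[x1]
    total = sum(num.values())
    kept = sum(v for v in num.values() if v * 10**7 <= obs * (10**7 + 1))
    return float(Fraction(kept, total))


class TestAsymptoticTests:
    def test_h_test_worked_example(self):
        res = h_test(RS17042882)
        # counts give MAFs 0.06101/0.02808; printed h used 3-decimal MAFs
        assert res.estimate == pytest.approx(0.163, abs=2e-3)
        # printed p is 4.00e-15; match to order of magnitude
        assert 4e-16 < res.p_value < 4e-14

    def test_rd_test_worked_example(self):
        res = rd_score_test(RS17042882)
        assert res.estimate == pytest.approx(0.033, abs=5e-4)
        assert 1.1e-16 < res.p_value < 1.1e-14

    def test_or_test_worked_example(self):
        res = or_wald_test(RS17042882)
        assert res.estimate == pytest.approx(2.255, abs=0.01)
        assert 4.9e-16 < res.p_value < 4.9e-14

    @pytest.mark.parametrize("test", [h_test, rd_score_test, or_wald_test])
    def test_identical_groups_give_p_one(self, test):
        res = test(AlleleCounts2x2(7, 40, 7, 40))
        assert res.p_value == pytest.approx(1.0)
        assert res.z_statistic == pytest.approx(0.0, abs=1e-12)

    def test_rd_degenerate_pooled_frequency(self):
        res = rd_score_test(AlleleCounts2x2(0, 40, 0, 40))
        assert res.p_value == 1.0 and math.isnan(res.z_statistic)

    def test_or_test_undefined_on_zero_cell(self):
        res = or_wald_test(AlleleCounts2x2(0, 3852, 28, 5876))
        assert math.isnan(res.estimate) and math.isnan(res.p_value)

    def test_rd_z_squared_is_pearson_chisquare(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(10, 500, size=2)
            x1 = rng.integers(1, n1)
            x2 = rng.integers(1, n2)
            table = [[x1, n1 - x1], [x2, n2 - x2]]
            chi2 = scipy.stats.chi2_contingency(table, correction=False).statistic
            z = rd_score_test(AlleleCounts2x2(x1, n1, x2, n2)).z_statistic
            assert z**2 == pytest.approx(chi2, abs=1e-9)

    @pytest.mark.parametrize("test", [h_test, rd_score_test])
    def test_two_sidedness_under_label_swap(self, test, rng):
        for _ in range(20):
            n1, n2 = rng.integers(20, 300, size=2)
            x1, x2 = rng.integers(1, n1), rng.integers(1, n2)
            a = test(AlleleCounts2x2(x1, n1, x2, n2))
            b = test(AlleleCounts2x2(x2, n2, x1, n1))
            assert a.p_value == pytest.approx(b.p_value, rel=1e-9)
            assert a.z_statistic == pytest.approx(-b.z_statistic, rel=1e-9)

    def test_asymptotic_p_near_conditional_permutation_p(self, rng):
        # label-permutation null = hypergeometric resampling of the table
        counts = AlleleCounts2x2(30, 400, 15, 400)
        obs = h_test(counts)
        s = counts.x1 + counts.x2
        draws = rng.hypergeometric(s, counts.n1 + counts.n2 - s, counts.n1, size=100_000)
        p1, p2 = draws / counts.n1, (s - draws) / counts.n2
        habs = np.abs(2 * np.arcsin(np.sqrt(p1)) - 2 * np.arcsin(np.sqrt(p2)))
        p_perm = float(np.mean(habs >= abs(obs.estimate) - 1e-12))
        # asymptotics are adequate but not exact at these counts
        assert p_perm / 2 < obs.p_value < p_perm * 2
        # the exact test targets the same conditional law as the permutation
        p_exact = fisher_exact_allelic(counts).p_value
        mc_se = math.sqrt(p_perm * (1 - p_perm) / 100_000)
        assert abs(p_exact - p_perm) < 4 * mc_se


class TestFisherExact:
    @pytest.mark.parametrize(
        "counts",
        [(0, 20, 10, 20), (3, 15, 9, 12), (1, 7, 6, 9), (5, 60, 1, 40)],
    )
    def test_matches_enumeration_oracle(self, counts):
        got = fisher_exact_allelic(AlleleCounts2x2(*counts)).p_value
        assert got == pytest.approx(fisher_enumeration_oracle(*counts), rel=1e-9)

    def test_symmetric_table_p_one(self):
        assert fisher_exact_allelic(AlleleCounts2x2(5, 20, 5, 20)).p_value == pytest.approx(1.0)

    def test_matches_scipy_on_random_tables(self, rng):
        # independent cross-check against the reference implementation
        for _ in range(200):
            n1, n2 = rng.integers(2, 80, size=2)
            x1, x2 = rng.integers(0, n1 + 1), rng.integers(0, n2 + 1)
            ours = fisher_exact_allelic(AlleleCounts2x2(x1, n1, x2, n2)).p_value
            ref = scipy.stats.fisher_exact(
                [[x1, n1 - x1], [x2, n2 - x2]]
            ).pvalue
            assert ours == pytest.approx(float(ref), rel=1e-6, abs=1e-12)

    def test_agrees_with_asymptotic_at_moderate_counts(self):
        exact = fisher_exact_allelic(AlleleCounts2x2(30, 400, 15, 400)).p_value
        asym = rd_score_test(AlleleCounts2x2(30, 400, 15, 400)).p_value
        assert exact / 2 < asym < exact * 2


class TestVariantDispatch:
    def test_fallback_on_zero_case_maf(self):
        res = run_variant_tests(AlleleCounts2x2(0, 3852, 28, 5848))
        assert res.fallback_used
        assert "fisher" in res.tests
        assert 0 <= res.tests["fisher"].p_value <= 1

    def test_no_fallback_for_common_clean_counts(self):
        res = run_variant_tests(AlleleCounts2x2(50, 1000, 40, 1000))
        assert not res.fallback_used and "fisher" not in res.tests

    def test_fallback_on_sub_threshold_maf(self):
        # control MAF 0.001 < default threshold 0.002
        res = run_variant_tests(AlleleCounts2x2(30, 4000, 4, 4000))
        assert res.fallback_used

    def test_threshold_is_configurable(self):
        cfg = ScanConfig(maf_fallback_threshold=0.05)
        res = run_variant_tests(AlleleCounts2x2(30, 1000, 20, 1000), cfg)
        assert res.fallback_used


class TestAdjustment:
    def test_bonferroni_genome_wide_threshold(self):
        # family level 0.05 over 413,059 tests
        assert 0.05 / 413_059 == pytest.approx(1.2e-7, rel=0.05)
        p = np.full(413_059, 1.3e-7)
        assert np.all(adjust_pvalues(p, "bonferroni") > 0.05)
        p[0] = 1.1e-7
        assert adjust_pvalues(p, "bonferroni")[0] < 0.05

    def test_single_p_unchanged(self):
        for method in ("bonferroni", "bh"):
            assert adjust_pvalues([0.031], method)[0] == pytest.approx(0.031)

    def test_bh_matches_step_up_oracle(self):
        pvals = [0.01, 0.02, 0.03, 0.04]
        # direct step-up definition: adj_(i) = min_{j>=i} min(1, m p_(j)/j)
        m = len(pvals)
        order = np.argsort(pvals)
        sorted_p = np.asarray(pvals)[order]
        raw = [m * p / (i + 1) for i, p in enumerate(sorted_p)]
        expected_sorted = [min(min(raw[i:]), 1.0) for i in range(m)]
        expected = np.empty(m)
        expected[order] = expected_sorted
        assert adjust_pvalues(pvals, "bh") == pytest.approx(expected)

    def test_bh_oracle_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(2, 50))
            m = p.size
            order = np.argsort(p)
            raw = m * p[order] / np.arange(1, m + 1)
            exp_sorted = np.minimum.accumulate(raw[::-1])[::-1].clip(max=1.0)
            expected = np.empty(m)
            expected[order] = exp_sorted
            assert adjust_pvalues(p, "bh") == pytest.approx(expected)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(30)
        for method in ("bonferroni", "bh"):
            assert np.all(adjust_pvalues(p, method) >= p - 1e-15)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5], "bonferroni")


class TestGenomeScan:
    def test_row_conservation_and_order(self, rng):
        rows = [
            (f"v{i}", AlleleCounts2x2(int(x), 100, int(y), 100))
            for i, (x, y) in enumerate(rng.integers(1, 50, size=(20, 2)))
        ]
        results = genome_scan(rows)
        assert [r.variant_id for r in results] == [r[0] for r in rows]

    def test_null_scan_rejection_rate(self, rng):
        # unadjusted rejections at nominal 0.05 on a null panel
        n = 2000
        p = 0.2
        rows = [
            ("v%d" % i, AlleleCounts2x2(int(a), 800, int(b), 800))
            for i, (a, b) in enumerate(
                zip(rng.binomial(800, p, n), rng.binomial(800, p, n))
            )
        ]
        results = genome_scan(rows, ScanConfig(adjustment="none"))
        rate = np.mean([r.tests["h"].p_value < 0.05 for r in results])
        ci = 2.58 * math.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) < ci + 0.005

    def test_zero_cell_variant_gets_fallback(self):
        rows = [
            ("a", AlleleCounts2x2(30, 400, 20, 400)),
            ("b", AlleleCounts2x2(0, 400, 20, 400)),
        ]
        results = genome_scan(rows)
        assert [r.fallback_used for r in results] == [False, True]

    def test_adjusted_p_at_least_raw(self):
        rows = [("v%d" % i, AlleleCounts2x2(10 + i, 200, 10, 200)) for i in range(8)]
        for adj in ("bonferroni", "bh"):
            for r in genome_scan(rows, ScanConfig(adjustment=adj)):
                for m in ("h", "rd", "or"):
                    assert r.adjusted_p[m] >= r.tests[m].p_value - 1e-15

    def test_duplicate_id_warns(self):
        rows = [("v", AlleleCounts2x2(5, 50, 5, 50))] * 2
        with pytest.warns(UserWarning, match="duplicate"):
            genome_scan(rows)

    def test_malformed_row_errors_with_position(self):
        rows = [("ok", AlleleCounts2x2(5, 50, 5, 50)), ("bad", (60, 50, 5, 50))]
        with pytest.raises(ValueError, match="row 1"):
            genome_scan(rows)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            genome_scan([])

    def test_significance_uses_exact_p_on_fallback(self):
        # strong effect but zero cell: asymptotic OR p undefined, exact decides
        rows = [("z", AlleleCounts2x2(0, 2000, 60, 2000))] + [
            ("v%d" % i, AlleleCounts2x2(10, 2000, 10, 2000)) for i in range(4)
        ]
        res = genome_scan(rows, ScanConfig(alpha_family=0.05))[0]
        assert res.fallback_used
        expected = res.adjusted_p["fisher"] <= 0.05
        assert res.significant["h"] == expected
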