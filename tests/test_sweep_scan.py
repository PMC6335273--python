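"""Window scan: tiling, 2x2 homogeneity test, Bonferroni, PASS merging."""


import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from passcan.sweep_scan import (WindowCounts, WindowTest,
                                bonferroni, call_pass, count_windows,
                                homogeneity_test, make_windows, scan)
from passcan.variants import SiteClass


def wc(f_a, p_a, f_b, p_b, chrom="chr1", start=0, end=50_000):
    return WindowCounts(chrom, start, end, p_a, f_a, p_b, f_b)


def fisher_by_enumeration(f_a, p_a, f_b, p_b) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    row1, col1, n = f_a + p_a, f_a + f_b, f_a + p_a + f_b + p_b
    pmf = [hypergeom.pmf(k, n, col1, row1)
           for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1)]
    p_obs = hypergeom.pmf(f_a, n, col1, row1)
    return float(sum(p for p in pmf if p <= p_obs * (1 + 1e-7)))


class TestMakeWindows:
    def test_tiling_with_truncated_last_window(self):
        windows = make_windows({"chr1": 100_000}, 50_000, 10_000)
        assert [w[1] for w in windows] == list(range(0, 100_000, 10_000))
        assert windows[-1] == ("chr1", 90_000, 100_000)

    def test_short_chromosome_single_window(self):
        assert make_windows({"chr1": 30_000}, 50_000, 10_000) == \
            [("chr1", 0, 30_000)]

    def test_window_equals_step_tiles_without_overlap(self):
        windows = make_windows({"chr1": 35_000}, 10_000, 10_000)
        assert windows == [("chr1", 0, 10_000), ("chr1", 10_000, 20_000),
                           ("chr1", 20_000, 30_000), ("chr1", 30_000, 35_000)]

    def test_every_base_covered(self):
        windows = make_windows({"c": 123_456}, 50_000, 10_000)
        covered = np.zeros(123_456, dtype=bool)
        for _, s, e in windows:
            covered[s:e] = True
        assert covered.all()

    def test_zero_length_chromosome_skipped(self):
        assert make_windows({"empty": 0, "c": 1000}, 500, 500) == \
            [("c", 0, 500), ("c", 500, 1000)]

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"c": 1000}, 100, 200)


class TestCountWindows:
    def classes(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "site_class"])

    def test_empty_window_all_zero(self):
        counts = count_windows(self.classes([]), [("chr1", 0, 50_000)])
        assert counts[0].table == [[0, 0], [0, 0]]

    def test_poly_both_increments_both_sides(self):
        table = self.classes([("chr1", 10, SiteClass.POLY_BOTH.value)])
        (w,) = count_windows(table, [("chr1", 0, 100)])
        assert (w.P_A, w.P_B, w.F_A, w.F_B) == (1, 1, 0, 0)

    def test_window_membership_is_half_open_on_zero_based(self):
        # 1-based pos p belongs to [s, e) iff s < p <= e
        table = self.classes([("chr1", 100, SiteClass.FIXED_A.value),
                              ("chr1", 200, SiteClass.FIXED_A.value)])
        w1, w2 = count_windows(table, [("chr1", 0, 100), ("chr1", 100, 200)])
        assert (w1.F_A, w2.F_A) == (1, 1)

    def test_overlapping_windows_count_site_repeatedly(self):
        table = self.classes([("chr1", 15_000, SiteClass.FIXED_A.value)])
        windows = make_windows({"chr1": 60_000}, 50_000, 10_000)
        counts = count_windows(table, windows)
        assert sum(w.F_A for w in counts) == 2  # [0,50k) and [10k,60k)

    def test_planted_sweep_window_matches_truth(self, default_world):
        truth = default_world.truth.site_truth.rename(
            columns={"truth_class": "site_class"})
        chrom, s, e = default_world.truth.sweep_intervals[0]
        (w,) = count_windows(truth, [(chrom, s, e)])
        n_truth = ((truth.chrom == chrom) & (truth.pos > s) & (truth.pos <= e)
                   & (truth.site_class == "FIXED_A")).sum()
        assert w.F_A == n_truth


class TestHomogeneityTest:
    def test_published_pass_contingency_table(self):
        # NS/S-in-PASS vs NS/S-elsewhere table; exact test
        p = homogeneity_test(wc(1021, 1553, 2481, 4587), "fisher")
        assert p == pytest.approx(4.239e-05, rel=1e-3)

    def test_identical_odds_give_p_one(self):
        assert homogeneity_test(wc(10, 10, 10, 10), "fisher") == 1.0

    def test_diagonal_three_table(self):
        assert homogeneity_test(wc(3, 0, 0, 3), "fisher") == \
            pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("counts", [wc(0, 0, 5, 5), wc(0, 4, 0, 7),
                                        wc(3, 0, 8, 0), wc(0, 0, 0, 0)])
    def test_zero_row_or_column_is_uninformative(self, counts):
        assert homogeneity_test(counts) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            WindowCounts("c", 0, 10, -1, 2, 3, 4)

    def test_chisq_variant_matches_pearson(self):
        from scipy.stats import chi2_contingency
        counts = wc(30, 50, 10, 60)
        expected = chi2_contingency([[30, 50], [10, 60]],
                                    correction=False).pvalue
        assert homogeneity_test(counts, "chisq") == pytest.approx(expected)

    def test_fisher_matches_enumeration_on_random_tables(self, rng):
        for _ in range(50):
            f_a, p_a, f_b, p_b = rng.integers(0, 13, size=4)
            counts = wc(int(f_a), int(p_a), int(f_b), int(p_b))
            got = homogeneity_test(counts, "fisher")
            if min(f_a + p_a, f_b + p_b, f_a + f_b, p_a + p_b) == 0:
                assert got == 1.0
            else:
                assert got == pytest.approx(
                    fisher_by_enumeration(f_a, p_a, f_b, p_b), rel=1e-9)

    def test_population_exchange_preserves_p(self, rng):
        for _ in range(30):
            f_a, p_a, f_b, p_b = map(int, rng.integers(0, 30, size=4))
            p1 = homogeneity_test(wc(f_a, p_a, f_b, p_b))
            p2 = homogeneity_test(wc(f_b, p_b, f_a, p_a))
            assert p1 == pytest.approx(p2, rel=1e-12)


class TestBonferroni:
    def test_single_test_unchanged(self):
        assert bonferroni([0.01]) == [0.01]

    def test_multiplies_by_family_size_and_caps(self):
        assert bonferroni([0.001, 0.2]) == [0.002, 0.4]
        assert bonferroni([0.9, 0.9]) == [1.0, 1.0]

    def test_thousand_windows(self):
        adj = bonferroni([1e-6] * 1000)
        assert all(a == pytest.approx(1e-3) for a in adj)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bonferroni([1.5])

    def test_adjusted_monotone_in_raw(self, rng):
        p = sorted(rng.random(100))
        adj = bonferroni(p)
        assert adj == sorted(adj)


class TestCallPass:
    def make_test(self, chrom, start, end, p_adj, f_a=50, f_b=0, p_a=10,
                  p_b=10):
        w = WindowCounts(chrom, start, end, p_a, f_a, p_b, f_b)
        return WindowTest(w, p_adj, p_adj, f_a * p_b > f_b * p_a and f_a > f_b)

    def test_overlapping_windows_merge(self):
        tests = [self.make_test("chr1", 0, 50_000, 1e-4),
                 self.make_test("chr1", 40_000, 90_000, 1e-5)]
        (region,) = call_pass(tests, alpha=0.05)
        assert (region.start, region.end) == (0, 90_000)
        assert region.n_windows == 2
        assert region.min_p_adj == 1e-5

    def test_bookended_windows_merge(self):
        tests = [self.make_test("chr1", 0, 50_000, 1e-4),
                 self.make_test("chr1", 50_000, 100_000, 1e-4)]
        assert len(call_pass(tests, 0.05)) == 1

    def test_direction_rule_blocks_b_skewed_window(self):
        t = self.make_test("chr1", 0, 50_000, 1e-9, f_a=0, f_b=50)
        assert call_pass([t], 0.05) == []

    def test_tie_at_alpha_not_significant(self):
        t = self.make_test("chr1", 0, 50_000, 0.05)
        assert call_pass([t], 0.05) == []

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            call_pass([], alpha=0.0)

    def test_min_f_ratio_tightens_selection(self):
        t = self.make_test("chr1", 0, 50_000, 1e-4, f_a=10, f_b=6)
        assert len(call_pass([t], 0.05)) == 1
        assert call_pass([t], 0.05, min_f_ratio=2.0) == []

    def test_merged_regions_disjoint_and_bounded(self, default_world):
        from passcan.pipeline import ScanParams, classify_stage, scan_stage
        spec = default_world.config.population_spec()
        table, _ = classify_stage(default_world.sites, spec)
        tests, regions = scan_stage(table, default_world.chrom_sizes,
                                    ScanParams())
        by_chrom = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for rs in by_chrom.values():
            rs.sort(key=lambda r: r.start)
            for a, b in zip(rs, rs[1:]):
                assert a.end < b.start  # disjoint, non-abutting
        selected_len = sum(t.window.end - t.window.start for t in tests
                           if np.isfinite(t.p_raw) and t.p_adj < 0.05
                           and t.direction_a)
        merged_len = sum(r.end - r.start for r in regions)
        assert merged_len <= selected_len


class TestScan:
    def test_family_size_excludes_empty_windows(self):
        table = pd.DataFrame(
            [("chr1", 5_000, SiteClass.FIXED_A.value),
             ("chr1", 6_000, SiteClass.POLY_B_ONLY.value)],
            columns=["chrom", "pos", "site_class"])
        # 10 windows but only those containing the two sites are testable
        tests = scan(table, {"chr1": 100_000}, 10_000, 10_000)
        testable = [t for t in tests if np.isfinite(t.p_raw)]
        assert len(testable) == 1
        assert testable[0].p_adj == testable[0].p_raw  # m = 1

    def test_population_exchange_inverts_direction(self):
        table = pd.DataFrame(
            [("chr1", p, SiteClass.FIXED_A.value) for p in range(100, 4000, 100)]
            + [("chr1", p, SiteClass.POLY_B_ONLY.value)
               for p in range(50, 4000, 100)],
            columns=["chrom", "pos", "site_class"])
        swapped = table.replace({"FIXED_A": "FIXED_B",
                                 "POLY_B_ONLY": "POLY_A_ONLY"})
        (t1,) = scan(table, {"chr1": 4000}, 4000, 4000)
        (t2,) = scan(swapped, {"chr1": 4000}, 4000, 4000)
        assert t1.p_raw == pytest.approx(t2.p_raw, rel=1e-12)
        assert t1.direction_a and not t2.direction_a
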