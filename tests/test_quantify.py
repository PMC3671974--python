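"""Region quantification, the exact differential test, BH, and quartiles."""

import numpy as np
import pandas as pd
import pytest

from ssi_cistrome.core import GenomeIndex, Interval, TagLibrary, make_tags
from ssi_cistrome.peaks import Peak, PeakSet, bh_adjust
from ssi_cistrome.quantify import (ConsolidatedRegion, assign_quartiles,
                                   count_tags, differential_test,
                                   group_height_summary, merge_condition_peaks,
                                   region_height, regions_to_frame)


def _brute_height(region, lib, fragment_bp):
    depth = np.zeros(len(region), dtype=int)
    for _, t in lib.tags.iterrows():
        if t.chrom != region.chrom:
            continue
        if t.strand == "+":
            lo, hi = t.pos5, t.pos5 + fragment_bp
        else:
            lo, hi = t.pos5 - fragment_bp + 1, t.pos5 + 1
        lo, hi = max(lo, region.start), min(hi, region.end)
        for b in range(lo, hi):
            depth[b - region.start] += 1
    return depth.max() * 1e6 / lib.n_tags if lib.n_tags else 0.0


def _brute_count(region, lib, fragment_bp):
    n = 0
    for _, t in lib.tags.iterrows():
        if t.chrom != region.chrom:
            continue
        if t.strand == "+":
            lo, hi = t.pos5, t.pos5 + fragment_bp
        else:
            lo, hi = t.pos5 - fragment_bp + 1, t.pos5 + 1
        n += lo < region.end and hi > region.start
    return n


class TestRegionQuantification:
    def test_single_covering_fragment_arithmetic(self):
        lib = TagLibrary(make_tags(["chr1"] * 10, [1000] + [50_000] * 9, ["+"] * 10),
                         "r", "fasted")
        h = region_height(Interval("chr1", 1000, 1100), lib, fragment_bp=108)
        assert h == pytest.approx(1e5)  # 1 fragment / 10 tags * 1e6

    def test_region_without_fragments_is_zero(self):
        lib = TagLibrary(make_tags(["chr1"], [10], ["+"]), "r", "fasted")
        assert region_height(Interval("chr1", 5_000, 5_100), lib) == 0.0
        assert count_tags(Interval("chr1", 5_000, 5_100), lib) == 0

    def test_seven_overlapping_fragments_counted(self):
        pos = [1000, 1010, 1020, 1030, 1040, 1050, 1060]
        lib = TagLibrary(make_tags(["chr1"] * 7, pos, ["+"] * 7), "r", "fasted")
        assert count_tags(Interval("chr1", 1050, 1200), lib, fragment_bp=108) == 7

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_pileup(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            center = int(rng.integers(500, 9_500))
            pos = center + rng.integers(-300, 300, size=50)
            strands = rng.choice(["+", "-"], 50)
            lib = TagLibrary(make_tags(["chr1"] * 50, pos, strands).drop_duplicates(),
                             "r", "fasted")
            w = int(rng.integers(50, 400))
            region = Interval("chr1", center - w // 2, center + w // 2)
            assert region_height(region, lib, 108) == pytest.approx(
                _brute_height(region, lib, 108))
            assert count_tags(region, lib, 108) == _brute_count(region, lib, 108)

    def test_rpm_invariant_under_library_duplication(self):
        rng = np.random.default_rng(21)
        tags = make_tags(["chr1"] * 100, rng.integers(0, 5_000, 100),
                         rng.choice(["+", "-"], 100))
        lib = TagLibrary(tags, "r", "fasted")
        doubled = TagLibrary(pd.concat([tags, tags]), "r2", "fasted")
        region = Interval("chr1", 2_000, 2_500)
        assert region_height(region, lib) == pytest.approx(region_height(region, doubled))


def _peakset(intervals):
    return PeakSet([Peak(iv, iv.center, 1.0) for iv in intervals])


def _site_library(rng, centers_heights, depth, rep, cond, span=50_000):
    """Library with n tags stacked at each center plus uniform background."""
    frames = []
    for center, n in centers_heights:
        frames.append(make_tags(["chr1"] * n, center - rng.integers(0, 108, n), ["+"] * n))
    n_bg = depth - sum(n for _, n in centers_heights)
    frames.append(make_tags(["chr1"] * n_bg, rng.integers(0, span, n_bg),
                            rng.choice(["+", "-"], n_bg)))
    return TagLibrary(pd.concat(frames), rep, cond)


class TestMergeConditionPeaks:
    def test_identical_sets_give_one_both_region(self):
        rng = np.random.default_rng(22)
        libs = [_site_library(rng, [(10_000, 100)], 2_000, f"rep{i}", cond)
                for cond in ("fasted", "refed") for i in (1, 2)]
        ps = _peakset([Interval("chr1", 9_900, 10_100)])
        regions = merge_condition_peaks(ps, ps, libs, height_threshold=0.35)
        assert len(regions) == 1 and regions[0].origin == "both"

    def test_one_sided_call_quantified_in_both_conditions(self):
        # a fasted-only CALL whose re-fed signal is comparable stays, with
        # both condition heights populated: call-set asymmetry != binding asymmetry
        rng = np.random.default_rng(23)
        libs = [_site_library(rng, [(10_000, 100)], 2_000, f"rep{i}", cond)
                for cond in ("fasted", "refed") for i in (1, 2)]
        fasted_only = _peakset([Interval("chr1", 9_900, 10_100)])
        regions = merge_condition_peaks(fasted_only, _peakset([]), libs)
        assert len(regions) == 1
        r = regions[0]
        assert r.origin == "fasted-only"
        assert r.mean_rpm["refed"] > 0
        assert r.mean_rpm["fasted"] == pytest.approx(r.mean_rpm["refed"], rel=0.5)

    def test_height_threshold_matches_direct_recomputation(self):
        rng = np.random.default_rng(24)
        centers = [(3_000 + 1_500 * i, h) for i, h in
                   enumerate([2, 4, 8, 16, 32, 64])]
        libs = [_site_library(rng, centers, 20_000, f"rep{i}", cond)
                for cond in ("fasted", "refed") for i in (1, 2)]
        ps = _peakset([Interval("chr1", c - 100, c + 100) for c, _ in centers])
        threshold = 0.35
        regions = merge_condition_peaks(ps, ps, libs, height_threshold=threshold)
        survivors = set()
        for c, _ in centers:
            iv = Interval("chr1", c - 100, c + 100)
            means = {}
            for cond in ("fasted", "refed"):
                hs = [region_height(iv, lib) for lib in libs if lib.condition == cond]
                means[cond] = np.mean(hs)
            if 0.5 * (means["fasted"] + means["refed"]) > threshold:
                survivors.add(c)
        assert {r.interval.center for r in regions} == survivors

    def test_quantification_ignores_origin_labels(self):
        rng = np.random.default_rng(25)
        libs = [_site_library(rng, [(10_000, 80)], 2_000, f"rep{i}", cond)
                for cond in ("fasted", "refed") for i in (1, 2)]
        iv = Interval("chr1", 9_900, 10_100)
        as_fasted = merge_condition_peaks(_peakset([iv]), _peakset([]), libs)
        as_refed = merge_condition_peaks(_peakset([]), _peakset([iv]), libs)
        assert as_fasted[0].heights_rpm == as_refed[0].heights_rpm
        assert as_fasted[0].origin != as_refed[0].origin


class TestDifferentialTest:
    def test_symmetric_counts_give_p_one(self):
        p = differential_test(np.array([5]), np.array([5]),
                              np.array([10_000]), np.array([10_000]))
        assert p == pytest.approx(1.0)

    def test_ten_versus_zero_exact_value(self):
        p = differential_test(np.array([10]), np.array([0]),
                              np.array([10_000]), np.array([10_000]))
        assert p == pytest.approx(2 / 2**10)

    def test_all_zero_counts(self):
        assert differential_test(np.array([0]), np.array([0]),
                                 np.array([1_000]), np.array([1_000])) == 1.0

    def test_null_rejection_rate_at_most_nominal(self):
        rng = np.random.default_rng(26)
        xf, xr = rng.poisson(200, 500), rng.poisson(200, 500)
        sizes = np.array([100_000])
        pvals = np.array([
            differential_test(np.array([a]), np.array([b]), sizes, sizes)
            for a, b in zip(xf, xr)
        ])
        rate = (pvals <= 0.05).mean()
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 500)

    def test_power_monotone_in_fold(self):
        rng = np.random.default_rng(27)
        sizes = np.array([100_000])
        rejections = []
        for fold in (1.0, 2.0, 4.0):
            lam_f, lam_r = 60 * np.sqrt(fold), 60 / np.sqrt(fold)
            ps = [
                differential_test(np.array([rng.poisson(lam_f)]),
                                  np.array([rng.poisson(lam_r)]), sizes, sizes)
                for _ in range(150)
            ]
            rejections.append(np.mean(np.array(ps) <= 0.05))
        assert rejections == sorted(rejections)


class TestBhAdjust:
    def test_all_ones_nothing_significant(self):
        q, sig = bh_adjust(np.ones(10), q=0.10)
        assert not sig.any()

    def test_step_up_example(self):
        q, sig = bh_adjust(np.array([0.01, 0.02, 0.03, 0.5]), q=0.10)
        assert sig.tolist() == [True, True, True, False]

    def test_single_pvalue_identity(self):
        q, sig = bh_adjust(np.array([0.04]), q=0.10)
        assert sig[0] and q[0] == pytest.approx(0.04)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, np.nan]))

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(28)
        for _ in range(10_000):
            p = rng.random(rng.integers(1, 40))
            qvals, sig = bh_adjust(p, q=0.10)
            ref_sig, ref_q, *_ = multipletests(p, alpha=0.10, method="fdr_bh")
            np.testing.assert_allclose(qvals, ref_q, atol=1e-12)
            assert (sig == ref_sig).all()


def _region(chrom, start, end, avg):
    r = ConsolidatedRegion(interval=Interval(chrom, start, end), origin="both")
    r.avg_height = avg
    r.mean_rpm = {"fasted": avg, "refed": avg}
    return r


class TestQuartiles:
    def test_four_distinct_heights(self):
        regions = [_region("chr1", i * 100, i * 100 + 50, h)
                   for i, h in enumerate([1.0, 2.0, 3.0, 4.0])]
        assert assign_quartiles(regions) == [1, 2, 3, 4]

    def test_degenerate_ties_deterministic_and_balanced(self):
        regions = [_region("chr1", i * 100, i * 100 + 50, 1.0) for i in range(10)]
        labels = assign_quartiles(regions)
        counts = pd.Series(labels).value_counts()
        assert counts.max() - counts.min() <= 1
        assert labels == assign_quartiles(list(regions))  # rerun identical

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(29)
        heights = rng.random(1_000)
        regions = [_region("chr1", i * 10, i * 10 + 5, h)
                   for i, h in enumerate(heights)]
        labels = np.array(assign_quartiles(regions))
        order = np.argsort(heights, kind="stable")
        expected = np.empty(1_000, dtype=int)
        expected[order] = np.arange(1_000) * 4 // 1_000 + 1
        assert (labels == expected).all()

    def test_fewer_than_four_regions_single_stratum(self):
        regions = [_region("chr1", 0, 10, 1.0), _region("chr1", 20, 30, 2.0)]
        assert assign_quartiles(regions) == [1, 1]


class TestGroupSummary:
    def test_symmetric_heights_center_log_ratio_at_zero(self):
        rng = np.random.default_rng(30)
        regions = []
        for i in range(400):
            r = _region("chr1", i * 10, i * 10 + 5, 1.0)
            f, re_ = rng.lognormal(0, 0.3), rng.lognormal(0, 0.3)
            r.mean_rpm = {"fasted": f, "refed": re_}
            r.log2_ratio = np.log2(f / re_)
            regions.append(r)
        summary = group_height_summary(regions, ["all"] * 400)
        assert abs(summary.loc[0, "log2_ratio_median"]) < 0.1

    def test_matches_percentile_oracle(self):
        rng = np.random.default_rng(31)
        regions, groups = [], []
        for i in range(300):
            g = "a" if i % 2 else "b"
            r = _region("chr1", i * 10, i * 10 + 5, float(rng.random() + (g == "a")))
            r.log2_ratio = float(rng.normal())
            regions.append(r)
            groups.append(g)
        summary = group_height_summary(regions, groups).set_index("group")
        for g in ("a", "b"):
            vals = [r.avg_height for r, gg in zip(regions, groups) if gg == g]
            assert summary.loc[g, "avg_height_median"] == pytest.approx(
                np.percentile(vals, 50))
            assert summary.loc[g, "avg_height_q1"] == pytest.approx(
                np.percentile(vals, 25))
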