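"""SNP-index arithmetic, windows, regions, and the dual-bulk filter."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mutmaplite import (
    BulkConfig,
    CandidateFilterConfig,
    GenomeSpec,
    candidate_snp_filter,
    compute_index_table,
    compute_snp_index,
    detect_candidate_regions,
    expected_wp_index,
    filter_sites,
    load_table1,
    simulate_cross,
    sliding_window_mean,
    wp_consistency_pvalue,
    wp_retention_probability,
)
from mutmaplite.pipeline import build_causal_gene_model
from mutmaplite.annotate import annotate_table
from mutmaplite.snpindex import WindowSeries


class TestSnpIndex:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [(13, 7, 0.35), (0, 25, 1.0), (10, 0, 0.0), (1, 1, 0.5)],
    )
    def test_index_is_alt_fraction(self, ref, alt, expected):
        assert compute_snp_index(ref, alt) == pytest.approx(expected)

    def test_zero_depth_is_undefined(self):
        assert math.isnan(compute_snp_index(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_snp_index(-1, 5)

    @settings(derandomize=True, max_examples=200)
    @given(ref=st.integers(0, 1000), alt=st.integers(0, 1000))
    def test_index_in_unit_interval_iff_depth_positive(self, ref, alt):
        idx = compute_snp_index(ref, alt)
        if ref + alt == 0:
            assert math.isnan(idx)
        else:
            assert 0.0 <= idx <= 1.0


class TestIndexTable:
    def test_toy_table_indices(self, toy_counts):
        table = compute_index_table(toy_counts)
        assert len(table) == 3
        assert table["wp_index"].tolist()[:2] == [pytest.approx(0.35), 1.0]
        assert math.isnan(table["wp_index"].iloc[2])  # zero WP depth
        assert table["mp_index"].tolist()[:2] == [1.0, 0.5]
        assert table["mp_depth"].tolist() == [20, 20, 5]

    def test_empty_table(self, toy_counts):
        table = compute_index_table(toy_counts.iloc[:0])
        assert len(table) == 0

    def test_unsorted_input_rejected(self, toy_counts):
        shuffled = toy_counts.iloc[[2, 0, 1]].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            compute_index_table(shuffled)

    def test_table1_fixture_has_ten_records_with_mp_index_one(self):
        records = load_table1().records()
        assert len(records) == 10
        assert (records["mp_index"] == 1).all()


class TestDepthFilter:
    def test_zero_threshold_is_identity(self, toy_counts):
        table = compute_index_table(toy_counts)
        assert filter_sites(table, 0).equals(table)

    def test_brute_force_subset_oracle(self, rng):
        n = 60
        table = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, n + 1),
                "ref": "C",
                "alt": "T",
                "wp_index": 0.5,
                "mp_index": 0.5,
                "wp_depth": rng.integers(0, 25, n),
                "mp_depth": rng.integers(0, 25, n),
            }
        )
        got = filter_sites(table, 10)
        expected = [
            i for i in range(n)
            if table["wp_depth"][i] >= 10 and table["mp_depth"][i] >= 10
        ]
        assert got["pos"].tolist() == [i + 1 for i in expected]


def naive_window_means(pos, idx, starts, window_bp):
    """O(n * windows) reference implementation of the window rule."""
    means, counts = [], []
    for s in starts:
        member = [
            v for p, v in zip(pos, idx) if s <= p - 1 < s + window_bp and not math.isnan(v)
        ]
        counts.append(len(member))
        means.append(sum(member) / len(member) if member else math.nan)
    return means, counts


class TestSlidingWindow:
    def _records(self, pos, idx):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": pos,
                "ref": "C",
                "alt": "T",
                "wp_index": idx,
                "mp_index": idx,
                "wp_depth": 30,
                "mp_depth": 30,
            }
        )

    def test_single_snp_fills_every_covering_window(self):
        series = sliding_window_mean(
            self._records([1_500_000], [0.8]), "chr1",
            window_bp=1_000_000, step_bp=1_000, chrom_length=3_000_000,
        )
        f = series.frame
        covering = (f["start"] <= 1_499_999) & (1_499_999 < f["end"])
        assert (f.loc[covering, "mean_index"] == 0.8).all()
        assert f.loc[~covering, "mean_index"].isna().all()

    def test_two_snps_average(self):
        series = sliding_window_mean(
            self._records([100, 200], [0.2, 1.0]), "chr1",
            window_bp=1_000, step_bp=1_000, chrom_length=1_000,
        )
        assert series.frame["mean_index"].iloc[0] == pytest.approx(0.6)

    def test_matches_naive_oracle_on_random_instance(self, rng):
        n = 500
        pos = np.sort(rng.choice(np.arange(1, 5_000_001), size=n, replace=False))
        idx = rng.random(n)
        idx[rng.random(n) < 0.05] = np.nan  # a few undefined sites
        series = sliding_window_mean(
            self._records(pos, idx), "chr1",
            window_bp=1_000_000, step_bp=1_000, chrom_length=5_000_000,
        )
        means, counts = naive_window_means(
            pos, idx, series.frame["start"].tolist(), 1_000_000
        )
        got = series.frame["mean_index"].to_numpy()
        assert np.allclose(got, means, equal_nan=True)
        assert series.frame["n_snps"].tolist() == counts

    def test_unsorted_records_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            sliding_window_mean(self._records([200, 100], [0.5, 0.5]), "chr1")


class TestRegions:
    def _series(self, means, step=1_000, window=10_000):
        starts = np.arange(0, len(means) * step, step)
        frame = pd.DataFrame(
            {
                "start": starts,
                "end": starts + window,
                "mean_index": means,
                "n_snps": [0 if math.isnan(v) else 1 for v in means],
            }
        )
        return WindowSeries("chr1", "mp", window, step, frame)

    def test_flat_series_below_threshold_yields_nothing(self):
        assert detect_candidate_regions(self._series([0.5] * 50)) == []

    def test_all_windows_above_threshold_span_everything(self):
        regions = detect_candidate_regions(self._series([0.95] * 50))
        assert len(regions) == 1
        assert regions[0].start == 0 and regions[0].end == 49_000 + 10_000

    def test_short_runs_are_dropped(self):
        means = [0.5] * 10 + [0.95] * 3 + [0.5] * 10
        assert detect_candidate_regions(self._series(means), min_windows=5) == []

    def test_overlapping_runs_merge(self):
        # two runs separated by one low window but overlapping genomically
        means = [0.95] * 10 + [0.5] + [0.95] * 10
        regions = detect_candidate_regions(self._series(means), min_windows=2)
        assert len(regions) == 1

    def test_simulated_mutant_bulk_yields_one_region_containing_causal(self, genome):
        cfg = BulkConfig(seed=42, mean_depth=30, error_rate=0.005)
        res = simulate_cross(genome, n_variants=300, config=cfg)
        table = filter_sites(compute_index_table(res.counts), 10)
        series = sliding_window_mean(
            table, "chr1", chrom_length=30_000_000
        )
        regions = detect_candidate_regions(series, 0.9, min_windows=10)
        assert len(regions) >= 1
        top = regions[0]
        assert top.start < res.truth.causal_pos - 1 < top.end


class TestWpExpectation:
    def test_recessive_wild_type_class_expectation_is_one_third(self):
        # AA : Aa = 1 : 2 -> (0*1 + 1*2) / (2*3)
        assert expected_wp_index() == pytest.approx(1 / 3)
        assert expected_wp_index({0: 1, 1: 2}) == (0 * 1 + 1 * 2) / (2 * 3)

    def test_mutant_class_and_reference_class_extremes(self):
        assert expected_wp_index({2: 1}) == 1.0
        assert expected_wp_index({0: 1}) == 0.0


def pvalue_by_summation(alt, depth, p0):
    """Brute-force minimum-likelihood two-sided binomial p-value."""
    pmf = [stats.binom.pmf(k, depth, p0) for k in range(depth + 1)]
    obs = pmf[alt]
    return sum(p for p in pmf if p <= obs * (1 + 1e-9))


class TestWpConsistency:
    def test_exact_expectation_has_pvalue_one(self):
        assert wp_consistency_pvalue(10, 30) == pytest.approx(1.0)

    def test_all_alt_reads_pvalue_equals_point_mass(self):
        p = wp_consistency_pvalue(30, 30)
        assert p == pytest.approx((1 / 3) ** 30, rel=1e-9)
        assert p == pytest.approx(pvalue_by_summation(30, 30, 1 / 3), rel=1e-9)

    def test_observed_035_not_rejected(self):
        # 7/20 = 0.35, the fixture's accepted wild-type bulk index
        p = wp_consistency_pvalue(7, 20)
        assert p >= 0.05
        assert p == pytest.approx(pvalue_by_summation(7, 20, 1 / 3), rel=1e-9)

    @pytest.mark.parametrize("alt,depth", [(0, 12), (5, 30), (14, 30), (25, 40)])
    def test_matches_summation_oracle(self, alt, depth):
        assert wp_consistency_pvalue(alt, depth) == pytest.approx(
            pvalue_by_summation(alt, depth, 1 / 3), rel=1e-9
        )

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ValueError):
            wp_consistency_pvalue(0, 0)


class TestCandidateFilter:
    REGION = ("chr12", 23_000_000, 27_000_000)

    def _fixture_report(self, **kw):
        fx = load_table1()
        cfg = CandidateFilterConfig(region=self.REGION, **kw)
        return candidate_snp_filter(fx.records(), fx.annotations(), cfg)

    def test_full_filter_leaves_unique_causative_snp(self):
        report = self._fixture_report()
        survivors = report[report["pass_all"]]
        assert len(survivors) == 1
        assert int(survivors["pos"].iloc[0]) == 26_056_055
        assert float(survivors["wp_index"].iloc[0]) == pytest.approx(0.35)
        assert float(survivors["rank"].iloc[0]) == 1.0

    def test_region_filter_alone_keeps_six(self):
        report = self._fixture_report()
        assert int(report["pass_region"].sum()) == 6

    def test_nonsynonymous_filter_alone_keeps_two(self):
        report = self._fixture_report()
        kept = report[report["pass_effect"]]
        assert set(kept["gene_id"]) == {"ORF2", "ORF6"}

    def test_verdicts_reported_for_every_record(self):
        report = self._fixture_report()
        assert len(report) == 10
        for col in ("pass_mp", "pass_region", "pass_wp_band", "pass_effect"):
            assert report[col].notna().all()

    def test_filter_composition_is_order_independent(self):
        """Intersecting single-filter survivor sets equals the full filter."""
        fx = load_table1()
        records, ann = fx.records(), fx.annotations()
        full = candidate_snp_filter(
            records, ann, CandidateFilterConfig(region=self.REGION)
        )
        survivors = set(full.loc[full["pass_all"], "pos"])
        verdict_cols = [
            "pass_depth", "pass_mp", "pass_region",
            "pass_wp_band", "pass_wp_consistency", "pass_effect",
        ]
        for order in ([0, 1, 2, 3, 4, 5], [5, 4, 3, 2, 1, 0], [2, 5, 0, 3, 1, 4]):
            kept = set(full["pos"])
            for i in order:
                kept &= set(full.loc[full[verdict_cols[i]], "pos"])
            assert kept == survivors

    def test_simulated_cross_ranks_causal_first(self, genome):
        cfg = BulkConfig(seed=7, mean_depth=30, error_rate=0.005)
        res = simulate_cross(genome, n_variants=300, config=cfg)
        table = filter_sites(compute_index_table(res.counts), 10)
        model = build_causal_gene_model(res.variants, genome, 123)
        ann = annotate_table(table, [model], chromosomes=("chr1",))
        report = candidate_snp_filter(table, ann, CandidateFilterConfig())
        top = report.iloc[0]
        assert top["pass_all"]
        assert int(top["pos"]) == res.truth.causal_pos

    def test_band_must_contain_target(self):
        with pytest.raises(ValueError):
            CandidateFilterConfig(wp_band=(0.6, 0.9))  # target 1/3 outside

    def test_missing_annotation_for_survivor_raises(self):
        fx = load_table1()
        ann = fx.annotations()
        ann = ann[ann["pos"] != 26_056_055]  # break the join for the survivor
        with pytest.raises(ValueError, match="annotation missing"):
            candidate_snp_filter(
                fx.records(), ann, CandidateFilterConfig(region=self.REGION)
            )


class TestFilterCalibration:
    def test_default_wp_criterion_retains_causal_site(self):
        """At the design depth the WP criterion must rarely miss a true
        causal site; the exact mixture computation keeps this auditable."""
        p = wp_retention_probability()
        assert p > 0.97

    def test_retention_is_monotone_in_band_width(self):
        narrow = wp_retention_probability(wp_band=(1 / 6, 0.5))
        wide = wp_retention_probability(wp_band=(0.1, 0.6))
        assert wide > narrow
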