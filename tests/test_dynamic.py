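"""Dynamic-feature thresholds, DMR merging/filtering, global methylation."""

import numpy as np
import pandas as pd
import pytest

import tempomod as tm
from tempomod.core import UndefinedInputError, merge_intervals


def regionset(intervals, chrom="chr1"):
    rows = [(chrom, s, e, f"c{i}", ".") for i, (s, e) in enumerate(intervals)]
    return tm.GenomicRegionSet.from_records(rows)


def brute_force_select(stats, levels, spec):
    """Row-by-row re-statement of the selection rule."""
    out = set()
    for _, row in stats.iterrows():
        if row["q"] > spec.q_threshold or abs(row["log2fc"]) < spec.min_abs_log2fc:
            continue
        lv = levels.loc[row["feature"], [row["cond_a"], row["cond_b"]]]
        if lv.max() >= spec.min_level:
            out.add(row["feature"])
    return out


def component_merge(intervals):
    """Quadratic connectivity oracle: intervals sharing >= 1 base merge;
    book-ended intervals stay separate."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if max(a[0], b[0]) < min(a[1], b[1]):
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return sorted(
        (min(intervals[i][0] for i in m), max(intervals[i][1] for i in m))
        for m in comps.values()
    )


class TestSelectDynamicFeatures:
    def stats_row(self, feature, lfc, q, cond_a="A", cond_b="B"):
        return {
            "feature": feature, "comparison": f"{cond_a}__vs__{cond_b}",
            "cond_a": cond_a, "cond_b": cond_b, "log2fc": lfc, "q": q,
        }

    def test_thresholds_select_and_reject_boundary_cases(self):
        levels = pd.DataFrame(
            {"A": [12.0, 8.0], "B": [1.0, 1.0]}, index=["hit", "lowlevel"]
        )
        stats = pd.DataFrame(
            [self.stats_row("hit", 1.6, 0.04), self.stats_row("lowlevel", 1.6, 0.04)]
        )
        spec = tm.FilterSpec(q_threshold=0.05, min_abs_log2fc=1.5, min_level=10.0)
        assert tm.select_dynamic_features(stats, levels, spec) == {"hit"}

    def test_level_scope_restricted_to_the_significant_comparison(self):
        # high level only in a condition outside the significant comparison
        levels = pd.DataFrame({"A": [2.0], "B": [3.0], "C": [50.0]}, index=["f"])
        stats = pd.DataFrame([self.stats_row("f", 2.0, 0.01)])
        spec = tm.FilterSpec(q_threshold=0.05, min_abs_log2fc=1.5, min_level=10.0)
        assert tm.select_dynamic_features(stats, levels, spec) == set()
        spec_overall = tm.FilterSpec(
            q_threshold=0.05, min_abs_log2fc=1.5, min_level=10.0, level_scope="overall"
        )
        assert tm.select_dynamic_features(stats, levels, spec_overall) == {"f"}

    def test_matches_brute_force_oracle_on_random_table(self):
        rng = np.random.default_rng(0)
        feats = [f"f{i}" for i in range(200)]
        conds = ["A", "B", "C"]
        levels = pd.DataFrame(
            rng.uniform(0, 20, size=(200, 3)), index=feats, columns=conds
        )
        rows = []
        for f in feats:
            for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
                rows.append(
                    self.stats_row(
                        f, rng.normal(0, 2), float(rng.uniform(0, 0.2)), a, b
                    )
                )
        stats = pd.DataFrame(rows)
        spec = tm.FilterSpec(q_threshold=0.05, min_abs_log2fc=1.5, min_level=10.0)
        assert tm.select_dynamic_features(stats, levels, spec) == brute_force_select(
            stats, levels, spec
        )

    def test_relaxing_any_threshold_is_monotone(self):
        rng = np.random.default_rng(1)
        feats = [f"f{i}" for i in range(100)]
        levels = pd.DataFrame(
            rng.uniform(0, 20, size=(100, 2)), index=feats, columns=["A", "B"]
        )
        stats = pd.DataFrame(
            [
                self.stats_row(f, rng.normal(0, 2), float(rng.uniform(0, 0.1)))
                for f in feats
            ]
        )
        strict = tm.FilterSpec(q_threshold=0.03, min_abs_log2fc=2.0, min_level=12.0)
        base = tm.select_dynamic_features(stats, levels, strict)
        for relaxed in (
            tm.FilterSpec(q_threshold=0.08, min_abs_log2fc=2.0, min_level=12.0),
            tm.FilterSpec(q_threshold=0.03, min_abs_log2fc=1.0, min_level=12.0),
            tm.FilterSpec(q_threshold=0.03, min_abs_log2fc=2.0, min_level=5.0),
        ):
            assert base <= tm.select_dynamic_features(stats, levels, relaxed)

    def test_unknown_feature_in_stats_raises_schema_error(self):
        levels = pd.DataFrame({"A": [1.0], "B": [1.0]}, index=["f"])
        stats = pd.DataFrame([self.stats_row("ghost", 2.0, 0.01)])
        with pytest.raises(tm.SchemaError):
            tm.select_dynamic_features(stats, levels, tm.FilterSpec())


class TestDmrMerging:
    def meth_calls(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total", "sample"])

    def test_overlapping_candidates_merge_bookended_stay_separate(self):
        cands = regionset([(100, 200), (150, 300), (400, 500)])
        merged = merge_intervals(cands.records)
        assert list(merged[["start", "end"]].itertuples(index=False, name=None)) == [
            (100, 300), (400, 500)
        ]

    def test_merge_matches_connectivity_oracle_on_random_intervals(self):
        rng = np.random.default_rng(2)
        intervals = [
            (int(s), int(s + rng.integers(1, 50)))
            for s in rng.integers(0, 500, size=60)
        ]
        merged = merge_intervals(regionset(intervals).records)
        got = list(merged[["start", "end"]].itertuples(index=False, name=None))
        assert got == component_merge(intervals)

    def test_merging_is_idempotent_and_conserves_union_length(self):
        rng = np.random.default_rng(3)
        intervals = [
            (int(s), int(s + rng.integers(1, 80)))
            for s in rng.integers(0, 1000, size=80)
        ]
        once = merge_intervals(regionset(intervals).records)
        twice = merge_intervals(once)
        pd.testing.assert_frame_equal(once.reset_index(drop=True), twice)
        union_length = len(set().union(*[range(s, e) for s, e in intervals]))
        assert (once["end"] - once["start"]).sum() == union_length

    def test_small_region_with_large_delta_not_differential(self):
        cands = regionset([(1000, 1090)])
        calls = self.meth_calls(
            [("chr1", 1050, m, 20, s) for s, m in [("s1", 2), ("s2", 2), ("s3", 16), ("s4", 16)]]
        )
        dmrs = tm.merge_and_filter_dmrs(cands, calls)
        assert not dmrs.differential.iloc[0]  # delta 0.7 but size 90 <= 100

    def test_delta_and_size_rule_flags_differential(self):
        cands = regionset([(0, 150)])
        calls = self.meth_calls(
            [("chr1", 50, m, 100, s) for s, m in [("s1", 10), ("s2", 10), ("s3", 45), ("s4", 45)]]
        )
        dmrs = tm.merge_and_filter_dmrs(
            cands, calls, sample_groups={"s1": "x", "s2": "x", "s3": "y", "s4": "y"}
        )
        assert dmrs.differential.iloc[0]  # delta 0.35 >= 0.3, size 150 > 100

    def test_coverage_must_strictly_exceed_min_reads(self):
        cands = regionset([(0, 150)])
        # exactly 5 reads in three samples: "more than five" fails
        calls = self.meth_calls(
            [("chr1", 50, 1, 5, s) for s in ["s1", "s2", "s3"]]
        )
        dmrs = tm.merge_and_filter_dmrs(cands, calls)
        assert len(dmrs.regions) == 0

    def test_weighted_methylation_is_pooled_read_fraction(self):
        cands = regionset([(0, 300)])
        calls = self.meth_calls(
            [("chr1", 10, 2, 10, "s1"), ("chr1", 200, 18, 30, "s1"),
             ("chr1", 10, 0, 10, "s2"), ("chr1", 200, 0, 30, "s2"),
             ("chr1", 10, 10, 10, "s3"), ("chr1", 200, 30, 30, "s3")]
        )
        dmrs = tm.merge_and_filter_dmrs(cands, calls)
        assert dmrs.methylation.iloc[0]["s1"] == pytest.approx(20 / 40)

    def test_cpg_outside_regions_ignored(self):
        cands = regionset([(0, 100)])
        calls = self.meth_calls(
            [("chr1", 50, 5, 10, s) for s in ["s1", "s2", "s3"]]
            + [("chr1", 5000, 10, 10, "s1")]
        )
        dmrs = tm.merge_and_filter_dmrs(cands, calls)
        assert dmrs.coverage.iloc[0]["s1"] == 10

    def test_proximity_merge_joins_regions_within_dis_merge(self):
        cands = regionset([(0, 100), (300, 400), (2000, 2100)])
        calls = self.meth_calls(
            [("chr1", 50, 5, 10, s) for s in ["s1", "s2", "s3"]]
            + [("chr1", 350, 5, 10, s) for s in ["s1", "s2", "s3"]]
            + [("chr1", 2050, 5, 10, s) for s in ["s1", "s2", "s3"]]
        )
        dmrs = tm.merge_and_filter_dmrs(cands, calls, proximity_merge=True)
        spans = list(
            dmrs.regions.records[["start", "end"]].itertuples(index=False, name=None)
        )
        assert spans == [(0, 400), (2000, 2100)]


class TestGlobalMethylation:
    def test_pooled_fraction(self):
        calls = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "pos": [1, 2], "meth": [30, 50],
             "total": [40, 60], "sample": ["s1", "s1"]}
        )
        assert tm.global_methylation(calls) == pytest.approx(80 / 100)

    def test_zero_methylation(self):
        calls = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [1], "meth": [0], "total": [100],
             "sample": ["s1"]}
        )
        assert tm.global_methylation(calls) == 0.0

    def test_mixed_coverage_matches_direct_summation(self):
        rng = np.random.default_rng(4)
        total = rng.integers(1, 50, size=100)
        meth = rng.integers(0, total + 1)
        calls = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(100), "meth": meth,
             "total": total, "sample": "s1"}
        )
        assert tm.global_methylation(calls) == pytest.approx(meth.sum() / total.sum())

    def test_no_detected_cpgs_is_undefined(self):
        calls = pd.DataFrame(
            {"chrom": [], "pos": [], "meth": [], "total": [], "sample": []}
        )
        with pytest.raises(UndefinedInputError):
            tm.global_methylation(calls)


class TestPrintedFixture:
    """The in-repo 30-record fixture with enumerated expected outputs."""

    def test_gene_filter_returns_exactly_the_expected_records(self, data_dir):
        stats = pd.read_csv(data_dir / "filter_genes_stats.tsv", sep="\t")
        levels = pd.read_csv(
            data_dir / "filter_genes_levels.tsv", sep="\t", index_col="feature"
        )
        expected = set((data_dir / "filter_genes_expected.txt").read_text().split())
        got = tm.select_dynamic_features(stats, levels, tm.FilterSpec.for_rna())
        assert got == expected

    def test_dmr_pipeline_returns_exactly_the_expected_regions(self, data_dir):
        cands = tm.GenomicRegionSet.from_bed(data_dir / "dmr_candidates.bed")
        calls = pd.read_csv(data_dir / "dmr_meth_calls.tsv", sep="\t")
        expected = pd.read_csv(data_dir / "dmr_expected.tsv", sep="\t")
        dmrs = tm.merge_and_filter_dmrs(
            cands, calls,
            sample_groups={"s1": "x", "s2": "x", "s3": "y", "s4": "y"},
        )
        got = dmrs.regions.records[["chrom", "start", "end"]].copy()
        got["differential"] = dmrs.differential.values
        pd.testing.assert_frame_equal(
            got.reset_index(drop=True), expected, check_dtype=False
        )

    def test_region_map_filter_returns_exactly_the_expected_records(self, data_dir):
        region_map = pd.read_csv(data_dir / "region_map.tsv", sep="\t")
        expected = (data_dir / "region_map_expected.txt").read_text().split()
        retained = tm.filter_mapped_regions(region_map)
        assert list(retained.records["id"]) == expected
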