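"""Genomic context, PWM scanning, entropy and conservation metrics."""

import itertools

import numpy as np
import pandas as pd
import pytest

import tempomod as tm
from tempomod.characterization import PSEUDOCOUNT, Pwm
from tempomod.core import UndefinedInputError


def regionset(intervals, chrom="chr1", prefix="r"):
    rows = [(chrom, s, e, f"{prefix}{i}", ".") for i, (s, e) in enumerate(intervals)]
    return tm.GenomicRegionSet.from_records(rows)


def tss_table(positions, chrom="chr1"):
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "strand": "+",
        }
    )


def enumerate_score_distribution(pwm: Pwm) -> dict[int, float]:
    """Independent 4^L oracle for the rounded-score background distribution."""
    scores = pwm.log_odds()
    dist: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=pwm.length):
        s = sum(int(scores[b, j]) for j, b in enumerate(word))
        p = 1.0
        for b in word:
            p *= pwm.background[b]
        dist[s] = dist.get(s, 0.0) + p
    return dist


class TestPromoterCgi:
    def test_region_inside_promoter_window_counted(self):
        regions = regionset([(9500, 10100)])  # TSS 10000: [TSS-500, TSS+100)
        frac, _ = tm.promoter_cgi_overlap(regions, tss_table([10000]), regionset([], prefix="c"))
        assert frac == 1.0

    def test_region_starting_at_window_end_not_counted(self):
        regions = regionset([(11000, 11100)])  # starts exactly at TSS+1000
        frac, _ = tm.promoter_cgi_overlap(regions, tss_table([10000]), regionset([], prefix="c"))
        assert frac == 0.0

    def test_cgi_fraction_counting_oracle(self):
        regions = regionset([(i * 1000, i * 1000 + 100) for i in range(10)])
        cgi = regionset([(50, 80), (1050, 1080), (2050, 2080)], prefix="c")
        _, cgi_frac = tm.promoter_cgi_overlap(regions, tss_table([500_000]), cgi)
        assert cgi_frac == pytest.approx(0.3)

    def test_empty_region_set_is_an_error(self):
        with pytest.raises(UndefinedInputError):
            tm.promoter_cgi_overlap(regionset([]), tss_table([0]), regionset([], prefix="c"))


class TestNearestTss:
    def test_tss_inside_region_links_at_distance_zero(self):
        links = tm.nearest_tss_link(regionset([(100, 200)]), tss_table([150]))
        assert links["r0"] == "g0"

    def test_tss_just_beyond_max_dist_unlinked(self):
        links = tm.nearest_tss_link(
            regionset([(200_000, 200_100)]), tss_table([99_999]), max_dist=100_000
        )
        assert "r0" not in links  # distance 100,001

    def test_tss_exactly_at_max_dist_linked(self):
        links = tm.nearest_tss_link(
            regionset([(200_000, 200_100)]), tss_table([100_000]), max_dist=100_000
        )
        assert links["r0"] == "g0"

    def test_closer_of_two_tss_wins(self):
        links = tm.nearest_tss_link(
            regionset([(100_000, 100_350)]), tss_table([95_000, 92_000])
        )
        assert links["r0"] == "g0"

    def test_agrees_with_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n_regions, n_tss = 50, 40
            starts = rng.integers(0, 1_000_000, size=n_regions)
            regions = regionset([(int(s), int(s) + int(rng.integers(50, 500))) for s in starts])
            tss = tss_table(sorted(int(p) for p in rng.integers(0, 1_000_000, size=n_tss)))
            links = tm.nearest_tss_link(regions, tss, max_dist=100_000)
            for row in regions.records.itertuples(index=False):
                dists = {}
                for t in tss.itertuples(index=False):
                    if row.start <= t.pos < row.end:
                        d = 0
                    elif t.pos < row.start:
                        d = row.start - t.pos
                    else:
                        d = t.pos - (row.end - 1)
                    dists[t.gene_id] = d
                best_gene = min(dists, key=dists.get)
                best_d = dists[best_gene]
                if best_d > 100_000:
                    assert row.id not in links
                else:
                    assert dists[links[row.id]] == best_d


class TestPwmThreshold:
    def test_deterministic_dinucleotide_max_score_mass(self):
        pwm = Pwm(matrix=np.array(
            [[1.0, 0.0], [0.0, 1.0], [0.0, 0.0], [0.0, 0.0]]
        ))  # "AC"
        dist = tm.pwm_score_distribution(pwm)
        top = max(dist)
        assert dist[top] == pytest.approx(1 / 16)
        # tail above 1/16 cannot reach 1e-4; p=0.0625 needs a laxer threshold
        t = tm.pwm_threshold(pwm, p_threshold=0.0625)
        assert t == top

    def test_threshold_with_p_one_admits_everything(self):
        rng = np.random.default_rng(1)
        m = rng.dirichlet(np.ones(4), size=5).T
        pwm = Pwm(matrix=m)
        t = tm.pwm_threshold(pwm, p_threshold=1.0)
        assert t == min(tm.pwm_score_distribution(pwm))

    @pytest.mark.parametrize("length", range(1, 9))
    def test_dp_distribution_equals_exhaustive_enumeration(self, length):
        rng = np.random.default_rng(length)
        m = rng.dirichlet(np.full(4, 0.5), size=length).T
        bg = rng.dirichlet(np.full(4, 5.0))
        pwm = Pwm(matrix=m, background=bg)
        dp = tm.pwm_score_distribution(pwm)
        brute = enumerate_score_distribution(pwm)
        assert set(dp) == set(brute)
        for s in dp:
            assert dp[s] == pytest.approx(brute[s], abs=1e-12)

    def test_degenerate_zero_probability_handled_by_pseudocount(self):
        pwm = Pwm(matrix=np.array([[1.0], [0.0], [0.0], [0.0]]))
        scores = pwm.log_odds()
        assert np.isfinite(scores).all()
        # zero-prob base keeps a large negative but finite score
        assert scores[1, 0] < np.log2(PSEUDOCOUNT) / 1e-3 * 0.5


class TestMotifScanning:
    def cg_pwm(self):
        m = np.full((4, 8), 0.02)
        for j, b in enumerate("CGCGCGCG"):
            m["ACGT".index(b), j] = 0.94
        return Pwm(matrix=m, id="cg8")

    def test_zero_matches_on_hostile_sequence(self):
        regions = regionset([(0, 40)])
        density = tm.motif_density(regions, {"r0": "A" * 40}, [self.cg_pwm()])
        assert density["r0"] == 0.0

    def test_match_count_to_density_arithmetic(self):
        pwm = self.cg_pwm()
        t = tm.pwm_threshold(pwm, 1e-4)
        seq = ("CGCGCGCG" + "TTTTTTTT") * 3 + "AA"  # 50 bp
        regions = regionset([(0, 50)])
        matches = tm.scan_sequence(seq, pwm, t)
        density = tm.motif_density(regions, {"r0": seq}, [pwm])
        assert density["r0"] == pytest.approx(matches / 0.05)

    def test_palindromic_pwm_counts_are_strand_symmetric(self):
        m = np.full((4, 6), 0.02)
        for j, b in enumerate("ACGCGT"):  # reverse complement of itself
            m["ACGT".index(b), j] = 0.94
        pwm = Pwm(matrix=m)
        t = tm.pwm_threshold(pwm, 0.01)
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        fwd = tm.scan_sequence(seq, pwm, t)
        assert fwd % 2 == 0  # every hit has its mirror on the other strand

    def test_window_containing_n_skipped(self):
        pwm = self.cg_pwm()
        assert tm.scan_sequence("CGCGNCGC", pwm, tm.pwm_threshold(pwm, 1.0)) == 0

    def test_random_sequence_match_rate_matches_background_expectation(self):
        pwm = self.cg_pwm()
        p = 1e-3
        t = tm.pwm_threshold(pwm, p)
        dist = tm.pwm_score_distribution(pwm)
        exact_p = sum(v for s, v in dist.items() if s >= t)
        rng = np.random.default_rng(4)
        n_regions, L = 200, 500
        positions = (L - pwm.length + 1) * 2
        hits = sum(
            tm.scan_sequence("".join(rng.choice(list("ACGT"), size=L)), pwm, t)
            for _ in range(n_regions)
        )
        mean = n_regions * positions * exact_p
        sd = np.sqrt(n_regions * positions * exact_p * (1 - exact_p))
        assert abs(hits - mean) <= 4 * sd

    def test_sequence_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tm.motif_density(regionset([(0, 100)]), {"r0": "ACGT"}, [self.cg_pwm()])


class TestEntropy:
    def test_single_symbol_zero_bits(self):
        assert tm.sequence_entropy("AAAA") == 0.0

    def test_uniform_four_symbols_two_bits(self):
        assert tm.sequence_entropy("ACGT") == 2.0

    def test_two_symbol_half_half_one_bit(self):
        assert tm.sequence_entropy("AACC") == pytest.approx(1.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=300, p=[0.4, 0.3, 0.2, 0.1]))
        shuffled = "".join(rng.permutation(list(seq)))
        assert tm.sequence_entropy(seq) == pytest.approx(tm.sequence_entropy(shuffled))

    def test_n_bases_excluded(self):
        assert tm.sequence_entropy("AANNCC") == pytest.approx(1.0)

    def test_all_n_undefined(self):
        with pytest.raises(UndefinedInputError):
            tm.sequence_entropy("NNNN")


class TestConservation:
    def track(self, rows):
        return tm.ScoreTrack(
            intervals=pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        )

    def test_constant_track_returns_constant_mean(self):
        track = self.track([("chr1", 0, 1000, 0.7)])
        out = tm.mean_conservation(regionset([(100, 350)]), track)
        assert out.loc["r0", "mean"] == pytest.approx(0.7)

    def test_half_and_half_averages(self):
        track = self.track([("chr1", 0, 50, 1.0), ("chr1", 50, 100, 0.0)])
        out = tm.mean_conservation(regionset([(0, 100)]), track)
        assert out.loc["r0", "mean"] == pytest.approx(0.5)

    def test_mixed_interval_lengths_match_per_base_expansion(self):
        rng = np.random.default_rng(6)
        edges = np.unique(rng.integers(0, 500, size=30))
        rows = [
            ("chr1", int(a), int(b), float(rng.normal()))
            for a, b in zip(edges[:-1], edges[1:])
        ]
        track = self.track(rows)
        region = (int(edges[2]) + 3, int(edges[-2]) - 3)
        per_base = np.full(600, np.nan)
        for _, a, b, v in rows:
            per_base[a:b] = v
        expected = np.nanmean(per_base[region[0]: region[1]])
        out = tm.mean_conservation(regionset([region]), track)
        assert out.loc["r0", "mean"] == pytest.approx(expected, abs=1e-12)

    def test_split_region_length_weighted_average_is_invariant(self):
        track = self.track([("chr1", 0, 1000, 0.3), ("chr1", 1000, 2000, 0.9)])
        whole = tm.mean_conservation(regionset([(500, 1700)]), track)
        parts = tm.mean_conservation(regionset([(500, 1000), (1000, 1700)]), track)
        lengths = np.array([500, 700])
        recombined = np.average(parts["mean"].to_numpy(float), weights=lengths)
        assert whole.loc["r0", "mean"] == pytest.approx(recombined)

    def test_uncovered_region_flagged_missing(self):
        track = self.track([("chr1", 0, 100, 1.0)])
        out = tm.mean_conservation(regionset([(5000, 5100)]), track)
        assert np.isnan(out.loc["r0", "mean"]) and out.loc["r0", "flagged"]


class TestSummarizeModules:
    def metrics(self, rows):
        return pd.DataFrame(rows, index=[f"m{i}" for i in range(len(rows))])

    def test_extreme_module_hits_all_ones(self):
        m = self.metrics([{"a": 1.0, "b": 10.0}, {"a": 0.0, "b": 2.0}, {"a": 0.5, "b": 5.0}])
        out = tm.summarize_modules(m)
        assert (out.loc["m0"] == 1.0).all()

    def test_two_modules_map_to_zero_one(self):
        out = tm.summarize_modules(self.metrics([{"a": 3.0}, {"a": 7.0}]))
        assert sorted(out["a"]) == [0.0, 1.0]

    def test_three_point_normalization_arithmetic(self):
        out = tm.summarize_modules(self.metrics([{"a": 1.0}, {"a": 2.0}, {"a": 3.0}]))
        assert list(out["a"]) == [0.0, 0.5, 1.0]

    def test_constant_metric_flagged_at_half(self):
        out = tm.summarize_modules(self.metrics([{"a": 2.0, "b": 1.0}, {"a": 2.0, "b": 3.0}]))
        assert (out["a"] == 0.5).all()
        assert out.attrs["constant_metrics"] == ["a"]

    def test_single_module_rejected(self):
        with pytest.raises(ValueError):
            tm.summarize_modules(self.metrics([{"a": 1.0}]))
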