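"""Promoter windows, one-vs-rest DEG calling, hypergeometric enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from pathphen import (call_deg_one_vs_rest, classify_promoter_peaks,
                      deg_target_overlap, hypergeom_enrichment,
                      promoter_target_genes, promoter_window, read_bed_peaks,
                      read_tss_table)
from pathphen.regulatory import collapse_tss


def tss_frame(records):
    return pd.DataFrame(records, columns=["gene", "chrom", "tss_position", "strand"])


def peak_frame(summits, chrom="chr1"):
    return pd.DataFrame({
        "chrom": chrom, "start": [s - 50 for s in summits],
        "end": [s + 50 for s in summits], "summit": summits,
    })


class TestPromoterWindow:
    def test_plus_strand_window(self):
        assert promoter_window(10000, "+") == (7500, 10100)

    def test_minus_strand_window(self):
        assert promoter_window(10000, "-") == (9900, 12500)

    @pytest.mark.parametrize("summit,expected", [
        (9999, True),    # inside, upstream of TSS
        (7500, True),    # exactly at -2500
        (7499, False),   # one bp beyond the upstream edge
        (10100, True),   # exactly at +100
        (10101, False),  # one bp past the downstream edge
    ])
    def test_plus_strand_boundaries(self, summit, expected):
        tss = tss_frame([("GENE1", "chr1", 10000, "+")])
        out = classify_promoter_peaks(peak_frame([summit]), tss)
        assert bool(out["is_promoter"].iloc[0]) is expected
        assert out["gene"].iloc[0] == "GENE1"

    @pytest.mark.parametrize("summit,expected", [
        (10200, True),   # downstream in genome = upstream in transcription
        (12500, True),   # exactly at the far edge
        (12501, False),
        (9900, True),    # exactly at -100 relative to transcription
        (9899, False),
    ])
    def test_minus_strand_boundaries(self, summit, expected):
        tss = tss_frame([("GENE1", "chr1", 10000, "-")])
        out = classify_promoter_peaks(peak_frame([summit]), tss)
        assert bool(out["is_promoter"].iloc[0]) is expected

    def test_nearest_tss_assignment_with_name_tie_break(self):
        tss = tss_frame([("BBB", "chr1", 9000, "+"), ("AAA", "chr1", 11000, "+")])
        out = classify_promoter_peaks(peak_frame([10000]), tss)
        assert out["gene"].iloc[0] == "AAA"  # equidistant: lexicographic winner
        out2 = classify_promoter_peaks(peak_frame([9400]), tss)
        assert out2["gene"].iloc[0] == "BBB"

    def test_unknown_chromosome_skipped_with_warning(self):
        tss = tss_frame([("G", "chr1", 1000, "+")])
        peaks = peak_frame([1000], chrom="chrUn")
        with pytest.warns(UserWarning):
            out = classify_promoter_peaks(peaks, tss)
        assert out["gene"].isna().all()

    def test_mirror_symmetry_of_strand_flip(self):
        """Mirroring coordinates and flipping strand preserves calls."""
        C = 1_000_000
        tss_pos = 10000
        summits = [7499, 7500, 9000, 10100, 10101]
        fwd = classify_promoter_peaks(
            peak_frame(summits), tss_frame([("G", "chr1", tss_pos, "+")]))
        mirrored = [C - s for s in summits]
        rev = classify_promoter_peaks(
            peak_frame(mirrored), tss_frame([("G", "chr1", C - tss_pos, "-")]))
        assert list(fwd["is_promoter"]) == list(rev["is_promoter"])


class TestReaders:
    def test_narrowpeak_summit_offset_converted_to_one_based(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t300\tpk1\t60\t.\t5.2\t3.1\t2.0\t50\n")
        peaks = read_bed_peaks(path)
        assert peaks["summit"].iloc[0] == 151
        assert peaks["q_value"].iloc[0] == pytest.approx(0.01)

    def test_plain_bed_summit_defaults_to_midpoint(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t100\t200\n")
        assert read_bed_peaks(path)["summit"].iloc[0] == 151

    def test_invalid_interval_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t200\t100\n")
        with pytest.raises(ValueError):
            read_bed_peaks(path)

    def test_tss_collapse_to_most_upstream(self, tmp_path):
        df = tss_frame([("G1", "chr1", 500, "+"), ("G1", "chr1", 300, "+"),
                        ("G2", "chr1", 900, "-"), ("G2", "chr1", 700, "-")])
        out = collapse_tss(df).set_index("gene")
        assert out.loc["G1", "tss_position"] == 300   # + strand: smallest
        assert out.loc["G2", "tss_position"] == 900   # - strand: largest
        path = tmp_path / "tss.tsv"
        df.to_csv(path, sep="\t", index=False)
        assert len(read_tss_table(path)) == 2


class TestDeg:
    def toy_matrix(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i:02d}" for i in range(20)]
        samples = [f"s{i}" for i in range(10)]
        base = rng.uniform(4, 6, 20)
        X = pd.DataFrame(np.tile(base[:, None], (1, 10)), index=genes,
                         columns=samples)
        X += rng.normal(0, 0.01, X.shape)
        return X

    def test_single_large_shift_is_sole_deg(self):
        X = self.toy_matrix()
        X.loc["g07", "s0"] += 10.0
        res = call_deg_one_vs_rest(X, "s0", already_log=True)
        assert res.loc["g07", "is_deg"]
        assert res["is_deg"].sum() == 1
        assert res.loc["g07", "direction"] == "up"

    def test_near_identical_focus_calls_nothing(self):
        X = self.toy_matrix()
        res = call_deg_one_vs_rest(X, "s3", already_log=True)
        assert res["is_deg"].sum() == 0

    def test_zero_delta_variance_rejected(self):
        X = pd.DataFrame(np.ones((5, 5)), index=list("abcde"),
                         columns=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError):
            call_deg_one_vs_rest(X, "s0", already_log=True)

    def test_needs_three_rest_samples(self):
        X = pd.DataFrame(np.ones((5, 3)), columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            call_deg_one_vs_rest(X, "a")

    def test_null_nominal_flag_rate_near_alpha(self):
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(5, 1, (1000, 13)),
                             index=[f"g{i}" for i in range(1000)],
                             columns=[f"s{i}" for i in range(13)])
            res = call_deg_one_vs_rest(X, "s0", already_log=True)
            fractions.append((res["p"] < 0.05).mean())
            assert res["is_deg"].mean() <= (res["p"] < 0.05).mean()
        pooled = np.mean(fractions)
        sd = np.sqrt(0.05 * 0.95 / (20 * 1000))
        assert abs(pooled - 0.05) < 4 * sd


class TestHypergeom:
    def test_complete_overlap_exact_probability(self):
        universe = [f"g{i}" for i in range(10)]
        target = universe[:5]
        k, p = hypergeom_enrichment(target, target, universe)
        assert k == 5
        assert p == pytest.approx(1 / comb(10, 5), rel=1e-12)

    def test_zero_overlap_probability_one(self):
        universe = [f"g{i}" for i in range(10)]
        k, p = hypergeom_enrichment(universe[:5], universe[5:], universe)
        assert (k, p) == (0, 1.0)

    def test_matches_exhaustive_enumeration(self):
        universe = list(range(10))
        pathway = set(universe[:5])
        observed_target = set(universe[2:7])
        k_obs, p = hypergeom_enrichment(observed_target, pathway, universe)
        count = sum(1 for draw in itertools.combinations(universe, 5)
                    if len(set(draw) & pathway) >= k_obs)
        assert p == pytest.approx(count / comb(10, 5), rel=1e-12)

    def test_monotone_decreasing_in_overlap(self):
        universe = [f"g{i}" for i in range(30)]
        pathway = universe[:10]
        ps = []
        for k in range(1, 8):
            target = universe[:k] + universe[10:10 + (8 - k)]
            ps.append(hypergeom_enrichment(target, pathway, universe)[1])
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(["a"], ["a"], [])


class TestOverlap:
    def test_set_arithmetic_example(self):
        out = deg_target_overlap({"a", "b", "c"}, {"b", "c", "d"})
        assert (out["n_deg"], out["n_deg_and_bound"]) == (3, 2)
        assert out["fraction_bound"] == pytest.approx(2 / 3)

    def test_disjoint_and_subset_fractions(self):
        assert deg_target_overlap({"a"}, {"b"})["fraction_bound"] == 0.0
        assert deg_target_overlap({"a", "b"}, {"a", "b", "c"})["fraction_bound"] == 1.0

    def test_direction_split_from_deg_frame(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(5, 0.01, (30, 8)),
                         index=[f"g{i:02d}" for i in range(30)],
                         columns=[f"s{i}" for i in range(8)])
        X.loc["g01", "s0"] += 5.0
        X.loc["g02", "s0"] -= 5.0
        res = call_deg_one_vs_rest(X, "s0", already_log=True)
        out = deg_target_overlap(res, {"G01", "g02", "g09"})
        assert out["n_up"] == 1 and out["n_down"] == 1
        assert out["n_deg_and_bound"] == 1  # case-sensitive names: only g02

    def test_promoter_targets_helper(self):
        tss = tss_frame([("G1", "chr1", 10000, "+"), ("G2", "chr1", 50000, "+")])
        peaks = peak_frame([9999, 30000])
        out = classify_promoter_peaks(peaks, tss)
        assert promoter_target_genes(out) == {"G1"}
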