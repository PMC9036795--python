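"""Match filtering, weighted identity, coverage, assignment, assembly metrics."""

import numpy as np
import pandas as pd
import pytest

from komaflux.genome import (MATCH_COLUMNS, assembly_metrics, assign_contigs,
                             coverage_fraction, filter_matches, merge_intervals,
                             weighted_identity)
from komaflux.io import load_published_assembly_metrics
from komaflux.synth import gen_genome_pair


def make_table(rows):
    return pd.DataFrame(rows, columns=MATCH_COLUMNS)


def match(tstart, tend, identity=0.9, mapq=60, query="ctg1", target="chr1",
          strand="+"):
    return (query, 0, tend - tstart, target, tstart, tend, strand, identity, mapq)


class TestFilterMatches:
    def test_both_predicates_applied(self):
        table = make_table([
            match(0, 500, mapq=60),
            match(0, 1200, mapq=0),
            match(0, 15000, mapq=60),
        ])
        kept = filter_matches(table, min_len=1000, min_mapq=1)
        assert len(kept) == 1
        assert kept.iloc[0]["target_end"] == 15000

    def test_no_thresholds_is_identity(self):
        table = make_table([match(0, 500), match(0, 1200)])
        assert len(filter_matches(table, 0, 0)) == 2

    def test_display_filter_10kbp(self):
        table = make_table([
            match(0, 500, mapq=60),
            match(0, 1200, mapq=0),
            match(0, 15000, mapq=60),
        ])
        kept = filter_matches(table, min_len=10000, min_mapq=1)
        assert len(kept) == 1

    def test_idempotent(self):
        table = make_table([match(0, 500), match(0, 1200), match(0, 15000)])
        once = filter_matches(table, 1000, 1)
        twice = filter_matches(once, 1000, 1)
        pd.testing.assert_frame_equal(once, twice)


class TestWeightedIdentity:
    @pytest.mark.parametrize("spans,expected", [
        ([(0.90, 1000)], 90.0),
        ([(0.80, 1000), (1.00, 3000)], 95.0),
        ([(0.90, 500), (0.95, 1500), (0.99, 2000)], 96.375),
    ])
    def test_hand_computed_weighted_means(self, spans, expected):
        rows, pos = [], 0
        for ident, length in spans:
            rows.append(match(pos, pos + length, identity=ident))
            pos += length
        out = weighted_identity(make_table(rows))
        assert out.iloc[0]["pct_id"] == pytest.approx(expected)
        assert out.iloc[0]["n_matches"] == len(spans)

    def test_matches_per_base_oracle_on_tiled_matches(self, rng):
        """On non-overlapping tiles the weighted mean must equal the exact
        per-base identity average (brute-force oracle)."""
        n_tiles = 20
        lengths = rng.integers(500, 3000, n_tiles)
        idents = rng.uniform(0.7, 1.0, n_tiles)
        rows, pos = [], 0
        base_sum = 0.0
        for length, ident in zip(lengths, idents):
            rows.append(match(pos, pos + int(length), identity=float(ident)))
            base_sum += ident * length  # identical bases contributed by tile
            pos += int(length)
        oracle = 100.0 * base_sum / lengths.sum()
        out = weighted_identity(make_table(rows))
        assert out.iloc[0]["pct_id"] == pytest.approx(oracle, abs=1e-9)


class TestCoverage:
    def test_overlapping_spans_merged(self):
        table = make_table([match(0, 4000), match(3000, 5000)])
        cov = coverage_fraction(table, {"chr1": 10000})
        assert cov["chr1"] == pytest.approx(50.0)

    def test_full_and_empty(self):
        table = make_table([match(0, 10000)])
        cov = coverage_fraction(table, {"chr1": 10000, "chr2": 5000})
        assert cov["chr1"] == pytest.approx(100.0)
        assert cov["chr2"] == 0.0

    def test_invariant_under_match_splitting(self):
        whole = make_table([match(100, 9000)])
        split = make_table([match(100, 4000), match(4000, 9000)])
        cov_a = coverage_fraction(whole, {"chr1": 10000})
        cov_b = coverage_fraction(split, {"chr1": 10000})
        assert cov_a["chr1"] == pytest.approx(cov_b["chr1"])

    def test_match_beyond_chromosome_errors(self):
        table = make_table([match(0, 20000)])
        with pytest.raises(ValueError, match="beyond"):
            coverage_fraction(table, {"chr1": 10000})

    def test_merge_intervals_handles_adjacency(self):
        merged = merge_intervals(np.array([[0, 10], [10, 20], [30, 40]]))
        assert merged.tolist() == [[0, 20], [30, 40]]


class TestAssignContigs:
    def test_majority_chromosome_and_reverse_orientation(self):
        table = make_table([
            match(0, 8000, query="ctgA", target="chr2", strand="-"),
            match(0, 2000, query="ctgA", target="chr1", strand="+"),
        ])
        out = assign_contigs(table)
        row = out.iloc[0]
        assert row["chromosome"] == "chr2"
        assert row["orientation"] == "reverse"
        assert row["support_fraction"] == pytest.approx(0.8)
        assert not row["ambiguous"]

    def test_single_forward_match_full_support(self):
        out = assign_contigs(make_table([match(0, 5000, query="c", target="chr3")]))
        assert out.iloc[0]["orientation"] == "forward"
        assert out.iloc[0]["support_fraction"] == 1.0

    def test_below_half_support_flagged_ambiguous(self):
        table = make_table([
            match(0, 3000, query="c", target="chr1"),
            match(0, 3000, query="c", target="chr2"),
            match(0, 3000, query="c", target="chr3"),
        ])
        out = assign_contigs(table)
        assert out.iloc[0]["ambiguous"]

    def test_order_follows_median_reference_position(self):
        table = make_table([
            match(50000, 60000, query="late", target="chr1"),
            match(0, 10000, query="early", target="chr1"),
        ])
        out = assign_contigs(table).set_index("contig")
        assert out.loc["early", "order_index"] == 0
        assert out.loc["late", "order_index"] == 1

    def test_recovers_generator_truth_with_one_inversion(self):
        bundle = gen_genome_pair(seed=11, snp_rate=0.05, n_rearrangements=1)
        out = assign_contigs(bundle.match_table).set_index("contig")
        truth = bundle.truth.set_index("contig")
        for contig in truth.index:
            assert out.loc[contig, "chromosome"] == truth.loc[contig, "chromosome"]
            expected = ("reverse" if truth.loc[contig, "strand"] == "-"
                        else "forward")
            assert out.loc[contig, "orientation"] == expected
        assert (out["orientation"] == "reverse").sum() == 1


class TestAssemblyMetrics:
    def test_worked_example(self):
        m = assembly_metrics([5, 4, 3, 2, 1])
        assert (m.n50, m.n50_number, m.longest, m.sum_top4) == (4, 2, 5, 14)

    def test_single_contig(self):
        m = assembly_metrics([100])
        assert (m.n50, m.n50_number) == (100, 1)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            assembly_metrics([])

    def test_published_n50_mean_of_new_assemblies(self):
        df = load_published_assembly_metrics()
        mean = df.loc[df["newly_assembled"] == 1, "n50_mbp"].mean()
        assert round(mean, 2) == 2.34
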