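"""Alignment filtering, genome/gene coverage, strain calls and the Fisher
enrichment test (checked against exhaustive 2×2 enumeration)."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from gutflux.strain_profiling import (
    AlignmentRecord,
    aggregate_prevalence,
    call_strains,
    enrichment_log_pvalue,
    enrichment_test,
    filter_alignments,
    gene_coverage_from_scaffolds,
    genome_coverage,
    profile_sample,
    read_blast_tab,
    read_sam,
)


def _rec(qid="q1", sid="g", ident=99.5, length=100, start=1, end=100):
    return AlignmentRecord(query_id=qid, subject_id=sid, identity=ident,
                           length=length, subject_start=start, subject_end=end)


class TestFilterAlignments:
    def test_identity_cutoff_is_inclusive(self):
        recs = [_rec(qid="lo", ident=98.0), _rec(qid="edge", ident=99.0),
                _rec(qid="hi", ident=99.5)]
        kept = filter_alignments(recs, min_identity=99.0, unique_only=False)
        assert [r.query_id for r in kept] == ["edge", "hi"]

    def test_multimappers_dropped_not_rescued(self):
        recs = [_rec(qid="multi", ident=99.5, start=1, end=100),
                _rec(qid="multi", ident=99.5, start=500, end=599),
                _rec(qid="solo", ident=99.5)]
        kept = filter_alignments(recs, min_identity=99.0, unique_only=True)
        assert [r.query_id for r in kept] == ["solo"]

    def test_uniqueness_counted_after_identity_filter(self):
        # the second hit fails identity, so the query becomes unique
        recs = [_rec(qid="q", ident=99.5), _rec(qid="q", ident=95.0, start=300, end=399)]
        kept = filter_alignments(recs, min_identity=99.0, unique_only=True)
        assert len(kept) == 1


class TestGenomeCoverage:
    def test_tiling_gives_depth_and_full_breadth(self):
        recs = [_rec(qid=f"q{i}", start=1 + 100 * i, end=100 * (i + 1))
                for i in range(10)]
        depth, breadth = genome_coverage(recs, genome_length=1000)
        assert depth == pytest.approx(1.0)
        assert breadth == pytest.approx(1.0)

    def test_single_alignment_fractions(self):
        depth, breadth = genome_coverage([_rec()], genome_length=1000)
        assert depth == pytest.approx(0.1)
        assert breadth == pytest.approx(0.1)

    def test_overlap_counts_once_for_breadth_twice_for_depth(self):
        recs = [_rec(qid="a"), _rec(qid="b")]  # same 100 bp twice
        depth, breadth = genome_coverage(recs, genome_length=1000)
        assert depth == pytest.approx(0.2)
        assert breadth == pytest.approx(0.1)

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError, match="outside genome"):
            genome_coverage([_rec(start=950, end=1049)], genome_length=1000)

    @given(st.lists(st.tuples(st.integers(1, 900), st.integers(1, 100)),
                    min_size=1, max_size=30))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_breadth_never_exceeds_depth_or_one(self, spans):
        recs = [_rec(qid=f"q{i}", start=s, end=s + ln - 1)
                for i, (s, ln) in enumerate(spans)]
        depth, breadth = genome_coverage(recs, genome_length=1000)
        assert breadth <= depth + 1e-12
        assert 0.0 <= breadth <= 1.0


class TestCallStrains:
    def test_depth_threshold_boundary_inclusive(self):
        calls = call_strains({"a": (10.0, 0.9), "b": (9.99, 0.9)},
                             depth_threshold=10.0)
        verdicts = {c.strain_id: c.present for c in calls}
        assert verdicts == {"a": True, "b": False}

    def test_prevalence_aggregation_sorted_descending(self):
        per_sample = []
        for i in range(10):
            per_sample.append(call_strains({
                "always": (12.0, 1.0),
                "often": (12.0 if i < 8 else 1.0, 1.0),
                "sometimes": (12.0 if i < 6 else 1.0, 1.0),
            }))
        df = aggregate_prevalence(per_sample)
        assert list(df["strain"]) == ["always", "often", "sometimes"]
        assert list(df["prevalence"]) == [1.0, 0.8, 0.6]


class TestGeneCoverage:
    GENES = [("g1", 100, 199)]  # 100 bp

    def test_exact_80_percent_boundary_is_covered(self):
        recs = [_rec(qid="scafA", start=100, end=179)]  # 80 bp of 100
        (cov,) = gene_coverage_from_scaffolds(recs, self.GENES)
        assert cov.best_fraction == pytest.approx(0.8)
        assert cov.covered

    def test_two_half_scaffolds_do_not_combine(self):
        recs = [_rec(qid="scafA", start=100, end=149),
                _rec(qid="scafB", start=150, end=199)]
        (cov,) = gene_coverage_from_scaffolds(recs, self.GENES)
        assert cov.best_fraction == pytest.approx(0.5)
        assert not cov.covered

    def test_spanning_scaffold_gives_full_coverage(self):
        recs = [_rec(qid="scafA", start=50, end=300, length=251)]
        (cov,) = gene_coverage_from_scaffolds(recs, self.GENES)
        assert cov.best_fraction == pytest.approx(1.0)

    def test_zero_length_gene_rejected(self):
        with pytest.raises(ValueError, match="length"):
            gene_coverage_from_scaffolds([_rec()], [("bad", 200, 199)])


class TestEnrichment:
    def test_known_tail_values(self):
        # P(X ≥ 8) for a balanced 20-item universe, 10 drawn, 10 marked
        assert enrichment_test(8, 10, 10, 20) == pytest.approx(2126 / 184756, rel=1e-12)
        # single-term tail: all 10 drawn are the 10 marked
        assert enrichment_test(10, 10, 10, 20) == pytest.approx(1 / 184756, rel=1e-12)

    def test_no_enrichment_gives_large_p(self):
        # equal proportions: observing the expected count is not surprising
        assert enrichment_test(5, 10, 10, 20) >= 0.5

    def test_matches_exhaustive_enumeration_small_margins(self):
        """Oracle: exact rational tail sums via math.comb for every
        consistent 2×2 table with universe ≤ 12."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    k_lo, k_hi = max(0, n + K - N), min(n, K)
                    for k in range(k_lo, k_hi + 1):
                        exact = sum(
                            math.comb(K, i) * math.comb(N - K, n - i)
                            for i in range(k, k_hi + 1)
                        ) / math.comb(N, n)
                        ours = enrichment_test(k, n, K, N)
                        assert ours == pytest.approx(exact, rel=1e-9), (k, n, K, N)

    def test_log_space_survives_tiny_p(self):
        # far below float underflow for the plain tail product
        logp = enrichment_log_pvalue(900, 1000, 1000, 100000)
        assert math.isfinite(logp)
        assert logp < -1000.0

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            enrichment_test(11, 10, 10, 20)


class TestParsers:
    def test_blast_tab_round_trip(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("r1\tgenome\t99.50\t100\t0\t0\t1\t100\t201\t300\t1e-30\t180\n"
                     "r2\tgenome\t98.00\t90\t2\t0\t1\t90\t1000\t909\t1e-20\t150\n")
        recs = read_blast_tab(p)
        assert len(recs) == 2
        assert recs[0].subject_start == 201 and recs[0].subject_end == 300
        # reverse-strand hit normalised so start <= end
        assert recs[1].subject_start == 909 and recs[1].subject_end == 1000

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("r1\tgenome\t99.5\n")
        with pytest.raises(ValueError, match="bad.tsv:1"):
            read_blast_tab(p)

    def test_sam_parsing_with_nm_identity(self, tmp_path):
        p = tmp_path / "aln.sam"
        p.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:genome\tLN:1000\n"
            "r1\t0\tgenome\t101\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\tNM:i:1\n"
            "r2\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\t*\n"
        )
        recs = read_sam(p)
        assert len(recs) == 1  # unmapped read skipped
        assert recs[0].subject_start == 101
        assert recs[0].identity == pytest.approx(99.0)


class TestEndToEnd:
    def test_profile_sample_filters_then_calls(self):
        recs = (  # 100 reads tiling a 1 kb genome ten times over: depth 10
            [_rec(qid=f"good{i}", sid="strainA", ident=99.5,
                  start=1 + 100 * (i % 10), end=100 * (i % 10 + 1))
             for i in range(100)]
            + [_rec(qid=f"low{i}", sid="strainB", ident=95.0,
                    start=1 + 100 * (i % 10), end=100 * (i % 10 + 1))
               for i in range(100)]
        )
        calls = profile_sample(recs, {"strainA": 1000, "strainB": 1000},
                               min_identity=99.0, depth_threshold=10.0)
        verdicts = {c.strain_id: c.present for c in calls}
        assert verdicts == {"strainA": True, "strainB": False}
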