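import random

import pytest

from spliceortho import (
    MatchType,
    OrthologPair,
    ScoringScheme,
    Source,
    TranscriptModel,
    GeneIndex,
    align_structures,
    best_match,
    classify_cohort,
    classify_colinear,
    enumerate_alignments,
)

from conftest import make_structure

DEFAULTS = ScoringScheme()


class TestClassifyColinear:
    @pytest.mark.parametrize(
        "lengths_a,lengths_b,expected",
        [
            ([50, 150, 100, 50], [50, 150, 100, 50], MatchType.ISO1),
            ([50, 150, 100, 50], [50, 150, 100, 53], MatchType.ISO2),
            ([50, 150, 100, 53], [50, 141, 100, 65], MatchType.ISO2),
            ([50, 150, 100, 50], [50, 150, 100, 51], MatchType.ISO3),
            ([50, 150, 100, 50], [50, 150, 100, 68], MatchType.ISO3),
            ([50, 150, 100, 50], [50, 159, 100, 50], MatchType.ISO2),
            ([50, 150, 100, 50], [50, 171, 100, 50], MatchType.ISO3),
            ([50, 150, 100, 50], [51, 150, 100, 50], MatchType.NONE),
            ([50, 150, 100, 50], [50, 150, 100], MatchType.NONE),
        ],
    )
    def test_three_criteria(self, lengths_a, lengths_b, expected):
        a = make_structure(lengths_a, accession="A")
        b = make_structure(lengths_b, accession="B")
        assert classify_colinear(a, b) is expected

    def test_symmetry(self):
        rng = random.Random(31)
        for _ in range(300):
            n = rng.randint(2, 6)
            la = [rng.randint(30, 120) for _ in range(n)]
            lb = [l + rng.choice((0, 0, 3, -3, 6, 1, 20)) for l in la]
            a = make_structure(la, accession="A")
            b = make_structure(lb, accession="B")
            assert classify_colinear(a, b) is classify_colinear(b, a)

    def test_stringency_order(self):
        assert MatchType.ISO1 > MatchType.ISO2 > MatchType.ISO3 > MatchType.NONE


class TestBestMatch:
    def test_identical_candidate_wins_as_iso1(self):
        query = make_structure([60, 90, 120, 75], accession="Q")
        cands = [
            make_structure([60, 90, 120, 75], accession="C1", gene="GB"),
            make_structure([200, 90, 120, 75], accession="C2", gene="GB"),
            make_structure([60, 90], accession="C3", gene="GB"),
        ]
        rec = best_match(query, cands, DEFAULTS)
        assert rec.best_accession == "C1"
        assert rec.match_type is MatchType.ISO1
        assert rec.score == pytest.approx(10.0 * 4 + 2.0 * 3)

    def test_score_tie_prefers_curated_over_predicted(self):
        query = make_structure([60, 90, 120, 75], accession="Q")
        curated = make_structure(
            [60, 90, 120, 75], accession="ZC", gene="GB", source=Source.CURATED
        )
        predicted = make_structure(
            [60, 90, 120, 75], accession="AP", gene="GB", source=Source.PREDICTED
        )
        rec = best_match(query, [predicted, curated], DEFAULTS)
        assert rec.best_accession == "ZC"
        assert rec.match_source is Source.CURATED

    def test_merge_winning_alignment_voids_colinear_type(self):
        # equal exon counts, but the best alignment uses merge moves (intron
        # gain/loss), so the pair must not be typed by the colinear criteria
        query = make_structure([100, 60, 90, 300], accession="Q")
        cand = make_structure([160, 90, 150, 150], accession="C", gene="GB")
        aln = align_structures(query, cand, DEFAULTS)
        assert not aln.is_colinear
        assert aln.score == pytest.approx(enumerate_alignments(query, cand, DEFAULTS))
        assert classify_colinear(query, cand) is MatchType.ISO3  # would mis-type
        rec = best_match(query, [cand], DEFAULTS)
        assert rec.match_type is MatchType.NONE
        assert rec.best_accession == "C"  # top scorer still reported, flagged NONE

    def test_empty_candidate_list(self):
        query = make_structure([60, 90, 120, 75], accession="Q")
        rec = best_match(query, [], DEFAULTS)
        assert rec.match_type is MatchType.NONE
        assert rec.best_accession is None and rec.score is None


def _transcript(accession, gene, lengths, cds_trim=0, offset=1000, source=Source.CURATED):
    """Lay coding lengths out as a plus-strand transcript with 150 bp introns."""
    exons, pos = [], offset
    for length in lengths:
        exons.append((pos, pos + length))
        pos += length + 150
    return TranscriptModel(
        accession, gene, "chr1", "+", tuple(exons), exons[0][0], exons[-1][1], source
    )


class TestClassifyCohort:
    def test_single_identical_pair(self):
        lengths = [60, 90, 120, 75]
        index_a = GeneIndex([_transcript("A1", "GA", lengths)])
        index_b = GeneIndex([_transcript("B1", "GB", lengths)])
        rab, rba, summary = classify_cohort(
            index_a, index_b, [OrthologPair("GA", "GB")], DEFAULTS
        )
        assert [r.match_type for r in rab] == [MatchType.ISO1]
        assert [r.match_type for r in rba] == [MatchType.ISO1]
        assert summary.gene_pair_counts["ISO1"] == 1
        assert summary.a_to_b.transcript_counts["ISO1"] == 1
        assert summary.b_to_a.transcript_counts["ISO1"] == 1

    def test_unmatched_second_isoform_counts_none(self):
        index_a = GeneIndex(
            [
                _transcript("A1", "GA", [60, 90, 120, 75]),
                _transcript("A2", "GA", [60, 90, 120, 200, 75], offset=50_000),
            ]
        )
        index_b = GeneIndex([_transcript("B1", "GB", [60, 90, 120, 75])])
        rab, _, summary = classify_cohort(
            index_a, index_b, [OrthologPair("GA", "GB")], DEFAULTS
        )
        types = sorted(r.match_type.name for r in rab)
        assert types == ["ISO1", "NONE"]
        assert summary.gene_pair_counts["ISO1"] == 1  # gene best over transcripts
        assert summary.a_to_b.transcript_counts["NONE"] == 1

    def test_absent_gene_is_skipped_not_fatal(self):
        index_a = GeneIndex([_transcript("A1", "GA", [60, 90, 120, 75])])
        index_b = GeneIndex([_transcript("B1", "GB", [60, 90, 120, 75])])
        pairs = [OrthologPair("GA", "GB"), OrthologPair("GHOST", "GB2")]
        _, _, summary = classify_cohort(index_a, index_b, pairs, DEFAULTS)
        assert summary.n_pairs_total == 2
        assert summary.n_pairs_analyzed == 1
        assert summary.n_pairs_skipped == 1

    def test_summary_counts_sum_to_totals(self, cohort42, cohort42_results):
        _, _, _, pairs, _ = cohort42
        rab, rba, summary = cohort42_results["predicted"]
        assert sum(summary.a_to_b.transcript_counts.values()) == len(rab)
        assert sum(summary.b_to_a.transcript_counts.values()) == len(rba)
        assert (
            sum(summary.gene_pair_counts.values()) == summary.n_pairs_analyzed
        )
        assert summary.n_pairs_analyzed + summary.n_pairs_skipped == len(pairs)

    def test_gene_level_is_max_over_transcript_level(self, cohort42_results):
        rab, rba, summary = cohort42_results["predicted"]
        best_by_gene = {}
        for rec in rab:
            best_by_gene[rec.query_gene] = max(
                best_by_gene.get(rec.query_gene, MatchType.NONE), rec.match_type
            )
        expected = {t.name: 0 for t in MatchType}
        for t in best_by_gene.values():
            expected[t.name] += 1
        assert summary.a_to_b.gene_counts == expected
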