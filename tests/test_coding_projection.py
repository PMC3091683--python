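import random

import pytest
from hypothesis import given, settings, strategies as st

from spliceortho import (
    NonCodingTranscriptError,
    Source,
    TranscriptModel,
    dedup_signature,
    dedup_transcripts,
    generate_redundant_set,
    passes_filters,
    project_cds,
)
from spliceortho.coding_projection import compute_phases

from conftest import make_structure

EXONS = ((0, 100), (200, 350), (500, 600), (700, 800))


def exonic_cds_length(t: TranscriptModel) -> int:
    """Independent oracle: interval intersection of exons with the CDS span."""
    return sum(
        max(0, min(e, t.cds_end) - max(s, t.cds_start)) for s, e in t.exons
    )


def mirror_flip(t: TranscriptModel) -> TranscriptModel:
    """Coordinate-mirror the transcript and flip its strand."""
    m = t.tx_end + 137
    return TranscriptModel(
        accession=t.accession,
        gene_id=t.gene_id,
        chrom=t.chrom,
        strand="-" if t.strand == "+" else "+",
        exons=tuple((m - e, m - s) for s, e in reversed(t.exons)),
        cds_start=m - t.cds_end,
        cds_end=m - t.cds_start,
        source=t.source,
    )


class TestProjectCds:
    def test_plus_strand_example(self):
        t = TranscriptModel("X", "G", "chr1", "+", EXONS, 50, 750)
        cs = project_cds(t)
        assert cs.coding_lengths == (50, 150, 100, 50)
        assert cs.phases == (2, 2, 0)
        assert cs.n_internal_fully_coding == 2
        assert cs.total_exon_count == 4

    def test_minus_strand_reverses_transcript_order(self):
        t = TranscriptModel("X", "G", "chr1", "-", EXONS, 50, 750)
        cs = project_cds(t)
        assert cs.coding_lengths == (50, 100, 150, 50)
        # phases recomputed from the reversed cumulative sums: 50, 150, 300
        assert cs.phases == (2, 0, 0)

    def test_utr_only_exons_dropped(self):
        t = TranscriptModel(
            "X", "G", "chr1", "+", ((0, 100),) + tuple((s + 200, e + 200) for s, e in EXONS), 250, 950
        )
        cs = project_cds(t)
        assert cs.coding_lengths == (50, 150, 100, 50)
        assert cs.total_exon_count == 5

    def test_non_coding_transcript_raises(self):
        t = TranscriptModel("X", "G", "chr1", "+", ((0, 100),), 0, 0)
        with pytest.raises(NonCodingTranscriptError):
            project_cds(t)

    def test_single_coding_exon(self):
        t = TranscriptModel("X", "G", "chr1", "+", ((0, 100), (200, 300)), 210, 260)
        cs = project_cds(t)
        assert cs.coding_lengths == (50,)
        assert cs.phases == ()

    @given(
        lengths=st.lists(st.integers(30, 300), min_size=1, max_size=8),
        utr5=st.integers(0, 120),
        utr3=st.integers(0, 120),
        minus=st.booleans(),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_length_conservation_and_phase_consistency(self, lengths, utr5, utr3, minus):
        """sum(coding_lengths) equals the exonic CDS length; phases are cumulative."""
        exons, pos = [], 1000
        for i, length in enumerate(lengths):
            glen = length + (utr5 if i == 0 else 0) + (utr3 if i == len(lengths) - 1 else 0)
            exons.append((pos, pos + glen))
            pos += glen + 150
        cds_start = exons[0][0] + utr5
        cds_end = exons[-1][1] - utr3
        t = TranscriptModel(
            "X", "G", "chr1", "-" if minus else "+", tuple(exons), cds_start, cds_end
        )
        cs = project_cds(t)
        assert sum(cs.coding_lengths) == exonic_cds_length(t)
        assert cs.phases == compute_phases(cs.coding_lengths)
        if minus:
            assert cs.coding_lengths == tuple(reversed(lengths))
        else:
            assert cs.coding_lengths == tuple(lengths)

    def test_strand_involution(self):
        t = TranscriptModel("X", "G", "chr1", "+", EXONS, 50, 750)
        assert project_cds(mirror_flip(t)) == project_cds(t)


class TestFilters:
    def test_four_exons_two_internal_passes(self):
        t = TranscriptModel("X", "G", "chr1", "+", EXONS, 50, 750)
        ok, reason = passes_filters(project_cds(t))
        assert ok and reason == "ok"

    def test_three_exon_transcript_fails(self):
        t = TranscriptModel("X", "G", "chr1", "+", EXONS[:3], 50, 550)
        ok, reason = passes_filters(project_cds(t))
        assert not ok
        assert reason == "fewer than four exons"

    def test_cds_covering_three_of_five_exons_fails(self):
        exons = EXONS + ((900, 1000),)
        t = TranscriptModel("X", "G", "chr1", "+", exons, 250, 550)
        cs = project_cds(t)
        assert cs.n_coding_exons == 2  # CDS touches exons 2-3 only
        t2 = TranscriptModel("X2", "G", "chr1", "+", exons, 250, 750)
        cs2 = project_cds(t2)
        assert cs2.n_internal_fully_coding == 1
        ok, reason = passes_filters(cs2)
        assert not ok
        assert reason == "fewer than two internal fully coding exons"

    def test_utr_only_exons_count_toward_four(self):
        # 2 UTR exons + 2 coding exons: four transcript exons but no internal
        # fully coding exon
        exons = ((0, 100), (200, 300), (400, 500), (600, 700))
        t = TranscriptModel("X", "G", "chr1", "+", exons, 400, 680)
        cs = project_cds(t)
        assert cs.total_exon_count == 4
        ok, reason = passes_filters(cs)
        assert not ok and "internal" in reason


class TestDedup:
    def test_redundant_externals_collapse_to_longest(self):
        a = make_structure([50, 150, 100, 50], accession="A1")
        b = make_structure([80, 150, 100, 50], accession="A2")
        assert dedup_signature(a) == dedup_signature(b)
        reps = dedup_transcripts([a, b])
        assert [r.accession for r in reps] == ["A2"]  # greater total coding length

    def test_tie_broken_by_accession(self):
        a = make_structure([50, 150, 100, 50], accession="A2")
        b = make_structure([50, 150, 100, 50], accession="A1")
        assert [r.accession for r in dedup_transcripts([a, b])] == ["A1"]

    def test_different_frames_not_collapsed(self):
        a = make_structure([50, 150, 100, 50], accession="A1")
        b = make_structure([51, 150, 100, 49], accession="A2")
        assert dedup_signature(a) != dedup_signature(b)
        assert len(dedup_transcripts([a, b])) == 2

    def test_idempotent_on_random_sets(self):
        rng = random.Random(11)
        for _ in range(100):
            structures = []
            for i in range(rng.randint(1, 6)):
                base = [rng.randint(30, 200) for _ in range(rng.randint(4, 7))]
                structures.append(make_structure(base, accession=f"S{i}"))
                if rng.random() < 0.5:  # add a redundant variant
                    variant = list(base)
                    variant[0] += rng.randint(1, 50)
                    structures.append(make_structure(variant, accession=f"S{i}v"))
            once = dedup_transcripts(structures)
            assert dedup_transcripts(once) == once


def test_redundant_set_shares_signature_and_collapses():
    base = make_structure([60, 90, 120, 75], accession="BASE")
    models = generate_redundant_set(base, 3, seed=5)
    structures = [project_cds(m) for m in models]
    sigs = {dedup_signature(cs) for cs in structures}
    assert sigs == {dedup_signature(base)}
    assert len(dedup_transcripts(structures)) == 1
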