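"""Iso-orthology classification of best-scoring transcript pairs.

Transcripts of orthologous genes are compared through their coding
exon-intron structures under three criteria in decreasing stringency:

ISO1  same number of coding exons, identical coding lengths, and introns in
      the same phase — identical structure.
ISO2  same exon count and phases, each corresponding exon's length differing
      by 0, 3, 6, 9, 12 or 15 bp (at least one nonzero) — small in-frame
      length drift.
ISO3  same exon count, phases preserved, length differences of any size.
NONE  anything else, including any pair whose best alignment requires a gap
      or a merge (intron gain/loss): such pairs are never typed colinearly,
      which prevents a gained/lost intron from faking a criterion match.

Each query transcript is aligned against every transcript of the partner
gene; only the highest-scoring alignment assigns the match type. Curated
transcripts are both queries and candidates; predicted transcripts are
candidates only, and can only strengthen an assignment, never weaken it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum

from .coding_projection import (
    CodingStructure,
    NonCodingTranscriptError,
    ProjectionError,
    dedup_signature,
    dedup_transcripts,
    passes_filters,
    project_cds,
)
from .gene_models import GeneIndex, OrthologPair, Source
from .structure_align import ScoringScheme, StructureAlignment, align_structures

logger = logging.getLogger(__name__)

#: Allowed per-exon absolute length differences under criterion ISO2.
ISO2_ALLOWED_DELTAS = frozenset({0, 3, 6, 9, 12, 15})


class MatchType(IntEnum):
    """Iso-orthology categories, ordered by stringency (ISO1 strongest)."""

    NONE = 0
    ISO3 = 1
    ISO2 = 2
    ISO1 = 3


@dataclass(frozen=True)
class MatchRecord:
    """A query transcript's best structural counterpart and its category.

    ``match_type`` is NONE when no candidate satisfied any criterion;
    ``best_accession`` may still name the top-scoring non-matching candidate.
    ``score`` is present iff a candidate exists.
    """

    query_accession: str
    query_gene: str
    best_accession: str | None
    best_gene: str | None
    match_type: MatchType
    score: float | None
    match_source: Source | None


@dataclass
class PreparationStats:
    """Funnel counters for one gene index (projection -> filters -> dedup)."""

    n_input: int = 0
    n_non_coding: int = 0
    n_projection_failed: int = 0
    n_filtered: int = 0
    filter_reasons: dict[str, int] = field(default_factory=dict)
    n_redundant_removed: int = 0
    n_kept: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_non_coding": self.n_non_coding,
            "n_projection_failed": self.n_projection_failed,
            "n_filtered": self.n_filtered,
            "filter_reasons": dict(sorted(self.filter_reasons.items())),
            "n_redundant_removed": self.n_redundant_removed,
            "n_kept": self.n_kept,
        }


@dataclass
class DirectionSummary:
    """Per-direction transcript- and gene-level category counts."""

    n_queries: int = 0
    transcript_counts: dict[str, int] = field(
        default_factory=lambda: {t.name: 0 for t in MatchType}
    )
    predicted_match_counts: dict[str, int] = field(
        default_factory=lambda: {t.name: 0 for t in MatchType}
    )
    gene_counts: dict[str, int] = field(
        default_factory=lambda: {t.name: 0 for t in MatchType}
    )

    def to_dict(self) -> dict:
        return {
            "n_queries": self.n_queries,
            "transcript_counts": self.transcript_counts,
            "predicted_match_counts": self.predicted_match_counts,
            "gene_counts": self.gene_counts,
        }


@dataclass
class CohortSummary:
    """Cohort-level report: both directions plus combined gene-pair counts."""

    a_to_b: DirectionSummary
    b_to_a: DirectionSummary
    gene_pair_counts: dict[str, int]
    n_pairs_total: int
    n_pairs_analyzed: int
    n_pairs_skipped: int
    prep_stats_a: PreparationStats | None = None
    prep_stats_b: PreparationStats | None = None

    def to_dict(self) -> dict:
        out = {
            "a_to_b": self.a_to_b.to_dict(),
            "b_to_a": self.b_to_a.to_dict(),
            "gene_pair_counts": self.gene_pair_counts,
            "n_pairs_total": self.n_pairs_total,
            "n_pairs_analyzed": self.n_pairs_analyzed,
            "n_pairs_skipped": self.n_pairs_skipped,
        }
        if self.prep_stats_a is not None:
            out["preparation_a"] = self.prep_stats_a.to_dict()
        if self.prep_stats_b is not None:
            out["preparation_b"] = self.prep_stats_b.to_dict()
        return out


def classify_colinear(a: CodingStructure, b: CodingStructure) -> MatchType:
    """Apply the three criteria to a one-to-one exon correspondence.

    Returns NONE when the exon counts differ or any intron phase disagrees;
    otherwise the strongest criterion the length differences allow.
    """
    if a.n_coding_exons != b.n_coding_exons:
        return MatchType.NONE
    if a.phases != b.phases:
        return MatchType.NONE
    deltas = [
        abs(x - y) for x, y in zip(a.coding_lengths, b.coding_lengths)
    ]
    if all(d == 0 for d in deltas):
        return MatchType.ISO1
    if all(d in ISO2_ALLOWED_DELTAS for d in deltas):
        return MatchType.ISO2
    return MatchType.ISO3


def _assign_type(
    query: CodingStructure, winner: CodingStructure, aln: StructureAlignment
) -> MatchType:
    # Intron gain/loss guard: a best alignment that needs a merge or gap is
    # never typed colinearly, even if raw exon counts happen to agree.
    if not aln.is_colinear:
        return MatchType.NONE
    return classify_colinear(query, winner)


def best_match(
    query: CodingStructure,
    candidates: list[CodingStructure],
    scheme: ScoringScheme | None = None,
) -> MatchRecord:
    """Align the query against every candidate and type the top scorer.

    Score ties are broken by CURATED before PREDICTED, then by stronger
    assigned match type, then by lexicographically smallest accession.
    """
    scheme = scheme or ScoringScheme()
    if not candidates:
        return MatchRecord(
            query_accession=query.accession,
            query_gene=query.gene_id,
            best_accession=None,
            best_gene=None,
            match_type=MatchType.NONE,
            score=None,
            match_source=None,
        )
    scored = []
    for cand in candidates:
        aln = align_structures(query, cand, scheme)
        mtype = _assign_type(query, cand, aln)
        scored.append((cand, aln, mtype))
    best_score = max(item[1].score for item in scored)
    contenders = [item for item in scored if item[1].score == best_score]
    winner, aln, mtype = min(
        contenders,
        key=lambda item: (
            0 if item[0].source is Source.CURATED else 1,
            -int(item[2]),
            item[0].accession,
        ),
    )
    return MatchRecord(
        query_accession=query.accession,
        query_gene=query.gene_id,
        best_accession=winner.accession,
        best_gene=winner.gene_id,
        match_type=mtype,
        score=aln.score,
        match_source=winner.source,
    )


def prepare_structures(
    index: GeneIndex,
) -> tuple[dict[str, list[CodingStructure]], PreparationStats]:
    """Project, filter and deduplicate an index; gene_id -> kept structures.

    Curated transcripts are deduplicated among themselves; predicted ones are
    deduplicated among themselves and additionally dropped when they share a
    signature with a kept curated structure (a predicted duplicate of a
    curated transcript can never change an assignment). This keeps the
    curated candidate set independent of predicted input.
    """
    stats = PreparationStats()
    out: dict[str, list[CodingStructure]] = {}
    for gene_id, transcripts in index.genes.items():
        kept: list[CodingStructure] = []
        for t in transcripts:
            stats.n_input += 1
            try:
                cs = project_cds(t)
            except NonCodingTranscriptError:
                stats.n_non_coding += 1
                continue
            except ProjectionError as exc:
                logger.warning("projection failed: %s", exc)
                stats.n_projection_failed += 1
                continue
            ok, reason = passes_filters(cs)
            if not ok:
                stats.n_filtered += 1
                stats.filter_reasons[reason] = stats.filter_reasons.get(reason, 0) + 1
                continue
            kept.append(cs)
        curated = dedup_transcripts([cs for cs in kept if cs.source is Source.CURATED])
        predicted = dedup_transcripts(
            [cs for cs in kept if cs.source is Source.PREDICTED]
        )
        curated_sigs = {dedup_signature(cs) for cs in curated}
        predicted = [
            cs for cs in predicted if dedup_signature(cs) not in curated_sigs
        ]
        stats.n_redundant_removed += len(kept) - len(curated) - len(predicted)
        stats.n_kept += len(curated) + len(predicted)
        if curated or predicted:
            out[gene_id] = curated + predicted
    return out, stats


def _stronger(a: MatchRecord, b: MatchRecord) -> MatchRecord:
    """Keep ``a`` unless ``b`` is strictly stronger in the stringency order."""
    return b if b.match_type > a.match_type else a


def _direction_records(
    prepared_q: dict[str, list[CodingStructure]],
    prepared_c: dict[str, list[CodingStructure]],
    pairs: list[tuple[str, str]],
    scheme: ScoringScheme,
    include_predicted: bool,
) -> list[MatchRecord]:
    records: list[MatchRecord] = []
    for q_gene, c_gene in pairs:
        queries = [
            cs for cs in prepared_q.get(q_gene, []) if cs.source is Source.CURATED
        ]
        all_cands = prepared_c.get(c_gene, [])
        curated_cands = [cs for cs in all_cands if cs.source is Source.CURATED]
        for q in queries:
            rec = best_match(q, curated_cands, scheme)
            if include_predicted and len(all_cands) > len(curated_cands):
                rec = _stronger(rec, best_match(q, all_cands, scheme))
            records.append(rec)
    return records


def _summarize_direction(
    records: list[MatchRecord], gene_of_query: dict[str, str] | None = None
) -> DirectionSummary:
    ds = DirectionSummary()
    gene_best: dict[str, MatchType] = {}
    for rec in records:
        ds.n_queries += 1
        ds.transcript_counts[rec.match_type.name] += 1
        if rec.match_source is Source.PREDICTED and rec.match_type is not MatchType.NONE:
            ds.predicted_match_counts[rec.match_type.name] += 1
        gene = rec.query_gene if gene_of_query is None else gene_of_query[
            rec.query_accession
        ]
        gene_best[gene] = max(gene_best.get(gene, MatchType.NONE), rec.match_type)
    for mtype in gene_best.values():
        ds.gene_counts[mtype.name] += 1
    return ds


def summarize_records(
    records_ab: list[MatchRecord],
    records_ba: list[MatchRecord],
    pairs: list[OrthologPair] | None = None,
    n_pairs_total: int | None = None,
    n_pairs_skipped: int = 0,
) -> CohortSummary:
    """Build a cohort summary from per-direction match records.

    The combined gene-pair category is the strongest type achieved by any of
    the pair's transcript records in either direction; it needs the ortholog
    pair list and is reported empty without one.
    """
    a_to_b = _summarize_direction(records_ab)
    b_to_a = _summarize_direction(records_ba)
    gene_pair_counts = {t.name: 0 for t in MatchType}
    n_analyzed = 0
    if pairs is not None:
        best_ab: dict[str, MatchType] = {}
        for rec in records_ab:
            best_ab[rec.query_gene] = max(
                best_ab.get(rec.query_gene, MatchType.NONE), rec.match_type
            )
        best_ba: dict[str, MatchType] = {}
        for rec in records_ba:
            best_ba[rec.query_gene] = max(
                best_ba.get(rec.query_gene, MatchType.NONE), rec.match_type
            )
        for pair in pairs:
            n_analyzed += 1
            best = max(
                best_ab.get(pair.gene_a, MatchType.NONE),
                best_ba.get(pair.gene_b, MatchType.NONE),
            )
            gene_pair_counts[best.name] += 1
    return CohortSummary(
        a_to_b=a_to_b,
        b_to_a=b_to_a,
        gene_pair_counts=gene_pair_counts,
        n_pairs_total=n_pairs_total if n_pairs_total is not None else n_analyzed,
        n_pairs_analyzed=n_analyzed,
        n_pairs_skipped=n_pairs_skipped,
    )


def classify_cohort(
    index_a: GeneIndex,
    index_b: GeneIndex,
    pairs: list[OrthologPair],
    scheme: ScoringScheme | None = None,
    include_predicted: bool = False,
) -> tuple[list[MatchRecord], list[MatchRecord], CohortSummary]:
    """Run the full comparison over a cohort of orthologous gene pairs.

    Projects, filters and deduplicates both indices, then produces match
    records in both directions (A->B and B->A; curated queries only) and a
    cohort summary. Pairs referencing a gene absent from either index are
    logged and counted as skipped, not fatal.
    """
    scheme = scheme or ScoringScheme()
    prepared_a, stats_a = prepare_structures(index_a)
    prepared_b, stats_b = prepare_structures(index_b)

    # A pair is skipped only when a gene is absent from the input index; a
    # gene whose transcripts were all filtered still yields records (its
    # partner's queries simply find no candidates and classify as NONE).
    usable: list[OrthologPair] = []
    n_skipped = 0
    for pair in pairs:
        if pair.gene_a not in index_a or pair.gene_b not in index_b:
            logger.info(
                "skipping pair %s/%s: gene absent from input",
                pair.gene_a,
                pair.gene_b,
            )
            n_skipped += 1
            continue
        usable.append(pair)

    records_ab = _direction_records(
        prepared_a,
        prepared_b,
        [(p.gene_a, p.gene_b) for p in usable],
        scheme,
        include_predicted,
    )
    records_ba = _direction_records(
        prepared_b,
        prepared_a,
        [(p.gene_b, p.gene_a) for p in usable],
        scheme,
        include_predicted,
    )
    summary = summarize_records(
        records_ab,
        records_ba,
        pairs=usable,
        n_pairs_total=len(pairs),
        n_pairs_skipped=n_skipped,
    )
    summary.prep_stats_a = stats_a
    summary.prep_stats_b = stats_b
    logger.info(
        "cohort: %d pairs in, %d analyzed, %d skipped; %d A->B and %d B->A queries",
        len(pairs),
        summary.n_pairs_analyzed,
        n_skipped,
        len(records_ab),
        len(records_ba),
    )
    return records_ab, records_ba, summary
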