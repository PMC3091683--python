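"""Transcript gene models and tab-delimited readers/writers.

The pipeline consumes UCSC-style refFlat/genePred annotations (one transcript
per line, 0-based half-open coordinates, comma-terminated exon lists) plus a
two-column ortholog-pair table, and emits a best-structural-match table.
Coordinates are genomic; transcript orientation is recovered from the strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

#: refFlat-style column layout consumed by :func:`read_genepred`.
GENEPRED_COLUMNS = (
    "accession",
    "gene_id",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsStart",
    "cdsEnd",
    "exonCount",
    "exonStarts",
    "exonEnds",
)

MATCH_TABLE_COLUMNS = (
    "query_accession",
    "query_gene",
    "best_match_accession",
    "best_match_gene",
    "match_source",
    "match_type",
    "alignment_score",
)

_ORTHOLOG_HEADER_TOKENS = {
    "gene_a",
    "gene_b",
    "gene",
    "gene_id",
    "gene_id_a",
    "gene_id_b",
    "species_a",
    "species_b",
    "a",
    "b",
}


class Source(str, Enum):
    """Provenance of a transcript model.

    CURATED marks transcripts from a curated collection (the RefSeq analog);
    PREDICTED marks computationally inferred isoforms (the ASPicDB analog).
    The distinction matters downstream: predicted transcripts may serve as
    match candidates but never as queries.
    """

    CURATED = "CURATED"
    PREDICTED = "PREDICTED"


class GenePredParseError(ValueError):
    """A line of a genePred/ortholog file could not be parsed."""


class ModelValidationError(ValueError):
    """A parsed record violates a structural invariant."""


@dataclass(frozen=True)
class TranscriptModel:
    """A genomic transcript annotation.

    Exons are ``(start, end)`` genomic intervals, 0-based half-open, sorted
    ascending and non-overlapping. ``cds_start``/``cds_end`` delimit the
    genomic CDS span; a non-coding transcript has ``cds_start == cds_end``.
    For coding transcripts both CDS boundaries must fall inside an exon — a
    CDS boundary in an intron is a malformed annotation and is rejected here
    rather than silently clipped, because it would corrupt downstream intron
    phase arithmetic.
    """

    accession: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    source: Source = Source.CURATED

    def __post_init__(self) -> None:
        if not self.accession:
            raise ModelValidationError("empty accession")
        if not self.gene_id:
            raise ModelValidationError(f"{self.accession}: empty gene_id")
        if self.strand not in ("+", "-"):
            raise ModelValidationError(
                f"{self.accession}: strand must be '+' or '-', got {self.strand!r}"
            )
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        if not exons:
            raise ModelValidationError(f"{self.accession}: transcript has no exons")
        for s, e in exons:
            if e <= s:
                raise ModelValidationError(
                    f"{self.accession}: empty or inverted exon ({s},{e})"
                )
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ModelValidationError(
                    f"{self.accession}: exons out of order or overlapping "
                    f"({s0},{e0}) vs ({s1},{e1})"
                )
        if self.cds_start > self.cds_end:
            raise ModelValidationError(
                f"{self.accession}: cds_start {self.cds_start} > cds_end {self.cds_end}"
            )
        if self.is_coding:
            if self.cds_start < exons[0][0] or self.cds_end > exons[-1][1]:
                raise ModelValidationError(
                    f"{self.accession}: CDS span outside transcript extent"
                )
            if not any(s <= self.cds_start < e for s, e in exons):
                raise ModelValidationError(
                    f"{self.accession}: CDS boundary not exonic (cds_start "
                    f"{self.cds_start} lies in an intron)"
                )
            if not any(s < self.cds_end <= e for s, e in exons):
                raise ModelValidationError(
                    f"{self.accession}: CDS boundary not exonic (cds_end "
                    f"{self.cds_end} lies in an intron)"
                )

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def exon_count(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class OrthologPair:
    """A 1:1 orthologous gene pair (species-A gene, species-B gene)."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise ModelValidationError("ortholog pair with empty gene id")


class GeneIndex:
    """Mapping gene_id -> transcripts, with index-wide accession uniqueness."""

    def __init__(self, transcripts: Iterable[TranscriptModel] = ()) -> None:
        self._genes: dict[str, list[TranscriptModel]] = {}
        self._accessions: set[str] = set()
        for t in transcripts:
            self.add(t)

    def add(self, t: TranscriptModel) -> None:
        if t.accession in self._accessions:
            raise ModelValidationError(f"duplicate accession {t.accession}")
        self._accessions.add(t.accession)
        self._genes.setdefault(t.gene_id, []).append(t)

    @property
    def genes(self) -> dict[str, list[TranscriptModel]]:
        return self._genes

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> list[TranscriptModel]:
        return self._genes[gene_id]

    def transcripts(self) -> Iterator[TranscriptModel]:
        for ts in self._genes.values():
            yield from ts

    @property
    def n_genes(self) -> int:
        return len(self._genes)

    @property
    def n_transcripts(self) -> int:
        return len(self._accessions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneIndex):
            return NotImplemented
        return self._genes == other._genes

    def __repr__(self) -> str:
        return f"GeneIndex({self.n_genes} genes, {self.n_transcripts} transcripts)"


def _parse_comma_list(text: str, *, line_no: int, what: str) -> tuple[int, ...]:
    items = [x for x in text.strip().split(",") if x != ""]
    try:
        return tuple(int(x) for x in items)
    except ValueError as exc:
        raise GenePredParseError(f"line {line_no}: malformed {what} list {text!r}") from exc


def read_genepred(path: str | Path, source_tag: Source) -> GeneIndex:
    """Read a refFlat-style genePred file into a validated :class:`GeneIndex`.

    Every transcript is tagged with ``source_tag`` (the format itself carries
    no provenance column). Comment lines starting with ``#`` and blank lines
    are skipped. Raises :class:`GenePredParseError` naming the offending line
    for malformed input, :class:`ModelValidationError` for records violating
    transcript invariants or duplicating an accession.
    """
    source_tag = Source(source_tag)
    index = GeneIndex()
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < len(GENEPRED_COLUMNS):
                raise GenePredParseError(
                    f"line {line_no}: expected {len(GENEPRED_COLUMNS)} "
                    f"tab-separated fields, got {len(fields)}"
                )
            acc, gene, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            try:
                cds_start = int(fields[6])
                cds_end = int(fields[7])
                exon_count = int(fields[8])
            except ValueError as exc:
                raise GenePredParseError(
                    f"line {line_no}: non-integer coordinate field"
                ) from exc
            starts = _parse_comma_list(fields[9], line_no=line_no, what="exonStarts")
            ends = _parse_comma_list(fields[10], line_no=line_no, what="exonEnds")
            if len(starts) != len(ends):
                raise ModelValidationError(
                    f"{acc}: exonStarts/exonEnds length mismatch "
                    f"({len(starts)} vs {len(ends)})"
                )
            if exon_count != len(starts):
                raise ModelValidationError(
                    f"{acc}: exonCount {exon_count} does not match "
                    f"{len(starts)} parsed exons"
                )
            model = TranscriptModel(
                accession=acc,
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                exons=tuple(zip(starts, ends)),
                cds_start=cds_start,
                cds_end=cds_end,
                source=source_tag,
            )
            index.add(model)
    return index


def write_genepred(index: GeneIndex, path: str | Path) -> None:
    """Write a GeneIndex back to refFlat-style genePred (round-trip safe)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for t in index.transcripts():
            starts = ",".join(str(s) for s, _ in t.exons) + ","
            ends = ",".join(str(e) for _, e in t.exons) + ","
            fh.write(
                "\t".join(
                    (
                        t.accession,
                        t.gene_id,
                        t.chrom,
                        t.strand,
                        str(t.tx_start),
                        str(t.tx_end),
                        str(t.cds_start),
                        str(t.cds_end),
                        str(t.exon_count),
                        starts,
                        ends,
                    )
                )
                + "\n"
            )


def read_ortholog_pairs(path: str | Path) -> list[OrthologPair]:
    """Read a two-column TSV of 1:1 orthologous gene pairs.

    De-duplicates exact repeats preserving file order. A gene that appears in
    two *different* pairs violates the 1:1 orthology assumption and raises
    :class:`ModelValidationError`. An optional header row is detected by its
    tokens and skipped.
    """
    pairs: list[OrthologPair] = []
    seen_pairs: set[tuple[str, str]] = set()
    partner_of_a: dict[str, str] = {}
    partner_of_b: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        first_data_row = True
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                continue
            if not line.strip():
                raise GenePredParseError(f"line {line_no}: blank line in ortholog table")
            fields = [f.strip() for f in line.split("\t")]
            if first_data_row and any(
                f.lower() in _ORTHOLOG_HEADER_TOKENS for f in fields
            ):
                first_data_row = False
                continue
            first_data_row = False
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise GenePredParseError(
                    f"line {line_no}: expected two tab-separated gene ids"
                )
            a, b = fields[0], fields[1]
            if (a, b) in seen_pairs:
                continue
            if a in partner_of_a and partner_of_a[a] != b:
                raise ModelValidationError(
                    f"non-unique ortholog mapping for {a!r} "
                    f"({partner_of_a[a]!r} vs {b!r})"
                )
            if b in partner_of_b and partner_of_b[b] != a:
                raise ModelValidationError(
                    f"non-unique ortholog mapping for {b!r} "
                    f"({partner_of_b[b]!r} vs {a!r})"
                )
            partner_of_a[a] = b
            partner_of_b[b] = a
            seen_pairs.add((a, b))
            pairs.append(OrthologPair(a, b))
    return pairs


def write_ortholog_pairs(pairs: Iterable[OrthologPair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_a\tgene_b\n")
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\n")


def write_match_table(records: Iterable, path: str | Path) -> None:
    """Write best-structural-match records as TSV.

    One row per query transcript; missing best-match fields are rendered as
    ``.`` (accessions/genes), ``NONE`` (source) and ``NA`` (score). Scores use
    ``repr`` so the table round-trips float-exactly through
    :func:`read_match_table`.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(MATCH_TABLE_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    (
                        rec.query_accession,
                        rec.query_gene,
                        rec.best_accession if rec.best_accession else ".",
                        rec.best_gene if rec.best_gene else ".",
                        rec.match_source.value if rec.match_source else "NONE",
                        rec.match_type.name,
                        repr(float(rec.score)) if rec.score is not None else "NA",
                    )
                )
                + "\n"
            )


def read_match_table(path: str | Path) -> list:
    """Read a match table written by :func:`write_match_table`."""
    from .ortholog_classify import MatchRecord, MatchType  # local: avoid cycle

    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != MATCH_TABLE_COLUMNS:
            raise GenePredParseError(f"unexpected match-table header {header!r}")
        for line_no, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(MATCH_TABLE_COLUMNS):
                raise GenePredParseError(
                    f"line {line_no}: expected {len(MATCH_TABLE_COLUMNS)} fields"
                )
            qacc, qgene, bacc, bgene, src, mtype, score = fields
            records.append(
                MatchRecord(
                    query_accession=qacc,
                    query_gene=qgene,
                    best_accession=None if bacc == "." else bacc,
                    best_gene=None if bgene == "." else bgene,
                    match_type=MatchType[mtype],
                    score=None if score == "NA" else float(score),
                    match_source=None if src == "NONE" else Source(src),
                )
            )
    return records
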