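"""Projection of transcripts onto coding exon-intron structures.

A transcript's comparable structure is the ordered list of its coding exon
lengths (UTR exons dropped, external exons trimmed to their coding portion)
together with the phase of each intron interrupting the CDS. The phase of the
intron preceding coding exon *i+1* is the cumulative coding length of exons
``0..i`` modulo 3 — i.e. where the intron falls relative to codon boundaries.
UTR structure is deliberately excluded: untranslated regions are far more
variable in length and number across species and far less consistently
annotated, so only the coding skeleton is compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .gene_models import Source, TranscriptModel

logger = logging.getLogger(__name__)


class ProjectionError(ValueError):
    """The transcript's CDS cannot be projected onto its exons."""


class NonCodingTranscriptError(ProjectionError):
    """The transcript has no annotated CDS."""


@dataclass(frozen=True)
class CodingStructure:
    """The CDS-projected exon-intron structure of one transcript.

    ``coding_lengths`` are bp of coding sequence per coding exon, 5'->3' in
    transcript orientation (genomic order reversed on the minus strand).
    ``phases[i]`` is the phase (0/1/2) of the intron preceding coding exon
    ``i+1``; it always equals the cumulative sum of ``coding_lengths[:i+1]``
    mod 3, stored for convenience and asserted at construction.
    """

    accession: str
    gene_id: str
    source: Source
    coding_lengths: tuple[int, ...]
    phases: tuple[int, ...]
    n_internal_fully_coding: int
    total_exon_count: int

    def __post_init__(self) -> None:
        if not self.coding_lengths:
            raise ProjectionError(f"{self.accession}: empty coding structure")
        if any(l <= 0 for l in self.coding_lengths):
            raise ProjectionError(f"{self.accession}: non-positive coding length")
        if len(self.phases) != len(self.coding_lengths) - 1:
            raise ProjectionError(
                f"{self.accession}: {len(self.phases)} phases for "
                f"{len(self.coding_lengths)} coding exons"
            )
        if self.phases != compute_phases(self.coding_lengths):
            raise ProjectionError(
                f"{self.accession}: stored phases {self.phases} disagree with "
                f"cumulative coding lengths"
            )

    @property
    def n_coding_exons(self) -> int:
        return len(self.coding_lengths)

    @property
    def total_coding_length(self) -> int:
        return sum(self.coding_lengths)


def compute_phases(coding_lengths: tuple[int, ...] | list[int]) -> tuple[int, ...]:
    """Intron phases from cumulative coding lengths (all introns but the last exon's)."""
    phases = []
    acc = 0
    for length in coding_lengths[:-1]:
        acc += length
        phases.append(acc % 3)
    return tuple(phases)


def project_cds(t: TranscriptModel) -> CodingStructure:
    """Project a transcript onto its coding structure.

    Fully non-coding exons are dropped; the first and last retained exons are
    trimmed to their CDS overlap; lengths are reported 5'->3' in transcript
    orientation. A CDS whose exonic length is not a multiple of 3 is accepted
    with a warning (curated collections contain such records); phases remain
    cumulative-sum mod 3.
    """
    if not t.is_coding:
        raise NonCodingTranscriptError(f"{t.accession}: non-coding transcript")
    # Model validation already guarantees exonic CDS boundaries; guard anyway
    # because projection arithmetic silently mis-phases otherwise.
    if not any(s <= t.cds_start < e for s, e in t.exons) or not any(
        s < t.cds_end <= e for s, e in t.exons
    ):
        raise ProjectionError(f"{t.accession}: CDS boundary not exonic")

    pieces: list[int] = []  # genomic order
    coding_exon_spans: list[tuple[int, int]] = []  # parent exon spans, genomic order
    for s, e in t.exons:
        lo, hi = max(s, t.cds_start), min(e, t.cds_end)
        if hi > lo:
            pieces.append(hi - lo)
            coding_exon_spans.append((s, e))
    if not pieces:
        raise ProjectionError(f"{t.accession}: CDS overlaps no exon")

    if t.strand == "-":
        pieces.reverse()
        coding_exon_spans.reverse()
    lengths = tuple(pieces)

    n_internal = sum(
        1
        for i, (s, e) in enumerate(coding_exon_spans)
        if 0 < i < len(coding_exon_spans) - 1
        and s >= t.cds_start
        and e <= t.cds_end
    )

    if sum(lengths) % 3 != 0:
        logger.warning(
            "%s: exonic CDS length %d not a multiple of 3", t.accession, sum(lengths)
        )

    return CodingStructure(
        accession=t.accession,
        gene_id=t.gene_id,
        source=t.source,
        coding_lengths=lengths,
        phases=compute_phases(lengths),
        n_internal_fully_coding=n_internal,
        total_exon_count=t.exon_count,
    )


def passes_filters(cs: CodingStructure) -> tuple[bool, str]:
    """Transcript inclusion filter for the orthology comparison.

    A transcript qualifies iff its parent transcript has at least four exons
    (UTR-only exons count) AND its coding structure has at least two internal
    fully coding exons — coding exons that are neither first nor last of the
    coding structure and whose whole transcript exon lies within the CDS.
    Returns ``(ok, reason)``; the reason names the failed condition.
    """
    if cs.total_exon_count < 4:
        return False, "fewer than four exons"
    if cs.n_internal_fully_coding < 2:
        return False, "fewer than two internal fully coding exons"
    return True, "ok"


def dedup_signature(cs: CodingStructure) -> tuple[tuple[int, int], ...]:
    """(size, frame) per internal coding exon; frame = phase of the preceding intron.

    Two structures with equal signatures share internal coding exons of the
    same size and reading frame and are redundant for structure comparison
    (they can differ only in external/UTR portions).
    """
    return tuple(
        (cs.coding_lengths[i], cs.phases[i - 1])
        for i in range(1, cs.n_coding_exons - 1)
    )


def dedup_transcripts(structures: list[CodingStructure]) -> list[CodingStructure]:
    """Collapse redundant structures of one gene to one representative each.

    Groups by :func:`dedup_signature`; the representative is the structure
    with the greatest total coding length (the most informative one), ties
    broken by lexicographically smallest accession. Output is sorted by
    accession for determinism.
    """
    groups: dict[tuple, list[CodingStructure]] = {}
    for cs in structures:
        groups.setdefault(dedup_signature(cs), []).append(cs)
    reps = [
        min(group, key=lambda cs: (-cs.total_coding_length, cs.accession))
        for group in groups.values()
    ]
    return sorted(reps, key=lambda cs: cs.accession)


def write_structure_dump(
    structures: list[CodingStructure], path, species: str = ""
) -> None:
    """Debug TSV dump of coding structures (one row per structure)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "species\taccession\tgene_id\tsource\ttotal_exon_count\t"
            "n_coding_exons\tn_internal_fully_coding\tcoding_lengths\tphases\n"
        )
        for cs in structures:
            fh.write(
                "\t".join(
                    (
                        species,
                        cs.accession,
                        cs.gene_id,
                        cs.source.value,
                        str(cs.total_exon_count),
                        str(cs.n_coding_exons),
                        str(cs.n_internal_fully_coding),
                        ",".join(str(x) for x in cs.coding_lengths),
                        ",".join(str(x) for x in cs.phases),
                    )
                )
                + "\n"
            )
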