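"""Synthetic orthologous-gene cohorts with labeled splicing divergence.

Every pipeline stage is testable without external downloads: the generator
emits a pair of gene indices (species A and B), an ortholog table, and a
ground-truth record per query transcript. Species-A transcripts are built
from random multi-exon coding structures (UTR exons and partially coding
external exons included); each species-B counterpart is derived by a labeled
perturbation chosen so that the truth label is, by construction, exactly the
category the classifier must recover:

ISO1                  identical coding structure.
ISO2                  1-3 exons shifted by multiples of 3 bp, each |delta|
                      <= 15, at least one nonzero.
ISO3                  phase-preserving shifts violating ISO2 (an internal
                      shift > 15 bp in multiples of 3, or a last-exon shift
                      outside {0,3,...,15}).
NONE_skip             one internal coding exon deleted (exon skipping).
NONE_introngain       one exon split in two (intron gain; lengths sum to the
                      original).
NONE_phasebreak       an internal exon shifted by a non-multiple of 3,
                      breaking downstream intron phases.
NONE_speciesspecific  the partner gene carries only a structurally unrelated
                      isoform.

Isoforms within a gene are given pairwise distinct coding-exon counts spaced
at least two apart. Since no perturbation changes the count by more than one,
a query can be colinear only with its intended counterpart, so truth labels
are unambiguous even under best-score candidate selection. Species-B genomic
layout (chromosome, offsets, intron sizes, strand) is drawn independently of
species A: nothing downstream may depend on coordinates, only on structure.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path

from .coding_projection import CodingStructure
from .gene_models import (
    GeneIndex,
    OrthologPair,
    Source,
    TranscriptModel,
    write_genepred,
    write_ortholog_pairs,
)
from .ortholog_classify import MatchType


class TruthLabel(str, Enum):
    ISO1 = "ISO1"
    ISO2 = "ISO2"
    ISO3 = "ISO3"
    NONE_SKIP = "NONE_skip"
    NONE_INTRON_GAIN = "NONE_introngain"
    NONE_PHASE_BREAK = "NONE_phasebreak"
    NONE_SPECIES_SPECIFIC = "NONE_speciesspecific"

    @property
    def expected_type(self) -> MatchType:
        if self is TruthLabel.ISO1:
            return MatchType.ISO1
        if self is TruthLabel.ISO2:
            return MatchType.ISO2
        if self is TruthLabel.ISO3:
            return MatchType.ISO3
        return MatchType.NONE


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth label and event list for one species-A query transcript."""

    gene_a: str
    gene_b: str
    query_accession: str
    expected_match_accession: str | None
    expected_type: MatchType
    event_list: tuple[str, ...]


@dataclass
class GeneratorConfig:
    """Conditions of a synthetic cohort.

    ``exon_count_range`` bounds the coding exon count per isoform (the lower
    bound of 4 guarantees at least two internal fully coding exons, the
    inclusion filter of the analysis); coding exon lengths are uniform on
    ``coding_length_range`` bp. ``utr_exon_probability`` adds a fully
    untranslated exon per transcript side; external coding exons additionally
    receive 0-150 bp UTR extensions. ``predicted_fraction`` is the fraction
    of species-B isoforms emitted as PREDICTED (candidate-only) transcripts.
    Identical seed and config produce byte-identical output files.
    """

    n_genes: int = 100
    exon_count_range: tuple[int, int] = (4, 12)
    coding_length_range: tuple[int, int] = (30, 300)
    utr_exon_probability: float = 0.3
    minus_strand_probability: float = 0.5
    isoforms_per_gene_range: tuple[int, int] = (1, 4)
    label_mixture: dict | None = None
    predicted_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.exon_count_range
        if lo < 4 or hi < lo:
            raise ValueError("exon_count_range must satisfy 4 <= min <= max")
        llo, lhi = self.coding_length_range
        if llo < 18 or lhi < llo:
            raise ValueError("coding_length_range must satisfy 18 <= min <= max")
        ilo, ihi = self.isoforms_per_gene_range
        if ilo < 1 or ihi < ilo:
            raise ValueError("isoforms_per_gene_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.predicted_fraction <= 1.0:
            raise ValueError("predicted_fraction must be in [0,1]")
        if not 0.0 <= self.utr_exon_probability <= 1.0:
            raise ValueError("utr_exon_probability must be in [0,1]")
        if not 0.0 <= self.minus_strand_probability <= 1.0:
            raise ValueError("minus_strand_probability must be in [0,1]")
        self.label_mixture = normalize_mixture(self.label_mixture)

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["label_mixture"] = {
            label.value: prob for label, prob in self.label_mixture.items()
        }
        return d


def normalize_mixture(mixture: dict | None) -> dict[TruthLabel, float]:
    """Validate a label mixture (keys may be TruthLabel or their string values)."""
    if mixture is None:
        p = 1.0 / len(TruthLabel)
        return {label: p for label in TruthLabel}
    out = {label: 0.0 for label in TruthLabel}
    for key, prob in mixture.items():
        label = key if isinstance(key, TruthLabel) else TruthLabel(key)
        if prob < 0:
            raise ValueError(f"negative probability for {label.value}")
        out[label] = float(prob)
    total = sum(out.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"label mixture sums to {total}, expected 1")
    return out


def _draw_label(rng: random.Random, mixture: dict[TruthLabel, float]) -> TruthLabel:
    labels = list(mixture.keys())
    return rng.choices(labels, weights=[mixture[l] for l in labels], k=1)[0]


def _lay_out(
    accession: str,
    gene_id: str,
    chrom: str,
    strand: str,
    coding_lengths: list[int],
    rng: random.Random,
    source: Source,
    utr_exon_probability: float,
) -> TranscriptModel:
    """Realize a coding structure as a genomic transcript model.

    Coding lengths are 5'->3' in transcript orientation; external coding
    exons get random UTR extensions and each side may gain a fully
    untranslated exon. A minus-strand transcript is produced by mirroring
    the plus-strand layout, which exercises the strand-handling of the
    projection code.
    """
    utr5_ext = rng.randint(0, 150)
    utr3_ext = rng.randint(0, 150)
    utr5_exons = [rng.randint(50, 300)] if rng.random() < utr_exon_probability else []
    utr3_exons = [rng.randint(50, 300)] if rng.random() < utr_exon_probability else []

    # transcript-order genomic exon lengths
    exon_lengths = list(utr5_exons)
    if len(coding_lengths) == 1:
        exon_lengths.append(utr5_ext + coding_lengths[0] + utr3_ext)
    else:
        exon_lengths.append(utr5_ext + coding_lengths[0])
        exon_lengths.extend(coding_lengths[1:-1])
        exon_lengths.append(coding_lengths[-1] + utr3_ext)
    exon_lengths.extend(utr3_exons)

    offset = rng.randint(1_000, 5_000_000)
    exons: list[tuple[int, int]] = []
    pos = offset
    for length in exon_lengths:
        exons.append((pos, pos + length))
        pos = pos + length + rng.randint(80, 2_000)

    first_coding = len(utr5_exons)
    last_coding = first_coding + len(coding_lengths) - 1
    cds_start = exons[first_coding][0] + utr5_ext
    cds_end = exons[last_coding][1] - utr3_ext

    if strand == "-":
        mirror = exons[-1][1] + rng.randint(100, 10_000)
        exons = [(mirror - e, mirror - s) for s, e in reversed(exons)]
        cds_start, cds_end = mirror - cds_end, mirror - cds_start

    return TranscriptModel(
        accession=accession,
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
        source=source,
    )


def _perturb(
    rng: random.Random,
    lengths: list[int],
    label: TruthLabel,
    forbidden_counts: set[int],
    count_range: tuple[int, int],
    length_range: tuple[int, int],
) -> tuple[list[int], tuple[str, ...]]:
    """Derive the species-B coding lengths and event list for a label."""
    c = len(lengths)
    out = list(lengths)

    def shift(idx: int, mag: int) -> int:
        sign = rng.choice((1, -1))
        if sign < 0 and out[idx] - mag < 3:
            sign = 1
        out[idx] += sign * mag
        return sign * mag

    if label is TruthLabel.ISO1:
        return out, ("identical",)
    if label is TruthLabel.ISO2:
        n_shift = rng.randint(1, min(3, c))
        idxs = sorted(rng.sample(range(c), n_shift))
        events = []
        for idx in idxs:
            delta = shift(idx, rng.choice((3, 6, 9, 12, 15)))
            events.append(f"shift exon {idx} by {delta:+d}")
        return out, tuple(events)
    if label is TruthLabel.ISO3:
        if rng.random() < 0.5:
            idx = rng.randint(1, c - 2)  # internal, in-frame but > 15 bp
            delta = shift(idx, rng.randrange(18, 46, 3))
        else:
            idx = c - 1  # last exon, difference outside {0,3,...,15}
            delta = shift(idx, rng.choice((1, 2, 16, 17, 20, 23)))
        return out, (f"shift exon {idx} by {delta:+d}",)
    if label is TruthLabel.NONE_SKIP:
        idx = rng.randint(1, c - 2)
        skipped = out.pop(idx)
        return out, (f"skip exon {idx} ({skipped} bp)",)
    if label is TruthLabel.NONE_INTRON_GAIN:
        idx = rng.randrange(c)
        total = out[idx]
        left = rng.randint(10, total - 10)
        out[idx : idx + 1] = [left, total - left]
        return out, (f"split exon {idx} into {left}+{total - left}",)
    if label is TruthLabel.NONE_PHASE_BREAK:
        idx = rng.randint(1, c - 2)
        delta = shift(idx, rng.choice((1, 2, 4, 5, 7, 8)))
        return out, (f"shift exon {idx} by {delta:+d} (frame-breaking)",)
    # NONE_SPECIES_SPECIFIC: structurally unrelated isoform with a coding
    # exon count outside the gene's count set, so it can never align
    # colinearly with any query of the gene.
    lo, hi = count_range
    choices = [x for x in range(lo, hi + 1) if x not in forbidden_counts]
    c_b = rng.choice(choices)
    out = [rng.randint(*length_range) for _ in range(c_b)]
    out[-1] -= sum(out) % 3
    return out, (f"unrelated partner ({c_b} coding exons)",)


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[GeneIndex, GeneIndex, list[OrthologPair], list[TruthRecord]]:
    """Generate a labeled cohort of orthologous gene pairs.

    Returns the species-A index (all CURATED), the species-B index (CURATED
    plus a ``predicted_fraction`` of PREDICTED isoforms), the ortholog pair
    list, and one :class:`TruthRecord` per species-A query transcript.
    """
    rng = random.Random(config.seed)
    index_a, index_b = GeneIndex(), GeneIndex()
    pairs: list[OrthologPair] = []
    truths: list[TruthRecord] = []

    lo, hi = config.exon_count_range
    count_slots = list(range(lo, hi + 1, 2))

    for g in range(config.n_genes):
        gene_a, gene_b = f"GA{g:05d}", f"GB{g:05d}"
        chrom_a = f"chr{rng.randint(1, 20)}"
        chrom_b = f"chr{rng.randint(1, 20)}"
        n_iso = min(rng.randint(*config.isoforms_per_gene_range), len(count_slots))
        counts = sorted(rng.sample(count_slots, n_iso))
        for i, c in enumerate(counts):
            lengths_a = [rng.randint(*config.coding_length_range) for _ in range(c)]
            lengths_a[-1] -= sum(lengths_a) % 3  # CDS is a whole number of codons
            label = _draw_label(rng, config.label_mixture)
            lengths_b, events = _perturb(
                rng,
                lengths_a,
                label,
                forbidden_counts=set(counts),
                count_range=config.exon_count_range,
                length_range=config.coding_length_range,
            )
            acc_a = f"NMA{g:05d}.{i}"
            predicted = rng.random() < config.predicted_fraction
            acc_b = (f"APB{g:05d}.{i}" if predicted else f"NMB{g:05d}.{i}")
            strand_a = "-" if rng.random() < config.minus_strand_probability else "+"
            strand_b = "-" if rng.random() < config.minus_strand_probability else "+"
            index_a.add(
                _lay_out(
                    acc_a,
                    gene_a,
                    chrom_a,
                    strand_a,
                    lengths_a,
                    rng,
                    Source.CURATED,
                    config.utr_exon_probability,
                )
            )
            index_b.add(
                _lay_out(
                    acc_b,
                    gene_b,
                    chrom_b,
                    strand_b,
                    lengths_b,
                    rng,
                    Source.PREDICTED if predicted else Source.CURATED,
                    config.utr_exon_probability,
                )
            )
            truths.append(
                TruthRecord(
                    gene_a=gene_a,
                    gene_b=gene_b,
                    query_accession=acc_a,
                    expected_match_accession=(
                        acc_b if label.expected_type is not MatchType.NONE else None
                    ),
                    expected_type=label.expected_type,
                    event_list=events,
                )
            )
        pairs.append(OrthologPair(gene_a, gene_b))
    return index_a, index_b, pairs, truths


def generate_redundant_set(
    base: CodingStructure, n: int, seed: int
) -> list[TranscriptModel]:
    """``n`` transcript variants of ``base`` differing only in UTR structure.

    All variants carry identical coding lengths (hence an identical dedup
    signature) but differ in UTR exons, external-exon UTR extents, strand and
    genomic layout; deduplication must collapse them to one representative.
    """
    if base.n_coding_exons < 4:
        raise ValueError("base structure needs at least two internal coding exons")
    rng = random.Random(seed)
    out = []
    for i in range(n):
        strand = rng.choice("+-")
        out.append(
            _lay_out(
                f"{base.accession}.r{i}",
                base.gene_id,
                f"chr{rng.randint(1, 20)}",
                strand,
                list(base.coding_lengths),
                rng,
                base.source,
                utr_exon_probability=0.5,
            )
        )
    return out


TRUTH_COLUMNS = (
    "gene_a",
    "gene_b",
    "query_accession",
    "expected_match_accession",
    "expected_type",
    "events",
)


def write_truth_table(truths: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            fh.write(
                "\t".join(
                    (
                        t.gene_a,
                        t.gene_b,
                        t.query_accession,
                        t.expected_match_accession or ".",
                        t.expected_type.name,
                        ";".join(t.event_list),
                    )
                )
                + "\n"
            )


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth-table header {header!r}")
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            ga, gb, qacc, macc, mtype, events = line.split("\t")
            records.append(
                TruthRecord(
                    gene_a=ga,
                    gene_b=gb,
                    query_accession=qacc,
                    expected_match_accession=None if macc == "." else macc,
                    expected_type=MatchType[mtype],
                    event_list=tuple(events.split(";")) if events else (),
                )
            )
    return records


def write_cohort(
    out_dir: str | Path,
    index_a: GeneIndex,
    index_b: GeneIndex,
    pairs: list[OrthologPair],
    truths: list[TruthRecord],
    config: GeneratorConfig | None = None,
) -> dict[str, Path]:
    """Write a cohort in the same dialects the pipeline readers consume.

    Species-B transcripts are split by source into a curated and (when
    non-empty) a predicted genePred file; a manifest records the generator
    configuration for reproducibility.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["species_a"] = out_dir / "species_a.curated.genepred"
    write_genepred(index_a, paths["species_a"])

    b_curated = GeneIndex(
        t for t in index_b.transcripts() if t.source is Source.CURATED
    )
    b_predicted = GeneIndex(
        t for t in index_b.transcripts() if t.source is Source.PREDICTED
    )
    paths["species_b"] = out_dir / "species_b.curated.genepred"
    write_genepred(b_curated, paths["species_b"])
    if b_predicted.n_transcripts:
        paths["species_b_predicted"] = out_dir / "species_b.predicted.genepred"
        write_genepred(b_predicted, paths["species_b_predicted"])

    paths["orthologs"] = out_dir / "orthologs.tsv"
    write_ortholog_pairs(pairs, paths["orthologs"])
    paths["truth"] = out_dir / "truth.tsv"
    write_truth_table(truths, paths["truth"])

    if config is not None:
        paths["manifest"] = out_dir / "manifest.json"
        with open(paths["manifest"], "w", encoding="utf-8", newline="\n") as fh:
            json.dump(config.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return paths
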