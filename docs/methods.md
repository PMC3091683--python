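# Methods

## Problem and model

`spliceortho` decides, for transcripts of 1:1 orthologous gene pairs, which
pairs of transcripts are *iso-orthologs* — the same splicing variant
expressed in both species. Because untranslated regions are highly variable
in length and number and inconsistently annotated, comparison is restricted
to the coding skeleton of each transcript:

- **Coding structure.** Exons with no CDS overlap are dropped; the external
  retained exons are trimmed to their CDS overlap; lengths are listed 5'→3'
  in transcript orientation. Intron phases are cumulative coding length
  mod 3. A CDS boundary falling inside an intron is rejected as a malformed
  annotation at model construction (it would corrupt phase arithmetic); a
  CDS whose exonic length is not a codon multiple is accepted with a logged
  warning, since curated collections genuinely contain such records.
- **Inclusion filter.** A transcript enters the comparison only if its
  parent transcript has ≥ 4 exons and its coding structure has ≥ 2 internal
  fully coding exons. The two conditions deliberately use different exon
  universes: the four-exon condition counts all transcript exons including
  UTR-only ones, while "internal fully coding" is evaluated on the coding
  structure (a coding exon that is neither first nor last and whose whole
  transcript exon lies within the CDS). The texts describing this analysis
  style name the two conditions separately, which implies the two universes;
  this is a documented reading, not the only possible one.
- **Redundancy collapsing.** Within a gene, structures sharing every
  internal coding exon's (size, frame) pair — frame being the phase of the
  exon's preceding intron — are interchangeable for structural comparison.
  One representative is kept: the structure with the greatest total coding
  length (the most informative), ties broken by smallest accession. Curated
  and predicted transcripts are deduplicated separately, and predicted
  structures duplicating a curated signature are dropped; this keeps the
  curated-only candidate set independent of whether predictions were loaded,
  which the monotonicity guarantee below relies on.

## Alignment

Structures are aligned by global dynamic programming over exons
(Needleman-Wunsch on exon lengths) extended with *merge* moves: k ≤ `k_max`
adjacent exons of one structure may align against a single exon of the
other, compared by summed length and penalized `m_merge` per merged intron
boundary. Merges model intron gain/loss, without which one gained intron
would frame-shift the whole column correspondence and make downstream exons
look divergent.

Scoring is deliberately parametric and transparent. Defaults (score units):
`s_max=10` exact-match reward, `w=0.1`/bp length-difference penalty capped
at `d_cap=100` bp (one grossly resized exon should not dominate),
`b_phase=2` bonus when the column's leading intron boundaries carry equal
phases (first-exon columns have no preceding intron and get no bonus),
`g_gap=8` per unaligned exon, `m_merge=5` per merged boundary, `k_max=3`.
The relative order matters more than the numbers: a gap (8) costs more than
a merge boundary (5), so a genuine intron gain/loss is explained by a merge
rather than two gaps; both cost more than moderate length drift, so
near-identical structures align colinearly. Downstream classification uses
the alignment only through (i) best-candidate selection and (ii)
colinearity detection, both stable across any scheme satisfying the
contract properties asserted in the test suite: identity self-alignments
are optimal, scores are symmetric under argument swap, and widening a
length difference never raises the score. All parameters are settable from
a flat `key=value` file (`--scoring`).

Determinism: ties during the DP fill are resolved by fixed move preference
(diagonal, then A-side merges by increasing k, then B-side merges, then
A-gap, then B-gap), so the traceback — and every downstream output — is
unique and byte-reproducible.

An exhaustive enumeration oracle (`enumerate_alignments`) recomputes the
optimum by brute force for structures of ≤ 6 exons; it shares only the
column-score definition with the DP and is used to validate it on random
pairs.

## Classification

For each query, the highest-scoring candidate alignment assigns the type:

- best alignment non-colinear (any merge/gap column) → NONE, regardless of
  exon counts — this operationalizes excluding wrong type assignment due to
  intron gain/loss;
- otherwise ISO1 / ISO2 / ISO3 / NONE per the criteria table in the README,
  with phases compared elementwise for all three criteria. ISO2 is read as
  *each* corresponding exon differing by an element of {0,3,6,9,12,15} with
  at least one nonzero: requiring every exon to differ would make criteria
  1 and 2 non-nested and contradict their decreasing stringency. Note that
  elementwise phase equality already forces every difference except the
  last exon's to be ≡ 0 (mod 3); the criteria algebra test asserts this.

Score ties are broken by curated before predicted, then stronger type, then
smallest accession. Predicted isoforms are candidates only, never queries.
When predicted candidates are enabled, the augmented assignment replaces
the curated-only one **only if strictly stronger** in the ISO1 > ISO2 >
ISO3 > NONE order. A higher-scoring predicted alignment of a weaker type
does not erase an iso-orthology relation already established against a
curated transcript: predictions are supplementary evidence, so "no match"
counts can only shrink when they are added. This monotone rule is a design
choice of this package; a strictly score-driven adjustment could in rare
cases downgrade a type.

Gene-pair categories are the strongest type over the pair's transcript
records in both directions; per-direction gene counts are also emitted,
since a pair can match under different criteria in the two directions. A
pair is skipped (counted, non-fatal) only when a gene is absent from the
input index; a gene whose transcripts are all filtered still yields records
for its partner's queries — they find no candidates and classify NONE,
exactly as a transcript with no comparable counterpart should.

## Synthetic cohorts

The generator emulates the shape of curated mammalian annotation sets:
multi-exon genes (4-12 coding exons), coding exon lengths uniform on
[30, 300] bp, CDS lengths adjusted to whole codons, optional UTR-only exons
(probability 0.3 per side) and 0-150 bp UTR extensions on external coding
exons, both strands equiprobable, 1-4 isoforms per gene, and a configurable
fraction (default 0.25) of partner-species isoforms emitted as PREDICTED.
Species-B genomic layout (chromosome, offsets, intron lengths 80-2000 bp,
strand) is drawn independently of species A so that no downstream result
can depend on coordinates, only on structure.

Each species-A isoform receives a truth label drawn from a configurable
mixture (default uniform over seven families) and a partner constructed as
that label's exact preimage under the classifier: identical structure
(ISO1); 1-3 exons shifted by in-frame amounts ≤ 15 bp (ISO2); an in-frame
internal shift > 15 bp or a last-exon shift outside {0,3,…,15} (ISO3); an
internal exon deleted, an exon split in two, an internal frame-breaking
shift, or a structurally unrelated partner (the four NONE families).
Frame-breaking shifts avoid multiples of 3 by construction, since an
in-frame internal shift can never break phase.

Two generator choices guarantee *unambiguous* truth, not just plausible
truth: isoform coding-exon counts within a gene are pairwise distinct with
spacing ≥ 2, and the unrelated-partner family draws its exon count outside
the gene's count set. Because no perturbation changes an exon count by more
than one, a query can align colinearly only with its intended counterpart;
independently drawn equal-count structures would otherwise be accidentally
phase-compatible with probability (1/3)^(n−1) per pair, polluting the
ground truth. What passing recovery tests therefore shows is that the
pipeline inverts the generative families exactly; it does not certify
behaviour on real annotations, where isoform structures within a gene are
correlated, length distributions are not uniform, and single-exon CDS
overlaps, non-codon CDS lengths and annotation errors occur.

Redundant-set generation realizes one coding structure under n different
UTR configurations (exons, extents, strand, layout); all variants share a
dedup signature by construction.

## Problem sizes and numerics

Default verification sizes: 200 random pairs (≤ 5 exons) for the
DP-vs-enumeration check; a 500-gene-pair cohort (~1250 isoform pairs,
uniform mixture, seed 42 in the test suite) for truth recovery and
monotonicity; 10,000 random colinear pairs for the criteria algebra; 100
redundant sets for deduplication. These sizes give stable percentages while
keeping the whole suite and the acceptance script each under a minute of
compute. Scores are floats; the DP uses exact float comparison for ties
(identical arithmetic on identical inputs) and the enumeration comparison
uses a 1e-9 tolerance. Alignment of empty structures, merges beyond
`k_max`, non-coding transcripts, and CDS boundaries in introns raise typed
errors rather than degrade silently.

## Known limitations

- The alignment scoring is a parametric stand-in, not a reimplementation of
  any published empirical exon-length scoring; absolute scores are not
  comparable across schemes.
- Only 1:1 orthologs are handled; many-to-many groups and paralogs are out
  of scope, as are protein-domain consequences of structural differences.
- Phase comparison is elementwise for all criteria; texts describing these
  criteria do not fully pin down whether phase equality was demanded per
  exon or only where lengths agree, and the elementwise reading is used
  throughout.
- Transcripts mapping to multiple loci are assumed to have been resolved to
  one mapping per accession upstream.
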