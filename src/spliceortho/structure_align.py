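"""Global alignment of coding exon-intron structures with intron gain/loss.

Two coding structures are aligned column-wise by dynamic programming, exactly
as sequences are in Needleman-Wunsch, except that the alignment units are
exons compared by coding length, and an extra *merge* move models intron
gain/loss: up to ``k_max`` adjacent exons of one structure may align against a
single exon of the other, compared by their summed length. Without this move,
a single intron gained or lost since the species split would shift every
downstream column and masquerade as wholesale structural divergence.

The scoring scheme is a transparent parametric one (every constant
configurable). Downstream classification depends on the alignment only
through best-candidate selection and colinearity detection, so any scheme
rewarding equal lengths, preferring phase agreement, and pricing gaps above
merges behaves equivalently; the identity-optimality and symmetry properties
are the contract any replacement scheme must keep.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

from .coding_projection import CodingStructure


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ScoringScheme:
    """Parameters of the structure-alignment score, all in score units.

    s_max     reward for an exact exon-length match (diagonal column).
    w         penalty per bp of length difference.
    d_cap     cap (bp) on the penalized difference, so one grossly resized
              exon cannot dominate the whole alignment.
    b_phase   bonus when both aligned exons are preceded by introns of equal
              phase (only columns where both sides have a preceding intron).
    g_gap     penalty for an unaligned exon.
    m_merge   penalty per merged intron boundary (intron gain/loss move).
    k_max     maximum exons mergeable into one block.
    """

    s_max: float = 10.0
    w: float = 0.1
    d_cap: int = 100
    b_phase: float = 2.0
    g_gap: float = 8.0
    m_merge: float = 5.0
    k_max: int = 3

    def __post_init__(self) -> None:
        if self.s_max <= 0:
            raise ValueError("s_max must be positive")
        if self.w < 0:
            raise ValueError("w must be non-negative")
        if self.g_gap <= 0 or self.m_merge <= 0:
            raise ValueError("g_gap and m_merge must be positive")
        if self.k_max < 2:
            raise ValueError("k_max must be at least 2")
        if self.d_cap < 0:
            raise ValueError("d_cap must be non-negative")

    def with_overrides(self, **kwargs) -> "ScoringScheme":
        return replace(self, **kwargs)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ScoringScheme":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown scoring parameters: {sorted(unknown)}")
        typed = {
            k: (int(v) if k in ("d_cap", "k_max") else float(v))
            for k, v in mapping.items()
        }
        return cls(**typed)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScoringScheme":
        """Load overrides from a flat ``key=value`` text file."""
        mapping: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line_no, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"line {line_no}: expected key=value")
                key, value = (part.strip() for part in line.split("=", 1))
                mapping[key] = value
        return cls.from_mapping(mapping)


class ColumnKind(Enum):
    DIAG = "DIAG"
    GAP_A = "GAP_A"
    GAP_B = "GAP_B"
    MERGE_A = "MERGE_A"  # k exons of A vs one exon of B
    MERGE_B = "MERGE_B"  # one exon of A vs k exons of B


@dataclass(frozen=True)
class AlignColumn:
    """One alignment column; ``a_indices``/``b_indices`` are 0-based exon indices."""

    kind: ColumnKind
    a_indices: tuple[int, ...]
    b_indices: tuple[int, ...]
    score: float


@dataclass(frozen=True)
class StructureAlignment:
    columns: tuple[AlignColumn, ...]
    score: float

    @property
    def is_colinear(self) -> bool:
        """True iff every column is a one-to-one exon correspondence."""
        return all(c.kind is ColumnKind.DIAG for c in self.columns)


def column_score(
    kind: ColumnKind,
    lengths_a: list[int] | tuple[int, ...],
    length_b: int | None,
    phase_ok: bool,
    scheme: ScoringScheme,
) -> float:
    """Score one alignment column.

    DIAG: ``s_max - w*min(|la-lb|, d_cap) (+ b_phase)``. MERGE of *k* exons:
    the same formula on the summed merged length, minus ``m_merge*(k-1)``.
    GAP: ``-g_gap``.
    """
    if kind in (ColumnKind.GAP_A, ColumnKind.GAP_B):
        return -scheme.g_gap
    if kind is ColumnKind.DIAG:
        if len(lengths_a) != 1:
            raise AlignmentError("DIAG column takes exactly one length per side")
        k = 1
    else:
        k = len(lengths_a)
        if not 2 <= k <= scheme.k_max:
            raise AlignmentError(
                f"merge of {k} exons outside allowed range 2..{scheme.k_max}"
            )
    diff = abs(sum(lengths_a) - int(length_b))
    score = scheme.s_max - scheme.w * min(diff, scheme.d_cap)
    if phase_ok:
        score += scheme.b_phase
    score -= scheme.m_merge * (k - 1)
    return score


def _phase_ok(
    a: CodingStructure, b: CodingStructure, a_lead: int, b_lead: int
) -> bool:
    """Phase agreement at a column's leading intron boundary.

    Requires both leading exons to have a preceding intron within the CDS
    (first-exon columns carry no phase bonus).
    """
    if a_lead < 1 or b_lead < 1:
        return False
    return a.phases[a_lead - 1] == b.phases[b_lead - 1]


def align_structures(
    a: CodingStructure, b: CodingStructure, scheme: ScoringScheme | None = None
) -> StructureAlignment:
    """Maximum-score global alignment of two coding structures.

    Every exon of both structures is consumed exactly once, in order. Ties are
    broken deterministically by move preference DIAG > MERGE_A > MERGE_B
    (smaller merge first) > GAP_A > GAP_B, applied during the DP fill so the
    traceback is unique.
    """
    scheme = scheme or ScoringScheme()
    la, lb = a.coding_lengths, b.coding_lengths
    n, m = len(la), len(lb)
    if n == 0 or m == 0:
        raise AlignmentError("cannot align an empty structure")

    NEG = float("-inf")
    score = [[NEG] * (m + 1) for _ in range(n + 1)]
    back: list[list[AlignColumn | None]] = [[None] * (m + 1) for _ in range(n + 1)]
    score[0][0] = 0.0

    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best = NEG
            best_col: AlignColumn | None = None

            def consider(prev_i: int, prev_j: int, col: AlignColumn) -> None:
                nonlocal best, best_col
                prev = score[prev_i][prev_j]
                if prev == NEG:
                    return
                cand = prev + col.score
                if cand > best:  # strict: earlier (preferred) moves win ties
                    best, best_col = cand, col

            if i >= 1 and j >= 1:
                ok = _phase_ok(a, b, i - 1, j - 1)
                s = column_score(ColumnKind.DIAG, [la[i - 1]], lb[j - 1], ok, scheme)
                consider(i - 1, j - 1, AlignColumn(ColumnKind.DIAG, (i - 1,), (j - 1,), s))
            for k in range(2, scheme.k_max + 1):
                if i >= k and j >= 1:
                    ok = _phase_ok(a, b, i - k, j - 1)
                    merged = list(la[i - k : i])
                    s = column_score(ColumnKind.MERGE_A, merged, lb[j - 1], ok, scheme)
                    consider(
                        i - k,
                        j - 1,
                        AlignColumn(
                            ColumnKind.MERGE_A, tuple(range(i - k, i)), (j - 1,), s
                        ),
                    )
            for k in range(2, scheme.k_max + 1):
                if j >= k and i >= 1:
                    ok = _phase_ok(a, b, i - 1, j - k)
                    merged = list(lb[j - k : j])
                    s = column_score(ColumnKind.MERGE_B, merged, la[i - 1], ok, scheme)
                    consider(
                        i - 1,
                        j - k,
                        AlignColumn(
                            ColumnKind.MERGE_B, (i - 1,), tuple(range(j - k, j)), s
                        ),
                    )
            if i >= 1:
                s = column_score(ColumnKind.GAP_A, [la[i - 1]], None, False, scheme)
                consider(i - 1, j, AlignColumn(ColumnKind.GAP_A, (i - 1,), (), s))
            if j >= 1:
                s = column_score(ColumnKind.GAP_B, [], lb[j - 1], False, scheme)
                consider(i, j - 1, AlignColumn(ColumnKind.GAP_B, (), (j - 1,), s))

            score[i][j] = best
            back[i][j] = best_col

    columns: list[AlignColumn] = []
    i, j = n, m
    while i > 0 or j > 0:
        col = back[i][j]
        assert col is not None
        columns.append(col)
        i -= len(col.a_indices)
        j -= len(col.b_indices)
    columns.reverse()
    return StructureAlignment(columns=tuple(columns), score=score[n][m])


def enumerate_alignments(
    a: CodingStructure,
    b: CodingStructure,
    scheme: ScoringScheme | None = None,
    max_exons: int = 6,
) -> float:
    """Best global alignment score by exhaustive enumeration (test oracle).

    Recursively enumerates every global alignment (merges up to ``k_max``)
    without memoization; intended only for small structures.
    """
    scheme = scheme or ScoringScheme()
    la, lb = a.coding_lengths, b.coding_lengths
    n, m = len(la), len(lb)
    if n == 0 or m == 0:
        raise AlignmentError("cannot align an empty structure")
    if n > max_exons or m > max_exons:
        raise AlignmentError(f"structure too large for enumeration (> {max_exons})")

    def best_from(i: int, j: int) -> float:
        if i == n and j == m:
            return 0.0
        options: list[float] = []
        if i < n and j < m:
            ok = _phase_ok(a, b, i, j)
            options.append(
                column_score(ColumnKind.DIAG, [la[i]], lb[j], ok, scheme)
                + best_from(i + 1, j + 1)
            )
            for k in range(2, scheme.k_max + 1):
                if i + k <= n:
                    options.append(
                        column_score(
                            ColumnKind.MERGE_A,
                            list(la[i : i + k]),
                            lb[j],
                            _phase_ok(a, b, i, j),
                            scheme,
                        )
                        + best_from(i + k, j + 1)
                    )
                if j + k <= m:
                    options.append(
                        column_score(
                            ColumnKind.MERGE_B,
                            list(lb[j : j + k]),
                            la[i],
                            _phase_ok(a, b, i, j),
                            scheme,
                        )
                        + best_from(i + 1, j + k)
                    )
        if i < n:
            options.append(-scheme.g_gap + best_from(i + 1, j))
        if j < m:
            options.append(-scheme.g_gap + best_from(i, j + 1))
        return max(options)

    return best_from(0, 0)


def render_alignment(
    a: CodingStructure, b: CodingStructure, alignment: StructureAlignment
) -> str:
    """Plain-text rendering: two rows of exon lengths with |, -, ~ markers.

    ``|`` one-to-one column, ``~`` merge column (intron gain/loss), ``-`` gap.
    """
    row_a, row_b, marks = [], [], []
    for col in alignment.columns:
        cell_a = "+".join(str(a.coding_lengths[i]) for i in col.a_indices) or "."
        cell_b = "+".join(str(b.coding_lengths[j]) for j in col.b_indices) or "."
        mark = {
            ColumnKind.DIAG: "|",
            ColumnKind.MERGE_A: "~",
            ColumnKind.MERGE_B: "~",
            ColumnKind.GAP_A: "-",
            ColumnKind.GAP_B: "-",
        }[col.kind]
        width = max(len(cell_a), len(cell_b))
        row_a.append(cell_a.rjust(width))
        row_b.append(cell_b.rjust(width))
        marks.append(mark.rjust(width))
    return (
        f"{a.accession}: {' '.join(row_a)}\n"
        f"{'':{len(a.accession)}}  {' '.join(marks)}\n"
        f"{b.accession}: {' '.join(row_b)}  score={alignment.score:g}"
    )
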