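"""Hits, pseudo-blocks and blocks.

A *hit* is a single alignment column; its dimension ``d`` counts the symbols
(gap included, as the 21st residue) that occur exactly once in the column.
The rows carrying those singletons are the hit's *exception rows*.

A hit is greedily extended one column at a time, left and right, into its
*pseudo-block*: an adjacent column is admitted iff (1) its own exception
count is at most ``d``, (2) its exceptions fall within the hit's exception
rows, and (3) among non-exception rows the word partition of the extended
interval still equals the residue partition of the hit column (rows sharing
a word share the hit residue, and vice versa).  The three conditions are
local, so the maximal extension is unique and order-independent.

*Blocks* are carved out of a pseudo-block by removing columns that are at
least 40% gapped (gap fraction computed over the rows carrying words with at
least two occurrences); each maximal remaining run of columns is kept only
if it still has exactly the hit's exceptions in the same rows and the same
word partition.  Blocks may overlap, and the block of a hit need not contain
the hit column itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .msa import GAP, Msa

#: gap thresholds, strict as printed: keep block column iff gap fraction < 0.40,
#: drop a positions-mode hit iff gap fraction >= 0.60
BLOCK_GAP_FRACTION = 0.40
HIT_GAP_FRACTION = 0.60

#: default maximum number of exceptions (the figures use dimensions 0, 1, 2)
DEFAULT_MAX_EXCEPTIONS = 2


@dataclass(frozen=True)
class Hit:
    """One alignment column seen as the seed of a block."""

    position: int  # 1-based column
    dimension: int
    exception_rows: frozenset[int]

    def __post_init__(self) -> None:
        assert 0 <= self.dimension <= 21
        assert len(self.exception_rows) == self.dimension


@dataclass(frozen=True)
class Block:
    """A maximal run of columns whose word distribution matches its hit's.

    ``word_table`` maps each word (gaps included) to the set of rows carrying
    it; exactly ``dimension`` rows carry single-occurrence words.
    """

    start: int  # 1-based inclusive
    end: int
    dimension: int
    hit_positions: frozenset[int]
    word_table: tuple[tuple[str, frozenset[int]], ...]
    exception_rows: frozenset[int]

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def label(self) -> str:
        span = str(self.start) if self.start == self.end else f"{self.start}-{self.end}"
        return f"{span}:{self.dimension}"

    def words(self, row_filter=None) -> dict[str, frozenset[int]]:
        if row_filter is None:
            return dict(self.word_table)
        rf = set(row_filter)
        out = {}
        for w, rows in self.word_table:
            kept = rows & rf
            if kept:
                out[w] = frozenset(kept)
        return out


@dataclass(frozen=True)
class PseudoBlock:
    """Maximal extension of a hit before the gap-column filter."""

    start: int
    end: int
    hit: Hit


def _column_word_rows(msa: Msa, start: int, end: int) -> dict[str, list[int]]:
    """Word -> rows over 1-based inclusive interval [start, end]."""
    table: dict[str, list[int]] = {}
    for r in range(msa.n):
        table.setdefault(msa.word(r, start, end), []).append(r)
    return table


def _exceptions(table: dict[str, list[int]]) -> set[int]:
    return {rows[0] for rows in table.values() if len(rows) == 1}


def _partition(table: dict[str, list[int]], exclude: set[int]) -> frozenset[frozenset[int]]:
    """Partition of the rows not in ``exclude`` induced by shared words."""
    groups = []
    for rows in table.values():
        kept = frozenset(r for r in rows if r not in exclude)
        if kept:
            groups.append(kept)
    return frozenset(groups)


def hit_dimension(msa: Msa, position: int) -> Hit:
    """Dimension and exception rows of one column (gap = 21st residue)."""
    if not 1 <= position <= msa.length:
        raise IndexError(f"column {position} outside 1..{msa.length}")
    table = _column_word_rows(msa, position, position)
    exc = _exceptions(table)
    return Hit(position, len(exc), frozenset(exc))


def _column_ok(msa: Msa, position: int, d: int, exc_rows: frozenset[int]) -> bool:
    """Extension conditions (1) and (2) for a single adjacent column."""
    col = hit_dimension(msa, position)
    return col.dimension <= d and col.exception_rows <= exc_rows


def extend_hit(msa: Msa, hit: Hit) -> PseudoBlock:
    """Greedy maximal extension of a hit; left/right order is immaterial.

    Condition (3) holds vacuously when every row is an exception.
    """
    target = _partition(_column_word_rows(msa, hit.position, hit.position), set(hit.exception_rows))
    start = end = hit.position

    def admits(s: int, e: int) -> bool:
        table = _column_word_rows(msa, s, e)
        return _partition(table, set(hit.exception_rows)) == target

    changed = True
    while changed:
        changed = False
        if start > 1 and _column_ok(msa, start - 1, hit.dimension, hit.exception_rows):
            if admits(start - 1, end):
                start -= 1
                changed = True
        if end < msa.length and _column_ok(msa, end + 1, hit.dimension, hit.exception_rows):
            if admits(start, end + 1):
                end += 1
                changed = True
    return PseudoBlock(start, end, hit)


def _make_block(msa: Msa, start: int, end: int, hit: Hit,
                target) -> Block | None:
    """Validate a candidate column run against the hit's word distribution."""
    table = _column_word_rows(msa, start, end)
    if _exceptions(table) != set(hit.exception_rows):
        return None  # exception count or localization changed
    if _partition(table, set(hit.exception_rows)) != target:
        return None  # word distribution no longer matches the hit's
    words = tuple(sorted((w, frozenset(rows)) for w, rows in table.items()))
    return Block(
        start=start,
        end=end,
        dimension=hit.dimension,
        hit_positions=frozenset({hit.position}),
        word_table=words,
        exception_rows=hit.exception_rows,
    )


def pseudo_block_to_blocks(pb: PseudoBlock, msa: Msa) -> list[Block]:
    """Split a pseudo-block on >=40%-gapped columns and re-validate each run.

    The gap fraction of a column is computed over the rows that carry words
    with at least two occurrences in the pseudo-block.  A run survives only
    if it preserves the number of exceptions, their rows, and the word
    partition of the hit; a pseudo-block may thus yield 0, 1 or several
    blocks.
    """
    hit = pb.hit
    table = _column_word_rows(msa, pb.start, pb.end)
    supported = [r for r in range(msa.n) if r not in _exceptions(table)]
    target = _partition(_column_word_rows(msa, hit.position, hit.position), set(hit.exception_rows))

    def gap_ok(position: int) -> bool:
        if not supported:
            return True  # all rows are exceptions: no words to test
        col = msa.column(position)
        gaps = sum(1 for r in supported if col[r] == GAP)
        return gaps / len(supported) < BLOCK_GAP_FRACTION

    blocks = []
    run_start = None
    for pos in range(pb.start, pb.end + 2):
        if pos <= pb.end and gap_ok(pos):
            if run_start is None:
                run_start = pos
        elif run_start is not None:
            blk = _make_block(msa, run_start, pos - 1, hit, target)
            if blk is not None:
                blocks.append(blk)
            run_start = None
    return blocks


def enumerate_blocks(msa: Msa, max_exceptions: int = DEFAULT_MAX_EXCEPTIONS) -> list[Block]:
    """All blocks from hits of dimension at most ``max_exceptions``.

    Duplicate blocks (same interval; the word table and dimension follow from
    it) are merged with their hit positions pooled.  Output is sorted by
    (start, end, dimension).
    """
    found: dict[tuple[int, int, int], Block] = {}
    for pos in range(1, msa.length + 1):
        hit = hit_dimension(msa, pos)
        if hit.dimension > max_exceptions:
            continue
        pb = extend_hit(msa, hit)
        for blk in pseudo_block_to_blocks(pb, msa):
            key = (blk.start, blk.end, blk.dimension)
            if key in found:
                prev = found[key]
                found[key] = Block(
                    prev.start,
                    prev.end,
                    prev.dimension,
                    prev.hit_positions | blk.hit_positions,
                    prev.word_table,
                    prev.exception_rows,
                )
            else:
                found[key] = blk
    return [found[k] for k in sorted(found)]


def position_hits(msa: Msa, max_exceptions: int = DEFAULT_MAX_EXCEPTIONS) -> list[Hit]:
    """Hits for positions-mode scoring: d <= D and gap fraction < 60%."""
    hits = []
    for pos in range(1, msa.length + 1):
        col = msa.column(pos)
        if col.count(GAP) / msa.n >= HIT_GAP_FRACTION:
            continue
        hit = hit_dimension(msa, pos)
        if hit.dimension <= max_exceptions:
            hits.append(hit)
    return hits


def hit_to_block(msa: Msa, hit: Hit) -> Block:
    """View a single column as a width-1 block (positions-mode scoring)."""
    table = _column_word_rows(msa, hit.position, hit.position)
    words = tuple(sorted((w, frozenset(rows)) for w, rows in table.items()))
    return Block(
        start=hit.position,
        end=hit.position,
        dimension=hit.dimension,
        hit_positions=frozenset({hit.position}),
        word_table=words,
        exception_rows=hit.exception_rows,
    )


def block_random_probability(n: int, counts) -> float:
    """Probability that a uniform word assignment realizes these counts.

    ``counts`` are the occurrence numbers (each >= 2, decreasing order) of
    the w distinguished words of a block over ``n`` sequences.  Rows beyond
    ``sum(counts)`` are exception rows, set aside; each remaining row draws
    one of the w words uniformly and the event is that word i occurs exactly
    ``counts[i]`` times: multinomial(n'; k_1..k_w) / w**n' with
    n' = sum(counts).
    """
    counts = list(counts)
    if any(k < 2 for k in counts):
        raise ValueError("every word must occur at least twice")
    if list(counts) != sorted(counts, reverse=True):
        raise ValueError("occurrence counts must be in decreasing order")
    total = sum(counts)
    if total > n:
        raise ValueError(f"occurrences sum to {total} > {n} sequences")
    w = len(counts)
    n_eff = total
    coeff = math.factorial(n_eff)
    for k in counts:
        coeff //= math.factorial(k)
    return coeff / w**n_eff


def blocks_to_tsv(blocks, path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\td\tn_hits\thit_positions\tn_words\twords\texception_rows\n")
        for b in blocks:
            words = ";".join(w for w, _ in b.word_table)
            hits = ",".join(str(p) for p in sorted(b.hit_positions))
            exc = ",".join(str(r) for r in sorted(b.exception_rows))
            fh.write(
                f"{b.start}\t{b.end}\t{b.dimension}\t{len(b.hit_positions)}\t{hits}\t"
                f"{len(b.word_table)}\t{words}\t{exc}\n"
            )
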