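"""Alignment data model, I/O and per-column summary statistics.

The central object is :class:`Msa`, an immutable multiple sequence alignment
over the 20 amino acids plus a single canonical gap symbol.  Both ``-`` and
``.`` are accepted on input and stored as :data:`GAP`.  All user-facing column
coordinates are 1-based; internal indexing is 0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import AlignIO

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: gap counts as the 21st residue throughout
ALPHABET = AMINO_ACIDS + GAP
ALPHABET_SIZE = 21

# 8-letter physico-chemical alphabet: hydrophobic, charged -, charged +,
# aromatic, polar, and C/G/P kept as special classes.
_PC_CLASSES = {
    "V": "VILMFWA",
    "D": "DE",
    "K": "KR",
    "Y": "YH",
    "N": "NSTQ",
    "C": "C",
    "G": "G",
    "P": "P",
}
PHYSICO_CHEMICAL_MAP = {aa: cls for cls, members in _PC_CLASSES.items() for aa in members}
PHYSICO_CHEMICAL_MAP[GAP] = GAP


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, duplicate ids, empty file...)."""


@dataclass(frozen=True)
class PositionProfile:
    """Per-column summary: identical-pair fraction and information content."""

    position: int  # 1-based column
    identity: float
    information_content: float


@dataclass(frozen=True)
class Msa:
    """An alignment of ``N`` rows of identical length ``L``.

    Rows are upper-case strings over the 21-letter alphabet (gap included);
    ids are unique.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in count")
        if len(self.rows) < 2:
            raise AlignmentError("an alignment needs at least 2 sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        if next(iter(lengths)) == 0:
            raise AlignmentError("alignment has zero columns")
        if len(set(self.ids)) != len(self.ids):
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dup}")
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - set(ALPHABET)
            if bad:
                raise AlignmentError(f"row {rid!r} contains non-residue symbols {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def column(self, position: int) -> str:
        """Column as a string of N symbols; ``position`` is 1-based."""
        if not 1 <= position <= self.length:
            raise IndexError(f"column {position} outside 1..{self.length}")
        j = position - 1
        return "".join(row[j] for row in self.rows)

    def word(self, row: int, start: int, end: int) -> str:
        """Subword of row ``row`` over 1-based inclusive columns [start, end]."""
        return self.rows[row][start - 1 : end]

    def subset(self, keep_ids) -> "Msa":
        keep = set(keep_ids)
        pairs = [(i, r) for i, r in zip(self.ids, self.rows) if i in keep]
        return Msa(tuple(p[0] for p in pairs), tuple(p[1] for p in pairs))


def _normalize_row(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def from_sequences(ids, seqs) -> Msa:
    """Build an :class:`Msa` from raw id/sequence pairs, normalizing symbols."""
    return Msa(tuple(ids), tuple(_normalize_row(s) for s in seqs))


def read_alignment(path, fmt: str = "fasta") -> Msa:
    """Read a FASTA or Stockholm alignment into an :class:`Msa`.

    Gap symbols ``.`` and ``-`` are both accepted and canonicalized;
    residues are upper-cased.
    """
    if fmt not in {"fasta", "stockholm"}:
        raise ValueError(f"unsupported alignment format {fmt!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        # Bio raises ValueError both for empty files and ragged records
        raise AlignmentError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(aln) == 0:
        raise AlignmentError(f"empty alignment in {path}")
    return from_sequences([rec.id for rec in aln], [str(rec.seq) for rec in aln])


def write_fasta(msa: Msa, path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")


def column_identity(column: str) -> float:
    """Fraction of identical unordered symbol pairs in one column.

    A gap-gap pair counts as identical; gap-residue does not (the gap is
    treated as the 21st residue).
    """
    n = len(column)
    if n < 2:
        raise AlignmentError("identity needs at least 2 sequences")
    counts: dict[str, int] = {}
    for ch in column:
        counts[ch] = counts.get(ch, 0) + 1
    same = sum(c * (c - 1) // 2 for c in counts.values())
    return same / (n * (n - 1) // 2)


def column_information_content(column: str) -> float:
    """Normalized Shannon entropy of the column's symbol frequencies.

    IC = -sum f ln f / ln 21, with the gap as 21st symbol.  0 means a fully
    conserved column; 1 the uniform distribution over the full alphabet.
    """
    n = len(column)
    counts: dict[str, int] = {}
    for ch in column:
        counts[ch] = counts.get(ch, 0) + 1
    h = -sum((c / n) * math.log(c / n) for c in counts.values())
    return h / math.log(ALPHABET_SIZE)


def percent_identity(msa: Msa) -> tuple[list[PositionProfile], float]:
    """Per-column profiles and the alignment's average percentage of identity.

    The API is the arithmetic mean over all columns of the identical-pair
    fraction (number of identical residue pairs in the column divided by
    N(N-1)/2).
    """
    profiles = []
    for pos in range(1, msa.length + 1):
        col = msa.column(pos)
        profiles.append(
            PositionProfile(pos, column_identity(col), column_information_content(col))
        )
    api = sum(p.identity for p in profiles) / len(profiles)
    return profiles, api


def information_content(msa: Msa) -> list[float]:
    """Per-column normalized entropy (0 = fully conserved)."""
    return [column_information_content(msa.column(p)) for p in range(1, msa.length + 1)]


def reduce_alphabet(msa: Msa) -> Msa:
    """Recode every residue into the 8-letter physico-chemical alphabet.

    V=hydrophobic(VILMFWA), D=negative(DE), K=positive(KR), Y=aromatic(YH),
    N=polar(NSTQ); C, G and P stay themselves; gaps are preserved.
    """
    rows = []
    for rid, row in zip(msa.ids, msa.rows):
        try:
            rows.append("".join(PHYSICO_CHEMICAL_MAP[ch] for ch in row))
        except KeyError as exc:
            raise AlignmentError(f"row {rid!r}: unknown residue {exc.args[0]!r}") from exc
    return Msa(msa.ids, tuple(rows))


def profiles_to_tsv(profiles, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tidentity\tinformation_content\n")
        for p in profiles:
            fh.write(f"{p.position}\t{p.identity:.6f}\t{p.information_content:.6f}\n")
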