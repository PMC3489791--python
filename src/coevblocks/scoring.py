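"""Comparison score S and tree-recursive correlated-distribution score C.

For two blocks b1 (words a_i) and b2 (words b_j) over a retained row set of
size N, the comparison score of b2 with respect to b1 is

    S(b2|b1) = sum_i (n_i/N) * (1/m_i) * sum_j (n_ij/n_i)

where n_i counts rows carrying a_i, n_ij rows carrying both a_i and b_j, and
m_i the number of distinct b2-words co-occurring with a_i.  S = 1 exactly
when every word of b1 pairs with a single word of b2; S is not symmetric.

The correlated-distribution score aggregates S over every subtree of the
sequence distance tree:  C(leaf) = 1 and, for a node with immediate subtrees
T1, T2 of n1 and n2 leaves,

    C(T) = ( S(T) + (n1*C(T1) + n2*C(T2)) / (n1+n2) ) / 2

with S(T) computed on T's leaves only.  Rows that are exceptions of either
block are removed, and the tree pruned to the remaining rows, before the
recursion starts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .blocks import Block
from .msa import Msa
from .phylo import TreeNode, prune_tree


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class PairCounts:
    """Co-occurrence counts of b2-words conditioned on b1-words.

    ``n`` maps each b1-word to its row count; ``n_joint`` maps (a_i, b_j) to
    the number of rows carrying both; ``m`` maps a_i to the number of
    distinct co-occurring b2-words.
    """

    total: int
    n: dict[str, int]
    n_joint: dict[tuple[str, str], int]
    m: dict[str, int]


def _row_words(block: Block) -> dict[int, str]:
    out: dict[int, str] = {}
    for word, rows in block.word_table:
        for r in rows:
            out[r] = word
    return out


def retained_rows(b1: Block, b2: Block, n_rows: int) -> list[int]:
    """Rows that are non-exception in both blocks."""
    excluded = set(b1.exception_rows) | set(b2.exception_rows)
    return [r for r in range(n_rows) if r not in excluded]


def pair_counts(b1: Block, b2: Block, rows) -> PairCounts:
    rows = sorted(rows)
    if not rows:
        raise ScoringError("empty retained row set")
    w1 = _row_words(b1)
    w2 = _row_words(b2)
    n: dict[str, int] = {}
    joint: dict[tuple[str, str], int] = {}
    for r in rows:
        a, b = w1[r], w2[r]
        n[a] = n.get(a, 0) + 1
        joint[(a, b)] = joint.get((a, b), 0) + 1
    m: dict[str, int] = {}
    for (a, _b), _c in joint.items():
        m[a] = m.get(a, 0) + 1
    return PairCounts(len(rows), dict(sorted(n.items())), dict(sorted(joint.items())), m)


def comparison_score(b1: Block, b2: Block, rows) -> float:
    """S(b2|b1) over the given retained rows."""
    pc = pair_counts(b1, b2, rows)
    score = 0.0
    for a, n_a in pc.n.items():
        inner = sum(c for (x, _), c in pc.n_joint.items() if x == a) / n_a
        score += (n_a / pc.total) * (1.0 / pc.m[a]) * inner
    return score


def correlation_score(tree: TreeNode, b1: Block, b2: Block, ids) -> float:
    """C(b2|b1) at the root of ``tree``.

    ``tree`` must already be pruned to the retained rows of the pair; its
    leaf labels are looked up in ``ids`` (the alignment's row ids) to recover
    row indices.
    """
    index = {rid: r for r, rid in enumerate(ids)}
    leaves = tree.leaves()
    missing = [l for l in leaves if l not in index]
    if missing:
        raise ScoringError(f"tree leaves not in alignment: {missing}")
    excluded = set(b1.exception_rows) | set(b2.exception_rows)
    bad = [l for l in leaves if index[l] in excluded]
    if bad:
        raise ScoringError(f"tree contains exception rows of the pair: {bad}")

    def rec(node: TreeNode) -> tuple[list[int], float]:
        if node.is_leaf:
            return [index[node.name]], 1.0
        (rows1, c1), (rows2, c2) = rec(node.children[0]), rec(node.children[1])
        rows = rows1 + rows2
        n1, n2 = len(rows1), len(rows2)
        s = comparison_score(b1, b2, rows)
        return rows, (s + (n1 * c1 + n2 * c2) / (n1 + n2)) / 2.0

    return rec(tree)[1]


@dataclass(frozen=True)
class ScoreMatrix:
    """All-pairs correlated-distribution scores.

    ``c[i][j]`` is C(block j | block i) at the root of the tree pruned to the
    rows retained for the pair; ``nan`` marks pairs whose retained row set
    has fewer than two rows.  ``sym`` is the symmetrized view (max of the two
    directions) consumed by clustering.
    """

    blocks: tuple[Block, ...]
    c: tuple[tuple[float, ...], ...]

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.blocks]

    @property
    def size(self) -> int:
        return len(self.blocks)

    @property
    def sym(self) -> tuple[tuple[float, ...], ...]:
        k = self.size
        out = []
        for i in range(k):
            row = []
            for j in range(k):
                a, b = self.c[i][j], self.c[j][i]
                row.append(float("nan") if math.isnan(a) or math.isnan(b) else max(a, b))
            out.append(tuple(row))
        return tuple(out)


def _index_tree(tree: TreeNode, index: dict[str, int]):
    """Nested (left, right) tuples with int row indices at the leaves."""
    if tree.is_leaf:
        return index[tree.name]
    left, right = tree.children
    return (_index_tree(left, index), _index_tree(right, index))


def _pair_scores(itree, code1, code2, w1: int, w2: int) -> tuple[float, float]:
    """C(b2|b1) and C(b1|b2) in one bottom-up pass.

    Carries the joint word-count table (a flat w1*w2 list) up the tree so S
    in both directions is recomputed at every internal node in O(w1*w2).
    """

    def rec(node):
        if isinstance(node, int):
            table = [0] * (w1 * w2)
            table[code1[node] * w2 + code2[node]] = 1
            return table, 1, 1.0, 1.0
        t1, n1, c12a, c21a = rec(node[0])
        t2, n2, c12b, c21b = rec(node[1])
        table = [x + y for x, y in zip(t1, t2)]
        n = n1 + n2
        s12 = 0.0
        for i in range(w1):
            seg = table[i * w2 : (i + 1) * w2]
            n_i = sum(seg)
            if n_i:
                s12 += (n_i / n) / sum(1 for v in seg if v)
        s21 = 0.0
        for j in range(w2):
            col = table[j :: w2]
            n_j = sum(col)
            if n_j:
                s21 += (n_j / n) / sum(1 for v in col if v)
        c12 = (s12 + (n1 * c12a + n2 * c12b) / n) / 2.0
        c21 = (s21 + (n1 * c21a + n2 * c21b) / n) / 2.0
        return table, n, c12, c21

    _, _, c12, c21 = rec(itree)
    return c12, c21


def score_matrix(msa: Msa, tree: TreeNode, blocks) -> ScoreMatrix:
    """Score every ordered pair of blocks, pruning the tree per pair.

    Blocks found at different exception counts are scored against each other
    like any other pair.  Pairs retaining fewer than two rows get ``nan``.
    """
    blocks = tuple(blocks)
    k = len(blocks)
    for b in blocks:
        if b.end > msa.length:
            raise IndexError(f"block {b.label} outside alignment of length {msa.length}")
    index = {rid: r for r, rid in enumerate(msa.ids)}
    tree_leaves = set(tree.leaves())
    if set(msa.ids) != tree_leaves:
        raise ScoringError("tree leaves do not match alignment ids")

    row_words = [_row_words(b) for b in blocks]
    word_order = [{w: i for i, (w, _) in enumerate(b.word_table)} for b in blocks]
    codes = [[word_order[bi][row_words[bi][r]] for r in range(msa.n)] for bi in range(k)]

    pruned_cache: dict[frozenset, object] = {}

    def pruned_index_tree(rows: frozenset):
        if rows not in pruned_cache:
            keep = {msa.ids[r] for r in rows}
            pruned_cache[rows] = _index_tree(prune_tree(tree, keep), index)
        return pruned_cache[rows]

    nan = float("nan")
    c = [[nan] * k for _ in range(k)]
    for i in range(k):
        c[i][i] = 1.0
        for j in range(i + 1, k):
            rows = frozenset(retained_rows(blocks[i], blocks[j], msa.n))
            if len(rows) < 2:
                continue
            itree = pruned_index_tree(rows)
            w1 = len(blocks[i].word_table)
            w2 = len(blocks[j].word_table)
            cij, cji = _pair_scores(itree, codes[i], codes[j], w1, w2)
            c[i][j] = cij
            c[j][i] = cji
    return ScoreMatrix(blocks, tuple(tuple(row) for row in c))


def write_matrix_tsv(matrix: ScoreMatrix, path, symmetrized: bool = False) -> None:
    values = matrix.sym if symmetrized else matrix.c
    labels = matrix.labels
    with open(path, "w") as fh:
        fh.write("block\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, values):
            cells = ["NA" if math.isnan(v) else f"{v:.6f}" for v in row]
            fh.write(lab + "\t" + "\t".join(cells) + "\n")
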