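"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's incremental/greedy code paths: blocks
are found by scanning every interval against the definitions directly, the
correlation score is assembled by explicit enumeration of all subtrees, and
the random-block probability is obtained by exhaustive enumeration or Monte
Carlo over word assignments.
"""

from __future__ import annotations

import itertools
import random
from collections import Counter

from coevblocks.msa import GAP, Msa
from coevblocks.phylo import TreeNode

# ---------------------------------------------------------------- blocks


def _words(msa: Msa, start: int, end: int) -> list[str]:
    return [row[start - 1 : end] for row in msa.rows]


def _partition_of(words, exclude: set[int]) -> set[frozenset]:
    groups: dict[str, set[int]] = {}
    for r, w in enumerate(words):
        if r not in exclude:
            groups.setdefault(w, set()).add(r)
    return {frozenset(g) for g in groups.values()}


def _interval_valid(msa: Msa, start: int, end: int, hit_pos: int, d: int,
                    exc_rows: frozenset) -> bool:
    """Extension validity of [start, end] for the given hit, checked whole."""
    for col in range(start, end + 1):
        cw = _words(msa, col, col)
        singles = {r for r, w in enumerate(cw) if Counter(cw)[w] == 1}
        if len(singles) > d or not singles <= set(exc_rows):
            return False
    hit_part = _partition_of(_words(msa, hit_pos, hit_pos), set(exc_rows))
    return _partition_of(_words(msa, start, end), set(exc_rows)) == hit_part


def brute_force_blocks(msa: Msa, max_exceptions: int) -> set[tuple[int, int, int]]:
    """(start, end, d) triples of every block, by exhaustive interval scan."""
    out: set[tuple[int, int, int]] = set()
    for pos in range(1, msa.length + 1):
        col = _words(msa, pos, pos)
        counts = Counter(col)
        exc = frozenset(r for r, w in enumerate(col) if counts[w] == 1)
        d = len(exc)
        if d > max_exceptions:
            continue
        # maximal valid interval containing the hit = the pseudo-block
        candidates = [
            (s, e)
            for s in range(1, pos + 1)
            for e in range(pos, msa.length + 1)
            if _interval_valid(msa, s, e, pos, d, exc)
        ]
        s_pb, e_pb = max(candidates, key=lambda se: se[1] - se[0])
        # gap filter over rows with repeated words, then re-validate runs
        pb_words = _words(msa, s_pb, e_pb)
        wc = Counter(pb_words)
        supported = [r for r, w in enumerate(pb_words) if wc[w] >= 2]
        kept_cols = []
        for c in range(s_pb, e_pb + 1):
            colw = _words(msa, c, c)
            if not supported:
                kept_cols.append(c)
                continue
            gaps = sum(1 for r in supported if colw[r] == GAP)
            if gaps / len(supported) < 0.40:
                kept_cols.append(c)
        hit_part = _partition_of(_words(msa, pos, pos), set(exc))
        for _key, grp in itertools.groupby(enumerate(kept_cols), key=lambda t: t[1] - t[0]):
            run = [c for _i, c in grp]
            s, e = run[0], run[-1]
            rw = _words(msa, s, e)
            rc = Counter(rw)
            run_exc = {r for r, w in enumerate(rw) if rc[w] == 1}
            if run_exc != set(exc):
                continue
            if _partition_of(rw, set(exc)) != hit_part:
                continue
            out.add((s, e, d))
    return out


# ---------------------------------------------------------------- scores


def oracle_comparison(words1: dict[int, str], words2: dict[int, str], rows) -> float:
    """S(b2|b1) from raw row->word maps, written independently."""
    rows = list(rows)
    n = len(rows)
    by_a: dict[str, list[int]] = {}
    for r in rows:
        by_a.setdefault(words1[r], []).append(r)
    total = 0.0
    for a, members in by_a.items():
        partners = {words2[r] for r in members}
        total += (len(members) / n) / len(partners)
    return total


def oracle_correlation(tree: TreeNode, words1, words2, ids) -> float:
    """C(b2|b1) by explicit enumeration of every subtree, combined bottom-up."""
    index = {rid: i for i, rid in enumerate(ids)}
    subtrees = [node for node in tree]  # pre-order; children appear after parents
    values: dict[int, float] = {}
    for node in reversed(subtrees):  # leaves first
        if node.is_leaf:
            values[id(node)] = 1.0
        else:
            left, right = node.children
            rows = [index[l] for l in node.leaves()]
            s = oracle_comparison(words1, words2, rows)
            n1 = len(left.leaves())
            n2 = len(right.leaves())
            inner = (n1 * values[id(left)] + n2 * values[id(right)]) / (n1 + n2)
            values[id(node)] = (s + inner) / 2.0
    return values[id(tree)]


# --------------------------------------------------- random-block probability


def enumerate_word_probability(n_eff: int, counts) -> float:
    """Exhaustive scan of all w**n_eff word assignments."""
    w = len(counts)
    hits = 0
    for assignment in itertools.product(range(w), repeat=n_eff):
        tally = [0] * w
        for a in assignment:
            tally[a] += 1
        if tally == list(counts):
            hits += 1
    return hits / w**n_eff


def montecarlo_word_probability(n_eff: int, counts, draws: int, seed: int) -> tuple[float, float]:
    """Estimate and its standard error from uniform word draws."""
    import numpy as np

    rng = np.random.default_rng(seed)
    w = len(counts)
    target = np.array(list(counts))  # labeled event: word k occurs counts[k] times
    hits = 0
    chunk = 200_000
    remaining = draws
    while remaining > 0:
        size = min(chunk, remaining)
        draws_block = rng.integers(0, w, size=(size, n_eff))
        tallies = np.stack([(draws_block == k).sum(axis=1) for k in range(w)], axis=1)
        hits += int((tallies == target).all(axis=1).sum())
        remaining -= size
    p = hits / draws
    se = (p * (1 - p) / draws) ** 0.5
    return p, se
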