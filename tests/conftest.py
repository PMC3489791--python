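"""Shared fixtures: tiny crafted alignments and random-alignment helpers."""

from __future__ import annotations

import random

import pytest

from coevblocks.msa import Msa, from_sequences
from coevblocks.phylo import TreeNode


@pytest.fixture
def amyloid_like() -> Msa:
    """Six rows mirroring the K/R/gap fragment narrative.

    The middle five columns carry three words (KLVFF, RLMLF, ..VFF), each
    twice; the flanking columns split the word groups, so extension of the
    column-2 hit stops exactly at the five-column fragment.
    """
    rows = ["EKLVFFP", "DKLVFFA", "ERLMLFP", "DRLMLFA", "E..VFFP", "E..VFFA"]
    return from_sequences(list("abcdef"), rows)


@pytest.fixture
def quartet_tree() -> TreeNode:
    """((s1,s2),(s3,s4)) with no branch lengths."""
    return TreeNode(
        None,
        (
            TreeNode(None, (TreeNode("s1"), TreeNode("s2"))),
            TreeNode(None, (TreeNode("s3"), TreeNode("s4"))),
        ),
    )


def random_alignment(rng: random.Random, n_min=4, n_max=8, l_min=6, l_max=10,
                     alphabet="ARND", gap_prob=0.08) -> Msa:
    """Small random alignment with repeats (skewed symbol use) and a few gaps."""
    n = rng.randint(n_min, n_max)
    length = rng.randint(l_min, l_max)
    rows = []
    for _ in range(n):
        chars = []
        for _c in range(length):
            if rng.random() < gap_prob:
                chars.append("-")
            else:
                # skew towards the first letters so words repeat
                k = min(int(rng.expovariate(1.2)), len(alphabet) - 1)
                chars.append(alphabet[k])
        rows.append("".join(chars))
    return from_sequences([f"s{i}" for i in range(n)], rows)


def random_binary_tree(rng: random.Random, ids) -> TreeNode:
    nodes = [TreeNode(i) for i in ids]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append(TreeNode(None, (a, b)))
    return nodes[0]


def word_block(words: str, position: int):
    """A width-1 block carrying the given per-row words, with no exceptions.

    Used by the score-law tests, which exercise S and C on arbitrary word
    assignments independently of the exception machinery.
    """
    from coevblocks.blocks import Block

    table = {}
    for r, w in enumerate(words):
        table.setdefault(w, set()).add(r)
    return Block(
        start=position, end=position, dimension=0,
        hit_positions=frozenset({position}),
        word_table=tuple(sorted((w, frozenset(rows)) for w, rows in table.items())),
        exception_rows=frozenset(),
    )
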