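"""Comparison score, tree-recursive correlation score and the score matrix."""

import math
import random

import pytest

from coevblocks.blocks import enumerate_blocks, hit_dimension, hit_to_block
from coevblocks.msa import from_sequences
from coevblocks.phylo import TreeNode
from coevblocks.scoring import (
    ScoringError,
    comparison_score,
    correlation_score,
    pair_counts,
    score_matrix,
)

from .conftest import random_alignment, random_binary_tree, word_block
from .oracles import oracle_correlation




def _col_block(msa, pos):
    return hit_to_block(msa, hit_dimension(msa, pos))


def _two_column_msa(col1: str, col2: str):
    ids = [f"s{i+1}" for i in range(len(col1))]
    return from_sequences(ids, [a + b for a, b in zip(col1, col2)])


class TestPairCounts:
    def test_bijective_pairing(self):
        msa = _two_column_msa("AARR", "GGHH")
        pc = pair_counts(_col_block(msa, 1), _col_block(msa, 2), range(4))
        assert pc.n == {"A": 2, "R": 2}
        assert pc.m == {"A": 1, "R": 1}
        assert pc.n_joint[("A", "G")] == 2

    def test_one_to_many(self):
        msa = _two_column_msa("AAAA", "GGHH")
        pc = pair_counts(_col_block(msa, 1), _col_block(msa, 2), range(4))
        assert pc.n == {"A": 4}
        assert pc.m == {"A": 2}
        assert pc.n_joint == {("A", "G"): 2, ("A", "H"): 2}

    def test_restriction_to_subtree_rows(self):
        msa = _two_column_msa("AARR", "GGHH")
        pc = pair_counts(_col_block(msa, 1), _col_block(msa, 2), [0, 1])
        assert pc.total == 2 and pc.n == {"A": 2}

    def test_counts_are_consistent(self):
        rng = random.Random(4)
        for _ in range(20):
            msa = random_alignment(rng, l_min=4, l_max=6)
            b1, b2 = _col_block(msa, 1), _col_block(msa, 2)
            pc = pair_counts(b1, b2, range(msa.n))
            assert sum(pc.n.values()) == pc.total
            for a, n_a in pc.n.items():
                joint = [c for (x, _), c in pc.n_joint.items() if x == a]
                assert sum(joint) == n_a
                assert pc.m[a] == len(joint) >= 1

    def test_empty_rows_rejected(self):
        msa = _two_column_msa("AARR", "GGHH")
        with pytest.raises(ScoringError):
            pair_counts(_col_block(msa, 1), _col_block(msa, 2), [])


class TestComparisonScore:
    @pytest.mark.parametrize("col1,col2", [("AARR", "GGHH"), ("AAARRNN", "GGGHHCC"), ("AR", "GH")])
    def test_bijective_pairing_scores_one_both_ways(self, col1, col2):
        msa = _two_column_msa(col1, col2)
        b1, b2 = _col_block(msa, 1), _col_block(msa, 2)
        rows = range(len(col1))
        assert comparison_score(b1, b2, rows) == pytest.approx(1.0)
        assert comparison_score(b2, b1, rows) == pytest.approx(1.0)

    def test_asymmetry_against_conserved(self):
        msa = _two_column_msa("AARR", "GGGG")
        b1, b2 = _col_block(msa, 1), _col_block(msa, 2)
        assert comparison_score(b1, b2, range(4)) == pytest.approx(1.0)
        assert comparison_score(b2, b1, range(4)) == pytest.approx(0.5)

    def test_one_word_splitting_in_two(self):
        msa = _two_column_msa("AAAA", "GGHH")
        assert comparison_score(_col_block(msa, 1), _col_block(msa, 2), range(4)) == pytest.approx(0.5)

    def test_bounded_in_unit_interval(self):
        rng = random.Random(9)
        for _ in range(50):
            msa = random_alignment(rng, l_min=3, l_max=5, gap_prob=0)
            b1, b2 = _col_block(msa, 1), _col_block(msa, 2)
            s = comparison_score(b1, b2, range(msa.n))
            assert 0 < s <= 1 + 1e-12


class TestCorrelationScore:
    def test_single_pair_leafward_base_case(self):
        tree = TreeNode(None, (TreeNode("s1"), TreeNode("s2")))
        b1, b2 = word_block("AR", 1), word_block("GH", 2)
        assert correlation_score(tree, b1, b2, ("s1", "s2")) == pytest.approx(1.0)

    def test_quartet_against_conserved(self, quartet_tree):
        msa = _two_column_msa("AARR", "GGGG")
        b1, b2 = _col_block(msa, 1), _col_block(msa, 2)
        # conditioned on the conserved block: S=0.5 at the root, 1 below
        assert correlation_score(quartet_tree, b2, b1, msa.ids) == pytest.approx(0.75)
        assert correlation_score(quartet_tree, b1, b2, msa.ids) == pytest.approx(1.0)

    def test_perfect_pairing_scores_one_on_any_tree(self):
        rng = random.Random(13)
        col1, col2 = "AAARRNN", "GGGHHCC"
        msa = _two_column_msa(col1, col2)
        b1, b2 = _col_block(msa, 1), _col_block(msa, 2)
        for _ in range(10):
            tree = random_binary_tree(rng, msa.ids)
            assert correlation_score(tree, b1, b2, msa.ids) == pytest.approx(1.0)

    def test_matches_explicit_subtree_oracle(self):
        rng = random.Random(17)
        for _ in range(100):
            n = rng.randint(2, 8)
            ids = [f"s{i}" for i in range(n)]
            col1 = "".join(rng.choice("AR") for _ in range(n))
            col2 = "".join(rng.choice("GH") for _ in range(n))
            tree = random_binary_tree(rng, ids)
            b1, b2 = word_block(col1, 1), word_block(col2, 2)
            w1 = {r: col1[r] for r in range(n)}
            w2 = {r: col2[r] for r in range(n)}
            got = correlation_score(tree, b1, b2, ids)
            want = oracle_correlation(tree, w1, w2, ids)
            assert got == pytest.approx(want)

    def test_invariant_under_child_order(self, quartet_tree):
        ids = ("s1", "s2", "s3", "s4")
        b1, b2 = word_block("AARG", 1), word_block("GGHH", 2)
        flipped = TreeNode(None, (quartet_tree.children[1], quartet_tree.children[0]))
        assert correlation_score(quartet_tree, b1, b2, ids) == pytest.approx(
            correlation_score(flipped, b1, b2, ids)
        )

    def test_perfect_score_propagates_to_subtrees(self):
        # S=1 on the full set implies S=1 on every subset, hence C=1
        rng = random.Random(23)
        col1, col2 = "AARRNNCC", "GGHHIIKK"
        msa = _two_column_msa(col1, col2)
        b1, b2 = _col_block(msa, 1), _col_block(msa, 2)
        for _ in range(10):
            rows = rng.sample(range(8), rng.randint(1, 8))
            assert comparison_score(b1, b2, rows) == pytest.approx(1.0)
        tree = random_binary_tree(rng, msa.ids)
        assert correlation_score(tree, b1, b2, msa.ids) == pytest.approx(1.0)

    def test_flip_under_larger_subtree_hurts_more(self):
        # perfect 8-leaf pairing; flip one leaf's word under a cherry vs the
        # same flip sitting under a 4-leaf clade
        ids = [f"s{i}" for i in range(8)]
        cherry_first = _balanced_tree(ids)
        base1, base2 = "AAAARRRR", "GGGGHHHH"
        msa_perfect = _two_column_msa_ids(ids, base1, base2)
        flipped = "HGGGHHHH"  # leaf s0 takes the other group's word
        msa_flip = _two_column_msa_ids(ids, base1, flipped)
        b1p, b2p = _col_block(msa_perfect, 1), _col_block(msa_perfect, 2)
        b1f, b2f = _col_block(msa_flip, 1), _col_block(msa_flip, 2)
        perfect = correlation_score(cherry_first, b1p, b2p, ids)
        hurt = correlation_score(cherry_first, b1f, b2f, ids)
        assert perfect == pytest.approx(1.0) and hurt < perfect
        # same word pattern, but rotate the tree so the flipped leaf's
        # smallest enclosing imperfect subtree is larger
        deep = _caterpillar_tree(ids)
        hurt_shallow = correlation_score(_balanced_tree(ids), b1f, b2f, ids)
        hurt_deep = correlation_score(deep, b1f, b2f, ids)
        assert hurt_deep < hurt_shallow


def _two_column_msa_ids(ids, col1, col2):
    return from_sequences(ids, [a + b for a, b in zip(col1, col2)])


def _balanced_tree(ids):
    def build(sub):
        if len(sub) == 1:
            return TreeNode(sub[0])
        mid = len(sub) // 2
        return TreeNode(None, (build(sub[:mid]), build(sub[mid:])))

    return build(list(ids))


def _caterpillar_tree(ids):
    node = TreeNode(ids[0])
    for rid in ids[1:]:
        node = TreeNode(None, (node, TreeNode(rid)))
    return node


class TestScoreMatrix:
    def _setup(self, rng=None):
        msa = from_sequences(
            [f"s{i}" for i in range(4)],
            ["AGAKC", "AGRKC", "RHNEC", "RHDEC"],
        )
        tree = _balanced_tree(msa.ids)
        blocks = enumerate_blocks(msa, 0)
        return msa, tree, blocks

    def test_square_with_unit_diagonal(self):
        msa, tree, blocks = self._setup()
        sm = score_matrix(msa, tree, blocks)
        assert sm.size == len(blocks) >= 2
        for i in range(sm.size):
            assert sm.c[i][i] == 1.0
            for j in range(sm.size):
                v = sm.c[i][j]
                assert math.isnan(v) or 0.0 <= v <= 1.0

    def test_planted_perfect_pair_scores_one(self):
        msa, tree, blocks = self._setup()
        by_iv = {b.interval: i for i, b in enumerate(blocks)}
        i, j = by_iv[(1, 2)], by_iv[(4, 5)]
        sm = score_matrix(msa, tree, blocks)
        assert sm.c[i][j] == pytest.approx(1.0)
        assert sm.c[j][i] == pytest.approx(1.0)

    def test_conserved_block_saturates_one_direction(self):
        msa, tree, blocks = self._setup()
        by_iv = {b.interval: i for i, b in enumerate(blocks)}
        i, j = by_iv[(1, 2)], by_iv[(5, 5)]  # (5,5) fully conserved
        sm = score_matrix(msa, tree, blocks)
        assert sm.c[i][j] == pytest.approx(1.0)  # C(conserved | other) = 1
        assert sm.c[j][i] < 1.0

    def test_matches_direct_recursion(self):
        rng = random.Random(31)
        for _ in range(10):
            msa = random_alignment(rng, n_min=4, n_max=6, l_min=4, l_max=7)
            tree = random_binary_tree(rng, msa.ids)
            blocks = enumerate_blocks(msa, 2)[:6]
            if len(blocks) < 2:
                continue
            sm = score_matrix(msa, tree, blocks)
            from coevblocks.phylo import prune_tree
            from coevblocks.scoring import retained_rows

            for i in range(len(blocks)):
                for j in range(len(blocks)):
                    if i == j:
                        continue
                    rows = retained_rows(blocks[i], blocks[j], msa.n)
                    if len(rows) < 2:
                        assert math.isnan(sm.c[i][j])
                        continue
                    sub = prune_tree(tree, {msa.ids[r] for r in rows})
                    want = correlation_score(sub, blocks[i], blocks[j], msa.ids)
                    assert sm.c[i][j] == pytest.approx(want)

    def test_sym_is_max_of_directions(self):
        msa, tree, blocks = self._setup()
        sm = score_matrix(msa, tree, blocks)
        for i in range(sm.size):
            for j in range(sm.size):
                if not math.isnan(sm.c[i][j]):
                    assert sm.sym[i][j] == pytest.approx(max(sm.c[i][j], sm.c[j][i]))

    def test_tree_alignment_mismatch_rejected(self):
        msa, tree, blocks = self._setup()
        bad = TreeNode(None, (TreeNode("s0"), TreeNode("zz")))
        with pytest.raises(ScoringError):
            score_matrix(msa, bad, blocks)
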