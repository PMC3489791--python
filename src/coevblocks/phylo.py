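"""Rooted binary trees over alignment rows.

The correlation score recurses over exactly two immediate subtrees, so every
tree is binarized on construction: multifurcations are resolved into a
caterpillar ordered by descending subtree leaf count, then by smallest leaf
id.  Unrooted Newick input is midpoint-rooted first (missing branch lengths
are treated as 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .msa import GAP, Msa


class TreeError(ValueError):
    """Malformed tree input or a leaf-set mismatch with the alignment."""


@dataclass(frozen=True)
class TreeNode:
    """A rooted tree node; leaves carry a sequence id in ``name``."""

    name: str | None = None
    children: tuple["TreeNode", ...] = ()
    length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def __iter__(self):
        """Pre-order traversal."""
        yield self
        for ch in self.children:
            yield from ch

    def to_newick(self) -> str:
        return _newick(self) + ";"


def _newick(node: TreeNode) -> str:
    suffix = "" if node.length is None else f":{node.length:g}"
    if node.is_leaf:
        return f"{node.name}{suffix}"
    inner = ",".join(_newick(ch) for ch in node.children)
    return f"({inner}){suffix}"


def _min_leaf(node: TreeNode) -> str:
    return min(node.leaves())


def _binarize(node: TreeNode) -> TreeNode:
    """Resolve multifurcations into a caterpillar, deterministically.

    Children are ordered by descending leaf count then smallest leaf id; the
    two smallest children are joined first so the caterpillar spine carries
    the larger subtrees near the root.
    """
    if node.is_leaf:
        return node
    kids = [_binarize(ch) for ch in node.children]
    if len(kids) == 1:
        only = kids[0]
        extra = (node.length or 0) + (only.length or 0) if node.length is not None else only.length
        return TreeNode(only.name, only.children, extra)
    kids.sort(key=lambda ch: (-len(ch.leaves()), _min_leaf(ch)))
    while len(kids) > 2:
        b = kids.pop()
        a = kids.pop()
        kids.append(TreeNode(None, (a, b), 0.0))
    return TreeNode(node.name, tuple(kids), node.length)


def _from_dendropy(node) -> TreeNode:
    length = node.edge.length
    if node.is_leaf():
        return TreeNode(node.taxon.label, (), length)
    return TreeNode(None, tuple(_from_dendropy(c) for c in node.child_nodes()), length)


def read_tree(path, msa: Msa | None = None) -> TreeNode:
    """Parse a Newick tree, midpoint-rooting unrooted input.

    A tree whose root has more than two children is considered unrooted.  If
    ``msa`` is given, the leaf labels must be a subset of its ids.
    """
    try:
        dtree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"cannot parse Newick file {path}: {exc}") from exc
    labels = [t.label for t in dtree.taxon_namespace]
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate leaf labels in tree")
    if msa is not None:
        missing = sorted(set(labels) - set(msa.ids))
        if missing:
            raise TreeError(f"tree leaves absent from alignment: {missing}")
    if len(dtree.seed_node.child_nodes()) > 2:
        for edge in dtree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 1.0
        dtree.reroot_at_midpoint(update_bipartitions=False)
    root = _from_dendropy(dtree.seed_node)
    return _binarize(root)


def _hamming_fraction(a: str, b: str) -> float:
    """1 - fraction of identical columns; gap==gap counts as identical."""
    same = sum(1 for x, y in zip(a, b) if x == y)
    return 1.0 - same / len(a)


def build_tree(msa: Msa, seed: int = 0) -> TreeNode:
    """Deterministic UPGMA guide tree on normalized Hamming distances.

    Ties in cluster joining are broken by the lexicographically smallest
    member id of each cluster, so the result does not depend on row order.
    ``seed`` is accepted for interface symmetry; the construction is fully
    deterministic and ignores it.
    """
    if msa.n < 2:
        raise TreeError("need at least 2 sequences to build a tree")
    nodes: dict[str, TreeNode] = {rid: TreeNode(rid) for rid in msa.ids}
    sizes = {rid: 1 for rid in msa.ids}
    dist: dict[frozenset, float] = {}
    ids = list(msa.ids)
    row = dict(zip(msa.ids, msa.rows))
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            dist[frozenset((a, b))] = _hamming_fraction(row[a], row[b])
    # cluster key = lexicographically smallest member id
    active = set(ids)
    heights = {rid: 0.0 for rid in ids}
    while len(active) > 1:
        best = min(
            (
                (dist[frozenset((a, b))], min(a, b), max(a, b), a, b)
                for i, a in enumerate(sorted(active))
                for b in sorted(active)
                if a < b
            ),
            key=lambda t: (t[0], t[1], t[2]),
        )
        d, _, _, a, b = best
        h = d / 2.0
        left, right = sorted((a, b))
        merged = TreeNode(
            None,
            (
                _with_length(nodes[left], h - heights[left]),
                _with_length(nodes[right], h - heights[right]),
            ),
        )
        new_key = min(a, b)
        other = max(a, b)
        for c in active:
            if c in (a, b):
                continue
            dac = dist[frozenset((a, c))]
            dbc = dist[frozenset((b, c))]
            na, nb = sizes[a], sizes[b]
            dist[frozenset((new_key, c))] = (na * dac + nb * dbc) / (na + nb)
        active.discard(other)
        sizes[new_key] = sizes[a] + sizes[b]
        nodes[new_key] = merged
        heights[new_key] = h
    return nodes[next(iter(active))]


def _with_length(node: TreeNode, length: float) -> TreeNode:
    return TreeNode(node.name, node.children, max(length, 0.0))


def prune_tree(tree: TreeNode, keep) -> TreeNode:
    """Restrict the tree to the leaf ids in ``keep``, collapsing unary nodes."""
    keep = set(keep)
    if not keep:
        raise TreeError("cannot prune to an empty leaf set")
    missing = keep - set(tree.leaves())
    if missing:
        raise TreeError(f"leaves not in tree: {sorted(missing)}")
    pruned = _prune(tree, keep)
    assert pruned is not None
    return pruned


def _prune(node: TreeNode, keep: set) -> TreeNode | None:
    if node.is_leaf:
        return node if node.name in keep else None
    kids = [k for k in (_prune(ch, keep) for ch in node.children) if k is not None]
    if not kids:
        return None
    if len(kids) == 1:
        child = kids[0]
        length = None
        if node.length is not None or child.length is not None:
            length = (node.length or 0.0) + (child.length or 0.0)
        return TreeNode(child.name, child.children, length)
    return TreeNode(node.name, tuple(kids), node.length)


def same_topology(a: TreeNode, b: TreeNode) -> bool:
    """Unordered rooted-topology equality on leaf label sets."""

    def canon(n: TreeNode):
        if n.is_leaf:
            return n.name
        return tuple(sorted((canon(c) for c in n.children), key=repr))

    return canon(a) == canon(b)
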