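"""Deterministic synthetic alignments, trees and toy structures.

The generator plants pairs of co-mutating fragments whose word changes
follow a clade of a random rooted binary tree, on top of a background whose
per-column variation is a skewed two-residue split calibrated to the target
identity.  Planted intervals are flanked by high-dimension "barrier" columns
so the planted fragments are recovered as blocks of exactly the planted
width.  Optional extras emulate real alignments: single-occurrence exception
sequences (unique words inside every planted fragment) and gapped regions.

Everything derives from one seeded NumPy generator, so a fixed spec is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np

from .msa import AMINO_ACIDS, GAP, Msa, from_sequences
from .phylo import TreeNode

#: one more singleton than the default block-search depth, so barriers
#: block both seeding and extension at dimensions 0..2
BARRIER_SINGLETONS = 3


class SynthSpecError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedPair:
    """Two intervals whose words co-mutate on one clade of the tree."""

    interval1: tuple[int, int]
    interval2: tuple[int, int]
    clade: tuple[str, ...] | None = None  # leaf ids; None = generator's choice


@dataclass(frozen=True)
class SynthSpec:
    seed: int = 0
    n_seqs: int = 40
    length: int = 120
    target_identity: float = 0.8
    planted_pairs: tuple[PlantedPair, ...] = (
        PlantedPair((11, 14), (31, 34)),
        PlantedPair((51, 54), (71, 74)),
        PlantedPair((91, 93), (104, 106)),
    )
    n_exception_seqs: int = 1
    gapped_regions: tuple[tuple[tuple[int, int], float], ...] = (((116, 118), 0.5),)
    #: rows whose interval2 word is flipped to the opposite group, as
    #: (planted pair index, leaf id)
    noise_flips: tuple[tuple[int, str], ...] = ()


@dataclass(frozen=True)
class GroundTruth:
    pairs: tuple[dict, ...]
    exception_ids: tuple[str, ...]
    barrier_columns: tuple[int, ...]
    background_columns: tuple[int, ...]
    gapped_columns: tuple[int, ...]


def _random_binary_tree(ids, rng) -> TreeNode:
    nodes = [TreeNode(i) for i in ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(None, (a, b)))
    return nodes[0]


def _clades(tree: TreeNode) -> list[tuple[str, ...]]:
    total = len(tree.leaves())
    out = []
    for node in tree:
        if node.is_leaf:
            continue
        leaves = node.leaves()
        if 2 <= len(leaves) <= total - 2:
            out.append(tuple(sorted(leaves)))
    return out


def _pair_identity(n: int, *groups: int) -> float:
    return sum(comb(g, 2) for g in groups) / comb(n, 2)


def _background_minority(n: int, needed: float, rng) -> int:
    """Minority size whose expected column identity matches ``needed``.

    Columns mix two adjacent minority sizes so the mean lands on target;
    sizes below 1 (fully conserved) are never produced.
    """
    best_m = 1
    for m in range(1, n // 2 + 1):
        if _pair_identity(n, m, n - m) >= needed:
            best_m = m
        else:
            lo, hi = _pair_identity(n, m, n - m), _pair_identity(n, best_m, n - best_m)
            q = 0.0 if hi == lo else (needed - lo) / (hi - lo)
            return best_m if rng.random() < q else m
    return best_m


def generate(spec: SynthSpec) -> tuple[Msa, TreeNode, GroundTruth]:
    """Build (alignment, tree, ground truth) from a spec, reproducibly."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_seqs
    L = spec.length
    ids = [f"s{i:03d}" for i in range(1, n + 1)]
    core = _random_binary_tree(ids, rng)

    intervals = []
    for p in spec.planted_pairs:
        intervals.extend([p.interval1, p.interval2])
    for s, e in intervals:
        if not (1 <= s <= e <= L):
            raise SynthSpecError(f"planted interval [{s},{e}] outside 1..{L}")
    for (s1, e1), (s2, e2) in zip(sorted(intervals), sorted(intervals)[1:]):
        if s2 <= e1 + 1:  # +1: every interval also needs room for a barrier
            raise SynthSpecError("planted intervals overlap or touch")
    gap_cols = {}
    for (s, e), frac in spec.gapped_regions:
        if not (1 <= s <= e <= L) or not 0 < frac <= 1:
            raise SynthSpecError(f"bad gapped region ({s},{e},{frac})")
        for c in range(s, e + 1):
            gap_cols[c] = frac
    planted_cols = {c for s, e in intervals for c in range(s, e + 1)}
    if planted_cols & set(gap_cols):
        raise SynthSpecError("gapped region overlaps a planted interval")

    available = _clades(core)
    if not available:
        raise SynthSpecError("tree too small to carry a planted clade")

    def bipartition(clade) -> frozenset:
        # a clade and its complement induce the same word split
        side = frozenset(clade)
        other = frozenset(ids) - side
        return min(side, other, key=lambda s: (len(s), sorted(s)))

    chosen: list[tuple[str, ...]] = []
    used: set[frozenset] = set()
    for p in spec.planted_pairs:
        if p.clade is not None:
            key = tuple(sorted(p.clade))
            if key not in available:
                raise SynthSpecError(f"{key} is not a clade of the generated tree")
            chosen.append(key)
            used.add(bipartition(key))
        else:
            free = [c for c in available if bipartition(c) not in used]
            if not free:
                raise SynthSpecError("not enough distinct clades for the planted pairs")
            pick_clade = free[rng.integers(len(free))]
            chosen.append(pick_clade)
            used.add(bipartition(pick_clade))

    barrier_cols = set()
    for s, e in intervals:
        if s - 1 >= 1 and s - 1 not in planted_cols:
            barrier_cols.add(s - 1)
        if e + 1 <= L and e + 1 not in planted_cols:
            barrier_cols.add(e + 1)
    barrier_cols -= set(gap_cols)

    n_total = n + spec.n_exception_seqs
    bg_cols = [
        c
        for c in range(1, L + 1)
        if c not in planted_cols and c not in barrier_cols and c not in gap_cols
    ]

    # calibrate background so the mean column identity hits the target
    special_identity = 0.0
    for p, clade in zip(spec.planted_pairs, chosen):
        a = len(clade)
        width = (p.interval1[1] - p.interval1[0] + 1) + (p.interval2[1] - p.interval2[0] + 1)
        special_identity += width * _pair_identity(n_total, a, n - a, *( [1] * spec.n_exception_seqs ))
    special_identity += len(barrier_cols) * _pair_identity(
        n_total, n_total - BARRIER_SINGLETONS, *( [1] * BARRIER_SINGLETONS )
    )
    for c, frac in gap_cols.items():
        g = int(round(frac * n_total))
        special_identity += _pair_identity(n_total, g, n_total - g)
    needed = 0.5
    if bg_cols:
        needed = (spec.target_identity * L - special_identity) / len(bg_cols)

    row_index = {rid: r for r, rid in enumerate(ids)}
    cols: dict[int, list[str]] = {}

    def pick(k: int, exclude=()):
        pool = [a for a in AMINO_ACIDS if a not in exclude]
        sel = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in sel]

    truth_pairs = []
    for pair_idx, (p, clade) in enumerate(zip(spec.planted_pairs, chosen)):
        clade_rows = {row_index[i] for i in clade}
        flips = {
            row_index[rid]
            for k, rid in spec.noise_flips
            if k == pair_idx and rid in row_index
        }
        for which, (s, e) in enumerate((p.interval1, p.interval2)):
            for c in range(s, e + 1):
                r_clade, r_comp, r_exc = pick(3)
                col = [r_clade if r in clade_rows else r_comp for r in range(n)]
                if which == 1:  # noise flips act on the second interval
                    for r in flips:
                        col[r] = r_comp if r in clade_rows else r_clade
                col.extend(pick(spec.n_exception_seqs, exclude={r_clade, r_comp}))
                cols[c] = col
        truth_pairs.append(
            {
                "interval1": list(p.interval1),
                "interval2": list(p.interval2),
                "clade": sorted(clade),
                "n_flips": len(flips),
            }
        )

    for c in barrier_cols:
        singles = pick(BARRIER_SINGLETONS + 1)
        majority = singles.pop()
        col = [majority] * n_total
        spots = rng.choice(n, size=BARRIER_SINGLETONS, replace=False)
        for s_row, res in zip(spots, singles):
            col[s_row] = res
        cols[c] = col

    for c, frac in gap_cols.items():
        g = int(round(frac * n_total))
        residue = pick(1)[0]
        col = [residue] * n_total
        spots = rng.choice(n_total, size=g, replace=False)
        for s_row in spots:
            col[s_row] = GAP
        cols[c] = col

    clade_row_sets = {frozenset(row_index[i] for i in clade) for clade in chosen}
    for c in bg_cols:
        m = _background_minority(n_total, needed, rng)
        minor, major = pick(2)
        col = [major] * n_total
        spots = rng.choice(n, size=min(m, n), replace=False)
        # background variation must stay uncorrelated with the planted
        # clades: redraw the rare subset that duplicates a clade exactly
        while frozenset(int(s) for s in spots) in clade_row_sets:
            spots = rng.choice(n, size=min(m, n), replace=False)
        for s_row in spots:
            col[s_row] = minor
        cols[c] = col

    exc_ids = [f"exc{i}" for i in range(1, spec.n_exception_seqs + 1)]
    rows = ["".join(cols[c][r] for c in range(1, L + 1)) for r in range(n_total)]
    msa = from_sequences(ids + exc_ids, rows)

    tree = core
    for rid in exc_ids:
        tree = TreeNode(None, (tree, TreeNode(rid)))

    truth = GroundTruth(
        pairs=tuple(truth_pairs),
        exception_ids=tuple(exc_ids),
        barrier_columns=tuple(sorted(barrier_cols)),
        background_columns=tuple(bg_cols),
        gapped_columns=tuple(sorted(gap_cols)),
    )
    return msa, tree, truth


def planted_recovery_precision(spec: SynthSpec, max_exceptions: int = 2) -> float:
    """Precision of the top-ranked symmetrized correlation entries.

    Runs the full detection pipeline on one generated alignment and ranks
    all unordered block pairs by symmetrized correlation score; returns the
    fraction of the top-k pairs (k = number of planted pairs) that are
    planted pairs.  Ties at the cut are resolved pessimistically (planted
    pairs last), so a reported precision is a lower bound.
    """
    from .blocks import enumerate_blocks
    from .scoring import score_matrix

    msa, tree, truth = generate(spec)
    found = enumerate_blocks(msa, max_exceptions)
    matrix = score_matrix(msa, tree, found)
    sym = matrix.sym
    planted = {
        tuple(sorted((tuple(p["interval1"]), tuple(p["interval2"])))) for p in truth.pairs
    }
    entries = []
    for i in range(matrix.size):
        for j in range(i + 1, matrix.size):
            v = sym[i][j]
            if v != v:
                continue
            key = tuple(sorted((found[i].interval, found[j].interval)))
            entries.append((-v, key in planted, key))
    # sort by descending score; among ties, non-planted first (pessimistic)
    entries.sort(key=lambda t: (t[0], t[1]))
    k = len(planted)
    top = entries[:k]
    return sum(1 for _v, is_planted, _k in top if is_planted) / k if k else 1.0


_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}

CONTACT_DISTANCE = 3.4
MIN_SEPARATION = 12.0


def make_toy_structure(blocks, contact_pairs, sequence: str | None = None) -> str:
    """Synthetic PDB text placing chosen block pairs in contact.

    ``blocks`` are (start, end) residue intervals on a single toy chain A
    with one CA atom per residue; ``contact_pairs`` are index pairs into
    ``blocks`` whose nearest atoms end up 3.4 Angstrom apart, while every
    other block pair stays beyond 8 Angstrom.  Contact graphs that cannot be
    laid out on a line (e.g. a triangle of single-residue blocks) raise
    :class:`SynthSpecError`.  ``sequence`` optionally sets residue types.
    """
    intervals = [(b.start, b.end) if hasattr(b, "start") else tuple(b) for b in blocks]
    length = max(e for _s, e in intervals) if intervals else 0
    if sequence is None:
        sequence = "A" * length
    if len(sequence) < length:
        raise SynthSpecError("sequence shorter than the last block")

    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(range(len(intervals)))
    graph.add_edges_from(tuple(p) for p in contact_pairs)

    placed: dict[int, float] = {}  # block index -> x of its first residue
    x_cursor = 0.0
    for comp in sorted(nx.connected_components(graph), key=min):
        order = list(nx.dfs_preorder_nodes(graph, source=min(comp)))
        prev = None
        for idx in order:
            width = intervals[idx][1] - intervals[idx][0]
            if prev is None:
                placed[idx] = x_cursor
            else:
                gap = CONTACT_DISTANCE if graph.has_edge(prev, idx) else MIN_SEPARATION
                placed[idx] = x_cursor + gap
            x_cursor = placed[idx] + width * 3.8
            prev = idx
        x_cursor += 50.0

    def min_dist(i: int, j: int) -> float:
        xi = [placed[i] + 3.8 * k for k in range(intervals[i][1] - intervals[i][0] + 1)]
        xj = [placed[j] + 3.8 * k for k in range(intervals[j][1] - intervals[j][0] + 1)]
        return min(abs(a - b) for a in xi for b in xj)

    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            want = graph.has_edge(i, j)
            d = min_dist(i, j)
            if want and d > 3.5:
                raise SynthSpecError(f"contradictory contact requests: blocks {i},{j} at {d:.1f} A")
            if not want and d < 8.0:
                raise SynthSpecError(f"contradictory contact requests: blocks {i},{j} at {d:.1f} A")

    coords: dict[int, tuple[float, float, float]] = {}
    for idx, (s, e) in enumerate(intervals):
        for k, res in enumerate(range(s, e + 1)):
            coords[res] = (placed[idx] + 3.8 * k, 0.0, 0.0)
    far_y = 100.0
    for res in range(1, length + 1):
        if res not in coords:
            coords[res] = (20.0 * res, far_y, 0.0)

    lines = []
    for serial, res in enumerate(sorted(coords), start=1):
        x, y, z = coords[res]
        resname = _THREE.get(sequence[res - 1].upper(), "ALA")
        lines.append(
            f"ATOM  {serial:5d}  CA  {resname} A{res:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
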