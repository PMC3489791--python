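"""Delta-environment clustering of the score matrix and motif grouping.

Clustering operationalizes what a cluster of coevolving blocks means —
blocks with near-maximal mutual scores that behave the same way towards
every other block — as a two-part cohesion criterion: with R the
range of the finite symmetrized scores, blocks i and j are delta-cohesive
iff sym(i, j) >= max - delta*R and their score profiles never differ by more
than delta*R on any third block.  Clusters are the connected components of
the cohesion graph; singletons are discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx

from .blocks import Block
from .scoring import ScoreMatrix

logger = logging.getLogger(__name__)

DEFAULT_DELTA = 0.1
#: default motif-extension distance, in alignment columns
DEFAULT_MOTIF_DISTANCE = 2


@dataclass(frozen=True)
class ClusterMember:
    """A block (or a width-1 hit record) belonging to a cluster."""

    start: int
    end: int
    dimension: int

    @property
    def label(self) -> str:
        span = str(self.start) if self.start == self.end else f"{self.start}-{self.end}"
        return f"{span}:{self.dimension}"

    def positions(self) -> range:
        return range(self.start, self.end + 1)


@dataclass(frozen=True)
class Cluster:
    id: str
    members: tuple[ClusterMember, ...]
    source: str  # "matrix-clustering" | "multi-hit-augmentation"

    @property
    def interval(self) -> tuple[int, int]:
        """Smallest and largest positions among all member blocks."""
        return (min(m.start for m in self.members), max(m.end for m in self.members))

    def positions(self) -> set[int]:
        out: set[int] = set()
        for m in self.members:
            out.update(m.positions())
        return out


def _member(block: Block) -> ClusterMember:
    return ClusterMember(block.start, block.end, block.dimension)


def cluster_matrix(matrix: ScoreMatrix, delta: float = DEFAULT_DELTA) -> list[Cluster]:
    """Connected components of the delta-cohesion graph on the symmetrized matrix.

    Missing (nan) entries never contribute cohesion and are skipped in the
    profile comparison.  A constant matrix (range 0) makes every finite pair
    cohesive; this degenerate case is accepted with a warning.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    sym = matrix.sym
    k = matrix.size
    finite = [sym[i][j] for i in range(k) for j in range(k) if not math.isnan(sym[i][j])]
    if not finite:
        return []
    top, bottom = max(finite), min(finite)
    spread = top - bottom
    if spread == 0 and k > 1:
        logger.warning("score matrix is constant; every block pair is cohesive")
    tol = delta * spread
    graph = nx.Graph()
    graph.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if math.isnan(sym[i][j]) or sym[i][j] < top - tol:
                continue
            profile_ok = all(
                abs(sym[i][x] - sym[j][x]) <= tol
                for x in range(k)
                if not (math.isnan(sym[i][x]) or math.isnan(sym[j][x]))
            )
            if profile_ok:
                graph.add_edge(i, j)
    clusters = []
    comps = sorted(nx.connected_components(graph), key=min)
    n = 1
    for comp in comps:
        if len(comp) < 2:
            continue
        members = tuple(_member(matrix.blocks[i]) for i in sorted(comp))
        clusters.append(Cluster(f"C{n}", members, "matrix-clustering"))
        n += 1
    return clusters


def augment_clusters(clusters: list[Cluster], blocks) -> list[Cluster]:
    """Add one cluster per unclustered multi-hit block.

    All hits of a block display the same behavior towards every other block,
    so the hits of an unclustered block with several hit positions form a
    cluster of width-1 members on their own.  Existing clusters are returned
    unchanged.
    """
    out = list(clusters)
    covered = {(m.start, m.end, m.dimension) for c in clusters for m in c.members}
    n = len(clusters) + 1
    for b in blocks:
        if (b.start, b.end, b.dimension) in covered:
            continue
        if len(b.hit_positions) < 2:
            continue
        members = tuple(
            ClusterMember(p, p, b.dimension) for p in sorted(b.hit_positions)
        )
        out.append(Cluster(f"C{n}", members, "multi-hit-augmentation"))
        n += 1
    return out


@dataclass(frozen=True)
class MotifReport:
    extended: tuple[tuple[tuple[int, int], tuple[int, int]], ...]  # (old, new)
    new_motifs: tuple[tuple[int, int], ...]
    singletons: tuple[int, ...]


def extend_motifs(
    coevolving_positions,
    known_motifs,
    t: int = DEFAULT_MOTIF_DISTANCE,
    boundaries=(),
) -> MotifReport:
    """Extend known motifs with nearby coevolving positions; group the rest.

    A motif absorbs, transitively, every coevolving position within ``t``
    columns of its current boundary.  Leftover positions within ``t`` of each
    other form new motifs; isolated leftovers are reported separately as
    single coevolved positions.  ``boundaries`` (e.g. fully gapped columns
    separating subdomains) are never crossed.
    """
    motifs = sorted(tuple(m) for m in known_motifs)
    for (s1, e1), (s2, e2) in zip(motifs, motifs[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping input motifs [{s1},{e1}] and [{s2},{e2}]")
    boundaries = set(boundaries)
    covered = {p for s, e in motifs for p in range(s, e + 1)}
    free = sorted(set(coevolving_positions) - boundaries - covered)

    def blocked(a: int, b: int) -> bool:
        lo, hi = min(a, b), max(a, b)
        return any(lo < x < hi for x in boundaries)

    extended = []
    for start, end in motifs:
        cur_s, cur_e = start, end
        changed = True
        while changed:
            changed = False
            for p in list(free):
                near = (cur_s - t <= p < cur_s and not blocked(p, cur_s)) or (
                    cur_e < p <= cur_e + t and not blocked(cur_e, p)
                )
                if near:
                    cur_s, cur_e = min(cur_s, p), max(cur_e, p)
                    free.remove(p)
                    changed = True
        extended.append(((start, end), (cur_s, cur_e)))

    new_motifs = []
    singles = []
    group: list[int] = []
    for p in free:
        if group and p - group[-1] <= t and not blocked(group[-1], p):
            group.append(p)
        else:
            if len(group) > 1:
                new_motifs.append((group[0], group[-1]))
            elif group:
                singles.append(group[0])
            group = [p]
    if len(group) > 1:
        new_motifs.append((group[0], group[-1]))
    elif group:
        singles.append(group[0])
    return MotifReport(tuple(extended), tuple(new_motifs), tuple(singles))
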