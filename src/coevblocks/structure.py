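"""Interval-graph partitions and mapping clusters onto a 3-D structure.

Partitions are the connected components of the graph whose nodes are cluster
intervals along the sequence, with an edge whenever two intervals overlap or
one contains the other (endpoints inclusive: touching intervals overlap).
Contact networks connect the blocks of one cluster whose mapped residues
come within a distance cutoff (default strictly below 4 Angstrom) of each
other, over any atom pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
from Bio.PDB import PDBParser
from Bio.Data.PDBData import protein_letters_3to1

from .clustering import Cluster
from .msa import GAP, Msa

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 4.0


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class Partition:
    """A connected component of the cluster interval graph."""

    id: str
    cluster_ids: tuple[str, ...]
    span: tuple[int, int]


def interval_graph(clusters: list[Cluster]) -> list[Partition]:
    """Group clusters whose sequence intervals overlap or nest."""
    graph = nx.Graph()
    graph.add_nodes_from(range(len(clusters)))
    ivs = [c.interval for c in clusters]
    for i in range(len(ivs)):
        for j in range(i + 1, len(ivs)):
            (s1, e1), (s2, e2) = ivs[i], ivs[j]
            if s1 <= e2 and s2 <= e1:
                graph.add_edge(i, j)
    partitions = []
    for n, comp in enumerate(sorted(nx.connected_components(graph), key=min), start=1):
        idx = sorted(comp)
        span = (min(ivs[i][0] for i in idx), max(ivs[i][1] for i in idx))
        partitions.append(Partition(f"P{n}", tuple(clusters[i].id for i in idx), span))
    return partitions


@dataclass(frozen=True)
class ResidueRef:
    """PDB residue identity: number plus (possibly blank) insertion code."""

    number: int
    icode: str = ""

    @property
    def label(self) -> str:
        return f"{self.number}{self.icode}".strip()


@dataclass(frozen=True)
class StructureMap:
    """Alignment column -> PDB residue mapping for one reference row."""

    ref_id: str
    chain: str
    column_to_residue: tuple[ResidueRef | None, ...]  # index 0 = column 1
    coordinates: dict[ResidueRef, tuple[tuple[str, float, float, float], ...]]

    def residues_for(self, positions) -> list[ResidueRef]:
        out = []
        for p in positions:
            ref = self.column_to_residue[p - 1]
            if ref is not None:
                out.append(ref)
        return out


def _chain_residues(structure, chain_id: str):
    model = next(structure.get_models())  # first model only for multi-model files
    if len(structure) > 1:
        logger.info("multi-model structure: using the first model only")
    for chain in model:
        if chain.id == chain_id:
            residues = []
            for res in chain:
                het, num, icode = res.id
                if het.strip():
                    continue  # skip waters/heteroatoms
                name = res.get_resname().strip()
                one = protein_letters_3to1.get(name, "X")
                residues.append((ResidueRef(num, icode.strip()), one, res))
            return residues
    raise StructureError(f"chain {chain_id!r} not found in structure")


def map_to_structure(
    msa: Msa, ref_id: str, pdb_path, chain: str, max_mismatches: int = 0
) -> StructureMap:
    """Map alignment columns of ``ref_id`` onto the residues of one chain.

    The ungapped reference row is matched positionally against the chain's
    residue sequence; gapped columns map to nothing.  The mapping is strictly
    increasing along ungapped columns.  More than ``max_mismatches``
    sequence/structure disagreements raise an error with an aligned diff.
    """
    if ref_id not in msa.ids:
        raise StructureError(f"reference id {ref_id!r} not in alignment")
    row = msa.rows[msa.ids.index(ref_id)]
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    residues = _chain_residues(structure, chain)
    ungapped = [(i, ch) for i, ch in enumerate(row) if ch != GAP]
    if len(residues) < len(ungapped):
        raise StructureError(
            f"chain {chain!r} has {len(residues)} residues but the reference row "
            f"has {len(ungapped)} ungapped columns"
        )
    mismatches = [
        (col + 1, aa, res_one)
        for (col, aa), (_ref, res_one, _res) in zip(ungapped, residues)
        if aa != res_one and res_one != "X"
    ]
    if len(mismatches) > max_mismatches:
        diff = "; ".join(f"column {c}: {a}!={b}" for c, a, b in mismatches[:10])
        raise StructureError(
            f"{len(mismatches)} sequence/structure mismatches beyond tolerance: {diff}"
        )
    mapping: list[ResidueRef | None] = [None] * msa.length
    coords: dict[ResidueRef, tuple] = {}
    for (col, _aa), (ref, _one, res) in zip(ungapped, residues):
        mapping[col] = ref
        coords[ref] = tuple(
            (atom.get_name(), *map(float, atom.coord)) for atom in res.get_atoms()
        )
    return StructureMap(ref_id, chain, tuple(mapping), coords)


@dataclass(frozen=True)
class ContactNetwork:
    cluster_id: str
    nodes: tuple[str, ...]  # member labels
    edges: tuple[tuple[str, str, float], ...]  # (label, label, min distance)
    unmapped: tuple[str, ...]
    connected: bool


def _min_distance(atoms_a, atoms_b, heavy_only: bool) -> float:
    best = math.inf
    for name_a, xa, ya, za in atoms_a:
        if heavy_only and name_a.startswith("H"):
            continue
        for name_b, xb, yb, zb in atoms_b:
            if heavy_only and name_b.startswith("H"):
                continue
            d = math.dist((xa, ya, za), (xb, yb, zb))
            if d < best:
                best = d
    return best


def contact_network(
    cluster: Cluster,
    smap: StructureMap,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    atom_set: str = "all",
) -> ContactNetwork:
    """Contact graph over one cluster's blocks (edge iff min distance < cutoff)."""
    if atom_set not in {"all", "heavy"}:
        raise ValueError("atom_set must be 'all' or 'heavy'")
    heavy = atom_set == "heavy"
    member_atoms = {}
    unmapped = []
    for member in cluster.members:
        refs = smap.residues_for(member.positions())
        atoms = [a for ref in refs for a in smap.coordinates[ref]]
        if atoms:
            member_atoms[member.label] = atoms
        else:
            unmapped.append(member.label)
            logger.warning("cluster %s member %s has no mapped residues", cluster.id, member.label)
    labels = sorted(member_atoms)
    graph = nx.Graph()
    graph.add_nodes_from(labels)
    edges = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d = _min_distance(member_atoms[a], member_atoms[b], heavy)
            if d < cutoff:
                graph.add_edge(a, b)
                edges.append((a, b, round(d, 3)))
    connected = len(labels) > 0 and nx.is_connected(graph)
    return ContactNetwork(cluster.id, tuple(labels), tuple(edges), tuple(unmapped), connected)


def annotate_pdb(pdb_path, out_path, smap: StructureMap, clusters: list[Cluster]) -> None:
    """Copy a PDB file with cluster ids written into the B-factor column.

    Residues of cluster ``Ck`` get B-factor ``k``; unassigned residues 0.
    A residue claimed by several clusters keeps the lowest cluster number.
    """
    assignment: dict[str, float] = {}
    for cluster in clusters:
        try:
            k = float(cluster.id.lstrip("C"))
        except ValueError:
            k = 0.0
        for ref in smap.residues_for(sorted(cluster.positions())):
            key = f"{smap.chain}|{ref.number}|{ref.icode}"
            if key not in assignment:
                assignment[key] = k
    with open(pdb_path) as src, open(out_path, "w") as dst:
        for line in src:
            if line.startswith(("ATOM", "HETATM")) and len(line) >= 66:
                chain = line[21]
                try:
                    num = int(line[22:26])
                except ValueError:
                    num = None
                icode = line[26].strip()
                b = assignment.get(f"{chain}|{num}|{icode}", 0.0)
                line = line[:60] + f"{b:6.2f}" + line[66:]
            dst.write(line)
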