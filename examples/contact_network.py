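"""Map clusters onto a synthetic structure and read off contact networks.

Builds a toy PDB chain in which two of three blocks are placed within the
4 Angstrom contact cutoff, maps an alignment row onto the chain, and checks
which block pairs of a cluster touch in 3-D.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from coevblocks.clustering import Cluster, ClusterMember
from coevblocks.msa import from_sequences
from coevblocks.structure import contact_network, map_to_structure
from coevblocks.synthetic import make_toy_structure

sequence = "KLAVFAARN"
pdb_text = make_toy_structure(
    blocks=[(1, 2), (4, 5), (8, 9)], contact_pairs=[(0, 1)], sequence=sequence
)

with TemporaryDirectory() as tmp:
    pdb = Path(tmp) / "toy.pdb"
    pdb.write_text(pdb_text)
    msa = from_sequences(["ref", "homolog"], [sequence, sequence])
    smap = map_to_structure(msa, "ref", pdb, chain="A")
    print("column -> residue:", [r.label if r else None for r in smap.column_to_residue])

    cluster = Cluster(
        "C1",
        (ClusterMember(1, 2, 0), ClusterMember(4, 5, 0), ClusterMember(8, 9, 0)),
        "matrix-clustering",
    )
    network = contact_network(cluster, smap, cutoff=4.0)
    print("nodes:", network.nodes)
    for a, b, d in network.edges:
        print(f"edge {a} -- {b}  (min atom distance {d} A)")
    print("connected:", network.connected)

print(
    "\nAn edge means at least one atom pair of the two blocks lies below the"
    "\ncutoff; blocks 1-2 and 4-5 touch, block 8-9 is isolated, so the"
    "\ncluster's three fragments do not form a single physical network."
)
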