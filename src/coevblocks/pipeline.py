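"""End-to-end detection and evaluation runs with auditable file outputs.

``run_detect`` executes the five pipeline stages — blocks (or gap-filtered
positions), pairwise scores, score matrix, clustering, cluster topology —
and writes every intermediate as TSV/JSON with the full configuration in a
run log.  Outputs are deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import blocks as blk
from . import clustering, evaluation, msa as msa_mod, phylo, scoring, structure

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    alignment: str
    tree: str = "auto"
    mode: str = "blocks"  # blocks | positions
    max_exceptions: int = blk.DEFAULT_MAX_EXCEPTIONS
    delta: float = clustering.DEFAULT_DELTA
    alphabet: str = "full"  # full | physicochemical
    alignment_format: str = "fasta"
    pdb: str | None = None
    chain: str | None = None
    ref_id: str | None = None
    validated: str | None = None
    out_dir: str = "coevblocks_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"blocks", "positions"}:
            raise ConfigError(f"mode must be blocks|positions, got {self.mode!r}")
        if self.alphabet not in {"full", "physicochemical"}:
            raise ConfigError(f"alphabet must be full|physicochemical, got {self.alphabet!r}")
        if self.max_exceptions < 0:
            raise ConfigError("max_exceptions must be >= 0")
        if not 0 < self.delta < 1:
            raise ConfigError("delta must lie in (0, 1)")


@dataclass
class DetectResult:
    msa: msa_mod.Msa
    tree: phylo.TreeNode
    blocks: list
    matrix: scoring.ScoreMatrix
    clusters: list
    partitions: list
    networks: list
    api: float
    files: dict[str, str] = field(default_factory=dict)


def _header(config: RunConfig) -> str:
    pairs = ", ".join(f"{k}={v}" for k, v in sorted(asdict(config).items()))
    return f"# coevblocks detect ({pairs})\n"


def run_detect(config: RunConfig) -> DetectResult:
    out = Path(config.out_dir)
    aln_path = Path(config.alignment)
    if not aln_path.exists():
        raise ConfigError(f"alignment file not found: {aln_path}")
    alignment = msa_mod.read_alignment(aln_path, config.alignment_format)
    if config.alphabet == "physicochemical":
        alignment = msa_mod.reduce_alphabet(alignment)

    if config.tree == "auto":
        tree = phylo.build_tree(alignment, seed=config.seed)
    else:
        tree = phylo.read_tree(config.tree, alignment)
        if set(tree.leaves()) != set(alignment.ids):
            raise ConfigError("tree must cover every alignment sequence")

    if config.mode == "blocks":
        found = blk.enumerate_blocks(alignment, config.max_exceptions)
    else:
        found = [
            blk.hit_to_block(alignment, h)
            for h in blk.position_hits(alignment, config.max_exceptions)
        ]
    matrix = scoring.score_matrix(alignment, tree, found)
    clusters = clustering.cluster_matrix(matrix, config.delta)
    clusters = clustering.augment_clusters(clusters, found)
    partitions = structure.interval_graph(clusters)

    networks = []
    smap = None
    if config.pdb:
        if not (config.chain and config.ref_id):
            raise ConfigError("--pdb requires --chain and --ref-id")
        smap = structure.map_to_structure(alignment, config.ref_id, config.pdb, config.chain)
        networks = [structure.contact_network(c, smap) for c in clusters]

    profiles, api = msa_mod.percent_identity(alignment)

    out.mkdir(parents=True, exist_ok=True)
    files = {}
    header = _header(config)

    def _path(name: str) -> Path:
        files[name] = str(out / name)
        return out / name

    blk.blocks_to_tsv(found, _path("blocks.tsv"))
    scoring.write_matrix_tsv(matrix, _path("matrix_directed.tsv"), symmetrized=False)
    scoring.write_matrix_tsv(matrix, _path("matrix_sym.tsv"), symmetrized=True)
    msa_mod.profiles_to_tsv(profiles, _path("positions.tsv"))
    with open(_path("clusters.json"), "w") as fh:
        json.dump(
            [
                {
                    "id": c.id,
                    "source": c.source,
                    "interval": list(c.interval),
                    "members": [m.label for m in c.members],
                    "positions": sorted(c.positions()),
                }
                for c in clusters
            ],
            fh,
            indent=2,
        )
    with open(_path("partitions.json"), "w") as fh:
        json.dump(
            [{"id": p.id, "clusters": list(p.cluster_ids), "span": list(p.span)} for p in partitions],
            fh,
            indent=2,
        )
    if config.pdb:
        with open(_path("networks.json"), "w") as fh:
            json.dump(
                [
                    {
                        "cluster": nw.cluster_id,
                        "nodes": list(nw.nodes),
                        "edges": [list(e) for e in nw.edges],
                        "unmapped": list(nw.unmapped),
                        "connected": nw.connected,
                    }
                    for nw in networks
                ],
                fh,
                indent=2,
            )
        structure.annotate_pdb(config.pdb, _path("annotated.pdb"), smap, clusters)

    per_d = {}
    for b in found:
        per_d[b.dimension] = per_d.get(b.dimension, 0) + 1
    with open(_path("run.log"), "w") as fh:
        fh.write(header)
        fh.write(f"sequences\t{alignment.n}\n")
        fh.write(f"columns\t{alignment.length}\n")
        fh.write(f"api\t{api:.4f}\n")
        for d in sorted(per_d):
            fh.write(f"blocks_d{d}\t{per_d[d]}\n")
        fh.write(f"blocks_total\t{len(found)}\n")
        scored = sum(
            1
            for i in range(matrix.size)
            for j in range(matrix.size)
            if i != j and matrix.c[i][j] == matrix.c[i][j]
        )
        fh.write(f"scored_pairs\t{scored}\n")
        fh.write(f"clusters\t{len(clusters)}\n")
        fh.write(f"partitions\t{len(partitions)}\n")

    return DetectResult(alignment, tree, found, matrix, clusters, partitions, networks, api, files)


@dataclass(frozen=True)
class EvalResult:
    confusion: evaluation.Confusion
    metrics: evaluation.Metrics
    probability: float
    predicted: tuple[int, ...]
    validated: tuple[int, ...]


def predicted_positions(clusters) -> set[int]:
    """Union of all positions of all blocks in retained clusters."""
    out: set[int] = set()
    for c in clusters:
        out.update(c.positions())
    return out


def run_eval(config: RunConfig, detect: DetectResult | None = None) -> EvalResult:
    if not config.validated:
        raise ConfigError("evaluation needs a validated-residue list")
    validated = evaluation.read_validated_positions(config.validated)
    if detect is None:
        detect = run_detect(config)
    length = detect.msa.length
    bad = [p for p in validated if p > length]
    if bad:
        raise ConfigError(f"validated positions beyond alignment length {length}: {bad}")
    predicted = predicted_positions(detect.clusters)
    conf = evaluation.confusion(predicted, validated, length)
    mets = evaluation.metrics(conf)
    prob = evaluation.prediction_probability(length, len(validated), len(predicted), conf.tp)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rounded = mets.rounded()
    with open(out / "evaluation.tsv", "w") as fh:
        fh.write(_header(config))
        fh.write("length\tn_validated\tn_predicted\tTP\tFP\tFN\tTN\tprob\tsen\tspe\tacc\tppv\n")
        cells = [
            length, len(validated), len(predicted), conf.tp, conf.fp, conf.fn, conf.tn,
            f"{prob:.3e}",
        ] + ["NA" if v is None else f"{v:.2f}" for v in rounded]
        fh.write("\t".join(str(c) for c in cells) + "\n")
    return EvalResult(conf, mets, prob, tuple(sorted(predicted)), tuple(validated))
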