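"""End-to-end orchestration of the host-prediction pipeline.

Stages: protein acquisition (given FASTA or naive ORF calls) ->
all-vs-all protein alignment -> similarity network + MCL clusters +
per-genome profiles -> skip-gram + CNN encoder trained on the
known-interaction viruses -> knowledge-graph assembly (shared-cluster
test, nucleotide alignment, known pairs) -> per-rank GCN training
(phylum to genus) -> thresholded, conflict-resolved predictions for the
query viruses.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import aligner, protein_clustering
from .encoder import (
    CNNModel,
    EncoderConfig,
    KmerEmbedding,
    encode_sequence,
    train_cnn,
    train_skipgram,
)
from .errors import ParameterError
from .gcn_model import (
    GCNConfig,
    Prediction,
    RankModel,
    evaluate,
    predict,
    train_gcn,
)
from .graph_builder import (
    EdgeTestParams,
    KnowledgeGraph,
    build_knowledge_graph,
    encode_host_nodes,
)
from .sequence_io import AlignmentHit, SeqRecord, find_orfs, segment_genome
from .synthetic_data import RANKS, TaxonomyTree

logger = logging.getLogger("hostgraph")


@dataclass
class PipelineConfig:
    """Every tunable of a pipeline run, serializable into a run manifest."""

    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    gcn: GCNConfig = field(default_factory=GCNConfig)
    tau1: float = 1.0
    tau2: float = 1e-5
    evalue_cutoff: float = 1e-5  # protein network edge cutoff
    mcl_inflation: float = 2.0
    confidence_threshold: float = 0.0
    min_orf_len_aa: int = 60
    rng_seed: int = 7


@dataclass
class RunResult:
    """All intermediates and outputs of one pipeline run."""

    config: PipelineConfig
    protein_hits: list[AlignmentHit]
    virus_host_hits: list[AlignmentHit]
    clusters: list[set[str]]
    profiles: dict
    embedding: KmerEmbedding
    cnn: CNNModel
    virus_features: dict[str, np.ndarray]
    graph: KnowledgeGraph
    edge_params: EdgeTestParams
    models: dict[str, RankModel]
    predictions: list[Prediction]
    metrics: pd.DataFrame | None
    timings: dict[str, float]


def _derive_labels(
    known_pairs: pd.DataFrame, host_taxonomy: pd.DataFrame
) -> dict[str, dict[str, str]]:
    """Per-virus host lineage for the viruses with known interactions."""
    tax = host_taxonomy.set_index("host_id")
    labels: dict[str, dict[str, str]] = {}
    for _, row in known_pairs.iterrows():
        h = str(row["host_id"])
        if h not in tax.index:
            raise ParameterError(f"known pair host {h!r} has no taxonomy row")
        labels[str(row["virus_id"])] = {r: str(tax.loc[h, r]) for r in RANKS}
    return labels


def taxonomy_from_table(host_taxonomy: pd.DataFrame) -> TaxonomyTree:
    """Build a taxonomy tree from the host lineage table."""
    nodes: dict[str, tuple[str, str | None]] = {}
    for _, row in host_taxonomy.iterrows():
        parent: str | None = None
        for rank in RANKS:
            name = str(row[rank])
            if name in nodes and nodes[name] != (rank, parent):
                raise ParameterError(f"inconsistent lineage at taxon {name!r}")
            nodes[name] = (rank, parent)
            parent = name
    return TaxonomyTree(nodes)


def run_pipeline(
    viruses: list[SeqRecord],
    hosts: list[SeqRecord],
    known_pairs: pd.DataFrame,
    host_taxonomy: pd.DataFrame,
    config: PipelineConfig | None = None,
    proteins: list[SeqRecord] | None = None,
    protein_hits: list[AlignmentHit] | None = None,
    virus_host_hits: list[AlignmentHit] | None = None,
    truth: pd.DataFrame | None = None,
) -> RunResult:
    """Run the full pipeline; external alignment tables may be supplied.

    ``proteins`` (ids ``<genome_id>_<n>``) defaults to naive ORF calls on
    the virus genomes; ``protein_hits``/``virus_host_hits`` default to the
    built-in aligner.  ``truth`` enables evaluation of the query viruses.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    def stage(name: str, fn: Callable):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %s: %.1fs", name, timings[name])
        return out

    virus_ids = {r.id for r in viruses}
    if proteins is None:
        proteins = stage(
            "orf_calling",
            lambda: [p for v in viruses for p in find_orfs(v, config.min_orf_len_aa)],
        )

    def protein_genome(pid: str) -> str:
        genome = pid.rsplit("_", 1)[0]
        if genome not in virus_ids:
            raise ParameterError(f"protein {pid!r} does not map to a virus genome")
        return genome

    protein_to_genome = {p.id: protein_genome(p.id) for p in proteins}

    if protein_hits is None:
        protein_hits = stage("protein_alignment", lambda: aligner.align_proteins(proteins))
    if virus_host_hits is None:
        virus_host_hits = stage(
            "nucleotide_alignment", lambda: aligner.align_nucleotide(viruses, hosts)
        )

    network = stage(
        "protein_network",
        lambda: protein_clustering.build_protein_network(
            protein_hits, config.evalue_cutoff, protein_ids=[p.id for p in proteins]
        ),
    )
    clusters = stage(
        "mcl", lambda: protein_clustering.mcl(network, inflation=config.mcl_inflation)
    )
    profiles = stage(
        "profiles",
        lambda: protein_clustering.profile_genomes(
            clusters, protein_to_genome, genomes=sorted(virus_ids)
        ),
    )

    labels = _derive_labels(known_pairs, host_taxonomy)
    genus_labels = {v: lin["genus"] for v, lin in labels.items()}
    train_records = [v for v in viruses if v.id in genus_labels]

    enc = config.encoder
    all_segments = [s for v in viruses for s in segment_genome(v, enc.segment_len)]
    embedding = stage(
        "skipgram",
        lambda: train_skipgram(
            all_segments,
            k=enc.k,
            d=enc.d,
            window=enc.sg_window,
            negatives=enc.sg_negatives,
            epochs=enc.sg_epochs,
            rng_seed=config.rng_seed,
            pairs_per_epoch=enc.sg_pairs,
            lr=enc.sg_lr,
        ),
    )
    cnn = stage(
        "cnn_training",
        lambda: train_cnn(train_records, genus_labels, embedding, enc, config.rng_seed),
    )
    virus_features = stage(
        "encoding", lambda: {v.id: encode_sequence(v, embedding, cnn) for v in viruses}
    )

    n_clusters = max(len(clusters), 1)
    edge_params = EdgeTestParams(
        n=n_clusters, N=len(viruses), tau1=config.tau1, tau2=config.tau2
    )
    graph = stage(
        "knowledge_graph",
        lambda: build_knowledge_graph(
            viruses, hosts, profiles, virus_host_hits, known_pairs, host_taxonomy, edge_params
        ),
    )
    stage("host_encoding", lambda: encode_host_nodes(graph, virus_features))
    n_vv = sum(1 for *_, e in graph.edge_list() if e.provenance == "virus-virus")
    n_vh = len(graph.edges) - n_vv
    logger.info(
        "knowledge graph: %d nodes, %d virus-virus edges, %d virus-host edges",
        len(graph.nodes), n_vv, n_vh,
    )

    models: dict[str, RankModel] = {}
    for rank in RANKS:  # phylum -> genus
        models[rank] = stage(
            f"gcn_{rank}",
            lambda r=rank: train_gcn(graph, r, config.gcn, rng_seed=config.rng_seed),
        )

    tree = taxonomy_from_table(host_taxonomy)
    predictions = stage(
        "prediction",
        lambda: predict(graph, models, tree, config.confidence_threshold),
    )
    metrics = evaluate(predictions, truth) if truth is not None else None

    return RunResult(
        config=config,
        protein_hits=protein_hits,
        virus_host_hits=virus_host_hits,
        clusters=clusters,
        profiles=profiles,
        embedding=embedding,
        cnn=cnn,
        virus_features=virus_features,
        graph=graph,
        edge_params=edge_params,
        models=models,
        predictions=predictions,
        metrics=metrics,
        timings=timings,
    )
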