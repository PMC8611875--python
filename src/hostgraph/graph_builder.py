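"""Knowledge-graph assembly.

Virus-virus edges come from a shared-protein-cluster significance test:
for two genomes containing ``a`` and ``b`` protein clusters sharing ``c``,
the tail probability P(y >= c) under an equal-probability hypergeometric
null is multiplied by the C(N, 2) pairs correction, and an edge is created
when -log(P * C(N,2)) >= tau1.  Virus-host edges come from nucleotide
alignment E-values below tau2, or from known interactions regardless of
alignment.  Host node features are E-value-weighted averages of their
neighboring virus features, which lets hosts from taxa absent from
training be added to the graph later.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import ParameterError
from .protein_clustering import ProteinClusterProfile, log_weight
from .sequence_io import AlignmentHit, SeqRecord
from .synthetic_data import RANKS, TaxonomyTree

#: node feature dimensionality across the whole graph
FEATURE_DIM = 512

#: weight of a known-interaction edge lacking an alignment E-value
KNOWN_PAIR_WEIGHT = 180.0


@dataclass
class EdgeTestParams:
    """Parameters of the edge tests.

    ``n`` is the total number of protein clusters, ``N`` the total number
    of virus sequences entering the C(N,2) pairs correction.  ``log_base``
    controls the logarithm in the significance statistic (natural log by
    default, paired with tau1 = 1).
    """

    n: int
    N: int
    tau1: float = 1.0
    tau2: float = 1e-5
    log_base: float = math.e

    def __post_init__(self) -> None:
        if self.tau2 <= 0:
            raise ParameterError("tau2 must be > 0")
        if self.n < 1:
            raise ParameterError("n must be >= 1")
        if self.N < 2:
            raise ParameterError("N must be >= 2")


def _log_binom(n: float, k: np.ndarray | float) -> np.ndarray | float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(a: int, b: int, c: int, n: int) -> float:
    """P(y >= c) for the number of shared clusters between two genomes.

    Two genomes contain ``a`` and ``b`` of the ``n`` protein clusters,
    each cluster equally likely; y is the overlap.  Computed in log space.
    """
    if a < 0 or b < 0 or c < 0:
        raise ParameterError("a, b, c must be >= 0")
    if a > n or b > n:
        raise ParameterError("a and b must be <= n")
    m = min(a, b)
    if c == 0:
        return 1.0
    if c > m:
        return 0.0
    i = np.arange(c, m + 1)
    log_terms = _log_binom(a, i) + _log_binom(n - a, b - i) - _log_binom(n, b)
    return float(np.exp(logsumexp(log_terms)))


def shared_cluster_significance(
    profile_a: ProteinClusterProfile,
    profile_b: ProteinClusterProfile,
    params: EdgeTestParams,
) -> float:
    """The edge statistic -log(P(y >= c) * C(N, 2)) in ``params.log_base``."""
    c = len(profile_a.clusters & profile_b.clusters)
    p = hypergeom_tail(profile_a.a, profile_b.a, c, params.n)
    log_pairs = _log_binom(params.N, 2)
    # log-space: -(ln P + ln C(N,2)) / ln base
    log_p = math.log(p) if p > 0 else -math.inf
    return -(log_p + float(log_pairs)) / math.log(params.log_base)


def virus_virus_edge(
    profile_a: ProteinClusterProfile,
    profile_b: ProteinClusterProfile,
    params: EdgeTestParams,
) -> bool:
    """Edge iff the shared-cluster significance statistic reaches tau1.

    Zero shared clusters never yields an edge.
    """
    if len(profile_a.clusters & profile_b.clusters) == 0:
        return False
    return shared_cluster_significance(profile_a, profile_b, params) >= params.tau1


def virus_host_edge(
    best_evalue: float | None,
    is_known_pair: bool,
    tau2: float = 1e-5,
) -> bool:
    """Edge iff the pair is a known interaction or aligns with E < tau2."""
    if is_known_pair:
        return True
    return best_evalue is not None and best_evalue < tau2


@dataclass
class Node:
    id: str
    role: str  # "virus" | "host"
    feature: np.ndarray | None = None
    labels: dict[str, str] | None = None  # rank -> taxon
    no_neighbors: bool = False


@dataclass
class Edge:
    provenance: str  # "virus-virus" | "virus-host-alignment" | "virus-host-known"
    evalue: float | None = None


class KnowledgeGraph:
    """Typed virus/host graph with per-node features and per-rank labels."""

    def __init__(self) -> None:
        self.nodes: dict[str, Node] = {}
        self.edges: dict[tuple[str, str], Edge] = {}  # keys sorted pairs

    def add_node(self, node: Node) -> None:
        if node.id in self.nodes:
            raise ParameterError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node

    def add_edge(self, u: str, v: str, edge: Edge) -> None:
        if u == v:
            raise ParameterError("self-edges are not allowed")
        if u not in self.nodes or v not in self.nodes:
            raise ParameterError(f"edge references unknown node: {u!r}-{v!r}")
        if self.nodes[u].role == "host" and self.nodes[v].role == "host":
            raise ParameterError("host-host edges are not allowed")
        key = (u, v) if u < v else (v, u)
        self.edges[key] = edge

    def neighbors(self, node_id: str) -> list[tuple[str, Edge]]:
        out = []
        for (u, v), e in self.edges.items():
            if u == node_id:
                out.append((v, e))
            elif v == node_id:
                out.append((u, e))
        return out

    def node_ids(self, role: str | None = None) -> list[str]:
        return sorted(
            n for n, node in self.nodes.items() if role is None or node.role == role
        )

    def edge_list(self) -> list[tuple[str, str, Edge]]:
        return [(u, v, e) for (u, v), e in sorted(self.edges.items())]

    def copy(self) -> "KnowledgeGraph":
        return copy.deepcopy(self)

    # -- serialization ----------------------------------------------------
    def write_tables(self, node_path, edge_path) -> None:
        rows = []
        for nid in sorted(self.nodes):
            node = self.nodes[nid]
            row = {"id": nid, "role": node.role, "no_neighbors": node.no_neighbors}
            for rank in RANKS:
                row[rank] = (node.labels or {}).get(rank, "")
            rows.append(row)
        pd.DataFrame(rows).to_csv(node_path, sep="\t", index=False)
        erows = [
            {
                "id_a": u,
                "id_b": v,
                "provenance": e.provenance,
                "evalue": "" if e.evalue is None else f"{e.evalue:.6g}",
            }
            for u, v, e in self.edge_list()
        ]
        pd.DataFrame(erows, columns=["id_a", "id_b", "provenance", "evalue"]).to_csv(
            edge_path, sep="\t", index=False
        )


def _taxonomy_lookup(host_taxonomy: pd.DataFrame) -> dict[str, dict[str, str]]:
    lookup: dict[str, dict[str, str]] = {}
    for _, row in host_taxonomy.iterrows():
        lookup[str(row["host_id"])] = {rank: str(row[rank]) for rank in RANKS}
    return lookup


def best_evalue_per_pair(hits: list[AlignmentHit]) -> dict[tuple[str, str], float]:
    """Minimum E-value per (virus, host) pair over all alignment hits."""
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        if key not in best or h.evalue < best[key]:
            best[key] = h.evalue
    return best


def build_knowledge_graph(
    virus_records: list[SeqRecord],
    host_records: list[SeqRecord],
    profiles: dict[str, ProteinClusterProfile],
    virus_host_hits: list[AlignmentHit],
    known_pairs: pd.DataFrame,
    host_taxonomy: pd.DataFrame,
    params: EdgeTestParams,
) -> KnowledgeGraph:
    """Assemble the knowledge graph from all pairwise evidence.

    Viruses listed in ``known_pairs`` are the training nodes and inherit
    the full lineage of their host; the rest stay unlabeled.  Duplicate
    alignment hits for a pair collapse to one edge carrying the best
    E-value.
    """
    graph = KnowledgeGraph()
    tax = _taxonomy_lookup(host_taxonomy)
    virus_ids = [r.id for r in virus_records]
    host_ids = [r.id for r in host_records]
    for hid in host_ids:
        if hid not in tax:
            raise ParameterError(f"host {hid!r} has no taxonomy row")

    for vid in virus_ids:
        graph.add_node(Node(id=vid, role="virus"))
    for hid in host_ids:
        graph.add_node(Node(id=hid, role="host", labels=tax[hid]))

    known: dict[str, str] = {}
    for _, row in known_pairs.iterrows():
        v, h = str(row["virus_id"]), str(row["host_id"])
        if v not in graph.nodes or h not in graph.nodes:
            raise ParameterError(f"known pair references unknown id: {v!r}-{h!r}")
        known[v] = h
        graph.nodes[v].labels = dict(tax[h])

    # virus-virus edges by the shared-cluster significance test
    empty = ProteinClusterProfile(genome_id="", clusters=frozenset())
    stat_cache: dict[tuple[int, int, int], bool] = {}
    for i in range(len(virus_ids)):
        pi = profiles.get(virus_ids[i], empty)
        for j in range(i + 1, len(virus_ids)):
            pj = profiles.get(virus_ids[j], empty)
            c = len(pi.clusters & pj.clusters)
            if c == 0:
                continue
            key = (min(pi.a, pj.a), max(pi.a, pj.a), c)
            hit = stat_cache.get(key)
            if hit is None:
                hit = virus_virus_edge(pi, pj, params)
                stat_cache[key] = hit
            if hit:
                graph.add_edge(virus_ids[i], virus_ids[j], Edge(provenance="virus-virus"))

    # virus-host edges: alignment below tau2, known pairs regardless
    best = best_evalue_per_pair(virus_host_hits)
    host_set = set(host_ids)
    virus_set = set(virus_ids)
    for (v, h), ev in best.items():
        if v not in virus_set or h not in host_set:
            continue
        if virus_host_edge(ev, is_known_pair=(known.get(v) == h), tau2=params.tau2):
            graph.add_edge(v, h, Edge(provenance="virus-host-alignment", evalue=ev))
    for v, h in known.items():
        key = (v, h) if v < h else (h, v)
        ev = best.get((v, h))
        graph.edges[key] = Edge(provenance="virus-host-known", evalue=ev)

    return graph


def encode_host_nodes(
    graph: KnowledgeGraph,
    virus_features: dict[str, np.ndarray],
    only_missing: bool = False,
) -> KnowledgeGraph:
    """Set virus features and derive host features as weighted averages.

    Host feature = sum_i v_i * w_i / sum_i w_i over neighboring viruses,
    with w_i = -log10(E_i) (clamped); known-interaction edges without an
    E-value use the maximum weight.  Hosts without virus neighbors get the
    zero vector with a warning.  Mutates and returns ``graph``.
    """
    for vid, feat in virus_features.items():
        if vid in graph.nodes:
            graph.nodes[vid].feature = np.asarray(feat, dtype=np.float64)
    for hid in graph.node_ids(role="host"):
        node = graph.nodes[hid]
        if only_missing and node.feature is not None:
            continue
        num = np.zeros(FEATURE_DIM)
        den = 0.0
        count = 0
        for vid, edge in graph.neighbors(hid):
            vfeat = graph.nodes[vid].feature
            if vfeat is None:
                raise ParameterError(f"virus {vid!r} lacks a feature vector")
            w = KNOWN_PAIR_WEIGHT if edge.evalue is None else log_weight(edge.evalue)
            num += w * vfeat
            den += w
            count += 1
        if count == 0 or den == 0.0:
            warnings.warn(f"host {hid!r} has no virus neighbors; zero feature", stacklevel=2)
            node.feature = np.zeros(FEATURE_DIM)
            node.no_neighbors = True
        else:
            node.feature = num / den
    return graph


def extend_graph(
    graph: KnowledgeGraph,
    new_host_records: list[SeqRecord],
    new_taxonomy_rows: pd.DataFrame,
    new_hits: list[AlignmentHit],
    params: EdgeTestParams,
) -> KnowledgeGraph:
    """Add labeled host nodes (possibly of novel taxa) to a copy of the graph.

    Edges are recomputed only for pairs involving the new hosts; existing
    nodes and edges are untouched.  New hosts with no qualifying hits stay
    as isolated labeled nodes (they still participate in the training
    loss).  Host features for the new nodes are derived from their virus
    neighbors afterwards via :func:`encode_host_nodes`.
    """
    out = graph.copy()
    tax = _taxonomy_lookup(new_taxonomy_rows)
    for rec in new_host_records:
        if rec.id in out.nodes:
            raise ParameterError(f"node id collision: {rec.id!r}")
        if rec.id not in tax:
            raise ParameterError(f"new host {rec.id!r} has no taxonomy row")
        out.add_node(Node(id=rec.id, role="host", labels=tax[rec.id]))
    new_ids = {rec.id for rec in new_host_records}
    best = best_evalue_per_pair(new_hits)
    for (v, h), ev in best.items():
        if h not in new_ids or v not in out.nodes or out.nodes[v].role != "virus":
            continue
        if virus_host_edge(ev, is_known_pair=False, tau2=params.tau2):
            out.add_edge(v, h, Edge(provenance="virus-host-alignment", evalue=ev))
    virus_feats = {
        vid: out.nodes[vid].feature
        for vid in out.node_ids(role="virus")
        if out.nodes[vid].feature is not None
    }
    if virus_feats:
        encode_host_nodes(out, virus_feats, only_missing=True)
    return out
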