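"""Protein similarity network and Markov clustering (MCL).

Alignment hits below an E-value cutoff become edges weighted by
-log10(E) (E clamped to >= 1e-180); protein clusters are the attractor
systems of the MCL iteration on the column-stochastic transition matrix.
Per-genome cluster-membership profiles feed the shared-cluster
significance test that creates virus-virus edges in the knowledge graph.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .sequence_io import AlignmentHit

#: E-values of 0.0 are clamped here before taking logs
EVALUE_CLAMP = 1e-180


def log_weight(evalue: float) -> float:
    """Edge weight -log10(E) with the 1e-180 clamp."""
    return -math.log10(max(evalue, EVALUE_CLAMP))


@dataclass
class WeightedGraph:
    """Undirected weighted protein similarity network."""

    nodes: list[str]
    edges: dict[tuple[str, str], float] = field(default_factory=dict)  # keys sorted pairs

    def add_edge(self, u: str, v: str, weight: float) -> None:
        if u == v:
            return
        key = (u, v) if u < v else (v, u)
        self.edges[key] = max(self.edges.get(key, 0.0), weight)

    def neighbors(self) -> dict[str, list[tuple[str, float]]]:
        adj: dict[str, list[tuple[str, float]]] = {n: [] for n in self.nodes}
        for (u, v), w in self.edges.items():
            adj[u].append((v, w))
            adj[v].append((u, w))
        return adj


@dataclass
class ProteinClusterProfile:
    """Cluster memberships of one genome; ``a`` is the Eq-style cluster count."""

    genome_id: str
    clusters: frozenset[str]

    @property
    def a(self) -> int:
        return len(self.clusters)


def build_protein_network(
    hits: list[AlignmentHit],
    evalue_cutoff: float = 1e-5,
    protein_ids: list[str] | None = None,
) -> WeightedGraph:
    """Build the similarity network from tabular hits.

    Reciprocal hits for a pair are merged keeping the smaller E-value; only
    pairs whose best E-value is below ``evalue_cutoff`` get an edge.
    ``protein_ids``, when given, fixes the node set so unaligned proteins
    appear as singletons.
    """
    best: dict[tuple[str, str], float] = {}
    seen: set[str] = set()
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        key = (h.query_id, h.subject_id) if h.query_id < h.subject_id else (h.subject_id, h.query_id)
        prev = best.get(key)
        if prev is None or h.evalue < prev:
            best[key] = h.evalue
        seen.add(h.query_id)
        seen.add(h.subject_id)
    nodes = list(protein_ids) if protein_ids is not None else sorted(seen)
    node_set = set(nodes)
    graph = WeightedGraph(nodes=nodes)
    for (u, v), ev in best.items():
        if ev < evalue_cutoff and u in node_set and v in node_set:
            graph.add_edge(u, v, log_weight(ev))
    return graph


def _connected_components(graph: WeightedGraph) -> list[list[str]]:
    adj = graph.neighbors()
    seen: set[str] = set()
    comps: list[list[str]] = []
    for start in graph.nodes:
        if start in seen:
            continue
        stack = [start]
        comp: list[str] = []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v, _ in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def _mcl_component(
    members: list[str],
    adj: dict[str, list[tuple[str, float]]],
    inflation: float,
    expansion: int,
    max_iter: int,
    prune: float,
    tol: float,
) -> list[set[str]]:
    k = len(members)
    if k == 1:
        return [set(members)]
    index = {n: i for i, n in enumerate(members)}
    M = np.zeros((k, k))
    for u in members:
        for v, w in adj[u]:
            M[index[v], index[u]] = w
    # self-loops at the column's max edge weight keep the iteration
    # invariant to uniform rescaling of all weights
    col_max = M.max(axis=0)
    col_max[col_max == 0] = 1.0
    M[np.diag_indices(k)] = col_max
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M**inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge; interpreting current matrix", stacklevel=2)

    # attractors: nodes with mass on their own diagonal
    eps = prune
    attractors = [i for i in range(k) if M[i, i] > eps]
    if not attractors:  # degenerate; treat max-row node as attractor
        attractors = [int(np.argmax(M.sum(axis=1)))]
    # attractor systems: connected attractors (overlap in any column or direct mass)
    att_set = set(attractors)
    parent = {i: i for i in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i in attractors:
        for j in attractors:
            if i < j and (M[i, j] > eps or M[j, i] > eps):
                union(i, j)
    for col in range(k):
        support = [i for i in attractors if M[i, col] > eps]
        for i in support[1:]:
            union(support[0], i)

    systems: dict[int, set[int]] = {}
    for i in attractors:
        systems.setdefault(find(i), set()).add(i)
    roots = sorted(systems)
    clusters: dict[int, set[str]] = {r: set() for r in roots}
    for col in range(k):
        masses = {r: sum(M[i, col] for i in systems[r]) for r in roots}
        best_mass = max(masses.values())
        if best_mass <= 0:
            # no attractor mass: node keeps to itself as a singleton
            clusters.setdefault(-col - 1, set()).add(members[col])
            continue
        # ties go to the system whose smallest member id sorts first
        cands = [r for r in roots if masses[r] == best_mass]
        best_r = min(cands, key=lambda r: min(members[i] for i in systems[r]))
        clusters[best_r].add(members[col])
    return [c for c in clusters.values() if c]


def mcl(
    graph: WeightedGraph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    prune: float = 1e-5,
    tol: float = 1e-8,
) -> list[set[str]]:
    """Markov clustering of the protein network.

    Runs the expansion/inflation/prune iteration per connected component
    (components can never merge, so this is exact) and returns disjoint
    clusters covering every node; singletons are allowed.  Clusters are
    sorted by their lexicographically smallest member.
    """
    if inflation <= 1.0:
        raise ParameterError("inflation must be > 1")
    if expansion < 2:
        raise ParameterError("expansion must be >= 2")
    adj = graph.neighbors()
    clusters: list[set[str]] = []
    for comp in _connected_components(graph):
        clusters.extend(
            _mcl_component(comp, adj, inflation, expansion, max_iter, prune, tol)
        )
    clusters.sort(key=lambda c: min(c))
    return clusters


def cluster_table(clusters: list[set[str]]) -> dict[str, str]:
    """Map each protein id to a stable cluster id (``PC_<n>``)."""
    out: dict[str, str] = {}
    for i, c in enumerate(clusters):
        cid = f"PC_{i:05d}"
        for p in c:
            out[p] = cid
    return out


def profile_genomes(
    clusters: list[set[str]],
    protein_to_genome: dict[str, str],
    genomes: list[str] | None = None,
) -> dict[str, ProteinClusterProfile]:
    """Per-genome sets of protein-cluster memberships.

    A genome's profile is the set of clusters containing at least one of
    its proteins.  Proteins whose genome is unknown raise
    :class:`ParameterError`.  ``genomes`` optionally fixes the output key
    set so genomes with no clustered proteins get empty profiles.
    """
    assignment = cluster_table(clusters)
    by_genome: dict[str, set[str]] = {g: set() for g in (genomes or [])}
    for protein, cid in assignment.items():
        genome = protein_to_genome.get(protein)
        if genome is None:
            raise ParameterError(f"protein {protein!r} has no genome mapping")
        by_genome.setdefault(genome, set()).add(cid)
    return {
        g: ProteinClusterProfile(genome_id=g, clusters=frozenset(cs))
        for g, cs in by_genome.items()
    }
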