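"""Per-rank graph convolutional networks with a calibration-aware loss.

A two-layer GCN (symmetric degree-normalized adjacency with self-loops)
followed by a dense SoftMax layer is trained separately for each
taxonomic rank on the same knowledge graph.  The training objective is
L = ECE + L2: the mean squared error between SoftMax rows and one-hot
labels over labeled nodes, plus the expected calibration error of the
labeled nodes' confidences, so that after training the SoftMax maximum is
a trustworthy confidence.  Predictions below a user-chosen confidence
threshold abstain, and cross-rank conflicts are resolved by truncating the
reported lineage at the highest inconsistent rank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ParameterError
from .graph_builder import FEATURE_DIM, KnowledgeGraph
from .synthetic_data import RANKS, TaxonomyTree


# --------------------------------------------------------------------------
# adjacency
# --------------------------------------------------------------------------

def normalize_adjacency(
    edges: list[tuple[str, str]], node_order: list[str]
) -> sp.csr_matrix:
    """Symmetric renormalized adjacency D^-1/2 (A + I) D^-1/2 (sparse)."""
    index = {n: i for i, n in enumerate(node_order)}
    k = len(node_order)
    rows, cols = list(range(k)), list(range(k))  # self-loops, exactly once
    for u, v in edges:
        if u not in index or v not in index:
            raise ParameterError(f"edge references unknown node: {u!r}-{v!r}")
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
    data = np.ones(len(rows))
    a_tilde = sp.coo_matrix((data, (rows, cols)), shape=(k, k)).tocsr()
    a_tilde.data = np.ones_like(a_tilde.data)  # dedupe any repeated edges
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    return (d_inv_sqrt @ a_tilde @ d_inv_sqrt).tocsr()


# --------------------------------------------------------------------------
# forward / calibration
# --------------------------------------------------------------------------

@dataclass
class GCNParams:
    theta0: np.ndarray  # (FEATURE_DIM, h1)
    theta1: np.ndarray  # (h1, h2)
    theta_dense: np.ndarray  # (h2, C)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def gcn_forward(features: np.ndarray, a_norm: sp.csr_matrix, params: GCNParams) -> np.ndarray:
    """SoftMax output of the two-layer GCN; rows sum to one."""
    if features.shape[1] != params.theta0.shape[0]:
        raise ParameterError("feature dimensionality does not match theta0")
    h1 = np.maximum(a_norm @ (features @ params.theta0), 0.0)
    h2 = np.maximum(a_norm @ (h1 @ params.theta1), 0.0)
    return _softmax(h2 @ params.theta_dense)


@dataclass
class CalibrationReport:
    """Per-bin reliability summary and the scalar ECE."""

    n_bins: int
    bin_counts: np.ndarray
    bin_accuracy: np.ndarray
    bin_confidence: np.ndarray
    ece: float

    def to_frame(self) -> pd.DataFrame:
        edges = np.arange(self.n_bins) / self.n_bins
        return pd.DataFrame(
            {
                "bin_lower": edges,
                "bin_upper": edges + 1.0 / self.n_bins,
                "count": self.bin_counts,
                "accuracy": self.bin_accuracy,
                "mean_confidence": self.bin_confidence,
            }
        )


def _bin_index(confidences: np.ndarray, n_bins: int) -> np.ndarray:
    # half-open bins [i/Nb, (i+1)/Nb); the top bin is closed at 1.0
    idx = np.floor(confidences * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def ece(confidences: np.ndarray, correct: np.ndarray, n_bins: int = 10) -> CalibrationReport:
    """Expected calibration error over uniform confidence bins.

    ECE = sum_i (T_i / T) * |Acc_i - conf_i| over non-empty bins, where
    Acc_i and conf_i are the accuracy and mean confidence of bin i.
    """
    confidences = np.asarray(confidences, dtype=np.float64)
    correct = np.asarray(correct, dtype=np.float64)
    if confidences.size == 0:
        raise ParameterError("ece() requires at least one sample")
    if confidences.shape != correct.shape:
        raise ParameterError("confidences and correctness must have equal length")
    if confidences.min() < 0 or confidences.max() > 1:
        raise ParameterError("confidences must lie in [0, 1]")
    idx = _bin_index(confidences, n_bins)
    counts = np.bincount(idx, minlength=n_bins).astype(np.float64)
    acc = np.zeros(n_bins)
    conf = np.zeros(n_bins)
    nonzero = counts > 0
    acc[nonzero] = np.bincount(idx, weights=correct, minlength=n_bins)[nonzero] / counts[nonzero]
    conf[nonzero] = (
        np.bincount(idx, weights=confidences, minlength=n_bins)[nonzero] / counts[nonzero]
    )
    total = counts.sum()
    value = float(np.sum(counts[nonzero] / total * np.abs(acc - conf)[nonzero]))
    return CalibrationReport(
        n_bins=n_bins, bin_counts=counts, bin_accuracy=acc, bin_confidence=conf, ece=value
    )


def loss(
    probs: np.ndarray,
    onehot: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 10,
    use_ece: bool = True,
) -> float:
    """Training objective L = ECE + L2 over the masked (labeled) nodes.

    L2 is the mean over masked nodes of the mean over classes of squared
    differences between the SoftMax row and the one-hot label.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterError("loss requires at least one labeled node")
    p = probs[mask]
    y = onehot[mask]
    l2 = float(np.mean((p - y) ** 2))
    if not use_ece:
        return l2
    conf = p.max(axis=1)
    correct = (p.argmax(axis=1) == y.argmax(axis=1)).astype(np.float64)
    return ece(conf, correct, n_bins).ece + l2


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class GCNConfig:
    h1: int = 256
    h2: int = 128
    lr: float = 1e-3
    epochs: int = 1000
    n_bins: int = 10
    use_ece: bool = True


@dataclass
class RankModel:
    """Trained GCN for one taxonomic rank."""

    rank: str
    classes: list[str]
    params: GCNParams
    node_order: list[str]
    calibration: CalibrationReport
    loss_history: list[float] = field(default_factory=list)


def _graph_tensors(graph: KnowledgeGraph) -> tuple[list[str], np.ndarray, sp.csr_matrix]:
    node_order = sorted(graph.nodes)
    feats = []
    for nid in node_order:
        f = graph.nodes[nid].feature
        if f is None:
            raise ParameterError(f"node {nid!r} has no feature vector")
        feats.append(f)
    features = np.stack(feats)
    a_norm = normalize_adjacency([(u, v) for u, v, _ in graph.edge_list()], node_order)
    return node_order, features, a_norm


def _labels_at_rank(graph: KnowledgeGraph, rank: str, node_order: list[str]):
    labels = {}
    for nid in node_order:
        node = graph.nodes[nid]
        if node.labels and rank in node.labels:
            labels[nid] = node.labels[rank]
    return labels


def train_gcn(
    graph: KnowledgeGraph,
    rank: str,
    config: GCNConfig | None = None,
    rng_seed: int = 0,
    exclude_from_loss: set[str] | None = None,
) -> RankModel:
    """Full-batch training of one rank's GCN with Adam on L = ECE + L2.

    All labeled nodes (every host plus the training viruses) enter the
    loss mask; ``exclude_from_loss`` holds labeled node ids out (used for
    held-out calibration checks).  The ECE term treats bin membership and
    per-bin accuracy as constants within a step, so its gradient flows
    only through the confidences.  Deterministic given ``rng_seed``.
    """
    config = config or GCNConfig()
    if rank not in RANKS:
        raise ParameterError(f"unknown rank {rank!r}")
    node_order, features, a_norm = _graph_tensors(graph)
    labels = _labels_at_rank(graph, rank, node_order)
    exclude = exclude_from_loss or set()
    train_labels = {n: t for n, t in labels.items() if n not in exclude}
    classes = sorted(set(train_labels.values()))
    if len(classes) < 2:
        raise ParameterError(f"rank {rank!r} has fewer than 2 label classes")
    class_index = {c: i for i, c in enumerate(classes)}

    k = len(node_order)
    onehot = np.zeros((k, len(classes)))
    mask = np.zeros(k, dtype=bool)
    for i, nid in enumerate(node_order):
        if nid in train_labels:
            mask[i] = True
            onehot[i, class_index[train_labels[nid]]] = 1.0

    rng = np.random.default_rng(rng_seed)
    dim = features.shape[1]
    theta0 = rng.standard_normal((dim, config.h1)) * math.sqrt(2.0 / dim)
    theta1 = rng.standard_normal((config.h1, config.h2)) * math.sqrt(2.0 / config.h1)
    theta_dense = rng.standard_normal((config.h2, len(classes))) * math.sqrt(2.0 / config.h2)
    params = [theta0, theta1, theta_dense]
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    n_masked = int(mask.sum())
    history: list[float] = []
    for step in range(1, config.epochs + 1):
        # forward with caches
        z0 = features @ params[0]
        h1_pre = a_norm @ z0
        h1 = np.maximum(h1_pre, 0.0)
        z1 = h1 @ params[1]
        h2_pre = a_norm @ z1
        h2 = np.maximum(h2_pre, 0.0)
        logits = h2 @ params[2]
        probs = _softmax(logits)

        p = probs[mask]
        y = onehot[mask]
        l2 = float(np.mean((p - y) ** 2))
        dL_dp_masked = 2.0 * (p - y) / p.size  # L2 part

        if config.use_ece:
            conf = p.max(axis=1)
            arg = p.argmax(axis=1)
            correct = (arg == y.argmax(axis=1)).astype(np.float64)
            report = ece(conf, correct, config.n_bins)
            total = report.ece + l2
            # d ECE / d conf_j = sign(conf_bin - acc_bin) / T  (bins, Acc detached)
            idx = _bin_index(conf, config.n_bins)
            sign = np.sign(report.bin_confidence - report.bin_accuracy)[idx]
            dL_dp_masked[np.arange(len(conf)), arg] += sign / n_masked
        else:
            total = l2
        history.append(total)

        dprobs = np.zeros_like(probs)
        dprobs[mask] = dL_dp_masked
        # softmax jacobian: dz = p * (g - sum(g * p))
        inner = (dprobs * probs).sum(axis=1, keepdims=True)
        dlogits = probs * (dprobs - inner)

        g_dense = h2.T @ dlogits
        dh2 = dlogits @ params[2].T
        dh2[h2_pre <= 0] = 0.0
        dz1 = a_norm.T @ dh2
        g_theta1 = h1.T @ dz1
        dh1 = dz1 @ params[1].T
        dh1[h1_pre <= 0] = 0.0
        dz0 = a_norm.T @ dh1
        g_theta0 = features.T @ dz0

        grads = [g_theta0, g_theta1, g_dense]
        lr_t = config.lr * math.sqrt(1 - beta2**step) / (1 - beta1**step)
        for pmat, g, m, v in zip(params, grads, adam_m, adam_v):
            m += (1 - beta1) * (g - m)
            v += (1 - beta2) * (g * g - v)
            pmat -= lr_t * m / (np.sqrt(v) + eps)

    final = GCNParams(theta0=params[0], theta1=params[1], theta_dense=params[2])
    probs = gcn_forward(features, a_norm, final)
    p = probs[mask]
    y = onehot[mask]
    conf = p.max(axis=1)
    correct = (p.argmax(axis=1) == y.argmax(axis=1)).astype(np.float64)
    report = ece(conf, correct, config.n_bins)
    return RankModel(
        rank=rank,
        classes=classes,
        params=final,
        node_order=node_order,
        calibration=report,
        loss_history=history,
    )


# --------------------------------------------------------------------------
# prediction / evaluation
# --------------------------------------------------------------------------

@dataclass
class Prediction:
    """Per-virus prediction across ranks, after conflict resolution."""

    virus_id: str
    per_rank: dict[str, tuple[str, float]]  # rank -> (taxon, confidence)
    lineage: dict[str, str]  # reported (post conflict resolution, thresholding)
    abstained: set[str]
    no_neighbors: bool = False


def resolve_conflicts(
    per_rank_taxa: dict[str, str], tree: TaxonomyTree
) -> dict[str, str]:
    """Truncate a predicted lineage at the first cross-rank inconsistency.

    Walking phylum downward, a rank's taxon must be a child of the taxon
    reported at the rank above; at the first violation (or gap) the report
    stops, keeping only the higher ranks.
    """
    reported: dict[str, str] = {}
    prev_taxon: str | None = None
    for rank in RANKS:
        taxon = per_rank_taxa.get(rank)
        if taxon is None:
            break
        if taxon not in tree.nodes:
            raise ParameterError(f"predicted taxon {taxon!r} absent from taxonomy")
        if tree.rank_of(taxon) != rank:
            raise ParameterError(f"taxon {taxon!r} is not at rank {rank!r}")
        if prev_taxon is not None and tree.parent(taxon) != prev_taxon:
            break
        reported[rank] = taxon
        prev_taxon = taxon
    return reported


def predict(
    graph: KnowledgeGraph,
    models: dict[str, RankModel],
    tree: TaxonomyTree,
    confidence_threshold: float = 0.0,
    virus_ids: list[str] | None = None,
) -> list[Prediction]:
    """Per-rank argmax predictions with confidence thresholding.

    Ranks whose confidence falls below the threshold abstain; the reported
    lineage is then truncated at the first abstention or inconsistency.
    Predictions are returned for ``virus_ids`` (default: all unlabeled
    virus nodes).
    """
    node_order, features, a_norm = _graph_tensors(graph)
    index = {n: i for i, n in enumerate(node_order)}
    if virus_ids is None:
        virus_ids = [
            n for n in graph.node_ids(role="virus") if not graph.nodes[n].labels
        ]
    for vid in virus_ids:
        if vid not in index:
            raise ParameterError(f"unknown node {vid!r}")

    rank_outputs: dict[str, np.ndarray] = {}
    for rank, model in models.items():
        if model.node_order != node_order:
            raise ParameterError("model node order does not match the graph")
        rank_outputs[rank] = gcn_forward(features, a_norm, model.params)

    neighbor_counts = {n: 0 for n in node_order}
    for u, v, _ in graph.edge_list():
        neighbor_counts[u] += 1
        neighbor_counts[v] += 1

    predictions: list[Prediction] = []
    for vid in virus_ids:
        i = index[vid]
        per_rank: dict[str, tuple[str, float]] = {}
        abstained: set[str] = set()
        surviving: dict[str, str] = {}
        for rank in RANKS:
            if rank not in models:
                continue
            model = models[rank]
            row = rank_outputs[rank][i]
            j = int(row.argmax())
            taxon, conf = model.classes[j], float(row[j])
            per_rank[rank] = (taxon, conf)
            if conf < confidence_threshold:
                abstained.add(rank)
            else:
                surviving[rank] = taxon
        lineage = resolve_conflicts(surviving, tree)
        predictions.append(
            Prediction(
                virus_id=vid,
                per_rank=per_rank,
                lineage=lineage,
                abstained=abstained,
                no_neighbors=neighbor_counts[vid] == 0,
            )
        )
    return predictions


def evaluate(predictions: list[Prediction], truth: pd.DataFrame) -> pd.DataFrame:
    """Prediction rate and accuracy per rank.

    rate = predicted / total; accuracy = correct / predicted, reported as
    NaN when nothing was predicted at a rank.
    """
    truth_map = {
        str(row["virus_id"]): {rank: str(row[rank]) for rank in RANKS}
        for _, row in truth.iterrows()
    }
    rows = []
    for rank in RANKS:
        total = 0
        predicted = 0
        correct = 0
        for pred in predictions:
            if pred.virus_id not in truth_map:
                continue
            total += 1
            taxon = pred.lineage.get(rank)
            if taxon is None:
                continue
            predicted += 1
            if taxon == truth_map[pred.virus_id][rank]:
                correct += 1
        rows.append(
            {
                "rank": rank,
                "total": total,
                "predicted": predicted,
                "prediction_rate": predicted / total if total else math.nan,
                "accuracy": correct / predicted if predicted else math.nan,
            }
        )
    return pd.DataFrame(rows)


def predictions_frame(predictions: list[Prediction]) -> pd.DataFrame:
    """Long-format table: one row per (virus, rank)."""
    rows = []
    for pred in predictions:
        for rank, (taxon, conf) in pred.per_rank.items():
            rows.append(
                {
                    "virus_id": pred.virus_id,
                    "rank": rank,
                    "taxon": taxon,
                    "confidence": conf,
                    "reported": pred.lineage.get(rank, ""),
                    "abstained": rank in pred.abstained,
                    "no_neighbors": pred.no_neighbors,
                }
            )
    return pd.DataFrame(rows)
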