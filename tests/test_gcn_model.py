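"""GCN forward pass, calibration error, loss, conflict resolution, metrics."""

import math

import numpy as np
import pandas as pd
import pytest

import hostgraph as hg
from hostgraph.gcn_model import (
    GCNConfig,
    GCNParams,
    Prediction,
    _graph_tensors,
    predictions_frame,
)
from hostgraph.graph_builder import FEATURE_DIM, Edge, KnowledgeGraph, Node
from hostgraph.synthetic_data import RANKS


class TestNormalizeAdjacency:
    def test_two_node_worked_case(self):
        a = hg.normalize_adjacency([("a", "b")], ["a", "b"])
        np.testing.assert_allclose(a.toarray(), [[0.5, 0.5], [0.5, 0.5]])

    def test_edgeless_graph_is_identity(self):
        a = hg.normalize_adjacency([], [f"n{i}" for i in range(5)])
        np.testing.assert_allclose(a.toarray(), np.eye(5))

    def test_symmetric_and_bounded_spectrum(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (nodes[i], nodes[j])
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.3
            ]
            dense = hg.normalize_adjacency(edges, nodes).toarray()
            np.testing.assert_allclose(dense, dense.T, atol=1e-12)
            eig = np.linalg.eigvalsh(dense)
            assert np.abs(eig).max() <= 1 + 1e-9

    def test_unknown_node_raises(self):
        with pytest.raises(hg.ParameterError):
            hg.normalize_adjacency([("a", "zz")], ["a", "b"])


def _random_params(rng, c=3, h1=8, h2=6, scale=0.05):
    # small weights keep the SoftMax away from saturation
    return GCNParams(
        theta0=rng.standard_normal((FEATURE_DIM, h1)) * scale,
        theta1=rng.standard_normal((h1, h2)) * scale,
        theta_dense=rng.standard_normal((h2, c)),
    )


class TestGCNForward:
    def test_rows_are_simplex_points(self):
        rng = np.random.default_rng(1)
        feats = rng.standard_normal((7, FEATURE_DIM))
        a = hg.normalize_adjacency([("n0", "n1"), ("n2", "n3")], [f"n{i}" for i in range(7)])
        out = hg.gcn_forward(feats, a, _random_params(rng))
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)
        assert (out >= 0).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        nodes = [f"n{i}" for i in range(6)]
        edges = [("n0", "n1"), ("n1", "n2"), ("n3", "n4"), ("n0", "n5")]
        feats = rng.standard_normal((6, FEATURE_DIM))
        params = _random_params(rng)
        out = hg.gcn_forward(feats, hg.normalize_adjacency(edges, nodes), params)
        perm = rng.permutation(6)
        perm_nodes = [nodes[i] for i in perm]
        out_p = hg.gcn_forward(
            feats[perm], hg.normalize_adjacency(edges, perm_nodes), params
        )
        np.testing.assert_allclose(out_p, out[perm], atol=1e-9)

    def test_edgeless_graph_isolates_nodes(self):
        rng = np.random.default_rng(3)
        feats = rng.standard_normal((4, FEATURE_DIM))
        a = hg.normalize_adjacency([], [f"n{i}" for i in range(4)])
        params = _random_params(rng)
        base = hg.gcn_forward(feats, a, params)
        feats2 = feats.copy()
        feats2[0] = rng.standard_normal(FEATURE_DIM)
        out = hg.gcn_forward(feats2, a, params)
        np.testing.assert_allclose(out[1:], base[1:], atol=1e-12)
        assert not np.allclose(out[0], base[0])

    def test_shape_mismatch_raises(self):
        rng = np.random.default_rng(4)
        a = hg.normalize_adjacency([], ["x", "y"])
        with pytest.raises(hg.ParameterError):
            hg.gcn_forward(rng.standard_normal((2, 7)), a, _random_params(rng))


def _ece_oracle(conf, corr, n_bins=10):
    """Independent per-bin loop implementation."""
    total = len(conf)
    value = 0.0
    for i in range(n_bins):
        lo, hi = i / n_bins, (i + 1) / n_bins
        members = [
            j for j, c in enumerate(conf)
            if (lo <= c < hi) or (i == n_bins - 1 and c == 1.0)
        ]
        if not members:
            continue
        acc = sum(corr[j] for j in members) / len(members)
        avg = sum(conf[j] for j in members) / len(members)
        value += len(members) / total * abs(acc - avg)
    return value


class TestECE:
    def test_perfect_calibration_zero(self):
        rep = hg.ece(np.ones(8), np.ones(8))
        assert rep.ece == 0.0

    def test_hand_computed_four_sample_case(self):
        rep = hg.ece(np.array([0.95, 0.85, 0.65, 0.30]), np.array([1, 1, 0, 1]))
        assert rep.ece == pytest.approx(0.3875, abs=1e-12)

    def test_single_bin_exact_match_zero(self):
        conf = np.array([0.62, 0.64, 0.66, 0.68])
        corr = np.array([1, 0, 1, 0.0])  # acc 0.5... mean conf 0.65
        rep = hg.ece(conf, corr)
        assert rep.ece == pytest.approx(abs(0.5 - 0.65))

    def test_empty_input_raises(self):
        with pytest.raises(hg.ParameterError):
            hg.ece(np.array([]), np.array([]))

    def test_matches_independent_loop_oracle(self):
        rng = np.random.default_rng(123)
        conf = rng.random(1000)
        corr = (rng.random(1000) < conf).astype(float)
        rep = hg.ece(conf, corr)
        assert rep.ece == pytest.approx(_ece_oracle(list(conf), list(corr)), abs=1e-12)
        assert rep.bin_counts.sum() == 1000


class TestLoss:
    def test_perfect_outputs_zero_loss(self):
        onehot = np.eye(4)
        assert hg.loss(onehot.copy(), onehot, np.ones(4, bool)) == 0.0

    def test_uniform_output_closed_form_l2(self):
        c = 5
        probs = np.full((3, c), 1 / c)
        onehot = np.zeros((3, c))
        onehot[:, 0] = 1.0
        expected_l2 = ((1 - 1 / c) ** 2 + (c - 1) / c**2) / c
        got = hg.loss(probs, onehot, np.ones(3, bool), use_ece=False)
        assert got == pytest.approx(expected_l2, abs=1e-12)

    def test_mask_contract(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((4, 3))
        probs = np.exp(z) / np.exp(z).sum(1, keepdims=True)
        onehot = np.eye(3)[[0, 1, 2, 0]]
        full = hg.loss(probs, onehot, np.array([True, True, True, True]))
        drop_labeled = hg.loss(probs, onehot, np.array([True, True, True, False]))
        assert full != pytest.approx(drop_labeled)

    def test_empty_mask_raises(self):
        with pytest.raises(hg.ParameterError):
            hg.loss(np.ones((2, 2)) / 2, np.eye(2), np.zeros(2, bool))


def _toy_graph(rng, n_per_class=6):
    """Two feature-separated classes of virus nodes + one labeled host each."""
    g = KnowledgeGraph()
    lineages = [
        dict(zip(RANKS, ["p0", "c0", "o0", "f0", "g0"])),
        dict(zip(RANKS, ["p1", "c1", "o1", "f1", "g1"])),
    ]
    for cls in range(2):
        center = np.zeros(FEATURE_DIM)
        center[cls * 10 : cls * 10 + 10] = 3.0
        for i in range(n_per_class):
            vid = f"v{cls}_{i}"
            labels = dict(lineages[cls]) if i < n_per_class - 2 else None
            g.add_node(Node(vid, "virus", feature=center + rng.standard_normal(FEATURE_DIM) * 0.3,
                            labels=labels))
        g.add_node(Node(f"h{cls}", "host", feature=center.copy(), labels=dict(lineages[cls])))
        for i in range(n_per_class):
            g.add_edge(f"v{cls}_{i}", f"h{cls}", Edge("virus-host-alignment", 1e-20))
    return g


class TestTrainPredict:
    def test_single_class_rank_raises(self):
        rng = np.random.default_rng(0)
        g = _toy_graph(rng)
        for node in g.nodes.values():
            if node.labels:
                node.labels = dict(node.labels, phylum="same")
        with pytest.raises(hg.ParameterError, match="fewer than 2"):
            hg.train_gcn(g, "phylum", GCNConfig(epochs=5))

    def test_learns_separable_toy_and_loss_decreases(self):
        rng = np.random.default_rng(1)
        g = _toy_graph(rng)
        model = hg.train_gcn(g, "genus", GCNConfig(epochs=300), rng_seed=7)
        assert model.loss_history[0] > model.loss_history[-1]
        node_order, feats, a = _graph_tensors(g)
        out = hg.gcn_forward(feats, a, model.params)
        idx = {n: i for i, n in enumerate(node_order)}
        for cls in range(2):
            for i in range(4, 6):  # the unlabeled viruses
                row = out[idx[f"v{cls}_{i}"]]
                assert model.classes[row.argmax()] == f"g{cls}"

    def test_determinism_same_seed(self):
        rng = np.random.default_rng(2)
        g = _toy_graph(rng)
        m1 = hg.train_gcn(g, "genus", GCNConfig(epochs=50), rng_seed=3)
        m2 = hg.train_gcn(g, "genus", GCNConfig(epochs=50), rng_seed=3)
        np.testing.assert_array_equal(m1.params.theta0, m2.params.theta0)
        assert m1.loss_history == m2.loss_history

    def test_threshold_monotonicity_and_abstention(self):
        rng = np.random.default_rng(3)
        g = _toy_graph(rng)
        tree = hg.TaxonomyTree({
            "p0": ("phylum", None), "c0": ("class", "p0"), "o0": ("order", "c0"),
            "f0": ("family", "o0"), "g0": ("genus", "f0"),
            "p1": ("phylum", None), "c1": ("class", "p1"), "o1": ("order", "c1"),
            "f1": ("family", "o1"), "g1": ("genus", "f1"),
        })
        models = {r: hg.train_gcn(g, r, GCNConfig(epochs=200), rng_seed=0) for r in RANKS}
        counts = []
        for thr in (0.0, 0.6, 0.9, 1.0):
            preds = hg.predict(g, models, tree, confidence_threshold=thr)
            counts.append(sum(len(p.lineage) for p in preds))
            if thr == 0.0:
                assert all(len(p.per_rank) == 5 for p in preds)
                assert all(not p.abstained for p in preds)
            if thr == 1.0:
                assert all(len(p.abstained) == 5 for p in preds)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestResolveConflicts:
    @pytest.fixture()
    def tree(self):
        return hg.generate_taxonomy(4, 2, 0)

    def test_consistent_lineage_unchanged(self, tree):
        lin = tree.lineage("genus_2")
        assert hg.resolve_conflicts(lin, tree) == lin

    def test_genus_conflicting_with_family_truncates_at_family(self, tree):
        lin = dict(tree.lineage("genus_0"))
        lin["genus"] = "genus_3"  # belongs to family_1, not family_0
        out = hg.resolve_conflicts(lin, tree)
        assert "genus" not in out
        assert out["family"] == "family_0"

    def test_conflict_at_class_keeps_only_phylum(self):
        tree = hg.generate_taxonomy(4, 1, 0)  # 4 distinct full lineages
        lin = dict(tree.lineage("genus_0"))
        lin["class"] = "class_1"
        out = hg.resolve_conflicts(lin, tree)
        assert set(out) == {"phylum"}

    def test_unknown_taxon_raises(self, tree):
        with pytest.raises(hg.ParameterError):
            hg.resolve_conflicts({"phylum": "martian"}, tree)


class TestEvaluate:
    def _truth(self, n):
        return pd.DataFrame(
            [
                {"virus_id": f"v{i}", "host_id": "h",
                 **{r: f"{r}_x" for r in RANKS}}
                for i in range(n)
            ]
        )

    def _pred(self, vid, genus_taxon=None):
        lineage = {r: f"{r}_x" for r in RANKS[:-1]}
        per_rank = {r: (lineage[r], 0.9) for r in RANKS[:-1]}
        if genus_taxon is not None:
            lineage["genus"] = genus_taxon
            per_rank["genus"] = (genus_taxon, 0.9)
        return Prediction(virus_id=vid, per_rank=per_rank, lineage=lineage, abstained=set())

    def test_rate_and_accuracy_arithmetic(self):
        preds = [self._pred(f"v{i}", "genus_x" if i < 6 else "genus_wrong")
                 for i in range(8)]
        preds += [self._pred("v8"), self._pred("v9")]
        m = hg.evaluate(preds, self._truth(10))
        genus = m[m["rank"] == "genus"].iloc[0]
        assert genus.prediction_rate == pytest.approx(0.8)
        assert genus.accuracy == pytest.approx(0.75)

    def test_all_abstain_gives_nan_accuracy(self):
        preds = [self._pred(f"v{i}") for i in range(3)]
        m = hg.evaluate(preds, self._truth(3))
        genus = m[m["rank"] == "genus"].iloc[0]
        assert genus.prediction_rate == 0.0
        assert math.isnan(genus.accuracy)

    def test_perfect_predictions(self):
        preds = [self._pred(f"v{i}", "genus_x") for i in range(4)]
        m = hg.evaluate(preds, self._truth(4))
        assert (m.prediction_rate == 1.0).all()
        assert (m.accuracy == 1.0).all()

    def test_predictions_frame_layout(self):
        preds = [self._pred("v0", "genus_x")]
        df = predictions_frame(preds)
        assert set(df.columns) >= {"virus_id", "rank", "taxon", "confidence", "reported"}
        assert len(df) == 5
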