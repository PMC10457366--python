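import dataclasses

import numpy as np
import pytest

from plmgraph.errors import DivergenceError, ValidationError
from plmgraph.gnn_ref import GNNConfig, forward, init_params, train
from plmgraph.graph_build import attach_features, build_graph, residue_onehot
from plmgraph.toy_tasks import ToyDataset, apr_labels, make_dataset

from conftest import random_rigid_transform


def small_graph(rng, n=12, feat_width=5):
    coords = rng.uniform(-10, 10, size=(n, 3))
    g = build_graph(coords, "knn", k=4)
    return attach_features(g, rng.normal(size=(n, feat_width)))


class TestForward:
    def test_invariance_under_rigid_motion(self, rng):
        g = small_graph(rng)
        cfg = GNNConfig(head="regress", layers=2, hidden_width=16,
                        head_hidden=8)
        params = init_params(cfg, 5)
        ref = forward(g, cfg, params)
        for trial in range(10):
            R, t = random_rigid_transform(rng, reflect=trial % 2 == 0)
            g2 = dataclasses.replace(g, coords=g.coords @ R.T + t)
            np.testing.assert_allclose(forward(g2, cfg, params), ref,
                                       atol=1e-5)

    def test_permutation_equivariance(self, rng):
        g = small_graph(rng)
        cfg = GNNConfig(head="classify", n_classes=4, layers=1,
                        hidden_width=8, head_hidden=8)
        params = init_params(cfg, 5)
        ref = forward(g, cfg, params)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        g2 = dataclasses.replace(
            g, coords=g.coords[perm], node_feats=g.node_feats[perm],
            edges=inv[g.edges],
        )
        np.testing.assert_allclose(forward(g2, cfg, params), ref[perm],
                                   atol=1e-10)

    def test_one_layer_path_graph_matches_hand_computation(self):
        """Naive per-edge loop re-derivation of a 1-layer forward pass."""
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [7.0, 0, 0]])
        g = build_graph(coords, "rball", cutoff=5.0)
        h = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        g = attach_features(g, h)
        cfg = GNNConfig(layers=1, hidden_width=2, aggregation="sum",
                        head="regress", head_hidden=2, dist_scale=100.0)
        params = init_params(cfg, 2, rng=np.random.default_rng(0))

        expected = []
        lay = params["layers"][0]
        hd = params["head"]
        agg = np.zeros((3, 2))
        for (i, j) in g.edges:
            d2 = np.sum((coords[i] - coords[j]) ** 2) / 100.0
            msg_in = np.concatenate([h[i], h[j], [d2]])
            agg[j] += np.tanh(msg_in @ lay["W_msg"] + lay["b_msg"])
        for i in range(3):
            hi = np.tanh(np.concatenate([h[i], agg[i]]) @ lay["W_upd"]
                         + lay["b_upd"])
            z = np.concatenate([h[i], hi])
            a = np.maximum(z @ hd["W1"] + hd["b1"], 0.0)
            expected.append((a @ hd["W2"] + hd["b2"])[0])

        np.testing.assert_allclose(forward(g, cfg, params), expected,
                                   atol=1e-12)

    def test_isometric_neighbourhoods_are_indistinguishable(self):
        """Two residues with the same features and congruent 1-hop
        environments get identical outputs from a 1-layer network."""
        coords = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
        g = build_graph(coords, "rball", cutoff=5.0)
        g = attach_features(g, residue_onehot("AGA"))
        cfg = GNNConfig(layers=1, hidden_width=8, head="regress",
                        head_hidden=4)
        params = init_params(cfg, 21)
        out = forward(g, cfg, params)
        assert out[0] == pytest.approx(out[2], abs=1e-12)
        assert out[0] != pytest.approx(out[1], abs=1e-6)


@pytest.fixture(scope="module")
def tiny_dataset():
    return make_dataset("apr", n_chains=30, length_range=(10, 16), seed=3)


class TestTrain:
    def test_constant_labels_reach_zero_rmse(self, tiny_dataset):
        ds = ToyDataset(
            chains=tiny_dataset.chains,
            labels=[[5] * len(s) for _, s in tiny_dataset.chains],
            task="rpe", splits=tiny_dataset.splits, gen_seed=3,
        )
        cfg = GNNConfig(head="regress", epochs=150, seed=0)
        report = train(ds, cfg)
        assert report.metric_name == "rmse"
        assert report.eval_metric < 0.1

    def test_linear_label_function_is_learned(self, tiny_dataset):
        """Labels equal to the position index, with the index available
        as a node feature: an identifiable regression."""
        from plmgraph.toy_tasks import build_features
        ds = ToyDataset(
            chains=tiny_dataset.chains,
            labels=[apr_labels(len(s)) for _, s in tiny_dataset.chains],
            task="rpe", splits=tiny_dataset.splits, gen_seed=3,
        )
        feats = build_features(ds, "with_index")
        graphs = [attach_features(build_graph(c, "knn", k=10), f)
                  for (c, _), f in zip(ds.chains, feats)]
        cfg = GNNConfig(head="regress", epochs=300, seed=0)
        report = train(ds, cfg, graphs=graphs)
        assert report.eval_metric < 0.5

    def test_training_is_reproducible(self, tiny_dataset):
        cfg = GNNConfig(head="classify", n_classes=tiny_dataset.max_len,
                        epochs=40, seed=11)
        r1 = train(tiny_dataset, cfg)
        r2 = train(tiny_dataset, cfg)
        assert r1.final_train_loss == r2.final_train_loss
        assert r1.eval_metric == r2.eval_metric

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_divergence_raises_with_epoch(self, tiny_dataset):
        ds = ToyDataset(
            chains=tiny_dataset.chains,
            labels=[[10**30] * len(s) for _, s in tiny_dataset.chains],
            task="rpe", splits=tiny_dataset.splits, gen_seed=3,
        )
        cfg = GNNConfig(head="regress", epochs=20, lr=1e20, seed=0)
        with pytest.raises(DivergenceError) as err:
            train(ds, cfg)
        assert err.value.epoch >= 1

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            GNNConfig(layers=0)
        with pytest.raises(ValidationError):
            GNNConfig(head="classify", n_classes=None)
        with pytest.raises(ValidationError):
            GNNConfig(aggregation="max")
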