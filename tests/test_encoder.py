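"""Message passing vs a dense oracle, JK aggregation, Set2Set invariance."""

import numpy as np
import pytest

from pockmol.nn.autodiff import Tensor
from pockmol.nn.encoder import (EncoderConfig, FEATURE_SCALE, GraphEncoder,
                                MessagePassingLayer, Set2Set, jk_aggregate)
from pockmol.pocket_graph import PocketGraph


def _random_graph(rng, n, d=8, p_edge=0.4):
    feats = rng.normal(size=(n, d)).astype(np.float32)
    edges, attr = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                a = float(rng.integers(0, 4))
                edges += [(i, j), (j, i)]
                attr += [a, a]
    edges = np.array(edges, dtype=np.int64).reshape(-1, 2)
    return feats, edges, np.array(attr, dtype=np.float32)


def _dense_reference(layer, feats, edges, attr):
    """Materialize the N×N weight matrix per channel with plain numpy."""
    n = feats.shape[0]
    channels = []
    for eps, net in zip(layer.eps, layer.edge_nets):
        W = np.zeros((n, n))
        for (src, dst), a in zip(edges.tolist(), attr.tolist()):
            h = np.tanh(np.array([[a]]) @ net.fc1.W.data + net.fc1.b.data)
            W[dst, src] = (h @ net.fc2.W.data + net.fc2.b.data).item()
        channels.append((1.0 + float(eps.data)) * feats + W @ feats)
    h = np.concatenate(channels, axis=1)
    h = np.maximum(0.0, h @ layer.update_fc1.W.data + layer.update_fc1.b.data)
    return h @ layer.update_fc2.W.data + layer.update_fc2.b.data


def test_message_passing_equals_dense_oracle():
    rng = np.random.default_rng(0)
    for n in (2, 5, 8):
        feats, edges, attr = _random_graph(rng, n)
        layer = MessagePassingLayer(rng, 8, 6, n_channels=3, edge_hidden=4)
        got = layer(Tensor(feats), edges,
                    Tensor(attr.reshape(-1, 1))).data
        want = _dense_reference(layer, feats, edges, attr)
        assert np.abs(got - want).max() < 1e-5


def test_isolated_node_uses_only_self_term():
    """With eps=0 and identity update nets, an isolated node passes through."""
    rng = np.random.default_rng(1)
    d = 4
    layer = MessagePassingLayer(rng, d, d, n_channels=1, edge_hidden=2)
    layer.update_fc1.W.data = np.eye(d, dtype=np.float32)
    layer.update_fc1.b.data[:] = 0
    layer.update_fc2.W.data = np.eye(d, dtype=np.float32)
    layer.update_fc2.b.data[:] = 0
    x = np.abs(rng.normal(size=(1, d))).astype(np.float32)  # positive: relu inert
    out = layer(Tensor(x), np.zeros((0, 2), dtype=np.int64),
                Tensor(np.zeros((0, 1), dtype=np.float32))).data
    assert np.allclose(out, x, atol=1e-6)


def test_two_node_weighted_sum():
    """x_i + w·x_j with the edge weight read off the frozen edge network."""
    rng = np.random.default_rng(2)
    d = 3
    layer = MessagePassingLayer(rng, d, d, n_channels=1, edge_hidden=2)
    layer.update_fc1.W.data = np.eye(d, dtype=np.float32)
    layer.update_fc1.b.data[:] = 0
    layer.update_fc2.W.data = np.eye(d, dtype=np.float32)
    layer.update_fc2.b.data[:] = 0
    x = np.abs(rng.normal(size=(2, d))).astype(np.float32) + 0.5
    attr = np.array([[1.0], [1.0]], dtype=np.float32)
    net = layer.edge_nets[0]
    w = (np.tanh(np.array([[1.0]]) @ net.fc1.W.data + net.fc1.b.data)
         @ net.fc2.W.data + net.fc2.b.data).item()
    out = layer(Tensor(x), np.array([[0, 1], [1, 0]]), Tensor(attr)).data
    want = x + w * x[::-1]
    assert np.allclose(out, want, atol=1e-5)


def test_jk_concat_slicing():
    rng = np.random.default_rng(3)
    mats = [Tensor(rng.normal(size=(4, 5)).astype(np.float32)) for _ in range(3)]
    out = jk_aggregate(mats, "concat").data
    for b, m in enumerate(mats):
        assert np.array_equal(out[:, 5 * b:5 * (b + 1)], m.data)
    assert np.array_equal(jk_aggregate(mats[:1], "concat").data, mats[0].data)
    with pytest.raises(ValueError):
        jk_aggregate([mats[0], Tensor(np.zeros((3, 5)))])


def test_jk_sum_and_max_modes():
    a = Tensor(np.array([[1.0, -2.0]], dtype=np.float32))
    b = Tensor(np.array([[0.5, 3.0]], dtype=np.float32))
    assert np.allclose(jk_aggregate([a, b], "sum").data, [[1.5, 1.0]])
    assert np.allclose(jk_aggregate([a, b], "max").data, [[1.0, 3.0]])


def test_set2set_single_node_and_symmetry():
    rng = np.random.default_rng(4)
    s2s = Set2Set(rng, dim=6, steps=3)
    node = rng.normal(size=(1, 6)).astype(np.float32)
    out1 = s2s(Tensor(node)).data
    # attention over one element is that element: second half = node embedding
    assert np.allclose(out1[6:], node[0], atol=1e-6)
    # two identical nodes read out exactly like one
    out2 = s2s(Tensor(np.vstack([node, node]))).data
    assert np.allclose(out1, out2, atol=1e-5)


def test_set2set_permutation_invariance():
    rng = np.random.default_rng(5)
    s2s = Set2Set(rng, dim=6, steps=3)
    nodes = rng.normal(size=(10, 6)).astype(np.float32)
    base = s2s(Tensor(nodes)).data
    for _ in range(5):
        perm = rng.permutation(10)
        assert np.abs(s2s(Tensor(nodes[perm])).data - base).max() < 1e-5


def _permute_graph(g, perm):
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return PocketGraph(g.pocket_id, g.node_features[perm],
                       inv[g.edges], g.edge_attr.copy(), g.coords[perm])


def test_encode_deterministic_and_permutation_invariant(fixture_pocket_graph):
    enc = GraphEncoder(EncoderConfig(node_dim=8, hidden_dim=8, num_layers=2,
                                     num_channels=2, set2set_steps=2, seed=7))
    g = fixture_pocket_graph
    e1, e2 = enc(g).data, enc(g).data
    assert np.array_equal(e1, e2)
    rng = np.random.default_rng(8)
    for _ in range(10):
        perm = rng.permutation(g.num_nodes)
        ep = enc(_permute_graph(g, perm)).data
        assert np.abs(ep - e1).max() < 1e-4


def test_graph_entry_applies_feature_scaling(fixture_pocket_graph):
    """encode(graph) equals the unscaled pipeline fed pre-scaled features."""
    enc = GraphEncoder(EncoderConfig(node_dim=8, hidden_dim=4, num_layers=1,
                                     num_channels=1, set2set_steps=1, seed=0))
    g = fixture_pocket_graph
    via_graph = enc(g).data
    manual = enc.readout(enc.node_embeddings(
        g.node_features * FEATURE_SCALE, g.edges, g.edge_attr)).data
    assert np.allclose(via_graph, manual, atol=1e-7)
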