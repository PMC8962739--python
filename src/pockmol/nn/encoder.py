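"""Graph neural network encoder for binding-pocket graphs.

Each message-passing layer computes, per channel c,

    m_i^c = (1 + eps_c) * x_i + sum_{j in N(i)} h_omega_c(e_ij) * x_j

where ``eps_c`` is a trainable scalar (initialized to 0) and
``h_omega_c`` is a two-layer fully connected network mapping the scalar
edge attribute to a scalar neighbour weight. The channels are
concatenated and passed through an update network ``h_theta``. Outputs
of all layers are aggregated by a jumping-knowledge network
(concatenation mode by default) and reduced to a fixed-size vector by a
Set2Set attention readout, whose output length is twice the node
dimension. The whole map is invariant to node relabeling.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Parameter, Tensor, concat, scatter_add, zeros
from .modules import LSTMCell, Linear, MLP2, Module


#: Fixed per-column scaling applied to raw node features on entry, so
#: every input is O(1) regardless of its physical unit (hydrophobicity
#: spans ±4.5, SASA tens of Å², coordinates tens of Å). Purely a
#: numerical convention of the model, recorded here once.
FEATURE_SCALE = np.array([1 / 4.5, 1.0, 1.0, 1 / 50.0, 1.0,
                          1 / 10.0, 1 / 10.0, 1 / 10.0], dtype=np.float32)


@dataclass
class EncoderConfig:
    node_dim: int = 8          # F: input features per node
    hidden_dim: int = 64       # H: width after each layer's update network
    num_layers: int = 4        # K
    num_channels: int = 8      # C
    edge_hidden: int = 8       # hidden width of the per-channel edge network
    set2set_steps: int = 3
    jk_mode: str = "concat"    # concat | max | sum
    seed: int = 0

    def __post_init__(self):
        if self.num_layers < 1 or self.num_channels < 1 or self.hidden_dim < 1:
            raise ValueError("layers, channels and hidden dim must be >= 1")

    @property
    def node_embedding_dim(self) -> int:
        if self.jk_mode == "concat":
            return self.num_layers * self.hidden_dim
        return self.hidden_dim

    @property
    def embedding_dim(self) -> int:
        return 2 * self.node_embedding_dim  # Set2Set doubles the node dim


class MessagePassingLayer(Module):
    def __init__(self, rng, n_in: int, n_out: int, n_channels: int, edge_hidden: int):
        self.eps = [Parameter(np.zeros(())) for _ in range(n_channels)]
        self.edge_nets = [MLP2(rng, 1, edge_hidden, 1) for _ in range(n_channels)]
        self.update_fc1 = Linear(rng, n_channels * n_in, n_out)
        self.update_fc2 = Linear(rng, n_out, n_out)

    def __call__(self, x: Tensor, edges: np.ndarray, edge_attr: Tensor) -> Tensor:
        n = x.shape[0]
        channels = []
        for eps, edge_net in zip(self.eps, self.edge_nets):
            self_term = (1.0 + eps) * x
            if len(edges):
                w = edge_net(edge_attr)                      # M×1 neighbour weights
                msg = w * x.gather_rows(edges[:, 0])          # M×d
                agg = scatter_add(msg, edges[:, 1], n)        # N×d
                channels.append(self_term + agg)
            else:
                channels.append(self_term)                    # isolated nodes
        h = concat(channels, axis=1)
        return self.update_fc2(self.update_fc1(h).relu())


def jk_aggregate(per_layer: list[Tensor], mode: str = "concat") -> Tensor:
    """Jumping-knowledge aggregation of per-layer node features."""
    if not per_layer:
        raise ValueError("need at least one layer output")
    if len({t.shape[0] for t in per_layer}) != 1:
        raise ValueError("inconsistent node counts across layers")
    if mode == "concat":
        return per_layer[0] if len(per_layer) == 1 else concat(per_layer, axis=1)
    if mode == "sum":
        out = per_layer[0]
        for t in per_layer[1:]:
            out = out + t
        return out
    if mode == "max":
        out = per_layer[0]
        for t in per_layer[1:]:
            gate = Tensor((t.data > out.data).astype(np.float32))
            out = gate * t + (1.0 - gate) * out
        return out
    raise ValueError(f"unknown JK mode {mode!r}")


class Set2Set(Module):
    """Order-invariant attention readout: N×D node set → length-2D vector."""

    def __init__(self, rng, dim: int, steps: int):
        self.lstm = LSTMCell(rng, 2 * dim, dim)
        self.steps = steps
        self.dim = dim

    def __call__(self, nodes: Tensor) -> Tensor:
        q_star = zeros(1, 2 * self.dim)
        h, c = zeros(1, self.dim), zeros(1, self.dim)
        for _ in range(self.steps):
            h, c = self.lstm(q_star, h, c)
            scores = nodes @ h.reshape(self.dim, 1)          # N×1
            alpha = scores.log_softmax(axis=0).exp()
            read = (alpha * nodes).sum(axis=0, keepdims=True)  # 1×D
            q_star = concat([h, read], axis=1)
        return q_star.reshape(2 * self.dim)


class GraphEncoder(Module):
    def __init__(self, config: EncoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        dims = [config.node_dim] + [config.hidden_dim] * config.num_layers
        self.layers = [
            MessagePassingLayer(rng, dims[k], dims[k + 1],
                                config.num_channels, config.edge_hidden)
            for k in range(config.num_layers)
        ]
        self.readout = Set2Set(rng, config.node_embedding_dim, config.set2set_steps)

    def node_embeddings(self, node_features, edges, edge_attr) -> Tensor:
        x = node_features if isinstance(node_features, Tensor) else Tensor(node_features)
        attr = edge_attr if isinstance(edge_attr, Tensor) else Tensor(
            np.asarray(edge_attr, dtype=np.float32).reshape(-1, 1))
        per_layer = []
        for layer in self.layers:
            x = layer(x, edges, attr)
            per_layer.append(x)
        return jk_aggregate(per_layer, self.config.jk_mode)

    def __call__(self, graph) -> Tensor:
        """PocketGraph → fixed-size graph embedding (length 2·K·H).

        Raw node features in physical units are rescaled to O(1) here
        (see :data:`FEATURE_SCALE`); features of non-standard width are
        passed through untouched.
        """
        feats = graph.node_features
        if feats.shape[1] == FEATURE_SCALE.shape[0]:
            feats = feats * FEATURE_SCALE
        nodes = self.node_embeddings(feats, graph.edges, graph.edge_attr)
        return self.readout(nodes)

    def encode_batch(self, graphs) -> Tensor:
        rows = [self(g).reshape(1, -1) for g in graphs]
        return rows[0] if len(rows) == 1 else concat(rows, axis=0)
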