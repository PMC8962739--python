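"""Small neural building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor, concat, glorot, zeros


class Module:
    """Base with recursive parameter discovery over attributes/lists."""

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item))
                    elif isinstance(item, Module):
                        out.extend(item.named_parameters(f"{key}.{i}."))
        return out

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def load_state(self, state: dict, prefix: str = ""):
        for name, p in self.named_parameters(prefix):
            p.data = np.asarray(state[name], dtype=p.data.dtype)

    def state(self, prefix: str = "") -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters(prefix)}


class Linear(Module):
    def __init__(self, rng, n_in: int, n_out: int, bias: bool = True):
        self.W = glorot(rng, n_in, n_out)
        self.b = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y


class MLP2(Module):
    """Two fully connected layers with a tanh in between."""

    def __init__(self, rng, n_in: int, n_hidden: int, n_out: int):
        self.fc1 = Linear(rng, n_in, n_hidden)
        self.fc2 = Linear(rng, n_hidden, n_out)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).tanh())


class Embedding(Module):
    def __init__(self, rng, n_tokens: int, dim: int):
        self.weight = Parameter(rng.normal(0.0, 0.1, size=(n_tokens, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight.gather_rows(idx)


class GRUCell(Module):
    def __init__(self, rng, n_in: int, n_hidden: int):
        self.Wz = glorot(rng, n_in, n_hidden)
        self.Uz = glorot(rng, n_hidden, n_hidden)
        self.bz = Parameter(np.zeros(n_hidden))
        self.Wr = glorot(rng, n_in, n_hidden)
        self.Ur = glorot(rng, n_hidden, n_hidden)
        self.br = Parameter(np.zeros(n_hidden))
        self.Wn = glorot(rng, n_in, n_hidden)
        self.Un = glorot(rng, n_hidden, n_hidden)
        self.bn = Parameter(np.zeros(n_hidden))

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        z = (x @ self.Wz + h @ self.Uz + self.bz).sigmoid()
        r = (x @ self.Wr + h @ self.Ur + self.br).sigmoid()
        n = (x @ self.Wn + (r * h) @ self.Un + self.bn).tanh()
        return (1.0 - z) * n + z * h


class LSTMCell(Module):
    def __init__(self, rng, n_in: int, n_hidden: int):
        self.Wi = glorot(rng, n_in, 4 * n_hidden)
        self.Ui = glorot(rng, n_hidden, 4 * n_hidden)
        # small random bias: with zero bias and zero initial state the
        # first hidden states are structurally zero and the recurrent
        # weights never see a gradient
        self.bi = Parameter(rng.normal(0.0, 0.1, size=4 * n_hidden))
        self.n_hidden = n_hidden

    def __call__(self, x: Tensor, h: Tensor, c: Tensor):
        gates = x @ self.Wi + h @ self.Ui + self.bi
        H = self.n_hidden
        i = gates[:, 0:H].sigmoid()
        f = gates[:, H:2 * H].sigmoid()
        g = gates[:, 2 * H:3 * H].tanh()
        o = gates[:, 3 * H:4 * H].sigmoid()
        c_new = f * c + i * g
        return o * c_new.tanh(), c_new
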