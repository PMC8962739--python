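"""GRU sequence decoder conditioned on a pocket graph embedding.

The decoder factorizes the conditional probability of a molecule string
as P(s_0|pocket) · Π_t P(s_t | pocket, s_0..s_{t-1}). The graph
embedding, linearly projected to the token-embedding width, occupies the
input slot of step 0 (there is no start-of-sequence token); every later
step consumes the embedded previous token — the ground-truth token under
teacher forcing, the model's own sample at inference. Generation stops
at the end-of-string token or at the length cap (flagged truncation).
Training minimizes the negative log likelihood −Σ_t log P(s_t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..tokenizer import EOS_IDX, PAD_IDX, TokenSequence
from .autodiff import Tensor, concat, zeros
from .modules import Embedding, GRUCell, Linear, Module


@dataclass
class DecoderConfig:
    vocab_size: int
    cond_dim: int              # graph-embedding length (2·K·H from the encoder)
    token_embedding_dim: int = 128
    hidden_dim: int = 512
    num_layers: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.vocab_size, self.cond_dim, self.token_embedding_dim,
               self.hidden_dim, self.num_layers) < 1:
            raise ValueError("all decoder dimensions must be positive")


class GruDecoder(Module):
    def __init__(self, config: DecoderConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.project = Linear(rng, config.cond_dim, config.token_embedding_dim)
        self.embed = Embedding(rng, config.vocab_size, config.token_embedding_dim)
        dims = [config.token_embedding_dim] + [config.hidden_dim] * config.num_layers
        self.cells = [GRUCell(rng, dims[i], dims[i + 1]) for i in range(config.num_layers)]
        self.head = Linear(rng, config.hidden_dim, config.vocab_size)

    # -- shared one-step machinery --------------------------------------
    def _step(self, x: Tensor, hidden: list[Tensor]) -> tuple[Tensor, list[Tensor]]:
        new_hidden = []
        for cell, h in zip(self.cells, hidden):
            x = cell(x, h)
            new_hidden.append(x)
        return self.head(x), new_hidden

    def _init_hidden(self, batch: int) -> list[Tensor]:
        return [zeros(batch, self.config.hidden_dim) for _ in self.cells]

    # -- teacher forcing -------------------------------------------------
    def step_logprob_matrix(self, embeddings: Tensor, targets: np.ndarray,
                            lengths: np.ndarray) -> Tensor:
        """B×T tensor of log P(s_t) at the target tokens; padded steps 0.

        ``targets`` is a right-padded index matrix whose rows end with
        <eos>; step 0 is conditioned on the projected graph embedding.
        """
        targets = np.asarray(targets)
        batch, t_max = targets.shape
        if t_max > 0 and int(lengths.max()) > t_max:
            raise ValueError("length exceeds target matrix width")
        hidden = self._init_hidden(batch)
        x = self.project(embeddings if isinstance(embeddings, Tensor) else Tensor(embeddings))
        cols = []
        rows_idx = np.arange(batch)
        for t in range(t_max):
            logits, hidden = self._step(x, hidden)
            logp = logits.log_softmax(axis=1)
            picked = logp[rows_idx, targets[:, t]]           # (B,)
            mask = (t < lengths).astype(np.float32)
            cols.append((picked * Tensor(mask)).reshape(batch, 1))
            x = self.embed(targets[:, t])
        return concat(cols, axis=1) if len(cols) > 1 else cols[0]

    def teacher_forced_logprobs(self, embedding, target: TokenSequence) -> np.ndarray:
        """Per-step log-probability vector for one sequence (incl. eos step)."""
        if not target.terminated:
            raise ValueError("teacher forcing requires a terminated sequence")
        idx = [i for i in target.indices if i != PAD_IDX]
        if any(i >= self.config.vocab_size for i in idx):
            raise ValueError("target index out of vocabulary range")
        emb = embedding if isinstance(embedding, Tensor) else Tensor(embedding)
        mat = np.asarray([idx])
        lengths = np.array([len(idx)])
        return self.step_logprob_matrix(emb.reshape(1, -1), mat, lengths).data[0]

    def nll_loss(self, embeddings: Tensor, targets: np.ndarray,
                 lengths: np.ndarray) -> Tensor:
        """Mean over sequences of the per-sequence token log-prob sum, negated."""
        logp = self.step_logprob_matrix(embeddings, targets, lengths)
        return -(logp.sum() / targets.shape[0])

    # -- sampling --------------------------------------------------------
    def sample(self, embeddings, max_len: int = 140, mode: str = "multinomial",
               temperature: float = 1.0, rng: np.random.Generator | None = None
               ) -> list[TokenSequence]:
        """Autoregressive sampling; one TokenSequence per embedding row.

        ``greedy`` takes the modal token each step and is deterministic;
        ``multinomial`` samples from the softmax at the given temperature
        (temperature → 0 reduces to greedy). <pad> is masked out of the
        sampling support. Rows that never emit <eos> within ``max_len``
        steps come back with ``terminated=False``.
        """
        if max_len < 1:
            raise ValueError("max_len must be >= 1")
        if mode not in ("greedy", "multinomial"):
            raise ValueError(f"unknown sampling mode {mode!r}")
        if mode == "multinomial" and temperature <= 1e-8:
            mode = "greedy"
        if rng is None:
            rng = np.random.default_rng()
        emb = embeddings if isinstance(embeddings, Tensor) else Tensor(embeddings)
        if emb.data.ndim == 1:
            emb = emb.reshape(1, -1)
        batch = emb.shape[0]
        hidden = self._init_hidden(batch)
        x = self.project(emb)
        alive = np.ones(batch, dtype=bool)
        emitted: list[list[int]] = [[] for _ in range(batch)]
        for _ in range(max_len):
            logits, hidden = self._step(x, hidden)
            scores = logits.data.astype(np.float64).copy()
            scores[:, PAD_IDX] = -np.inf
            if mode == "greedy":
                tokens = scores.argmax(axis=1)
            else:
                scores /= temperature
                scores -= scores.max(axis=1, keepdims=True)
                probs = np.exp(scores)
                probs /= probs.sum(axis=1, keepdims=True)
                u = rng.random((batch, 1))
                tokens = (probs.cumsum(axis=1) < u).sum(axis=1)
                tokens = np.minimum(tokens, probs.shape[1] - 1)
            for b in range(batch):
                if alive[b]:
                    emitted[b].append(int(tokens[b]))
                    if tokens[b] == EOS_IDX:
                        alive[b] = False
            if not alive.any():
                break
            x = self.embed(tokens)
        out = []
        for b in range(batch):
            terminated = bool(emitted[b] and emitted[b][-1] == EOS_IDX)
            out.append(TokenSequence(emitted[b], terminated=terminated))
        return out

    def step_distribution(self, embedding, prefix: list[int]) -> np.ndarray:
        """Exact next-token distribution P(s_t | pocket, prefix) as probabilities."""
        emb = embedding if isinstance(embedding, Tensor) else Tensor(embedding)
        x = self.project(emb.reshape(1, -1))
        hidden = self._init_hidden(1)
        logits, hidden = self._step(x, hidden)
        for tok in prefix:
            x = self.embed(np.array([tok]))
            logits, hidden = self._step(x, hidden)
        z = logits.data[0].astype(np.float64)
        z -= z.max()
        p = np.exp(z)
        return p / p.sum()


def sequence_nll(logprobs: np.ndarray) -> float:
    """Eq-3-style loss for a single sequence: −Σ_t log P(s_t)."""
    lp = np.asarray(logprobs, dtype=np.float64)
    if not np.all(np.isfinite(lp)):
        raise ValueError("non-finite log-probabilities")
    return float(-lp.sum())
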