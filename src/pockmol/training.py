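"""Dataset assembly and the end-to-end training loop.

Dataset logic follows the study protocol: pocket/ligand pairs are
filtered on synthetic accessibility (molecules with SA score ≤ 1 or ≥ 6
are removed as trivially simple or implausibly complex), then randomly
split 90/10 into train and test subsets under a recorded seed. Training
minimizes the mean per-sequence negative log likelihood with Adam and
gradient-norm clipping; encoder and decoder parameters are updated
jointly (end-to-end), which is what lets the model learn
P(molecule | pocket) rather than a pocket-independent P(molecule).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .nn.autodiff import Tensor
from .nn.decoder import DecoderConfig
from .nn.encoder import EncoderConfig
from .nn.model import PocketToMol
from .pocket_graph import PocketGraph
from .tokenizer import TokenSequence, Vocabulary


# ---------------------------------------------------------------------------
# dataset


@dataclass
class PairedDataset:
    pairs: list[tuple[PocketGraph, TokenSequence]]
    vocab: Vocabulary
    split: str = "all"

    def __post_init__(self):
        ids = [g.pocket_id for g, _ in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("pocket_ids must be unique within a dataset")
        v = self.vocab.size
        for _, seq in self.pairs:
            if any(i >= v for i in seq.indices):
                raise ValueError("token sequence not encodable under the vocabulary")

    def __len__(self) -> int:
        return len(self.pairs)


def sa_filter(records: list[tuple], low: float = 1.0, high: float = 6.0) -> list[tuple]:
    """Keep records whose SA score lies strictly between the bounds.

    ``records`` are (id, smiles, sa_score) tuples; boundary scores equal
    to the bounds are removed along with everything outside them. The SA
    score itself is supplied by the caller (see :func:`default_sa_scorer`).
    """
    out = []
    for rec in records:
        score = float(rec[2])
        if not math.isfinite(score):
            raise ValueError(f"non-finite SA score in record {rec[0]!r}")
        if low < score < high:
            out.append(rec)
    return out


def default_sa_scorer():
    """The Ertl–Schuffenhauer synthetic-accessibility estimator (RDKit contrib).

    Returned as a SMILES → float callable; raises ImportError if the
    contrib tree is unavailable, in which case callers supply scores.
    """
    import os
    import sys

    from rdkit import Chem
    from rdkit.Chem import RDConfig
    sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
    if sa_dir not in sys.path:
        sys.path.append(sa_dir)
    import sascorer  # type: ignore

    def score(smiles: str) -> float:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return float(sascorer.calculateScore(mol))

    return score


def split_dataset(dataset: PairedDataset, test_fraction: float = 0.10,
                  seed: int = 0) -> tuple[PairedDataset, PairedDataset]:
    """Seeded disjoint+exhaustive train/test partition (default 90/10)."""
    n = len(dataset)
    if n < 10:
        raise ValueError("need at least 10 pairs to split")
    n_test = int(round(test_fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [p for i, p in enumerate(dataset.pairs) if i not in test_idx]
    test = [p for i, p in enumerate(dataset.pairs) if i in test_idx]
    return (PairedDataset(train, dataset.vocab, split="train"),
            PairedDataset(test, dataset.vocab, split="test"))


# ---------------------------------------------------------------------------
# optimization


@dataclass
class OptimConfig:
    lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 32
    clip_norm: float = 5.0
    seed: int = 0
    max_len: int = 140
    freeze_encoder: bool = False   # zero encoder gradients (ablation)
    unconditional: bool = False    # replace the embedding with a constant


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else 0.0
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = (p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def state(self) -> dict:
        return {"t": self.t,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state(self, state: dict) -> None:
        self.t = int(state["t"])
        for m, src in zip(self.m, state["m"]):
            m[...] = src
        for v, src in zip(self.v, state["v"]):
            v[...] = src


def clip_gradients(params, max_norm: float) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = math.sqrt(total)
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


# ---------------------------------------------------------------------------
# fit


@dataclass
class FitResult:
    model: PocketToMol
    losses: list[float]            # mean NLL per epoch (post-update evaluation order)
    initial_loss: float
    config: OptimConfig

    @property
    def final_loss(self) -> float:
        return self.losses[-1]


class DivergenceError(RuntimeError):
    pass


def evaluate_loss(model: PocketToMol, dataset: PairedDataset,
                  max_len: int = 140, unconditional: bool = False) -> float:
    graphs = [g for g, _ in dataset.pairs]
    seqs = [s for _, s in dataset.pairs]
    return float(model.batch_loss(graphs, seqs, max_len=max_len,
                                  unconditional=unconditional).data)


def fit(dataset: PairedDataset, encoder_config: EncoderConfig,
        decoder_config: DecoderConfig, optim: OptimConfig = OptimConfig(),
        log_path=None) -> FitResult:
    """Train an encoder-decoder model on a paired dataset.

    Returns the trained model and the epoch loss curve; raises
    :class:`DivergenceError` on a NaN loss. With ``freeze_encoder`` the
    encoder keeps its random initialization (only the decoder adapts);
    with ``unconditional`` the decoder sees a constant zero embedding,
    the pocket-blind baseline.
    """
    if len(dataset) == 0:
        raise ValueError("empty training dataset")
    model = PocketToMol(encoder_config, decoder_config, dataset.vocab)
    enc_params = set(id(p) for p in model.encoder.parameters())
    params = model.parameters()
    opt = Adam(params, lr=optim.lr)
    rng = np.random.default_rng(optim.seed)
    log = open(log_path, "w") if log_path else None

    initial = evaluate_loss(model, dataset, max_len=optim.max_len,
                            unconditional=optim.unconditional)
    losses: list[float] = []
    n = len(dataset)
    for epoch in range(optim.epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, optim.batch_size):
            batch = [dataset.pairs[i] for i in order[start:start + optim.batch_size]]
            graphs = [g for g, _ in batch]
            seqs = [s for _, s in batch]
            model.zero_grad()
            loss = model.batch_loss(graphs, seqs, max_len=optim.max_len,
                                    unconditional=optim.unconditional)
            value = float(loss.data)
            if not math.isfinite(value):
                raise DivergenceError(f"loss diverged at epoch {epoch}: {value}")
            loss.backward()
            if optim.freeze_encoder or optim.unconditional:
                for p in params:
                    if id(p) in enc_params:
                        p.grad = None
            clip_gradients(params, optim.clip_norm)
            opt.step()
            epoch_loss += value * len(batch)
            seen += len(batch)
        losses.append(epoch_loss / seen)
        if log:
            log.write(json.dumps({"epoch": epoch, "loss": losses[-1]}) + "\n")
            log.flush()
    if log:
        log.close()
    return FitResult(model=model, losses=losses, initial_loss=initial, config=optim)
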