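"""Batch sampling from a trained model, frequency ranking, top-k selection.

For a target pocket, molecules are drawn in fixed-size batches (default
2,048; a total of 20,480 therefore takes exactly 10 batches), decoded to
canonical SMILES, grouped by identity, ranked by sampling frequency and
cut to the top-k (default 100) most frequent candidates. Samples that
hit the length cap without emitting end-of-string are excluded from the
ranking but counted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .tokenizer import decode as decode_indices
from .nn.autodiff import Tensor


@dataclass(frozen=True)
class GeneratedSample:
    smiles: str
    frequency: int
    rank: int


@dataclass
class SampleResult:
    molecules: list[str]        # canonical SMILES of terminated samples
    truncated_count: int
    n_batches: int
    n_total: int


def sample_batch(graph, model, n_total: int, batch_size: int = 2048,
                 seed: int = 0, max_len: int = 140,
                 temperature: float = 1.0) -> SampleResult:
    """Draw ``n_total`` molecules for one pocket; reproducible per seed.

    The pocket is encoded once; the decoder then samples in batches of
    ``batch_size`` rows conditioned on the same embedding.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    emb = model.encoder(graph).data
    rng = np.random.default_rng(seed)
    molecules: list[str] = []
    truncated = 0
    n_batches = 0
    remaining = n_total
    while remaining > 0:
        b = min(batch_size, remaining)
        tiled = Tensor(np.tile(emb, (b, 1)))
        seqs = model.decoder.sample(tiled, max_len=max_len, mode="multinomial",
                                    temperature=temperature, rng=rng)
        for seq in seqs:
            if seq.terminated:
                molecules.append(decode_indices(seq, model.vocab))
            else:
                truncated += 1
        remaining -= b
        n_batches += 1
    return SampleResult(molecules=molecules, truncated_count=truncated,
                        n_batches=n_batches, n_total=n_total)


def frequency_rank(samples) -> list[GeneratedSample]:
    """Group canonical strings, sort by frequency (ties lexicographic)."""
    samples = list(samples)
    if not samples:
        raise ValueError("no samples to rank")
    counts = Counter(samples)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [GeneratedSample(smiles=s, frequency=c, rank=r + 1)
            for r, (s, c) in enumerate(ordered)]


def top_k(ranked: list[GeneratedSample], k: int = 100) -> list[GeneratedSample]:
    if k < 0:
        raise ValueError("k must be >= 0")
    return ranked[:k]


def write_ranked_tsv(ranked: list[GeneratedSample], path) -> None:
    import pandas as pd
    pd.DataFrame([(g.rank, g.smiles, g.frequency) for g in ranked],
                 columns=["rank", "smiles", "frequency"]).to_csv(
        path, sep="\t", index=False)
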