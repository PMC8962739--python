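"""End-to-end pocket-to-molecule model: graph encoder + GRU decoder."""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np

from ..tokenizer import Vocabulary, TokenSequence, pad_batch, decode as decode_indices
from .autodiff import Tensor, zeros
from .decoder import DecoderConfig, GruDecoder
from .encoder import EncoderConfig, GraphEncoder
from .modules import Module

CHECKPOINT_VERSION = 1


class PocketToMol(Module):
    """Encoder-decoder model of P(molecule | pocket).

    One checkpoint archive holds both halves plus the vocabulary and
    the configs/seeds, so a saved model is self-describing.
    """

    def __init__(self, encoder_config: EncoderConfig, decoder_config: DecoderConfig,
                 vocab: Vocabulary):
        if decoder_config.cond_dim != encoder_config.embedding_dim:
            raise ValueError("decoder cond_dim must equal encoder embedding_dim")
        if decoder_config.vocab_size != vocab.size:
            raise ValueError("decoder vocab_size must equal vocabulary size")
        self.encoder = GraphEncoder(encoder_config)
        self.decoder = GruDecoder(decoder_config)
        self.vocab = vocab

    def embed_graphs(self, graphs, unconditional: bool = False) -> Tensor:
        if unconditional:
            return zeros(len(graphs), self.encoder.config.embedding_dim)
        return self.encoder.encode_batch(graphs)

    def batch_loss(self, graphs, seqs: list[TokenSequence], max_len: int = 140,
                   unconditional: bool = False) -> Tensor:
        emb = self.embed_graphs(graphs, unconditional=unconditional)
        mat, lengths, _ = pad_batch(seqs, max_len=max_len)
        mat = mat[:, :int(lengths.max())]
        return self.decoder.nll_loss(emb, mat, lengths)

    def greedy_smiles(self, graph, max_len: int = 140) -> str:
        emb = self.encoder(graph)
        seq = self.decoder.sample(emb, max_len=max_len, mode="greedy")[0]
        return decode_indices(seq, self.vocab)

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "version": CHECKPOINT_VERSION,
            "encoder_config": asdict(self.encoder.config),
            "decoder_config": asdict(self.decoder.config),
            "vocab": self.vocab.token_to_index,
        }
        arrays = {f"param::{k}": v for k, v in self.state().items()}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "PocketToMol":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            model = cls(EncoderConfig(**meta["encoder_config"]),
                        DecoderConfig(**meta["decoder_config"]),
                        Vocabulary(meta["vocab"]))
            state = {k[len("param::"):]: archive[k]
                     for k in archive.files if k.startswith("param::")}
        model.load_state(state)
        return model
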