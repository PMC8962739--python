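"""Decoder probability laws: teacher forcing, NLL, sampling."""

import numpy as np
import pytest

from conftest import tiny_model
from pockmol.nn.decoder import DecoderConfig, GruDecoder, sequence_nll
from pockmol.tokenizer import EOS_IDX, PAD_IDX, TokenSequence, Vocabulary


def _uniform_head(dec):
    """Freeze the output head so every step distribution is uniform."""
    dec.head.W.data[:] = 0.0
    dec.head.b.data[:] = 0.0


def _eos_head(dec):
    dec.head.W.data[:] = 0.0
    dec.head.b.data[:] = 0.0
    dec.head.b.data[EOS_IDX] = 50.0


@pytest.fixture
def tiny_decoder():
    cfg = DecoderConfig(vocab_size=3, cond_dim=4, token_embedding_dim=5,
                        hidden_dim=6, seed=3)
    return GruDecoder(cfg)


def _enumerate_sequences(dec, emb, max_len):
    """All terminated sequences with exact probabilities, plus truncation mass.

    Independent of the teacher-forcing path: multiplies one-step softmax
    distributions along the full sequence tree (every vocabulary index
    is a branch; a sequence terminates on <eos>). This is the measure
    the conditional factorization defines, so it must sum to one.
    """
    others = [i for i in range(dec.config.vocab_size) if i != EOS_IDX]
    results, trunc = {}, 0.0
    stack = [((), 1.0)]
    while stack:
        prefix, mass = stack.pop()
        dist = dec.step_distribution(emb, list(prefix))
        results[prefix + (EOS_IDX,)] = mass * dist[EOS_IDX]
        for t in others:
            if len(prefix) + 1 >= max_len:
                trunc += mass * dist[t]
            else:
                stack.append((prefix + (t,), mass * dist[t]))
    return results, trunc


def test_uniform_logits_closed_form_nll():
    """V=4, uniform logits, 3 steps incl. eos: loss = 3·ln 4 ≈ 4.1589."""
    vocab = Vocabulary({"<pad>": 0, "<eos>": 1, "[C]": 2, "[O]": 3})
    cfg = DecoderConfig(vocab_size=4, cond_dim=4, token_embedding_dim=5,
                        hidden_dim=6, seed=0)
    dec = GruDecoder(cfg)
    _uniform_head(dec)
    target = TokenSequence([2, 3, EOS_IDX])
    logp = dec.teacher_forced_logprobs(np.zeros(4, np.float32), target)
    assert logp.shape == (3,)
    assert np.allclose(logp, -np.log(4.0), atol=1e-6)
    assert sequence_nll(logp) == pytest.approx(3 * np.log(4.0), abs=1e-5)


def test_perfect_certainty_gives_zero_nll(tiny_decoder):
    _eos_head(tiny_decoder)
    logp = tiny_decoder.teacher_forced_logprobs(
        np.zeros(4, np.float32), TokenSequence([EOS_IDX]))
    assert sequence_nll(logp) == pytest.approx(0.0, abs=1e-6)


def test_teacher_forcing_matches_enumeration(tiny_decoder):
    """exp(Σ log P) equals the enumerated path probability for every sequence."""
    emb = np.array([0.3, -0.8, 0.5, 0.1], np.float32)
    probs, trunc = _enumerate_sequences(tiny_decoder, emb, max_len=3)
    checked = 0
    for seq_tokens, want in probs.items():
        if PAD_IDX in seq_tokens:
            continue  # pad-bearing paths carry mass but are not valid targets
        logp = tiny_decoder.teacher_forced_logprobs(
            emb, TokenSequence(list(seq_tokens)))
        assert np.exp(logp.sum()) == pytest.approx(want, abs=1e-6)
        checked += 1
    assert checked >= 3


def test_sequence_tree_consistency(tiny_decoder):
    """Two targets sharing a prefix agree on every pre-divergence step."""
    emb = np.zeros(4, np.float32)
    a = tiny_decoder.teacher_forced_logprobs(emb, TokenSequence([2, 2, EOS_IDX]))
    b = tiny_decoder.teacher_forced_logprobs(emb, TokenSequence([2, EOS_IDX]))
    assert a[0] == pytest.approx(b[0], abs=1e-7)
    # step 1 entries come from the same distribution, different indices
    dist = tiny_decoder.step_distribution(emb, [2])
    assert np.exp(a[1]) == pytest.approx(dist[2], abs=1e-6)
    assert np.exp(b[1]) == pytest.approx(dist[EOS_IDX], abs=1e-6)


def test_nll_matches_enumeration_oracle(tiny_decoder):
    emb = np.array([1.0, 0.0, -1.0, 0.4], np.float32)
    seq = TokenSequence([2, EOS_IDX])
    logp = tiny_decoder.teacher_forced_logprobs(emb, seq)
    d0 = tiny_decoder.step_distribution(emb, [])
    d1 = tiny_decoder.step_distribution(emb, [2])
    want = -(np.log(d0[2]) + np.log(d1[EOS_IDX]))
    assert sequence_nll(logp) == pytest.approx(want, abs=1e-5)


def test_immediate_eos_sampling(tiny_decoder):
    _eos_head(tiny_decoder)
    seq = tiny_decoder.sample(np.zeros(4, np.float32), max_len=5, mode="greedy")[0]
    assert seq.indices == [EOS_IDX] and seq.terminated


def test_zero_temperature_equals_greedy(tiny_decoder):
    emb = np.array([0.2, 0.1, -0.4, 0.9], np.float32)
    greedy = tiny_decoder.sample(emb, max_len=8, mode="greedy")[0]
    cold = tiny_decoder.sample(emb, max_len=8, mode="multinomial",
                               temperature=1e-12,
                               rng=np.random.default_rng(0))[0]
    assert cold.indices == greedy.indices


def test_greedy_bit_stable(tiny_decoder):
    emb = np.array([0.2, 0.1, -0.4, 0.9], np.float32)
    runs = [tiny_decoder.sample(emb, max_len=8, mode="greedy")[0].indices
            for _ in range(3)]
    assert runs[0] == runs[1] == runs[2]


def test_sampled_sequences_satisfy_invariants(tiny_decoder):
    rng = np.random.default_rng(1)
    emb = np.zeros((16, 4), np.float32)
    for seq in tiny_decoder.sample(emb, max_len=6, mode="multinomial", rng=rng):
        assert PAD_IDX not in seq.indices
        if seq.terminated:
            assert seq.indices[-1] == EOS_IDX
        else:
            assert len(seq.indices) == 6


def test_multinomial_reproducible_under_seed(tiny_decoder):
    emb = np.zeros((8, 4), np.float32)
    a = [s.indices for s in tiny_decoder.sample(
        emb, max_len=6, rng=np.random.default_rng(42))]
    b = [s.indices for s in tiny_decoder.sample(
        emb, max_len=6, rng=np.random.default_rng(42))]
    assert a == b


def test_step0_sampling_frequencies_match_distribution(tiny_decoder):
    """Monte-Carlo token frequencies vs the exact softmax, 3 binomial SEs."""
    emb = np.array([0.5, -0.2, 0.8, 0.0], np.float32)
    dist = tiny_decoder.step_distribution(emb, [])
    dist[PAD_IDX] = 0.0
    dist /= dist.sum()
    n = 10_000
    tiled = np.tile(emb, (n, 1))
    seqs = tiny_decoder.sample(tiled, max_len=1, mode="multinomial",
                               rng=np.random.default_rng(9))
    first = np.array([s.indices[0] for s in seqs])
    for tok in range(3):
        p = dist[tok]
        se = np.sqrt(p * (1 - p) / n)
        assert abs((first == tok).mean() - p) <= 3 * se + 1e-12


def test_sampling_argument_validation(tiny_decoder):
    with pytest.raises(ValueError):
        tiny_decoder.sample(np.zeros(4, np.float32), max_len=0)
    with pytest.raises(ValueError):
        tiny_decoder.sample(np.zeros(4, np.float32), mode="beam")


def test_sequence_distribution_normalizes(tiny_decoder):
    """Terminated mass + truncation mass telescopes to exactly 1."""
    emb = np.array([0.1, 0.7, -0.3, 0.2], np.float32)
    probs, trunc = _enumerate_sequences(tiny_decoder, emb, max_len=3)
    assert sum(probs.values()) + trunc == pytest.approx(1.0, abs=1e-6)
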