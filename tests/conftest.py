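import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def property_table():
    from pockmol.pocket_graph import ResiduePropertyTable
    return ResiduePropertyTable.default()


@pytest.fixture(scope="session")
def toy_pdb():
    """3 residues, 12 heavy atoms + 4 hydrogens, known geometry."""
    lines = []
    serial = 0
    rng = np.random.default_rng(42)
    coords = []
    for res_i, res in enumerate(["ALA", "GLY", "TRP"]):
        for a_i in range(4):
            serial += 1
            element = ["N", "C", "C", "O"][a_i]
            xyz = np.array([res_i * 3.0, a_i * 1.5, 0.1 * serial])
            coords.append(xyz)
            lines.append(
                f"ATOM  {serial:5d}  {element}{a_i + 1:<2d}{res:>4s} A{res_i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
                f"{element:>2s}")
        # a hydrogen per residue plus one extra
    for h in range(4):
        serial += 1
        lines.append(
            f"ATOM  {serial:5d}  H{h + 1:<2d}{'ALA':>4s} A{1:4d}    "
            f"{0.0:8.3f}{0.0:8.3f}{float(h):8.3f}  1.00  0.00           H")
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def fixture_pocket_graph():
    from pockmol.fixtures import make_pocket_pdb
    from pockmol.pocket_graph import pocket_from_pdb
    return pocket_from_pdb(make_pocket_pdb(30, seed=11, signature_residue="PHE"),
                           pocket_id="fixture30")


@pytest.fixture(scope="session")
def ligand_library():
    from pockmol.fixtures import LIGAND_LIBRARY
    return LIGAND_LIBRARY


def tiny_model(vocab=None, enc_seed=1, dec_seed=1, hidden=7, emb=6):
    """Small encoder-decoder for structural tests."""
    from pockmol.nn.decoder import DecoderConfig
    from pockmol.nn.encoder import EncoderConfig
    from pockmol.nn.model import PocketToMol
    from pockmol.tokenizer import Vocabulary
    if vocab is None:
        vocab = Vocabulary({"<pad>": 0, "<eos>": 1, "[C]": 2, "[O]": 3})
    enc = EncoderConfig(node_dim=8, hidden_dim=5, num_layers=2, num_channels=2,
                        set2set_steps=2, seed=enc_seed)
    dec = DecoderConfig(vocab_size=vocab.size, cond_dim=enc.embedding_dim,
                        token_embedding_dim=emb, hidden_dim=hidden, seed=dec_seed)
    return PocketToMol(enc, dec, vocab)
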