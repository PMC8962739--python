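"""Synthetic pockets and planted pocket→ligand datasets.

Everything the test-bench needs is generated from a seed: compact
pseudo-pocket PDB files with realistic geometry (nearest-neighbour
spacing in the covalent/contact range, standard residue names), a small
built-in library of valid drug-like molecules spanning ~3–30 heavy
atoms, and planted datasets in which pocket *i* carries a distinctive
residue composition injectively mapped to ligand *i*. A model that
recovers the planted mapping has demonstrably learned
P(molecule | pocket) — the signal lives only in graph features the
encoder can see, never in identifiers. With ``signal_strength = 0`` the
pockets are statistically indistinguishable (null control).

These are *not* physically realistic proteins: side-chain topology,
secondary structure and packing density are absent, so learning results
on fixtures demonstrate the machinery, not chemistry-scale accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pocket_graph import PocketGraph, ResiduePropertyTable, parse_pocket, to_graph, parse_conect
from .tokenizer import TokenSequence, Vocabulary, build_vocab, encode
from .training import PairedDataset

#: Built-in library of valid, neutral, drug-like molecules (3–30 heavy
#: atoms), all encodable by the grammar. Ordered smallest to largest so
#: size-group statistics get exercised.
LIGAND_LIBRARY = [
    "CCO",                                   # ethanol, 3
    "CC(C)=O",                               # acetone, 4
    "CC(=O)O",                               # acetic acid, 4
    "c1ccccc1",                              # benzene, 6
    "Cc1ccccc1",                             # toluene, 7
    "Clc1ccccc1",                            # chlorobenzene, 7
    "NC(=O)c1ccccc1",                        # benzamide, 9
    "O=C(O)c1ccccc1O",                       # salicylic acid, 10
    "c1ccc2ccccc2c1",                        # naphthalene, 10
    "NCCc1ccc(O)c(O)c1",                     # dopamine, 11
    "CC(=O)Nc1ccc(O)cc1",                    # paracetamol, 11
    "Nc1ccc(S(N)(=O)=O)cc1",                 # sulfanilamide, 11
    "OCC1OC(O)C(O)C(O)C1O",                  # glucose (no stereo), 12
    "CN1CCCC1c1cccnc1",                      # nicotine (no stereo), 12
    "CC(=O)Oc1ccccc1C(=O)O",                 # aspirin, 13
    "CN1C=NC2=C1C(=O)N(C)C(=O)N2C",          # caffeine, 14
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",            # ibuprofen, 15
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",         # melatonin, 17
    "CC(C)NCC(O)COc1ccc(COCCN)cc1",          # atenolol-like, 19
    "CC12CCC3C(CCC4=CC(=O)CCC34C)C1CCC2O",   # steroid scaffold, 21
]

STANDARD_RESIDUES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]

_ELEMENTS = ["C", "C", "C", "C", "N", "O", "S"]  # realistic heavy-atom mix
_ATOMS_PER_RESIDUE = 6


@dataclass
class FixtureSpec:
    n_pockets: int = 8
    atoms_range: tuple[int, int] = (50, 120)
    ligands: list[str] = field(default_factory=lambda: list(LIGAND_LIBRARY))
    signal_strength: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pockets > len(self.ligands):
            raise ValueError("need at least one distinct ligand per pocket")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")


def _cluster_coords(n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """Compact cluster with nearest-neighbour spacing ~1.2–2.0 Å."""
    coords = [np.zeros(3)]
    while len(coords) < n_atoms:
        parent = coords[rng.integers(len(coords))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        cand = parent + rng.uniform(1.4, 2.0) * direction
        d = np.linalg.norm(np.array(coords) - cand, axis=1)
        if d.min() >= 1.2 and np.linalg.norm(cand) <= 18.0:
            coords.append(cand)
    return np.array(coords)


def _residue_names(n_res: int, signature: str | None, signal: float,
                   rng: np.random.Generator) -> list[str]:
    names = []
    for _ in range(n_res):
        if signature is not None and rng.random() < signal:
            names.append(signature)
        else:
            names.append(STANDARD_RESIDUES[rng.integers(len(STANDARD_RESIDUES))])
    return names


def make_pocket_pdb(n_atoms: int, seed: int, signature_residue: str | None = None,
                    signal_strength: float = 1.0) -> str:
    """Syntactically valid single-pocket PDB text; deterministic per seed."""
    if n_atoms < 4:
        raise ValueError("need at least 4 atoms")
    rng = np.random.default_rng(seed)
    coords = _cluster_coords(n_atoms, rng)
    n_res = int(np.ceil(n_atoms / _ATOMS_PER_RESIDUE))
    res_names = _residue_names(n_res, signature_residue, signal_strength, rng)
    lines = []
    for i in range(n_atoms):
        res_i = i // _ATOMS_PER_RESIDUE
        element = _ELEMENTS[rng.integers(len(_ELEMENTS))]
        name = f"{element}{(i % _ATOMS_PER_RESIDUE) + 1}"
        x, y, z = coords[i]
        lines.append(
            f"ATOM  {i + 1:5d} {name:<4s}{res_names[res_i]:>4s} A{res_i + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_planted_dataset(spec: FixtureSpec,
                         table: ResiduePropertyTable | None = None,
                         vocab: Vocabulary | None = None):
    """Planted pocket→ligand dataset with ground truth.

    Pocket *i* is biased toward signature residue *i* (injective across
    pockets) with probability ``signal_strength`` per residue and paired
    with ligand *i* from the library. Returns
    ``(PairedDataset, mapping)`` where mapping is pocket_id → SMILES.
    The vocabulary is built over the full ligand list so held-out
    ligands stay encodable.
    """
    table = table or ResiduePropertyTable.default()
    vocab = vocab or build_vocab(spec.ligands)
    rng = np.random.default_rng(spec.seed)
    signatures = STANDARD_RESIDUES[:spec.n_pockets]
    pairs, mapping = [], {}
    for i in range(spec.n_pockets):
        n_atoms = int(rng.integers(spec.atoms_range[0], spec.atoms_range[1] + 1))
        pdb = make_pocket_pdb(
            n_atoms, seed=int(rng.integers(2 ** 31)),
            signature_residue=signatures[i] if spec.signal_strength > 0 else None,
            signal_strength=spec.signal_strength)
        atoms = parse_pocket(pdb)
        pocket_id = f"pocket_{i:03d}"
        smiles = spec.ligands[i]
        graph = to_graph(atoms, table=table, pocket_id=pocket_id,
                         bond_table=parse_conect(pdb), label_smiles=smiles)
        pairs.append((graph, encode(smiles, vocab)))
        mapping[pocket_id] = smiles
    return PairedDataset(pairs, vocab), mapping


def write_fixture_dir(spec: FixtureSpec, out_dir) -> None:
    """Materialize pocket PDBs plus a pairing file for the CLI pipeline."""
    import os
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    signatures = STANDARD_RESIDUES[:spec.n_pockets]
    rows = []
    for i in range(spec.n_pockets):
        n_atoms = int(rng.integers(spec.atoms_range[0], spec.atoms_range[1] + 1))
        pdb = make_pocket_pdb(
            n_atoms, seed=int(rng.integers(2 ** 31)),
            signature_residue=signatures[i] if spec.signal_strength > 0 else None,
            signal_strength=spec.signal_strength)
        pocket_id = f"pocket_{i:03d}"
        with open(os.path.join(out_dir, f"{pocket_id}.pdb"), "w") as fh:
            fh.write(pdb)
        rows.append(f"{pocket_id}\t{spec.ligands[i]}")
    with open(os.path.join(out_dir, "pairs.tsv"), "w") as fh:
        fh.write("\n".join(rows) + "\n")
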