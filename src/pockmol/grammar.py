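"""Valence-constrained, self-referencing molecule string grammar.

This implements a SELFIES-style token grammar with the robustness
guarantee that motivates such grammars for generative models: *every*
sequence of chemical tokens decodes to a chemically valid molecule.
Validity is achieved by construction — the decoder is a derivation
machine that never exceeds element valences and silently skips
instructions that cannot be satisfied — so an autoregressive model
sampling arbitrary tokens can never emit an invalid string.

Ring and branch information is localized: a ``[Branch1]``/``[Ring1]``
identifier is immediately followed by index token(s) carrying the branch
length or ring gap, which keeps long-range dependencies out of the token
stream (the property that makes these grammars easier for recurrent
models to learn than raw SMILES).

The grammar is deliberately small: neutral organic subset (C, N, O, S,
P, halogens), no stereochemistry, no isotopes, no formal charges.
``encode`` rejects molecules outside the subset with an explicit error;
``decode`` is total over the token alphabet.
"""

from __future__ import annotations

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Maximum total bond order per element. These are the valences RDKit's
#: sanitizer accepts for the neutral atom (possibly after implicit-H
#: completion to the next allowed valence), so any derivation respecting
#: them yields a sanitizable molecule.
MAX_VALENCE = {
    "C": 4, "N": 3, "O": 2, "S": 6, "P": 5,
    "F": 1, "Cl": 1, "Br": 1, "I": 1,
}

_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_PREFIX_BOND = {"": 1, "=": 2, "#": 3}

_ATOM_TOKENS = [
    "[C]", "[=C]", "[#C]",
    "[N]", "[=N]", "[#N]",
    "[O]", "[=O]",
    "[S]", "[=S]",
    "[P]",
    "[F]", "[Cl]", "[Br]", "[I]",
]

_CONTROL_TOKENS = ["[Branch1]", "[Branch2]", "[Ring1]", "[=Ring1]", "[Ring2]", "[=Ring2]"]

#: The full chemical alphabet, in the fixed order that doubles as the
#: index encoding: an index token's numeric value is its position here.
ALPHABET = _ATOM_TOKENS + _CONTROL_TOKENS

_INDEX_OF = {t: i for i, t in enumerate(ALPHABET)}
_BASE = len(ALPHABET)

# (#index tokens, ring bond order) per control token
_BRANCH_ARITY = {"[Branch1]": 1, "[Branch2]": 2}
_RING_SPEC = {"[Ring1]": (1, 1), "[=Ring1]": (1, 2), "[Ring2]": (2, 1), "[=Ring2]": (2, 2)}


class GrammarError(ValueError):
    """Raised when a molecule cannot be expressed in the grammar."""


def _parse_atom_token(token: str):
    body = token[1:-1]
    if body[:1] in ("=", "#"):
        return _PREFIX_BOND[body[0]], body[1:]
    return 1, body


def _index_value(tokens) -> int:
    v = 0
    for t in tokens:
        v = v * _BASE + _INDEX_OF[t]
    return v


def _index_tokens(value: int, width: int):
    digits = []
    for _ in range(width):
        digits.append(ALPHABET[value % _BASE])
        value //= _BASE
    if value:
        raise GrammarError(f"index value too large for width {width}")
    return digits[::-1]


# ---------------------------------------------------------------------------
# decoding: tokens -> molecule


class _Derivation:
    """Mutable molecular graph built while consuming tokens."""

    def __init__(self) -> None:
        self.elements: list[str] = []
        self.used: list[int] = []  # total bond order consumed per atom
        self.bonds: dict[tuple[int, int], int] = {}

    def free(self, i: int) -> int:
        return MAX_VALENCE[self.elements[i]] - self.used[i]

    def add_atom(self, element: str) -> int:
        self.elements.append(element)
        self.used.append(0)
        return len(self.elements) - 1

    def add_bond(self, i: int, j: int, order: int) -> None:
        self.bonds[(min(i, j), max(i, j))] = order
        self.used[i] += order
        self.used[j] += order

    def _consume(self, tokens: list[str], attach: int | None) -> None:
        """Derive one chain level. `attach` is the atom the first bond leaves from."""
        cur = attach
        i = 0
        n = len(tokens)
        while i < n:
            tok = tokens[i]
            if tok in _BRANCH_ARITY:
                width = _BRANCH_ARITY[tok]
                idx_toks = tokens[i + 1:i + 1 + width]
                if len(idx_toks) < width:
                    return  # truncated index — nothing left to do
                length = _index_value(idx_toks) + 1
                content = tokens[i + 1 + width:i + 1 + width + length]
                i += 1 + width + length
                if cur is not None and self.free(cur) >= 2 and content:
                    self._consume(content, cur)
            elif tok in _RING_SPEC:
                width, order = _RING_SPEC[tok]
                idx_toks = tokens[i + 1:i + 1 + width]
                if len(idx_toks) < width:
                    return
                gap = _index_value(idx_toks)
                i += 1 + width
                if cur is None:
                    continue
                target = cur - (gap + 1)
                if target < 0 or target == cur:
                    continue
                key = (min(target, cur), max(target, cur))
                if key in self.bonds:
                    continue
                o = min(order, self.free(cur), self.free(target))
                if o >= 1:
                    self.add_bond(cur, target, o)
            else:
                order, element = _parse_atom_token(tok)
                if cur is None:
                    cur = self.add_atom(element)
                else:
                    if self.free(cur) == 0:
                        return  # chain saturated: remaining tokens at this level are inert
                    o = min(order, self.free(cur), MAX_VALENCE[element])
                    new = self.add_atom(element)
                    self.add_bond(cur, new, o)
                    cur = new
                i += 1

    def to_mol(self) -> Chem.Mol:
        rw = Chem.RWMol()
        for el in self.elements:
            rw.AddAtom(Chem.Atom(el))
        for (i, j), order in self.bonds.items():
            rw.AddBond(i, j, Chem.BondType.values[order])
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol


def decode(tokens: list[str]) -> str:
    """Decode a chemical-token sequence to a canonical SMILES string.

    Total over the alphabet: any in-alphabet sequence yields a valid
    (possibly empty) molecule. An empty derivation returns ``""``.
    """
    for t in tokens:
        if t not in _INDEX_OF:
            raise GrammarError(f"unknown token {t!r}")
    d = _Derivation()
    d._consume(list(tokens), None)
    if not d.elements:
        return ""
    return Chem.MolToSmiles(d.to_mol())


# ---------------------------------------------------------------------------
# encoding: molecule -> tokens


def canonical_smiles(smiles: str) -> str:
    """The repository-wide canonical form of a molecule string.

    This single definition is shared by the tokenizer, the generation
    frequency counter and the evaluation protocol.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GrammarError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _check_encodable(mol: Chem.Mol) -> None:
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in MAX_VALENCE:
            raise GrammarError(f"element {sym} outside the grammar alphabet")
        if atom.GetFormalCharge() != 0:
            raise GrammarError("charged atoms are outside the grammar")
        if atom.GetIsotope() != 0:
            raise GrammarError("isotopes are outside the grammar")
        if atom.GetNumRadicalElectrons() != 0:
            raise GrammarError("radicals are outside the grammar")
        total = int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))
        if total > MAX_VALENCE[sym]:
            raise GrammarError(f"atom valence {total} exceeds grammar maximum for {sym}")


def encode(smiles: str) -> list[str]:
    """Tokenize a SMILES string; ``decode`` of the result round-trips.

    Stereochemistry is stripped (the grammar does not carry it); charged,
    isotopic or radical species raise :class:`GrammarError`.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GrammarError(f"unparseable SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    # re-canonicalize so the traversal (and hence token stream) is stable
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    Chem.Kekulize(mol, clearAromaticFlags=True)
    _check_encodable(mol)
    if mol.GetNumAtoms() == 0:
        return []

    order_idx: dict[int, int] = {}
    emitted: set[tuple[int, int]] = set()

    def visit(a: int, parent: int | None, bond_order: int) -> list[str]:
        atom = mol.GetAtomWithIdx(a)
        toks = [f"[{_BOND_PREFIX[bond_order]}{atom.GetSymbol()}]"]
        order_idx[a] = len(order_idx)
        # ring closures back to already-derived atoms
        for nb in sorted((n.GetIdx() for n in atom.GetNeighbors())):
            if nb == parent or nb not in order_idx:
                continue
            key = (min(a, nb), max(a, nb))
            if key in emitted:
                continue
            emitted.add(key)
            o = int(mol.GetBondBetweenAtoms(a, nb).GetBondTypeAsDouble())
            if o > 2:
                raise GrammarError("triple-bond ring closures are not supported")
            gap = order_idx[a] - order_idx[nb] - 1
            if gap < _BASE:
                toks += [f"[{'=' if o == 2 else ''}Ring1]"] + _index_tokens(gap, 1)
            else:
                toks += [f"[{'=' if o == 2 else ''}Ring2]"] + _index_tokens(gap, 2)
        children = [nb.GetIdx() for nb in atom.GetNeighbors()
                    if nb.GetIdx() != parent and nb.GetIdx() not in order_idx]
        children.sort()
        for k, ch in enumerate(children):
            # a child may have been reached through a ring by a sibling branch
            if ch in order_idx:
                continue
            o = int(mol.GetBondBetweenAtoms(a, ch).GetBondTypeAsDouble())
            remaining = [c for c in children[k + 1:] if c not in order_idx]
            sub = visit(ch, a, o)
            if remaining:
                if len(sub) <= _BASE:
                    toks += ["[Branch1]"] + _index_tokens(len(sub) - 1, 1)
                else:
                    toks += ["[Branch2]"] + _index_tokens(len(sub) - 1, 2)
            toks += sub
        return toks

    return visit(0, None, 1)
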