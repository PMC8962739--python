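"""Binding-pocket graph construction.

A pocket arrives as ATOM/HETATM records (one pocket per PDB file) and
leaves as a :class:`PocketGraph`: non-hydrogen atoms become nodes
carrying residue-level physicochemical features (hydrophobicity, charge,
binding probability, sequence entropy), per-atom solvent accessibility
and PCA-normalized coordinates; edges join every atom pair within a
distance cutoff (default 4.5 Å), with the edge attribute equal to the
bond multiplicity for covalently bonded pairs and 0 for non-covalent
contacts.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import gemmi
import numpy as np
import yaml
from scipy.spatial import cKDTree

from . import sasa as _sasa

CONTACT_CUTOFF = 4.5  # Å

#: Covalent-pair distance thresholds (Å): pairs involving S (or P, same
#: row of the periodic table) bond at longer range than first-row pairs.
COVALENT_CUTOFF = 1.9
COVALENT_CUTOFF_S = 2.1

FEATURE_NAMES = ("hydrophobicity", "charge", "binding_probability",
                 "sasa", "entropy", "x", "y", "z")


class PocketParseError(ValueError):
    """Malformed or empty pocket file."""


@dataclass(frozen=True)
class PocketAtom:
    atom_index: int
    element: str
    atom_name: str
    residue_name: str
    residue_index: int  # 0-based, consecutive in chain order
    coords: np.ndarray

    def __post_init__(self):
        if self.element.upper() == "H":
            raise ValueError("hydrogens are excluded from pocket graphs")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")


class ResiduePropertyTable:
    """Residue-type → scalar feature lookup with an explicit UNK fallback.

    The shipped defaults (Kyte–Doolittle hydrophobicity, net formal
    charge, binding-site propensity) live in an editable YAML config;
    any table with the same three keys per residue can be substituted.
    """

    KEYS = ("hydrophobicity", "charge", "binding_probability")

    def __init__(self, table: dict[str, dict[str, float]]):
        if "UNK" not in table:
            raise ValueError("property table must contain an UNK fallback row")
        self.table = {k.upper(): dict(v) for k, v in table.items()}

    @classmethod
    def default(cls) -> "ResiduePropertyTable":
        ref = importlib.resources.files("pockmol.data") / "residue_properties.yaml"
        return cls(yaml.safe_load(ref.read_text()))

    @classmethod
    def from_yaml(cls, path) -> "ResiduePropertyTable":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def lookup(self, residue_name: str) -> dict[str, float]:
        return self.table.get(residue_name.upper(), self.table["UNK"])


@dataclass
class PocketGraph:
    pocket_id: str
    node_features: np.ndarray        # N×F float32, columns = FEATURE_NAMES
    edges: np.ndarray                # M×2 int64, stored symmetrically
    edge_attr: np.ndarray            # M float32, bond multiplicity or 0
    coords: np.ndarray               # N×3 normalized Å
    label_smiles: str | None = None
    normalized: bool = True          # False when PCA fell back to centering

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    def to_json(self) -> str:
        return json.dumps({
            "pocket_id": self.pocket_id,
            "node_features": self.node_features.tolist(),
            "edges": self.edges.tolist(),
            "edge_attr": self.edge_attr.tolist(),
            "coords": self.coords.tolist(),
            "label_smiles": self.label_smiles,
            "normalized": self.normalized,
            "feature_names": list(FEATURE_NAMES),
        })

    @classmethod
    def from_json(cls, text: str) -> "PocketGraph":
        d = json.loads(text)
        return cls(
            pocket_id=d["pocket_id"],
            node_features=np.asarray(d["node_features"], dtype=np.float32),
            edges=np.asarray(d["edges"], dtype=np.int64).reshape(-1, 2),
            edge_attr=np.asarray(d["edge_attr"], dtype=np.float32),
            coords=np.asarray(d["coords"], dtype=np.float64),
            label_smiles=d.get("label_smiles"),
            normalized=d.get("normalized", True),
        )


# ---------------------------------------------------------------------------
# parsing


def _validate_coordinate_columns(content: str) -> None:
    for lineno, line in enumerate(content.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PocketParseError(
                        f"malformed coordinate field {fieldtxt!r} on line {lineno}")


def parse_pocket(content: str) -> list[PocketAtom]:
    """Parse PDB-format text into non-hydrogen :class:`PocketAtom` records.

    Atoms keep file order; hydrogens are dropped; only the first
    alternate location of an atom is kept; residue indices are
    renumbered 0,1,2,… in order of first appearance along the chains.
    """
    if not content.strip():
        raise PocketParseError("empty pocket file")
    _validate_coordinate_columns(content)
    structure = gemmi.read_pdb_string(content)
    structure.remove_alternative_conformations()
    atoms: list[PocketAtom] = []
    res_index: dict[tuple, int] = {}
    if len(structure) == 0:
        raise PocketParseError("no model in pocket file")
    model = structure[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                key = (chain.name, residue.seqid.num, residue.seqid.icode, residue.name)
                if key not in res_index:
                    res_index[key] = len(res_index)
                atoms.append(PocketAtom(
                    atom_index=len(atoms),
                    element=atom.element.name,
                    atom_name=atom.name,
                    residue_name=residue.name,
                    residue_index=res_index[key],
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                ))
    if not atoms:
        raise PocketParseError("pocket contains no non-hydrogen atoms")
    return atoms


def parse_conect(content: str) -> dict[frozenset, int]:
    """Bond multiplicities from CONECT records.

    A neighbour serial repeated k times in the records of one atom is
    read as a bond of multiplicity k (the PDB convention for conveying
    bond order through duplication). Serial numbers are mapped onto the
    0-based indices of the parsed (hydrogen-free) atom list.
    """
    serial_of: dict[int, int] = {}
    idx = 0
    for line in content.splitlines():
        if line[:6] in ("ATOM  ", "HETATM"):
            element = line[76:78].strip() or line[12:16].strip()[:1]
            if element.upper() == "H":
                continue
            try:
                serial_of[int(line[6:11])] = idx
            except ValueError:
                continue
            idx += 1
    counts: dict[frozenset, int] = {}
    for line in content.splitlines():
        if line.startswith("CONECT"):
            fields = [line[i:i + 5].strip() for i in range(6, len(line.rstrip()), 5)]
            serials = [int(f) for f in fields if f]
            if not serials or serials[0] not in serial_of:
                continue
            a = serial_of[serials[0]]
            for s in serials[1:]:
                if s in serial_of:
                    pair = frozenset((a, serial_of[s]))
                    if len(pair) == 2:
                        counts[pair] = counts.get(pair, 0) + 1
    # CONECT lists each bond from both endpoints: k repeats from each
    # side of a multiplicity-k bond
    return {pair: max(1, c // 2) if c > 1 else 1 for pair, c in counts.items()}


# ---------------------------------------------------------------------------
# graph construction


def compute_sasa(atoms: list[PocketAtom]) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å², Shrake–Rupley)."""
    if not atoms:
        raise ValueError("no atoms")
    coords = np.array([a.coords for a in atoms])
    return _sasa.shrake_rupley(coords, [a.element for a in atoms])


def _covalent_threshold(el_a: str, el_b: str) -> float:
    heavy = {"S", "P"}
    if el_a.upper() in heavy or el_b.upper() in heavy:
        return COVALENT_CUTOFF_S
    return COVALENT_CUTOFF


def build_edges(atoms: list[PocketAtom], cutoff: float = CONTACT_CUTOFF,
                bond_table: dict[frozenset, int] | None = None):
    """All atom pairs within ``cutoff`` Å, stored symmetrically.

    Edge attribute: bond multiplicity for pairs classified covalent
    (distance below element-dependent thresholds, multiplicity 1 unless
    the bond table says otherwise), 0 for non-covalent contacts.
    """
    if len(atoms) < 2:
        raise ValueError("need at least two atoms to build edges")
    coords = np.array([a.coords for a in atoms])
    pairs = sorted(cKDTree(coords).query_pairs(cutoff))
    edges, attr = [], []
    for i, j in pairs:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        a = 0.0
        if d <= _covalent_threshold(atoms[i].element, atoms[j].element):
            mult = (bond_table or {}).get(frozenset((i, j)), 1)
            a = float(mult)
        edges.append((i, j))
        edges.append((j, i))
        attr.extend([a, a])
    return (np.array(edges, dtype=np.int64).reshape(-1, 2),
            np.array(attr, dtype=np.float32))


def normalize_coordinates(coords: np.ndarray):
    """Center at the origin and align principal axes with x, y, z.

    Returns ``(normalized_coords, ok)``. Axes are ordered by decreasing
    variance; each axis' sign is fixed by forcing its largest-magnitude
    coordinate positive, making the rigid transform deterministic.
    Degenerate clouds (N < 3 or rank-deficient) fall back to centering
    only, with ``ok = False``.
    """
    coords = np.asarray(coords, dtype=np.float64)
    centered = coords - coords.mean(axis=0)
    if len(coords) < 3:
        return centered, False
    cov = np.cov(centered.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0 or evals[-1] / evals[0] < 1e-12:
        return centered, False
    rotated = centered @ evecs
    for axis in range(3):
        col = rotated[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            rotated[:, axis] = -col
    return rotated, True


def featurize(atoms: list[PocketAtom], table: ResiduePropertyTable,
              sasa_values: np.ndarray, coords: np.ndarray,
              entropy: np.ndarray | None = None) -> np.ndarray:
    """Per-atom feature rows, columns fixed as :data:`FEATURE_NAMES`.

    Residue-level scalars (hydrophobicity, charge, binding probability,
    entropy) are broadcast to every atom of the residue; SASA and the
    normalized coordinates are per-atom. With no entropy profile the
    entropy column is all zeros.
    """
    n_res = max(a.residue_index for a in atoms) + 1
    if entropy is None:
        entropy = np.zeros(n_res)
    entropy = np.asarray(entropy, dtype=np.float64)
    if entropy.shape != (n_res,):
        raise ValueError(
            f"entropy profile has {entropy.shape[0]} entries for {n_res} residues")
    rows = []
    for a, s, xyz in zip(atoms, sasa_values, coords):
        props = table.lookup(a.residue_name)
        rows.append([props["hydrophobicity"], props["charge"],
                     props["binding_probability"], float(s),
                     float(entropy[a.residue_index]), *xyz])
    return np.asarray(rows, dtype=np.float32)


def to_graph(atoms: list[PocketAtom], table: ResiduePropertyTable | None = None,
             pocket_id: str = "pocket", cutoff: float = CONTACT_CUTOFF,
             bond_table: dict[frozenset, int] | None = None,
             entropy: np.ndarray | None = None,
             label_smiles: str | None = None) -> PocketGraph:
    """Compose SASA → edges → coordinate normalization → featurization."""
    table = table or ResiduePropertyTable.default()
    sasa_values = compute_sasa(atoms)
    edges, edge_attr = build_edges(atoms, cutoff=cutoff, bond_table=bond_table)
    coords, ok = normalize_coordinates(np.array([a.coords for a in atoms]))
    features = featurize(atoms, table, sasa_values, coords, entropy=entropy)
    return PocketGraph(pocket_id=pocket_id, node_features=features,
                       edges=edges, edge_attr=edge_attr, coords=coords,
                       label_smiles=label_smiles, normalized=ok)


def pocket_from_pdb(content: str, pocket_id: str = "pocket",
                    table: ResiduePropertyTable | None = None,
                    cutoff: float = CONTACT_CUTOFF,
                    entropy: np.ndarray | None = None,
                    label_smiles: str | None = None) -> PocketGraph:
    """Full pipeline from PDB text (ATOM/HETATM + optional CONECT)."""
    atoms = parse_pocket(content)
    bond_table = parse_conect(content)
    return to_graph(atoms, table=table, pocket_id=pocket_id, cutoff=cutoff,
                    bond_table=bond_table, entropy=entropy,
                    label_smiles=label_smiles)


def read_profile(text: str) -> np.ndarray:
    """Entropy profile from a tab-separated (residue_index, entropy) table."""
    pairs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("residue"):
            continue
        idx, val = line.split("\t")
        pairs.append((int(idx), float(val)))
    if not pairs:
        raise ValueError("empty profile")
    out = np.zeros(max(i for i, _ in pairs) + 1)
    for i, v in pairs:
        out[i] = v
    return out
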