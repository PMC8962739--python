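"""Pocket parsing, contact edges, coordinate normalization, featurization."""

import numpy as np
import pytest

from pockmol.pocket_graph import (CONTACT_CUTOFF, PocketGraph, PocketParseError,
                                  build_edges, compute_sasa, featurize,
                                  normalize_coordinates, parse_conect,
                                  parse_pocket, pocket_from_pdb, to_graph)


def _atoms_from_coords(coords, element="C"):
    from pockmol.pocket_graph import PocketAtom
    return [PocketAtom(i, element, f"{element}{i}", "ALA", 0, np.asarray(c, float))
            for i, c in enumerate(coords)]


# ---------------------------------------------------------------------------
# parsing

def test_parse_drops_hydrogens_keeps_heavy(toy_pdb):
    atoms = parse_pocket(toy_pdb)
    assert len(atoms) == 12
    assert all(a.element != "H" for a in atoms)
    assert [a.residue_index for a in atoms] == [0] * 4 + [1] * 4 + [2] * 4


def test_parse_rejects_empty_and_hydrogen_only():
    with pytest.raises(PocketParseError):
        parse_pocket("")
    h_only = ("ATOM      1  H1  ALA A   1       0.000   0.000   0.000"
              "  1.00  0.00           H\nEND\n")
    with pytest.raises(PocketParseError):
        parse_pocket(h_only)


def test_parse_names_malformed_coordinate_line(toy_pdb):
    broken = toy_pdb.splitlines()
    broken[2] = broken[2][:30] + "  xx.xxx" + broken[2][38:]
    with pytest.raises(PocketParseError, match="line 3"):
        parse_pocket("\n".join(broken))


def test_fixture_pocket_atom_count_matches_request():
    from pockmol.fixtures import make_pocket_pdb
    for n in (12, 57):
        assert len(parse_pocket(make_pocket_pdb(n, seed=2))) == n


def test_conect_multiplicity_parsing():
    pdb = (
        "ATOM      1  C1  LIG A   1       0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  C2  LIG A   1       1.300   0.000   0.000  1.00  0.00           C\n"
        "CONECT    1    2    2\n"
        "CONECT    2    1    1\n"
        "END\n")
    assert parse_conect(pdb) == {frozenset({0, 1}): 2}


# ---------------------------------------------------------------------------
# edges

def test_edge_cutoff_inclusion_and_exclusion():
    far = _atoms_from_coords([[0, 0, 0], [5.0, 0, 0]])
    edges, attr = build_edges(far)
    assert len(edges) == 0
    near = _atoms_from_coords([[0, 0, 0], [4.0, 0, 0]])
    edges, attr = build_edges(near)
    assert sorted(map(tuple, edges.tolist())) == [(0, 1), (1, 0)]
    assert attr.tolist() == [0.0, 0.0]  # 4.0 Å is a contact, not a bond


def test_covalent_classification_thresholds():
    bonded = _atoms_from_coords([[0, 0, 0], [1.5, 0, 0]])
    _, attr = build_edges(bonded)
    assert attr.tolist() == [1.0, 1.0]
    # 2.0 Å: covalent only if sulfur is involved
    cs = _atoms_from_coords([[0, 0, 0], [2.0, 0, 0]])
    _, attr_cc = build_edges(cs)
    assert attr_cc.tolist() == [0.0, 0.0]
    from pockmol.pocket_graph import PocketAtom
    s_pair = [PocketAtom(0, "S", "S1", "CYS", 0, np.zeros(3)),
              PocketAtom(1, "C", "C1", "CYS", 0, np.array([2.0, 0.0, 0.0]))]
    _, attr_sc = build_edges(s_pair)
    assert attr_sc.tolist() == [1.0, 1.0]


def test_edges_match_brute_force_oracle():
    """200 random points in a 20 Å box vs O(N²) distance thresholding."""
    rng = np.random.default_rng(7)
    coords = rng.uniform(0, 20, size=(200, 3))
    atoms = _atoms_from_coords(coords)
    edges, attr = build_edges(atoms)
    got = set(map(tuple, edges.tolist()))
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    want = {(i, j) for i in range(200) for j in range(200)
            if i != j and d[i, j] <= CONTACT_CUTOFF}
    assert got == want
    # symmetry with equal attributes
    attr_of = {tuple(e): a for e, a in zip(edges.tolist(), attr.tolist())}
    assert all(attr_of[(i, j)] == attr_of[(j, i)] for i, j in got)


def test_bond_table_overrides_multiplicity():
    atoms = _atoms_from_coords([[0, 0, 0], [1.3, 0, 0]])
    _, attr = build_edges(atoms, bond_table={frozenset({0, 1}): 2})
    assert attr.tolist() == [2.0, 2.0]


# ---------------------------------------------------------------------------
# normalization

def test_normalized_coords_centered_and_decorrelated():
    rng = np.random.default_rng(3)
    cloud = rng.normal(size=(50, 3)) @ np.diag([5.0, 2.0, 1.0])
    cloud += np.array([10.0, -4.0, 2.0])
    out, ok = normalize_coordinates(cloud)
    assert ok
    assert np.abs(out.mean(axis=0)).max() < 1e-9
    cov = np.cov(out.T)
    evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    off = np.abs(cov - np.diag(np.diag(cov))).max()
    assert off < 1e-6 * evals[0]
    assert np.all(np.diff(np.diag(cov)) <= 1e-9)  # variance nonincreasing
    # rigid: pairwise distances preserved
    d0 = np.linalg.norm(cloud[:, None] - cloud[None, :], axis=-1)
    d1 = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
    assert np.abs(d0 - d1).max() < 1e-9


def test_normalization_is_idempotent_up_to_sign():
    rng = np.random.default_rng(4)
    cloud = rng.normal(size=(40, 3)) @ np.diag([6.0, 3.0, 1.0])
    once, _ = normalize_coordinates(cloud)
    twice, _ = normalize_coordinates(once)
    assert np.allclose(np.abs(once), np.abs(twice), atol=1e-8)


def test_degenerate_cloud_falls_back_to_centering():
    out, ok = normalize_coordinates(np.array([[0.0, 0, 0], [1, 0, 0]]))
    assert not ok
    assert np.abs(out.mean(axis=0)).max() < 1e-12
    collinear = np.array([[float(i), 0.0, 0.0] for i in range(5)])
    out, ok = normalize_coordinates(collinear)
    assert not ok


# ---------------------------------------------------------------------------
# featurization

def test_residue_features_broadcast_to_atoms(toy_pdb, property_table):
    atoms = parse_pocket(toy_pdb)
    coords = np.array([a.coords for a in atoms])
    sasa = compute_sasa(atoms)
    feats = featurize(atoms, property_table, sasa, coords)
    assert feats.shape == (12, 8)
    for res_i in range(3):
        block = feats[4 * res_i:4 * res_i + 4]
        # residue-level columns constant within a residue
        assert np.all(block[:, :3] == block[0, :3])
        assert np.all(block[:, 4] == block[0, 4])
    trp = property_table.lookup("TRP")
    assert feats[8, 0] == np.float32(trp["hydrophobicity"])


def test_entropy_defaults_to_zero_and_validates_length(toy_pdb, property_table):
    atoms = parse_pocket(toy_pdb)
    coords = np.array([a.coords for a in atoms])
    sasa = compute_sasa(atoms)
    feats = featurize(atoms, property_table, sasa, coords)
    assert np.all(feats[:, 4] == 0.0)
    with pytest.raises(ValueError):
        featurize(atoms, property_table, sasa, coords, entropy=np.ones(2))
    feats = featurize(atoms, property_table, sasa, coords,
                      entropy=np.array([0.1, 0.2, 0.3]))
    assert np.allclose(feats[4:8, 4], 0.2)


def test_unknown_residue_maps_to_unk_row(property_table):
    assert property_table.lookup("XYZ") == property_table.table["UNK"]


# ---------------------------------------------------------------------------
# composition

def test_to_graph_composition_and_determinism(toy_pdb):
    atoms = parse_pocket(toy_pdb)
    g1 = to_graph(atoms, pocket_id="toy")
    g2 = to_graph(atoms, pocket_id="toy")
    assert g1.num_nodes == 12
    assert np.array_equal(g1.node_features, g2.node_features)
    assert np.array_equal(g1.edges, g2.edges)
    assert np.abs(g1.coords.mean(axis=0)).max() < 1e-9
    # no self edges; symmetric storage
    assert all(i != j for i, j in g1.edges.tolist())
    pairs = set(map(tuple, g1.edges.tolist()))
    assert all((j, i) in pairs for i, j in pairs)


def test_pocket_graph_invariants_on_fixture(fixture_pocket_graph):
    g = fixture_pocket_graph
    d = np.linalg.norm(g.coords[g.edges[:, 0]] - g.coords[g.edges[:, 1]], axis=1)
    assert d.max() <= CONTACT_CUTOFF + 1e-9
    assert np.abs(g.coords.mean(axis=0)).max() < 1e-9
    cov = np.cov(g.coords.T)
    assert np.abs(cov - np.diag(np.diag(cov))).max() < 1e-6 * np.diag(cov).max()


def test_graph_json_round_trip(fixture_pocket_graph):
    g = fixture_pocket_graph
    back = PocketGraph.from_json(g.to_json())
    assert back.pocket_id == g.pocket_id
    assert np.allclose(back.node_features, g.node_features)
    assert np.array_equal(back.edges, g.edges)
    assert np.allclose(back.coords, g.coords)
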