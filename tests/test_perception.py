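"""Ring finding, aromaticity models, planarity, and 3D stereo perception."""

import numpy as np
import pytest

from molpat import fixtures, matcher, perception, smiles
from molpat.perception import (
    find_rings,
    huckel_count,
    perceive_aromaticity,
    planarity,
    stereo_from_3d,
    tetrahedral_parity,
    torsion,
)
from molpat.smiles import parse_smiles


# -- ring enumeration ------------------------------------------------------


def _brute_force_cycles(mol, cap):
    """Independent all-simple-cycles enumeration by path extension."""
    n = len(mol.atoms)
    adj = {i: set(mol.neighbors(i)) for i in range(n)}
    cycles = set()
    def extend(path):
        last = path[-1]
        for nb in adj[last]:
            if nb == path[0] and len(path) >= 3:
                cycles.add(frozenset(path))
            elif nb not in path and len(path) < cap and nb > path[0]:
                extend(path + [nb])
    for start in range(n):
        extend([start])
    return cycles


@pytest.mark.parametrize("smi", [
    "CCC", "C1CC1", "C1CCC1C", "c1ccccc1", "c1ccc2c(c1)cc[nH]2",
    "C1CC2CCC1CC2", "C12CC1C2", "O=C1C=CC(=O)C=C1",
])
def test_find_rings_equals_brute_force(smi):
    mol = parse_smiles(smi)
    assert len(mol.atoms) <= 12
    for cap in (8, 9):
        rs = find_rings(mol, [cap])
        assert {frozenset(r) for r in rs.rings} == _brute_force_cycles(mol, cap)


def test_indole_ring_counts_depend_on_cap():
    indole = parse_smiles("c1ccc2c(c1)cc[nH]2")
    rs = find_rings(indole)  # default cap 8: the 9-ring is not seen
    fusion = [a for a in range(9) if rs.ring_count(a) == 2]
    assert len(fusion) == 2
    rs9 = find_rings(indole, [9])
    assert sorted(rs9.ring_count(a) for a in fusion) == [3, 3]


def test_propane_has_no_rings():
    assert find_rings(parse_smiles("CCC")).rings == []


# -- Hueckel counting ------------------------------------------------------


def _ring_of(mol, size):
    rs = find_rings(mol)
    return next(r for r in rs.rings if len(r) == size)


def test_huckel_benzene_six():
    mol = parse_smiles("C1=CC=CC=C1")
    assert huckel_count(_ring_of(mol, 6), mol) == 6


def test_huckel_cyclobutadiene_four():
    mol = parse_smiles("C1=CC=C1")
    assert huckel_count(_ring_of(mol, 4), mol) == 4


def test_huckel_pyrrole_six():
    mol = parse_smiles("C1=CC=CN1")
    assert huckel_count(_ring_of(mol, 5), mol) == 6


def test_huckel_quinone_disqualified_under_open():
    mol = parse_smiles("O=C1C=CC(=O)C=C1")
    assert huckel_count(_ring_of(mol, 6), mol, "open") is None


# -- planarity -------------------------------------------------------------


def test_planarity_of_hexagon_and_displaced_atom():
    ring = fixtures.planar_ring(6)
    coords = ring.coords_array(range(6))
    assert planarity(coords)
    coords[0][2] = 0.5
    assert not planarity(coords)


def test_chair_is_not_planar():
    chair = fixtures.cyclohexane("chair")
    coords = chair.coords_array(range(6))
    assert not planarity(coords)
    # ideal chair pucker is ~0.25 A out of plane
    dev = np.abs(coords[:, 2] - coords[:, 2].mean())
    assert 0.2 < dev.max() < 0.3


def test_collinear_points_not_planar():
    pts = np.array([[float(i), 0.0, 0.0] for i in range(4)])
    assert not planarity(pts)


# -- aromaticity models ----------------------------------------------------


def test_furan_aromatic_under_open_and_strict():
    for model in ("open", "strict"):
        mol = parse_smiles("C1=CC=CO1")
        perceive_aromaticity(mol, model)
        assert all(a.aromatic for a in mol.atoms)


def test_quinone_models_disagree():
    graph = parse_smiles("O=C1C=CC(=O)C=C1")
    perceive_aromaticity(graph, "open")
    assert not any(a.aromatic for a in graph.atoms)
    planar = fixtures.quinone()
    perceive_aromaticity(planar, "planar")
    assert sum(a.aromatic for a in planar.atoms) == 6


def test_cyclobutadiene_not_aromatic_under_strict():
    mol = fixtures.cyclobutadiene()
    perceive_aromaticity(mol, "strict")
    assert not any(a.aromatic for a in mol.atoms)
    # but the planarity-only model accepts the planar ring
    perceive_aromaticity(mol, "planar")
    assert all(a.aromatic for a in mol.atoms if a.element == "C")


def test_none_model_clears_all_flags(fixture_mol):
    perceive_aromaticity(fixture_mol, "none")
    assert not any(a.aromatic for a in fixture_mol.atoms)
    assert not any(b.aromatic for b in fixture_mol.bonds)


def test_defined_model_copies_declared_flags():
    mol = parse_smiles("C1=CC=CC=C1")  # Kekule, nothing declared
    perceive_aromaticity(mol, "defined")
    assert not any(a.aromatic for a in mol.atoms)


def test_benzene_aromatic_under_three_models():
    for model in ("open", "strict", "planar"):
        mol = fixtures.benzene()
        perceive_aromaticity(mol, model)
        assert all(a.aromatic for a in mol.atoms)


def test_planar_model_requires_coordinates():
    with pytest.raises(ValueError):
        perceive_aromaticity(parse_smiles("c1ccccc1"), "planar")


# -- stereo from 3D --------------------------------------------------------


def _chiral_fixture():
    """A tetrahedral center with four distinct substituents."""
    mol = fixtures.zigzag_chain(2)
    center = mol.atoms[0]
    from molpat.chem_graph import ideal_tetrahedral_directions
    dirs = ideal_tetrahedral_directions(
        [(mol.atoms[1].coords - center.coords) / 1.54], 3)
    for el, d in zip(("N", "O", "F"), dirs):
        a = mol.new_atom(el, coords=center.coords + 1.4 * d)
        mol.add_bond(0, a.index, order=1)
    center.implicit_h = 0
    return mol


def test_tetrahedral_parity_by_construction():
    # neighbors arranged so that, viewed from the first, the rest read
    # anticlockwise: that is "@" and flips when two neighbors swap
    pos = [np.array([0.0, 0.0, 1.0]),
           np.array([1.0, 0.0, -0.35]),
           np.array([-0.5, 0.866, -0.35]),
           np.array([-0.5, -0.866, -0.35])]
    assert tetrahedral_parity(pos) == "@"
    assert tetrahedral_parity([pos[0], pos[2], pos[1], pos[3]]) == "@@"


def test_parity_flips_under_mirror_and_survives_rotation(rng):
    mol = _chiral_fixture()
    seq = [1, 2, 3, 4]
    base = stereo_from_3d(mol, 0, "TH", seq).parity
    mirrored = fixtures.mirror(mol)
    assert stereo_from_3d(mirrored, 0, "TH", seq).parity != base
    for _ in range(5):
        moved = fixtures.rigidly_moved(mol, rng)
        assert stereo_from_3d(moved, 0, "TH", seq).parity == base


def _pyramid_fixture():
    """Phosphine-like center: three distinct substituents plus a lone pair."""
    mol = fixtures.zigzag_chain(2, element="P")
    center = mol.atoms[0]
    from molpat.chem_graph import ideal_tetrahedral_directions
    dirs = ideal_tetrahedral_directions(
        [(mol.atoms[1].coords - center.coords) / 1.54], 2)
    for el, d in zip(("N", "O"), dirs):
        a = mol.new_atom(el, coords=center.coords + 1.4 * d)
        mol.add_bond(0, a.index, order=1)
    center.implicit_h = 0
    return mol


def test_trigonal_pyramid_uses_lone_pair_phantom(rng):
    mol = _pyramid_fixture()
    seq = [1, 2, 3, -1]
    base = stereo_from_3d(mol, 0, "TP", seq).parity
    assert stereo_from_3d(fixtures.mirror(mol), 0, "TP", seq).parity != base
    moved = fixtures.rigidly_moved(mol, rng)
    assert stereo_from_3d(moved, 0, "TP", seq).parity == base


def test_cis_trans_from_torsion():
    anti = fixtures.zigzag_chain(4, [180])
    desc = stereo_from_3d(anti, 0, "cistrans", [0, 1, 2, 3])
    assert desc.parity == "trans"
    syn = fixtures.zigzag_chain(4, [0])
    assert stereo_from_3d(syn, 0, "cistrans", [0, 1, 2, 3]).parity == "cis"


def test_atrop_parity_is_torsion_sign():
    plus = fixtures.zigzag_chain(4, [60])
    minus = fixtures.zigzag_chain(4, [-60])
    p1 = stereo_from_3d(plus, 0, "atrop", [0, 1, 2, 3]).parity
    p2 = stereo_from_3d(minus, 0, "atrop", [0, 1, 2, 3]).parity
    assert {p1, p2} == {"@", "@@"}
    mirrored = fixtures.mirror(plus)
    assert stereo_from_3d(mirrored, 0, "atrop", [0, 1, 2, 3]).parity == p2


def test_trans_butene_geometry_matches_trans_pattern():
    butene = fixtures.zigzag_chain(4, [180])
    butene.bonds[1].order = 2  # make the central bond double
    fixtures._fill_valence_h(butene)
    assert matcher.smiles_match(butene, "C/C=C/C")
    assert not matcher.smiles_match(butene, "C/C=C\\C")
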