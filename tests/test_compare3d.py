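"""Quaternion superposition, atom mapping, isomer classification, and
dihedral driving."""

import numpy as np
import pytest

from molpat import compare3d, fixtures, smiles
from molpat.compare3d import (
    AlignmentError,
    best_alignment,
    classify_isomers,
    drive_dihedrals,
    map_atoms,
    superpose,
)
from molpat.perception import torsion
from molpat.smiles import parse_smiles


# -- independent Kabsch/SVD oracle ----------------------------------------


def kabsch_rmsd(P, Q):
    """Minimum RMSD of R@Q + t onto P via SVD, reflection forbidden."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = (R @ Qc.T).T - Pc
    return float(np.sqrt((diff ** 2).sum() / len(P)))


# -- superpose -------------------------------------------------------------


def test_identical_point_sets_rmsd_zero():
    pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    res = superpose(pts, pts)
    assert res.rmsd < 1e-12
    np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)


def test_rigid_copy_recovered(rng):
    P = rng.normal(size=(8, 3))
    R = fixtures.random_rotation(rng)
    t = rng.normal(size=3)
    Q = P  # original
    A = (R @ P.T).T + t
    res = superpose(A, Q)
    assert res.rmsd < 1e-10
    np.testing.assert_allclose(res.rotation, R, atol=1e-8)
    np.testing.assert_allclose(res.translation, t, atol=1e-8)


def test_displaced_corner_matches_svd_oracle():
    square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
    bent = square.copy()
    bent[2] += [0.0, 0.0, 0.4]
    res = superpose(square, bent)
    assert res.rmsd == pytest.approx(kabsch_rmsd(square, bent), abs=1e-12)


def test_agrees_with_svd_on_100_random_sets(rng):
    for _ in range(100):
        n = int(rng.integers(4, 12))
        P = rng.normal(size=(n, 3))
        Q = rng.normal(size=(n, 3))
        assert superpose(P, Q).rmsd == pytest.approx(
            kabsch_rmsd(P, Q), abs=1e-9)


def test_rmsd_invariant_under_common_rigid_motion(rng):
    P = rng.normal(size=(6, 3))
    Q = rng.normal(size=(6, 3))
    base = superpose(P, Q).rmsd
    for _ in range(5):
        R = fixtures.random_rotation(rng)
        t = rng.normal(size=3)
        assert superpose((R @ P.T).T + t, (R @ Q.T).T + t).rmsd == \
            pytest.approx(base, abs=1e-9)


def test_rotation_is_never_a_reflection(rng):
    for _ in range(20):
        P = rng.normal(size=(5, 3))
        res = superpose(P, -P)  # mirrored target tempts a reflection
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)


def test_degenerate_inputs_raise():
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
    with pytest.raises(AlignmentError):
        superpose(line, line)
    two = np.zeros((2, 3))
    with pytest.raises(AlignmentError):
        superpose(two, two)


# -- atom mapping ----------------------------------------------------------


def test_permuted_molecule_mapping():
    maps = map_atoms(parse_smiles("CCO"), parse_smiles("OCC"))
    assert maps
    m = dict((b, a) for a, b in maps[0])
    # the pattern oxygen (index 0 in OCC) maps onto the target oxygen
    assert m[0] == 2


def test_caffeine_maps_14_heavy_atoms_onto_itself():
    caf = parse_smiles("[n]1(C)c(=O)c2c3[n](C)c1(=O).[n]2(C)c[n]3")
    maps = map_atoms(caf, caf.copy())
    assert maps and all(len(m) == 14 for m in maps)


def test_smarts_restricted_mapping():
    a = fixtures.zigzag_chain(5)
    b = fixtures.zigzag_chain(5)
    maps = map_atoms(a, b, pattern="CCC")
    assert maps and all(len(m) == 3 for m in maps)


# -- best alignment --------------------------------------------------------


def test_benzene_self_alignment_rmsd_zero_over_symmetry():
    b = fixtures.benzene()
    res = best_alignment(b, b.copy())
    assert res.rmsd < 1e-9
    assert len(res.all_candidate_rmsds) >= 2  # symmetry mappings checked


def test_best_alignment_is_minimum_over_candidates(rng):
    a = fixtures.zigzag_chain(6)
    b = fixtures.rigidly_moved(a, rng)
    res = best_alignment(a, b)
    assert res.rmsd == pytest.approx(min(res.all_candidate_rmsds), abs=1e-12)
    assert res.rmsd < 1e-9


def test_chiral_fixture_vs_mirror_has_positive_rmsd():
    mol = fixtures.zigzag_chain(2)
    from molpat.chem_graph import ideal_tetrahedral_directions
    dirs = ideal_tetrahedral_directions(
        [(mol.atoms[1].coords - mol.atoms[0].coords) / 1.54], 3)
    for el, d in zip(("N", "O", "F"), dirs):
        a = mol.new_atom(el, coords=mol.atoms[0].coords + 1.4 * d)
        mol.add_bond(0, a.index, order=1)
    mol.atoms[0].implicit_h = 0
    mirrored = fixtures.mirror(mol)
    res = best_alignment(mol, mirrored, directives=smiles.Directives(no_stereo=True))
    assert res.rmsd > 0.1  # a proper rotation cannot realize the reflection
    for m in map_atoms(mol, mirrored,
                       directives=smiles.Directives(no_stereo=True)):
        pairs = [[a_, b_] for a_, b_ in m]
        P = np.array([mol.atoms[a_].coords for a_, _ in pairs])
        Q = np.array([mirrored.atoms[b_].coords for _, b_ in pairs])
        assert superpose(P, Q).rmsd == pytest.approx(kabsch_rmsd(P, Q), abs=1e-9)


# -- isomer classification -------------------------------------------------


ISOMER_PANEL = [
    ("CCO", "CCO", "IDENTICAL"),
    ("CCO", "OCC", "IDENTICAL"),
    ("CCO", "CO", "NONE"),
    ("CCCC", "CC(C)C", "CONSTITUTIONAL"),
    ("[C@H](F)(Cl)Br", "[C@@H](F)(Cl)Br", "ENANTIOMERS"),
    ("[C@H](F)(Cl)Br", "[C@H](F)(Cl)Br", "IDENTICAL"),
    ("F/C=C/F", "F/C=C\\F", "DIASTEREOMERS"),
    # (S,S) vs (R,R) tartaric-style pair; CIP labels checked against RDKit
    ("C[C@H](O)[C@@H](O)C", "C[C@@H](O)[C@H](O)C", "ENANTIOMERS"),
    # (S,S) vs the meso form
    ("C[C@H](O)[C@@H](O)C", "C[C@H](O)[C@H](O)C", "DIASTEREOMERS"),
    # the meso compound is its own mirror image
    ("C[C@H](O)[C@H](O)C", "C[C@@H](O)[C@@H](O)C", "IDENTICAL"),
    ("c1ccccc1", "C1=CC=CC=C1", "IDENTICAL"),
]


@pytest.mark.parametrize("a,b,expected", ISOMER_PANEL)
def test_isomer_panel(a, b, expected):
    assert classify_isomers(a, b) == expected


@pytest.mark.parametrize("a,b,expected", ISOMER_PANEL)
def test_isomer_classification_is_symmetric(a, b, expected):
    assert classify_isomers(b, a) == expected


# -- dihedral driving ------------------------------------------------------


def test_drive_gauche_butane_to_anti():
    ref = fixtures.zigzag_chain(4, [180])
    mov = fixtures.zigzag_chain(4, [60])
    driven = drive_dihedrals(ref, mov, "CCCC")
    t = torsion(*[driven.atoms[i].coords for i in range(4)])
    assert abs(abs(t) - 180.0) < 1e-6
    assert best_alignment(ref, driven).rmsd < 1e-6


def test_drive_is_noop_when_already_aligned():
    ref = fixtures.zigzag_chain(5, [180, 180])
    driven = drive_dihedrals(ref, ref.copy(), "CCCCC")
    np.testing.assert_allclose(driven.coords_array(), ref.coords_array(),
                               atol=1e-9)


def test_two_independent_torsions_driven_simultaneously():
    ref = fixtures.zigzag_chain(5, [170, -60])
    mov = fixtures.zigzag_chain(5, [60, 180])
    driven = drive_dihedrals(ref, mov, "CCCCC")
    t1 = torsion(*[driven.atoms[i].coords for i in range(4)])
    t2 = torsion(*[driven.atoms[i].coords for i in range(1, 5)])
    assert t1 == pytest.approx(170.0, abs=1e-6)
    assert t2 == pytest.approx(-60.0, abs=1e-6)


def test_ring_bonds_are_skipped():
    ref = fixtures.cyclohexane("chair")
    mov = fixtures.cyclohexane("chair")
    driven = drive_dihedrals(ref, mov, "C1CCCCC1")
    np.testing.assert_allclose(driven.coords_array(), mov.coords_array(),
                               atol=1e-9)
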