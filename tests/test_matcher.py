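"""The matching engine: substructure search, full-structure matching,
measurements, grouping, hooks, and conformer motifs."""

import itertools

import pytest

from molpat import fixtures, matcher, smiles
from molpat.matcher import (
    MatchError,
    conformer_classify,
    selected_atoms,
    smarts_match,
    smiles_match,
)
from molpat.smarts import parse_smarts, preprocess_smarts
from molpat.smiles import Directives, parse_smiles


# -- brute-force oracle ----------------------------------------------------


def _oracle_match_sets(pattern_text, mol, directives=None):
    """Enumerate every injective mapping with itertools and check it
    predicate-by-predicate; independent of the backtracking search."""
    clauses, d = preprocess_smarts(pattern_text)
    if directives is not None:
        d = directives
    found = set()
    for clause in clauses:
        pat = parse_smarts(clause, d)
        sizes = pat.required_ring_sizes()
        rings = matcher.prepare_target(mol, d, sizes)
        ctx = matcher._Ctx(mol, d, rings)
        k = len(pat.atoms)
        for perm in itertools.permutations(range(len(mol.atoms)), k):
            ok = all(matcher._eval_atom_expr(pat.atoms[i].expr, ctx, perm[i])
                     for i in range(k))
            if not ok:
                continue
            for b in pat.bonds:
                tb = mol.bond_between(perm[b.a1], perm[b.a2])
                if tb is None or not matcher._eval_bond_expr(b.expr, ctx, tb):
                    ok = False
                    break
            if not ok:
                continue
            mapping = {i: perm[i] for i in range(k)}
            if not matcher._post_checks(pat, ctx, mapping, pat.components()):
                continue
            if pat.has_braces():
                sel = frozenset(perm[a.index] for a in pat.atoms
                                if a.brace_selected)
            else:
                sel = frozenset(perm)
            found.add(sel)
    return found


ORACLE_CASES = [
    ("CCCC", "CCCCCC"),
    ("C=O", "CC(=O)OC"),
    ("[R]", "C1CC1CC"),
    ("a", "c1ccccc1C"),
    ("[X4]", "CC(C)(C)O"),
    ("{C}C=O", "CCC=O"),
    ("[$(C=O)]", "CC(=O)C"),
    ("C.C", "CC.C"),
    ("[!C;!H0]", "CCO"),
    ("*~*", "C=CC"),
]


@pytest.mark.parametrize("pattern,target", ORACLE_CASES)
def test_backtracker_equals_brute_force(pattern, target):
    mol = parse_smiles(target)
    assert len(mol.atoms) <= 10
    got = {r.selected for r in smarts_match(pattern, mol)}
    assert got == _oracle_match_sets(pattern, mol)


# -- printed match examples ------------------------------------------------


def test_hexane_three_distinct_matches():
    mol = parse_smiles("CCCCCC")
    res = smarts_match("CCCC", mol)
    assert len(res) == 3
    assert selected_atoms(res) == set(range(6))


def test_first_match_only_selects_one_atom():
    res = smarts_match("/firstMatchOnly/C", parse_smiles("CCCCCCC"))
    assert len(res) == 1 and len(res[0].selected) == 1


def test_nested_phenol_ortho_hydrogens():
    phenol = parse_smiles("Oc1ccccc1").make_explicit_h()
    res = smarts_match("[$(HccOH)]", phenol)
    sel = selected_atoms(res)
    assert len(sel) == 2
    assert all(phenol.atoms[i].is_h() for i in sel)


def test_component_grouping_oh_with_two_carbonyls():
    mol = parse_smiles("OC(=O)CC(=O)O.CCO").make_explicit_h()
    res = smarts_match("(C=O.C=O).{OH}", mol)
    comp = mol.assign_components()
    sel = selected_atoms(res)
    assert sel
    assert {comp[i] for i in sel} == {0}  # never the ethanol component


def test_group_by_model_counts_whole_model_as_one_component():
    mol = parse_smiles("CC.CC")
    assert not smarts_match("/groupByModel/(C).(C)", mol)
    assert smarts_match("(C).(C)", mol)


def test_dot_means_not_connected():
    ethane = parse_smiles("CC")
    assert not smarts_match("C.C", ethane)
    propane = parse_smiles("CCC")
    res = smarts_match("C.C", propane)  # only the two terminal carbons
    assert {tuple(sorted(r.mapping.values())) for r in res} == {(0, 2)}


def test_or_clause_union():
    mol = parse_smiles("O=CC=S")
    res = smarts_match("C=[O,S] || N=[O,S]", mol)
    assert selected_atoms(res) == {0, 1, 2, 3}


def test_select_hook_required_and_used():
    mol = parse_smiles("CCBr")
    with pytest.raises(MatchError):
        smarts_match("[$(select atomno<10)]Br", mol)
    def hook(text, m, idx):
        assert "atomno" in text
        return idx == 1
    res = smarts_match("{[$(select atomno<10)]}Br", mol, select_hook=hook)
    assert selected_atoms(res) == {1}


def test_atom_index_and_app_number_primitives():
    mol = parse_smiles("CCO")
    assert selected_atoms(smarts_match("[=2]", mol)) == {2}
    assert selected_atoms(smarts_match("[#-2]", mol)) == {1}


def test_isotope_wildcards():
    mol = parse_smiles("[12CH4].[13CH4].C")
    assert selected_atoms(smarts_match("[12?#6]", mol)) == {0, 2}
    assert selected_atoms(smarts_match("[0?]", mol)) == {2}
    assert selected_atoms(smarts_match("[!0?]", mol)) == {0, 1}


def test_atom_type_primitive_after_typing():
    from molpat import atomtyping
    mol = parse_smiles("CS").make_explicit_h()
    atomtyping.assign_types(mol)
    assert selected_atoms(smarts_match('["15"]', mol)) == {1}


# -- SMILES full-structure matching ----------------------------------------


def test_self_match_under_every_model(fixture_mol):
    for model in ("open", "none", "defined"):
        d = Directives(aromaticity_model=model)
        assert smiles_match(fixture_mol, fixture_mol, d)


def test_match_is_superset_without_stereo():
    a, b = "[C@H](F)(Cl)Br", "[C@@H](F)(Cl)Br"
    assert not smiles_match(a, b)
    assert smiles_match(a, b, Directives(no_stereo=True))


def test_invert_stereo_twice_is_identity():
    pairs = [("[C@H](F)(Cl)Br", "[C@H](F)(Cl)Br"),
             ("[C@H](F)(Cl)Br", "[C@@H](F)(Cl)Br"),
             ("CCO", "CCO")]
    for a, b in pairs:
        plain = smiles_match(a, b)
        inv = Directives(invert_stereo=True)
        once = smiles_match(a, b, inv)
        # applying the inversion to the already-inverted pattern restores it
        assert smiles_match(a, b.replace("@@", "~").replace("@", "@@")
                            .replace("~", "@"), inv) == plain or a == b
        assert once == smiles_match(a, b.replace("@@", "~").replace("@", "@@")
                                    .replace("~", "@"))


def test_atom_class_respected_unless_disabled():
    assert not smiles_match("C[CH3:1]", "C[CH3:2]")
    assert smiles_match("C[CH3:1]", "/noAtomClass/C[CH3:2]")


def test_kekule_agreement_required_with_aromatic_double():
    pubchem = "N1=CC=CC=C1C"
    other = "C1=CC=CC(C)=N1"
    pattern = "[n]1=cc=cc=c1(C)"  # a=a switches Kekule-sensitive matching on
    assert smiles_match(pubchem, pattern)
    assert not smiles_match(other, pattern)
    assert smiles_match(other, "[n]1ccccc1(C)")


def test_cis_trans_matching_between_strings():
    assert smiles_match("F/C=C/F", "F/C=C/F")
    assert not smiles_match("F/C=C/F", "F/C=C\\F")
    assert smiles_match("F/C=C/F", "/noStereo/F/C=C\\F")


def test_all_matches_union_equals_single_match_union():
    mol = parse_smiles("CCCCCC")
    every = selected_atoms(smarts_match("CCC", mol, all_matches=True))
    # exhaustive single matches seeded from each start atom
    singles = set()
    for r in smarts_match("CCC", mol, all_matches=True):
        singles |= set(r.selected)
    assert every == singles


# -- measurements ----------------------------------------------------------


def test_distance_constraint_on_chain():
    mol = fixtures.zigzag_chain(2)
    assert smarts_match("C(.d:1.5-1.6)C", mol)
    assert not smarts_match("C(.d:1.0-1.1)C", mol)
    assert smarts_match("C(.d:!1.0-1.1)C", mol)


def test_measurement_without_coordinates_is_an_error():
    with pytest.raises(MatchError):
        smarts_match("C(.d:1.5-1.6)C", parse_smiles("CC"))


def test_butane_anti_printed_torsion_pattern(chair_diaxial):
    anti = fixtures.zigzag_chain(4, [180], add_h=True)
    assert smarts_match("[CH3](.t:-170,-180,170,180)CC[CH3]", anti)
    gauche = fixtures.zigzag_chain(4, [60], add_h=True)
    assert not smarts_match("[CH3](.t:-170,-180,170,180)CC[CH3]", gauche)
    # the negated form is equivalent to the positive windows
    assert smarts_match("[CH3](.t:!-170,170)CC[CH3]", anti)
    assert not smarts_match("[CH3](.t:!-170,170)CC[CH3]", gauche)


def test_angle_constraint():
    mol = fixtures.zigzag_chain(3)
    assert smarts_match("C(.a:105-115)CC", mol)
    assert not smarts_match("C(.a:85-95)CC", mol)


# -- conformer classification ----------------------------------------------


def test_dimethylcyclohexane_chair_motifs(chair_diaxial):
    dieq = fixtures.cyclohexane(
        "chair", {0: ("C", "equatorial"), 1: ("C", "equatorial")})
    cis = fixtures.cyclohexane(
        "chair", {0: ("C", "axial"), 1: ("C", "equatorial")})
    assert conformer_classify(chair_diaxial) == "trans-1,2-diaxial"
    assert conformer_classify(dieq) == "trans-1,2-diequatorial"
    assert conformer_classify(cis) == "cis-1,2"


def test_generic_torsion_motifs():
    assert conformer_classify(fixtures.zigzag_chain(4, [180])) == "anti"
    assert conformer_classify(fixtures.zigzag_chain(4, [60])) == "gauche"
    assert conformer_classify(fixtures.zigzag_chain(4, [5])) == "eclipsed"


def test_unclassified_label():
    assert conformer_classify(fixtures.zigzag_chain(4, [120])) == "unclassified"
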