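"""Preprocessing, parsing, and generation of the SMILES dialect."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molpat import matcher, smiles
from molpat.smiles import Directives, SmilesError, parse_smiles, preprocess


# -- preprocessing ---------------------------------------------------------


def test_comment_removal():
    clean, d = preprocess("//* prod. by Jmol *// C C")
    assert clean == "CC"
    assert d == Directives()


def test_directive_block_with_separator():
    clean, d = preprocess("/noAromatic,noStereo/CC")
    assert clean == "CC"
    assert d.aromaticity_model == "none" and d.no_stereo


def test_directives_case_insensitive():
    for text in ("/noaromatic/c1ccccc1", "/NoAromatic/c1ccccc1"):
        _, d = preprocess(text)
        assert d.aromaticity_model == "none"


def test_open_strict_combination_means_strict():
    _, d = preprocess("/open,Strict/C")
    assert d.aromaticity_model == "strict"


def test_unknown_directive_and_unterminated_comment():
    with pytest.raises(SmilesError):
        preprocess("/bogusDirective/C")
    with pytest.raises(SmilesError):
        preprocess("//* never closed C")


def test_preprocess_idempotent():
    clean, _ = preprocess("//* x *// /strict/ C C O")
    assert preprocess(clean)[0] == clean


def test_whitespace_preserved_in_select_bodies():
    clean, _ = preprocess("[$(select atomno < 10)]Br")
    assert "atomno < 10" in clean


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=200), max_size=8))
def test_whitespace_insertion_is_harmless(positions):
    """Whitespace is stripped before tokenization, so inserting it anywhere
    leaves the parsed molecule unchanged."""
    base = "CC(=O)NC1=CC=C(C=C1)O"
    chars = list(base)
    for p in sorted(positions, reverse=True):
        chars.insert(p % (len(chars) + 1), " ")
    spaced = "".join(chars)
    ref = parse_smiles(base)
    got = parse_smiles(spaced)
    assert len(got.atoms) == len(ref.atoms)
    assert smiles.generate_smiles(got) == smiles.generate_smiles(ref)


# -- parsing ---------------------------------------------------------------


def test_caffeine_string_atom_counts():
    mol = parse_smiles("[n]1(C)c(=O)c2c3[n](C)c1(=O).[n]2(C)c[n]3")
    assert len(mol.heavy_atoms()) == 14
    assert sum(a.implicit_h for a in mol.atoms) == 10
    assert mol.atom_count_with_implicit_h() == 24


def test_large_ring_closure_number():
    mol = parse_smiles("C%(102)CCC%(102)")
    assert len(mol.bonds) == 4  # cyclobutane


def test_two_digit_ring_closure():
    mol = parse_smiles("C%12CCC%12")
    assert len(mol.bonds) == 4


def test_dummy_atom():
    mol = parse_smiles("[Xx]")
    assert mol.atoms[0].atomic_number == 0
    assert mol.atoms[0].element == "Xx"


def test_plain_carbon_and_unbracketed_h():
    assert parse_smiles("C").atoms[0].implicit_h == 4
    mol = parse_smiles("HO")  # Jmol allows unbracketed H
    assert [a.element for a in mol.atoms] == ["H", "O"]


def test_reaction_arrow_read_as_dot():
    mol = parse_smiles("C>>C")
    assert len(mol.atoms) == 2 and len(mol.bonds) == 0


@pytest.mark.parametrize("token,expected_h", [
    ("[nH]", 1), ("[n]", 0), ("[CH3]", 3), ("[C]", 0),
])
def test_bracket_hcount(token, expected_h):
    assert parse_smiles(token).atoms[0].implicit_h == expected_h


def test_aromatic_implicit_h_rule():
    benzene = parse_smiles("c1ccccc1")
    assert all(a.implicit_h == 1 for a in benzene.atoms)
    indole = parse_smiles("c1ccc2c(c1)cc[nH]2")
    fusion = [a for a in indole.atoms if len(indole.neighbors(a.index)) == 3]
    assert all(a.implicit_h == 0 for a in fusion)


@pytest.mark.parametrize("text,charge", [
    ("[NH4+]", 1), ("[O-]", -1), ("[Ca+2]", 2), ("[Ca++]", 2), ("[Fe-3]", -3),
])
def test_charge_forms(text, charge):
    assert parse_smiles(text).atoms[0].charge == charge


def test_atom_class_parsed():
    assert parse_smiles("[CH3:7]C").atoms[0].atom_class == 7


def test_aromatic_double_flag_auto_set():
    mol = parse_smiles("c1cc(O)=c(O)cc1")
    assert mol.directives.aromatic_double


def test_lowercase_restriction_under_open():
    with pytest.raises(SmilesError):
        parse_smiles("[te]1cccc1")
    # but fine under a non-electron-counting model
    mol = parse_smiles("/aromaticDefined/[te]1cccc1")
    assert mol.atoms[0].atomic_number == 52


@pytest.mark.parametrize("bad", [
    "C1CC",            # unmatched ring closure
    "C(C",             # unbalanced branch
    "[C@H",            # unterminated bracket
    "[]",              # empty bracket
    "FC=C/Cl",         # one-sided cis/trans mark
    "F/C(/Cl)=CF",     # conflicting marks on one atom
    "C==C",            # two bond symbols
    "[C?]",            # SMARTS-only token in SMILES
])
def test_parse_errors(bad):
    with pytest.raises(SmilesError):
        parse_smiles(bad)


def test_cis_trans_units_recorded():
    trans = parse_smiles("F/C=C/F")
    assert trans.double_bond_marks[0].relation == "trans"
    cis = parse_smiles("F/C=C\\F")
    assert cis.double_bond_marks[0].relation == "cis"
    equiv = parse_smiles("C(/F)=C/F")  # same arrangement written atom-first
    assert equiv.double_bond_marks[0].relation == "cis"


def test_cumulene_even_number_of_atoms_is_cis_trans():
    mol = parse_smiles("F/C=C=C=C/F")
    assert len(mol.double_bond_marks) == 1
    assert mol.double_bond_marks[0].relation == "trans"


def test_tetrahedral_token_with_implicit_h():
    mol = parse_smiles("[C@H](F)(Cl)Br")
    tok = mol.stereo_centers[0]
    assert tok.shape == "TH" and tok.parity == "@"
    assert tok.neighbor_sequence[0] == smiles.PHANTOM_H


def test_trigonal_pyramidal_inferred_for_three_neighbor_center():
    mol = parse_smiles("C[P@](CC)C1CCCCC1")  # chiral phosphine
    tok = mol.stereo_centers[0]
    assert tok.shape == "TP"
    assert tok.neighbor_sequence[-1] == smiles.PHANTOM_LONE_PAIR


def test_allene_stereo_collects_end_substituents():
    mol = parse_smiles("NC(Br)=[C@]=C(O)C")
    tok = mol.stereo_centers[0]
    assert tok.shape == "allenic"
    assert len(tok.neighbor_sequence) == 4


def test_atropisomer_bond_mark():
    mol = parse_smiles("c1ccccc1^^12-c1ccccc1")
    marked = [b for b in mol.bonds if b.stereo_mark == "^^"]
    assert len(marked) == 1
    assert marked[0].atrop_digits == (1, 2)


# -- generation ------------------------------------------------------------


def test_generate_methane():
    assert smiles.generate_smiles(parse_smiles("C")) == "C"


def test_generate_benzene_with_hydrogens():
    out = smiles.generate_smiles(parse_smiles("c1ccccc1"),
                                 Directives(gen_hydrogens=True))
    assert out.count("[H]") == 6
    assert out.startswith("c1([H])")


def test_generate_topology_indane():
    indane = parse_smiles("C1Cc2ccccc2C1")
    out = smiles.generate_smiles(indane, Directives(gen_topology=True))
    assert set(out) <= set("*0123456789%()")
    assert out.count("*") == 9
    # the topology string itself matches the indane skeleton as a pattern
    assert matcher.smarts_match(out, indane, all_matches=False)


def test_generate_atom_comments_name_source_atoms():
    out = smiles.generate_smiles(parse_smiles("CO"),
                                 Directives(gen_atom_comments=True))
    assert "//* #1 C1 *//" in out and "//* #2 O2 *//" in out
    clean, _ = preprocess(out)
    assert clean == "CO"


def test_round_trip_matches_source(fixture_mol):
    """generate_smiles output full-structure-matches its source molecule."""
    text = smiles.generate_smiles(fixture_mol)
    assert matcher.smiles_match(fixture_mol, text)
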