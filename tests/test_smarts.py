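"""Lexical preprocessing and pattern-graph construction for SMARTS."""

import pytest

from molpat import smarts
from molpat.smarts import (
    Expr,
    Prim,
    expand_repeats,
    expand_variables,
    parse_smarts,
    preprocess_smarts,
    split_or_clauses,
)
from molpat.smiles import Directives, SmilesError


# -- variables -------------------------------------------------------------


def test_variable_substitution_bracket_form():
    assert expand_variables('$R1="C=O";$(*[$R1])') == "$(*C=O)"


def test_variable_chaining():
    assert expand_variables('$A="[OH]";$B="c[$A]";$B') == "c[OH]"


def test_no_definitions_text_unchanged():
    assert expand_variables("CC") == "CC"


def test_undefined_variable_is_an_error():
    with pytest.raises(SmilesError):
        expand_variables('$A="[OH]";[$B]')


def test_quadruple_bond_not_mistaken_for_variable():
    # with no definitions in play, $ stays the quadruple-bond symbol
    pat = parse_smarts("[#6]$[#6]", Directives())
    assert len(pat.atoms) == 2


# -- repeats ---------------------------------------------------------------


def test_fixed_repeat_inside_bracket():
    assert expand_repeats("C[$3(C=C)]C") == ["C[$(C=CC=CC=C)]C"]


def test_variable_repeat_inside_bracket_is_or_clause():
    assert expand_repeats("C[$2-3(C=C)]C") == \
        ["C[$(C=CC=C),$(C=CC=CC=C)]C"]


def test_trivial_repeat_outside_bracket():
    assert expand_repeats("$1(CC)") == ["CC"]


def test_repeat_errors():
    with pytest.raises(SmilesError):
        expand_repeats("$0(C)")
    with pytest.raises(SmilesError):
        expand_repeats("$3-2(C)")


# -- || clauses ------------------------------------------------------------


def test_split_or_clauses():
    assert len(split_or_clauses("C=[O,S] || N=[O,S]")) == 2
    assert split_or_clauses("CC") == ["CC"]
    assert len(split_or_clauses("a||A||*")) == 3
    with pytest.raises(SmilesError):
        split_or_clauses("C || ")


# -- parsing ---------------------------------------------------------------


def _prims(node):
    if isinstance(node, Prim):
        yield node
    else:
        for c in node.children:
            yield from _prims(c)


def test_precedence_low_and_versus_high_and():
    low = parse_smarts("[S,O;X2]", Directives()).atoms[0].expr
    high = parse_smarts("[S,O&X2]", Directives()).atoms[0].expr
    # [S,O;X2]: (S or O) with X2 -> top node is the low-precedence AND
    assert isinstance(low, Expr) and low.op == "and_low"
    assert low.children[0].op == "or"
    # [S,O&X2]: S or (O and X2) -> top node is the OR
    assert isinstance(high, Expr) and high.op == "or"


def test_default_operator_is_high_and():
    a = parse_smarts("[S,OX2]", Directives()).atoms[0].expr
    b = parse_smarts("[S,O&X2]", Directives()).atoms[0].expr
    assert repr(a) == repr(b)


def test_nd3_reads_as_misplaced_mass_on_neodymium():
    with pytest.raises(SmilesError, match="mass"):
        parse_smarts("[nd3]", Directives())
    pat = parse_smarts("[n;d3]", Directives())
    kinds = {p.kind for p in _prims(pat.atoms[0].expr)}
    assert kinds == {"element", "heavy_conn"}


def test_ch_unbracketed_is_two_atoms():
    assert len(parse_smarts("CH", Directives()).atoms) == 2
    one = parse_smarts("[CH]", Directives())
    assert len(one.atoms) == 1


def test_nested_pattern_anchors_first_atom():
    pat = parse_smarts("[$(cc[OH])]", Directives())
    prim = next(p for p in _prims(pat.atoms[0].expr) if p.kind == "nested")
    assert len(prim.value.atoms) == 3  # c, c, [OH] (one bracket atom)


def test_braces_mark_selection():
    pat = parse_smarts("{c}1c{c}c{c}c1[OH]", Directives())
    assert len(pat.atoms) == 7
    assert sum(a.brace_selected for a in pat.atoms) == 3


def test_numbered_measurement_binds_tagged_atoms():
    pat = parse_smarts("[*.CA](.a1:105-110)C(.a1)(O)N(.a1)", Directives())
    (mc,) = pat.measurements
    assert mc.kind == "angle" and mc.member_atoms == [0, 1, 3]
    assert mc.ranges == [(105.0, 110.0)]


def test_default_measurement_takes_next_atoms_lexically():
    pat = parse_smarts("C(.a:0,120)C(C)C", Directives())
    (mc,) = pat.measurements
    assert mc.member_atoms == [0, 1, 2]


def test_misplaced_measurement_before_ring_digit():
    with pytest.raises(SmilesError):
        parse_smarts("C(.d:1.30-1.40)1C", Directives())


def test_measurement_range_validation():
    with pytest.raises(SmilesError):
        parse_smarts("C(.t:100-200)CCC", Directives())
    with pytest.raises(SmilesError):
        parse_smarts("C(.a:-10,20)CC", Directives())


def test_component_grouping_structure():
    pat = parse_smarts("(C=O.C=O).{OH}", Directives())
    assert pat.n_groups == 1
    assert sum(a.group_id == 0 for a in pat.atoms) == 4
    assert pat.not_connected  # the dot carries a not-connected constraint


def test_ring_sizes_collected_for_cap_raising():
    pat = parse_smarts("[R2&r9]", Directives())
    assert pat.required_ring_sizes() == [9]


def test_r500_and_r600_are_aromatic_ring_primitives():
    pat = parse_smarts("[n;r500]", Directives())
    kinds = [p.kind for p in _prims(pat.atoms[0].expr)]
    assert "aromatic_ring_size" in kinds
    pat = parse_smarts("[O;r3]", Directives())
    assert any(p.kind == "ringsize" and p.value == 3
               for p in _prims(pat.atoms[0].expr))


def test_unsupported_daylight_primitives_rejected():
    with pytest.raises(SmilesError):
        parse_smarts("F/?C=C/Cl", Directives())
    with pytest.raises(SmilesError):
        parse_smarts("[C@?H](F)(Cl)Br", Directives())


def test_pdb_spec_five_parts():
    pat = parse_smarts("[G#129^A.P#15]", Directives())
    prim = next(p for p in _prims(pat.atoms[0].expr) if p.kind == "pdb")
    spec = prim.value
    assert (spec.res_name, spec.res_num, spec.ins_code,
            spec.atom_name, spec.atomic_num) == ("G", 129, "A", "P", 15)


PRINTED_PATTERNS = [
    "*1**1", "a1aaaa1", "AAAA", "OH", "[#-36]", "[12?#6]", "[0?]", "[!0?]",
    "[X2]", "[n;d3]", "[#6D3]", "[C;h2]", "[CH3]", "[H0]", "[!H0]", "[x1]",
    "[x0]", "[!x0]", "[x]", "[R]", "[!R]", "[R2]", "[O;r3]", "[O;!r3]",
    "[n;r500]", "[n;r600]", "[C;v3]", "[ALA.C]", "[ILE#35.*]", "[#35.*]",
    "[*.CA&!CA.CA]", "[*.CA#6]", "[=22]", '["7"]', "[$(aaN)$(aaaC)]",
    "C[$3(C=C)]C", "C[$2-3(C=C)]C", "{[#6]}C=O", "C(.d:1.5-1.6)C",
    "C(.d:!1.5-1.6)C", "C(.a:115-125)CC", "(F.O)", "(F).(O)", "(*).(*)",
    "{C}C=O", "{C}[CH]=O", "[sD2r500]", "[$([SD2](-*)-*)]",
    "{*}(.t:-170,-180,170,180)C=C{*}", "[$(cc[OH])]",
]


@pytest.mark.parametrize("text", PRINTED_PATTERNS)
def test_published_pattern_strings_parse(text):
    clauses, d = preprocess_smarts(text)
    for c in clauses:
        parse_smarts(c, d)


def test_preprocessing_is_purely_lexical():
    raw = 'C[$2(C=C)]C'
    expanded = expand_repeats(raw)[0]
    a = parse_smarts(expanded, Directives())
    clauses, d = preprocess_smarts(raw)
    b = parse_smarts(clauses[0], d)
    assert len(a.atoms) == len(b.atoms)
    assert repr(a.atoms[1].expr) == repr(b.atoms[1].expr)
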