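"""Jmol SMILES: preprocessing, parsing, and generation.

The dialect is a superset of OpenSMILES.  On top of the standard grammar it
accepts ``//* ... *//`` comments, free whitespace, a leading ``/.../``
directive block, unbracketed ``H``, the dummy atom ``[Xx]``, ring-closure
numbers of any size via ``%(n)``, explicit aromatic double bonds ``a=a``
(which switch on Kekule-sensitive matching), atropisomer bond marks
``^nm-``/``^^nm-``, and extended stereo shapes (trigonal pyramidal,
T-shaped, seesaw, cumulene/imine cis-trans).

``preprocess`` handles comments, directives and whitespace; ``parse_smiles``
builds a :class:`~molpat.chem_graph.Molecule`; ``generate_smiles`` writes a
deterministic (non-canonical) string back out.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Optional

from .chem_graph import ATOMIC_NUMBER, DEFAULT_VALENCES, Atom, Molecule

logger = logging.getLogger("molpat")


class SmilesError(ValueError):
    """Raised for any syntax or semantic error in SMILES/SMARTS input."""


# --------------------------------------------------------------------------
# directives
# --------------------------------------------------------------------------


@dataclass
class Directives:
    """Processing directives attached to a parse/match/generate job.

    ``aromaticity_model`` is one of open, strict, planar, defined, none.
    ``no_stereo`` wins over ``invert_stereo`` when both are set.
    """

    aromaticity_model: str = "open"
    no_stereo: bool = False
    invert_stereo: bool = False
    no_atom_class: bool = False
    aromatic_double: bool = False
    first_match_only: bool = False
    group_mode: str = "by_molecule"
    gen_atom_comments: bool = False
    gen_hydrogens: bool = False
    gen_topology: bool = False

    def copy(self) -> "Directives":
        return replace(self)


_DIRECTIVE_ACTIONS = {
    "open": ("aromaticity_model", "open"),
    "strict": ("aromaticity_model", "strict"),
    "noaromatic": ("aromaticity_model", "none"),
    "aromaticplanar": ("aromaticity_model", "planar"),
    "aromaticdefined": ("aromaticity_model", "defined"),
    "nostereo": ("no_stereo", True),
    "invertstereo": ("invert_stereo", True),
    "noatomclass": ("no_atom_class", True),
    "aromaticdouble": ("aromatic_double", True),
    "firstmatchonly": ("first_match_only", True),
    "groupbymolecule": ("group_mode", "by_molecule"),
    "groupbymodel": ("group_mode", "by_model"),
    "atomcomments": ("gen_atom_comments", True),
    "hydrogens": ("gen_hydrogens", True),
    "topology": ("gen_topology", True),
}


def strip_comments(text: str) -> str:
    out = []
    i = 0
    while i < len(text):
        if text.startswith("//*", i):
            end = text.find("*//", i + 3)
            if end < 0:
                raise SmilesError("unterminated comment (missing '*//')")
            i = end + 3
        else:
            out.append(text[i])
            i += 1
    return "".join(out)


def _parse_directive_block(text: str) -> tuple[str, Directives]:
    directives = Directives()
    stripped = text.lstrip()
    if stripped.startswith("/"):
        end = stripped.find("/", 1)
        if end < 0:
            raise SmilesError("unterminated directive block")
        block = stripped[1:end]
        names = [n for n in re.split(r"[^A-Za-z]+", block) if n]
        strict_seen = False
        for name in names:
            action = _DIRECTIVE_ACTIONS.get(name.lower())
            if action is None:
                raise SmilesError(f"unknown directive {name!r}")
            attr, value = action
            if name.lower() == "strict":
                strict_seen = True
            setattr(directives, attr, value)
        if strict_seen:  # /open,strict/ means strict
            directives.aromaticity_model = "strict"
        text = stripped[end + 1:]
    return text, directives


def _strip_whitespace(text: str) -> str:
    """Remove whitespace except inside quoted atom types and $(select ...)."""
    out = []
    i = 0
    in_quote = False
    select_depth = 0
    while i < len(text):
        c = text[i]
        if in_quote:
            out.append(c)
            if c == '"':
                in_quote = False
            i += 1
            continue
        if select_depth > 0:
            if c == "(":
                select_depth += 1
            elif c == ")":
                select_depth -= 1
            out.append(c)
            i += 1
            continue
        if c == '"':
            in_quote = True
            out.append(c)
            i += 1
            continue
        m = re.match(r"\$\(\s*select\b", text[i:])
        if m:
            out.append(text[i:i + m.end()])
            select_depth = 1
            i += m.end()
            continue
        if c.isspace():
            i += 1
            continue
        out.append(c)
        i += 1
    return "".join(out)


def preprocess(text: str) -> tuple[str, Directives]:
    """Strip comments, consume the leading directive block, remove whitespace.

    Whitespace inside quoted atom-type tokens and ``[$(select ...)]`` bodies
    is preserved.  Idempotent on its own output.
    """
    text = strip_comments(text)
    text, directives = _parse_directive_block(text)
    return _strip_whitespace(text), directives


# --------------------------------------------------------------------------
# stereo tokens
# --------------------------------------------------------------------------

PHANTOM_H = -1
PHANTOM_LONE_PAIR = -2

_SHAPE_ARITY = {"TH": 4, "AL": 4, "SP": 4, "TB": 5, "OH": 6, "TP": 3, "TS": 3, "SS": 4}


@dataclass
class StereoToken:
    """Stereo descriptor written at one atom of a SMILES/SMARTS string."""

    center: int
    shape: str  # TH, TP, SP, TB, OH, TS, SS, allenic
    order_index: int  # 1 for @, 2 for @@ (or the written index)
    neighbor_sequence: list = field(default_factory=list)

    @property
    def parity(self) -> Optional[str]:
        if self.order_index == 1:
            return "@"
        if self.order_index == 2:
            return "@@"
        return None


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

_ORGANIC = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I", "H"}
_AROMATIC_ORGANIC = {"b", "c", "n", "o", "p", "s"}
_OPEN_AROMATIC = {"b", "c", "n", "o", "p", "s", "as", "se"}
_AROMATIC_VALENCE = {"b": 3, "c": 4, "n": 3, "o": 2, "p": 3, "s": 2, "as": 3, "se": 2}

_BOND_ORDERS = {"-": 1, "=": 2, "#": 3, "$": 4}


@dataclass
class _PendingBond:
    order: Optional[int] = 1
    aromatic: bool = False
    default: bool = False  # no symbol written
    mark: Optional[str] = None
    atrop: Optional[tuple[int, int]] = None


def _parse_bond_token(s: str, i: int) -> tuple[Optional[_PendingBond], int]:
    c = s[i]
    if c in _BOND_ORDERS:
        return _PendingBond(order=_BOND_ORDERS[c]), i + 1
    if c == ":":
        return _PendingBond(order=None, aromatic=True), i + 1
    if c in "/\\":
        return _PendingBond(order=1, mark=c), i + 1
    if c == "^":
        j = i + 1
        mark = "^"
        if j < len(s) and s[j] == "^":
            mark = "^^"
            j += 1
        m = re.match(r"(\d)(\d)-", s[j:])
        if not m:
            raise SmilesError(f"malformed atropisomer bond at position {i}")
        return _PendingBond(order=1, mark=mark,
                            atrop=(int(m.group(1)), int(m.group(2)))), j + 3
    return None, i


_STEREO_RE = re.compile(r"@(@|(?:TH|AL|SP|TB|OH|TP|TS|SS)\d+)?")


def _parse_bracket_atom(s: str, i: int, directives: Directives,
                        smarts_ok: bool = False) -> tuple[dict, int]:
    """Parse the inside of a bracket atom starting after '['.

    Returns a dict of atom properties and the index just past ']'.
    """
    start = i
    props: dict = {"isotope": None, "charge": 0, "hcount": 0, "atom_class": None,
                   "aromatic": False, "stereo": None}
    m = re.match(r"(\d+)", s[i:])
    if m:
        props["isotope"] = int(m.group(1))
        i += m.end()
        if i < len(s) and s[i] == "?":
            raise SmilesError("mass wildcard 'n?' is a SMARTS primitive, not SMILES")
    # symbol
    sym = None
    if s.startswith("Xx", i):
        sym, z, arom = "Xx", 0, False
        i += 2
    elif s[i] == "*":
        sym, z, arom = "*", None, False
        i += 1
    else:
        two = s[i:i + 2]
        one = s[i:i + 1]
        if len(two) == 2 and two[0].isupper() and two[1].islower() and two in ATOMIC_NUMBER:
            sym, z, arom = two, ATOMIC_NUMBER[two], False
            i += 2
        elif one.isupper() and one in ATOMIC_NUMBER:
            sym, z, arom = one, ATOMIC_NUMBER[one], False
            i += 1
        elif two.islower() and two.isalpha() and two.capitalize() in ATOMIC_NUMBER and (
            two in _OPEN_AROMATIC
            or directives.aromaticity_model not in ("open", "strict")
        ):
            sym, z, arom = two.capitalize(), ATOMIC_NUMBER[two.capitalize()], True
            i += 2
        elif one.islower() and one.isalpha() and one.capitalize() in ATOMIC_NUMBER:
            if one not in _OPEN_AROMATIC and directives.aromaticity_model in ("open", "strict"):
                raise SmilesError(
                    f"lowercase (aromatic) symbol {one!r} not allowed under the "
                    f"{directives.aromaticity_model} model"
                )
            sym, z, arom = one.upper(), ATOMIC_NUMBER[one.upper()], True
            i += 1
        else:
            raise SmilesError(f"bad element symbol in bracket atom at {start}")
    props["element"], props["atomic_number"], props["aromatic"] = sym, z, arom
    # stereo
    if i < len(s) and s[i] == "@":
        m = _STEREO_RE.match(s, i)
        tag = m.group(1)
        if tag is None:
            shape, order = None, 1
        elif tag == "@":
            shape, order = None, 2
        else:
            shape, order = tag[:2], int(tag[2:])
        props["stereo"] = (shape, order)
        i = m.end()
        if i < len(s) and s[i] == "?":
            raise SmilesError("unspecified stereochemistry '@..?' is not supported")
    # hcount
    if i < len(s) and s[i] == "H":
        i += 1
        m = re.match(r"(\d+)", s[i:])
        if m:
            props["hcount"] = int(m.group(1))
            i += m.end()
        else:
            props["hcount"] = 1
    # charge
    if i < len(s) and s[i] in "+-":
        sign = 1 if s[i] == "+" else -1
        c = s[i]
        i += 1
        m = re.match(r"(\d+)", s[i:])
        if m:
            props["charge"] = sign * int(m.group(1))
            i += m.end()
        else:
            n = 1
            while i < len(s) and s[i] == c:
                n += 1
                i += 1
            props["charge"] = sign * n
    # atom class
    if i < len(s) and s[i] == ":":
        i += 1
        m = re.match(r"(\d+)", s[i:])
        if not m:
            raise SmilesError(f"missing atom class number at {i}")
        props["atom_class"] = int(m.group(1))
        i += m.end()
    if i >= len(s) or s[i] != "]":
        raise SmilesError(
            f"bad bracket-atom ordering near position {start} "
            "(expected [mass symbol stereo hcount charge :class])"
        )
    return props, i + 1


def parse_smiles(text: str, directives: Optional[Directives] = None) -> Molecule:
    """Parse a Jmol SMILES string into a Molecule.

    When ``directives`` is None, the full preprocessing pipeline (comments,
    directive block, whitespace) runs first and the parsed directives are
    attached to the returned molecule as ``mol.directives``.
    """
    if directives is None:
        text, directives = preprocess(text)

    s = text.replace(">>", ".")
    mol = Molecule()
    prev: Optional[int] = None
    pending: Optional[_PendingBond] = None
    stack: list[Optional[int]] = []
    ring_open: dict[int, tuple[int, Optional[_PendingBond], int]] = {}
    seq: dict[int, list] = {}  # written-order neighbor sequences
    stereo_raw: list[tuple[int, tuple]] = []

    def make_bond(a: int, b: int, pb: Optional[_PendingBond],
                  ring_slot: Optional[int] = None) -> None:
        if pb is None or pb.default:
            both_arom = mol.atoms[a].aromatic and mol.atoms[b].aromatic
            order, arom = (None, True) if both_arom else (1, False)
            mark = atrop = None
            written = False
        else:
            order, arom, mark, atrop = pb.order, pb.aromatic, pb.mark, pb.atrop
            written = True
            if order == 2 and mol.atoms[a].aromatic and mol.atoms[b].aromatic:
                arom = True
                directives.aromatic_double = True  # a=a auto-flag
        mol.add_bond(a, b, order=order, aromatic=arom,
                     stereo_mark=mark, atrop_digits=atrop,
                     order_written=written)
        if ring_slot is not None:
            seq[a][ring_slot] = b
        else:
            seq[a].append(b)
        seq[b].append(a)

    i = 0
    while i < len(s):
        c = s[i]
        if c == "(":
            stack.append(prev)
            i += 1
            continue
        if c == ")":
            if not stack:
                raise SmilesError(f"unbalanced ')' at {i}")
            prev = stack.pop()
            i += 1
            continue
        if c == ".":
            prev = None
            pending = None
            i += 1
            continue
        pb, j = _parse_bond_token(s, i)
        if pb is not None:
            if pending is not None:
                raise SmilesError(f"two bond symbols in a row at {i}")
            pending = pb
            i = j
            continue
        if c == "%" or c.isdigit():
            if prev is None:
                raise SmilesError(f"ring closure digit with no preceding atom at {i}")
            if c == "%":
                if i + 1 < len(s) and s[i + 1] == "(":
                    m = re.match(r"%\((\d+)\)", s[i:])
                    if not m:
                        raise SmilesError(f"malformed %(n) ring closure at {i}")
                    num = int(m.group(1))
                    i += m.end()
                else:
                    m = re.match(r"%(\d\d)", s[i:])
                    if not m:
                        raise SmilesError(f"malformed %nn ring closure at {i}")
                    num = int(m.group(1))
                    i += m.end()
            else:
                num = int(c)
                i += 1
            if num in ring_open:
                a, pb_open, slot = ring_open.pop(num)
                if a == prev:
                    raise SmilesError(f"ring closure {num} to the same atom")
                use = pending if pending is not None and not pending.default else pb_open
                if (pending is not None and pb_open is not None
                        and not pending.default and not pb_open.default
                        and pending.order != pb_open.order):
                    raise SmilesError(f"conflicting bond types for ring closure {num}")
                make_bond(prev, a, use)
                # fix ordering: bond was recorded at prev; patch the slot at a
                seq[a][slot] = prev
                seq[prev].pop()  # undo double append at prev from make_bond
                seq[prev].append(a)
                pending = None
            else:
                ring_open[num] = (prev, pending, len(seq[prev]))
                seq[prev].append(("ring", num))
                pending = None
            continue
        # atom token
        if c == "[":
            props, i = _parse_bracket_atom(s, i + 1, directives)
            atom = mol.add_atom(Atom(
                index=-1, element=props["element"],
                atomic_number=props["atomic_number"] if props["atomic_number"] is not None else 0,
                isotope=props["isotope"], charge=props["charge"],
                implicit_h=props["hcount"], aromatic=props["aromatic"],
                atom_class=props["atom_class"],
            ))
            if props["element"] == "*":
                atom.element = "*"
            stereo = props["stereo"]
        else:
            two = s[i:i + 2]
            if two in ("Cl", "Br"):
                symbol, arom = two, False
                i += 2
            elif c in "BCNOPSFI" or c == "H":
                symbol, arom = c, False
                i += 1
            elif c in "bcnops":
                symbol, arom = c.upper(), True
                i += 1
            else:
                raise SmilesError(f"unexpected character {c!r} at position {i}")
            atom = mol.add_atom(Atom(index=-1, element=symbol,
                                     atomic_number=ATOMIC_NUMBER[symbol],
                                     aromatic=arom, implicit_h=-1))
            stereo = None
        if directives.aromaticity_model == "none":
            atom.aromatic = False  # upper/lower case is not significant
        seq[atom.index] = []
        if prev is not None:
            make_bond(prev, atom.index, pending)
        pending = None
        if stereo is not None:
            stereo_raw.append((atom.index, stereo))
            if atom.implicit_h and atom.implicit_h > 0:
                seq[atom.index].append(PHANTOM_H)
        prev = atom.index

    if stack:
        raise SmilesError("unbalanced '(' in SMILES")
    if ring_open:
        raise SmilesError(f"unmatched ring closure number(s): {sorted(ring_open)}")
    if pending is not None:
        raise SmilesError("dangling bond symbol at end of SMILES")

    _fill_implicit_h(mol)
    _resolve_stereo(mol, seq, stereo_raw)
    _collect_cis_trans(mol, seq)
    mol.directives = directives
    return mol


def implicit_h(mol: Molecule, idx: int, bracket: bool) -> int:
    """Implicit hydrogen count for one atom by the normal-valence rule."""
    a = mol.atoms[idx]
    if bracket:
        return max(a.implicit_h, 0)
    bond_sum = sum(
        mol.bond_between(idx, n).valence_order() for n in mol.neighbors(idx)
    )
    if a.aromatic:
        val = _AROMATIC_VALENCE.get(a.element.lower(), 4)
        # the -1 stands for the atom's pi electron; an explicit a=a Kekule
        # double bond already accounts for it
        pi = 0 if any(
            mol.bond_between(idx, n).order == 2 and mol.atoms[n].aromatic
            for n in mol.neighbors(idx)
        ) else 1
        return max(val - bond_sum - pi, 0)
    valences = DEFAULT_VALENCES.get(a.atomic_number, ())
    for v in valences:
        if v >= bond_sum:
            return v - bond_sum
    return 0


def _fill_implicit_h(mol: Molecule) -> None:
    for a in mol.atoms:
        if a.implicit_h == -1:  # unbracketed: apply normal valence
            a.implicit_h = implicit_h(mol, a.index, bracket=False)


def _resolve_stereo(mol: Molecule, seq: dict[int, list], raw) -> None:
    for idx, (shape, order) in raw:
        neighbors = list(seq[idx])
        atom = mol.atoms[idx]
        double_bonds = [
            n for n in mol.neighbors(idx)
            if mol.bond_between(idx, n).order == 2
        ]
        if shape is None:
            if len(double_bonds) == 2 and len(mol.neighbors(idx)) == 2:
                shape = "AL"
            elif len(neighbors) == 4:
                shape = "TH"
            elif len(neighbors) == 3 and PHANTOM_H not in neighbors:
                shape = "TP"
            else:
                shape = "TH"
        if shape == "AL":
            neighbors = _allene_sequence(mol, seq, idx)
            token = StereoToken(idx, "allenic", order, neighbors)
        elif shape == "TP":
            token = StereoToken(idx, "TP", order,
                                neighbors + [PHANTOM_LONE_PAIR])
        else:
            arity = _SHAPE_ARITY.get(shape)
            if shape in ("TH", "SP", "TB", "OH", "TS", "SS") and arity is not None:
                expect = arity if shape != "TS" else 3
                if len(neighbors) != expect and shape == "TH":
                    raise SmilesError(
                        f"stereo atom {idx} has {len(neighbors)} neighbors, "
                        f"expected {expect} for shape {shape}"
                    )
            token = StereoToken(idx, shape, order, neighbors)
        atom.stereo = token
        mol.stereo_centers.append(token)


def _allene_sequence(mol: Molecule, seq: dict[int, list], center: int) -> list:
    """Substituent sequence across an odd-cumulene axis, in written order."""
    ends = []
    for start in mol.neighbors(center):
        prev_a, cur = center, start
        while True:
            nxt = [
                n for n in mol.neighbors(cur)
                if n != prev_a and mol.bond_between(cur, n).order == 2
            ]
            if not nxt or len(mol.neighbors(cur)) != 2:
                break
            prev_a, cur = cur, nxt[0]
        ends.append((prev_a, cur) if not nxt else (cur, nxt[0]))
    out = []
    for _, end in [(None, e[1] if isinstance(e, tuple) else e) for e in ends]:
        subs = [n for n in seq[end] if not isinstance(n, tuple) and n >= 0
                and mol.bond_between(end, n) is not None
                and mol.bond_between(end, n).order != 2]
        if mol.atoms[end].implicit_h:
            subs = subs + [PHANTOM_H]
        out.extend(subs[:2])
    return out


# -- cis/trans bookkeeping -------------------------------------------------


@dataclass
class CisTransUnit:
    """One double bond (or even cumulene) with resolved side information."""

    end1: int
    end2: int
    sub1: int
    sub2: int
    relation: str  # "cis" or "trans"


def _mark_factor(bond, end: int) -> int:
    """+1/-1 side factor of a marked flanking bond, relative to its end atom."""
    sigma = 1 if bond.stereo_mark == "/" else -1
    direction = 1 if bond.a2 == end else -1  # written substituent-first?
    return sigma * direction


def _collect_cis_trans(mol: Molecule, seq) -> None:
    units = []
    done = set()
    for b in mol.bonds:
        if b.order != 2:
            continue
        key = (min(b.a1, b.a2), max(b.a1, b.a2))
        if key in done:
            continue
        # walk the cumulene chain both ways
        chain = _double_chain(mol, b)
        for i in range(len(chain) - 1):
            done.add((min(chain[i], chain[i + 1]), max(chain[i], chain[i + 1])))
        if len(chain) % 2 != 0:
            continue  # odd number of atoms: allenic, handled by stereo tokens
        e1, e2 = chain[0], chain[-1]
        m1 = _marked_substituents(mol, e1, chain[1])
        m2 = _marked_substituents(mol, e2, chain[-2])
        if not m1 and not m2:
            continue
        if bool(m1) != bool(m2):
            raise SmilesError(
                "cis/trans marks must be present on both sides of a double bond"
            )
        for marks in (m1, m2):
            if len(marks) == 2 and marks[0][1] == marks[1][1]:
                raise SmilesError("conflicting cis/trans marks on one atom")
        (s1, f1), (s2, f2) = m1[0], m2[0]
        units.append(CisTransUnit(e1, e2, s1, s2,
                                  "cis" if f1 == f2 else "trans"))
    mol.double_bond_marks = units


def _double_chain(mol: Molecule, bond) -> list[int]:
    chain = [bond.a1, bond.a2]
    for head in (0, -1):
        while True:
            end = chain[head]
            inner = chain[1] if head == 0 else chain[-2]
            ext = [
                n for n in mol.neighbors(end)
                if n != inner and mol.bond_between(end, n).order == 2
            ]
            if len(mol.neighbors(end)) == 2 and len(ext) == 1:
                if head == 0:
                    chain.insert(0, ext[0])
                else:
                    chain.append(ext[0])
            else:
                break
    return chain


def _marked_substituents(mol: Molecule, end: int, axis_neighbor: int):
    out = []
    for n in mol.neighbors(end):
        if n == axis_neighbor:
            continue
        b = mol.bond_between(end, n)
        if b.stereo_mark in ("/", "\\"):
            out.append((n, _mark_factor(b, end)))
    return out


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def _atom_token(mol: Molecule, idx: int, extra_h: int, directives: Directives) -> str:
    a = mol.atoms[idx]
    if directives.gen_topology:
        return "*"
    total_h = a.implicit_h + extra_h
    if directives.gen_hydrogens:
        total_h = 0  # hydrogens written as explicit [H] branches
    sym = a.element.lower() if a.aromatic else a.element
    needs_bracket = (
        a.isotope is not None
        or a.charge != 0
        or (a.atom_class is not None and not directives.no_atom_class)
        or a.element not in _ORGANIC
        or (a.aromatic and sym not in _AROMATIC_ORGANIC)
        or a.element == "H"
    )
    if not needs_bracket:
        # does the normal-valence rule reproduce the H count?
        saved = a.implicit_h
        a.implicit_h = -1
        inferred = implicit_h(mol, idx, bracket=False)
        a.implicit_h = saved
        if directives.gen_hydrogens:
            inferred_ok = inferred == 0 or True  # H emitted explicitly anyway
        else:
            inferred_ok = inferred == total_h
        if inferred_ok:
            return sym
        needs_bracket = True
    parts = ["["]
    if a.isotope is not None:
        parts.append(str(a.isotope))
    parts.append(sym if a.element != "Xx" else "Xx")
    if total_h == 1:
        parts.append("H")
    elif total_h > 1:
        parts.append(f"H{total_h}")
    if a.charge:
        parts.append(f"{a.charge:+d}" if abs(a.charge) > 1
                     else ("+" if a.charge > 0 else "-"))
    if a.atom_class is not None and not directives.no_atom_class:
        parts.append(f":{a.atom_class}")
    parts.append("]")
    return "".join(parts)


def _bond_token(bond, mol: Molecule, directives: Directives) -> str:
    if directives.gen_topology:
        return ""
    a1, a2 = mol.atoms[bond.a1], mol.atoms[bond.a2]
    if bond.aromatic and a1.aromatic and a2.aromatic:
        return ""
    if bond.order is None:
        return ":"
    if bond.order == 1:
        if a1.aromatic and a2.aromatic:
            return "-"  # biaryl single bond is significant
        return ""
    return {2: "=", 3: "#", 4: "$"}[bond.order]


def _ring_digit(n: int) -> str:
    if n <= 9:
        return str(n)
    if n <= 99:
        return f"%{n:02d}"
    return f"%({n})"


def generate_smiles(mol: Molecule, directives: Optional[Directives] = None) -> str:
    """Write a deterministic, non-canonical SMILES string.

    Traversal starts at the lowest atom index of each component and visits
    neighbors in ascending index order; ring-closure digits are allocated
    lowest-free-first.  Stereochemistry is not emitted: the string records
    constitution and aromaticity, which is what the non-canonical matching
    workflow consumes.

    With ``gen_atom_comments`` each atom is followed by a
    ``//* #<index+1> <name> *//`` comment naming the source atom.
    """
    if directives is None:
        directives = Directives()
    from . import perception

    if mol.aromaticity_model != directives.aromaticity_model:
        perception.perceive_aromaticity(mol, directives.aromaticity_model)

    # fold terminal explicit hydrogens into their heavy neighbor
    folded: dict[int, int] = {}
    skip: set[int] = set()
    if not directives.gen_hydrogens:
        for a in mol.atoms:
            if a.is_h() and len(mol.neighbors(a.index)) == 1:
                heavy = mol.neighbors(a.index)[0]
                if not mol.atoms[heavy].is_h():
                    folded[heavy] = folded.get(heavy, 0) + 1
                    skip.add(a.index)

    open_digits: set[int] = set()
    out: list[str] = []
    emitted_atoms: list[int] = []  # generated-token -> source-atom correlation

    def alloc_digit() -> int:
        n = 1
        while n in open_digits:
            n += 1
        open_digits.add(n)
        return n

    def emit_atom(idx: int) -> None:
        extra = folded.get(idx, 0)
        out.append(_atom_token(mol, idx, extra, directives))
        emitted_atoms.append(idx)
        if directives.gen_atom_comments:
            a = mol.atoms[idx]
            name = a.atom_name or f"{a.element}{idx + 1}"
            out.append(f"//* #{idx + 1} {name} *//")

    # Back (ring) edges of a DFS over ascending neighbor indices; the emit
    # traversal below uses the same ordering, so digits open at the
    # first-visited endpoint.
    ring_digits: dict[tuple[int, int], int] = {}
    seen: set[int] = set(skip)

    def find_back_edges(start: int) -> None:
        stack = [(start, None, iter(sorted(mol.neighbors(start))))]
        seen.add(start)
        while stack:
            node, parent, it = stack[-1]
            advanced = False
            for n in it:
                if n in skip or n == parent:
                    continue
                key = (min(node, n), max(node, n))
                if n in seen:
                    ring_digits.setdefault(key, 0)
                else:
                    seen.add(n)
                    stack.append((n, node, iter(sorted(mol.neighbors(n)))))
                    advanced = True
                    break
            if not advanced:
                stack.pop()

    for start in range(len(mol.atoms)):
        if start not in seen:
            find_back_edges(start)

    visited: set[int] = set(skip)

    def emit(idx: int) -> None:
        visited.add(idx)
        emit_atom(idx)
        # ring digits: open or close
        for n in sorted(mol.neighbors(idx)):
            if n in skip:
                continue
            key = (min(idx, n), max(idx, n))
            if key in ring_digits:
                val = ring_digits[key]
                if val == 0 and n not in visited:  # open at first endpoint
                    d = alloc_digit()
                    ring_digits[key] = d
                    bond = mol.bond_between(idx, n)
                    out.append(_bond_token(bond, mol, directives) + _ring_digit(d))
                elif val > 0 and n in visited:
                    out.append(_ring_digit(val))
                    ring_digits[key] = -val
                    open_digits.discard(val)
        if directives.gen_hydrogens and not directives.gen_topology:
            for _ in range(mol.atoms[idx].implicit_h):
                out.append("([H])")
        children = [
            n for n in sorted(mol.neighbors(idx))
            if n not in skip and n not in visited
            and (min(idx, n), max(idx, n)) not in ring_digits
        ]
        for k, child in enumerate(children):
            if child in visited:
                continue
            bond = mol.bond_between(idx, child)
            last = k == len(children) - 1
            if not last:
                out.append("(")
            out.append(_bond_token(bond, mol, directives))
            emit(child)
            if not last:
                out.append(")")

    first = True
    for start in range(len(mol.atoms)):
        if start in visited:
            continue
        if not first:
            out.append(".")
        first = False
        emit(start)
    smiles = "".join(out)
    mol.last_generated_order = emitted_atoms
    return smiles
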