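"""Jmol SMARTS parsing: preprocessing and pattern-graph construction.

The preprocessing stages are purely lexical and run in a fixed order:
comments are stripped, the ``/.../`` directive block is consumed, predefined
variables (``$name="value";``) are substituted, pattern repeats
(``$n(P)``, ``$m-n(P)``) are expanded, and ``||`` splits the text into
independent clauses whose match results the caller unions.

``parse_smarts`` then builds a :class:`PatternGraph`: atom-expression trees
over the full primitive set, bond expressions, selection braces, geometric
measurement constraints, and component-level grouping.

Tokenization inside brackets resolves element symbols greedily (two-letter
first), so ``[nd3]`` reads as aromatic neodymium followed by a misplaced
atomic mass - and errors out - exactly as the cautionary reading warns;
write ``[n;d3]`` for a trivalent aromatic nitrogen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .chem_graph import ATOMIC_NUMBER
from .smiles import (
    PHANTOM_H,
    Directives,
    SmilesError,
    StereoToken,
    _STEREO_RE,
    preprocess,
)

# --------------------------------------------------------------------------
# lexical preprocessing
# --------------------------------------------------------------------------

_VARDEF_RE = re.compile(r'^\$([A-Za-z]\w*)="([^"]*)";?')
_VARREF_RE = re.compile(r"\$([A-Za-z]\w*)")


def expand_variables(text: str) -> str:
    """Consume leading ``$name="value";`` definitions and substitute references.

    ``[$name]`` is replaced (brackets included) by the value; a bare
    ``$name`` likewise.  Later definitions may use earlier ones.
    """
    defs: dict[str, str] = {}
    while True:
        m = _VARDEF_RE.match(text)
        if not m:
            break
        name, value = m.group(1), m.group(2)
        defs[name] = _substitute(value, defs, where=f"definition of ${name}")
        text = text[m.end():]
    return _substitute(text, defs, where="pattern")


def _substitute(text: str, defs: dict[str, str], where: str) -> str:
    for name in sorted(defs, key=len, reverse=True):
        text = text.replace(f"[${name}]", defs[name])
        text = text.replace(f"${name}", defs[name])
    if defs:
        # once variables are in play, any leftover $word is an undefined
        # (or forward/circular) reference; without definitions a "$X" is
        # left alone as a quadruple bond followed by an atom
        m = _VARREF_RE.search(text)
        if m:
            raise SmilesError(f"undefined variable ${m.group(1)} in {where}")
    return text


_REPEAT_RE = re.compile(r"\$(\d+)(?:-(\d+))?\(")


def _balanced(text: str, start: int) -> int:
    """Index of the ')' matching the '(' at ``start``."""
    depth = 0
    for i in range(start, len(text)):
        if text[i] == "(":
            depth += 1
        elif text[i] == ")":
            depth -= 1
            if depth == 0:
                return i
    raise SmilesError("unbalanced parentheses")


def expand_repeats(text: str) -> list[str]:
    """Expand ``$n(P)`` and ``$min-max(P)`` repeats.

    Inside brackets the expansion stays a nested primitive
    (``[$3(C=C)]`` becomes ``[$(C=CC=CC=C)]``, a variable count becomes a
    comma OR-clause); outside brackets ``$n(P)`` is plain concatenation and
    a variable count multiplies the surrounding pattern into alternatives.
    """
    texts = [text]
    out: list[str] = []
    while texts:
        t = texts.pop(0)
        m = _REPEAT_RE.search(t)
        if not m:
            out.append(t)
            continue
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        if lo <= 0:
            raise SmilesError("repeat count must be positive")
        if lo > hi:
            raise SmilesError(f"bad repeat range {lo}-{hi}")
        open_paren = m.end() - 1
        close = _balanced(t, open_paren)
        body = t[open_paren + 1:close]
        in_bracket = t.count("[", 0, m.start()) > t.count("]", 0, m.start())
        if in_bracket:
            alts = ",".join(f"$({body * k})" for k in range(lo, hi + 1))
            texts.insert(0, t[:m.start()] + alts + t[close + 1:])
        else:
            for k in range(lo, hi + 1):
                texts.append(t[:m.start()] + body * k + t[close + 1:])
    return out


def split_or_clauses(text: str) -> list[str]:
    """Split on the lexical large-scope OR ``||``."""
    clauses = [c for c in text.split("||")]
    if any(c.strip() == "" for c in clauses):
        raise SmilesError("empty '||' clause")
    return clauses


def preprocess_smarts(text: str) -> tuple[list[str], Directives]:
    """Full lexical pipeline; returns clause texts and directives."""
    clean, directives = preprocess(text)
    clean = expand_variables(clean)
    clauses: list[str] = []
    for t in split_or_clauses(clean):
        clauses.extend(expand_repeats(t))
    return clauses, directives


# --------------------------------------------------------------------------
# expression trees
# --------------------------------------------------------------------------


@dataclass
class Prim:
    """Leaf primitive of an atom or bond expression."""

    kind: str
    value: object = None


@dataclass
class Expr:
    """Interior node: ``not``, ``and_high`` (&), ``or`` (,), ``and_low`` (;)."""

    op: str
    children: list

    def walk(self):
        yield self
        for c in self.children:
            if isinstance(c, Expr):
                yield from c.walk()
            else:
                yield c


def _walk_prims(node):
    if isinstance(node, Prim):
        yield node
    else:
        for c in node.children:
            yield from _walk_prims(c)


@dataclass
class PdbSpec:
    res_name: Optional[str] = None
    res_num: Optional[int] = None
    ins_code: Optional[str] = None
    atom_name: Optional[str] = None
    atomic_num: Optional[int] = None


# --------------------------------------------------------------------------
# pattern graph
# --------------------------------------------------------------------------


@dataclass
class PatternAtom:
    index: int
    expr: object  # Expr or Prim
    brace_selected: bool = False
    group_id: Optional[int] = None
    seq: list = field(default_factory=list)  # written-order neighbors
    stereo: Optional[StereoToken] = None


@dataclass
class PatternBond:
    a1: int
    a2: int
    expr: object  # Expr or Prim ("default" when no symbol written)


@dataclass
class MeasurementConstraint:
    kind: str  # "distance", "angle", "torsion"
    mid: Optional[int]
    ranges: list[tuple[float, float]]
    negated: bool
    member_atoms: list[int]

    ARITY = {"distance": 2, "angle": 3, "torsion": 4}


@dataclass
class PatternGraph:
    atoms: list[PatternAtom] = field(default_factory=list)
    bonds: list[PatternBond] = field(default_factory=list)
    measurements: list[MeasurementConstraint] = field(default_factory=list)
    n_groups: int = 0
    source: str = ""
    #: "." pairs whose mapped images must be absolutely not connected
    not_connected: list[tuple[int, int]] = field(default_factory=list)

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.a1 == idx:
                out.append(b.a2)
            elif b.a2 == idx:
                out.append(b.a1)
        return out

    def bond_between(self, a1: int, a2: int) -> Optional[PatternBond]:
        for b in self.bonds:
            if {b.a1, b.a2} == {a1, a2}:
                return b
        return None

    def has_braces(self) -> bool:
        return any(a.brace_selected for a in self.atoms)

    def required_ring_sizes(self) -> list[int]:
        sizes = []
        for a in self.atoms:
            for p in _walk_prims(a.expr):
                if p.kind == "ringsize" and p.value is not None:
                    sizes.append(p.value)
                elif p.kind == "nested":
                    sizes.extend(p.value.required_ring_sizes())
        return sizes

    def components(self) -> list[int]:
        """Connected-component label per pattern atom."""
        labels = [-1] * len(self.atoms)
        comp = 0
        adj: dict[int, list[int]] = {i: [] for i in range(len(self.atoms))}
        for b in self.bonds:
            adj[b.a1].append(b.a2)
            adj[b.a2].append(b.a1)
        for start in range(len(self.atoms)):
            if labels[start] != -1:
                continue
            stack = [start]
            labels[start] = comp
            while stack:
                cur = stack.pop()
                for n in adj[cur]:
                    if labels[n] == -1:
                        labels[n] = comp
                        stack.append(n)
            comp += 1
        return labels


# --------------------------------------------------------------------------
# atom expression parsing
# --------------------------------------------------------------------------

_COUNT_PRIMS = {"X": "total_conn", "D": "explicit_conn", "d": "heavy_conn",
                "h": "implicit_h", "H": "total_h", "x": "ring_conn",
                "v": "valence"}

_AROMATIC_TWO = {"as", "se"}


class _AtomExprParser:
    def __init__(self, s: str):
        self.s = s
        self.i = 0
        self.symbol_seen = False
        self.only_mass_seen = True  # for the leading-H-is-hydrogen rule
        self.nprims = 0

    # grammar: low := or (';' or)* ; or := high (',' high)* ;
    #          high := unary+ ; unary := '!' unary | primitive
    def parse(self):
        node = self._or()
        parts = [node]
        while self._peek() == ";":
            self.i += 1
            parts.append(self._or())
        if self.i < len(self.s):
            raise SmilesError(
                f"unparsed atom-expression text {self.s[self.i:]!r}")
        return parts[0] if len(parts) == 1 else Expr("and_low", parts)

    def _peek(self) -> str:
        return self.s[self.i] if self.i < len(self.s) else ""

    def _or(self):
        parts = [self._high()]
        while self._peek() == ",":
            self.i += 1
            parts.append(self._high())
        return parts[0] if len(parts) == 1 else Expr("or", parts)

    def _high(self):
        parts = [self._unary()]
        while True:
            c = self._peek()
            if c == "&":
                self.i += 1
                parts.append(self._unary())
            elif c not in ("", ",", ";"):
                parts.append(self._unary())
            else:
                break
        return parts[0] if len(parts) == 1 else Expr("and_high", parts)

    def _unary(self):
        if self._peek() == "!":
            self.i += 1
            return Expr("not", [self._unary()])
        prim = self._primitive()
        if prim.kind not in ("isotope", "isotope_or_unspec"):
            self.only_mass_seen = False
        return prim

    # -- primitives -------------------------------------------------------

    def _primitive(self) -> Prim:
        s, i = self.s, self.i
        if i >= len(s):
            raise SmilesError("empty atom primitive")
        self.nprims += 1
        c = s[i]

        # PDB residue.atom spec: recognized solely by an interior "."
        m = re.match(r"[A-Za-z0-9*#^]*\.[A-Za-z0-9*#^]*", s[i:])
        if m and "." in m.group(0):
            self.i = i + m.end()
            return Prim("pdb", _parse_pdb_spec(m.group(0)))

        if c == "$":
            if not s.startswith("$(", i):
                raise SmilesError(f"bad '$' primitive at {i} in [{s}]")
            close = _balanced(s, i + 1)
            inner = s[i + 2:close]
            self.i = close + 1
            if re.match(r"\s*select\b", inner):
                return Prim("select", inner)
            return Prim("nested", parse_smarts(inner, Directives()))
        if c == '"':
            end = s.find('"', i + 1)
            if end < 0:
                raise SmilesError("unterminated atom-type quote")
            self.i = end + 1
            return Prim("atomtype", s[i + 1:end])
        if c == "@":
            mm = _STEREO_RE.match(s, i)
            tag = mm.group(1)
            self.i = mm.end()
            if self._peek() == "?":
                raise SmilesError(
                    "unspecified stereochemistry '@..?' is not supported")
            if tag is None:
                return Prim("stereo", (None, 1))
            if tag == "@":
                return Prim("stereo", (None, 2))
            return Prim("stereo", (tag[:2], int(tag[2:])))
        if c == "=":
            mm = re.match(r"=(\d+)", s[i:])
            if not mm:
                raise SmilesError(f"bad atom-index primitive at {i}")
            self.i = i + mm.end()
            return Prim("atomindex", int(mm.group(1)))
        if c == "#":
            mm = re.match(r"#(-?)(\d+)", s[i:])
            if not mm:
                raise SmilesError(f"bad '#' primitive at {i}")
            self.i = i + mm.end()
            n = int(mm.group(2))
            return Prim("appnumber" if mm.group(1) else "elemno", n)
        if c.isdigit():
            mm = re.match(r"(\d+)(\??)", s[i:])
            if self.symbol_seen:
                raise SmilesError(
                    "atomic mass improperly positioned (must precede the "
                    "element symbol)")
            self.i = i + mm.end()
            n = int(mm.group(1))
            if mm.group(2):
                return Prim("isotope_or_unspec", n)
            return Prim("isotope", n)
        if c in "+-":
            mm = re.match(r"(\+\++|--+|[+-]\d*)", s[i:])
            tok = mm.group(1)
            self.i = i + mm.end()
            if tok in ("+", "-"):
                charge = 1 if tok == "+" else -1
            elif set(tok) <= {"+"}:
                charge = len(tok)
            elif set(tok) <= {"-"}:
                charge = -len(tok)
            else:
                charge = int(tok)
            return Prim("charge", charge)
        if c == "*":
            self.i = i + 1
            return Prim("wildcard")
        if c == ":":
            mm = re.match(r":(\d+)", s[i:])
            if not mm:
                raise SmilesError("missing atom class number")
            self.i = i + mm.end()
            return Prim("atomclass", int(mm.group(1)))

        if c.isalpha():
            return self._letter_primitive()
        raise SmilesError(f"unknown atom primitive {c!r} in [{s}]")

    def _letter_primitive(self) -> Prim:
        s, i = self.s, self.i
        two = s[i:i + 2]
        # greedy two-letter element symbols first
        if len(two) == 2 and two[0].isupper() and two[1].islower() \
                and two in ATOMIC_NUMBER:
            self.i = i + 2
            self.symbol_seen = True
            return Prim("element", (ATOMIC_NUMBER[two], False))
        if len(two) == 2 and two.islower() and two.isalpha() \
                and two.capitalize() in ATOMIC_NUMBER:
            self.i = i + 2
            self.symbol_seen = True
            return Prim("element", (ATOMIC_NUMBER[two.capitalize()], True))
        c = s[i]
        if c == "a":
            self.i = i + 1
            return Prim("any_aromatic")
        if c == "A":
            self.i = i + 1
            return Prim("any_aliphatic")
        if c == "H" and self.only_mass_seen and not re.match(r"H\d", s[i:]):
            # leading H (only a mass may precede) with no digit: hydrogen
            self.i = i + 1
            self.symbol_seen = True
            return Prim("element", (1, False))
        if c == "r":
            mm = re.match(r"r(\d*)", s[i:])
            self.i = i + mm.end()
            n = int(mm.group(1)) if mm.group(1) else None
            if n == 500:
                return Prim("aromatic_ring_size", 5)
            if n == 600:
                return Prim("aromatic_ring_size", 6)
            return Prim("ringsize", n)
        if c == "R":
            mm = re.match(r"R(\d*)", s[i:])
            self.i = i + mm.end()
            return Prim("ringcount", int(mm.group(1)) if mm.group(1) else None)
        if c in _COUNT_PRIMS:
            mm = re.match(rf"{c}(\d*)", s[i:])
            self.i = i + mm.end()
            n = int(mm.group(1)) if mm.group(1) else None
            if c == "x":
                return Prim("ring_conn", n)
            if n is None:
                n = 1
            return Prim(_COUNT_PRIMS[c], n)
        if c.isupper() and c in ATOMIC_NUMBER:
            self.i = i + 1
            self.symbol_seen = True
            return Prim("element", (ATOMIC_NUMBER[c], False))
        if c.islower() and c.upper() in ATOMIC_NUMBER:
            self.i = i + 1
            self.symbol_seen = True
            return Prim("element", (ATOMIC_NUMBER[c.upper()], True))
        raise SmilesError(f"unknown atom primitive {c!r} in [{s}]")


def _parse_pdb_spec(tok: str) -> PdbSpec:
    res, atom = tok.split(".", 1)
    spec = PdbSpec()
    m = re.match(r"([A-Za-z0-9*]*)(?:#(\d+))?(?:\^([A-Za-z*]))?$", res)
    if not m:
        raise SmilesError(f"bad PDB residue spec {res!r}")
    spec.res_name = m.group(1).upper() or None
    spec.res_num = int(m.group(2)) if m.group(2) else None
    spec.ins_code = m.group(3).upper() if m.group(3) else None
    m = re.match(r"([A-Za-z0-9*']*)(?:#(\d+))?$", atom)
    if not m:
        raise SmilesError(f"bad PDB atom spec {atom!r}")
    spec.atom_name = m.group(1).upper() or None
    spec.atomic_num = int(m.group(2)) if m.group(2) else None
    for fieldname in ("res_name", "ins_code", "atom_name"):
        if getattr(spec, fieldname) == "*":
            setattr(spec, fieldname, None)
    return spec


def parse_atom_expr(text: str):
    """Parse the inside of a bracket atom into an expression tree."""
    return _AtomExprParser(text).parse()


# --------------------------------------------------------------------------
# bond expressions
# --------------------------------------------------------------------------

_BOND_START = set("-=#$:~@/\\!^")


class _BondExprParser:
    def __init__(self, s: str, i: int):
        self.s = s
        self.i = i

    def parse(self):
        node = self._or()
        parts = [node]
        while self._peek() == ";":
            self.i += 1
            parts.append(self._or())
        return (parts[0] if len(parts) == 1 else Expr("and_low", parts)), self.i

    def _peek(self):
        return self.s[self.i] if self.i < len(self.s) else ""

    def _or(self):
        parts = [self._high()]
        while self._peek() == ",":
            self.i += 1
            parts.append(self._high())
        return parts[0] if len(parts) == 1 else Expr("or", parts)

    def _high(self):
        parts = [self._unary()]
        while True:
            c = self._peek()
            if c == "&":
                self.i += 1
                parts.append(self._unary())
            elif c in _BOND_START:
                parts.append(self._unary())
            else:
                break
        return parts[0] if len(parts) == 1 else Expr("and_high", parts)

    def _unary(self):
        if self._peek() == "!":
            self.i += 1
            return Expr("not", [self._unary()])
        c = self._peek()
        self.i += 1
        if c == "-":
            return Prim("order", 1)
        if c == "=":
            return Prim("order", 2)
        if c == "#":
            return Prim("order", 3)
        if c == "$":
            return Prim("order", 4)
        if c == ":":
            return Prim("arom_bond")
        if c == "~":
            return Prim("any_bond")
        if c == "@":
            return Prim("arom_bond")
        if c in "/\\":
            if self._peek() == "?":
                raise SmilesError(
                    "'/?' and '\\?' bond primitives are not supported")
            return Prim("updown", c)
        if c == "^":
            mark = "^"
            if self._peek() == "^":
                mark = "^^"
                self.i += 1
            m = re.match(r"(\d)(\d)-", self.s[self.i:])
            if not m:
                raise SmilesError("malformed atropisomer bond")
            self.i += 3
            return Prim("atrop", (mark, int(m.group(1)), int(m.group(2))))
        raise SmilesError(f"unknown bond primitive {c!r}")


# --------------------------------------------------------------------------
# pattern parsing
# --------------------------------------------------------------------------

_MEASURE_OPEN = re.compile(r"\(\.([dat])(\d*):?")
_MEASURE_KIND = {"d": "distance", "a": "angle", "t": "torsion"}

_ORGANIC_SMARTS = {"B", "C", "N", "O", "P", "S", "F", "I", "H"}


def parse_smarts(text: str, directives: Optional[Directives] = None) -> PatternGraph:
    """Parse a single (preprocessed) Jmol SMARTS clause into a PatternGraph.

    When ``directives`` is None the full lexical pipeline runs first and the
    text must reduce to one clause.
    """
    if directives is None:
        clauses, directives = preprocess_smarts(text)
        if len(clauses) != 1:
            raise SmilesError(
                "pattern expands to multiple '||' clauses; use the matcher")
        text = clauses[0]

    s = text.replace(">>", ".")
    pat = PatternGraph(source=text)
    prev: Optional[int] = None
    pending = None  # bond expr or None
    stack: list = []
    ring_open: dict[int, tuple[int, object, int]] = {}
    brace = False
    group_stack: list[int] = []
    last_atom: Optional[int] = None
    pending_dot: Optional[int] = None
    measured_since_atom: dict[int, bool] = {}
    measure_by_id: dict[tuple[str, int], MeasurementConstraint] = {}
    pending_default_measures: list[tuple[MeasurementConstraint, int]] = []

    def add_atom(expr, stereo=None) -> PatternAtom:
        a = PatternAtom(index=len(pat.atoms), expr=expr, brace_selected=brace,
                        group_id=group_stack[-1] if group_stack else None)
        if stereo is not None:
            a.stereo = StereoToken(a.index, stereo[0] or "TH", stereo[1], [])
        pat.atoms.append(a)
        return a

    def add_bond(a: int, b: int, expr) -> None:
        if expr is None:
            expr = Prim("default")
        pat.bonds.append(PatternBond(a, b, expr))
        pat.atoms[a].seq.append(b)
        pat.atoms[b].seq.append(a)

    i = 0
    while i < len(s):
        c = s[i]
        if c == "{":
            brace = True
            i += 1
            continue
        if c == "}":
            brace = False
            i += 1
            continue
        m = _MEASURE_OPEN.match(s, i)
        if m:
            if prev is None:
                raise SmilesError("measurement with no preceding atom")
            kind = _MEASURE_KIND[m.group(1)]
            mid = int(m.group(2)) if m.group(2) else None
            close = _balanced(s, i)
            body = s[m.end():close]
            i = close + 1
            measured_since_atom[prev] = True
            if mid is not None and not body:
                key = (kind, mid)
                if key not in measure_by_id:
                    raise SmilesError(
                        f"measurement id {mid} referenced before its ranges")
                measure_by_id[key].member_atoms.append(prev)
                continue
            negated = body.startswith("!")
            if negated:
                body = body[1:]
            ranges = _parse_ranges(body, kind)
            mc = MeasurementConstraint(kind, mid, ranges, negated, [prev])
            pat.measurements.append(mc)
            if mid is not None:
                measure_by_id[(kind, mid)] = mc
            else:
                pending_default_measures.append((mc, prev))
            continue
        if c == "(":
            if prev is None:
                gid = pat.n_groups
                pat.n_groups += 1
                group_stack.append(gid)
                stack.append(("group", None))
            else:
                stack.append(("branch", prev))
            i += 1
            continue
        if c == ")":
            if not stack:
                raise SmilesError(f"unbalanced ')' at {i}")
            kind_, saved = stack.pop()
            if kind_ == "group":
                group_stack.pop()
                prev = None
            else:
                prev = saved
            i += 1
            continue
        if c == ".":
            pending_dot = last_atom
            prev = None
            pending = None
            i += 1
            continue
        if s.startswith("$(", i):
            # unbracketed nested primitive (or select hook) as a whole atom
            close = _balanced(s, i + 1)
            inner = s[i + 2:close]
            if re.match(r"\s*select\b", inner):
                expr = Prim("select", inner)
            else:
                expr = Prim("nested", parse_smarts(inner, Directives()))
            atom = add_atom(expr)
            measured_since_atom[atom.index] = False
            if prev is not None:
                add_bond(prev, atom.index, pending)
            elif pending is not None:
                raise SmilesError("bond expression with no preceding atom")
            elif pending_dot is not None:
                pat.not_connected.append((pending_dot, atom.index))
                pending_dot = None
            pending = None
            prev = atom.index
            last_atom = atom.index
            i = close + 1
            continue
        if c in _BOND_START:
            if pending is not None:
                raise SmilesError(f"two bond expressions in a row at {i}")
            pending, i = _BondExprParser(s, i).parse()
            continue
        if c == "%" or c.isdigit():
            if prev is None:
                raise SmilesError(f"ring closure with no preceding atom at {i}")
            if measured_since_atom.get(prev):
                raise SmilesError(
                    "ring-closure digit must precede measurements "
                    "(atom-connections-measurements order)")
            if c == "%":
                if s.startswith("%(", i):
                    mm = re.match(r"%\((\d+)\)", s[i:])
                else:
                    mm = re.match(r"%(\d\d)", s[i:])
                if not mm:
                    raise SmilesError(f"malformed ring closure at {i}")
                num = int(mm.group(1))
                i += mm.end()
            else:
                num = int(c)
                i += 1
            if num in ring_open:
                a, expr_open, slot = ring_open.pop(num)
                use = pending if pending is not None else expr_open
                add_bond(prev, a, use)
                pat.atoms[a].seq[slot] = prev
                pat.atoms[prev].seq.pop()
                pat.atoms[prev].seq.append(a)
                pending = None
            else:
                ring_open[num] = (prev, pending, len(pat.atoms[prev].seq))
                pat.atoms[prev].seq.append(("ring", num))
                pending = None
            continue
        # atom token
        if c == "[":
            close = _find_bracket_end(s, i)
            inner = s[i + 1:close]
            expr = parse_atom_expr(inner)
            stereo = _extract_stereo(expr)
            atom = add_atom(expr, stereo)
            i = close + 1
        else:
            expr, i = _unbracketed_primitive(s, i)
            atom = add_atom(expr)
        measured_since_atom[atom.index] = False
        if prev is not None:
            add_bond(prev, atom.index, pending)
        elif pending is not None:
            raise SmilesError("bond expression with no preceding atom")
        elif pending_dot is not None:
            pat.not_connected.append((pending_dot, atom.index))
            pending_dot = None
        pending = None
        prev = atom.index
        last_atom = atom.index

    if stack:
        raise SmilesError("unbalanced '(' in SMARTS")
    if ring_open:
        raise SmilesError(f"unmatched ring closure number(s): {sorted(ring_open)}")
    if brace:
        raise SmilesError("unbalanced '{' in SMARTS")
    if pending is not None:
        raise SmilesError("dangling bond expression")

    # resolve default (unnumbered) measurement membership: the attached atom
    # plus the next N-1 atoms in lexical order
    for mc, anchor in pending_default_measures:
        need = MeasurementConstraint.ARITY[mc.kind]
        members = [anchor] + list(range(anchor + 1, anchor + need))
        if members[-1] >= len(pat.atoms):
            raise SmilesError(
                f"{mc.kind} measurement needs {need} atoms after position "
                f"{anchor}")
        mc.member_atoms = members
    for mc in pat.measurements:
        need = MeasurementConstraint.ARITY[mc.kind]
        if len(mc.member_atoms) != need:
            raise SmilesError(
                f"{mc.kind} measurement has {len(mc.member_atoms)} member "
                f"atoms, needs {need}")
    _resolve_pattern_stereo(pat)
    return pat


def _find_bracket_end(s: str, i: int) -> int:
    depth = 0
    j = i
    in_quote = False
    while j < len(s):
        c = s[j]
        if in_quote:
            if c == '"':
                in_quote = False
        elif c == '"':
            in_quote = True
        elif c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
        elif c == "]" and depth == 0 and j > i:
            return j
        j += 1
    raise SmilesError("unterminated bracket atom")


def _unbracketed_primitive(s: str, i: int):
    c = s[i]
    two = s[i:i + 2]
    if two in ("Cl", "Br"):
        return Prim("element", (ATOMIC_NUMBER[two], False)), i + 2
    if c == "*":
        return Prim("wildcard"), i + 1
    if c == "a":
        return Prim("any_aromatic"), i + 1
    if c == "A":
        return Prim("any_aliphatic"), i + 1
    if c in _ORGANIC_SMARTS:
        return Prim("element", (ATOMIC_NUMBER[c], False)), i + 1
    if c in "bcnops":
        return Prim("element", (ATOMIC_NUMBER[c.upper()], True)), i + 1
    raise SmilesError(f"unexpected character {c!r} at position {i}")


def _extract_stereo(expr):
    for p in _walk_prims(expr):
        if p.kind == "stereo":
            return p.value
    return None


def _parse_ranges(body: str, kind: str) -> list[tuple[float, float]]:
    # a "-" directly after a digit separates range bounds ("1.5-1.6");
    # after a comma or the colon it is a minus sign ("-170,-180")
    body = re.sub(r"(?<=[0-9.])-", " ", body)
    nums = re.findall(r"-?\d+(?:\.\d+)?", body)
    if not nums or len(nums) % 2 != 0:
        raise SmilesError(f"bad measurement range list {body!r}")
    vals = [float(x) for x in nums]
    ranges = []
    for k in range(0, len(vals), 2):
        lo, hi = sorted(vals[k:k + 2])
        if kind == "torsion" and (lo < -180 or hi > 180):
            raise SmilesError("torsion ranges must lie within [-180, 180]")
        if kind == "angle" and (lo < 0 or hi > 180):
            raise SmilesError("angle ranges must lie within [0, 180]")
        ranges.append((lo, hi))
    return ranges


def _resolve_pattern_stereo(pat: PatternGraph) -> None:
    for a in pat.atoms:
        if a.stereo is None:
            continue
        seq = [n for n in a.seq if not isinstance(n, tuple)]
        # an H-count primitive acts as the phantom hydrogen neighbor, placed
        # right after the preceding atom as in SMILES
        hcount = 0
        for p in _walk_prims(a.expr):
            if p.kind == "total_h":
                hcount = p.value or 0
                break
        if hcount and len(seq) < 4:
            pos = 1 if (seq and seq[0] < a.index) else 0
            seq = seq[:pos] + [PHANTOM_H] + seq[pos:]
        a.stereo.neighbor_sequence = seq
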