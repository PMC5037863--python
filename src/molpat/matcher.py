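"""Substructure (SMARTS) and full-structure (SMILES) matching.

The engine is a backtracking subgraph-isomorphism search.  Candidate atoms
are filtered by atom-expression evaluation (element, aromaticity, counts,
ring membership, PDB fields, nested patterns, hooks), bond expressions are
checked pairwise, and four classes of whole-mapping constraints run after a
complete assignment: fragment separation ("." means absolutely not
connected), component-level grouping, geometric measurement constraints,
and stereochemistry.

Results are de-duplicated by their selected-atom set, which is what makes
``CCCC`` against hexane report three matches rather than six
direction-reversed mappings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import perception
from .chem_graph import Molecule
from .smarts import (
    Expr,
    MeasurementConstraint,
    PatternAtom,
    PatternBond,
    PatternGraph,
    Prim,
    preprocess_smarts,
    parse_smarts,
)
from .smiles import (
    PHANTOM_H,
    PHANTOM_LONE_PAIR,
    CisTransUnit,
    Directives,
    StereoToken,
    parse_smiles,
)

logger = logging.getLogger("molpat")

SelectHook = Callable[[str, Molecule, int], bool]


@dataclass
class MatchResult:
    """One injective pattern-to-target mapping plus the selected subset."""

    mapping: dict[int, int]
    selected: frozenset[int]


class MatchError(ValueError):
    pass


# --------------------------------------------------------------------------
# evaluation context
# --------------------------------------------------------------------------


@dataclass
class _Ctx:
    mol: Molecule
    directives: Directives
    rings: perception.RingSet
    select_hook: Optional[SelectHook] = None


def _merge_directives(base: Optional[Directives], parsed: Directives) -> Directives:
    if base is None:
        return parsed
    out = base.copy()
    defaults = Directives()
    for f in parsed.__dataclass_fields__:
        pv = getattr(parsed, f)
        if pv != getattr(defaults, f):
            setattr(out, f, pv)
    return out


def prepare_target(mol: Molecule, directives: Directives,
                   ring_sizes: Sequence[int] = ()) -> perception.RingSet:
    """Run ring and aromaticity perception as the pattern requires."""
    rings = mol.ring_info
    cap = max([perception.DEFAULT_RING_CAP, *ring_sizes]) if ring_sizes \
        else perception.DEFAULT_RING_CAP
    if rings is None or rings.max_size_searched < cap:
        rings = perception.find_rings(mol, ring_sizes)
    if mol.aromaticity_model != directives.aromaticity_model:
        perception.perceive_aromaticity(mol, directives.aromaticity_model, rings)
    return rings


# --------------------------------------------------------------------------
# atom expression evaluation
# --------------------------------------------------------------------------


def _eval_atom_expr(node, ctx: _Ctx, idx: int) -> bool:
    if isinstance(node, Expr):
        if node.op == "not":
            return not _eval_atom_expr(node.children[0], ctx, idx)
        if node.op in ("and_high", "and_low"):
            return all(_eval_atom_expr(c, ctx, idx) for c in node.children)
        if node.op == "or":
            return any(_eval_atom_expr(c, ctx, idx) for c in node.children)
        raise MatchError(f"bad expression node {node.op}")
    return _eval_prim(node, ctx, idx)


def _eval_prim(p: Prim, ctx: _Ctx, idx: int) -> bool:
    mol = ctx.mol
    atom = mol.atoms[idx]
    kind = p.kind
    if kind == "wildcard":
        return not atom.is_dummy()
    if kind == "any_aromatic":
        return atom.aromatic
    if kind == "any_aliphatic":
        return not atom.aromatic and not atom.is_dummy()
    if kind == "element":
        z, want_aromatic = p.value
        if z == 0:
            return atom.is_dummy()
        return atom.atomic_number == z and atom.aromatic == want_aromatic
    if kind == "elemno":
        return atom.atomic_number == p.value
    if kind == "appnumber":
        return idx + 1 == p.value  # application atom number is 1-based
    if kind == "atomindex":
        return idx == p.value
    if kind == "isotope":
        return atom.isotope == p.value
    if kind == "isotope_or_unspec":
        if p.value == 0:
            return atom.isotope is None
        return atom.isotope is None or atom.isotope == p.value
    if kind == "charge":
        return atom.charge == p.value
    if kind == "atomclass":
        if ctx.directives.no_atom_class:
            return True
        return (atom.atom_class or 0) == p.value
    if kind in ("total_conn", "explicit_conn", "heavy_conn", "implicit_h",
                "total_h", "valence", "ring_conn"):
        c = mol.env_counts(idx)
        if kind == "ring_conn":
            return c.x >= 1 if p.value is None else c.x == p.value
        attr = {"total_conn": "X", "explicit_conn": "D", "heavy_conn": "d",
                "implicit_h": "h", "total_h": "H", "valence": "v"}[kind]
        return getattr(c, attr) == p.value
    if kind == "ringcount":
        rc = ctx.rings.ring_count(idx)
        return rc >= 1 if p.value is None else rc == p.value
    if kind == "ringsize":
        if p.value is None:
            return ctx.rings.in_any_ring(idx)
        return ctx.rings.in_ring_of_size(idx, p.value)
    if kind == "aromatic_ring_size":
        return ctx.rings.in_aromatic_ring_of_size(idx, p.value)
    if kind == "pdb":
        return _eval_pdb(p.value, atom)
    if kind == "atomtype":
        label = atom.atom_type if atom.atom_type is not None else atom.atom_name
        return label is not None and str(label) == p.value
    if kind == "nested":
        sub: PatternGraph = p.value
        return bool(_backtrack(sub, ctx, seed={0: idx}, all_matches=False))
    if kind == "select":
        if ctx.select_hook is None:
            raise MatchError(
                "[$(select ...)] requires a registered selection hook")
        return bool(ctx.select_hook(p.value, mol, idx))
    if kind == "stereo":
        return True  # checked after the mapping is complete
    if kind == "molatom":
        return _eval_molatom(p.value, ctx, idx)
    raise MatchError(f"unknown primitive {kind}")


def _eval_pdb(spec, atom) -> bool:
    if spec.res_name is not None and (atom.residue_name or "").upper() != spec.res_name:
        return False
    if spec.res_num is not None and atom.residue_number != spec.res_num:
        return False
    if spec.ins_code is not None and (atom.insertion_code or "").upper() != spec.ins_code:
        return False
    if spec.atom_name is not None and (atom.atom_name or "").upper() != spec.atom_name:
        return False
    if spec.atomic_num is not None and atom.atomic_number != spec.atomic_num:
        return False
    return True


# --------------------------------------------------------------------------
# bond expression evaluation
# --------------------------------------------------------------------------


def _eval_bond_expr(node, ctx: _Ctx, bond) -> bool:
    if isinstance(node, Expr):
        if node.op == "not":
            return not _eval_bond_expr(node.children[0], ctx, bond)
        if node.op in ("and_high", "and_low"):
            return all(_eval_bond_expr(c, ctx, bond) for c in node.children)
        if node.op == "or":
            return any(_eval_bond_expr(c, ctx, bond) for c in node.children)
    p = node
    kind = p.kind
    if kind == "default":
        # an unwritten bond matches any bond: only written bond symbols
        # constrain the order (this is what lets the published sulfur
        # typing rules see S=O through a default bond)
        return True
    if kind == "order":
        if p.value == 1:
            return bond.order == 1 and not bond.aromatic
        return bond.order == p.value
    if kind == "arom_bond":
        return bond.aromatic or bond.order is None
    if kind == "any_bond":
        return True
    if kind in ("updown", "atrop"):
        return bond.order == 1
    if kind == "molbond":
        return _eval_molbond(p.value, ctx, bond)
    raise MatchError(f"unknown bond primitive {kind}")


# --------------------------------------------------------------------------
# molecule-as-pattern (SMILES full-structure matching)
# --------------------------------------------------------------------------


@dataclass
class _MolAtomConstraint:
    atomic_number: int
    aromatic: bool
    total_h: int
    charge: int
    isotope: Optional[int]
    atom_class: int
    is_h_atom: bool = False


def _eval_molatom(c: _MolAtomConstraint, ctx: _Ctx, idx: int) -> bool:
    atom = ctx.mol.atoms[idx]
    if atom.atomic_number != c.atomic_number:
        return False
    if c.is_h_atom:
        return True
    model = ctx.directives.aromaticity_model
    if model != "none" and atom.aromatic != c.aromatic:
        return False
    if ctx.mol.total_h(idx) != c.total_h:
        return False
    if atom.charge != c.charge:
        return False
    if c.isotope is not None and atom.isotope != c.isotope:
        return False
    if not ctx.directives.no_atom_class and (atom.atom_class or 0) != c.atom_class:
        return False
    return True


@dataclass
class _MolBondConstraint:
    order: Optional[int]
    aromatic: bool
    written: bool = False


def _eval_molbond(c: _MolBondConstraint, ctx: _Ctx, bond) -> bool:
    model = ctx.directives.aromaticity_model
    if model == "none":
        # only explicitly written bond symbols must match exactly
        if not c.written or c.order is None or bond.order is None:
            return True
        return c.order == bond.order
    if c.aromatic != bond.aromatic:
        return False
    if c.aromatic:
        if ctx.directives.aromatic_double:
            if c.order is not None and bond.order is not None:
                return c.order == bond.order
        return True
    if c.order is None or bond.order is None:
        return True
    return c.order == bond.order


def pattern_from_molecule(molB: Molecule, directives: Directives,
                          include_h: bool = False) -> tuple[PatternGraph, list[int]]:
    """Convert a molecule into a pattern for full-structure matching.

    Heavy atoms become pattern atoms (hydrogens too with ``include_h``);
    explicit hydrogens otherwise fold into the total-H constraint of their
    neighbor.  Returns the pattern plus the source-atom index per pattern
    atom.
    """
    pat = PatternGraph(source="<molecule>")
    src: list[int] = []
    b_to_p: dict[int, int] = {}
    for a in molB.atoms:
        if a.is_h() and not include_h:
            heavy_nbrs = [n for n in molB.neighbors(a.index)
                          if not molB.atoms[n].is_h()]
            if heavy_nbrs:
                continue  # folded into the neighbor's H count
        constraint = _MolAtomConstraint(
            atomic_number=a.atomic_number,
            aromatic=a.aromatic,
            total_h=molB.total_h(a.index),
            charge=a.charge,
            isotope=a.isotope,
            atom_class=a.atom_class or 0,
            is_h_atom=a.is_h(),
        )
        pa = PatternAtom(index=len(pat.atoms), expr=Prim("molatom", constraint))
        pat.atoms.append(pa)
        b_to_p[a.index] = pa.index
        src.append(a.index)
    for b in molB.bonds:
        if b.a1 not in b_to_p or b.a2 not in b_to_p:
            continue
        pat.bonds.append(PatternBond(
            b_to_p[b.a1], b_to_p[b.a2],
            Prim("molbond",
                 _MolBondConstraint(b.order, b.aromatic, b.order_written))))
    # carry stereo in pattern-atom space
    pat.mol_stereo = []
    for tok in molB.stereo_centers:
        if tok.center not in b_to_p:
            continue
        seq = []
        ok = True
        for n in tok.neighbor_sequence:
            if isinstance(n, tuple):
                seq.append((n[0], b_to_p.get(n[1])))
            elif n in (PHANTOM_H, PHANTOM_LONE_PAIR):
                seq.append(n)
            elif n in b_to_p:
                seq.append(b_to_p[n])
            elif molB.atoms[n].is_h():
                seq.append(("H", b_to_p.get(tok.center)))
            else:
                ok = False
        if ok:
            pat.mol_stereo.append(
                StereoToken(b_to_p[tok.center], tok.shape, tok.order_index, seq))
    pat.mol_cistrans = []
    for u in molB.double_bond_marks:
        if all(x in b_to_p for x in (u.end1, u.end2, u.sub1, u.sub2)):
            pat.mol_cistrans.append(CisTransUnit(
                b_to_p[u.end1], b_to_p[u.end2],
                b_to_p[u.sub1], b_to_p[u.sub2], u.relation))
    return pat, src


# --------------------------------------------------------------------------
# the backtracking search
# --------------------------------------------------------------------------


def _search_order(pat: PatternGraph, seeded: bool) -> list[int]:
    n = len(pat.atoms)
    order: list[int] = []
    placed = set()
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for b in pat.bonds:
        adj[b.a1].append(b.a2)
        adj[b.a2].append(b.a1)
    starts = [0] if seeded else []
    remaining = [i for i in range(n)]
    while len(order) < n:
        if starts:
            s = starts.pop(0)
        else:
            s = next(i for i in remaining if i not in placed)
        if s in placed:
            continue
        stack = [s]
        while stack:
            cur = stack.pop()
            if cur in placed:
                continue
            placed.add(cur)
            order.append(cur)
            for nb in sorted(adj[cur], reverse=True):
                if nb not in placed:
                    stack.append(nb)
    return order


def _backtrack(pat: PatternGraph, ctx: _Ctx, seed: Optional[dict[int, int]] = None,
               all_matches: bool = True, dedupe: str = "selected",
               skip_post: bool = False) -> list[MatchResult]:
    n = len(pat.atoms)
    mol = ctx.mol
    order = _search_order(pat, seeded=bool(seed))
    mapping: dict[int, int] = {}
    used: set[int] = set()
    results: list[MatchResult] = []
    seen_keys: set = set()
    components = pat.components()
    first_only = ctx.directives.first_match_only or not all_matches

    if seed:
        for p, t in seed.items():
            if not _eval_atom_expr(pat.atoms[p].expr, ctx, t):
                return []
            mapping[p] = t
            used.add(t)

    pat_adj: dict[int, list[tuple[int, PatternBond]]] = {i: [] for i in range(n)}
    for b in pat.bonds:
        pat_adj[b.a1].append((b.a2, b))
        pat_adj[b.a2].append((b.a1, b))

    def candidates(p: int):
        anchored = [(q, b) for q, b in pat_adj[p] if q in mapping]
        if anchored:
            q, _ = anchored[0]
            return list(mol.neighbors(mapping[q]))
        return range(len(mol.atoms))

    def feasible(p: int, t: int) -> bool:
        if t in used:
            return False
        if not _eval_atom_expr(pat.atoms[p].expr, ctx, t):
            return False
        for q, b in pat_adj[p]:
            if q in mapping:
                tb = mol.bond_between(t, mapping[q])
                if tb is None or not _eval_bond_expr(b.expr, ctx, tb):
                    return False
        return True

    stop = [False]

    def record() -> None:
        if not skip_post and not _post_checks(pat, ctx, mapping, components):
            return
        if pat.has_braces():
            selected = frozenset(
                mapping[a.index] for a in pat.atoms if a.brace_selected)
        else:
            selected = frozenset(mapping.values())
        key = selected if dedupe == "selected" else tuple(sorted(mapping.items()))
        if key in seen_keys:
            return
        seen_keys.add(key)
        results.append(MatchResult(dict(mapping), selected))
        if first_only:
            stop[0] = True

    def extend(k: int) -> None:
        if stop[0]:
            return
        while k < n and order[k] in mapping:
            k += 1
        if k == n:
            record()
            return
        p = order[k]
        for t in candidates(p):
            if stop[0]:
                return
            if feasible(p, t):
                mapping[p] = t
                used.add(t)
                extend(k + 1)
                del mapping[p]
                used.discard(t)

    extend(0)
    return results


def _post_checks(pat: PatternGraph, ctx: _Ctx, mapping: dict[int, int],
                 components: list[int]) -> bool:
    mol = ctx.mol
    # "." is absolutely "not connected": the dot-adjacent atoms must not be
    # bonded in the target
    for u, v in getattr(pat, "not_connected", ()):
        if mol.bond_between(mapping[u], mapping[v]) is not None:
            return False
    # component-level grouping
    if pat.n_groups > 0:
        if mol.component_id is None or getattr(mol, "_component_mode", None) \
                != ctx.directives.group_mode:
            mol.assign_components(ctx.directives.group_mode)
            mol._component_mode = ctx.directives.group_mode
        comp_of_group: dict[int, int] = {}
        grouped_comps: dict[int, int] = {}
        for a in pat.atoms:
            if a.group_id is None:
                continue
            tcomp = mol.component_id[mapping[a.index]]
            if a.group_id in comp_of_group:
                if comp_of_group[a.group_id] != tcomp:
                    return False
            else:
                if tcomp in grouped_comps and grouped_comps[tcomp] != a.group_id:
                    return False
                comp_of_group[a.group_id] = tcomp
                grouped_comps[tcomp] = a.group_id
        # ungrouped atoms must live in a component occupied by some group
        if comp_of_group:
            occupied = set(comp_of_group.values())
            for a in pat.atoms:
                if a.group_id is None:
                    if mol.component_id[mapping[a.index]] not in occupied:
                        return False
    # measurements
    if pat.measurements:
        if not eval_measurements(mapping, pat.measurements, mol):
            return False
    # stereochemistry
    if not _check_stereo(pat, ctx, mapping):
        return False
    return True


# --------------------------------------------------------------------------
# measurements
# --------------------------------------------------------------------------


def eval_measurements(mapping: dict[int, int],
                      constraints: Sequence[MeasurementConstraint],
                      mol: Molecule) -> bool:
    """True iff every constraint's measured value lies in one of its ranges
    (complemented when negated)."""
    for mc in constraints:
        pts = []
        for p in mc.member_atoms:
            t = mapping[p]
            if mol.atoms[t].coords is None:
                raise MatchError(
                    "measurement constraint requires 3D coordinates")
            pts.append(mol.atoms[t].coords)
        if mc.kind == "distance":
            value = float(np.linalg.norm(pts[0] - pts[1]))
        elif mc.kind == "angle":
            value = perception.angle(*pts)
        else:
            value = perception.torsion(*pts)
        inside = any(lo <= value <= hi for lo, hi in mc.ranges)
        if mc.negated:
            inside = not inside
        if not inside:
            return False
    return True


# --------------------------------------------------------------------------
# stereochemistry checks (post-mapping)
# --------------------------------------------------------------------------


def _translate_entry(n, mapping, center_t):
    if isinstance(n, tuple):
        owner = mapping.get(n[1]) if isinstance(n[1], int) else None
        return (n[0], owner if owner is not None else center_t)
    if n == PHANTOM_H:
        return ("H", center_t)
    if n == PHANTOM_LONE_PAIR:
        return ("LP", center_t)
    return mapping[n]


def _phantom_position(mol: Molecule, kind: str, owner: int,
                      taken: set) -> Optional[np.ndarray]:
    from .chem_graph import ideal_tetrahedral_directions

    atom = mol.atoms[owner]
    if kind == "H":
        hs = [n for n in mol.neighbors(owner)
              if mol.atoms[n].is_h() and n not in taken]
        if len(hs) == 1 and mol.atoms[hs[0]].coords is not None:
            return mol.atoms[hs[0]].coords
        if len(hs) > 1:
            return None  # ambiguous
    if atom.coords is None:
        return None
    dirs = []
    for n in mol.neighbors(owner):
        if mol.atoms[n].coords is None:
            return None
        d = mol.atoms[n].coords - atom.coords
        dirs.append(d / np.linalg.norm(d))
    try:
        completion = ideal_tetrahedral_directions(dirs, 1)
    except ValueError:
        return None
    if not completion:
        return None
    return atom.coords + completion[0]


def _observed_parity_3d(mol: Molecule, entries) -> Optional[str]:
    taken = {e for e in entries if isinstance(e, int)}
    pts = []
    for e in entries:
        if isinstance(e, int):
            if mol.atoms[e].coords is None:
                return None
            pts.append(mol.atoms[e].coords)
        else:
            pos = _phantom_position(mol, e[0], e[1], taken)
            if pos is None:
                return None
            pts.append(pos)
    try:
        return perception.tetrahedral_parity(pts)
    except ValueError:
        return None


def _permutation_sign(a: list, b: list) -> Optional[int]:
    if len(a) != len(b) or set(map(repr, a)) != set(map(repr, b)):
        return None
    b = list(b)
    sign = 1
    for i in range(len(a)):
        if b[i] != a[i]:
            j = next(k for k in range(i + 1, len(b)) if b[k] == a[i])
            b[i], b[j] = b[j], b[i]
            sign = -sign
    return sign


def _check_stereo(pat: PatternGraph, ctx: _Ctx, mapping: dict[int, int]) -> bool:
    d = ctx.directives
    if d.no_stereo:
        return True
    mol = ctx.mol
    tokens: list[StereoToken] = list(getattr(pat, "mol_stereo", []))
    for a in pat.atoms:
        if a.stereo is not None and a.stereo.neighbor_sequence:
            tokens.append(a.stereo)
    for tok in tokens:
        if tok.parity is None:
            continue  # extended order indices: stored, not evaluated
        if tok.shape not in ("TH", "TP", "allenic"):
            continue
        want = tok.parity
        if d.invert_stereo and tok.shape in ("TH", "TP"):
            want = "@" if want == "@@" else "@@"
        center_t = mapping.get(tok.center)
        if center_t is None:
            continue
        entries = [_translate_entry(n, mapping, center_t)
                   for n in tok.neighbor_sequence]
        if len(entries) != 4:
            continue
        # written stereo on the target takes priority for graph-only input
        target_tok = mol.atoms[center_t].stereo if tok.shape != "allenic" else None
        if target_tok is None and tok.shape == "allenic":
            target_tok = mol.atoms[center_t].stereo
        if target_tok is not None and target_tok.parity is not None:
            t_entries = [_translate_entry(n, {i: i for i in range(len(mol.atoms))},
                                          center_t)
                         for n in target_tok.neighbor_sequence]
            sign = _permutation_sign(t_entries, entries)
            if sign is None:
                continue
            observed = target_tok.parity if sign > 0 else (
                "@" if target_tok.parity == "@@" else "@@")
            if observed != want:
                return False
            continue
        if mol.has_coords():
            observed = _observed_parity_3d(mol, entries)
            if observed is not None and observed != want:
                return False
    # cis/trans units
    units: list[CisTransUnit] = list(getattr(pat, "mol_cistrans", []))
    units.extend(_pattern_cistrans(pat))
    for u in units:
        e1, e2 = mapping.get(u.end1), mapping.get(u.end2)
        s1, s2 = mapping.get(u.sub1), mapping.get(u.sub2)
        if None in (e1, e2, s1, s2):
            continue
        observed = _target_cistrans(mol, e1, e2, s1, s2)
        if observed is not None and observed != u.relation:
            return False
    return True


def _target_cistrans(mol: Molecule, e1, e2, s1, s2) -> Optional[str]:
    if mol.has_coords():
        t = perception.torsion(mol.atoms[s1].coords, mol.atoms[e1].coords,
                               mol.atoms[e2].coords, mol.atoms[s2].coords)
        return "cis" if abs(t) < 90 else "trans"
    for u in mol.double_bond_marks:
        if {u.end1, u.end2} == {e1, e2}:
            rel = u.relation
            # re-reference onto the requested substituents
            if u.end1 == e2:
                u_s1, u_s2 = u.sub2, u.sub1
            else:
                u_s1, u_s2 = u.sub1, u.sub2
            if u_s1 != s1:
                rel = "cis" if rel == "trans" else "trans"
            if u_s2 != s2:
                rel = "cis" if rel == "trans" else "trans"
            return rel
    return None


def _pattern_cistrans(pat: PatternGraph) -> list[CisTransUnit]:
    units = []
    for b in pat.bonds:
        if not (isinstance(b.expr, Prim) and b.expr.kind == "order"
                and b.expr.value == 2):
            continue
        m1 = _pattern_marks(pat, b.a1, b.a2)
        m2 = _pattern_marks(pat, b.a2, b.a1)
        if not m1 or not m2:
            continue
        (s1, f1), (s2, f2) = m1[0], m2[0]
        units.append(CisTransUnit(b.a1, b.a2, s1, s2,
                                  "cis" if f1 == f2 else "trans"))
    return units


def _pattern_marks(pat: PatternGraph, end: int, other: int):
    out = []
    for b in pat.bonds:
        if other in (b.a1, b.a2) or end not in (b.a1, b.a2):
            continue
        prims = [p for p in _iter_prims(b.expr)]
        for p in prims:
            if p.kind == "updown":
                sigma = 1 if p.value == "/" else -1
                direction = 1 if b.a2 == end else -1
                sub = b.a1 if b.a2 == end else b.a2
                out.append((sub, sigma * direction))
    return out


def _iter_prims(node):
    if isinstance(node, Prim):
        yield node
    else:
        for c in node.children:
            yield from _iter_prims(c)


# --------------------------------------------------------------------------
# public entry points
# --------------------------------------------------------------------------


def smarts_match(pattern: Union[str, PatternGraph], mol: Molecule,
                 directives: Optional[Directives] = None,
                 all_matches: bool = True,
                 select_hook: Optional[SelectHook] = None) -> list[MatchResult]:
    """Match a Jmol SMARTS pattern against a molecule.

    ``pattern`` may be raw text (full preprocessing pipeline, ``||`` clauses
    unioned) or an already-parsed :class:`PatternGraph`.  Results are
    de-duplicated by selected-atom set; ``/firstMatchOnly/`` or
    ``all_matches=False`` stops at the first hit.
    """
    if isinstance(pattern, str):
        clauses, parsed_dir = preprocess_smarts(pattern)
        directives = _merge_directives(directives, parsed_dir)
        pats = [parse_smarts(c, directives) for c in clauses]
    else:
        pats = [pattern]
        directives = directives or Directives()

    sizes: list[int] = []
    for p in pats:
        sizes.extend(p.required_ring_sizes())
    rings = prepare_target(mol, directives, sizes)
    ctx = _Ctx(mol, directives, rings, select_hook)

    if any(p.measurements for p in pats) and not mol.has_coords():
        raise MatchError("pattern has measurement constraints but the "
                         "target has no 3D coordinates")

    results: list[MatchResult] = []
    seen: set[frozenset] = set()
    for p in pats:
        for r in _backtrack(p, ctx, all_matches=all_matches):
            if r.selected not in seen:
                seen.add(r.selected)
                results.append(r)
            if directives.first_match_only and results:
                return results[:1]
        if not all_matches and results:
            break
    return results


def selected_atoms(results: Sequence[MatchResult]) -> set[int]:
    out: set[int] = set()
    for r in results:
        out |= set(r.selected)
    return out


def _as_molecule(x: Union[str, Molecule],
                 directives: Optional[Directives]) -> tuple[Molecule, Directives]:
    if isinstance(x, Molecule):
        return x, directives if directives is not None else Directives()
    from .smiles import preprocess

    clean, parsed = preprocess(x)
    merged = _merge_directives(directives, parsed)
    return parse_smiles(clean, merged), merged


def smiles_match(A: Union[str, Molecule], B: Union[str, Molecule],
                 directives: Optional[Directives] = None,
                 return_mappings: bool = False, all_matches: bool = False,
                 include_h: bool = False):
    """Full-structure match: do the atoms and bonds of B map into A?

    ``A`` and ``B`` may each be a SMILES string or a molecule.  Directive
    blocks embedded in either string merge with ``directives`` (pattern-side
    wins).  The match requires every heavy atom of B to map injectively into
    A honoring element, charge, isotope (unspecified matches anything),
    total hydrogen count, aromaticity-reconciled bond orders, atom classes,
    and stereochemistry, as modulated by the directives.

    Returns a bool, or ``(bool, mappings)`` with ``return_mappings`` where
    each mapping is a list of ``[a_index, b_index]`` pairs.
    """
    molA, dirA = _as_molecule(A, directives)
    molB, directives = _as_molecule(B, dirA)

    rings = prepare_target(molA, directives)
    prepare_target(molB, directives)
    pat, src = pattern_from_molecule(molB, directives, include_h=include_h)
    ctx = _Ctx(molA, directives, rings)
    res = _backtrack(pat, ctx, all_matches=all_matches or return_mappings,
                     dedupe="mapping")
    if not return_mappings:
        return bool(res)
    mappings = [
        sorted([t, src[p]] for p, t in r.mapping.items())
        for r in res
    ]
    return bool(res), mappings


def conformer_classify(mol: Molecule,
                       motif_library: Optional[Sequence[tuple[str, str]]] = None,
                       directives: Optional[Directives] = None) -> str:
    """Return the label of the first conformational motif that matches.

    The default library carries the three 1,2-dimethylcyclohexane chair
    motifs plus generic anti/gauche/eclipsed torsion windows.
    """
    if not mol.has_coords():
        raise MatchError("conformer classification requires 3D coordinates")
    if motif_library is None:
        motif_library = DEFAULT_MOTIFS
    for label, pattern in motif_library:
        try:
            if smarts_match(pattern, mol, directives, all_matches=False):
                return label
        except MatchError:
            continue
    return "unclassified"


DEFAULT_MOTIFS: list[tuple[str, str]] = [
    ("cis-1,2",
     "[CH3](.t:-170,-180,170,180)C1CCC(.t:50,70,-50,-70)CC1[CH3]"),
    ("trans-1,2-diequatorial",
     "[CH3](.t:-170,-180,170,180)C1CCC(.t:-170,-180,170,180)CC1[CH3]"),
    # ring-qualified so the generic acyclic anti/gauche motifs below stay
    # reachable for plain chains
    ("trans-1,2-diaxial",
     "[CH3](.t:-170,-180,170,180)[C;R][C;R][CH3]"),
    ("anti", "*(.t:170,180,-170,-180)***"),
    ("gauche", "*(.t:50,70,-50,-70)***"),
    ("eclipsed", "*(.t:-20,20)***"),
]
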