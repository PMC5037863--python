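"""Ring finding, aromaticity models, and stereo perception from 3D coordinates.

Ring membership uses *all* simple cycles up to a size cap (default 8), not a
smallest-set-of-smallest-rings reduction.  The cap rises automatically when a
pattern asks about a larger ring, so for indole ``[R2]`` sees only the 5- and
6-membered rings (two fusion atoms in two rings each) while ``[R2&r9]`` also
sees the 9-membered envelope and the fusion atoms move to ring count 3.

Five aromaticity models are supported:

``open``
    Hueckel 4n+2 electron counting on each candidate ring; an exocyclic
    double bond is tolerated only when the terminal atom is not more
    electronegative than carbon.
``strict``
    ``open`` plus no exocyclic double bonds at all, plus 3D ring planarity
    when coordinates are available.
``planar``
    Geometry only: any candidate ring of sp2-plausible atoms whose atoms lie
    within tolerance of their least-squares plane.
``defined``
    Trust the aromatic flags declared by the input file or string.
``none``
    Clear all aromatic flags; ":" bonds become order-unspecified.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

from .chem_graph import ELECTRONEGATIVITY, Molecule

logger = logging.getLogger("molpat")

DEFAULT_RING_CAP = 8
PLANARITY_TOL = 0.1  # Angstrom

AROMATICITY_MODELS = ("open", "strict", "planar", "defined", "none")


# --------------------------------------------------------------------------
# rings
# --------------------------------------------------------------------------


@dataclass
class RingSet:
    """All simple cycles of a molecule up to ``max_size_searched``."""

    rings: list[tuple[int, ...]]
    max_size_searched: int
    _count: dict[int, int] = field(default_factory=dict)
    _sizes: dict[int, set] = field(default_factory=dict)
    aromatic_rings: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ring in self.rings:
            for a in ring:
                self._count[a] = self._count.get(a, 0) + 1
                self._sizes.setdefault(a, set()).add(len(ring))

    def ring_count(self, atom: int) -> int:
        """R<n>: number of enumerated cycles containing the atom."""
        return self._count.get(atom, 0)

    def in_ring_of_size(self, atom: int, n: int) -> bool:
        return n in self._sizes.get(atom, ())

    def in_any_ring(self, atom: int) -> bool:
        return atom in self._count

    def in_aromatic_ring_of_size(self, atom: int, n: int) -> bool:
        return any(atom in r and len(r) == n for r in self.aromatic_rings)

    def bond_in_ring(self, a1: int, a2: int) -> bool:
        for ring in self.rings:
            k = len(ring)
            for i in range(k):
                p, q = ring[i], ring[(i + 1) % k]
                if (p, q) == (a1, a2) or (q, p) == (a1, a2):
                    return True
        return False


def find_rings(mol: Molecule, required_sizes: Iterable[int] = ()) -> RingSet:
    """Enumerate all simple cycles up to ``max(8, max(required_sizes))``.

    The result is attached to ``mol.ring_info`` so that environment counts
    (``x``) and ring primitives can use it.
    """
    cap = DEFAULT_RING_CAP
    sizes = [s for s in required_sizes if s is not None]
    if sizes:
        cap = max(cap, max(sizes))
    g = nx.Graph()
    g.add_nodes_from(range(len(mol.atoms)))
    g.add_edges_from((b.a1, b.a2) for b in mol.bonds)
    rings: list[tuple[int, ...]] = []
    seen: set[frozenset] = set()
    for cyc in nx.simple_cycles(g, length_bound=cap):
        if len(cyc) < 3:
            continue
        key = frozenset(cyc)
        if key in seen:  # guard against duplicates up to rotation/reflection
            continue
        seen.add(key)
        rings.append(tuple(cyc))
    rs = RingSet(rings=rings, max_size_searched=cap)
    mol.ring_info = rs
    return rs


# --------------------------------------------------------------------------
# planarity
# --------------------------------------------------------------------------


def planarity(coords: np.ndarray, tol: float = PLANARITY_TOL) -> bool:
    """True iff points lie within ``tol`` of their least-squares plane.

    Degenerate (collinear) rings are reported as non-planar.
    """
    pts = np.asarray(coords, dtype=float)
    centered = pts - pts.mean(axis=0)
    # smallest singular direction is the plane normal
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-6:  # collinear
        return False
    normal = vt[2]
    dev = np.abs(centered @ normal)
    return bool(dev.max() <= tol)


def ring_is_planar(mol: Molecule, ring: Sequence[int], tol: float = PLANARITY_TOL) -> bool:
    if any(mol.atoms[a].coords is None for a in ring):
        raise ValueError("planarity check requires coordinates for all ring atoms")
    return planarity(mol.coords_array(ring), tol)


# --------------------------------------------------------------------------
# Hueckel electron counting
# --------------------------------------------------------------------------

_RING_FAIL = -1


def _pi_contribution(mol: Molecule, atom: int, ring: Sequence[int], model: str) -> int:
    """Pi-electron contribution of one ring atom, or ``_RING_FAIL``.

    Contribution table: 1 per atom carrying an endocyclic double (or
    declared-aromatic) bond; 2 for a neutral heteroatom donating a lone
    pair; 0 for a ring carbocation; an exocyclic double bond contributes 1
    under ``open`` when the terminal atom is not more electronegative than
    carbon, and disqualifies the ring otherwise (always under ``strict``).
    """
    a = mol.atoms[atom]
    ring_set = set(ring)
    endo_double = endo_aromatic = False
    exo_double_to = None
    has_double = False
    for n in mol.neighbors(atom):
        b = mol.bond_between(atom, n)
        order = b.order
        if n in ring_set:
            if order == 2:
                endo_double = True
            if b.aromatic or order is None:
                endo_aromatic = True
        elif order is not None and order >= 2:
            exo_double_to = n
        if order is not None and order >= 2:
            has_double = True
    if endo_double:
        return 1
    if exo_double_to is not None:
        if model == "strict":
            return _RING_FAIL
        chi = ELECTRONEGATIVITY.get(mol.atoms[exo_double_to].atomic_number, 2.0)
        if chi > ELECTRONEGATIVITY[6]:
            return _RING_FAIL
        return 1
    if endo_aromatic:
        # declared-aromatic ring bond without a Kekule order: infer the
        # contribution from element and substitution
        z = a.atomic_number
        counts = mol.env_counts(atom)
        if z == 6:
            return 2 if a.charge < 0 else (0 if a.charge > 0 else 1)
        if z in (7, 15, 33):
            # pyrrole-type (three sigma connections) donates the lone pair
            return 2 if counts.X >= 3 else 1
        if z in (8, 16, 34):
            return 2
        if z == 5:
            return 0
        return 1
    # no multiple bond at all
    if has_double:
        return _RING_FAIL
    z = a.atomic_number
    if z == 6:
        if a.charge > 0:
            return 0
        if a.charge < 0:
            return 2
        return _RING_FAIL  # saturated ring carbon
    if z in (7, 8, 15, 16, 33, 34) and a.charge == 0:
        return 2
    if z == 5:
        return 0
    return _RING_FAIL


def huckel_count(ring: Sequence[int], mol: Molecule, model: str = "open") -> Optional[int]:
    """Total pi-electron count of a ring, or ``None`` if any atom disqualifies it."""
    total = 0
    for atom in ring:
        c = _pi_contribution(mol, atom, ring, model)
        if c == _RING_FAIL:
            return None
        total += c
    return total


def _sp2_plausible(mol: Molecule, atom: int) -> bool:
    c = mol.env_counts(atom)
    return c.X <= 3


# --------------------------------------------------------------------------
# aromaticity models
# --------------------------------------------------------------------------


def perceive_aromaticity(
    mol: Molecule,
    model: str = "open",
    ring_set: Optional[RingSet] = None,
    tol: float = PLANARITY_TOL,
) -> None:
    """Set per-atom and per-bond aromatic flags under the chosen model.

    String- or file-declared aromaticity (lowercase atoms, molfile bond
    types 4/6/7) is honored as-is under every model except ``none``; the
    electron-counting and planarity rules decide the fate of rings written
    in Kekule form or read from plain 3D coordinates.
    """
    if model not in AROMATICITY_MODELS:
        raise ValueError(f"unknown aromaticity model {model!r}")
    mol.aromaticity_model = model

    if model == "none":
        for a in mol.atoms:
            a.aromatic = False
        for b in mol.bonds:
            b.aromatic = False
            # ":" bonds become plain order-unspecified
        if mol.ring_info is not None:
            mol.ring_info.aromatic_rings = []
        return

    if ring_set is None:
        ring_set = mol.ring_info if mol.ring_info is not None else find_rings(mol)

    declared_bonds = {
        (min(b.a1, b.a2), max(b.a1, b.a2)) for b in mol.bonds if b.aromatic
    }

    if model == "defined":
        # keep flags exactly as declared; just record the aromatic rings
        ring_set.aromatic_rings = [
            r for r in ring_set.rings
            if all(mol.atoms[a].aromatic for a in r)
        ]
        return

    aromatic_atoms: set[int] = set()
    aromatic_rings: list[tuple[int, ...]] = []

    need_coords = model in ("strict", "planar")
    if need_coords and not mol.has_coords():
        if model == "planar":
            raise ValueError("planar aromaticity model requires 3D coordinates")
        logger.warning(
            "strict aromaticity requested without 3D coordinates; "
            "falling back to electron counting only"
        )

    for ring in ring_set.rings:
        if len(ring) > 8:
            continue  # envelope cycles of fused systems are not candidates
        ring_declared = all(
            (min(ring[i], ring[(i + 1) % len(ring)]),
             max(ring[i], ring[(i + 1) % len(ring)])) in declared_bonds
            for i in range(len(ring))
        ) and len(declared_bonds) > 0

        if model == "planar":
            if not all(_sp2_plausible(mol, a) for a in ring):
                continue
            if ring_is_planar(mol, ring, tol):
                aromatic_rings.append(ring)
                aromatic_atoms.update(ring)
            continue

        if ring_declared:
            aromatic_rings.append(ring)
            aromatic_atoms.update(ring)
            continue

        count = huckel_count(ring, mol, model)
        if count is None or count % 4 != 2:
            continue
        if model == "strict" and mol.has_coords() and not ring_is_planar(mol, ring, tol):
            continue
        aromatic_rings.append(ring)
        aromatic_atoms.update(ring)

    for a in mol.atoms:
        a.aromatic = a.index in aromatic_atoms
    for b in mol.bonds:
        b.aromatic = any(_ring_has_edge(r, b.a1, b.a2) for r in aromatic_rings)
    ring_set.aromatic_rings = aromatic_rings


def _ring_has_edge(ring: Sequence[int], a1: int, a2: int) -> bool:
    k = len(ring)
    for i in range(k):
        p, q = ring[i], ring[(i + 1) % k]
        if (p, q) == (a1, a2) or (q, p) == (a1, a2):
            return True
    return False


# --------------------------------------------------------------------------
# geometric stereo perception
# --------------------------------------------------------------------------


def signed_volume(p0, p1, p2, p3) -> float:
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    return float(np.linalg.det(np.stack([p1 - p0, p2 - p0, p3 - p0])))


def torsion(p0, p1, p2, p3) -> float:
    """Dihedral angle in degrees, IUPAC sign convention, range (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = math.degrees(math.atan2(np.dot(m, n2), np.dot(n1, n2)))
    return ang


def angle(p0, p1, p2) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    v1, v2 = p0 - p1, p2 - p1
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


@dataclass
class StereoDescriptor:
    center: tuple[int, ...]
    shape: str  # TH, TP, allenic, cistrans, atrop, ...
    parity: str  # "@" or "@@" (or "cis"/"trans" for double bonds)
    source: str = "from_3d"


def tetrahedral_parity(positions: Sequence[np.ndarray]) -> str:
    """Parity of four neighbor positions taken in sequence order.

    ``@`` means: looking from the first neighbor toward the center, the
    remaining three appear anticlockwise in listed order.  This maps onto
    the sign of the signed volume of the four points (negative = ``@``).
    """
    if len(positions) != 4:
        raise ValueError("tetrahedral parity needs exactly 4 positions")
    v = signed_volume(*positions)
    if abs(v) < 1e-9:
        raise ValueError("degenerate (coplanar) neighbor geometry")
    return "@" if v < 0 else "@@"


def parity_sign(parity: str) -> int:
    return -1 if parity == "@" else 1


def lone_pair_position(mol: Molecule, center: int) -> np.ndarray:
    """Phantom position opposing the mean of the existing bond directions."""
    c = mol.atoms[center].coords
    dirs = []
    for n in mol.neighbors(center):
        d = mol.atoms[n].coords - c
        dirs.append(d / np.linalg.norm(d))
    s = np.sum(dirs, axis=0)
    if np.linalg.norm(s) < 1e-8:
        raise ValueError("cannot place lone-pair phantom: symmetric environment")
    return c - s / np.linalg.norm(s)


def stereo_from_3d(mol: Molecule, center: int, shape: str,
                   neighbor_sequence: Sequence[int]) -> StereoDescriptor:
    """Perceive a stereo descriptor for one center from 3D coordinates.

    ``neighbor_sequence`` lists neighbor atom indices in the order of
    interest; ``-1`` entries stand for a lone-pair phantom (trigonal
    pyramid) and are replaced by a computed phantom position.
    """
    if not mol.has_coords():
        raise ValueError("stereo perception requires coordinates")
    if shape in ("TH", "TP"):
        pos = []
        for n in neighbor_sequence:
            pos.append(lone_pair_position(mol, center) if n < 0
                       else mol.atoms[n].coords)
        if len(pos) != 4:
            raise ValueError(f"{shape} needs 4 sequence entries, got {len(pos)}")
        return StereoDescriptor((center,), shape, tetrahedral_parity(pos))
    if shape == "cistrans":
        a, j, k, d = neighbor_sequence
        t = torsion(mol.atoms[a].coords, mol.atoms[j].coords,
                    mol.atoms[k].coords, mol.atoms[d].coords)
        return StereoDescriptor((j, k), shape, "cis" if abs(t) < 90 else "trans")
    if shape in ("allenic", "atrop"):
        a, j, k, d = neighbor_sequence
        t = torsion(mol.atoms[a].coords, mol.atoms[j].coords,
                    mol.atoms[k].coords, mol.atoms[d].coords)
        return StereoDescriptor((j, k), shape, "@@" if t > 0 else "@")
    raise ValueError(f"unsupported stereo shape {shape!r}")
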