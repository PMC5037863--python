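"""Core molecular graph model.

A :class:`Molecule` is an ordered list of :class:`Atom` records plus a list
of :class:`Bond` records and a derived adjacency table.  Hydrogens may be
present as explicit atoms, as per-atom implicit counts, or as a mixture;
every environment query (``d``, ``h``, ``H`` ...) is defined so that the
answer is the same before and after hydrogens are made explicit.

Atom indices are 0-based everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("molpat")

# --------------------------------------------------------------------------
# element data
# --------------------------------------------------------------------------

_SYMBOLS = (
    "H He "
    "Li Be B C N O F Ne "
    "Na Mg Al Si P S Cl Ar "
    "K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr "
    "Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe "
    "Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu "
    "Hf Ta W Re Os Ir Pt Au Hg Tl Pb Bi Po At Rn "
    "Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr"
).split()

#: symbol -> atomic number.  "Xx" is the dummy atom (atomic number 0).
ATOMIC_NUMBER: dict[str, int] = {s: i + 1 for i, s in enumerate(_SYMBOLS)}
ATOMIC_NUMBER["Xx"] = 0

#: atomic number -> symbol
SYMBOL: dict[int, str] = {v: k for k, v in ATOMIC_NUMBER.items()}

# Single-bond covalent radii (Angstrom), Pyykko-style values for the
# elements that actually occur in small-molecule and PDB test data.
COVALENT_RADIUS: dict[int, float] = {
    1: 0.32, 2: 0.46,
    3: 1.33, 4: 1.02, 5: 0.85, 6: 0.75, 7: 0.71, 8: 0.63, 9: 0.64, 10: 0.67,
    11: 1.55, 12: 1.39, 13: 1.26, 14: 1.16, 15: 1.11, 16: 1.03, 17: 0.99,
    18: 0.96, 19: 1.96, 20: 1.71, 25: 1.19, 26: 1.16, 27: 1.11, 28: 1.10,
    29: 1.12, 30: 1.18, 33: 1.21, 34: 1.16, 35: 1.14, 53: 1.33,
}
_DEFAULT_RADIUS = 1.4

# Pauling electronegativities for the exocyclic-substituent test of the
# open aromaticity model ("not more electronegative than carbon").
ELECTRONEGATIVITY: dict[int, float] = {
    1: 2.20, 5: 2.04, 6: 2.55, 7: 3.04, 8: 3.44, 9: 3.98,
    14: 1.90, 15: 2.19, 16: 2.58, 17: 3.16, 33: 2.18, 34: 2.55,
    35: 2.96, 53: 2.66,
}

# Nominal (most-abundant-isotope) integer masses, for the exact molecular
# weight gate of isomer classification.
NOMINAL_MASS: dict[int, int] = {
    0: 0, 1: 1, 2: 4, 3: 7, 4: 9, 5: 11, 6: 12, 7: 14, 8: 16, 9: 19,
    10: 20, 11: 23, 12: 24, 13: 27, 14: 28, 15: 31, 16: 32, 17: 35,
    18: 40, 19: 39, 20: 40, 25: 55, 26: 56, 27: 59, 28: 58, 29: 63,
    30: 64, 33: 75, 34: 80, 35: 79, 50: 120, 53: 127,
}

#: normal valences used for implicit-hydrogen filling (smallest first)
DEFAULT_VALENCES: dict[int, tuple[int, ...]] = {
    5: (3,), 6: (4,), 7: (3, 5), 8: (2,), 9: (1,),
    15: (3, 5), 16: (2, 4, 6), 17: (1,), 35: (1,), 53: (1,), 1: (1,),
}


def nominal_mass(atomic_number: int, isotope: Optional[int] = None) -> int:
    if isotope:
        return isotope
    try:
        return NOMINAL_MASS[atomic_number]
    except KeyError:
        # crude A ~ 2.07 Z fallback for exotic elements; only the *equality*
        # of sums matters for the isomer gate, not the absolute value
        return int(round(2.07 * atomic_number))


# --------------------------------------------------------------------------
# atoms and bonds
# --------------------------------------------------------------------------


@dataclass
class Atom:
    """One atom of a molecular graph.

    ``implicit_h`` counts hydrogens that are not explicit atoms.  The PDB
    metadata fields are stored uppercased and matched lexically.
    """

    index: int
    element: str = "C"
    atomic_number: int = 6
    isotope: Optional[int] = None
    charge: int = 0
    implicit_h: int = 0
    aromatic: bool = False
    atom_class: Optional[int] = None
    coords: Optional[np.ndarray] = None
    atom_name: Optional[str] = None
    residue_name: Optional[str] = None
    residue_number: Optional[int] = None
    insertion_code: Optional[str] = None
    atom_type: Optional[str] = None
    # stereo token recorded at parse time (see smiles.StereoToken)
    stereo: Optional[object] = None

    def is_h(self) -> bool:
        return self.atomic_number == 1

    def is_dummy(self) -> bool:
        return self.atomic_number == 0


@dataclass
class Bond:
    """Bond between two atom indices.

    ``order`` is 1, 2, 3 or 4; ``None`` means aromatic-unspecified (written
    ":" or declared by a file as type 4).  ``aromatic`` is the perceived or
    file-declared flag; it can be true on a bond that also carries an
    explicit Kekule order.  Aromatic-unspecified bonds contribute 1 to
    valence.
    """

    a1: int
    a2: int
    order: Optional[int] = 1
    aromatic: bool = False
    stereo_mark: Optional[str] = None  # "/", "\\", "^nm", "^^nm"
    atrop_digits: Optional[tuple[int, int]] = None
    order_written: bool = False  # an explicit bond symbol appeared

    def other(self, idx: int) -> int:
        return self.a2 if idx == self.a1 else self.a1

    def valence_order(self) -> int:
        return 1 if self.order is None else self.order


@dataclass
class EnvCounts:
    """Per-atom environment counts used by pattern primitives."""

    X: int  # total connections incl. implicit H
    d: int  # non-hydrogen connections
    D: int  # explicit connections
    h: int  # implicit hydrogens
    H: int  # total hydrogen count (implicit + attached explicit H)
    v: int  # total bond order (valence) incl. implicit H
    x: int = 0  # bonds terminating on ring atoms (needs ring perception)


class Molecule:
    """Atom/bond graph with optional 3D coordinates."""

    def __init__(self) -> None:
        self.atoms: list[Atom] = []
        self.bonds: list[Bond] = []
        self._adj: dict[int, list[int]] = {}
        self._bond_map: dict[tuple[int, int], Bond] = {}
        self.model_id: Optional[int] = None
        self.component_id: Optional[list[int]] = None
        # perception results, populated lazily by the perception module
        self.ring_info = None
        self.aromaticity_model: Optional[str] = None
        # stereo descriptors collected at parse time
        self.stereo_centers: list = []
        self.double_bond_marks: list = []

    # -- construction -----------------------------------------------------

    def add_atom(self, atom: Atom) -> Atom:
        atom.index = len(self.atoms)
        self.atoms.append(atom)
        self._adj[atom.index] = []
        return atom

    def new_atom(self, element: str = "C", **kw) -> Atom:
        z = ATOMIC_NUMBER.get(element)
        if z is None:
            raise ValueError(f"unknown element symbol {element!r}")
        return self.add_atom(Atom(index=-1, element=element, atomic_number=z, **kw))

    def add_bond(self, a1: int, a2: int, order: Optional[int] = 1,
                 aromatic: bool = False, **kw) -> Bond:
        if a1 == a2:
            raise ValueError("self-bond")
        key = (min(a1, a2), max(a1, a2))
        if key in self._bond_map:
            raise ValueError(f"duplicate bond {key}")
        bond = Bond(a1, a2, order=order, aromatic=aromatic, **kw)
        self.bonds.append(bond)
        self._bond_map[key] = bond
        self._adj[a1].append(a2)
        self._adj[a2].append(a1)
        return bond

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def neighbors(self, idx: int) -> list[int]:
        return self._adj[idx]

    def bond_between(self, a1: int, a2: int) -> Optional[Bond]:
        return self._bond_map.get((min(a1, a2), max(a1, a2)))

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_h()]

    def total_h(self, idx: int) -> int:
        a = self.atoms[idx]
        return a.implicit_h + sum(1 for n in self._adj[idx] if self.atoms[n].is_h())

    def atom_count_with_implicit_h(self) -> int:
        """Explicit atoms plus all implicit hydrogen counts."""
        return len(self.atoms) + sum(a.implicit_h for a in self.atoms)

    def env_counts(self, idx: int) -> EnvCounts:
        if not 0 <= idx < len(self.atoms):
            raise IndexError(f"atom index {idx} out of range")
        a = self.atoms[idx]
        nbrs = self._adj[idx]
        D = len(nbrs)
        h = a.implicit_h
        d = sum(1 for n in nbrs if not self.atoms[n].is_h())
        H = h + (D - d)
        v = h + sum(self.bond_between(idx, n).valence_order() for n in nbrs)
        x = 0
        if self.ring_info is not None:
            x = sum(1 for n in nbrs if self.ring_info.ring_count(n) > 0)
        return EnvCounts(X=D + h, d=d, D=D, h=h, H=H, v=v, x=x)

    def nominal_mass(self) -> int:
        total = 0
        for a in self.atoms:
            total += nominal_mass(a.atomic_number, a.isotope)
            total += a.implicit_h  # each implicit H is mass 1
        return total

    def has_coords(self) -> bool:
        return bool(self.atoms) and all(a.coords is not None for a in self.atoms)

    def coords_array(self, indices: Optional[Sequence[int]] = None) -> np.ndarray:
        idx = range(len(self.atoms)) if indices is None else indices
        return np.array([self.atoms[i].coords for i in idx], dtype=float)

    # -- components -------------------------------------------------------

    def assign_components(self, mode: str = "by_molecule") -> list[int]:
        """Label each atom with a component id.

        ``by_molecule`` labels connected components of the covalent graph;
        ``by_model`` gives one label per model (all atoms of a molecule
        object share a model unless ``model_id`` says otherwise).
        """
        if mode == "by_model":
            labels = [self.model_id or 0] * len(self.atoms)
        elif mode == "by_molecule":
            labels = [-1] * len(self.atoms)
            comp = 0
            for start in range(len(self.atoms)):
                if labels[start] != -1:
                    continue
                stack = [start]
                labels[start] = comp
                while stack:
                    cur = stack.pop()
                    for n in self._adj[cur]:
                        if labels[n] == -1:
                            labels[n] = comp
                            stack.append(n)
                comp += 1
        else:
            raise ValueError(f"unknown component mode {mode!r}")
        self.component_id = labels
        return labels

    # -- transforms -------------------------------------------------------

    def copy(self) -> "Molecule":
        import copy as _copy

        m = Molecule()
        for a in self.atoms:
            na = _copy.copy(a)
            if a.coords is not None:
                na.coords = np.array(a.coords, dtype=float)
            m.atoms.append(na)
            m._adj[na.index] = []
        for b in self.bonds:
            m.add_bond(b.a1, b.a2, order=b.order, aromatic=b.aromatic,
                       stereo_mark=b.stereo_mark, atrop_digits=b.atrop_digits,
                       order_written=b.order_written)
        m.model_id = self.model_id
        m.stereo_centers = list(self.stereo_centers)
        m.double_bond_marks = list(self.double_bond_marks)
        return m

    def make_explicit_h(self) -> "Molecule":
        """Return a copy in which every implicit hydrogen is an explicit atom.

        When the parent atom has coordinates the hydrogens are placed at
        idealized tetrahedral positions (1.09 A); otherwise they are added
        without coordinates.
        """
        m = self.copy()
        n0 = len(m.atoms)
        for idx in range(n0):
            a = m.atoms[idx]
            nh = a.implicit_h
            if nh == 0:
                continue
            positions = [None] * nh
            if a.coords is not None and all(
                m.atoms[n].coords is not None for n in m.neighbors(idx)
            ):
                dirs = [
                    _unit(m.atoms[n].coords - a.coords) for n in m.neighbors(idx)
                ]
                hdirs = ideal_tetrahedral_directions(dirs, nh)
                positions = [a.coords + 1.09 * d for d in hdirs]
            for k in range(nh):
                h = m.new_atom("H", implicit_h=0)
                if positions[k] is not None:
                    h.coords = positions[k]
                m.add_bond(idx, h.index, order=1)
            a.implicit_h = 0
        return m


# --------------------------------------------------------------------------
# small geometry helpers shared by fixtures and make_explicit_h
# --------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def ideal_tetrahedral_directions(existing: list[np.ndarray], needed: int) -> list[np.ndarray]:
    """Unit vectors completing an approximately tetrahedral arrangement.

    ``existing`` are unit vectors of bonds already present (0-3 of them).
    """
    cos_t = -1.0 / 3.0  # cos(109.47 deg)
    if len(existing) == 0:
        base = [
            np.array([1.0, 1.0, 1.0]), np.array([1.0, -1.0, -1.0]),
            np.array([-1.0, 1.0, -1.0]), np.array([-1.0, -1.0, 1.0]),
        ]
        return [_unit(b) for b in base[:needed]]
    if len(existing) == 1:
        a = existing[0]
        # arbitrary perpendicular
        p = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(p) < 1e-6:
            p = np.cross(a, [0.0, 1.0, 0.0])
        p = _unit(p)
        q = _unit(np.cross(a, p))
        out = []
        for k in range(3):
            ang = 2.0 * np.pi * k / 3.0
            d = cos_t * a + np.sqrt(1 - cos_t**2) * (np.cos(ang) * p + np.sin(ang) * q)
            out.append(_unit(d))
        return out[:needed]
    if len(existing) == 2:
        a, b = existing
        s = a + b
        mu2 = 1.0 - np.dot(s, s) / 4.0
        mu = np.sqrt(max(mu2, 0.0))
        w = np.cross(a, b)
        if np.linalg.norm(w) < 1e-8:  # collinear: fall back to perpendicular pair
            return ideal_tetrahedral_directions([a], needed)
        w = _unit(w)
        c = -s / 2.0 + mu * w
        d = -s / 2.0 - mu * w
        return [_unit(c), _unit(d)][:needed]
    # three existing bonds: the remaining direction opposes their sum
    s = sum(existing)
    if np.linalg.norm(s) < 1e-8:
        s = np.cross(existing[0], existing[1])
    return [_unit(-s)][:needed]


def assign_components(mol: Molecule, mode: str = "by_molecule") -> list[int]:
    """Module-level convenience wrapper for :meth:`Molecule.assign_components`."""
    return mol.assign_components(mode)
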