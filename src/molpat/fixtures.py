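"""Synthetic molecule and geometry generators.

Every test runs without downloads: idealized planar rings (benzene,
quinone, cyclobutadiene), sp3 zig-zag chains with settable backbone
torsions, cyclohexane chairs/boats with axial or equatorial substituents,
and graph-only molecules straight from SMILES.  Geometry families are
intentionally minimal - there is no general 3D embedding from SMILES, just
the templates the 3D features need.

Bond lengths default to textbook values: 1.54 A sp3 C-C, 1.40 A aromatic
C-C, 1.22 A C=O, 109.47 deg tetrahedral angles.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq, fsolve

from .chem_graph import (
    DEFAULT_VALENCES,
    Molecule,
    _unit,
    ideal_tetrahedral_directions,
)
from .perception import torsion
from .smiles import parse_smiles


def mol_from_smiles(text: str) -> Molecule:
    """Graph-only molecule (no coordinates) from a SMILES string."""
    return parse_smiles(text)


def _fill_valence_h(mol: Molecule) -> None:
    """Set implicit H so every C/N/O reaches its default valence."""
    for a in mol.atoms:
        valences = DEFAULT_VALENCES.get(a.atomic_number)
        if not valences:
            continue
        bond_sum = sum(mol.bond_between(a.index, n).valence_order()
                       for n in mol.neighbors(a.index))
        for v in valences:
            if v >= bond_sum:
                a.implicit_h = v - bond_sum
                break
        else:
            a.implicit_h = 0


# --------------------------------------------------------------------------
# planar rings
# --------------------------------------------------------------------------


def planar_ring(
    n: int,
    bond_length: float = 1.40,
    elements: Optional[Sequence[str]] = None,
    ring_orders: Optional[Sequence[int]] = None,
    aromatic: bool = False,
    substituents: Optional[dict[int, tuple[str, float, int]]] = None,
) -> Molecule:
    """Regular n-gon in the z=0 plane.

    ``ring_orders[i]`` is the order of the bond from atom i to i+1 (default
    all single); ``aromatic`` declares ring atoms/bonds aromatic instead.
    ``substituents`` maps ring position to ``(element, bond_length, order)``,
    placed in-plane along the exterior bisector.
    """
    if n < 3:
        raise ValueError("ring size must be >= 3")
    mol = Molecule()
    radius = bond_length / (2.0 * math.sin(math.pi / n))
    for i in range(n):
        ang = 2.0 * math.pi * i / n
        el = elements[i] if elements else "C"
        mol.new_atom(el, coords=np.array(
            [radius * math.cos(ang), radius * math.sin(ang), 0.0]),
            aromatic=aromatic)
    for i in range(n):
        order = ring_orders[i] if ring_orders else (None if aromatic else 1)
        mol.add_bond(i, (i + 1) % n, order=order, aromatic=aromatic)
    if substituents:
        for pos, (el, length, order) in substituents.items():
            direction = _unit(mol.atoms[pos].coords)  # exterior bisector
            s = mol.new_atom(el, coords=mol.atoms[pos].coords + length * direction)
            mol.add_bond(pos, s.index, order=order)
    _fill_valence_h(mol)
    return mol


def benzene(kekule: bool = True) -> Molecule:
    if kekule:
        return planar_ring(6, ring_orders=[2, 1, 2, 1, 2, 1])
    return planar_ring(6, aromatic=True)


def quinone() -> Molecule:
    """para-benzoquinone: Kekule ring with two exocyclic C=O, fully planar."""
    return planar_ring(
        6, bond_length=1.45, ring_orders=[1, 2, 1, 1, 2, 1],
        substituents={0: ("O", 1.22, 2), 3: ("O", 1.22, 2)})


def cyclobutadiene() -> Molecule:
    return planar_ring(4, bond_length=1.45, ring_orders=[2, 1, 2, 1])


# --------------------------------------------------------------------------
# chains
# --------------------------------------------------------------------------


def _nerf(A, B, C, length: float, ang_deg: float, tor_deg: float) -> np.ndarray:
    """Place atom D given A-B-C with |CD|, angle(BCD), torsion(ABCD)."""
    ang = math.radians(ang_deg)
    tor = -math.radians(tor_deg)  # sign chosen to reproduce the IUPAC
    # torsion convention of perception.torsion
    bc = _unit(C - B)
    nrm = _unit(np.cross(B - A, bc))
    m = np.cross(nrm, bc)
    d_local = np.array([
        -length * math.cos(ang),
        length * math.sin(ang) * math.cos(tor),
        length * math.sin(ang) * math.sin(tor),
    ])
    return C + d_local[0] * bc + d_local[1] * m + d_local[2] * nrm


def zigzag_chain(
    n: int,
    torsions: Optional[Sequence[float]] = None,
    bond_length: float = 1.54,
    angle: float = 109.47,
    element: str = "C",
    add_h: bool = False,
) -> Molecule:
    """sp3 chain of ``n`` atoms; per-bond backbone torsions settable.

    ``torsions`` has ``max(n-3, 0)`` entries (default all 180, the anti
    zig-zag).  With ``add_h`` hydrogens are placed explicitly at ideal
    tetrahedral positions; otherwise they stay implicit.
    """
    if n < 2:
        raise ValueError("chain needs at least 2 atoms")
    want = max(n - 3, 0)
    if torsions is None:
        torsions = [180.0] * want
    if len(torsions) != want:
        raise ValueError(f"need {want} torsions for a {n}-atom chain")
    mol = Molecule()
    coords = [np.zeros(3), np.array([bond_length, 0.0, 0.0])]
    if n >= 3:
        a = math.radians(angle)
        coords.append(coords[1] + bond_length *
                      np.array([-math.cos(a), math.sin(a), 0.0]))
    for k in range(3, n):
        coords.append(_nerf(coords[k - 3], coords[k - 2], coords[k - 1],
                            bond_length, angle, torsions[k - 3]))
    for k in range(n):
        mol.new_atom(element, coords=coords[k])
    for k in range(n - 1):
        mol.add_bond(k, k + 1, order=1)
    _fill_valence_h(mol)
    if add_h:
        return mol.make_explicit_h()
    return mol


# --------------------------------------------------------------------------
# cyclohexane
# --------------------------------------------------------------------------


def _chair_params(bond_length: float, ring_torsion: float) -> tuple[float, float]:
    """Radius and pucker of an ideal chair with the requested ring torsion."""

    def tors(d: float) -> float:
        r = math.sqrt(bond_length**2 - 4.0 * d * d)
        pts = [np.array([r * math.cos(math.pi * i / 3.0),
                         r * math.sin(math.pi * i / 3.0),
                         d if i % 2 == 0 else -d]) for i in range(4)]
        return abs(torsion(*pts)) - ring_torsion

    d = brentq(tors, 0.05, bond_length / 2.0 - 1e-6)
    r = math.sqrt(bond_length**2 - 4.0 * d * d)
    return r, d


def _boat_coords(bond_length: float) -> list[np.ndarray]:
    """C2v boat: four coplanar atoms plus two prows, tetrahedral angles."""
    L = bond_length
    theta = math.radians(109.47)
    x1 = L / 2.0

    def eqs(v):
        x0, z0, y1 = v
        p0 = np.array([x0, 0.0, z0])
        p1 = np.array([x1, y1, 0.0])
        p2 = np.array([-x1, y1, 0.0])
        p5 = np.array([x1, -y1, 0.0])
        def ang(a, b, c):
            v1, v2 = a - b, c - b
            return math.acos(np.dot(v1, v2) /
                             (np.linalg.norm(v1) * np.linalg.norm(v2)))
        return [np.linalg.norm(p0 - p1) - L,
                ang(p0, p1, p2) - theta,
                ang(p5, p0, p1) - theta]

    x0, z0, y1 = fsolve(eqs, [1.4, 0.7, 1.25], full_output=False)
    return [np.array([x0, 0.0, z0]), np.array([x1, y1, 0.0]),
            np.array([-x1, y1, 0.0]), np.array([-x0, 0.0, z0]),
            np.array([-x1, -y1, 0.0]), np.array([x1, -y1, 0.0])]


def cyclohexane(
    conformer: str = "chair",
    substituents: Optional[dict[int, tuple[str, str]]] = None,
    bond_length: float = 1.54,
    ring_torsion: float = 55.0,
) -> Molecule:
    """Cyclohexane ring with ideal chair (alternating +-ring_torsion) or boat
    geometry.  ``substituents`` maps ring position to ``(element, "axial" |
    "equatorial")``; placement uses ideal tetrahedral completion.
    """
    if conformer == "chair":
        r, d = _chair_params(bond_length, ring_torsion)
        coords = [np.array([r * math.cos(math.pi * i / 3.0),
                            r * math.sin(math.pi * i / 3.0),
                            d if i % 2 == 0 else -d]) for i in range(6)]
    elif conformer == "boat":
        coords = _boat_coords(bond_length)
    else:
        raise ValueError(f"unknown conformer {conformer!r}")
    mol = Molecule()
    for c in coords:
        mol.new_atom("C", coords=c)
    for i in range(6):
        mol.add_bond(i, (i + 1) % 6, order=1)
    if substituents:
        for pos, (el, style) in substituents.items():
            if style not in ("axial", "equatorial"):
                raise ValueError(f"bad substituent style {style!r}")
            here = mol.atoms[pos].coords
            dirs = [_unit(mol.atoms[nb].coords - here)
                    for nb in mol.neighbors(pos) if nb < 6]
            cand = ideal_tetrahedral_directions(dirs, 2)
            # the axial direction is (anti)parallel to the ring axis (z)
            cand.sort(key=lambda v: abs(v[2]), reverse=True)
            direction = cand[0] if style == "axial" else cand[1]
            s = mol.new_atom(el, coords=here + bond_length * direction)
            mol.add_bond(pos, s.index, order=1)
    _fill_valence_h(mol)
    return mol


# --------------------------------------------------------------------------
# transforms for robustness tests
# --------------------------------------------------------------------------


def mirror(mol: Molecule) -> Molecule:
    """Reflect through the yz plane (inverts all stereo parities)."""
    m = mol.copy()
    for a in m.atoms:
        if a.coords is not None:
            a.coords = a.coords * np.array([-1.0, 1.0, 1.0])
    return m


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def rigidly_moved(mol: Molecule, rng: np.random.Generator) -> Molecule:
    """Apply a random rotation + translation (stereo-preserving)."""
    R = random_rotation(rng)
    t = rng.normal(scale=5.0, size=3)
    m = mol.copy()
    for a in m.atoms:
        if a.coords is not None:
            a.coords = R @ a.coords + t
    return m


def perturbed(mol: Molecule, sigma: float, rng: np.random.Generator) -> Molecule:
    """Gaussian coordinate noise, for planarity/RMSD robustness tests."""
    m = mol.copy()
    for a in m.atoms:
        if a.coords is not None:
            a.coords = a.coords + rng.normal(scale=sigma, size=3)
    return m
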