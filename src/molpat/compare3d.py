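"""3D applications: atom mapping, quaternion superposition, isomer
classification, and dihedral driving.

``superpose`` uses the closed-form quaternion eigenvalue method: the optimal
rigid rotation is recovered from the principal eigenvector of the 4x4
cross-covariance matrix, which can never produce a reflection.
``best_alignment`` superposes every candidate atom mapping and keeps the
minimum-RMSD result, so symmetry-equivalent mappings are all considered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import matcher, perception
from .chem_graph import Molecule
from .smiles import Directives
from .perception import torsion

logger = logging.getLogger("molpat")


class AlignmentError(ValueError):
    pass


@dataclass
class AlignmentResult:
    """Rigid-body alignment of mapped atoms of B onto A."""

    mapping: list[list[int]]  # [a_index, b_index] pairs
    rotation: np.ndarray  # 3x3 proper rotation applied to B
    translation: np.ndarray  # 3-vector; R @ b + t ~ a
    rmsd: float
    all_candidate_rmsds: list[float] = field(default_factory=list)

    @property
    def matrix4(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


# --------------------------------------------------------------------------
# atom mapping
# --------------------------------------------------------------------------


def map_atoms(
    A: Molecule,
    B: Molecule,
    pattern: Optional[str] = None,
    include_h: bool = False,
    directives: Optional[Directives] = None,
) -> list[list[list[int]]]:
    """1:1 atom correlations between two structures.

    Without a pattern, a SMILES string generated from B is matched into A
    (a full-structure correlation).  With a SMARTS ``pattern``, the pattern
    is matched into both structures and the first match in B is composed
    with every match in A.  Returns a list of mappings, each a list of
    ``[a_index, b_index]`` pairs.
    """
    directives = directives or Directives()
    if pattern is None:
        molA, molB = A, B
        if include_h:
            molA, molB = A.make_explicit_h(), B.make_explicit_h()
        ok, mappings = matcher.smiles_match(
            molA, molB, directives, return_mappings=True, all_matches=True,
            include_h=include_h)
        return mappings if ok else []
    resA = matcher.smarts_match(pattern, A, directives, all_matches=True)
    resB = matcher.smarts_match(pattern, B, directives, all_matches=False)
    if not resA or not resB:
        return []
    mb = resB[0].mapping
    out = []
    for ra in resA:
        out.append(sorted([ra.mapping[p], mb[p]] for p in ra.mapping))
    return out


# --------------------------------------------------------------------------
# quaternion superposition
# --------------------------------------------------------------------------


def superpose(
    coordsA: np.ndarray,
    coordsB: np.ndarray,
    mapping: Optional[Sequence[Sequence[int]]] = None,
) -> AlignmentResult:
    """Optimal rigid transform of B onto A over mapped pairs.

    ``mapping`` holds ``[a_index, b_index]`` pairs (default: positional).
    Raises :class:`AlignmentError` for fewer than 3 pairs or collinear
    geometry, where the rotation is not unique.
    """
    coordsA = np.asarray(coordsA, dtype=float)
    coordsB = np.asarray(coordsB, dtype=float)
    if mapping is None:
        if len(coordsA) != len(coordsB):
            raise AlignmentError("coordinate sets differ in length")
        P = coordsA
        Q = coordsB
        mapping = [[i, i] for i in range(len(coordsA))]
    else:
        P = np.array([coordsA[a] for a, _ in mapping], dtype=float)
        Q = np.array([coordsB[b] for _, b in mapping], dtype=float)
    if len(P) < 3:
        raise AlignmentError("need at least 3 mapped pairs for a unique fit")
    cP, cQ = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cP, Q - cQ
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or \
            np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise AlignmentError("degenerate (collinear) geometry; rotation "
                             "about the line is unconstrained")
    S = Qc.T @ Pc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    eigvals, eigvecs = np.linalg.eigh(K)
    q = eigvecs[:, -1]  # principal eigenvector
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = cP - R @ cQ
    residuals = (R @ Q.T).T + t - P
    rmsd = float(np.sqrt((residuals ** 2).sum() / len(P)))
    return AlignmentResult(mapping=[list(m) for m in mapping],
                           rotation=R, translation=t, rmsd=rmsd)


def best_alignment(
    A: Molecule,
    B: Molecule,
    pattern: Optional[str] = None,
    include_h: bool = False,
    directives: Optional[Directives] = None,
) -> AlignmentResult:
    """Superpose every candidate mapping; return the minimum-RMSD fit."""
    molA = A.make_explicit_h() if include_h else A
    molB = B.make_explicit_h() if include_h else B
    mappings = map_atoms(molA, molB, pattern=pattern, directives=directives)
    if not mappings:
        raise AlignmentError("no atom mapping between the two structures")
    coordsA = molA.coords_array()
    coordsB = molB.coords_array()
    best: Optional[AlignmentResult] = None
    rmsds = []
    for m in mappings:
        res = superpose(coordsA, coordsB, m)
        rmsds.append(res.rmsd)
        if best is None or res.rmsd < best.rmsd:
            best = res
    best.all_candidate_rmsds = rmsds
    return best


# --------------------------------------------------------------------------
# isomer classification
# --------------------------------------------------------------------------

ISOMER_LABELS = ("NONE", "IDENTICAL", "CONSTITUTIONAL", "ENANTIOMERS",
                 "DIASTEREOMERS")


def classify_isomers(A: Union[str, Molecule], B: Union[str, Molecule],
                     directives: Optional[Directives] = None) -> str:
    """Five-way isomer relationship of two structures.

    The decision sequence: unequal molecular weight -> NONE; plain match ->
    IDENTICAL; no match ignoring stereo -> CONSTITUTIONAL; match with all
    chirality centers inverted -> ENANTIOMERS; otherwise DIASTEREOMERS.
    The weight gate sums exact nominal isotope masses, so it is a formula
    comparison with no float tolerance.
    """
    base = directives.copy() if directives else Directives()
    molA, _ = matcher._as_molecule(A, base.copy())
    molB, _ = matcher._as_molecule(B, base.copy())
    if molA.nominal_mass() != molB.nominal_mass():
        return "NONE"
    if matcher.smiles_match(molA, molB, base.copy()):
        return "IDENTICAL"
    nostereo = base.copy()
    nostereo.no_stereo = True
    if not matcher.smiles_match(molA, molB, nostereo):
        return "CONSTITUTIONAL"
    invert = base.copy()
    invert.invert_stereo = True
    if matcher.smiles_match(molA, molB, invert):
        return "ENANTIOMERS"
    return "DIASTEREOMERS"


# --------------------------------------------------------------------------
# dihedral driving
# --------------------------------------------------------------------------


def _rotate_about_axis(coords: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                       angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of points about the axis p1->p2."""
    u = p2 - p1
    u = u / np.linalg.norm(u)
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    shifted = coords - p1
    rotated = (shifted * c
               + np.cross(u, shifted) * s
               + np.outer(shifted @ u, u) * (1 - c))
    return rotated + p1


def _bond_is_bridge(mol: Molecule, a: int, b: int) -> bool:
    """True when removing bond a-b disconnects a from b (acyclic bond)."""
    seen = {a}
    stack = [a]
    while stack:
        cur = stack.pop()
        for n in mol.neighbors(cur):
            if cur == a and n == b:
                continue
            if n == b:
                return False
            if n not in seen:
                seen.add(n)
                stack.append(n)
    return True


def _side_atoms(mol: Molecule, keep: int, far: int) -> set[int]:
    """Atoms reachable from ``far`` without crossing the keep-far bond."""
    seen = {keep, far}
    stack = [far]
    out = {far}
    while stack:
        cur = stack.pop()
        for n in mol.neighbors(cur):
            if n not in seen:
                seen.add(n)
                out.add(n)
                stack.append(n)
    return out


def drive_dihedrals(reference: Molecule, moving: Molecule, pattern: str,
                    directives: Optional[Directives] = None) -> Molecule:
    """Rotate matched acyclic bonds of ``moving`` so every matched torsion
    equals its counterpart in ``reference``; returns a modified copy.

    Bonds are processed in pattern order; the smaller side of each bond is
    rotated (ties broken toward the lower atom index).  A matched bond that
    lies in a ring is skipped with a warning.
    """
    directives = directives or Directives()
    resR = matcher.smarts_match(pattern, reference, directives, all_matches=False)
    resM = matcher.smarts_match(pattern, moving, directives, all_matches=False)
    if not resR or not resM:
        raise matcher.MatchError("pattern must match both structures")
    mR, mM = resR[0].mapping, resM[0].mapping

    from .smarts import parse_smarts, preprocess_smarts

    clauses, pdir = preprocess_smarts(pattern)
    pat = parse_smarts(clauses[0], pdir)

    out = moving.copy()
    for pb in pat.bonds:
        p, q = pb.a1, pb.a2
        j, k = mM[p], mM[q]
        i_p = next((x for x in pat.neighbors(p) if x != q), None)
        l_p = next((x for x in pat.neighbors(q) if x != p), None)
        if i_p is None or l_p is None:
            continue  # terminal bond: no torsion to drive
        if not _bond_is_bridge(out, j, k):
            logger.warning("matched bond %d-%d lies in a ring; skipped", j, k)
            continue
        iM, lM = mM[i_p], mM[l_p]
        tau_ref = torsion(reference.atoms[mR[i_p]].coords,
                          reference.atoms[mR[p]].coords,
                          reference.atoms[mR[q]].coords,
                          reference.atoms[mR[l_p]].coords)
        tau_mov = torsion(out.atoms[iM].coords, out.atoms[j].coords,
                          out.atoms[k].coords, out.atoms[lM].coords)
        delta = tau_ref - tau_mov
        side_k = _side_atoms(out, j, k)
        side_j = _side_atoms(out, k, j)
        if len(side_j) < len(side_k) or (
                len(side_j) == len(side_k) and min(side_j) < min(side_k)):
            rotate_set, angle = side_j, -delta
        else:
            rotate_set, angle = side_k, delta
        idxs = sorted(rotate_set)
        pts = np.array([out.atoms[x].coords for x in idxs])
        newpts = _rotate_about_axis(pts, out.atoms[j].coords,
                                    out.atoms[k].coords, angle)
        for x, ptn in zip(idxs, newpts):
            out.atoms[x].coords = ptn
        # sign convention check: if the torsion moved the wrong way, flip
        tau_now = torsion(out.atoms[iM].coords, out.atoms[j].coords,
                          out.atoms[k].coords, out.atoms[lM].coords)
        err = (tau_now - tau_ref + 180.0) % 360.0 - 180.0
        if abs(err) > 1e-6:
            newpts = _rotate_about_axis(newpts, out.atoms[j].coords,
                                        out.atoms[k].coords, -2.0 * angle)
            for x, ptn in zip(idxs, newpts):
                out.atoms[x].coords = ptn
    return out
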