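"""Readers for 3D structure formats: MDL molfile/SDF (V2000), XYZ, and PDB.

The molfile reader keeps the query bond types used by SDF query files:
type 4 is aromatic-unspecified, type 6 is "aromatic single" and type 7
"aromatic double"; the aromatic flag they declare feeds the ``defined``
aromaticity model.  XYZ and (CONECT-less) PDB input get distance-based bond
perception from a fixed covalent-radius table, which keeps the result
deterministic across platforms.
"""

from __future__ import annotations

import logging
import numpy as np

from .chem_graph import ATOMIC_NUMBER, COVALENT_RADIUS, _DEFAULT_RADIUS, Molecule

logger = logging.getLogger("molpat")

DEFAULT_BOND_TOLERANCE = 1.15


class FormatError(ValueError):
    pass


# --------------------------------------------------------------------------
# MDL molfile / SDF
# --------------------------------------------------------------------------

_CHARGE_CODES = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}


def read_molfile(text: str, model_id: int = 0) -> Molecule:
    """Read one V2000 molfile record into a Molecule."""
    lines = text.splitlines()
    if len(lines) < 4:
        raise FormatError("molfile too short (no counts line)")
    counts = lines[3]
    try:
        natoms = int(counts[0:3])
        nbonds = int(counts[3:6])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed counts line {counts!r}") from exc
    mol = Molecule()
    mol.model_id = model_id
    for line in lines[4:4 + natoms]:
        x, y, z = float(line[0:10]), float(line[10:20]), float(line[20:30])
        symbol = line[31:34].strip()
        if symbol not in ATOMIC_NUMBER:
            raise FormatError(f"unknown element symbol {symbol!r}")
        atom = mol.new_atom(symbol, coords=np.array([x, y, z]))
        code = line[36:39].strip()
        if code:
            atom.charge = _CHARGE_CODES.get(int(code), 0)
    for line in lines[4 + natoms:4 + natoms + nbonds]:
        a1, a2, btype = int(line[0:3]) - 1, int(line[3:6]) - 1, int(line[6:9])
        if not (0 <= a1 < natoms and 0 <= a2 < natoms):
            raise FormatError(f"bond references missing atom: {line!r}")
        if btype in (1, 2, 3):
            mol.add_bond(a1, a2, order=btype)
        elif btype == 4:
            mol.add_bond(a1, a2, order=None, aromatic=True)
        elif btype == 6:
            mol.add_bond(a1, a2, order=1, aromatic=True)
        elif btype == 7:
            mol.add_bond(a1, a2, order=2, aromatic=True)
        else:
            logger.warning("unsupported bond type %d treated as single", btype)
            mol.add_bond(a1, a2, order=1)
    for line in lines[4 + natoms + nbonds:]:
        if line.startswith("M  CHG"):
            fields = line.split()
            n = int(fields[2])
            for k in range(n):
                idx = int(fields[3 + 2 * k]) - 1
                mol.atoms[idx].charge = int(fields[4 + 2 * k])
        elif line.startswith("M  ISO"):
            fields = line.split()
            n = int(fields[2])
            for k in range(n):
                idx = int(fields[3 + 2 * k]) - 1
                mol.atoms[idx].isotope = int(fields[4 + 2 * k])
        elif line.startswith("M  END"):
            break
    # file-declared aromatic atoms follow from the declared bonds
    for b in mol.bonds:
        if b.aromatic:
            mol.atoms[b.a1].aromatic = True
            mol.atoms[b.a2].aromatic = True
    return mol


def read_sdf(text: str) -> list[Molecule]:
    """Read a (possibly multi-record) SDF; data blocks are ignored."""
    records: list[list[str]] = [[]]
    for line in text.splitlines():
        if line.strip() == "$$$$":
            records.append([])
        else:
            records[-1].append(line)
    mols = []
    for rec in records:
        if not any(ln.strip() for ln in rec):
            continue
        mols.append(read_molfile("\n".join(rec), model_id=len(mols)))
    return mols


# --------------------------------------------------------------------------
# XYZ
# --------------------------------------------------------------------------


def perceive_bonds(mol: Molecule, tolerance: float = DEFAULT_BOND_TOLERANCE) -> None:
    """Create single bonds where the distance is within ``tolerance`` times
    the sum of covalent radii.  Symmetric and deterministic."""
    n = len(mol.atoms)
    for i in range(n):
        ai = mol.atoms[i]
        for j in range(i + 1, n):
            aj = mol.atoms[j]
            if ai.is_h() and aj.is_h():
                continue
            rsum = (COVALENT_RADIUS.get(ai.atomic_number, _DEFAULT_RADIUS)
                    + COVALENT_RADIUS.get(aj.atomic_number, _DEFAULT_RADIUS))
            dist = float(np.linalg.norm(ai.coords - aj.coords))
            if dist <= tolerance * rsum:
                mol.add_bond(i, j, order=1)


def read_xyz(text: str, bond_tolerance: float = DEFAULT_BOND_TOLERANCE) -> Molecule:
    lines = [ln for ln in text.splitlines()]
    if not lines:
        raise FormatError("empty XYZ input")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise FormatError("first XYZ line must be the atom count") from exc
    body = lines[2:2 + n]
    if len(body) != n:
        raise FormatError(f"XYZ atom count mismatch: header {n}, got {len(body)}")
    mol = Molecule()
    for ln in body:
        fields = ln.split()
        symbol = fields[0].capitalize() if len(fields[0]) > 1 else fields[0].upper()
        if symbol not in ATOMIC_NUMBER:
            raise FormatError(f"unknown element symbol {fields[0]!r}")
        mol.new_atom(symbol, coords=np.array([float(f) for f in fields[1:4]]))
    perceive_bonds(mol, bond_tolerance)
    return mol


def write_xyz(mol: Molecule, comment: str = "") -> str:
    lines = [str(len(mol.atoms)), comment]
    for a in mol.atoms:
        x, y, z = a.coords if a.coords is not None else (0.0, 0.0, 0.0)
        lines.append(f"{a.element:<3s} {x:15.8f} {y:15.8f} {z:15.8f}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# PDB (ATOM/HETATM/CONECT subset)
# --------------------------------------------------------------------------


def read_pdb(text: str, bond_tolerance: float = DEFAULT_BOND_TOLERANCE) -> Molecule:
    """Read ATOM/HETATM records; CONECT is honored when present, otherwise
    bonds are perceived by distance.  Unparseable lines are skipped with a
    warning.  Matching metadata is stored uppercase."""
    mol = Molecule()
    serial_to_index: dict[int, int] = {}
    conect: list[tuple[int, int]] = []
    model_id = 0
    for line in text.splitlines():
        rec = line[0:6].strip()
        if rec == "MODEL":
            try:
                model_id = int(line.split()[1]) - 1
            except (ValueError, IndexError):
                pass
            continue
        if rec in ("ATOM", "HETATM"):
            try:
                serial = int(line[6:11])
                name = line[12:16].strip().upper()
                res_name = line[17:20].strip().upper()
                res_num = int(line[22:26])
                ins = line[26:27].strip().upper() or None
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError):
                logger.warning("skipping unparseable PDB line: %r", line)
                continue
            symbol = line[76:78].strip() if len(line) >= 78 else ""
            symbol = symbol.capitalize()
            if symbol not in ATOMIC_NUMBER:
                symbol = _element_from_name(name)
            atom = mol.new_atom(symbol, coords=np.array([x, y, z]))
            atom.atom_name = name
            atom.residue_name = res_name
            atom.residue_number = res_num
            atom.insertion_code = ins
            serial_to_index[serial] = atom.index
        elif rec == "CONECT":
            try:
                fields = [int(line[6 + 5 * k:11 + 5 * k])
                          for k in range(5)
                          if line[6 + 5 * k:11 + 5 * k].strip()]
            except ValueError:
                logger.warning("skipping unparseable CONECT line: %r", line)
                continue
            for other in fields[1:]:
                conect.append((fields[0], other))
    mol.model_id = model_id
    if conect:
        done = set()
        for s1, s2 in conect:
            if s1 in serial_to_index and s2 in serial_to_index:
                i, j = serial_to_index[s1], serial_to_index[s2]
                key = (min(i, j), max(i, j))
                if key not in done:
                    done.add(key)
                    mol.add_bond(i, j, order=1)
    else:
        perceive_bonds(mol, bond_tolerance)
    return mol


def _element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name (fallback heuristic)."""
    stripped = name.strip("0123456789'")
    # "CA"/"CB" etc. are carbons; only unambiguous two-letter metals and
    # halogens are taken as such (calcium needs the element columns)
    if len(stripped) >= 2 and stripped[:2].capitalize() in (
            "Cl", "Br", "Fe", "Zn", "Mg", "Na", "Mn", "Cu", "Se"):
        return stripped[:2].capitalize()
    if stripped and stripped[0] in ATOMIC_NUMBER:
        return stripped[0]
    raise FormatError(f"cannot infer element from atom name {name!r}")
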