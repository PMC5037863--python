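# molpat

Pattern matching and 3D comparison for molecules, implementing the **Jmol
SMILES** and **Jmol SMARTS** dialects — supersets of OpenSMILES and
OpenSMARTS designed for interrogating 3D structural models rather than
canonical database keys.

The toolkit is for cheminformatics work where the inputs are 3D structures
from heterogeneous sources (SDF, XYZ, PDB, drawn structures, database
SMILES) and the questions are structural: *do these two structures match,
and how are their atoms correlated? are they enantiomers or diastereomers?
how similar are their geometries after optimal superposition? is this
cyclohexane chair trans-diaxial? what MMFF94 atom type is this sulfur?*

## What the dialects add

On top of the standard grammars:

* **Free format and directives** — `//* comments *//`, whitespace, and a
  `/.../` prefix selecting the aromaticity model (`open` Hückel 4n+2,
  `strict` = Hückel + planarity + no exocyclic double bonds, 
  `aromaticPlanar` geometry-only, `aromaticDefined` file-declared,
  `noAromatic`) and stereo handling (`noStereo`, `invertStereo`), plus
  generation and matching options (`topology`, `hydrogens`,
  `atomComments`, `firstMatchOnly`, `aromaticDouble`,
  `groupByMolecule`/`groupByModel`).
* **Extended stereochemistry** — tetrahedral, cumulene/imine cis-trans,
  allene-type axial chirality, trigonal pyramidal (chiral phosphines),
  T-shaped, seesaw, and atropisomer bond marks `^nm-`/`^^nm-`.
* **3D-aware SMARTS primitives** — non-hydrogen connections `[d2]`,
  aromatic 5/6-ring shortcuts `[r500]`/`[r600]`, mass-or-unspecified
  `[12?C]`, PDB residue.atom specs `[ALA.C]`, atom indices `[=22]`,
  application hooks `[$(select ...)]`, repeats `[$3(C=C)]`, variables
  `$R1="...";`, selection braces `{c}1ccccc1`, large-scope OR `||`, and
  component-level grouping `(C=O.C=O).{OH}`.
* **Geometric constraints** — distance `(.d:1.5-1.6)`, angle
  `(.a:105-110)` and torsion `(.t:-170,-180,170,180)` windows evaluated on
  the mapped 3D coordinates, which makes conformational motifs
  (anti/gauche, chair substituent patterns) expressible as patterns.

Full-structure SMILES matching is performed **without canonicalization**:
two structures match if one maps onto the other atom by atom under the
active aromaticity model, so database SMILES written in different Kekulé
forms or atom orders compare directly.

## Worked example

```python
from molpat import fixtures, matcher, compare3d, atomtyping, smiles

# substructure search: butane backbone inside hexane
hexane = smiles.parse_smiles("CCCCCC")
res = matcher.smarts_match("CCCC", hexane)
print("matches:", len(res))                          # matches: 3
print("selected:", sorted(matcher.selected_atoms(res)))
                                                     # selected: [0, 1, 2, 3, 4, 5]

# stereochemical relationship of two SMILES strings
print("isomer:", compare3d.classify_isomers("[C@H](F)(Cl)Br",
                                            "[C@@H](F)(Cl)Br"))
                                                     # isomer: ENANTIOMERS

# flexible fit: drive the gauche butane torsion to anti, then align
anti = fixtures.zigzag_chain(4, [180])
gauche = fixtures.zigzag_chain(4, [60])
driven = compare3d.drive_dihedrals(anti, gauche, "CCCC")
print("rmsd: %.2e" % compare3d.best_alignment(anti, driven).rmsd)
                                                     # rmsd: 3.69e-16

# MMFF94-style sulfur typing (rule order carries the chemistry)
dmso = smiles.parse_smiles("CS(=O)C").make_explicit_h()
print("types:", atomtyping.assign_types(dmso))       # types: [0, 17, 0, ...]

# conformer identification by torsion motifs
chair = fixtures.cyclohexane("chair", {0: ("C", "axial"), 1: ("C", "axial")})
print("conformer:", matcher.conformer_classify(chair))
                                                     # conformer: trans-1,2-diaxial
```

The three matches report 3 distinct atom sets whose union is all six
carbons; the driven butane aligns onto the anti reference to machine
precision; DMSO's sulfur receives MMFF94 type 17 (sulfoxide).

A command-line front end covers the same workflows:

```bash
molpat match "CCCC" smiles:CCCCCC --all
molpat isomer smiles:CCO smiles:OCC
molpat compare a.xyz b.xyz --json
molpat atomtype thiophene.sdf
```

## Layout

| module | contents |
| --- | --- |
| `chem_graph` | `Molecule`/`Atom`/`Bond`, environment counts, components |
| `io_formats` | molfile/SDF (V2000 incl. query bond types 6/7), XYZ, PDB |
| `smiles` | directives, Jmol SMILES parser, deterministic generator |
| `smarts` | variables/repeats/`||` preprocessing, pattern-graph parser |
| `perception` | ring enumeration, five aromaticity models, 3D stereo |
| `matcher` | backtracking matcher, measurements, grouping, stereo checks |
| `compare3d` | atom mapping, quaternion superposition, isomers, dihedrals |
| `atomtyping` | rule-ordered typing engine + the sulfur MMFF94 ruleset |
| `fixtures` | deterministic geometry generators (rings, chains, chairs) |
| `cli` | `molpat` command-line front end |
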