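# Methods

This note records how molpat implements the Jmol SMILES / Jmol SMARTS
dialects: the models, the numerical choices, and the places where the
dialect specification is silent and the package had to pick a convention.

## Molecular graph and hydrogen accounting

A `Molecule` is an ordered atom list plus bonds; hydrogens may be explicit
atoms, per-atom implicit counts, or both. The pattern primitives read:

* `X` = explicit connections + implicit H, `D` = explicit connections,
  `d` = non-hydrogen connections, `h` = implicit H, `H` = implicit H +
  attached explicit H, `v` = bond-order sum + implicit H, `x` = bonds
  ending on ring atoms.
* `d`, `H`, `X` and `v` are invariant under making hydrogens explicit;
  `h` is not, by design — `[C;h2]` is the idiom for "a methylene from an
  H-free structure file", which only works if `h` counts *implicit*
  hydrogens.
* Aromatic-unspecified bonds (`:`, molfile type 4) contribute 1 to
  valence; Kekulé orders count as written.

Implicit hydrogen filling uses the OpenSMILES normal-valence rule
(smallest default valence ≥ bond-order sum). For lowercase aromatic atoms
one electron is reserved for the π system (`valence − bonds − 1`, clamped
at 0) unless the atom already carries an explicit Kekulé double bond to
another aromatic atom, which *is* its π contribution. This reproduces the
printed caffeine atom total (24) and keeps both Kekulé pyridine forms at
the right H counts.

## Bond semantics

An **unwritten** bond in a SMARTS pattern matches any bond. This is a
deliberate departure from Daylight's single-or-aromatic default, forced by
two facts of the dialect: the published MMFF94 sulfur rules reach S=O and
C=S through unwritten bonds (`[SD3]([OD1,ND2])...`), and under
`/noAromatic/` the pattern `C1CCCCC1` is documented to match benzene.
Written symbols constrain as usual: `-` is single-and-not-aromatic (so a
biaryl single bond is distinguishable), `=`/`#`/`$` match the explicit
order, `:`/`@` aromatic, `~` anything.

For full-structure SMILES matching the pattern is the molecule itself:
element, charge, isotope (unspecified matches anything; `n?` matches n or
unspecified), total hydrogen count, atom class, and aromaticity-reconciled
bond orders must agree. Aromatic bonds match aromatic bonds regardless of
Kekulé form unless `/aromaticDouble/` is active (set automatically by a
written `a=a`), in which case explicit double bonds must coincide — this
distinguishes the PubChem and NCI Kekulé forms of 2-methylpyridine.
Under `/noAromatic/` case is ignored entirely and only written bond
orders are compared.

`.` means *absolutely not connected*: the two dot-adjacent atoms must not
be bonded in the target. It is deliberately not a whole-fragment
separation — in `(C=O.C=O).{OH}` the hydroxyl oxygen of a carboxylic acid
is bonded to a carbonyl carbon and must still be selectable.

Component-level grouping: atoms inside one `(...)` group must map into a
single connected component (or model, under `/groupByModel/`), distinct
groups into distinct components, and atoms outside any group must land in
a component occupied by some group. The last clause realizes "an OH in a
component that has at least two carbonyls".

## Rings and aromaticity

Ring membership means "member of *some* simple cycle", with no
smallest-set-of-smallest-rings reduction. All simple cycles up to a cap
(default 8) are enumerated via depth-bounded cycle search; any `r<n>`
primitive larger than the cap raises it for that match. Hence indole's
`[R2]` selects the two fusion atoms, while `[R2&r9]` sees the 9-membered
envelope, lifts the fusion atoms to ring count 3, and selects the other
seven atoms.

Five aromaticity models:

* **open** — per-ring Hückel counting: 1 π electron per atom with an
  endocyclic double (or declared-aromatic) bond, 2 for a neutral
  lone-pair heteroatom with no multiple bond, 0 for a ring carbocation;
  an exocyclic double bond contributes 1 only if its terminal atom is not
  more electronegative than carbon (Pauling χ > 2.55 disqualifies the
  ring — quinone fails here). Ring aromatic iff every atom contributes
  and the total ≡ 2 (mod 4).
* **strict** — open, plus no exocyclic double bonds at all, plus ring
  planarity when 3D coordinates exist (graph-only input falls back to
  electron counting with a logged warning).
* **planar** — geometry only: every ring atom sp2-plausible (≤ 3
  connections) and within tolerance of the ring's least-squares plane.
  Planar quinone and cyclobutadiene are aromatic here.
* **defined** — trust the flags declared by the input (lowercase SMILES,
  molfile bond types 4/6/7).
* **none** — no aromaticity of any kind; `:` becomes order-unspecified.

String- or file-declared aromatic rings are honored as declared under
every model except `none`; electron counting and planarity adjudicate
rings written in Kekulé form or read from bare coordinates. Re-deriving
Hückel counts for declared rings would require kekulization, which the
non-canonical matching workflow deliberately avoids.

Planarity tolerance is 0.1 Å from the least-squares plane (the dialect
names the criterion but no number; an ideal chair deviates ±0.25 Å, so
0.1 Å separates the cases robustly). Collinear "rings" are non-planar.

## Stereochemistry

Parity conventions (self-consistent, and pinned by construction tests
rather than claimed byte-identical to any other implementation):

* **Tetrahedral** — `@` means: looking from the first listed neighbor
  toward the center, the remaining three read anticlockwise. Numerically,
  `@` iff the signed volume det[p2−p1, p3−p1, p4−p1] of the neighbor
  positions in sequence order is negative. Implicit hydrogens occupy
  their written position as phantom neighbors; against 3D targets a
  phantom resolves to the unique explicit hydrogen or to an ideal
  tetrahedral completion position.
* **Trigonal pyramidal (TP)** — tetrahedral with the lone pair appended
  as a phantom fourth neighbor opposite the mean bond direction.
* **cis/trans** (double bonds, even cumulenes, imines) — `/` and `\`
  marks are reduced to a side factor per flanking bond; equal factors on
  the two ends mean cis. Against 3D targets the substituent torsion
  decides (|τ| < 90° = cis). One-sided or conflicting marks are parse
  errors.
* **Allenic** (odd cumulenes, carbodiimides) — the four end substituents
  in written order behave as a tetrahedral quadruple; in 3D the sign of
  the inter-plane dihedral decides.
* **Atropisomers** — `^nm-`/`^^nm-` marks are parsed and stored; 3D
  evaluation uses the sign of the inter-ring torsion. Evaluation beyond
  the torsion sign is experimental.
* **SP/TB/OH/TS/SS** — parsed and stored with their order indices;
  matching evaluates only the tetrahedral-reducible cases above. The
  permutation conventions for the exotic order indices are not
  documented in running text anywhere we trust, so they are recorded but
  not silently guessed.

All parities flip under mirror inversion and survive rigid motion (tested
with seeded random rotations). `/noStereo/` skips every check;
`/invertStereo/` flips chirality centers only, not double bonds.
A target with no stereo information matches any requested parity.

## Matching engine

Backtracking subgraph search over pattern atoms in a connectivity-aware
DFS order; candidates are neighbor-propagated where possible. After a
complete assignment: dot constraints, grouping, measurement windows
(value inside any listed range, complemented by `!`), and stereo run as
whole-mapping checks. Results de-duplicate by selected-atom set, which
collapses direction-reversed mappings and yields the documented "3
matches of CCCC in hexane". Measurements are evaluated post-mapping
rather than used for pruning; at the intended problem sizes (tens of
atoms) this is not a bottleneck. `map_atoms` keeps mapping-level
duplicates because the alignment step wants every symmetry-equivalent
correlation. The brute-force oracle in the test suite enumerates all
injective mappings with `itertools.permutations` and must agree exactly
on every ≤10-atom fixture.

## Superposition and dihedral driving

Optimal rigid superposition is the quaternion eigenvalue method: the
rotation is the principal eigenvector of the 4×4 cross-covariance matrix
(symmetric eigendecomposition), which cannot produce a reflection — a
chiral molecule vs its mirror image retains a strictly positive RMSD.
The test suite requires agreement with an independent Kabsch/SVD
implementation to 1e-9 Å on 100 seeded random point sets. Fewer than
three pairs or collinear geometry raise an error (the rotation is not
unique). `best_alignment` superposes every candidate mapping and returns
the minimum.

Dihedral driving processes matched bonds in pattern order: for each
acyclic matched bond, the torsion defined by the pattern-neighbor quad is
set to the reference value by a Rodrigues rotation of the smaller side
(ties toward the lower atom index); ring bonds are skipped with a
warning. Disjoint rotations commute, so independent torsions drive
simultaneously; a final quaternion alignment is the caller's choice.

## Isomer classification

The five-way decision runs exactly: unequal molecular weight → NONE;
match → IDENTICAL; no match under `/noStereo/` → CONSTITUTIONAL; match
under `/invertStereo/` → ENANTIOMERS; otherwise DIASTEREOMERS. The
weight gate sums exact integer nominal isotope masses — a formula
comparison, immune to float tolerance.

## Atom typing

The typing engine walks an ordered ruleset, assigning each rule's type to
all matched, still-untyped atoms, under the strict aromaticity model with
Kekulé-double matching, and skipping rules whose element gate is absent
from the molecule. The shipped ruleset is the published MMFF94 sulfur
block, in its published order; order is semantic (S=C before terminal S).
The thiocarboxylate fixture is the Kekulé anion `CC(=S)[S-]`; with the
any-order default bond both termini are caught by the
`[SD1][CD3][SD1]` rule before the C=S rule, as intended.

## Synthetic geometry

The fixtures module generates exactly the template families the 3D
features need — no general embedding from SMILES:

* regular planar n-gons (bond 1.40 Å default; quinone uses 1.45 Å ring /
  1.22 Å C=O), with in-plane exterior substituents;
* sp3 zig-zag chains (1.54 Å, 109.47°) with settable backbone torsions
  via natural extension of reference frame placement, accurate to 1e-6°;
* cyclohexane chairs with alternating ±55° ring torsions (radius and
  pucker solved from the bond length by bisection) and ideal
  tetrahedral axial/equatorial substituent placement, plus a C2v boat
  solved for tetrahedral angles;
* mirror, seeded random rigid motion, and Gaussian perturbation helpers.

These fixtures are idealized: real conformers have relaxed bond lengths,
nonideal angles, and thermal spread, so geometric tests passing on them
demonstrate the correctness of the measurement and alignment machinery,
not robustness to experimental noise (the perturbation helper exists for
spot-checking tolerance behavior).

## Conformer motif library

The default library holds the three published 1,2-dimethylcyclohexane
torsion motifs followed by generic anti (170–180°), gauche (50–70°) and
eclipsed (±20°) windows; the first matching label wins. The diaxial motif
carries an added `[C;R]` ring qualifier: verbatim it would also match
anti-butane and shadow the generic "anti" label the same library provides.

## Problem sizes and determinism

Everything in the test suite and the acceptance script runs on molecules
of a few dozen atoms and completes in well under a minute in total; all
randomness (rotations, point sets, noise) flows through seeded
`numpy.random.Generator` instances. The acceptance script's `--seed`
drives the random rigid motion applied before the geometry-only
aromaticity check; every reported count is otherwise deterministic.

## Known limitations

* No canonical SMILES generation — deliberate; comparison never
  canonicalizes. The generator is deterministic (lowest-index DFS,
  lowest-free ring digits) but makes no cross-implementation claims.
* Generated SMILES omit stereo descriptors; round-trip identity is
  constitutional + aromatic, and 3D workflows re-perceive stereo from
  coordinates.
* Pattern H atoms match only explicit hydrogen atoms; H-count primitives
  (`[CH3]`, `[h2]`) are the way to reach implicit hydrogens.
* Extended stereo order indices (SP/TB/OH/TS/SS beyond the
  tetrahedral-reducible cases) and atropisomer digit semantics are parsed
  and stored but not fully evaluated.
* `[$(select ...)]` is a callback hook; no native selection language is
  embedded, and an unregistered hook is a hard error.
* Reaction input is tolerated only by reading `>>` as ".".
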