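"""Rule-ordered SMARTS atom typing (MMFF94 style).

A ruleset is an ordered list of (type id, label, pattern) entries.  The
engine scans through *types* rather than atoms: the first rule whose
pattern matches assigns its type to all matched, still-untyped atoms, and
an atom, once typed, is never re-tested.  Rule order therefore carries
chemistry: the sulfur ruleset must test S=C (type 16) before the generic
terminal-sulfur rules (type 72), or thiocarbonyl sulfurs would be mistyped.

Only the sulfur block ships with the package (``data/mmff_sulfur.tsv``);
the engine itself is generic and takes any TSV with columns
``type_id<TAB>label<TAB>smarts[<TAB>element]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

from . import matcher
from .chem_graph import Molecule
from .smarts import parse_smarts, preprocess_smarts
from .smiles import Directives

logger = logging.getLogger("molpat")

UNTYPED = 0


@dataclass
class TypingRule:
    type_id: int
    label: str
    smarts: str
    element: Optional[str] = None  # element gate ("only run tests on
    # element/valence combinations that are present")


def load_ruleset(source: Union[str, Path]) -> list[TypingRule]:
    """Load a TSV ruleset (text content or a path)."""
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\t" not in source
                                    and "\n" not in source):
        text = Path(source).read_text()
    else:
        text = str(source)
    rules = []
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"ruleset line needs >= 3 tab-separated "
                             f"columns: {line!r}")
        rules.append(TypingRule(
            type_id=int(fields[0]), label=fields[1], smarts=fields[2],
            element=fields[3] if len(fields) > 3 else None))
    for rule in rules:  # fail fast on unparseable patterns
        clauses, d = preprocess_smarts(rule.smarts)
        for c in clauses:
            parse_smarts(c, d)
    return rules


def sulfur_ruleset() -> list[TypingRule]:
    """The shipped MMFF94 sulfur rules, in their published order."""
    text = resources.files("molpat").joinpath("data/mmff_sulfur.tsv").read_text()
    return load_ruleset(text)


def assign_types(
    mol: Molecule,
    ruleset: Optional[Sequence[TypingRule]] = None,
    directives: Optional[Directives] = None,
) -> list[int]:
    """Per-atom type ids; 0 marks an atom no rule claimed.

    Aromaticity is perceived under the strict model (with the explicit
    Kekule-double flag), which is what MMFF94 typing assumes.
    """
    if ruleset is None:
        ruleset = sulfur_ruleset()
    if directives is None:
        directives = Directives(aromaticity_model="strict", aromatic_double=True)
    types = [UNTYPED] * len(mol.atoms)
    elements_present = {a.element for a in mol.atoms}
    for rule in ruleset:
        if rule.element is not None and rule.element not in elements_present:
            continue
        results = matcher.smarts_match(rule.smarts, mol, directives.copy(),
                                       all_matches=True)
        claimed = False
        for r in results:
            for t in r.selected:
                if types[t] == UNTYPED:
                    types[t] = rule.type_id
                    mol.atoms[t].atom_type = str(rule.type_id)
                    claimed = True
        if claimed:
            logger.debug("rule %s (%s) typed atoms", rule.type_id, rule.label)
    gated = [a.index for a in mol.atoms
             if types[a.index] == UNTYPED
             and any(r.element == a.element for r in ruleset)]
    for idx in gated:
        logger.warning("atom %d (%s) matched no typing rule", idx,
                       mol.atoms[idx].element)
    return types
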