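import logging

import numpy as np
import pytest

from molpat import fixtures, smiles

logging.getLogger("molpat").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


#: small graph-only molecules shared by round-trip and oracle tests
FIXTURE_SMILES = [
    "C",
    "CC",
    "CCO",
    "OCC",
    "CCCCCC",
    "C(C)(C)C",
    "c1ccccc1",
    "Oc1ccccc1",
    "C1CCCCC1",
    "CC(=O)NC1=CC=C(C=C1)O",
    "[n]1(C)c(=O)c2c3[n](C)c1(=O).[n]2(C)c[n]3",
    "c1ccc2c(c1)cc[nH]2",
    "CC(=S)[S-]",
    "[13CH4]",
    "[NH4+]",
    "F/C=C/F",
    "[C@H](F)(Cl)Br",
]


@pytest.fixture(params=FIXTURE_SMILES)
def fixture_mol(request):
    return smiles.parse_smiles(request.param)


@pytest.fixture
def chair_diaxial():
    return fixtures.cyclohexane("chair", {0: ("C", "axial"), 1: ("C", "axial")})
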