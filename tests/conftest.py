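import numpy as np
import pytest

from mcligand.ligand import topology_from_smiles
from mcligand.synthetic import fixture_ligands


@pytest.fixture(scope="session")
def archetypes():
    """The four benchmark ligand archetypes (deterministic)."""
    return fixture_ligands()


@pytest.fixture(scope="session")
def torsion_fixture(archetypes):
    return next(f for f in archetypes if f.archetype == "torsion_shift")


@pytest.fixture(scope="session")
def butanol():
    """Small acyclic test ligand: topology + relaxed conformer."""
    return topology_from_smiles("CCCCO", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
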