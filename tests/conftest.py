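import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from torsionforge.torsion_id import MolecularGraph, perceive_all
from torsionforge.fixtures_io import builtin_fixture, fixture_names


def embedded_graph(smiles: str, seed: int = 7, name: str = "") -> MolecularGraph:
    """Graph with deterministic ETKDG 3D coordinates, for pipeline tests."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    assert AllChem.EmbedMolecule(mol, params) == 0
    return MolecularGraph.from_rdkit(mol, name=name)


def perceived(smiles: str) -> MolecularGraph:
    return perceive_all(MolecularGraph.from_smiles(smiles))


@pytest.fixture(scope="session")
def all_fixtures():
    return {name: builtin_fixture(name) for name in fixture_names()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20190807)
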