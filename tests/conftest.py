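import warnings

import numpy as np
import pytest

from pharmscreen.chem_core import ConformerSettings, Molecule, generate_conformers
from pharmscreen.synthetic_data import (
    PlantedModelSpec,
    default_planted_model,
    plant_feature_clouds,
)

#: small conformer budget used throughout the tests
SMALL_SETTINGS = ConformerSettings(max_pool=30, max_conformers=3)


@pytest.fixture(scope="session")
def planted_model():
    return default_planted_model()


@pytest.fixture(scope="session")
def planted_library(planted_model):
    """Mid-size planted benchmark: 60 positives (jitter 0.2 Å) + 120 negatives."""
    spec = PlantedModelSpec(planted_model, n_positives=60, n_negatives=120,
                            jitter=0.2, seed=11)
    return plant_feature_clouds(spec)


def _mol_with_conformers(smiles: str, name: str, seed: int = 7,
                         settings: ConformerSettings = SMALL_SETTINGS) -> Molecule:
    mol = Molecule.from_smiles(smiles, name)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        generate_conformers(mol, settings, seed=seed)
    return mol


@pytest.fixture(scope="session")
def lca():
    return _mol_with_conformers("CC(CCC(=O)O)C1CCC2C3CCC4CC(O)CCC4(C)C3CCC12C",
                                "lithocholic_acid")


@pytest.fixture(scope="session")
def benzene():
    return _mol_with_conformers("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def cyclohexane():
    return _mol_with_conformers("C1CCCCC1", "cyclohexane")


@pytest.fixture(scope="session")
def acetate():
    return _mol_with_conformers("CC(=O)[O-]", "acetate")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
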