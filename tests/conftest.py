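import random
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings
from rdkit import Chem

from fragxscreen.chem import Molecule, parse_structure
from fragxscreen.synth import default_config, default_receptor_models, generate_library, simulate_dual_screen

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

REPO_ROOT = Path(__file__).resolve().parents[1]
EXAMPLES = REPO_ROOT / "examples"

# diverse, hand-picked fixture set used for invariance properties
FIXTURE_SMILES = {
    "benzene": "c1ccccc1",
    "histamine": "NCCc1c[nH]cn1",
    "serotonin": "NCCc1c[nH]c2ccc(O)cc12",
    "naphthalene": "c1ccc2ccccc2c1",
    "imidazole": "c1c[nH]cn1",
    "quinazoline": "c1ccc2ncncc2c1",
    "quinoxaline": "c1ccc2nccnc2c1",
    "benzimidazole": "c1ccc2[nH]cnc2c1",
    "aminopyrimidine": "Nc1ncccn1",
    "biphenyl": "c1ccc(-c2ccccc2)cc1",
    "pyridine": "c1ccncc1",
    "piperidine": "C1CCNCC1",
    "morpholine": "C1COCCN1",
    "diethyl_ether": "CCOCC",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "aniline": "Nc1ccccc1",
    "indole": "c1ccc2[nH]ccc2c1",
    "thiophene": "c1ccsc1",
    "furan": "c1ccoc1",
    "methylpiperazine_phenyl": "CN1CCN(c2ccccc2)CC1",
    "acetophenone": "CC(=O)c1ccccc1",
    "benzamide": "NC(=O)c1ccccc1",
    "tryptamine": "NCCc1c[nH]c2ccccc12",
}


@pytest.fixture(scope="session")
def fixture_molecules() -> dict[str, Molecule]:
    return {name: parse_structure(smi, name) for name, smi in FIXTURE_SMILES.items()}


def permuted_smiles(smiles: str, seed: int) -> str:
    """The same molecule written with a shuffled atom order."""
    mol = Chem.MolFromSmiles(smiles)
    order = list(range(mol.GetNumAtoms()))
    random.Random(seed).shuffle(order)
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)


@pytest.fixture(scope="session")
def default_library():
    """Synthetic 1000-fragment library at seed 0 (candidate pool is cached)."""
    return generate_library(default_config(seed=0))


@pytest.fixture(scope="session")
def default_screen(default_library):
    model_a, model_b = default_receptor_models()
    screen_a, screen_b, truth = simulate_dual_screen(
        default_library, model_a, model_b, seed=0
    )
    return screen_a, screen_b, truth
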