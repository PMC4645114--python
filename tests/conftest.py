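import numpy as np
import pytest
from rdkit import Chem

from ensemblevs.chemio import FixtureSpec, MoleculeRecord, generate_fixtures
from ensemblevs.pharmacophore import generate_conformers


def make_record(mol_id: str, smiles: str, label: str = "unknown") -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    return MoleculeRecord(id=mol_id, mol=mol, label=label)


@pytest.fixture(scope="session")
def benzene_3d() -> MoleculeRecord:
    return generate_conformers(make_record("benzene", "c1ccccc1"), max_confs=1, seed=1)


@pytest.fixture(scope="session")
def aspirin_3d() -> MoleculeRecord:
    return generate_conformers(
        make_record("aspirin", "CC(=O)Oc1ccccc1C(=O)O"), max_confs=3, seed=1
    )


@pytest.fixture(scope="session")
def small_fixture_bundle():
    spec = FixtureSpec(n_actives=20, decoy_ratio=20, n_structures=3, seed=42)
    return generate_fixtures(spec)


def rigid_transform(coords: np.ndarray, seed: int) -> np.ndarray:
    """Random proper rotation + translation of a coordinate set."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.uniform(-10, 10, size=3)
    return coords @ Q.T + t
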