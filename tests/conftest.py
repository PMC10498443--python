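import numpy as np
import pytest

from confsmith import forcefield as ff
from confsmith import molprep


@pytest.fixture(scope="session")
def prep():
    """Prepare a molecule graph from SMILES (cached per session)."""
    cache = {}

    def _prep(smiles, canonical=False):
        key = (smiles, canonical)
        if key not in cache:
            cache[key] = molprep.prepare(molprep.from_smiles(smiles), canonical=canonical)
        return cache[key]

    return _prep


@pytest.fixture(scope="session")
def param_for(prep):
    cache = {}

    def _param(smiles, **kw):
        key = (smiles, tuple(sorted(kw.items())))
        if key not in cache:
            cache[key] = ff.parametrize(prep(smiles), **kw)
        return cache[key]

    return _param


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def perturbed_coords(mg, seed=0, scale=0.1):
    """Reference-geometry coordinates jittered away from any minimum."""
    from rdkit.Chem import AllChem
    from rdkit import Chem

    m = Chem.Mol(mg.mol)
    AllChem.EmbedMolecule(m, randomSeed=7)
    xyz = np.asarray(m.GetConformer().GetPositions(), dtype=float)
    g = np.random.default_rng(seed)
    return xyz + scale * g.standard_normal(xyz.shape)
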