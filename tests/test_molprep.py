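"""Preprocessing: perception, stereo assignment, hydrogens, canonical order."""

import itertools

import numpy as np
import pytest
from rdkit import Chem
from scipy.sparse.csgraph import floyd_warshall

from confsmith import molprep
from confsmith.io import make_fixtures


class TestPerception:
    def test_methane_sp3(self, prep):
        mg = prep("C")
        heavy = mg.heavy_atoms()
        assert mg.hybridization(heavy[0]) == "sp3"

    def test_benzene_aromatic_single_ring(self, prep):
        mg = prep("c1ccccc1")
        ri = mg.mol.GetRingInfo()
        assert ri.NumRings() == 1
        assert all(mg.is_aromatic_atom(i) for i in mg.heavy_atoms())
        assert all(
            b.GetIsAromatic() for b in mg.mol.GetBonds()
            if b.GetBeginAtom().GetAtomicNum() > 1 and b.GetEndAtom().GetAtomicNum() > 1
        )

    def test_naphthalene_sssr_is_cyclomatic_count(self, prep):
        mg = prep("c1ccc2ccccc2c1")
        heavy_bonds = sum(
            1 for b in mg.mol.GetBonds()
            if b.GetBeginAtom().GetAtomicNum() > 1 and b.GetEndAtom().GetAtomicNum() > 1
        )
        assert mg.mol.GetRingInfo().NumRings() == heavy_bonds - 10 + 1 == 2

    def test_impossible_valence_rejected(self):
        mol = Chem.RWMol()
        c = mol.AddAtom(Chem.Atom(6))
        for _ in range(5):
            h = mol.AddAtom(Chem.Atom(9))
            mol.AddBond(c, h, Chem.BondType.SINGLE)
        with pytest.raises(molprep.PreparationError):
            molprep.perceive_atom_properties(molprep.from_rdkit(mol.GetMol()))


class TestStereoAssignment:
    def test_undefined_butene_becomes_trans(self, prep):
        mg = prep("CC=CC")
        bidx = next(
            b.GetIdx() for b in mg.mol.GetBonds()
            if b.GetBondType() == Chem.BondType.DOUBLE
        )
        assert mg.bond_stereo(bidx) == "trans"

    def test_cis_input_retained(self, prep):
        mg = prep(r"C/C=C\C")
        bidx = next(
            b.GetIdx() for b in mg.mol.GetBonds()
            if b.GetBondType() == Chem.BondType.DOUBLE
        )
        assert mg.bond_stereo(bidx) == "cis"

    def test_undefined_tetrahedral_left_unspecified(self, prep):
        mg = prep("CC(N)C(=O)O")
        center = next(
            a.GetIdx() for a in mg.mol.GetAtoms()
            if a.GetAtomicNum() == 6 and not a.GetIsAromatic()
            and sum(nb.GetAtomicNum() > 1 for nb in a.GetNeighbors()) == 3
            and sum(nb.GetAtomicNum() == 1 for nb in a.GetNeighbors()) == 1
        )
        assert mg.atom_stereo(center) == "unspecified"

    def test_defined_center_keeps_cip_label(self, prep):
        mg = prep("C[C@H](N)C(=O)O")
        labels = {mg.atom_stereo(i) for i in mg.heavy_atoms()}
        assert "S" in labels

    def test_stereo_from_3d_coordinates(self, prep):
        # build (R)-CHFClBr coordinates by hand and feed them as input 3D
        base = molprep.prepare(molprep.from_smiles("[C@H](F)(Cl)Br"))
        from confsmith import forcefield as ff
        from confsmith import distgeom as dg

        param = ff.parametrize(base)
        conf = dg.generate_random_conformer(base, param, rng=np.random.default_rng(0))
        stripped = Chem.RWMol(base.mol)
        for a in stripped.GetAtoms():
            a.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
        mg = molprep.MoleculeGraph(mol=stripped.GetMol(), coords_3d=conf.coords)
        out = molprep.assign_stereo(molprep.perceive_atom_properties(mg))
        want = base.mol.GetAtomWithIdx(0).GetChiralTag()
        got = out.mol.GetAtomWithIdx(0).GetChiralTag()
        assert got != Chem.ChiralType.CHI_UNSPECIFIED
        assert got == want


class TestHydrogens:
    @pytest.mark.parametrize(
        "smiles, n_h", [("C", 4), ("[NH4+]", 4), ("c1ccccc1", 6)]
    )
    def test_explicit_hydrogen_counts(self, prep, smiles, n_h):
        mg = prep(smiles)
        assert sum(1 for a in mg.mol.GetAtoms() if a.GetAtomicNum() == 1) == n_h

    def test_charge_and_heavy_graph_preserved(self):
        for smiles in ("[NH4+]", "CC(=O)[O-]", "c1ccncc1", "CS(=O)(=O)N"):
            raw = molprep.perceive_atom_properties(molprep.from_smiles(smiles))
            before_heavy = [a.GetAtomicNum() for a in raw.mol.GetAtoms()]
            before_charge = sum(a.GetFormalCharge() for a in raw.mol.GetAtoms())
            out = molprep.add_missing_hydrogens(raw)
            after_heavy = [
                a.GetAtomicNum() for a in out.mol.GetAtoms() if a.GetAtomicNum() > 1
            ]
            assert after_heavy == [z for z in before_heavy if z > 1]
            assert sum(a.GetFormalCharge() for a in out.mol.GetAtoms()) == before_charge


class TestCanonicalization:
    def test_permuted_inputs_identical(self):
        variants = ["CCCC", "C(C)CC", "C(CC)C"]
        serial = set()
        for smi in variants:
            mg = molprep.prepare(molprep.from_smiles(smi), canonical=True)
            serial.add(Chem.MolToSmiles(mg.mol, canonical=False))
        assert len(serial) == 1

    def test_idempotent(self, prep):
        mg = molprep.perceive_atom_properties(molprep.from_smiles("CC(=O)Oc1ccccc1"))
        mg = molprep.assign_stereo(mg)
        c1 = molprep.canonicalize(mg)
        c2 = molprep.canonicalize(c1)
        assert Chem.MolToSmiles(c1.mol, canonical=False) == Chem.MolToSmiles(
            c2.mol, canonical=False
        )

    def test_constitutional_isomers_differ(self):
        a = molprep.prepare(molprep.from_smiles("CCO"), canonical=True)
        b = molprep.prepare(molprep.from_smiles("COC"), canonical=True)
        assert Chem.MolToSmiles(a.mol) != Chem.MolToSmiles(b.mol)


class TestComponents:
    @pytest.mark.parametrize(
        "smiles, n", [("CC(=O)[O-].[Na+]", 2), ("CCO", 1), ("C.C.O", 3)]
    )
    def test_component_counts(self, smiles, n):
        mg = molprep.prepare(molprep.from_smiles(smiles))
        assert mg.component_ids is not None
        assert len(set(mg.component_ids.tolist())) == n

    def test_every_atom_labelled_once(self, prep):
        mg = molprep.prepare(molprep.from_smiles("CC(=O)[O-].[Na+]"))
        assert mg.component_ids.shape == (mg.n_atoms,)


class TestTopologicalDistances:
    def test_propane_and_cyclohexane(self, prep):
        mg = prep("CCC")
        heavy = mg.heavy_atoms()
        td = molprep.topological_distances(mg, heavy)
        ends = [k for k in range(3) if td[k].max() == 2]
        assert td[ends[0], ends[1]] == 2

        ring = prep("C1CCCCC1")
        heavy = ring.heavy_atoms()
        td = molprep.topological_distances(ring, heavy)
        assert td.max() == 3  # opposite ring atoms via the shorter arc

    def test_matches_floyd_warshall_oracle(self):
        rows = make_fixtures("smallmol", 20, seed=5)
        for smiles, _ in rows:
            mg = molprep.prepare(molprep.from_smiles(smiles))
            td = molprep.topological_distances(mg)
            adj = Chem.GetAdjacencyMatrix(mg.mol)
            oracle = floyd_warshall(adj.astype(float), directed=False)
            assert np.array_equal(td, oracle)
            assert np.array_equal(td, td.T)
            assert np.all(np.diag(td) == 0)
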