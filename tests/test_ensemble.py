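"""Symmetry mappings, Kabsch RMSD and greedy diversity selection."""

import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from confsmith import distgeom as dg
from confsmith import ensemble as ens
from confsmith import forcefield as ff


def brute_force_automorphisms(mg):
    """Exhaustive permutation check of the heavy-atom graph."""
    from rdkit import Chem

    mol = mg.mol
    heavy = mg.heavy_atoms()
    pos = {g: k for k, g in enumerate(heavy)}
    z = [mol.GetAtomWithIdx(a).GetAtomicNum() for a in heavy]
    edges = {}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in pos and j in pos:
            edges[frozenset((pos[i], pos[j]))] = b.GetBondTypeAsDouble()
    count = 0
    n = len(heavy)
    for perm in itertools.permutations(range(n)):
        if any(z[perm[k]] != z[k] for k in range(n)):
            continue
        ok = True
        for e, order in edges.items():
            a, b_ = tuple(e)
            if edges.get(frozenset((perm[a], perm[b_]))) != order:
                ok = False
                break
        if ok:
            count += 1
    return count


class TestSymmetryMappings:
    @pytest.mark.parametrize("smiles, expected", [
        ("c1ccccc1", 12),
        ("CC(C)(C)C", 24),
        ("C[C@H](N)C(=O)O", 1),
    ])
    def test_counts_match_brute_force(self, prep, smiles, expected):
        mg = prep(smiles)
        maps, cap_hit = ens.enumerate_symmetry_mappings(mg)
        assert len(maps) == expected == brute_force_automorphisms(mg)
        assert not cap_hit

    def test_identity_first_and_bijective(self, prep):
        mg = prep("CC(C)(C)C")
        maps, _ = ens.enumerate_symmetry_mappings(mg)
        n = len(mg.heavy_atoms())
        assert np.array_equal(maps[0], np.arange(n))
        for m in maps:
            assert sorted(m.tolist()) == list(range(n))

    def test_cap_reported(self, prep):
        mg = prep("c1ccccc1")
        maps, cap_hit = ens.enumerate_symmetry_mappings(mg, cap=5)
        assert len(maps) == 5
        assert cap_hit


class TestKabsch:
    def test_identical_zero(self, rng):
        x = rng.standard_normal((8, 3))
        assert ens.kabsch_rmsd(x, x) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_zero(self, rng):
        x = rng.standard_normal((8, 3))
        rot = Rotation.random(random_state=5).as_matrix()
        y = x @ rot.T + np.array([1.0, -2.0, 0.5])
        assert ens.kabsch_rmsd(x, y) < 1e-6

    def test_matches_independent_superposition(self, rng):
        # scipy's align_vectors is an independently implemented
        # least-squares superposition; rssd/sqrt(n) equals the RMSD
        for _ in range(10):
            a = rng.standard_normal((5, 3))
            b = rng.standard_normal((5, 3))
            ac = a - a.mean(axis=0)
            bc = b - b.mean(axis=0)
            _, rssd = Rotation.align_vectors(ac, bc)
            assert ens.kabsch_rmsd(a, b) == pytest.approx(
                rssd / np.sqrt(5), abs=1e-4)

    def test_symmetric_in_arguments(self, rng):
        a = rng.standard_normal((6, 3))
        b = rng.standard_normal((6, 3))
        assert ens.kabsch_rmsd(a, b) == pytest.approx(ens.kabsch_rmsd(b, a), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ens.kabsch_rmsd(np.zeros((0, 3)), np.zeros((0, 3)))


class TestMinSymmetryRmsd:
    def _benzene_conf(self, prep, rng):
        mg = prep("c1ccccc1")
        param = ff.parametrize(mg)
        return mg, dg.generate_random_conformer(mg, param, rng=rng)

    def test_in_plane_rotation_is_symmetry_equivalent(self, prep, rng):
        mg, conf = self._benzene_conf(prep, rng)
        heavy = mg.heavy_atoms()
        x = conf.coords[heavy]
        center = x.mean(axis=0)
        normal = np.linalg.svd(x - center)[2][2]
        rot = Rotation.from_rotvec(np.radians(60.0) * normal).as_matrix()
        rotated = conf.coords.copy()
        rotated[heavy] = (x - center) @ rot.T + center
        assert ens.min_symmetry_rmsd(mg, conf.coords, rotated) < 1e-3

    def test_automorphic_relabeling_needs_symmetry_mapping(self, prep, rng):
        # a distorted hexagon is not geometrically symmetric, so only the
        # matching ring automorphism recovers the zero distance
        mg = prep("c1ccccc1")
        heavy = mg.heavy_atoms()
        maps, _ = ens.enumerate_symmetry_mappings(mg)
        shift = next(m for m in maps if not np.array_equal(m, maps[0]))
        a = np.zeros((mg.n_atoms, 3))
        a[heavy] = rng.standard_normal((6, 3))  # arbitrary distorted geometry
        b = a.copy()
        b[heavy] = a[np.array(heavy)[shift]]
        assert ens.kabsch_rmsd(a[heavy], b[heavy]) > 1e-3
        assert ens.min_symmetry_rmsd(mg, a, b) < 1e-6

    def test_never_above_identity_mapping(self, prep, rng):
        mg, conf = self._benzene_conf(prep, rng)
        other = dg.generate_random_conformer(
            mg, ff.parametrize(mg), rng=np.random.default_rng(4))
        heavy = mg.heavy_atoms()
        ident = ens.kabsch_rmsd(conf.coords[heavy], other.coords[heavy])
        assert ens.min_symmetry_rmsd(mg, conf, other) <= ident + 1e-12

    def test_asymmetric_equals_identity_mapping(self, prep, rng):
        mg = prep("C[C@H](N)C(=O)O")
        param = ff.parametrize(mg)
        a = dg.generate_random_conformer(mg, param, rng=rng)
        b = dg.generate_random_conformer(mg, param, rng=np.random.default_rng(9))
        heavy = mg.heavy_atoms()
        assert ens.min_symmetry_rmsd(mg, a, b) == pytest.approx(
            ens.kabsch_rmsd(a.coords[heavy], b.coords[heavy]))

    def test_self_distance_zero(self, prep, rng):
        mg, conf = self._benzene_conf(prep, rng)
        assert ens.min_symmetry_rmsd(mg, conf, conf) == pytest.approx(0.0, abs=1e-9)


class TestCompileOutputEnsemble:
    def _candidates(self, prep, smiles, n, seed=0):
        mg = prep(smiles)
        param = ff.parametrize(mg)
        gen = dg.RandomConformerGenerator(mg, param)
        rng = np.random.default_rng(seed)
        return mg, [gen.generate(rng) for _ in range(n)]

    def test_near_duplicates_collapsed(self, prep):
        mg, cands = self._candidates(prep, "c1ccccc1", 4)
        out = ens.compile_output_ensemble(mg, cands)
        assert len(out) == 1
        assert out.conformers[0].energy == min(c.energy for c in cands)

    def test_max_size_enforced(self, prep):
        mg, cands = self._candidates(prep, "CC(C)CO", 8)
        out = ens.compile_output_ensemble(
            mg, cands, ens.SelectionSettings(rmsd_threshold=1e-6, max_size=3))
        assert len(out) <= 3

    def test_window_excludes_high_energy(self, prep):
        mg, cands = self._candidates(prep, "CC(C)CO", 4)
        shifted = [dg.Conformer(cands[0].coords + 50.0, cands[0].energy + 100.0)]
        out = ens.compile_output_ensemble(
            mg, cands + shifted, ens.SelectionSettings(energy_window=15.0))
        assert all(c.energy <= out.conformers[0].energy + 15.0 for c in out.conformers)

    def test_ordering_and_pairwise_invariants(self, prep):
        mg, cands = self._candidates(prep, "CC(C)CO", 10)
        out = ens.compile_output_ensemble(mg, cands)
        energies = [c.energy for c in out.conformers]
        assert energies == sorted(energies)
        for a, b in itertools.combinations(out.conformers, 2):
            assert ens.min_symmetry_rmsd(mg, a, b) >= 0.5 - 1e-9

    def test_empty_candidates_rejected(self, prep):
        with pytest.raises(ens.EmptyCandidateSet):
            ens.compile_output_ensemble(prep("CCO"), [])

    def test_input_structure_participates(self, prep):
        mg, cands = self._candidates(prep, "CC(C)CO", 3)
        inp = dg.Conformer(cands[0].coords.copy(), cands[0].energy)
        out = ens.compile_output_ensemble(
            mg, cands, input_structure=inp)
        # the duplicate of the input structure must not appear twice
        assert sum(
            1 for c in out.conformers
            if np.allclose(c.coords, inp.coords)
        ) == 1
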