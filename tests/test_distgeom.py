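"""Distance-geometry constraint construction, embedding and refinement."""

import numpy as np
import pytest
from rdkit import Chem

from confsmith import distgeom as dg
from confsmith import forcefield as ff
from confsmith import molprep


def bounds_for(prep, smiles):
    mg = prep(smiles)
    param = ff.parametrize(mg)
    bounds, emb = dg.build_distance_bounds(mg, param)
    return mg, param, bounds, emb


class TestDistanceBounds:
    def test_bonded_pair_fixed_at_reference_length(self, prep):
        mg, param, bounds, emb = bounds_for(prep, "CC")
        heavy = mg.heavy_atoms()
        la, lb = emb.index(heavy[0]), emb.index(heavy[1])
        k = np.flatnonzero(
            ((bounds.i == la) & (bounds.j == lb)) | ((bounds.i == lb) & (bounds.j == la))
        )[0]
        r0 = param.ref_bond_length(heavy[0], heavy[1])
        assert bounds.lower[k] == pytest.approx(r0)
        assert bounds.upper[k] == pytest.approx(r0)

    def test_geminal_pair_law_of_cosines(self, prep):
        mg, param, bounds, emb = bounds_for(prep, "CCC")
        heavy = mg.heavy_atoms()
        mid = next(
            h for h in heavy
            if sum(1 for nb in mg.mol.GetAtomWithIdx(h).GetNeighbors()
                   if nb.GetAtomicNum() > 1) == 2
        )
        ends = [h for h in heavy if h != mid]
        r1 = param.ref_bond_length(ends[0], mid)
        r2 = param.ref_bond_length(ends[1], mid)
        t0 = param.ref_angle(ends[0], mid, ends[1])
        expected = np.sqrt(r1**2 + r2**2 - 2 * r1 * r2 * np.cos(np.radians(t0)))
        la, lb = emb.index(ends[0]), emb.index(ends[1])
        k = np.flatnonzero(
            ((bounds.i == la) & (bounds.j == lb)) | ((bounds.i == lb) & (bounds.j == la))
        )[0]
        assert bounds.lower[k] == pytest.approx(expected, abs=1e-9)
        assert bounds.upper[k] == pytest.approx(expected, abs=1e-9)

    def test_nonlocal_lower_bound_from_covalent_radii(self, prep):
        mg, param, bounds, emb = bounds_for(prep, "CCCCCC")
        heavy = mg.heavy_atoms()
        td = molprep.topological_distances(mg)
        # find a carbon pair at topological distance 5
        pair = next(
            (a, b) for a in heavy for b in heavy if td[a, b] == 5
        )
        la, lb = emb.index(pair[0]), emb.index(pair[1])
        k = np.flatnonzero(
            ((bounds.i == la) & (bounds.j == lb)) | ((bounds.i == lb) & (bounds.j == la))
        )[0]
        expected = 2 * dg.COVALENT_RADII[6] + 1.5
        assert bounds.lower[k] == pytest.approx(expected)
        assert bounds.upper[k] == pytest.approx(float(np.sum(param.bond_r0)))

    def test_defined_double_bond_fixes_vicinal_distance(self, prep):
        for smiles, cis in ((r"C/C=C\C", True), ("C/C=C/C", False)):
            mg, param, bounds, emb = bounds_for(prep, smiles)
            heavy = mg.heavy_atoms()
            td = molprep.topological_distances(mg)
            ends = [(a, b) for a in heavy for b in heavy if a < b and td[a, b] == 3]
            la, lb = emb.index(ends[0][0]), emb.index(ends[0][1])
            k = np.flatnonzero(
                ((bounds.i == la) & (bounds.j == lb))
                | ((bounds.i == lb) & (bounds.j == la))
            )[0]
            assert bounds.lower[k] == pytest.approx(bounds.upper[k])
            # cis methyls sit much closer than trans
            if cis:
                assert bounds.lower[k] < 3.3
            else:
                assert bounds.lower[k] > 3.6

    def test_matrix_view_invariants(self, prep):
        _, _, bounds, _ = bounds_for(prep, "CC(C)CO")
        lo, up = bounds.as_matrices()
        assert np.array_equal(lo, lo.T) and np.array_equal(up, up.T)
        off = ~np.eye(bounds.n, dtype=bool)
        assert np.all(lo[off] > 0)
        assert np.all(lo[off] <= up[off])
        assert np.all(np.diag(lo) == 0) and np.all(np.diag(up) == 0)


class TestVolumeConstraints:
    def test_defined_stereocenter_one_sided(self, prep):
        mg = prep("[C@H](F)(Cl)Br")
        vols = dg.build_volume_constraints(mg)
        chiral = [v for v in vols if not (v.lo == 0 and v.hi == 0)]
        assert len(chiral) == 1
        v = chiral[0]
        assert (v.lo, v.hi) in ((0.5, 1000.0), (-1000.0, -0.5))

    def test_amide_nitrogen_planar(self, prep):
        mg = prep("NC=O")
        vols = dg.build_volume_constraints(mg)
        assert any(v.lo == 0 and v.hi == 0 for v in vols)

    def test_methane_unconstrained(self, prep):
        assert dg.build_volume_constraints(prep("C")) == []


class TestEmbed:
    def test_single_pair_hits_fixed_distance(self, rng):
        bounds = dg.DistanceBounds(
            n=2,
            i=np.array([0]), j=np.array([1]),
            lower=np.array([1.54]), upper=np.array([1.54]),
            tight=np.array([True]),
        )
        x = dg.embed(bounds, [], rng, init_range=3.0)
        assert np.linalg.norm(x[0] - x[1]) == pytest.approx(1.54, abs=1e-3)

    def test_signed_volume_sign_enforced(self, rng):
        # regular-ish 4-atom cluster forced into a specific handedness
        iu, ju = np.triu_indices(4, k=1)
        bounds = dg.DistanceBounds(
            n=4, i=iu, j=ju,
            lower=np.full(6, 1.5), upper=np.full(6, 1.8),
            tight=np.ones(6, dtype=bool),
        )
        for lo, hi in ((0.5, 1000.0), (-1000.0, -0.5)):
            vol = dg.VolumeConstraint((0, 1, 2, 3), lo, hi)
            x = dg.embed(bounds, [vol], rng, init_range=3.0)
            v = dg.signed_volume(x, (0, 1, 2, 3))
            assert np.sign(v) == np.sign(lo + hi)

    def test_deterministic_for_fixed_seed(self, prep):
        mg = prep("CC(C)CO")
        param = ff.parametrize(mg)
        bounds, emb = dg.build_distance_bounds(mg, param)
        vols = dg.build_volume_constraints(mg, embed_atoms=emb)
        a = dg.embed(bounds, vols, np.random.default_rng(9), init_range=4.0)
        b = dg.embed(bounds, vols, np.random.default_rng(9), init_range=4.0)
        assert np.array_equal(a, b)

    def test_unsatisfiable_triangle_fails(self, rng):
        bounds = dg.DistanceBounds(
            n=3,
            i=np.array([0, 0, 1]), j=np.array([1, 2, 2]),
            lower=np.array([1.0, 1.0, 10.0]), upper=np.array([1.0, 1.0, 10.0]),
            tight=np.ones(3, dtype=bool),
        )
        with pytest.raises(dg.EmbedError):
            dg.embed(bounds, [], rng, init_range=3.0)


class TestHydrogenPlacement:
    def _generated(self, prep, smiles, seed=0):
        mg = prep(smiles)
        param = ff.parametrize(mg)
        gen = dg.RandomConformerGenerator(mg, param)
        local = None
        for trial in range(10):
            try:
                local = dg.embed(
                    gen.bounds, gen.volumes, np.random.default_rng(seed + trial),
                    init_range=max(0.25 * mg.n_atoms, 3.0))
                break
            except dg.EmbedError:
                continue
        assert local is not None
        coords = np.zeros((mg.n_atoms, 3))
        placed = np.zeros(mg.n_atoms, dtype=bool)
        coords[gen.embedded] = local
        placed[gen.embedded] = True
        return mg, param, dg.place_hydrogens(mg, param, coords, placed), placed

    def test_sp3_completion_is_tetrahedral(self, prep):
        mg, param, x, placed = self._generated(prep, "CC(C)C")
        center = next(
            a.GetIdx() for a in mg.mol.GetAtoms()
            if a.GetAtomicNum() == 6 and a.GetDegree() == 4
            and sum(nb.GetAtomicNum() > 1 for nb in a.GetNeighbors()) == 3
        )
        h = next(nb.GetIdx() for nb in mg.mol.GetAtomWithIdx(center).GetNeighbors()
                 if nb.GetAtomicNum() == 1)
        for nb in mg.mol.GetAtomWithIdx(center).GetNeighbors():
            if nb.GetIdx() == h or nb.GetAtomicNum() == 1:
                continue
            u = x[h] - x[center]
            v = x[nb.GetIdx()] - x[center]
            ang = np.degrees(np.arccos(
                np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v)))
            assert ang == pytest.approx(109.5, abs=5.0)

    def test_aromatic_hydrogens_in_ring_plane(self, prep):
        mg, param, x, _ = self._generated(prep, "c1ccccc1")
        ring = mg.heavy_atoms()
        centered = x[ring] - x[ring].mean(axis=0)
        normal = np.linalg.svd(centered)[2][2]
        for a in mg.mol.GetAtoms():
            if a.GetAtomicNum() == 1:
                d = x[a.GetIdx()] - x[ring].mean(axis=0)
                assert abs(np.dot(d, normal)) < 0.05

    def test_water_angle_near_equilibrium(self, prep):
        mg = prep("O")
        param = ff.parametrize(mg)
        coords = np.zeros((3, 3))
        placed = np.array([a.GetAtomicNum() > 1 for a in mg.mol.GetAtoms()])
        x = dg.place_hydrogens(mg, param, coords, placed)
        hs = [a.GetIdx() for a in mg.mol.GetAtoms() if a.GetAtomicNum() == 1]
        o = mg.heavy_atoms()[0]
        u, v = x[hs[0]] - x[o], x[hs[1]] - x[o]
        ang = np.degrees(np.arccos(np.dot(u, v) / np.linalg.norm(u) / np.linalg.norm(v)))
        t0 = param.ref_angle(hs[0], o, hs[1])
        assert ang == pytest.approx(t0, abs=5.0)


class TestRefine:
    def test_stretched_ethane_recovers_reference_length(self, prep, rng):
        mg = prep("CC")
        param = ff.parametrize(mg)
        conf0 = dg.generate_random_conformer(mg, param, rng=rng)
        heavy = mg.heavy_atoms()
        x = conf0.coords.copy()
        axis = x[heavy[1]] - x[heavy[0]]
        axis /= np.linalg.norm(axis)
        # displace one methyl group to stretch the C-C bond to 2.0 A
        shift = (2.0 - np.linalg.norm(x[heavy[1]] - x[heavy[0]])) * axis
        side = [heavy[1]] + [nb.GetIdx() for nb in
                             mg.mol.GetAtomWithIdx(heavy[1]).GetNeighbors()
                             if nb.GetAtomicNum() == 1]
        x[side] += shift
        out = dg.refine(param, x, stop_criterion="gradient_norm", stop_threshold=0.01)
        r = np.linalg.norm(out.coords[heavy[0]] - out.coords[heavy[1]])
        assert r == pytest.approx(param.ref_bond_length(*heavy), abs=0.02)

    def test_energy_never_increases(self, prep, rng):
        mg = prep("CC(C)CO")
        param = ff.parametrize(mg)
        conf = dg.generate_random_conformer(mg, param, rng=rng)
        x = conf.coords + 0.05 * np.random.default_rng(0).standard_normal(conf.coords.shape)
        e_in = ff.energy(param, x).total
        out = dg.refine(param, x)
        assert out.energy <= e_in + 1e-9

    def test_already_minimized_input_unchanged(self, prep, rng):
        mg = prep("CCO")
        param = ff.parametrize(mg)
        conf = dg.generate_random_conformer(
            mg, param, dg.DGSettings(stop_threshold=0.01), rng)
        again = dg.refine(param, conf.coords, stop_criterion="energy_delta",
                          stop_threshold=0.001)
        assert again.energy == pytest.approx(conf.energy, abs=0.01)


class TestStereoCheck:
    def test_embedded_configuration_recovered(self, prep, rng):
        mg = prep("C[C@H](N)C(=O)O")
        param = ff.parametrize(mg)
        conf = dg.generate_random_conformer(mg, param, rng=rng)
        assert dg.stereo_ok(mg, conf.coords)

    def test_mirror_image_flips_all_centers(self, prep, rng):
        mg = prep("C[C@H](N)C(=O)O")
        param = ff.parametrize(mg)
        conf = dg.generate_random_conformer(mg, param, rng=rng)
        mirrored = conf.coords * np.array([-1.0, 1.0, 1.0])
        checks = dg.check_stereo(mg, mirrored)
        atoms = {k: v for k, v in checks.items() if k[0] == "atom"}
        assert atoms and not any(atoms.values())

    def test_wrong_double_bond_geometry_flagged(self, prep, rng):
        cis = prep(r"C/C=C\C")
        trans = prep("C/C=C/C")
        param = ff.parametrize(trans)
        conf = dg.generate_random_conformer(trans, param, rng=rng)
        # trans coordinates, cis declaration (same atom indexing)
        checks = dg.check_stereo(cis, conf.coords)
        assert not all(checks.values())


class TestGenerateRandomConformer:
    def test_benzene_planar_with_good_bonds(self, prep, rng):
        mg = prep("c1ccccc1")
        param = ff.parametrize(mg)
        conf = dg.generate_random_conformer(mg, param, rng=rng)
        heavy = mg.heavy_atoms()
        centered = conf.coords[heavy] - conf.coords[heavy].mean(axis=0)
        assert np.linalg.svd(centered)[1][2] < 0.1
        for k, (i, j) in enumerate(param.bond_idx):
            r = np.linalg.norm(conf.coords[i] - conf.coords[j])
            assert abs(r - param.bond_r0[k]) < 0.05

    def test_alanine_stereo_stable_across_seeds(self, prep):
        mg = prep("C[C@@H](N)C(=O)O")  # (S)-alanine
        param = ff.parametrize(mg)
        gen = dg.RandomConformerGenerator(mg, param)
        for seed in range(15):
            conf = gen.generate(np.random.default_rng(seed))
            assert dg.stereo_ok(mg, conf.coords)

    def test_trial_cap_respected(self, prep, monkeypatch):
        mg = prep("CC(C)CO")
        param = ff.parametrize(mg)
        gen = dg.RandomConformerGenerator(mg, param)
        # unsatisfiable hook: every tight pair demands 1 A and 10 A at once
        gen.bounds = dg.DistanceBounds(
            n=gen.bounds.n,
            i=np.array([0, 0, 1]), j=np.array([1, 2, 2]),
            lower=np.array([1.0, 1.0, 10.0]), upper=np.array([1.0, 1.0, 10.0]),
            tight=np.ones(3, dtype=bool),
        )
        calls = {"n": 0}
        orig = dg.embed

        def counting_embed(*a, **kw):
            calls["n"] += 1
            return orig(*a, **kw)

        monkeypatch.setattr(dg, "embed", counting_embed)
        with pytest.raises(dg.GenerationError):
            gen.generate(np.random.default_rng(0))
        assert calls["n"] == 10

    def test_fixed_seed_reproducible(self, prep):
        mg = prep("CC(C)CO")
        param = ff.parametrize(mg)
        gen = dg.RandomConformerGenerator(mg, param)
        a = gen.generate(np.random.default_rng(77))
        b = gen.generate(np.random.default_rng(77))
        assert np.array_equal(a.coords, b.coords)
        assert a.energy == b.energy
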