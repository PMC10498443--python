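"""Fragmentation, fragment conformers, library and FCC enumeration."""

import numpy as np
import pytest
from rdkit import Chem

from confsmith import distgeom as dg
from confsmith import molprep
from confsmith import systematic as sy


class TestFragmentation:
    def test_cyclohexane_single_fragment(self, prep):
        res = sy.fragment_molecule(prep("C1CCCCC1"))
        assert len(res.fragments) == 1
        assert res.fragments[0].links == ()

    def test_biphenyl_two_fragments_one_link(self, prep):
        res = sy.fragment_molecule(prep("c1ccc(-c2ccccc2)cc1"))
        assert len(res.fragments) == 2
        assert len(res.cut_bonds) == 1

    def test_fragment_count_is_cut_count_plus_one(self, prep):
        for smiles in ("CCCCCC", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "CC(=O)NC1CCCCC1"):
            res = sy.fragment_molecule(prep(smiles))
            assert len(res.fragments) == len(res.cut_bonds) + 1

    def test_cores_partition_molecule(self, prep):
        mg = prep("CC(C)Cc1ccc(cc1)C(C)C(=O)O")
        res = sy.fragment_molecule(mg)
        cores = [set(f.core_atoms) for f in res.fragments]
        union = set().union(*cores)
        assert union == set(range(mg.n_atoms))
        assert sum(len(c) for c in cores) == mg.n_atoms

    def test_rejoining_links_reconstructs_graph(self, prep):
        mg = prep("CC(=O)NC1CCCCC1")
        res = sy.fragment_molecule(mg)
        seen_bonds = set()
        for f in res.fragments:
            core = set(f.core_atoms)
            for b in mg.mol.GetBonds():
                i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
                if i in core and j in core:
                    seen_bonds.add((min(i, j), max(i, j)))
            for l in f.links:
                seen_bonds.add((min(l.inside, l.outside), max(l.inside, l.outside)))
        all_bonds = {
            (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
             max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
            for b in mg.mol.GetBonds()
        }
        assert seen_bonds == all_bonds

    def test_rings_never_split(self, prep):
        mg = prep("CC(C)Cc1ccc(cc1)C(C)C(=O)O")
        res = sy.fragment_molecule(mg)
        for (i, j, bidx, _) in res.cut_bonds:
            assert not mg.mol.GetBondWithIdx(bidx).IsInRing()

    def test_amide_bond_cut_and_flagged(self, prep):
        res = sy.fragment_molecule(prep("CC(=O)NC1CCCCC1"))
        amides = [c for c in res.cut_bonds if c[3]]
        assert len(amides) == 1

    def test_terminal_hydrogen_rotors_not_cut(self, prep):
        res = sy.fragment_molecule(prep("Cc1ccccc1O"))  # methyl + hydroxyl
        assert len(res.cut_bonds) == 0


class TestClassification:
    def test_phenyl_rigid(self, prep):
        mg = prep("c1ccc(-c2ccccc2)cc1")
        res = sy.fragment_molecule(mg)
        assert all(f.frag_class == "rigid" for f in res.fragments)

    def test_cyclohexyl_flexible_ring(self, prep):
        mg = prep("CC(=O)NC1CCCCC1")
        res = sy.fragment_molecule(mg)
        assert "flexible_ring" in {f.frag_class for f in res.fragments}

    def test_chain_with_internal_rotor_flexible(self, prep):
        mg = prep("CCCCCC")
        heavy = mg.heavy_atoms()
        hs = [a.GetIdx() for a in mg.mol.GetAtoms() if a.GetAtomicNum() == 1]
        frag = sy.Fragment(core_atoms=tuple(heavy) + tuple(hs), links=())
        assert sy.classify_fragment(frag, mg) == "flexible_chain"


class TestCappedFragments:
    def test_partner_atoms_kept_and_capped(self, prep):
        mg = prep("c1ccc(-c2ccccc2)cc1")
        res = sy.fragment_molecule(mg)
        capped, l2p, masked = sy.build_capped_fragment(mg, res.fragments[0])
        parents = set(l2p[l2p >= 0].tolist())
        frag = res.fragments[0]
        assert set(frag.core_atoms) <= parents
        assert {l.outside for l in frag.links} <= parents
        assert not masked

    def test_masked_stereocenter_flagged(self, prep):
        # capping turns the vinyl substituent into a methyl, collapsing
        # the stereocenter's substituent distinction
        mg = prep("C[C@@H](N)/C=C/c1ccccc1")
        res = sy.fragment_molecule(mg)
        flags = []
        for f in res.fragments:
            _, _, masked = sy.build_capped_fragment(mg, f)
            flags.append(masked)
        assert any(flags)


class TestFragmentLibrary:
    def test_cache_hit_skips_generation(self, prep, rng):
        mg = prep("CC(=O)NC1CCCCC1")
        res = sy.fragment_molecule(mg)
        lib = sy.FragmentLibrary()
        frag = res.fragments[0]
        sy.fragment_conformers(frag, mg, lib, rng=rng)
        misses = lib.misses
        sy.fragment_conformers(frag, mg, lib, rng=rng)
        assert lib.misses == misses
        assert lib.hits >= 1

    def test_round_trip_under_atom_permutation(self, rng):
        lib = sy.FragmentLibrary()
        a = molprep.prepare(molprep.from_smiles("CC(=O)NC1CCCCC1"))
        b = molprep.prepare(molprep.from_smiles("C1CCCCC1NC(C)=O"))
        fa = sy.fragment_molecule(a)
        fb = sy.fragment_molecule(b)
        ring_a = next(f for f in fa.fragments if f.frag_class == "flexible_ring")
        ring_b = next(f for f in fb.fragments if f.frag_class == "flexible_ring")
        sa = sy.fragment_conformers(ring_a, a, lib, rng=rng)
        misses = lib.misses
        sb = sy.fragment_conformers(ring_b, b, lib, rng=rng)
        assert lib.misses == misses  # served from cache despite permutation
        # identical conformer sets up to atom relabeling: compare sorted
        # interatomic distance multisets
        for ca, cb in zip(sa.conformers, sb.conformers):
            da = np.sort(np.linalg.norm(
                ca.coords[:, None] - ca.coords[None, :], axis=-1).ravel())
            db = np.sort(np.linalg.norm(
                cb.coords[:, None] - cb.coords[None, :], axis=-1).ravel())
            assert np.allclose(da, db, atol=1e-6)
            assert ca.energy == pytest.approx(cb.energy, abs=1e-6)

    def test_save_load_round_trip(self, tmp_path, prep, rng):
        mg = prep("c1ccc(-c2ccccc2)cc1")
        res = sy.fragment_molecule(mg)
        lib = sy.FragmentLibrary()
        before = sy.fragment_conformers(res.fragments[0], mg, lib, rng=rng)
        path = str(tmp_path / "frags.sdf")
        lib.save(path)
        lib2 = sy.FragmentLibrary(path)
        assert len(lib2) == len(lib)
        after = sy.fragment_conformers(res.fragments[0], mg, lib2, rng=rng)
        assert lib2.hits == 1
        for x, y in zip(before.conformers, after.conformers):
            assert np.allclose(x.coords, y.coords, atol=1e-3)

    def test_rigid_fragment_single_conformer(self, prep, rng):
        mg = prep("c1ccc(-c2ccccc2)cc1")
        res = sy.fragment_molecule(mg)
        lib = sy.FragmentLibrary()
        out = sy.fragment_conformers(res.fragments[0], mg, lib, rng=rng)
        assert len(out.conformers) == 1

    def test_cyclohexane_fragment_multiple_ring_conformers(self, prep, rng):
        mg = prep("CC(=O)NC1CCCCC1")
        res = sy.fragment_molecule(mg)
        ring = next(f for f in res.fragments if f.frag_class == "flexible_ring")
        lib = sy.FragmentLibrary()
        out = sy.fragment_conformers(ring, mg, lib, rng=rng)
        assert len(out.conformers) >= 2  # chair + at least one twist-boat


def _make_sets(energy_lists):
    """Minimal FragmentConformerSet stand-ins for enumeration tests."""
    sets = []
    for energies in energy_lists:
        confs = [dg.Conformer(np.zeros((1, 3)), e) for e in energies]
        sets.append(
            sy.FragmentConformerSet(
                fragment=sy.Fragment(core_atoms=(0,), links=()),
                conformers=confs,
                local_to_parent=np.array([0]),
                capped=None,
            )
        )
    return sets


class TestFCCEnumeration:
    def test_full_product_within_window(self):
        fccs = sy.enumerate_fccs(_make_sets([[0.0, 1.0], [0.0, 1.0, 2.0]]), window=15.0)
        assert len(fccs) == 6
        energies = [f.energy for f in fccs]
        assert energies == sorted(energies)

    def test_window_threshold_arithmetic(self):
        # members {0, 10} x {0, 10}, window 5 -> threshold 7.5 keeps only (0, 0)
        fccs = sy.enumerate_fccs(_make_sets([[0.0, 10.0], [0.0, 10.0]]), window=5.0)
        assert len(fccs) == 1
        assert fccs[0].energy == 0.0

    def test_cap_keeps_lowest(self):
        fccs = sy.enumerate_fccs(
            _make_sets([[0.0, 1.0], [0.0, 2.0, 4.0]]), window=100.0, cap=2)
        assert len(fccs) == 2
        assert [f.energy for f in fccs] == [0.0, 1.0]

    def test_energy_is_member_sum(self):
        sets = _make_sets([[0.5, 1.5], [0.25]])
        for fcc in sy.enumerate_fccs(sets, window=50.0):
            expect = sum(
                sets[d].conformers[k].energy for d, k in enumerate(fcc.indices)
            )
            assert fcc.energy == pytest.approx(expect)
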