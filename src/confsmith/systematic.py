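"""Systematic conformer sampling support: fragmentation and fragment
conformers.

The molecule is decomposed into building blocks by cutting rotatable
bonds; ring systems are never split.  Cut ("link") bonds keep both of
their atoms: each fragment consists of a core atom set plus the partner
atom of every cut bond, whose remaining valence is capped with hydrogens
for fragment-level parametrization.  This one-atom overlap makes the
incremental energy bookkeeping of the torsion driver exact - every
angle-bend, stretch-bend and out-of-plane interaction of the parent
molecule lies entirely inside one fragment, and only the rotor-bond
stretch, the rotor torsions and the through-space nonbonded interactions
cross fragment boundaries.

Fragment conformers are served from an on-disk/in-memory library keyed by
the canonical SMILES of the capped fragment (including stereo) and are
generated on the fly on a miss: a single structure for rigid fragments, a
stochastically sampled set for flexible rings.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from . import distgeom as dg
from . import forcefield as ff
from . import stochastic
from .molprep import MoleculeGraph, from_rdkit, prepare

__all__ = [
    "Fragment",
    "FragmentConformerSet",
    "FragmentLibrary",
    "FCC",
    "FragmentationResult",
    "fragment_molecule",
    "classify_fragment",
    "build_capped_fragment",
    "fragment_conformers",
    "enumerate_fccs",
    "FragmentSamplingSettings",
]

FCC_CAP = 100_000
FCC_WINDOW_SAFETY = 1.5


@dataclass(frozen=True)
class LinkBond:
    """A cut bond: ``inside`` belongs to the fragment core, ``outside`` is
    the retained partner atom of the adjacent fragment."""

    inside: int
    outside: int
    bond_idx: int
    amide: bool = False


@dataclass
class Fragment:
    core_atoms: tuple[int, ...]            # partition of the molecule
    links: tuple[LinkBond, ...]
    frag_class: str = ""                   # rigid | flexible_chain | flexible_ring

    @property
    def atoms_with_partners(self) -> tuple[int, ...]:
        extra = tuple(l.outside for l in self.links)
        return tuple(sorted(set(self.core_atoms) | set(extra)))


@dataclass
class FragmentationResult:
    fragments: list[Fragment]
    cut_bonds: list[tuple[int, int, int, bool]]  # (i, j, bond_idx, amide)


@dataclass
class FragmentConformerSet:
    fragment: Fragment
    conformers: list[dg.Conformer]     # local (capped-fragment) coordinates
    local_to_parent: np.ndarray        # -1 for cap hydrogens
    capped: MoleculeGraph


@dataclass(frozen=True)
class FCC:
    """One conformer index per fragment; energy is the member sum."""

    indices: tuple[int, ...]
    energy: float


# ---------------------------------------------------------------------------
# fragmentation


def _is_amide_bond(bond: Chem.Bond) -> bool:
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    for c, n in ((a, b), (b, a)):
        if c.GetAtomicNum() == 6 and n.GetAtomicNum() == 7:
            mol = c.GetOwningMol()
            for nb in c.GetNeighbors():
                bb = mol.GetBondBetweenAtoms(c.GetIdx(), nb.GetIdx())
                if nb.GetAtomicNum() == 8 and bb.GetBondType() == Chem.BondType.DOUBLE:
                    return True
    return False


def _moves_only_hydrogens(atom: Chem.Atom, across: int) -> bool:
    """True if rotating the bond towards ``atom`` permutes hydrogens only."""
    return all(
        nb.GetAtomicNum() == 1
        for nb in atom.GetNeighbors()
        if nb.GetIdx() != across
    )


def _on_linear_axis(atom: Chem.Atom) -> bool:
    """Atom participates in a triple bond or a cumulated double-bond axis."""
    mol = atom.GetOwningMol()
    n_double = 0
    for nb in atom.GetNeighbors():
        bt = mol.GetBondBetweenAtoms(atom.GetIdx(), nb.GetIdx()).GetBondType()
        if bt == Chem.BondType.TRIPLE:
            return True
        if bt == Chem.BondType.DOUBLE:
            n_double += 1
    return n_double >= 2


def is_rotatable(bond: Chem.Bond) -> bool:
    """Shipped cut rule: single, acyclic, heavy-heavy, both ends carrying
    at least one further heavy neighbor, not on a linear axis, and the
    rotation must move heavy atoms on both sides."""
    if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
        return False
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
        return False
    if _on_linear_axis(a) or _on_linear_axis(b):
        return False
    if _moves_only_hydrogens(a, b.GetIdx()) or _moves_only_hydrogens(b, a.GetIdx()):
        return False
    return True


def fragment_molecule(mg: MoleculeGraph) -> FragmentationResult:
    """Cut all rotatable bonds; hydrogens follow their heavy atom.

    Amide C-N bonds are cut as well but flagged, which restricts their
    torsion angles to the planar pair during driving.  A molecule without
    cuttable bonds yields a single fragment.
    """
    mol = mg.mol
    cut = []
    for b in mol.GetBonds():
        if is_rotatable(b):
            cut.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetIdx(),
                        _is_amide_bond(b)))

    cut_ids = {c[2] for c in cut}
    n = mol.GetNumAtoms()
    # connected components of the graph minus cut bonds
    comp = np.full(n, -1, dtype=int)
    cid = 0
    for start in range(n):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = cid
        while stack:
            cur = stack.pop()
            for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
                j = nb.GetIdx()
                bid = mol.GetBondBetweenAtoms(cur, j).GetIdx()
                if bid in cut_ids or comp[j] >= 0:
                    continue
                comp[j] = cid
                stack.append(j)
        cid += 1

    frags = []
    for c in range(cid):
        core = tuple(int(i) for i in np.flatnonzero(comp == c))
        links = []
        for (i, j, bid, amide) in cut:
            if comp[i] == c:
                links.append(LinkBond(i, j, bid, amide))
            elif comp[j] == c:
                links.append(LinkBond(j, i, bid, amide))
        frag = Fragment(core_atoms=core, links=tuple(links))
        frag.frag_class = classify_fragment(frag, mg)
        frags.append(frag)
    return FragmentationResult(fragments=frags, cut_bonds=cut)


def classify_fragment(frag: Fragment, mg: MoleculeGraph) -> str:
    """rigid / flexible_chain / flexible_ring per ring saturation and
    remaining internal rotors."""
    mol = mg.mol
    core = set(frag.core_atoms)
    ring_bonds = [
        b for b in mol.GetBonds()
        if b.IsInRing()
        and b.GetBeginAtomIdx() in core
        and b.GetEndAtomIdx() in core
    ]
    if ring_bonds:
        if all(b.GetIsAromatic() for b in ring_bonds):
            return "rigid"
        return "flexible_ring"
    internal_rotors = [
        b for b in mol.GetBonds()
        if b.GetBeginAtomIdx() in core and b.GetEndAtomIdx() in core
        and is_rotatable(b)
    ]
    return "flexible_chain" if internal_rotors else "rigid"


# ---------------------------------------------------------------------------
# capped fragments


def build_capped_fragment(
    mg: MoleculeGraph, frag: Fragment
) -> tuple[MoleculeGraph, np.ndarray, bool]:
    """Extract core + partner atoms; cap open partner valences with H.

    Returns the prepared fragment graph, the local-to-parent index map
    (-1 for cap hydrogens), and a flag marking fragments whose parent
    stereo had to be re-imposed because capping made it locally
    non-stereogenic.  Such "masked" stereo is invisible to the canonical
    fragment key, so these fragments must bypass the fragment library.
    """
    mol = mg.mol
    keep = set(frag.core_atoms)
    partners = {l.outside for l in frag.links}
    keep |= partners
    for i in frag.core_atoms:
        for nb in mol.GetAtomWithIdx(i).GetNeighbors():
            if nb.GetAtomicNum() == 1:
                keep.add(nb.GetIdx())

    work = Chem.RWMol(mol)
    for a in work.GetAtoms():
        a.SetIntProp("_parent_idx", a.GetIdx())
    for idx in sorted(set(range(mol.GetNumAtoms())) - keep, reverse=True):
        work.RemoveAtom(idx)

    for a in work.GetAtoms():
        if a.GetIntProp("_parent_idx") in partners:
            # partner keeps element and charge; dangling valence -> H caps
            a.SetIsAromatic(False)
            a.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
            a.SetNoImplicit(False)
            a.SetNumExplicitHs(0)
            for b in a.GetBonds():
                if b.GetBondType() == Chem.BondType.AROMATIC:
                    b.SetBondType(Chem.BondType.SINGLE)

    capped = work.GetMol()
    try:
        Chem.SanitizeMol(capped)
    except Exception as exc:  # pragma: no cover - capping is total for sane input
        raise ff.ParametrizationError(f"capping failed for fragment: {exc}") from exc
    capped = Chem.AddHs(capped)
    fmg = prepare(from_rdkit(capped, name="fragment"), canonical=False)

    l2p = np.full(fmg.n_atoms, -1, dtype=int)
    for a in fmg.mol.GetAtoms():
        if a.HasProp("_parent_idx"):
            l2p[a.GetIdx()] = a.GetIntProp("_parent_idx")

    # Re-impose the parent's stereo descriptors: capping may have made a
    # center locally non-stereogenic (two cap-identical substituents), in
    # which case stereo perception has wiped the descriptor even though
    # the parent configuration must still be enforced geometrically.
    p2l = {int(p): l for l, p in enumerate(l2p) if p >= 0}
    work2 = Chem.RWMol(fmg.mol)
    changed = False
    for center, nbrs, _sign in dg.tetrahedral_stereocenters(mol):
        if center not in p2l:
            continue
        la = work2.GetAtomWithIdx(p2l[center])
        want = mol.GetAtomWithIdx(center).GetChiralTag()
        if la.GetChiralTag() != want and all(n in p2l for n in nbrs):
            la.SetChiralTag(want)
            changed = True
    for bidx, (ra, rb, cis) in dg._defined_double_bonds(mol).items():
        b = mol.GetBondWithIdx(bidx)
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if not all(x in p2l for x in (i, j, ra, rb)):
            continue
        lb = work2.GetBondBetweenAtoms(p2l[i], p2l[j])
        if lb is None or lb.GetStereo() != Chem.BondStereo.STEREONONE:
            continue
        lb.SetStereoAtoms(p2l[ra], p2l[rb])
        lb.SetStereo(
            Chem.BondStereo.STEREOCIS if cis else Chem.BondStereo.STEREOTRANS
        )
        changed = True
    if changed:
        fmg.mol = work2.GetMol()
    return fmg, l2p, changed


def fragment_key(capped: MoleculeGraph) -> str:
    return Chem.MolToSmiles(Chem.RemoveHs(Chem.Mol(capped.mol)), isomericSmiles=True)


def _canonical_order(mol: Chem.Mol) -> np.ndarray:
    """Full canonical ordering (ties broken) including hydrogens."""
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=True, includeChirality=True))
    return np.asarray(ranks, dtype=int)


# ---------------------------------------------------------------------------
# fragment library


@dataclass
class FragmentSamplingSettings:
    """Sampling intensity for on-the-fly fragment conformer generation.

    Flexible rings are sampled stochastically with a reduced cap and
    check period relative to whole-molecule sampling: ring fragments are
    small, their conformer count is low (chair/boat families), and the
    resulting ensembles are cached in the fragment library.
    """

    ring_max_samples: int = 50
    ring_period: int = 10
    ring_energy_window: float = 10.0
    dg: dg.DGSettings = field(default_factory=lambda: dg.DGSettings(
        stop_criterion="gradient_norm", stop_threshold=0.5))


class FragmentLibrary:
    """Canonical-key conformer store, optionally persisted as tagged SDF."""

    def __init__(self, path: Optional[str] = None):
        self._store: dict[str, list[tuple[float, np.ndarray]]] = {}
        self.path = path
        self.hits = 0
        self.misses = 0
        if path is not None:
            try:
                self._load(path)
            except OSError:
                pass

    def _load(self, path: str) -> None:
        supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=True)
        for m in supplier:
            if m is None or not m.HasProp("FragmentKey"):
                continue
            key = m.GetProp("FragmentKey")
            energy = float(m.GetProp("Energy"))
            order = _canonical_order(m)
            coords = np.asarray(m.GetConformer().GetPositions(), dtype=float)
            canon = np.empty_like(coords)
            canon[order] = coords
            self._store.setdefault(key, []).append((energy, canon))

    def save(self, path: Optional[str] = None) -> int:
        from rdkit.Geometry import Point3D

        path = path or self.path
        if path is None:
            raise ValueError("no library path given")
        writer = Chem.SDWriter(path)
        writer.SetForceV3000(False)
        count = 0
        for key, entries in sorted(self._store.items()):
            mol = Chem.AddHs(Chem.MolFromSmiles(key))
            order = _canonical_order(mol)
            for energy, canon in entries:
                conf = Chem.Conformer(mol.GetNumAtoms())
                for i in range(mol.GetNumAtoms()):
                    conf.SetAtomPosition(i, Point3D(*map(float, canon[order[i]])))
                m2 = Chem.Mol(mol)
                m2.RemoveAllConformers()
                m2.AddConformer(conf, assignId=True)
                m2.SetProp("FragmentKey", key)
                m2.SetProp("Energy", f"{energy:.4f}")
                writer.write(m2)
                count += 1
        writer.close()
        return count

    def lookup(self, key: str, capped: MoleculeGraph) -> Optional[list[dg.Conformer]]:
        entries = self._store.get(key)
        if entries is None:
            self.misses += 1
            return None
        self.hits += 1
        order = _canonical_order(capped.mol)
        out = []
        for energy, canon in entries:
            out.append(dg.Conformer(canon[order], energy))
        return out

    def store(self, key: str, capped: MoleculeGraph, conformers: Sequence[dg.Conformer]) -> None:
        order = _canonical_order(capped.mol)
        entries = []
        for c in conformers:
            canon = np.empty_like(c.coords)
            canon[order] = c.coords
            entries.append((c.energy, canon))
        self._store[key] = entries

    def __len__(self) -> int:
        return len(self._store)


# ---------------------------------------------------------------------------
# fragment conformers


def fragment_conformers(
    frag: Fragment,
    mg: MoleculeGraph,
    lib: FragmentLibrary,
    settings: Optional[FragmentSamplingSettings] = None,
    rng: Optional[np.random.Generator] = None,
) -> FragmentConformerSet:
    """Conformers of one fragment, from the library or generated on the fly.

    Rigid fragments receive a single structure; flexible rings a
    stochastically sampled, energy-deduplicated set; flexible chains a
    single template (their torsional freedom is exhausted later by
    torsion driving).  Fresh results are stored back into the library.
    """
    settings = settings or FragmentSamplingSettings()
    rng = rng if rng is not None else np.random.default_rng()
    capped, l2p, masked_stereo = build_capped_fragment(mg, frag)
    key = fragment_key(capped)

    stored = None if masked_stereo else lib.lookup(key, capped)
    if stored is None:
        param = ff.parametrize(capped, variant="MMFF94s", electrostatics=True)
        if frag.frag_class == "flexible_ring":
            sset = stochastic.StochasticSettings(
                max_samples=settings.ring_max_samples,
                convergence_period=settings.ring_period,
                energy_window=settings.ring_energy_window,
                dg=settings.dg,
            )
            stored = stochastic.sample(capped, param, sset, rng)
        else:
            gen = dg.RandomConformerGenerator(capped, param, settings.dg)
            stored = [gen.generate(rng)]
        if not masked_stereo:
            lib.store(key, capped, stored)

    return FragmentConformerSet(
        fragment=frag,
        conformers=[c.copy() for c in stored],
        local_to_parent=l2p,
        capped=capped,
    )


# ---------------------------------------------------------------------------
# fragment conformer combinations


def enumerate_fccs(
    sets: Sequence[FragmentConformerSet],
    window: float,
    cap: int = FCC_CAP,
) -> list[FCC]:
    """Energy-ordered FCC list via lazy best-first product enumeration.

    Combinations are emitted in ascending order of summed member energy,
    so truncation at ``cap`` keeps the globally lowest sums without
    materializing the full product.  Only combinations with energy at
    most ``min + 1.5 x window`` are retained.
    """
    if not sets or any(not s.conformers for s in sets):
        raise ValueError("every fragment needs at least one conformer")
    orders = []
    energies = []
    for s in sets:
        order = sorted(range(len(s.conformers)), key=lambda k: (s.conformers[k].energy, k))
        orders.append(order)
        energies.append([s.conformers[k].energy for k in order])

    base = sum(e[0] for e in energies)
    threshold = base + FCC_WINDOW_SAFETY * window
    n = len(sets)
    start = tuple([0] * n)
    heap = [(base, start)]
    seen = {start}
    out: list[FCC] = []
    while heap and len(out) < cap:
        e, pos = heapq.heappop(heap)
        if e > threshold:
            break
        out.append(FCC(tuple(orders[d][p] for d, p in enumerate(pos)), e))
        for d in range(n):
            if pos[d] + 1 >= len(energies[d]):
                continue
            nxt = list(pos)
            nxt[d] += 1
            key = tuple(nxt)
            if key in seen:
                continue
            seen.add(key)
            heapq.heappush(
                heap, (e - energies[d][pos[d]] + energies[d][pos[d] + 1], key)
            )
    return out
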