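"""Fragment-tree torsion driving with incremental MMFF94 energies.

Molecule conformers are assembled bottom-up over a binary tree whose
leaves hold fragment conformers and whose internal nodes each reference
one rotatable (link) bond.  A node's conformers arise by rigidly
overlaying every pair of left/right child conformers at the referenced
bond and applying each library dihedral angle.

Because fragments overlap in exactly the two atoms of each link bond
(see :mod:`confsmith.systematic`), every parametrized interaction of the
parent molecule can be assigned to exactly one tree node: to the lowest
node whose atom set contains all its atoms, except for link-bond
stretches, which belong to the internal node referencing the bond.  The
energy of a merged conformer A-B for dihedral theta is then

    E(A-B) = E(A) + E(B) + E_BS + E_T(theta) + E_C(theta) + E_VdW(theta)

where E_BS is the (angle-independent) rotor-bond stretch, E_T the rotor
torsion terms and E_C / E_VdW the electrostatic and van der Waals
interactions between the two substructures.  Child energies and E_BS are
reused across angles, so in the worst case every interaction term is
evaluated once per generated conformer.  The root energy equals the full
force-field energy of the assembled geometry up to floating-point
round-off, which is asserted by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import forcefield as ff
from . import torsion as tr
from .distgeom import Conformer
from .molprep import MoleculeGraph
from .systematic import FCC, FragmentConformerSet, LinkBond

__all__ = [
    "FragmentTreeNode",
    "DriveSettings",
    "build_fragment_tree",
    "assign_torsion_angles",
    "combine_node_conformers",
    "drive_fccs",
]

POOL_CAP = 10_000


@dataclass
class DriveSettings:
    energy_window: float = 15.0          # kcal/mol
    pool_cap: int = POOL_CAP             # per-node conformer store limit
    max_pool: int = POOL_CAP             # working-set early-exit threshold
    tolerance_sampling: bool = False
    torsion_libraries: tuple = ()


@dataclass
class FragmentTreeNode:
    atoms: frozenset
    left: Optional["FragmentTreeNode"] = None
    right: Optional["FragmentTreeNode"] = None
    bond: Optional[LinkBond] = None        # inside -> left, outside -> right
    fragment_index: Optional[int] = None   # leaves only
    angles: list = field(default_factory=list)
    ref_a: Optional[int] = None
    ref_b: Optional[int] = None
    selection: Optional[ff.TermSelection] = None
    conformers: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return self.fragment_index is not None

    def post_order(self):
        if self.left is not None:
            yield from self.left.post_order()
        if self.right is not None:
            yield from self.right.post_order()
        yield self


def _leaf_atoms(mg: MoleculeGraph, fcs: FragmentConformerSet) -> frozenset:
    atoms = set(fcs.fragment.atoms_with_partners)
    mol = mg.mol
    for i in fcs.fragment.core_atoms:
        for nb in mol.GetAtomWithIdx(i).GetNeighbors():
            if nb.GetAtomicNum() == 1:
                atoms.add(nb.GetIdx())
    return frozenset(atoms)


def build_fragment_tree(
    mg: MoleculeGraph,
    sets: Sequence[FragmentConformerSet],
    link_bonds: Sequence[tuple[int, int, int, bool]],
) -> FragmentTreeNode:
    """Construct the tree by greedily pairing the smallest subtrees first.

    The link graph over fragments is a tree (cut bonds are acyclic), so N
    fragments always yield N - 1 internal nodes; the greedy order keeps
    the tree balanced-ish and is deterministic under canonical atom order.
    """
    leaves = [
        FragmentTreeNode(atoms=_leaf_atoms(mg, s), fragment_index=i)
        for i, s in enumerate(sets)
    ]
    core_owner: dict[int, FragmentTreeNode] = {}
    for leaf, s in zip(leaves, sets):
        for a in s.fragment.core_atoms:
            core_owner[a] = leaf

    subtree = {id(l): l for l in leaves}
    owner = dict(core_owner)
    pending = list(link_bonds)
    while pending:

        def cost(lb):
            i, j, bidx, _ = lb
            return (len(owner[i].atoms) + len(owner[j].atoms), bidx)

        pending.sort(key=cost)
        i, j, bidx, amide = pending.pop(0)
        left, right = owner[i], owner[j]
        if left is right:  # pragma: no cover - cut bonds are acyclic
            continue
        node = FragmentTreeNode(
            atoms=frozenset(left.atoms | right.atoms),
            left=left,
            right=right,
            bond=LinkBond(inside=i, outside=j, bond_idx=bidx, amide=amide),
        )
        for a in list(owner):
            if owner[a] in (left, right):
                owner[a] = node
    roots = {id(owner[a]): owner[a] for a in owner}
    if len(roots) != 1:  # pragma: no cover - guaranteed by connectivity
        raise ValueError("link bonds do not connect all fragments")
    return next(iter(roots.values()))


def assign_torsion_angles(
    mg: MoleculeGraph,
    root: FragmentTreeNode,
    settings: DriveSettings,
) -> None:
    """Look up, symmetry-reduce and (optionally) tolerance-expand the
    dihedral angles of every internal node's rotor bond."""
    for node in root.post_order():
        if node.is_leaf:
            continue
        bond = (node.bond.inside, node.bond.outside)
        asg = tr.match_torsion_rules(mg, bond, settings.torsion_libraries)
        angles = tr.expand_tolerance_angles(
            asg.angles, asg.tolerances, settings.tolerance_sampling
        )
        if node.bond.amide:
            # flagged amide rotors stay planar regardless of generic rules
            angles = [a for a in (180.0, 0.0) if a in angles] or [180.0, 0.0]
        angles = tr.reduce_symmetric_angles(mg, bond, angles)
        node.angles = angles
        node.ref_a, node.ref_b = asg.ref_a, asg.ref_b


def assign_terms(
    param: ff.ForceFieldParametrization,
    root: FragmentTreeNode,
    link_bond_ids: set[int],
    mg: MoleculeGraph,
) -> None:
    """Assign every force-field interaction to exactly one tree node."""
    n = param.n_atoms
    mol = mg.mol
    link_pairs = set()
    for b in mol.GetBonds():
        if b.GetIdx() in link_bond_ids:
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            link_pairs.add((min(i, j), max(i, j)))

    bond_is_link = np.array(
        [
            (min(i, j), max(i, j)) in link_pairs
            for i, j in param.bond_idx
        ],
        dtype=bool,
    ) if len(param.bond_idx) else np.zeros(0, dtype=bool)

    def member(node):
        m = np.zeros(n, dtype=bool)
        m[list(node.atoms)] = True
        return m

    cats = {
        "bonds": param.bond_idx,
        "angles": param.angle_idx,
        "stretch_bends": param.sb_idx,
        "oops": param.oop_idx,
        "torsions": param.tor_idx,
        "vdws": param.vdw_idx,
        "eles": param.ele_idx,
    }

    masks = {}

    def inside(node, idx):
        if len(idx) == 0:
            return np.zeros(0, dtype=bool)
        return np.all(masks[id(node)][idx], axis=1)

    for node in root.post_order():
        masks[id(node)] = member(node)

    for node in root.post_order():
        sel = {}
        for cat, idx in cats.items():
            if len(idx) == 0:
                sel[cat] = np.zeros(0, dtype=int)
                continue
            own = inside(node, idx)
            if not node.is_leaf:
                own &= ~inside(node.left, idx) & ~inside(node.right, idx)
            if cat == "bonds":
                if node.is_leaf:
                    own &= ~bond_is_link
                else:
                    i, j = node.bond.inside, node.bond.outside
                    key = (min(i, j), max(i, j))
                    mine = np.array(
                        [(min(a, b), max(a, b)) == key for a, b in idx], dtype=bool
                    )
                    own = (own & ~bond_is_link) | mine
            sel[cat] = np.flatnonzero(own)
        node.selection = ff.TermSelection(
            bonds=sel["bonds"], angles=sel["angles"],
            stretch_bends=sel["stretch_bends"], oops=sel["oops"],
            torsions=sel["torsions"], vdws=sel["vdws"], eles=sel["eles"],
        )


# ---------------------------------------------------------------------------
# rigid-body alignment


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 degrees about any axis perpendicular to u
        p = np.array([1.0, 0.0, 0.0])
        if abs(u[0]) > 0.9:
            p = np.array([0.0, 1.0, 0.0])
        axis = np.cross(u, p)
        axis /= np.linalg.norm(axis)
        return _axis_rotation(axis, np.pi)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    axis = axis / s
    return _axis_rotation(axis, float(np.arctan2(s, c)))


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def _dihedral_single(x, i, j, k, l) -> float:
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / max(np.linalg.norm(b2), 1e-12))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def merge_pair(
    left_coords: np.ndarray,
    right_coords: np.ndarray,
    node: FragmentTreeNode,
    theta_deg: float,
) -> np.ndarray:
    """Overlay the right child on the left at the rotor bond, then rotate
    the right substructure to the requested dihedral."""
    a1, b1 = node.bond.inside, node.bond.outside
    right_atoms = np.fromiter(
        (a for a in node.right.atoms if a not in (a1, b1)), dtype=int
    )
    la, lb = left_coords[a1], left_coords[b1]
    ra, rb = right_coords[a1], right_coords[b1]
    u = (rb - ra) / max(np.linalg.norm(rb - ra), 1e-12)
    v = (lb - la) / max(np.linalg.norm(lb - la), 1e-12)
    rot = _rotation_between(u, v)
    moved = (right_coords[right_atoms] - ra) @ rot.T + la

    merged = left_coords.copy()
    merged[right_atoms] = moved

    phi = _dihedral_single(merged, node.ref_a, a1, b1, node.ref_b)
    # rotating the b1 side about the a1->b1 axis by +alpha decreases the
    # signed dihedral by alpha
    delta = phi - np.radians(theta_deg)
    axis = (merged[b1] - merged[a1])
    axis = axis / max(np.linalg.norm(axis), 1e-12)
    spin = _axis_rotation(axis, delta)
    # the right substructure is the moving side
    merged[right_atoms] = (merged[right_atoms] - merged[a1]) @ spin.T + merged[a1]
    return merged


# ---------------------------------------------------------------------------
# driving


def init_leaf_conformer(
    node: FragmentTreeNode,
    fcs: FragmentConformerSet,
    conf_index: int,
    param: ff.ForceFieldParametrization,
    n_atoms: int,
) -> Conformer:
    """Map one fragment conformer into parent indexing, snap link-bond
    lengths to the parent reference, and evaluate the leaf's term share."""
    local = fcs.conformers[conf_index].coords
    coords = np.zeros((n_atoms, 3))
    mask = fcs.local_to_parent >= 0
    coords[fcs.local_to_parent[mask]] = local[mask]
    for link in fcs.fragment.links:
        a, o = link.inside, link.outside
        r0 = param.ref_bond_length(a, o)
        d = coords[o] - coords[a]
        coords[o] = coords[a] + d * (r0 / max(np.linalg.norm(d), 1e-12))
    e = ff.energy(param, coords, node.selection).total
    return Conformer(coords, e)


def combine_node_conformers(
    node: FragmentTreeNode,
    param: ff.ForceFieldParametrization,
    settings: DriveSettings,
) -> None:
    """Populate an internal node's conformer store from its children.

    Every (left, right, angle) triple yields a candidate; candidates above
    the running minimum plus the energy window are discarded immediately,
    the survivors are re-filtered against the final minimum, sorted by
    energy and truncated to the pool cap.
    """
    store: list[Conformer] = []
    e_min = np.inf
    window = settings.energy_window
    for cl in node.left.conformers:
        for cr in node.right.conformers:
            base = cl.energy + cr.energy
            for theta in node.angles:
                merged = merge_pair(cl.coords, cr.coords, node, theta)
                e_own = ff.energy(param, merged, node.selection).total
                e = base + e_own
                if e > e_min + window:
                    continue
                e_min = min(e_min, e)
                store.append(Conformer(merged, e))
    store = [c for c in store if c.energy <= e_min + window]
    store.sort(key=lambda c: c.energy)
    node.conformers = store[: settings.pool_cap]


def drive_fccs(
    mg: MoleculeGraph,
    root: FragmentTreeNode,
    sets: Sequence[FragmentConformerSet],
    fccs: Sequence[FCC],
    param: ff.ForceFieldParametrization,
    settings: Optional[DriveSettings] = None,
    deadline: Optional[float] = None,
) -> list[Conformer]:
    """Torsion-drive the energy-ordered FCC list into a candidate ensemble.

    Two early exits: (1) the next FCC's energy exceeds the energy of the
    FCC that produced the current best conformer plus the window; (2) the
    working set has reached the maximum pool size.  The working set is
    re-pruned whenever a new minimum-energy conformer lowers the upper
    energy limit.
    """
    import time

    settings = settings or DriveSettings()
    window = settings.energy_window
    n_atoms = mg.n_atoms
    leaf_cache: dict[tuple[int, int], Conformer] = {}
    leaves = [n for n in root.post_order() if n.is_leaf]
    internals = [n for n in root.post_order() if not n.is_leaf]

    working: list[Conformer] = []
    e_min = np.inf
    best_fcc_energy = None
    for fcc in fccs:
        if deadline is not None and time.monotonic() > deadline:
            break
        if best_fcc_energy is not None and fcc.energy > best_fcc_energy + window:
            break
        for leaf in leaves:
            fi = leaf.fragment_index
            ci = fcc.indices[fi]
            key = (fi, ci)
            if key not in leaf_cache:
                leaf_cache[key] = init_leaf_conformer(
                    leaf, sets[fi], ci, param, n_atoms
                )
            leaf.conformers = [leaf_cache[key]]
        for node in internals:
            combine_node_conformers(node, param, settings)
        for conf in root.conformers:
            if conf.energy > e_min + window:
                continue
            if conf.energy < e_min:
                e_min = conf.energy
                best_fcc_energy = fcc.energy
                working = [c for c in working if c.energy <= e_min + window]
            working.append(conf)
        if len(working) >= settings.max_pool:
            break
    return working
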