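"""Compound preprocessing.

Prepares a raw connection table for 3D structure generation: atom
hybridization and aromaticity perception (SSSR-based), stereo descriptor
assignment, completion of implicit hydrogens, optional canonical atom
ordering, connected-component perception and topological distance matrices.

The aromaticity model is RDKit's default perception, which is the model the
MMFF94 atom typer shipped with RDKit expects; hybridization states are
reduced to the four classes relevant for geometry construction
(``sp``/``sp2``/``sp3``/``other``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdmolops
from rdkit.Geometry import Point3D

__all__ = [
    "MoleculeGraph",
    "PreparationError",
    "from_smiles",
    "from_rdkit",
    "perceive_atom_properties",
    "assign_stereo",
    "add_missing_hydrogens",
    "canonicalize",
    "perceive_components",
    "topological_distances",
    "prepare",
    "morgan_connectivity_values",
]

# hybridization classes used downstream (hydrogen placement, planarity
# constraints); everything beyond sp/sp2/sp3 is lumped into "other"
_HYB_MAP = {
    Chem.HybridizationType.SP: "sp",
    Chem.HybridizationType.SP2: "sp2",
    Chem.HybridizationType.SP3: "sp3",
}


class PreparationError(ValueError):
    """Raised when an input connection table cannot be prepared.

    Covers impossible valences, contradictory stereo specifications and
    unparsable records.
    """


@dataclass
class MoleculeGraph:
    """Annotated connection table wrapping an RDKit molecule.

    Attributes
    ----------
    mol:
        The underlying RDKit molecule.  After :func:`prepare` it is
        sanitized and hydrogen-complete.
    name:
        Compound name (SMILES second column or SD title).
    coords_3d:
        Optional input coordinates in Angstrom (one row per atom), used
        only for stereo perception or optional inclusion in the output.
    component_ids:
        Per-atom connected-component label, filled by
        :func:`perceive_components`.
    """

    mol: Chem.Mol
    name: str = ""
    coords_3d: Optional[np.ndarray] = None
    component_ids: Optional[np.ndarray] = None
    canonical: bool = False
    _perceived: bool = field(default=False, repr=False)

    # -- annotation accessors -----------------------------------------
    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def hybridization(self, idx: int) -> str:
        return _HYB_MAP.get(self.mol.GetAtomWithIdx(idx).GetHybridization(), "other")

    def is_aromatic_atom(self, idx: int) -> bool:
        return self.mol.GetAtomWithIdx(idx).GetIsAromatic()

    def atom_stereo(self, idx: int) -> str:
        """CIP-style descriptor: ``R``/``S``/``unspecified``/``none``."""
        atom = self.mol.GetAtomWithIdx(idx)
        if atom.HasProp("_CIPCode"):
            return atom.GetProp("_CIPCode")
        if atom.GetChiralTag() in (
            Chem.ChiralType.CHI_TETRAHEDRAL_CW,
            Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
        ):
            # defined parity without a CIP label (e.g. pseudo-asymmetric)
            return "unspecified"
        if idx in {s.centeredOn for s in Chem.FindPotentialStereo(self.mol)
                   if s.type == Chem.StereoType.Atom_Tetrahedral}:
            return "unspecified"
        return "none"

    def bond_stereo(self, bond_idx: int) -> str:
        """``cis``/``trans``/``unspecified``/``none`` for a double bond."""
        for info in Chem.FindPotentialStereo(self.mol):
            if info.type != Chem.StereoType.Bond_Double:
                continue
            if info.centeredOn != bond_idx:
                continue
            if info.specified != Chem.StereoSpecified.Specified:
                return "unspecified"
            if info.descriptor == Chem.StereoDescriptor.Bond_Cis:
                return "cis"
            return "trans"
        return "none"

    def heavy_atoms(self) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]

    def copy(self) -> "MoleculeGraph":
        coords = None if self.coords_3d is None else self.coords_3d.copy()
        comp = None if self.component_ids is None else self.component_ids.copy()
        return replace(self, mol=Chem.Mol(self.mol), coords_3d=coords, component_ids=comp)


# ---------------------------------------------------------------------------
# construction


def from_smiles(smiles: str, name: str = "") -> MoleculeGraph:
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        raise PreparationError(f"unparsable SMILES: {smiles!r}")
    return from_rdkit(mol, name=name)


def from_rdkit(mol: Chem.Mol, name: str = "") -> MoleculeGraph:
    coords = None
    if mol.GetNumConformers() > 0:
        conf = mol.GetConformer()
        if conf.Is3D():
            coords = np.asarray(conf.GetPositions(), dtype=float)
    work = Chem.RWMol(mol)
    work.RemoveAllConformers()
    if not name and mol.HasProp("_Name"):
        name = mol.GetProp("_Name")
    return MoleculeGraph(mol=work.GetMol(), name=name, coords_3d=coords)


# ---------------------------------------------------------------------------
# perception steps


def perceive_atom_properties(mg: MoleculeGraph) -> MoleculeGraph:
    """Determine hybridization states, the SSSR and aromaticity.

    Hybridization follows from the element, formal charge and the number
    and order of incident bonds; ring perception computes a smallest set
    of smallest rings which, combined with the hybridization states,
    drives aromatic-ring identification.
    """
    out = mg.copy()
    try:
        Chem.SanitizeMol(out.mol)
    except (Chem.AtomValenceException, Chem.KekulizeException, ValueError) as exc:
        raise PreparationError(f"invalid connection table for {mg.name!r}: {exc}") from exc
    rdmolops.FastFindRings(out.mol)  # ensure ring info is current
    out._perceived = True
    return out


def morgan_connectivity_values(mol: Chem.Mol, rounds: int = 5) -> np.ndarray:
    """Iterated extended-connectivity values estimating substituent bulk.

    Starts from the heavy-atom degree and sums neighbor values for a fixed
    number of rounds; ties between equal sums are broken by atomic number,
    formal charge and total hydrogen count so that the resulting order is a
    pure function of the graph.
    """
    n = mol.GetNumAtoms()
    cv = np.array(
        [sum(1 for nb in a.GetNeighbors() if nb.GetAtomicNum() > 1) for a in mol.GetAtoms()],
        dtype=float,
    )
    for _ in range(rounds):
        nxt = cv.copy()
        for a in mol.GetAtoms():
            nxt[a.GetIdx()] += sum(cv[nb.GetIdx()] for nb in a.GetNeighbors())
        cv = nxt
    # deterministic sub-integer tie-breaks
    for a in mol.GetAtoms():
        i = a.GetIdx()
        cv[i] += (
            a.GetAtomicNum() * 1e-3
            + (a.GetFormalCharge() + 8) * 1e-6
            + a.GetTotalNumHs() * 1e-8
        )
    return cv


def assign_stereo(mg: MoleculeGraph) -> MoleculeGraph:
    """Assign stereo descriptors.

    Input descriptors are retained; descriptors derivable from supplied 3D
    coordinates are computed; stereogenic double bonds that remain
    undefined are set *trans* with respect to the bulkiest substituent on
    either side (bulk estimated by Morgan-style connectivity values).
    Undefined tetrahedral centers stay unspecified - a suitable
    configuration is chosen implicitly by the 3D generation stage.
    """
    if not mg._perceived:
        mg = perceive_atom_properties(mg)
    out = mg.copy()
    mol = Chem.RWMol(out.mol)

    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)

    # derive missing descriptors from input 3D coordinates, if any
    if out.coords_3d is not None:
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, p in enumerate(out.coords_3d):
            conf.SetAtomPosition(i, Point3D(*map(float, p)))
        mol.AddConformer(conf, assignId=True)
        Chem.AssignStereochemistryFrom3D(mol)
        mol.RemoveAllConformers()

    # remaining stereogenic double bonds: trans w.r.t. bulkiest substituents
    cv = morgan_connectivity_values(mol)
    for info in Chem.FindPotentialStereo(mol):
        if info.type != Chem.StereoType.Bond_Double:
            continue
        if info.specified == Chem.StereoSpecified.Specified:
            continue
        bond = mol.GetBondWithIdx(info.centeredOn)
        if bond.IsInRing() and bond.GetOwningMol().GetRingInfo().MinBondRingSize(
            bond.GetIdx()
        ) < 8:
            continue
        ref = []
        for end in (bond.GetBeginAtom(), bond.GetEndAtom()):
            other = bond.GetOtherAtom(end)
            nbrs = [nb.GetIdx() for nb in end.GetNeighbors() if nb.GetIdx() != other.GetIdx()]
            nbrs = [i for i in nbrs if mol.GetAtomWithIdx(i).GetAtomicNum() > 1] or nbrs
            if not nbrs:
                ref = []
                break
            ref.append(max(nbrs, key=lambda i: cv[i]))
        if len(ref) == 2:
            bond.SetStereoAtoms(ref[0], ref[1])
            bond.SetStereo(Chem.BondStereo.STEREOTRANS)

    Chem.AssignStereochemistry(mol, cleanIt=False, force=True)
    out.mol = mol.GetMol()
    return out


def add_missing_hydrogens(mg: MoleculeGraph) -> MoleculeGraph:
    """Convert implicit hydrogens to explicit atoms.

    Completes the standard valence implied by element and formal charge;
    the protonation state is never altered.
    """
    out = mg.copy()
    n_before = out.mol.GetNumAtoms()
    if out.coords_3d is not None:
        mol = Chem.RWMol(out.mol)
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, p in enumerate(out.coords_3d):
            conf.SetAtomPosition(i, Point3D(*map(float, p)))
        mol.AddConformer(conf, assignId=True)
        with_h = Chem.AddHs(mol.GetMol(), addCoords=True)
        out.coords_3d = np.asarray(with_h.GetConformer().GetPositions(), dtype=float)
        with_h = Chem.RWMol(with_h)
        with_h.RemoveAllConformers()
        out.mol = with_h.GetMol()
    else:
        out.mol = Chem.AddHs(out.mol)
    assert out.mol.GetNumAtoms() >= n_before
    return out


def canonicalize(mg: MoleculeGraph) -> MoleculeGraph:
    """Rebuild the connection table in a canonical, graph-determined order.

    Implemented as a canonical-SMILES round trip, which fixes both the
    atom and the bond enumeration order as a pure function of the
    labelled graph (element, charge, degree, hydrogen count, ring
    membership, stereo).  Idempotent; applied before explicit-hydrogen
    completion, so hydrogen order follows canonical heavy-atom order.
    Heavy-atom input coordinates are carried along; explicit-hydrogen
    coordinates are re-derived later.
    """
    import ast

    out = mg.copy()
    base = Chem.RemoveHs(out.mol)
    smi = Chem.MolToSmiles(base, isomericSmiles=True, canonical=True)
    order = ast.literal_eval(base.GetProp("_smilesAtomOutputOrder"))
    new = Chem.MolFromSmiles(smi)
    if new is None:  # pragma: no cover - canonical SMILES always re-parses
        raise PreparationError(f"canonical SMILES round trip failed for {mg.name!r}")
    Chem.AssignStereochemistry(new, cleanIt=True, force=True)
    if out.coords_3d is not None and base.GetNumAtoms() == out.mol.GetNumAtoms():
        out.coords_3d = out.coords_3d[list(order)]
    elif out.coords_3d is not None:
        # explicit hydrogens were dropped by the round trip; their
        # coordinates are regenerated during hydrogen completion
        heavy_coords = out.coords_3d[
            [a.GetIdx() for a in out.mol.GetAtoms() if a.GetAtomicNum() > 1]
        ]
        out.coords_3d = heavy_coords[list(order)]
    out.mol = new
    out.canonical = True
    out._perceived = True
    return out


def perceive_components(mg: MoleculeGraph) -> MoleculeGraph:
    """Label maximal connected subgraphs (molecules of the compound)."""
    out = mg.copy()
    frags = Chem.GetMolFrags(out.mol, asMols=False, sanitizeFrags=False)
    comp = np.empty(out.n_atoms, dtype=int)
    for cid, atom_ids in enumerate(frags):
        for i in atom_ids:
            comp[i] = cid
    out.component_ids = comp
    return out


def topological_distances(mg: MoleculeGraph, atoms: Optional[Sequence[int]] = None) -> np.ndarray:
    """Shortest bond-path length matrix (whole molecule or a subset).

    Off-component entries are reported as ``inf``.
    """
    full = np.asarray(Chem.GetDistanceMatrix(Chem.Mol(mg.mol)), dtype=float)
    if atoms is not None:
        idx = np.asarray(list(atoms), dtype=int)
        full = full[np.ix_(idx, idx)]
    return full


def prepare(mg: MoleculeGraph, canonical: bool = False) -> MoleculeGraph:
    """Run the full preprocessing sequence on a raw compound."""
    mg = perceive_atom_properties(mg)
    mg = assign_stereo(mg)
    if canonical:
        mg = canonicalize(mg)
    mg = add_missing_hydrogens(mg)
    mg = perceive_components(mg)
    return mg
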