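"""Output ensemble compilation and symmetry-aware RMSD machinery.

The final ensemble is picked greedily from the energy-ranked candidate
set: a candidate is accepted iff its heavy-atom RMSD to every previously
accepted conformer is at least the diversity threshold, where the RMSD of
a pair is minimized over rigid superposition (Kabsch) *and* over all
topological symmetry mappings (graph automorphisms of the heavy-atom
skeleton, capped at 131,072).  Selection stops at the maximum ensemble
size or when the energy window above the lowest-energy conformer is
exhausted.

Note that the symmetry-minimized RMSD is not a metric (different pairs
may realize their minimum under different mappings), so no triangle-type
guarantees hold between ensemble members - only the pairwise threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .distgeom import Conformer
from .molprep import MoleculeGraph

__all__ = [
    "SelectionSettings",
    "ConformerEnsemble",
    "MAPPING_CAP",
    "enumerate_symmetry_mappings",
    "kabsch_rmsd",
    "min_symmetry_rmsd",
    "compile_output_ensemble",
    "EmptyCandidateSet",
]

MAPPING_CAP = 131_072


class EmptyCandidateSet(RuntimeError):
    """Ensemble compilation received no candidates."""


@dataclass
class SelectionSettings:
    rmsd_threshold: float = 0.5      # A, heavy atoms
    max_size: int = 100
    energy_window: float = 15.0      # kcal/mol
    include_input: bool = False
    mapping_cap: int = MAPPING_CAP

    def __post_init__(self):
        if self.rmsd_threshold <= 0 or self.max_size < 1:
            raise ValueError("threshold must be > 0 and max_size >= 1")


@dataclass
class ConformerEnsemble:
    """Energy-ordered output conformers of one molecule."""

    molecule: MoleculeGraph
    conformers: list[Conformer]
    mapping_cap_hit: bool = False

    def __len__(self) -> int:
        return len(self.conformers)

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.energy for c in self.conformers])


def _heavy_skeleton(mol: Chem.Mol) -> tuple[Chem.Mol, list[int]]:
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    work = Chem.RWMol(mol)
    for idx in sorted(
        (a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 1), reverse=True
    ):
        work.RemoveAtom(idx)
    return work.GetMol(), heavy


def enumerate_symmetry_mappings(
    mg: MoleculeGraph, cap: int = MAPPING_CAP
) -> tuple[list[np.ndarray], bool]:
    """Automorphisms of the heavy-atom graph (element/bond-order
    preserving), as permutations of heavy-atom positions.

    The identity comes first; at most ``cap`` mappings are returned and
    the second element reports whether the cap was hit (in which case the
    downstream diversity guarantee is only approximate).
    """
    skel, _ = _heavy_skeleton(mg.mol)
    n = skel.GetNumAtoms()
    matches = skel.GetSubstructMatches(
        skel, uniquify=False, maxMatches=cap + 1, useChirality=False,
    )
    cap_hit = len(matches) > cap
    perms = []
    identity = tuple(range(n))
    seen = set()
    for m in ([identity] + [m for m in matches if m != identity])[:cap]:
        if m in seen:
            continue
        seen.add(m)
        perms.append(np.asarray(m, dtype=int))
    return perms, cap_hit


def kabsch_rmsd(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    mapping: Optional[np.ndarray] = None,
) -> float:
    """Minimal RMSD over proper rotations and translations.

    ``mapping`` permutes the second coordinate set before superposition
    (``coords_b[mapping[i]]`` is compared against ``coords_a[i]``).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if mapping is not None:
        b = b[np.asarray(mapping, dtype=int)]
    if a.shape != b.shape or a.shape[0] < 1:
        raise ValueError("coordinate sets must match and be non-empty")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = bc.T @ ac
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s_corr = np.array([1.0, 1.0, d])
    # rmsd^2 = (|A|^2 + |B|^2 - 2 * sum corrected singular values) / n
    msd = (np.sum(ac * ac) + np.sum(bc * bc) - 2.0 * np.sum(s * s_corr)) / a.shape[0]
    return float(np.sqrt(max(msd, 0.0)))


def min_symmetry_rmsd(
    mg: MoleculeGraph,
    conf_a: Conformer | np.ndarray,
    conf_b: Conformer | np.ndarray,
    mappings: Optional[Sequence[np.ndarray]] = None,
    cap: int = MAPPING_CAP,
) -> float:
    """Heavy-atom RMSD minimized over rigid motion and topological
    symmetry mappings."""
    heavy = mg.heavy_atoms()
    xa = (conf_a.coords if isinstance(conf_a, Conformer) else conf_a)[heavy]
    xb = (conf_b.coords if isinstance(conf_b, Conformer) else conf_b)[heavy]
    if mappings is None:
        mappings, _ = enumerate_symmetry_mappings(mg, cap)
    return min(kabsch_rmsd(xa, xb, m) for m in mappings)


def compile_output_ensemble(
    mg: MoleculeGraph,
    candidates: Sequence[Conformer],
    settings: Optional[SelectionSettings] = None,
    input_structure: Optional[Conformer] = None,
) -> ConformerEnsemble:
    """Greedy energy-ranked, diversity-filtered output selection.

    Candidates are visited in ascending energy order (stable w.r.t.
    generation order for ties); when requested, the input structure is
    inserted as the very first candidate and then competes under the same
    window and diversity rules.
    """
    settings = settings or SelectionSettings()
    if not candidates and input_structure is None:
        raise EmptyCandidateSet(f"no conformer candidates for {mg.name!r}")

    ranked = sorted(
        range(len(candidates)), key=lambda k: (candidates[k].energy, k)
    )
    pool: list[Conformer] = [candidates[k] for k in ranked]
    if input_structure is not None:
        pool.insert(0, input_structure)

    mappings, cap_hit = enumerate_symmetry_mappings(mg, settings.mapping_cap)
    heavy = mg.heavy_atoms()

    e_min = min(c.energy for c in pool)
    selected: list[Conformer] = []
    for conf in pool:
        if len(selected) >= settings.max_size:
            break
        if conf.energy > e_min + settings.energy_window:
            if conf is input_structure:
                continue
            break
        xa = conf.coords[heavy]
        accept = True
        for prev in selected:
            rmsd = min(kabsch_rmsd(xa, prev.coords[heavy], m) for m in mappings)
            if rmsd < settings.rmsd_threshold:
                accept = False
                break
        if accept:
            selected.append(conf)

    selected.sort(key=lambda c: c.energy)
    if not selected:
        raise EmptyCandidateSet(f"all candidates rejected for {mg.name!r}")
    return ConformerEnsemble(molecule=mg, conformers=selected, mapping_cap_hit=cap_hit)
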