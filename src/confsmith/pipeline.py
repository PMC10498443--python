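"""Per-compound conformer generation orchestration.

Preprocessing, per-component sampling-mode selection (systematic torsion
driving for typical drug-like molecules, stochastic distance-geometry
sampling for macrocycles), candidate generation, output ensemble
compilation, multi-component assembly and failure/timeout accounting.

Errors in any stage downgrade the compound to a failure report; a batch
never aborts because of a single compound.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from rdkit import Chem

from . import distgeom as dg
from . import ensemble as ens
from . import forcefield as ff
from . import fragtree as ft
from . import stochastic as st
from . import systematic as sy
from .molprep import MoleculeGraph, PreparationError, from_rdkit, prepare

__all__ = [
    "GenerationSettings",
    "GenerationReport",
    "MoleculeTimeout",
    "detect_macrocycle",
    "generate",
    "run_batch",
]

MACROCYCLE_MIN_ROT_BONDS = 10  # "more than 10 nonaromatic single bonds"
COMPONENT_SPACING = 5.0        # A between component bounding boxes


class MoleculeTimeout(RuntimeError):
    pass


@dataclass
class GenerationSettings:
    mode: str = "auto"                  # auto | systematic | stochastic
    energy_window: Optional[float] = None  # default: 15 systematic / 20 stochastic
    rmsd_threshold: float = 0.5
    max_ensemble_size: int = 100
    time_budget: float = 0.0            # seconds per molecule; 0 = off
    seed: int = 0
    canonicalize: bool = False
    tolerance_sampling: bool = False
    include_input: bool = False
    max_samples: int = 2000             # stochastic sample cap
    torsion_libraries: tuple = ()
    fragment_library: Optional[sy.FragmentLibrary] = None
    ff_variant: str = "MMFF94s"
    electrostatics: bool = True

    def window_for(self, mode: str) -> float:
        if self.energy_window is not None:
            return self.energy_window
        return 20.0 if mode == "stochastic" else 15.0


@dataclass
class GenerationReport:
    name: str
    status: str = "ok"                  # ok | failed:<stage> | timeout
    seconds: float = 0.0
    ensemble_size: int = 0
    log: list[str] = field(default_factory=list)

    def note(self, msg: str) -> None:
        self.log.append(msg)


def detect_macrocycle(mg: MoleculeGraph) -> bool:
    """True iff some SSSR ring has more than 10 nonaromatic single bonds."""
    mol = mg.mol
    ri = mol.GetRingInfo()
    for ring_bonds in ri.BondRings():
        count = 0
        for bidx in ring_bonds:
            b = mol.GetBondWithIdx(bidx)
            if b.GetBondType() == Chem.BondType.SINGLE and not b.GetIsAromatic():
                count += 1
        if count > MACROCYCLE_MIN_ROT_BONDS:
            return True
    return False


def _component_graphs(mg: MoleculeGraph) -> list[tuple[MoleculeGraph, list[int]]]:
    """Split a prepared compound into prepared per-component graphs.

    Returns (component graph, atom indices into the compound) pairs.
    """
    frag_idx = Chem.GetMolFrags(mg.mol, asMols=False, sanitizeFrags=False)
    if len(frag_idx) == 1:
        return [(mg, list(frag_idx[0]))]
    out = []
    for atoms in frag_idx:
        amap = {g: l for l, g in enumerate(atoms)}
        work = Chem.RWMol()
        for g in atoms:
            work.AddAtom(Chem.Atom(mg.mol.GetAtomWithIdx(g)))
        for b in mg.mol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i in amap and j in amap:
                work.AddBond(amap[i], amap[j], b.GetBondType())
                nb = work.GetBondBetweenAtoms(amap[i], amap[j])
                nb.SetIsAromatic(b.GetIsAromatic())
                if b.GetStereo() != Chem.BondStereo.STEREONONE:
                    sa = [amap[s] for s in b.GetStereoAtoms()]
                    if len(sa) == 2:
                        nb.SetStereoAtoms(sa[0], sa[1])
                        nb.SetStereo(b.GetStereo())
        sub = work.GetMol()
        Chem.SanitizeMol(sub)
        Chem.AssignStereochemistry(sub, cleanIt=False, force=True)
        cg = MoleculeGraph(mol=sub, name=mg.name)
        cg._perceived = True
        if mg.coords_3d is not None:
            cg.coords_3d = mg.coords_3d[list(atoms)]
        out.append((cg, list(atoms)))
    return out


def _systematic_candidates(
    cg: MoleculeGraph,
    param: ff.ForceFieldParametrization,
    settings: GenerationSettings,
    rng: np.random.Generator,
    report: GenerationReport,
    deadline: Optional[float],
) -> list[dg.Conformer]:
    lib = settings.fragment_library
    if lib is None:
        lib = sy.FragmentLibrary()
    window = settings.window_for("systematic")
    res = sy.fragment_molecule(cg)
    report.note(f"fragments={len(res.fragments)} cuts={len(res.cut_bonds)}")
    sets = []
    for frag in res.fragments:
        _check_deadline(deadline)
        sets.append(sy.fragment_conformers(frag, cg, lib, rng=rng))
    fccs = sy.enumerate_fccs(sets, window=window)
    report.note(f"fccs={len(fccs)}")
    root = ft.build_fragment_tree(cg, sets, res.cut_bonds)
    drive = ft.DriveSettings(
        energy_window=window,
        tolerance_sampling=settings.tolerance_sampling,
        torsion_libraries=tuple(settings.torsion_libraries),
    )
    ft.assign_torsion_angles(cg, root, drive)
    ft.assign_terms(param, root, {c[2] for c in res.cut_bonds}, cg)
    candidates = ft.drive_fccs(cg, root, sets, fccs, param, drive, deadline=deadline)
    # defensive molecule-level stereo validation of assembled conformers
    has_stereo = bool(
        dg.tetrahedral_stereocenters(cg.mol) or dg._defined_double_bonds(cg.mol)
    )
    if has_stereo:
        n_before = len(candidates)
        candidates = [c for c in candidates if dg.stereo_ok(cg, c.coords)]
        if len(candidates) != n_before:
            report.note(
                f"dropped {n_before - len(candidates)} stereo-inconsistent candidates"
            )
    return candidates


def _stochastic_candidates(
    cg: MoleculeGraph,
    param: ff.ForceFieldParametrization,
    settings: GenerationSettings,
    rng: np.random.Generator,
    report: GenerationReport,
    deadline: Optional[float],
) -> list[dg.Conformer]:
    sset = st.StochasticSettings(
        max_samples=settings.max_samples,
        energy_window=settings.window_for("stochastic"),
    )
    return st.sample(cg, param, sset, rng, deadline=deadline)


def _check_deadline(deadline: Optional[float]) -> None:
    if deadline is not None and time.monotonic() > deadline:
        raise MoleculeTimeout("per-molecule time budget exhausted")


def generate(
    compound: MoleculeGraph,
    settings: Optional[GenerationSettings] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Optional[ens.ConformerEnsemble], GenerationReport]:
    """Generate the output conformer ensemble of one input compound.

    Multi-molecule compounds (salts, mixtures) get a separate ensemble
    per component; compound conformers are then assembled by translating
    the components apart along x with a fixed spacing - a simple,
    documented placement that keeps components non-overlapping.
    """
    settings = settings or GenerationSettings()
    rng = rng if rng is not None else np.random.default_rng(settings.seed)
    report = GenerationReport(name=compound.name or "")
    t0 = time.monotonic()
    deadline = t0 + settings.time_budget if settings.time_budget > 0 else None

    try:
        mg = prepare(compound, canonical=settings.canonicalize)
        report.name = report.name or mg.name
    except PreparationError as exc:
        report.status = "failed:preprocessing"
        report.note(str(exc))
        report.seconds = time.monotonic() - t0
        return None, report

    components = _component_graphs(mg)
    report.note(f"components={len(components)}")
    comp_ensembles: list[ens.ConformerEnsemble] = []
    comp_atoms: list[list[int]] = []
    try:
        for cg, atoms in components:
            _check_deadline(deadline)
            td = np.asarray(Chem.GetDistanceMatrix(cg.mol), dtype=float)
            param = ff.parametrize(
                cg, variant=settings.ff_variant,
                electrostatics=settings.electrostatics, td=td,
            )
            if settings.mode == "auto":
                mode = "stochastic" if detect_macrocycle(cg) else "systematic"
            else:
                mode = settings.mode
            report.note(f"component mode={mode}")
            if cg.n_atoms == 1:
                candidates = [dg.Conformer(np.zeros((1, 3)), 0.0)]
            elif mode == "stochastic":
                candidates = _stochastic_candidates(
                    cg, param, settings, rng, report, deadline)
            else:
                candidates = _systematic_candidates(
                    cg, param, settings, rng, report, deadline)
            _check_deadline(deadline)
            input_conf = None
            if settings.include_input and cg.coords_3d is not None:
                e_in = ff.energy(param, cg.coords_3d).total
                input_conf = dg.Conformer(cg.coords_3d.copy(), e_in)
            sel = ens.SelectionSettings(
                rmsd_threshold=settings.rmsd_threshold,
                max_size=settings.max_ensemble_size,
                energy_window=settings.window_for(mode),
            )
            comp_ensembles.append(
                ens.compile_output_ensemble(cg, candidates, sel, input_conf))
            comp_atoms.append(atoms)
    except MoleculeTimeout:
        report.status = "timeout"
        report.seconds = time.monotonic() - t0
        return None, report
    except ff.ParametrizationError as exc:
        report.status = "failed:parametrization"
        report.note(str(exc))
        report.seconds = time.monotonic() - t0
        return None, report
    except (dg.GenerationError, st.SamplingFailure, ens.EmptyCandidateSet,
            ValueError) as exc:
        report.status = "failed:generation"
        report.note(str(exc))
        report.seconds = time.monotonic() - t0
        return None, report

    if len(comp_ensembles) == 1:
        out = comp_ensembles[0]
        out.molecule = mg
    else:
        out = _assemble_components(mg, comp_ensembles, comp_atoms)
    report.ensemble_size = len(out)
    report.seconds = time.monotonic() - t0
    report.note(f"ensemble_size={len(out)}")
    return out, report


def _assemble_components(
    mg: MoleculeGraph,
    ensembles: list[ens.ConformerEnsemble],
    atoms: list[list[int]],
) -> ens.ConformerEnsemble:
    """Naive spatial placement of component conformers along x."""
    k = min(len(e) for e in ensembles)
    out: list[dg.Conformer] = []
    n = mg.n_atoms
    for i in range(k):
        coords = np.zeros((n, 3))
        offset = 0.0
        energy = 0.0
        for e, idx in zip(ensembles, atoms):
            c = e.conformers[i]
            x = c.coords - c.coords.min(axis=0)
            coords[idx] = x + np.array([offset, 0.0, 0.0])
            offset += x[:, 0].max() + COMPONENT_SPACING
            energy += c.energy
        out.append(dg.Conformer(coords, energy))
    return ens.ConformerEnsemble(molecule=mg, conformers=out)


def run_batch(
    compounds: Iterable[MoleculeGraph],
    settings: Optional[GenerationSettings] = None,
) -> list[tuple[Optional[ens.ConformerEnsemble], GenerationReport]]:
    """Process a batch; every input yields exactly one report record.

    Each compound gets an independent random stream derived from the
    batch seed and its position, so results do not depend on how a batch
    is split.
    """
    settings = settings or GenerationSettings()
    if settings.fragment_library is None:
        settings.fragment_library = sy.FragmentLibrary()
    out = []
    for i, compound in enumerate(compounds):
        rng = np.random.default_rng([settings.seed, i])
        out.append(generate(compound, settings, rng))
    return out
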