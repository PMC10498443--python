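"""Benchmarking: best RMSD against reference structures and summaries.

The "best" RMSD of an ensemble against a reference structure is the
minimum over all ensemble conformers and all topological symmetry
mappings of the heavy-atom Kabsch RMSD - the standard protocol for
judging reproduction of bioactive conformations.  For macrocycles the
comparison can be restricted to the macrocyclic ring atoms.

Summaries report mean/median/min/max best RMSD, ensemble size and
processing time over successful molecules, the percentage of molecules
reproduced below each RMSD threshold, and failure counts (failed
molecules are excluded from the RMSD statistics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from . import ensemble as ens
from .distgeom import Conformer
from .molprep import MoleculeGraph
from .pipeline import MACROCYCLE_MIN_ROT_BONDS

__all__ = ["BenchmarkRecord", "best_rmsd", "summarize", "records_to_frame"]


@dataclass
class BenchmarkRecord:
    name: str
    status: str = "ok"
    best_rmsd: Optional[float] = None
    ring_best_rmsd: Optional[float] = None
    ensemble_size: int = 0
    seconds: float = 0.0


def _macrocycle_ring_atoms(mg: MoleculeGraph) -> list[int]:
    mol = mg.mol
    ri = mol.GetRingInfo()
    atoms: set[int] = set()
    for ring_bonds, ring_atoms in zip(ri.BondRings(), ri.AtomRings()):
        count = sum(
            1 for bidx in ring_bonds
            if mol.GetBondWithIdx(bidx).GetBondType() == Chem.BondType.SINGLE
            and not mol.GetBondWithIdx(bidx).GetIsAromatic()
        )
        if count > MACROCYCLE_MIN_ROT_BONDS:
            atoms.update(ring_atoms)
    return sorted(atoms)


def best_rmsd(
    ensemble: ens.ConformerEnsemble,
    reference: np.ndarray | Conformer,
    ring_only: bool = False,
    cap: int = ens.MAPPING_CAP,
) -> float:
    """Minimum symmetry-aware heavy-atom RMSD over all ensemble members.

    ``reference`` carries coordinates on the same atom indexing as the
    ensemble's molecule (a graph mismatch therefore surfaces as a shape
    error).  ``ring_only`` restricts the comparison to macrocyclic ring
    atoms; symmetry mappings that do not keep that subset invariant are
    skipped.
    """
    mg = ensemble.molecule
    ref = reference.coords if isinstance(reference, Conformer) else np.asarray(reference)
    if ref.shape != (mg.n_atoms, 3):
        raise ValueError(
            f"reference has shape {ref.shape}, expected {(mg.n_atoms, 3)}"
        )
    heavy = mg.heavy_atoms()
    mappings, _ = ens.enumerate_symmetry_mappings(mg, cap)
    if ring_only:
        ring = _macrocycle_ring_atoms(mg)
        if not ring:
            raise ValueError("no macrocyclic ring atoms found")
        pos = {g: k for k, g in enumerate(heavy)}
        sub = np.array([pos[a] for a in ring if a in pos], dtype=int)
        subset = set(sub.tolist())
        kept = []
        for m in mappings:
            if set(m[sub].tolist()) == subset:
                kept.append(m)
        mappings = kept or [np.arange(len(heavy))]
        best = np.inf
        ref_h = ref[heavy]
        for conf in ensemble.conformers:
            xa = conf.coords[heavy]
            for m in mappings:
                best = min(best, ens.kabsch_rmsd(ref_h[sub], xa[m][sub]))
        return float(best)
    best = np.inf
    ref_h = ref[heavy]
    for conf in ensemble.conformers:
        xa = conf.coords[heavy]
        for m in mappings:
            best = min(best, ens.kabsch_rmsd(ref_h, xa, m))
    return float(best)


def records_to_frame(records: Sequence[BenchmarkRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.name for r in records],
            "status": [r.status for r in records],
            "best_rmsd": [r.best_rmsd for r in records],
            "ring_best_rmsd": [r.ring_best_rmsd for r in records],
            "ensemble_size": [r.ensemble_size for r in records],
            "seconds": [r.seconds for r in records],
        }
    )


def summarize(
    records: Sequence[BenchmarkRecord],
    thresholds: Sequence[float] = (0.5, 1.0, 1.5, 2.0),
    ring_only: bool = False,
) -> dict:
    """Summary statistics plus threshold-percentile table.

    ``percent_below[t]`` is the percentage of successful molecules whose
    best RMSD is below ``t`` (non-decreasing in ``t``).  Failures are
    counted, never averaged in.
    """
    ok = [r for r in records if r.status == "ok"]
    failed = [r for r in records if r.status != "ok"]
    key = "ring_best_rmsd" if ring_only else "best_rmsd"
    vals = np.array([getattr(r, key) for r in ok if getattr(r, key) is not None])
    out: dict = {
        "n_total": len(records),
        "n_ok": len(ok),
        "n_failed": len(failed),
        "empty": len(vals) == 0,
    }
    if len(vals) == 0:
        out["percent_below"] = {float(t): None for t in thresholds}
        return out
    out.update(
        mean_rmsd=float(np.mean(vals)),
        median_rmsd=float(np.median(vals)),
        min_rmsd=float(np.min(vals)),
        max_rmsd=float(np.max(vals)),
        mean_ensemble_size=float(np.mean([r.ensemble_size for r in ok])),
        mean_seconds=float(np.mean([r.seconds for r in ok])),
        median_seconds=float(np.median([r.seconds for r in ok])),
    )
    out["percent_below"] = {
        float(t): float(100.0 * np.mean(vals < t)) for t in thresholds
    }
    return out
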