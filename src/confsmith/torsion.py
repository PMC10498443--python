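"""Torsion-rule matching and angle-list processing.

Rotatable bonds are assigned discrete dihedral angles from an ordered
library of SMARTS-keyed rules.  Each rule's pattern describes a linear
four-atom path whose central bond is the rotor; the matched outer atoms
double as the dihedral reference atoms during torsion driving.  User
libraries take precedence over the built-in one, and a generic staggered
fallback guarantees that every rotor receives at least one angle.

The built-in library shipped with the package is a compact set of
hybridization- and functional-group-based rules (amide, ester, biaryl,
conjugated, sulfonyl, generic staggered); it uses the same file format as
user libraries and can be replaced wholesale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from rdkit import Chem

from .molprep import MoleculeGraph, morgan_connectivity_values

__all__ = [
    "TorsionRule",
    "TorsionLibrary",
    "TorsionAssignment",
    "builtin_library",
    "load_library",
    "match_torsion_rules",
    "reduce_symmetric_angles",
    "expand_tolerance_angles",
    "detect_side_symmetry",
]

_FALLBACK_ANGLES = ((60.0, 20.0), (180.0, 20.0), (300.0, 20.0))


@dataclass
class TorsionRule:
    """A SMARTS-keyed list of preferred dihedral angles with tolerances."""

    smarts: str
    angles: tuple[tuple[float, float], ...]  # (angle_deg, tolerance_deg)
    pattern: Chem.Mol = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.angles:
            raise ValueError("torsion rule needs at least one angle")
        norm = tuple((a % 360.0, t) for a, t in self.angles)
        object.__setattr__(self, "angles", norm)
        if self.pattern is None:
            patt = Chem.MolFromSmarts(self.smarts)
            if patt is None or patt.GetNumAtoms() not in (3, 4):
                raise ValueError(f"invalid torsion SMARTS {self.smarts!r}")
            object.__setattr__(self, "pattern", patt)


@dataclass
class TorsionLibrary:
    """Ordered rule list with first-match semantics."""

    rules: list[TorsionRule]

    @classmethod
    def from_file(cls, path) -> "TorsionLibrary":
        rules = []
        with open(path) as fh:
            for raw in fh:
                line = raw.rstrip("\n").strip()
                # '#' also occurs inside SMARTS, so only whole-line comments
                if not line or line.startswith("#"):
                    continue
                try:
                    smarts, angle_spec = line.split("\t")
                except ValueError as exc:
                    raise ValueError(f"malformed torsion rule line: {raw!r}") from exc
                angles = []
                for tok in angle_spec.split(","):
                    ang, _, tol = tok.partition(":")
                    angles.append((float(ang), float(tol) if tol else 0.0))
                rules.append(TorsionRule(smarts, tuple(angles)))
        return cls(rules)


@dataclass
class TorsionAssignment:
    """Angles assigned to one rotor bond plus the matched reference atoms."""

    angles: list[float]
    tolerances: list[float]
    ref_a: int  # dihedral reference neighbor on the begin-atom side
    ref_b: int
    rule: Optional[TorsionRule] = None


_builtin_cache: Optional[TorsionLibrary] = None


def builtin_library() -> TorsionLibrary:
    global _builtin_cache
    if _builtin_cache is None:
        ref = resources.files("confsmith.data").joinpath("torsion_lib.txt")
        with resources.as_file(ref) as path:
            _builtin_cache = TorsionLibrary.from_file(path)
    return _builtin_cache


def load_library(path) -> TorsionLibrary:
    return TorsionLibrary.from_file(path)


def _canonical_ranks(mol: Chem.Mol):
    return list(Chem.CanonicalRankAtoms(mol, breakTies=False))


def _default_refs(mol: Chem.Mol, i: int, j: int) -> tuple[int, int]:
    """Highest-canonical-rank heavy neighbor on each side of bond i-j."""
    ranks = _canonical_ranks(mol)

    def pick(center, other):
        nbrs = [a.GetIdx() for a in mol.GetAtomWithIdx(center).GetNeighbors()
                if a.GetIdx() != other]
        heavy = [n for n in nbrs if mol.GetAtomWithIdx(n).GetAtomicNum() > 1]
        pool = heavy or nbrs
        return max(pool, key=lambda n: (ranks[n], n)) if pool else None

    return pick(i, j), pick(j, i)


def match_torsion_rules(
    mg: MoleculeGraph,
    bond: tuple[int, int],
    libraries: Optional[Sequence[TorsionLibrary]] = None,
) -> TorsionAssignment:
    """First matching rule for a rotor bond.

    ``libraries`` are searched in order before the built-in library.  The
    terminal fallback (generic staggered angles, canonical reference
    atoms) fires when no pattern matches, so the result is never empty.
    """
    mol = mg.mol
    i, j = bond
    libs = list(libraries or []) + [builtin_library()]
    for lib in libs:
        for rule in lib.rules:
            n_patt = rule.pattern.GetNumAtoms()
            if n_patt != 4:
                continue
            for match in mol.GetSubstructMatches(rule.pattern, uniquify=False, maxMatches=256):
                a, b, c, d = match
                if (b, c) == (i, j) or (b, c) == (j, i):
                    if (b, c) == (j, i):
                        a, b, c, d = d, c, b, a
                    return TorsionAssignment(
                        angles=[ang for ang, _ in rule.angles],
                        tolerances=[tol for _, tol in rule.angles],
                        ref_a=a, ref_b=d, rule=rule,
                    )
    ref_a, ref_b = _default_refs(mol, i, j)
    return TorsionAssignment(
        angles=[a for a, _ in _FALLBACK_ANGLES],
        tolerances=[t for _, t in _FALLBACK_ANGLES],
        ref_a=ref_a, ref_b=ref_b, rule=None,
    )


# ---------------------------------------------------------------------------
# rotational symmetry of the bond sides


def _branch_signature(mol: Chem.Mol, start: int, blocked: int) -> str:
    """Canonical signature of the branch reachable from ``start`` without
    crossing ``blocked``."""
    seen = {blocked, start}
    stack = [start]
    while stack:
        cur = stack.pop()
        for nb in mol.GetAtomWithIdx(cur).GetNeighbors():
            if nb.GetIdx() not in seen:
                seen.add(nb.GetIdx())
                stack.append(nb.GetIdx())
    atoms = sorted(seen - {blocked})
    return Chem.MolFragmentToSmiles(
        mol, atomsToUse=atoms, rootedAtAtom=start, canonical=True,
        isomericSmiles=True, allHsExplicit=True,
    )


def detect_side_symmetry(mg: MoleculeGraph, axis_atom: int, other_atom: int) -> int:
    """Rotational symmetry order (1, 2 or 3) of the group rooted at
    ``axis_atom`` about the ``axis_atom``-``other_atom`` axis.

    Threefold requires a tetrahedral atom with three identical branches
    (trifluoromethyl, tert-butyl, ...); twofold requires a planar
    (sp2/aromatic) atom whose two flanking branches are identical
    (phenyl, nitro, ...).  Identity of branches is decided on canonical
    rooted fragment signatures, so the test is independent of input atom
    order.
    """
    mol = mg.mol
    atom = mol.GetAtomWithIdx(axis_atom)
    nbrs = [a.GetIdx() for a in atom.GetNeighbors() if a.GetIdx() != other_atom]
    sigs = [_branch_signature(mol, n, axis_atom) for n in nbrs]
    planar = atom.GetIsAromatic() or atom.GetHybridization() == Chem.HybridizationType.SP2
    if planar and len(sigs) == 2 and sigs[0] == sigs[1]:
        return 2
    if (not planar) and len(sigs) == 3 and len(set(sigs)) == 1:
        return 3
    return 1


def reduce_symmetric_angles(
    mg: MoleculeGraph,
    bond: tuple[int, int],
    angles: Sequence[float],
) -> list[float]:
    """Collapse angles made redundant by rotational symmetry of either
    bond side.

    With symmetry orders k1 and k2 on the two sides, dihedrals equivalent
    modulo ``360 / lcm(k1, k2)`` generate duplicate conformers; one
    representative (the smallest) per equivalence class is kept.
    """
    i, j = bond
    k1 = detect_side_symmetry(mg, i, j)
    k2 = detect_side_symmetry(mg, j, i)
    k = math.lcm(k1, k2)
    if k <= 1:
        return list(angles)
    period = 360.0 / k
    kept: list[float] = []
    for a in sorted(x % 360.0 for x in angles):
        red = a % period
        if any(min(abs(red - b % period), period - abs(red - b % period)) < 1e-6
               for b in kept):
            continue
        kept.append(a)
    return kept


def expand_tolerance_angles(
    angles: Sequence[float],
    tolerances: Sequence[float],
    enabled: bool = False,
) -> list[float]:
    """Optionally add the bounds of each angle's first tolerance range.

    Disabled by default; when enabled every angle ``a`` with tolerance
    ``t`` contributes ``a - t``, ``a`` and ``a + t`` (normalized to
    [0, 360) and de-duplicated, preserving first appearance).
    """
    if not enabled:
        return list(angles)
    out: list[float] = []
    for a, t in zip(angles, tolerances):
        for cand in (a - t, a, a + t) if t else (a,):
            cand %= 360.0
            if cand >= 360.0:  # fp round-up of (360 - eps) % 360
                cand = 0.0
            if not any(abs(cand - e) < 1e-9 for e in out):
                out.append(cand)
    return out
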