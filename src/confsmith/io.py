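"""Readers, writers and synthetic test-set generation.

Input: SMILES files (one molecule per line, optional whitespace-separated
name) and SDF/MOL V2000 multi-record files (3D coordinates, when present,
are kept for stereo perception or optional output inclusion).  Output:
multi-conformer SD files, one V2000 record per conformer with ``Energy``
(kcal/mol, four decimals), ``Name`` and ``ConformerIndex`` tags.

The fixture generator assembles small deterministic molecule sets from
curated templates restricted to MMFF94-covered chemistry; it is the
package's own test surface (drug-like small molecules, macrocycles,
multi-component salts, stereo-defined molecules).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

from . import forcefield as ff
from .ensemble import ConformerEnsemble
from .molprep import MoleculeGraph, PreparationError, from_rdkit, from_smiles, prepare

logger = logging.getLogger("confsmith")

__all__ = ["read_compounds", "write_ensemble", "make_fixtures", "write_fixture_file"]


def read_compounds(path, fmt: Optional[str] = None) -> Iterator[MoleculeGraph]:
    """Lazily yield compounds from a SMILES or SD file.

    Format is taken from the extension unless given explicitly
    (``smiles``/``smi`` or ``sdf``/``mol``).  Unparsable records are
    skipped with a logged diagnostic.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in (".sdf", ".mol", ".sd") else "smiles"
    fmt = fmt.lower()
    if fmt in ("smiles", "smi"):
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split(None, 1)
                smiles = parts[0]
                name = parts[1].strip() if len(parts) > 1 else f"mol{ln}"
                try:
                    yield from_smiles(smiles, name=name)
                except PreparationError as exc:
                    logger.warning("skipping line %d: %s", ln, exc)
    elif fmt in ("sdf", "mol", "sd"):
        if path.stat().st_size == 0:
            return
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        for rec, mol in enumerate(supplier):
            if mol is None or mol.GetNumAtoms() == 0:
                logger.warning("skipping unreadable SD record %d", rec)
                continue
            yield from_rdkit(mol)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_ensemble(ensemble: ConformerEnsemble, sink) -> int:
    """Write one V2000 SD record per conformer; returns the record count.

    Round trip: coordinates are preserved to the four decimals of the
    connection table, energies exactly as formatted in the ``Energy`` tag.
    """
    own = False
    if isinstance(sink, (str, Path)):
        handle = open(sink, "w")
        own = True
    else:
        handle = sink
    try:
        writer = Chem.SDWriter(handle)
        writer.SetForceV3000(False)
        count = 0
        base = Chem.Mol(ensemble.molecule.mol)
        base.RemoveAllConformers()
        for k, conf in enumerate(ensemble.conformers):
            mol = Chem.Mol(base)
            c = Chem.Conformer(mol.GetNumAtoms())
            for i, p in enumerate(conf.coords):
                c.SetAtomPosition(i, Point3D(*map(float, p)))
            mol.AddConformer(c, assignId=True)
            mol.SetProp("_Name", ensemble.molecule.name or "")
            mol.SetProp("Energy", f"{conf.energy:.4f}")
            mol.SetProp("Name", ensemble.molecule.name or "")
            mol.SetProp("ConformerIndex", str(k))
            writer.write(mol)
            count += 1
        writer.close()
        return count
    finally:
        if own:
            handle.close()


# ---------------------------------------------------------------------------
# fixture generation

_SMALL_SCAFFOLDS = [
    "c1ccc({A})cc1",
    "c1ccc({A})nc1",
    "c1ccc2ccccc2c1",
    "c1ccc(CC({A})C)cc1",
    "C1CCC({A})CC1",
    "c1ccc(OC{A})cc1",
    "CC({A})CC(C)C",
    "CCC(C{A})CC",
    "c1csc({A})c1",
    "c1ccc(C(=O)N{A})cc1",
    "CC(=O)N({A})C",
    "c1ccc(S(=O)(=O)N)cc1",
    "CCOC(=O)C{A}",
    "C1CCN({A})CC1",
    "c1ccc(CO{A})cc1",
]
_SMALL_SUBS = [
    "C", "CC", "CCC", "OC", "O", "N", "F", "Cl", "C#N",
    "C(C)C", "COC", "CO", "CC(=O)OC", "Cc9ccccc9", "C(F)(F)F",
]
_STEREO_TEMPLATES = [
    "C[C@H]({A})/C=C/{B}",
    "C[C@@H]({A})/C=C/{B}",
    "C[C@H]({A})C/C=C/{B}",
    "O[C@@H](C{A})/C=C/C{B}",
    "C[C@H](N{A})/C=C/{B}",
]
_STEREO_A = ["O", "N", "F", "Cl", "c9ccccc9", "C(=O)OC", "CO"]
_STEREO_B = ["C", "CC", "Cl", "c9ccccc9", "C(C)C"]
_IONS = ["[Na+]", "[K+]", "[Cl-]", "CC(=O)[O-]", "C[NH3+]", "[Br-]"]


def _valid_fixture(smiles: str, require=None) -> bool:
    try:
        mg = prepare(from_smiles(smiles))
        ff.parametrize(mg)
    except (PreparationError, ff.ParametrizationError, ValueError):
        return False
    if require is not None:
        return require(mg)
    return True


def _has_defined_stereo(mg: MoleculeGraph) -> bool:
    infos = Chem.FindPotentialStereo(mg.mol)
    has_atom = any(
        i.type == Chem.StereoType.Atom_Tetrahedral
        and i.specified == Chem.StereoSpecified.Specified
        for i in infos
    )
    has_bond = any(
        i.type == Chem.StereoType.Bond_Double
        and i.specified == Chem.StereoSpecified.Specified
        for i in infos
    )
    return has_atom and has_bond


def _macro_ring_smiles(rng: np.random.Generator) -> str:
    size = int(rng.integers(12, 25))
    atoms = ["C"] * size
    # sprinkle ring oxygens/nitrogens, never adjacent
    n_het = int(rng.integers(0, max(size // 6, 1) + 1))
    used = set()
    for _ in range(n_het):
        pos = int(rng.integers(1, size))
        if pos in used or (pos - 1) in used or (pos + 1) in used:
            continue
        atoms[pos] = "O" if rng.random() < 0.7 else "N"
        used.add(pos)
    # optional methyl / hydroxyl substituent on a carbon
    subs = {"C": "C(C)", "O": "C(O)"}
    if rng.random() < 0.6:
        pos = int(rng.integers(0, size))
        if atoms[pos] == "C" and pos not in used:
            atoms[pos] = subs["C" if rng.random() < 0.5 else "O"]
    return atoms[0] + "1" + "".join(atoms[1:]) + "1"


def make_fixtures(kind: str, n: int, seed: int) -> list[tuple[str, str]]:
    """Deterministic synthetic molecule sets for tests and benchmarks.

    Kinds: ``smallmol`` (template-assembled drug-like molecules, at most
    eight rotors), ``macrocycle`` (saturated 12-24 rings with random ring
    heteroatoms and substituents), ``salt`` (multi-component records),
    ``stereo`` (at least one defined R/S center and one defined double
    bond each).  Every emitted molecule parses, prepares and parametrizes
    under MMFF94.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    kind_tag = sum(ord(c) * (i + 1) for i, c in enumerate(kind)) % (2**31)
    rng = np.random.default_rng([seed, kind_tag])
    out: list[tuple[str, str]] = []
    attempts = 0
    while len(out) < n and attempts < 200 * n:
        attempts += 1
        if kind == "smallmol":
            scaf = _SMALL_SCAFFOLDS[int(rng.integers(len(_SMALL_SCAFFOLDS)))]
            sub = _SMALL_SUBS[int(rng.integers(len(_SMALL_SUBS)))]
            smiles = scaf.replace("{A}", sub)
            ok = _valid_fixture(smiles)
        elif kind == "stereo":
            tmpl = _STEREO_TEMPLATES[int(rng.integers(len(_STEREO_TEMPLATES)))]
            a = _STEREO_A[int(rng.integers(len(_STEREO_A)))]
            b = _STEREO_B[int(rng.integers(len(_STEREO_B)))]
            smiles = tmpl.replace("{A}", a).replace("{B}", b)
            ok = _valid_fixture(smiles, require=_has_defined_stereo)
        elif kind == "macrocycle":
            smiles = _macro_ring_smiles(rng)
            ok = _valid_fixture(smiles)
        elif kind == "salt":
            scaf = _SMALL_SCAFFOLDS[int(rng.integers(len(_SMALL_SCAFFOLDS)))]
            sub = _SMALL_SUBS[int(rng.integers(len(_SMALL_SUBS)))]
            ion = _IONS[int(rng.integers(len(_IONS)))]
            smiles = scaf.replace("{A}", sub) + "." + ion
            ok = _valid_fixture(smiles)
        else:
            raise ValueError(f"unknown fixture kind {kind!r}")
        if not ok:
            continue
        out.append((smiles, f"{kind}_{len(out):03d}"))
    if len(out) < n:
        raise RuntimeError(f"fixture generation stalled for kind {kind!r}")
    return out


def write_fixture_file(path, kind: str, n: int, seed: int) -> int:
    """Write a fixture SMILES file (deterministic for a given seed)."""
    rows = make_fixtures(kind, n, seed)
    with open(path, "w", newline="\n") as fh:
        for smiles, name in rows:
            fh.write(f"{smiles} {name}\n")
    return len(rows)
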