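# confsmith

Conformer ensemble generation for drug-like small molecules and
macrocycles, with MMFF94 energies and symmetry-aware RMSD diversity
selection.

## The problem

Most small-molecule modelling tasks — docking, pharmacophore searching,
shape screening, strain analysis — start from plausible 3D structures,
ideally a compact ensemble that covers the low-energy conformational
space well enough to contain something close to the bioactive
conformation. `confsmith` turns connection tables (SMILES or SDF) into
such ensembles:

* **Systematic sampling** for typical drug-like molecules: the molecule
  is cut at its rotatable bonds into building blocks (ring systems,
  linkers, side chains); conformers of each building block are generated
  once (and cached in a fragment library); whole-molecule conformers are
  then assembled over a *fragment tree* by rigid-body torsion driving,
  where each rotatable bond receives discrete dihedral angles from a
  SMARTS-keyed torsion library.
* **Stochastic sampling** for macrocycles (any ring with more than 10
  nonaromatic single bonds): repeated distance-geometry generation of
  random energy-minimized conformers until the set of unique energies
  stops growing.
* **Output compilation**: candidates are ranked by energy and picked
  greedily subject to an energy window and a minimum pairwise heavy-atom
  RMSD, where the RMSD of a pair is minimized over rigid superposition
  (Kabsch) *and* all topological symmetry mappings (graph automorphisms,
  capped at 131,072).

The energy model is MMFF94s (parameters sourced from RDKit's validated
implementation), evaluated by the package's own decomposed per-interaction
engine. The torsion driver prices each assembled conformer incrementally:

    E(A-B) = E(A) + E(B) + E_BS + E_T(theta) + E_C(theta) + E_VdW(theta)

with `E(A)`, `E(B)` the child-substructure energies, `E_BS` the rotor-bond
stretch, `E_T` the rotor torsion terms, and `E_C`/`E_VdW` the nonbonded
interactions between the two sides — so every force-field term is
evaluated at most once per generated conformer, and the root energy equals
a from-scratch evaluation of the assembled geometry to machine precision.

## Worked example

```python
from confsmith import from_smiles, generate, GenerationSettings

ensemble, report = generate(from_smiles("CCCC"), GenerationSettings(seed=1))
print(report.status, len(ensemble))
for conf in ensemble.conformers:
    print(f"{conf.energy:8.4f}")
```

prints

```
ok 2
 -4.9242
 -2.8431
```

n-Butane's torsion driver samples the three staggered rotamers (anti at
−4.92 kcal/mol, two degenerate gauche forms at −2.84 kcal/mol); the two
gauche mirror forms are 0.46 Å apart in symmetry-aware heavy-atom RMSD,
so with the default 0.5 Å diversity threshold one of them is removed and
the output ensemble holds the anti and one gauche conformer, lowest
energy first.

The same pipeline runs from the shell:

```
confsmith -i molecules.smi -o conformers.sdf -m auto -e 15 -r 0.5 -n 100 --seed 1
confsmith-bench --ensembles conformers.sdf --references xtal.sdf --thresholds 0.5,1.0,2.0
```

`confsmith` writes one V2000 SD record per conformer with `Energy`
(kcal/mol), `Name` and `ConformerIndex` tags and logs one status line per
compound; `confsmith-bench` reports best-RMSD summary statistics of
generated ensembles against reference structures (minimum over all
conformers and symmetry mappings, heavy atoms only).

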