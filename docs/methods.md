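# Methods

This note documents the models and algorithms implemented in
`confsmith`, the parameters that matter, and the numerical and design
choices made where more than one reasonable option existed.

## Preprocessing

An input connection table is prepared in a fixed sequence:
hybridization/SSSR/aromaticity perception, stereo assignment, optional
canonicalization, explicit-hydrogen completion, component perception and
topological distance matrices (breadth-first shortest bond paths).
Perception delegates to RDKit; its default aromaticity model is the one
the MMFF94 atom typer expects.

Stereo rules: input descriptors are always retained; missing descriptors
derivable from supplied 3D coordinates are computed; stereogenic double
bonds that remain undefined are set *trans* with respect to the bulkiest
substituent on each side, where bulk is estimated by five rounds of
iterated extended-connectivity sums started from the heavy-atom degree
(ties broken by atomic number, formal charge, hydrogen count — the exact
round count matters little, five is enough to separate substituents in
drug-sized molecules and keeps the value a pure graph function).
Undefined tetrahedral centers stay unspecified and are resolved
implicitly by 3D generation.

Canonicalization (off by default) is implemented as a canonical-SMILES
round trip and applied *before* hydrogen completion. The round trip
fixes both the atom and the bond enumeration order as a function of the
labelled graph; this is what makes the whole pipeline — including
floating-point summation order inside the force field and every
neighbor-iteration order — independent of the input atom order, so two
atom-permuted encodings of the same molecule produce byte-identical
output files under a fixed seed. Plain atom renumbering would leave the
bond order input-dependent.

## Force field

Energies are MMFF94 or MMFF94s (default; enforces planar delocalized
nitrogens), in kcal/mol. Atom types, partial charges, force constants
and reference geometries are taken from RDKit's validated MMFF94
implementation through its per-interaction parameter getters; the
package's own contribution is the *decomposed* engine: interaction lists
(bond stretching, angle bending with the linear-type special case,
stretch-bend, out-of-plane, torsion, van der Waals, electrostatics) as
index arrays that can be evaluated on any subset of terms, with analytic
gradients for all categories. Nonbonded pairs at topological distance
less than 3 are excluded and 1-4 electrostatics are scaled by 0.75 per
the MMFF94 convention; electrostatics use the buffered Coulomb form
(0.05 Å buffer, dielectric 1). Two variant switches exist beyond the
MMFF94/MMFF94s choice: electrostatics can be dropped entirely, and a
refined-torsion override table (plain text, four MMFF atom types plus
V1 V2 V3 per line; empty by default) can replace stock torsion
parameters.

Numerical details: term arrays are canonically sorted so that summation
order is graph-determined; near-coincident nonbonded pairs are clamped
at 10⁻³ Å so the energy stays finite; angle/torsion geometry uses
guarded norms. The test suite verifies every category against the
reference implementation (agreement ~10⁻⁹ kcal/mol) and the gradient
against central differences (max deviation < 10⁻⁴ kcal/mol/Å).

## Random conformer generation (distance geometry)

A single random structure is produced by embedding the heavy atoms (plus
hydrogens on defined stereocenters) against a constraint system, placing
the remaining hydrogens, and refining with BFGS:

* **Distance bounds.** Bonded pairs are fixed at the MMFF94 reference
  length; geminal pairs at the law-of-cosines distance of the two
  reference lengths and the equilibrium angle; vicinal pairs range from
  the coplanar to the anti-coplanar distance, collapsed to a single
  value across configured double bonds (cis or trans as declared);
  all remaining pairs get a lower bound of the two covalent radii plus a
  1.5 Å safety spacing and an upper bound equal to the sum of all
  reference bond lengths. Conflicting multi-path constraints (fused
  rings) are widened to the union and resolved by refinement.
* **Volume constraints.** Scalar-triple-product windows: ±[0.5, 1000] Å³
  with the sign of the declared configuration for tetrahedral
  stereocenters (a clockwise RDKit chiral tag corresponds to a positive
  signed volume of the neighbors in bond-listing order — a convention
  frozen by measurement and enforced in tests), and [0, 0] for planar
  groups (sp2/aromatic trivalent atoms, amide nitrogens, substituent
  quadruples of double/aromatic/amide bonds). Planarity residuals are
  normalized by the product of the three edge lengths (the sine of the
  out-of-plane angle): raw triple products grow with the cube of the
  interatomic distances and would otherwise dominate the squared-distance
  penalty, distorting embeddings of crowded planar groups such as
  N-trifluoromethyl amides. Chirality constraints keep absolute volumes,
  whose ±0.5 Å³ magnitude floor is meaningful.
* **Embedding.** Random initial positions in a box of side
  `init_factor x atom count` (0.5 for macrocycles, 0.25 otherwise — the
  smaller factor keeps small molecules compact and is a free choice, the
  macrocycle value matches the stochastic-sampling setting) are
  optimized by quasi-Newton minimization of the summed squared bound and
  volume violations in two stages: short-range (topological distance <=
  3) constraints plus volumes first, then the full system. The staging
  avoids the long-range lower bounds trapping a collapsed initial cloud.
  Embedding succeeds when the mean squared violation per constraint
  drops below 2.5 x 10⁻³ (RMS ≈ 0.05 Å) within 600 iterations; these
  values were chosen for reliability on drug-sized molecules and are
  deliberately loose — the force-field refinement, not the embedding,
  owns the final geometry.
* **Hydrogen placement.** Ideal tetrahedral / trigonal-planar / linear
  directions at MMFF94 reference X–H lengths; methyl-type rotors are
  staggered against a substituent of the placed neighbor; isolated heavy
  atoms (water) use the equilibrium H–X–H angle.
* **Refinement.** L-BFGS minimization of the full MMFF94 energy with the
  caller-selected stop rule: gradient norm (implemented as the
  equivalent per-component box tolerance) or energy change between
  quasi-Newton sweeps. Defaults: energy change <= 0.001 kcal/mol for
  stand-alone and stochastic-sampling use, gradient norm <= 0.5
  kcal/mol/Å for fragment-conformer generation (fragment geometry is
  re-priced by the parent force field during driving, so tight
  fragment-level convergence buys little).
* **Stereo validation** (geometric: signed volumes, cis/trans
  dihedrals) runs on the raw embedding and again after refinement; a
  failure triggers a retry from fresh random positions, up to 10 trials.

## Stochastic sampling

Random conformers are generated iteratively (default cap 2000 samples);
each conformer within the energy window above the running minimum enters
the working ensemble. Every 100 cycles the ensemble is reduced by
energy-duplicate removal (pairs within 0.01 kcal/mol collapse to the
lower member); if the unique count did not grow since the last check,
sampling has converged. A final pass re-applies duplicate removal and
the (possibly lowered) energy window. A cycle is one generation attempt,
successful or not, so hard molecules cannot loop forever; a wall-time
budget can additionally bound the loop. Energy-only duplicate detection
can in principle merge distinct isoenergetic conformers; the geometric
de-duplication in output compilation is the backstop.

## Systematic sampling

**Fragmentation.** A bond is cut iff it is a single, acyclic bond
between two heavy atoms that both carry at least one further heavy
neighbor, it is not adjacent to a triple-bond/allene axis, and rotation
moves heavy atoms on both sides (so terminal –CH3/–OH/–NH2 stay
attached). Amide C–N bonds are cut but flagged; their driving angles are
restricted to the planar pair {180°, 0°}. Fragment *core* atom sets
partition the molecule; in addition each fragment retains the partner
atom of every cut bond. This one-atom overlap is what makes the
incremental energy exact: every angle-bend, stretch-bend and
out-of-plane term of the parent lies fully inside one fragment, and only
the rotor-bond stretch, the rotor torsions and through-space nonbonded
terms cross a merge boundary.

**Capping and the fragment library.** For fragment-level generation the
partner atoms' open valences are hydrogen-capped. Fragment conformer
sets are stored in a library keyed by the canonical SMILES of the capped
fragment (stereo included), with coordinates held in canonical atom
order so lookups are independent of atom numbering; the library persists
as a tagged SD file. Rigid fragments (aromatic ring systems, rotor-free
moieties) get one structure; flexible rings are sampled stochastically
with a reduced budget (cap 50, period 10, window 10 kcal/mol — ring
conformer families are small, and the result is cached, so a modest
budget suffices); chains get a single template since their torsional
freedom is exhausted by the driver. When capping makes a stereocenter or
configured double bond locally non-stereogenic (e.g. a vinyl substituent
collapsing to methyl), the parent descriptor is re-imposed as an
explicit tag, such "masked" fragments bypass the library (the canonical
key cannot see the tag), and every driven conformer is re-validated
against the parent's descriptors.

**FCC enumeration.** Fragment conformer combinations are enumerated
best-first (lazy k-smallest-sums over the per-fragment energy-sorted
lists), so the 100,000-combination cap always keeps the lowest sums;
combinations above the minimum plus 1.5x the energy window are dropped.

**Fragment tree and torsion driving.** Leaves hold fragment conformers;
each internal node references one cut bond and merges its two subtrees.
The tree is built by greedily pairing the smallest subtrees first —
deterministic under canonical order. Any other association order over
the link-bond graph would yield the same result set; the greedy pairing
merely keeps intermediate stores small. Each force-field term is assigned to exactly
one node: the lowest node containing all its atoms, except link-bond
stretches, which belong to their internal node. Merging overlays the
right child on the left at the shared bond (both children carry both
bond atoms; link-bond lengths are snapped to the parent reference length
when leaves are initialized, making the overlay exact) and spins the
right substructure to each library dihedral, measured over the
rule-matched reference atoms with the IUPAC sign convention. A node
conformer's energy is the two child energies plus the node's own terms
evaluated on the merged geometry; at the root this equals the full
force-field energy to round-off, which the acceptance suite asserts at
< 10⁻³ kcal/mol. Node stores prune to the running minimum plus the
energy window and truncate to a 10,000-conformer pool; the FCC loop
exits when an FCC's energy exceeds the energy of the FCC that produced
the current best conformer plus the window, or when the working set
reaches the pool cap.

**Torsion library.** Rules are `SMARTS<TAB>angle:tolerance,...` lines;
the SMARTS describes a four-atom path whose central bond is the rotor;
first match wins, user libraries are searched before the built-in one,
and a generic staggered fallback ({60°, 180°, 300°}) always matches. The
built-in library is a compact functional-group set (amide, ester,
biaryl, conjugated sp²–sp², sp³–sp², sulfonyl, generic staggered) —
deliberately small, documented and designed for wholesale replacement by
a user library in the same format. Angles made redundant by rotational
symmetry of a bond side are removed: threefold for tetrahedral atoms
with three identical branches (CF3, tert-butyl), twofold for planar
atoms with two identical flanking branches (phenyl, nitro); branch
identity is decided on canonical rooted fragment signatures, and for two
symmetric sides the angle period is 360°/lcm(k1, k2). Optional tolerance
sampling (off by default) adds the first tolerance-range endpoints of
every angle.

## Output ensemble compilation

Candidates are ranked by increasing energy (stable for ties) and picked
greedily: a candidate is accepted iff its heavy-atom RMSD to every
already-selected conformer, minimized over proper-rotation superposition
and over all topological symmetry mappings (automorphisms of the
heavy-atom skeleton, enumerated up to 131,072 — beyond the cap the
diversity guarantee degrades gracefully), is at least the threshold
(default 0.5 Å). Selection stops at the maximum ensemble size or when
the energy window (default 15 kcal/mol systematic, 20 kcal/mol
stochastic/macrocycle) above the lowest-energy member is exhausted. An
input 3D structure can optionally join as the first-visited candidate
and then competes under the same rules. The symmetry-minimized RMSD is
not a metric (different pairs may minimize under different mappings), so
only the pairwise threshold — no triangle-type property — is guaranteed.

Multi-molecule compounds (salts, mixtures) get one ensemble per
component; compound conformers pair the i-th member of every component
ensemble, translated apart along x with a 5 Å bounding-box gap — a
simple placement that guarantees non-overlap and nothing more.

## Benchmark metrics

The "best RMSD" of an ensemble against a reference structure is the
minimum over all conformers and all symmetry mappings of the heavy-atom
Kabsch RMSD; for macrocycles the comparison can be restricted to the
macrocyclic ring atoms (mappings that do not stabilize the ring subset
are skipped). Summaries report mean/median/min/max best RMSD, ensemble
size, timing, the percentage of molecules below each RMSD threshold, and
failure counts; failed molecules are never averaged into the statistics.

## Synthetic fixtures

The fixture generator emits deterministic molecule sets from curated
templates restricted to MMFF94-covered chemistry (C, N, O, S, F, Cl
plus common functional groups): `smallmol` (template-assembled drug-like
molecules, up to ~25 heavy atoms and eight rotors), `macrocycle`
(saturated 12–24-rings with scattered ring heteroatoms and small
substituents), `salt` (small molecule plus counterion), `stereo` (one
defined tetrahedral center and one defined double bond each). These
fixtures exercise the full pipeline but are simpler than real screening
libraries: no fused polycyclics beyond naphthalene, no charged
zwitterions, no rotor counts beyond eight, no conformationally coupled
macrocycle substituents. Passing tests therefore demonstrate
correctness of the algorithms and invariants on this chemistry, not
benchmark-grade accuracy on crystallographic datasets.

Problem sizes used by the test suite and the acceptance script (100
molecules per invariant batch, 50 stereo fixtures, 30 torsion-driving
molecules, 2000-sample stochastic runs on benzene/cyclohexane) were
chosen so each check exercises the full pipeline at a few seconds per
molecule on a single core.

## Known limitations

* The built-in torsion library is a minimal stand-in; production use
  should supply a statistically derived library (the file format admits
  drop-in replacement).
* Duplicate detection during stochastic sampling is energy-only by
  design; geometrically distinct isoenergetic conformers can merge
  before output compilation.
* One documented physical edge: MMFF94 minima of sterically crowded
  branched alkanes carry bond lengths up to ~0.05 Å away from the
  reference bond lengths (confirmed against the reference
  implementation); checks that compare minimized bonds to reference
  lengths must allow for this strain.
* Hydrogen-only rotors (–OH, –NH2) are not driven; their orientation
  comes from placement plus refinement, so ensembles do not enumerate
  hydroxyl rotamers (lowering the RMSD threshold retains more of them
  implicitly, mirroring the tool's recommendation).
* Conformer generation is single-threaded; batches parallelize naturally
  at the process level.
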