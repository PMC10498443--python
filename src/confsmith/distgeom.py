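"""Random conformer generation by distance geometry.

A single random 3D structure is produced by (1) building pairwise distance
bounds and signed-volume constraints from the force-field reference
geometry and the declared stereochemistry, (2) optimizing randomly
initialized heavy-atom coordinates against those constraints, (3) placing
hydrogens from hybridization-ideal geometry, (4) refining the complete
structure against the MMFF94 energy with BFGS, and (5) validating that all
defined stereocenters come out with the declared configuration, retrying
from fresh random positions a bounded number of times otherwise.

Only heavy atoms and hydrogens bonded to defined stereocenters take part in
the embedding; all other hydrogens are attached afterwards, which roughly
halves the dimension of the embedding problem for organic molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from scipy.optimize import minimize

from . import forcefield as ff
from .molprep import MoleculeGraph

__all__ = [
    "DistanceBounds",
    "VolumeConstraint",
    "Conformer",
    "DGSettings",
    "EmbedError",
    "RefineError",
    "StereoError",
    "GenerationError",
    "build_distance_bounds",
    "build_volume_constraints",
    "embed",
    "place_hydrogens",
    "refine",
    "check_stereo",
    "stereo_ok",
    "generate_random_conformer",
    "RandomConformerGenerator",
]

# single-bond covalent radii (A) used for the TD > 3 lower-bound rule
COVALENT_RADII = {
    1: 0.31, 5: 0.84, 6: 0.76, 7: 0.71, 8: 0.66, 9: 0.57, 14: 1.11,
    15: 1.07, 16: 1.05, 17: 1.02, 33: 1.19, 34: 1.20, 35: 1.20, 53: 1.39,
}
_DEFAULT_RADIUS = 1.0
_SAFETY_SPACING = 1.5  # A, added to covalent radii for nonlocal lower bounds

# signed-volume window for tetrahedral stereocenters (A^3)
_VOL_LO, _VOL_HI = 0.5, 1000.0


class EmbedError(RuntimeError):
    """Constraint violation could not be reduced below tolerance."""


class RefineError(RuntimeError):
    """BFGS energy refinement failed (non-finite energy or no progress)."""


class StereoError(RuntimeError):
    """A defined stereocenter came out with the wrong configuration."""


class GenerationError(RuntimeError):
    """No valid conformer within the allowed number of trials."""


@dataclass
class Conformer:
    """3D coordinates (A) plus the MMFF94 energy (kcal/mol)."""

    coords: np.ndarray
    energy: float

    def copy(self) -> "Conformer":
        return Conformer(self.coords.copy(), self.energy)


@dataclass
class DistanceBounds:
    """Condensed lower/upper distance bounds over the embedded atoms.

    ``i``/``j`` are positions into the embedded-atom list; ``tight`` marks
    short-range (topological distance <= 3) constraints that are satisfied
    first during embedding.
    """

    n: int
    i: np.ndarray
    j: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    tight: np.ndarray

    def as_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.zeros((self.n, self.n))
        up = np.full((self.n, self.n), np.inf)
        np.fill_diagonal(up, 0.0)
        lo[self.i, self.j] = self.lower
        lo[self.j, self.i] = self.lower
        up[self.i, self.j] = self.upper
        up[self.j, self.i] = self.upper
        return lo, up


@dataclass
class VolumeConstraint:
    """Signed-volume window for an ordered atom quadruple (local indices).

    The volume is the scalar triple product
    ``(r1 - r0) . ((r2 - r0) x (r3 - r0))``; planar groups use ``lo = hi =
    0`` and defined tetrahedral stereocenters a one-sided window whose sign
    encodes the configuration.  Planarity constraints set ``normalized``:
    their residual is the triple product divided by the product of the
    three edge lengths (the sine of the out-of-plane angle, order of
    magnitude 1), which keeps them commensurate with the squared-distance
    penalty terms during embedding.
    """

    atoms: tuple[int, int, int, int]
    lo: float
    hi: float
    normalized: bool = False


@dataclass
class DGSettings:
    """Knobs of the random conformer generator."""

    trials: int = 10
    init_factor: float = 0.25      # 0.5 for macrocycle sampling
    stop_criterion: str = "energy_delta"   # or "gradient_norm"
    stop_threshold: float = 0.001  # kcal/mol resp. kcal/mol/A
    max_refine_iter: int = 400
    embed_tol: float = 2.5e-3      # mean squared violation per constraint
    max_embed_iter: int = 600


# ---------------------------------------------------------------------------
# constraint construction


def _embedded_atoms(mg: MoleculeGraph, atoms: Optional[Sequence[int]] = None) -> list[int]:
    """Heavy atoms plus hydrogens bonded to defined stereocenters."""
    mol = mg.mol
    keep = []
    pool = range(mol.GetNumAtoms()) if atoms is None else atoms
    for i in pool:
        a = mol.GetAtomWithIdx(i)
        if a.GetAtomicNum() > 1:
            keep.append(i)
        else:
            nb = a.GetNeighbors()[0]
            if nb.GetChiralTag() in (
                Chem.ChiralType.CHI_TETRAHEDRAL_CW,
                Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
            ):
                keep.append(i)
    return keep


def _geminal_distance(r1: float, r2: float, theta_deg: float) -> float:
    th = np.radians(theta_deg)
    return float(np.sqrt(r1 * r1 + r2 * r2 - 2 * r1 * r2 * np.cos(th)))


def _vicinal_distance(r_ij, r_jk, r_kl, th_ijk, th_jkl, cis: bool) -> float:
    """Distance i..l of a 4-atom chain in the coplanar (cis) or
    anti-coplanar (trans) arrangement."""
    t1 = np.radians(th_ijk)
    t2 = np.radians(th_jkl)
    pj = np.zeros(3)
    pk = np.array([r_jk, 0.0, 0.0])
    pi = np.array([r_ij * np.cos(t1), r_ij * np.sin(t1), 0.0])
    sgn = 1.0 if cis else -1.0
    pl = pk + np.array([-r_kl * np.cos(t2), sgn * r_kl * np.sin(t2), 0.0])
    return float(np.linalg.norm(pi - pl))


def _defined_double_bonds(mol: Chem.Mol) -> dict:
    """bond idx -> (ref_a, ref_b, is_cis) for configured double bonds.

    Besides perceived stereogenic double bonds, explicitly tagged
    cis/trans bonds are honored even when the bond is not locally
    stereogenic - capped fragments use such tags to carry the parent
    molecule's configuration across fragmentation.
    """
    out = {}
    for info in Chem.FindPotentialStereo(mol):
        if info.type != Chem.StereoType.Bond_Double:
            continue
        if info.specified != Chem.StereoSpecified.Specified:
            continue
        ctrl = list(info.controllingAtoms)
        ref_a, ref_b = int(ctrl[0]), int(ctrl[2])
        cis = info.descriptor == Chem.StereoDescriptor.Bond_Cis
        out[int(info.centeredOn)] = (ref_a, ref_b, cis)
    for b in mol.GetBonds():
        if b.GetIdx() in out:
            continue
        if b.GetStereo() in (Chem.BondStereo.STEREOCIS, Chem.BondStereo.STEREOTRANS):
            sa = list(b.GetStereoAtoms())
            if len(sa) != 2:
                continue
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            ra, rb = int(sa[0]), int(sa[1])
            # stereo atoms are stored begin-side first
            if ra not in [n.GetIdx() for n in mol.GetAtomWithIdx(i).GetNeighbors()]:
                ra, rb = rb, ra
            out[b.GetIdx()] = (ra, rb, b.GetStereo() == Chem.BondStereo.STEREOCIS)
    return out


def build_distance_bounds(
    mg: MoleculeGraph,
    param: ff.ForceFieldParametrization,
    td: Optional[np.ndarray] = None,
    embed_atoms: Optional[Sequence[int]] = None,
) -> tuple[DistanceBounds, list[int]]:
    """Distance bounds for the embedded atoms of one component.

    Bounds by topological distance class: bonded pairs are fixed at the
    MMFF94 reference length; geminal pairs at the law-of-cosines distance
    of the two reference lengths and the equilibrium angle; vicinal pairs
    range from the coplanar to the anti-coplanar distance (collapsed to a
    single value across configured double bonds); all remaining pairs get
    a covalent-radii-plus-1.5-A lower bound and an upper bound equal to
    the total sum of reference bond lengths.

    Returns the bounds plus the embedded-atom index list (global indices).
    """
    mol = mg.mol
    if td is None:
        td = np.asarray(Chem.GetDistanceMatrix(mol), dtype=float)
    emb = _embedded_atoms(mg, embed_atoms)
    local = {g: l for l, g in enumerate(emb)}
    nloc = len(emb)

    upper_default = float(np.sum(param.bond_r0))
    dbl = _defined_double_bonds(mol)

    lo: dict[tuple[int, int], float] = {}
    up: dict[tuple[int, int], float] = {}
    tight: set[tuple[int, int]] = set()

    def key(a, b):
        la, lb = local[a], local[b]
        return (la, lb) if la < lb else (lb, la)

    def narrow(a, b, low, high, is_tight=True):
        k = key(a, b)
        lo[k] = max(lo.get(k, 0.0), low) if k in lo else low
        up[k] = min(up.get(k, np.inf), high) if k in up else high
        if lo[k] > up[k]:  # conflicting paths: widen to the union
            lo[k], up[k] = min(lo[k], low), max(up[k], high)
        if is_tight:
            tight.add(k)

    embset = set(emb)

    # TD = 1 and the geminal/vicinal path enumerations
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in embset and j in embset:
            r0 = param.ref_bond_length(i, j)
            narrow(i, j, r0, r0)

    for a in mol.GetAtoms():
        j = a.GetIdx()
        nbrs = [x.GetIdx() for x in a.GetNeighbors()]
        for ii in range(len(nbrs)):
            for kk in range(ii + 1, len(nbrs)):
                i, k = nbrs[ii], nbrs[kk]
                if i not in embset or k not in embset or td[i, k] != 2:
                    continue
                t0 = param.ref_angle(i, j, k)
                if t0 is None:
                    continue
                d = _geminal_distance(
                    param.ref_bond_length(i, j), param.ref_bond_length(j, k), t0
                )
                narrow(i, k, d, d)

    for b in mol.GetBonds():
        j, k = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        config = dbl.get(b.GetIdx())
        for i in (x.GetIdx() for x in mol.GetAtomWithIdx(j).GetNeighbors()):
            if i == k:
                continue
            for l in (x.GetIdx() for x in mol.GetAtomWithIdx(k).GetNeighbors()):
                if l == j or l == i:
                    continue
                if i not in embset or l not in embset or td[i, l] != 3:
                    continue
                t1 = param.ref_angle(i, j, k)
                t2 = param.ref_angle(j, k, l)
                if t1 is None or t2 is None:
                    continue
                args = (
                    param.ref_bond_length(i, j),
                    param.ref_bond_length(j, k),
                    param.ref_bond_length(k, l),
                    t1, t2,
                )
                if config is not None:
                    ref_a, ref_b, is_cis = config
                    # flip the declared relation once per side where the
                    # substituent is not the reference atom
                    rel_cis = is_cis ^ (i != ref_a) ^ (l != ref_b)
                    d = _vicinal_distance(*args, cis=rel_cis)
                    narrow(i, l, d, d)
                else:
                    d_cis = _vicinal_distance(*args, cis=True)
                    d_trans = _vicinal_distance(*args, cis=False)
                    narrow(i, l, min(d_cis, d_trans), max(d_cis, d_trans))

    # TD > 3 (and any embedded pair not covered above)
    ii, jj, ll, uu, tt = [], [], [], [], []
    for la in range(nloc):
        for lb in range(la + 1, nloc):
            k = (la, lb)
            if k in lo:
                ii.append(la)
                jj.append(lb)
                ll.append(lo[k])
                uu.append(up[k])
                tt.append(k in tight)
                continue
            ga, gb = emb[la], emb[lb]
            za = mol.GetAtomWithIdx(ga).GetAtomicNum()
            zb = mol.GetAtomWithIdx(gb).GetAtomicNum()
            low = (
                COVALENT_RADII.get(za, _DEFAULT_RADIUS)
                + COVALENT_RADII.get(zb, _DEFAULT_RADIUS)
                + _SAFETY_SPACING
            )
            ii.append(la)
            jj.append(lb)
            ll.append(low)
            uu.append(upper_default)
            tt.append(False)

    bounds = DistanceBounds(
        n=nloc,
        i=np.array(ii, dtype=int),
        j=np.array(jj, dtype=int),
        lower=np.array(ll, dtype=float),
        upper=np.array(uu, dtype=float),
        tight=np.array(tt, dtype=bool),
    )
    return bounds, emb


def _is_amide_nitrogen(atom: Chem.Atom) -> bool:
    if atom.GetAtomicNum() != 7:
        return False
    for nb in atom.GetNeighbors():
        if nb.GetAtomicNum() != 6:
            continue
        for nb2 in nb.GetNeighbors():
            bond = nb.GetOwningMol().GetBondBetweenAtoms(nb.GetIdx(), nb2.GetIdx())
            if nb2.GetAtomicNum() == 8 and bond.GetBondType() == Chem.BondType.DOUBLE:
                return True
    return False


def tetrahedral_stereocenters(mol: Chem.Mol) -> list[tuple[int, list[int], int]]:
    """(center, neighbor indices in bond-listing order, demanded sign).

    A clockwise chiral tag corresponds to a positive scalar triple product
    of the neighbors taken in bond-listing order (center substituted for
    the missing fourth neighbor on trivalent centers).
    """
    out = []
    for a in mol.GetAtoms():
        tag = a.GetChiralTag()
        if tag not in (
            Chem.ChiralType.CHI_TETRAHEDRAL_CW,
            Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
        ):
            continue
        nbrs = [x.GetIdx() for x in a.GetNeighbors()]
        if len(nbrs) < 3:
            continue
        sign = 1 if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW else -1
        out.append((a.GetIdx(), nbrs, sign))
    return out


def build_volume_constraints(
    mg: MoleculeGraph,
    embed_atoms: Optional[Sequence[int]] = None,
) -> list[VolumeConstraint]:
    """Signed-volume constraints over the embedded atoms.

    One chirality constraint per defined tetrahedral stereocenter and
    zero-volume (planarity) constraints for trivalent sp2/aromatic atoms,
    amide nitrogens and the substituent quadruples of amide, aromatic and
    double bonds.  With the default ``embed_atoms=None`` constraints are
    produced over all atoms; pass the embedded-atom list to restrict (and
    re-index) them for the embedding stage.
    """
    mol = mg.mol
    if embed_atoms is None:
        local = {i: i for i in range(mol.GetNumAtoms())}
    else:
        emb = _embedded_atoms(mg, embed_atoms)
        local = {g: l for l, g in enumerate(emb)}
    out: list[VolumeConstraint] = []

    for center, nbrs, sign in tetrahedral_stereocenters(mol):
        pts = list(nbrs) if len(nbrs) == 4 else [center] + list(nbrs)
        if any(p not in local for p in pts):
            continue
        quad = tuple(local[p] for p in pts)
        if sign > 0:
            out.append(VolumeConstraint(quad, _VOL_LO, _VOL_HI))
        else:
            out.append(VolumeConstraint(quad, -_VOL_HI, -_VOL_LO))

    for a in mol.GetAtoms():
        if a.GetDegree() != 3:
            continue
        planar = (
            a.GetIsAromatic()
            or a.GetHybridization() == Chem.HybridizationType.SP2
            or _is_amide_nitrogen(a)
        )
        if not planar:
            continue
        pts = [a.GetIdx()] + [x.GetIdx() for x in a.GetNeighbors()]
        if any(p not in local for p in pts):
            continue
        out.append(
            VolumeConstraint(tuple(local[p] for p in pts), 0.0, 0.0, normalized=True)
        )

    for b in mol.GetBonds():
        planar_bond = b.GetBondType() == Chem.BondType.DOUBLE or b.GetIsAromatic() or (
            b.GetBondType() == Chem.BondType.SINGLE
            and _is_amide_nitrogen(b.GetBeginAtom()) != _is_amide_nitrogen(b.GetEndAtom())
            and any(_is_amide_nitrogen(x) for x in (b.GetBeginAtom(), b.GetEndAtom()))
        )
        if not planar_bond:
            continue
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        for x in (n.GetIdx() for n in mol.GetAtomWithIdx(i).GetNeighbors()):
            if x == j:
                continue
            for y in (n.GetIdx() for n in mol.GetAtomWithIdx(j).GetNeighbors()):
                if y == i:
                    continue
                pts = (x, i, j, y)
                if any(p not in local for p in pts):
                    continue
                out.append(
                    VolumeConstraint(
                        tuple(local[p] for p in pts), 0.0, 0.0, normalized=True)
                )

    return out


# ---------------------------------------------------------------------------
# embedding


def signed_volume(coords: np.ndarray, quad: Sequence[int]) -> float:
    p0, p1, p2, p3 = (coords[q] for q in quad)
    return float(np.dot(p1 - p0, np.cross(p2 - p0, p3 - p0)))


def _volume_residual(x, v: VolumeConstraint) -> float:
    """Constraint residual: signed volume (chiral) or normalized triple
    product (planarity)."""
    q0, q1, q2, q3 = v.atoms
    a = x[q1] - x[q0]
    b = x[q2] - x[q0]
    c = x[q3] - x[q0]
    vol = float(np.dot(a, np.cross(b, c)))
    if not v.normalized:
        return vol
    scale = max(
        np.linalg.norm(a) * np.linalg.norm(b) * np.linalg.norm(c), 1e-6
    )
    return vol / scale


def _violation_terms(x, bounds: DistanceBounds, volumes, mask=None):
    i, j, lo, up = bounds.i, bounds.j, bounds.lower, bounds.upper
    if mask is not None:
        i, j, lo, up = i[mask], j[mask], lo[mask], up[mask]
    d = x[i] - x[j]
    r = np.sqrt(np.maximum(np.sum(d * d, axis=1), 1e-12))
    under = np.maximum(lo - r, 0.0)
    over = np.maximum(r - up, 0.0)
    vviol = np.array(
        [
            max(v.lo - _volume_residual(x, v), 0.0)
            + max(_volume_residual(x, v) - v.hi, 0.0)
            for v in volumes
        ]
    )
    return under, over, vviol


def _penalty_and_grad(flat, n, bi, bj, lo, up, volumes):
    x = flat.reshape(n, 3)
    g = np.zeros_like(x)
    d = x[bi] - x[bj]
    r = np.sqrt(np.maximum(np.sum(d * d, axis=1), 1e-12))
    under = np.maximum(lo - r, 0.0)
    over = np.maximum(r - up, 0.0)
    e = float(np.sum(under**2) + np.sum(over**2))
    coef = (2.0 * (over - under) / r)[:, None] * d
    np.add.at(g, bi, coef)
    np.add.at(g, bj, -coef)
    for v in volumes:
        q0, q1, q2, q3 = v.atoms
        a = x[q1] - x[q0]
        b = x[q2] - x[q0]
        c = x[q3] - x[q0]
        vol = float(np.dot(a, np.cross(b, c)))
        dv1 = np.cross(b, c)
        dv2 = np.cross(c, a)
        dv3 = np.cross(a, b)
        if v.normalized:
            na = max(np.linalg.norm(a), 1e-6)
            nb = max(np.linalg.norm(b), 1e-6)
            nc = max(np.linalg.norm(c), 1e-6)
            scale = na * nb * nc
            res = vol / scale
            # d(res)/da = (b x c)/scale - res * a/|a|^2, and cyclic
            dv1 = dv1 / scale - (res / na**2) * a
            dv2 = dv2 / scale - (res / nb**2) * b
            dv3 = dv3 / scale - (res / nc**2) * c
        else:
            res = vol
        if res < v.lo:
            viol = res - v.lo
        elif res > v.hi:
            viol = res - v.hi
        else:
            continue
        e += viol * viol
        g[q1] += 2 * viol * dv1
        g[q2] += 2 * viol * dv2
        g[q3] += 2 * viol * dv3
        g[q0] -= 2 * viol * (dv1 + dv2 + dv3)
    return e, g.ravel()


def embed(
    bounds: DistanceBounds,
    volumes: Sequence[VolumeConstraint],
    rng: np.random.Generator,
    init_range: float,
    tol: float = 2.5e-3,
    max_iter: int = 600,
) -> np.ndarray:
    """Optimize random initial positions against the constraint system.

    Runs a two-stage quasi-Newton minimization of the summed squared bound
    and volume violations: short-range (tight) constraints plus volumes
    first, the full system second.  Raises :class:`EmbedError` when the
    mean squared violation per constraint stays above ``tol``.
    """
    n = bounds.n
    x0 = rng.uniform(-0.5 * init_range, 0.5 * init_range, size=(n, 3))
    if n == 1:
        return x0

    stages = []
    if np.any(bounds.tight):
        stages.append(bounds.tight)
    stages.append(np.ones(len(bounds.i), dtype=bool))

    flat = x0.ravel()
    for mask in stages:
        res = minimize(
            _penalty_and_grad,
            flat,
            args=(n, bounds.i[mask], bounds.j[mask], bounds.lower[mask],
                  bounds.upper[mask], list(volumes)),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-10},
        )
        flat = res.x
    x = flat.reshape(n, 3)

    n_constraints = len(bounds.i) + len(volumes)
    under, over, vviol = _violation_terms(x, bounds, volumes)
    total = float(np.sum(under**2) + np.sum(over**2) + np.sum(vviol**2))
    if total > tol * max(n_constraints, 1):
        raise EmbedError(
            f"embedding stalled: mean squared violation "
            f"{total / max(n_constraints, 1):.2e} > {tol:.2e}"
        )
    return x


# ---------------------------------------------------------------------------
# hydrogen placement


def _orthonormal_pair(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def _unit(v):
    return v / max(np.linalg.norm(v), 1e-12)


def place_hydrogens(
    mg: MoleculeGraph,
    param: ff.ForceFieldParametrization,
    coords: np.ndarray,
    placed: np.ndarray,
) -> np.ndarray:
    """Fill in coordinates of not-yet-placed hydrogens.

    Positions follow the hybridization-ideal geometry of the parent heavy
    atom (tetrahedral / trigonal-planar / linear) at the MMFF94 reference
    X-H bond length; the subsequent force-field refinement relaxes the
    remaining strain.
    """
    mol = mg.mol
    x = coords.copy()
    done = placed.copy()
    for a in mol.GetAtoms():
        h_idx = sorted(nb.GetIdx() for nb in a.GetNeighbors()
                       if nb.GetAtomicNum() == 1 and not done[nb.GetIdx()])
        if not h_idx:
            continue
        c = a.GetIdx()
        nbrs = sorted(nb.GetIdx() for nb in a.GetNeighbors() if done[nb.GetIdx()])
        dirs = [_unit(x[i] - x[c]) for i in nbrs]
        hyb = mg.hybridization(c)
        m = len(h_idx)
        new_dirs: list[np.ndarray] = []

        if hyb == "sp" or (hyb == "other" and len(dirs) == 1 and m == 1):
            new_dirs = [-dirs[0]] if dirs else [np.array([1.0, 0.0, 0.0])]
        elif hyb == "sp2" or (hyb == "other" and a.GetIsAromatic()):
            if len(dirs) >= 2:
                new_dirs = [-_unit(dirs[0] + dirs[1])]
            elif len(dirs) == 1:
                # plane from the neighbor's substituents keeps conjugated
                # groups planar (e.g. terminal =CH2)
                nb = mol.GetAtomWithIdx(nbrs[0])
                normal = None
                others = sorted(o.GetIdx() for o in nb.GetNeighbors()
                                if o.GetIdx() != c and done[o.GetIdx()])
                if others:
                    normal = np.cross(dirs[0], _unit(x[others[0]] - x[nbrs[0]]))
                    if np.linalg.norm(normal) < 1e-6:
                        normal = None
                if normal is None:
                    normal = np.cross(dirs[0], _orthonormal_pair(dirs[0])[0])
                normal = _unit(normal)
                inplane = _unit(np.cross(normal, dirs[0]))
                # rotate d0 by +-120 deg within the plane
                ca, sa = np.cos(np.radians(120.0)), np.sin(np.radians(120.0))
                for sgn in (1.0, -1.0)[:m]:
                    new_dirs.append(_unit(dirs[0] * ca + sgn * inplane * sa))
            else:
                u, v = _orthonormal_pair(np.array([0.0, 0.0, 1.0]))
                for t in range(m):
                    ang = 2 * np.pi * t / max(m, 3)
                    new_dirs.append(_unit(u * np.cos(ang) + v * np.sin(ang)))
        else:  # sp3 / fallback
            theta_t = np.radians(109.471)
            if len(dirs) >= 3:
                new_dirs = [-_unit(dirs[0] + dirs[1] + dirs[2])]
            elif len(dirs) == 2:
                b = -_unit(dirs[0] + dirs[1])
                p = np.cross(dirs[0], dirs[1])
                if np.linalg.norm(p) < 1e-6:
                    p = _orthonormal_pair(b)[0]
                p = _unit(p)
                half = 0.5 * theta_t
                for sgn in (1.0, -1.0)[:m]:
                    new_dirs.append(_unit(b * np.cos(half) + sgn * p * np.sin(half)))
            elif len(dirs) == 1:
                axis = -dirs[0]
                u, v = _orthonormal_pair(axis)
                # stagger against a substituent of the placed neighbor
                offset = 0.0
                nb = mol.GetAtomWithIdx(nbrs[0])
                ref = sorted(o.GetIdx() for o in nb.GetNeighbors()
                             if o.GetIdx() != c and done[o.GetIdx()])
                if ref:
                    w = x[ref[0]] - x[nbrs[0]]
                    w_perp = w - np.dot(w, axis) * axis
                    if np.linalg.norm(w_perp) > 1e-6:
                        w_perp = _unit(w_perp)
                        offset = np.arctan2(np.dot(w_perp, v), np.dot(w_perp, u)) + np.pi
                tilt = np.pi - theta_t
                for t in range(m):
                    ang = offset + 2 * np.pi * t / 3.0
                    new_dirs.append(
                        _unit(axis * np.cos(tilt)
                              + (u * np.cos(ang) + v * np.sin(ang)) * np.sin(tilt))
                    )
            else:
                # isolated heavy atom (water oxygen, methane carbon, ...)
                t0 = None
                if m >= 2:
                    t0 = param.ref_angle(h_idx[0], c, h_idx[1])
                th = np.radians(t0 if t0 else 109.471)
                if m == 1:
                    new_dirs = [np.array([1.0, 0.0, 0.0])]
                elif m == 2:
                    new_dirs = [
                        np.array([np.sin(th / 2), 0.0, np.cos(th / 2)]),
                        np.array([-np.sin(th / 2), 0.0, np.cos(th / 2)]),
                    ]
                elif m == 3:
                    axis = np.array([0.0, 0.0, 1.0])
                    u, v = _orthonormal_pair(axis)
                    new_dirs = [
                        _unit(axis * np.cos(th)
                              + (u * np.cos(2 * np.pi * t / 3)
                                 + v * np.sin(2 * np.pi * t / 3)) * np.sin(th))
                        for t in range(3)
                    ]
                else:  # methane-like
                    new_dirs = [
                        _unit(np.array(d))
                        for d in ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))
                    ]

        for h, d in zip(h_idx, new_dirs):
            r0 = param.ref_bond_length(c, h)
            x[h] = x[c] + d * r0
            done[h] = True

    return x


# ---------------------------------------------------------------------------
# refinement


def refine(
    param: ff.ForceFieldParametrization,
    coords: np.ndarray,
    stop_criterion: str = "gradient_norm",
    stop_threshold: float = 0.1,
    max_iter: int = 400,
) -> Conformer:
    """BFGS minimization of the MMFF94 energy.

    ``stop_criterion`` selects the caller-specified termination test:
    ``gradient_norm`` (kcal/mol/A, Euclidean norm) or ``energy_delta``
    (kcal/mol between successive quasi-Newton sweeps).  Energy decreases
    monotonically over accepted steps; the lowest-energy point seen is
    returned.
    """
    if stop_criterion not in ("gradient_norm", "energy_delta"):
        raise ValueError(f"unknown stop criterion {stop_criterion!r}")
    n = param.n_atoms
    x = np.asarray(coords, dtype=float).reshape(n, 3).copy()

    def fun(flat):
        e, g = ff.energy_and_gradient(param, flat.reshape(n, 3))
        return e, g.ravel()

    e_prev, g0 = fun(x.ravel())
    if not np.isfinite(e_prev):
        raise RefineError("non-finite energy at start geometry")
    best_x, best_e = x.copy(), e_prev

    if stop_criterion == "gradient_norm":
        # max|g_i| <= thr/sqrt(3n) implies ||g||_2 <= thr, so a single
        # quasi-Newton run with that box tolerance usually suffices
        res = minimize(
            fun, x.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": max_iter,
                     "ftol": 1e-14,
                     "gtol": stop_threshold / np.sqrt(3.0 * n)},
        )
        e_now = float(res.fun)
        if not np.isfinite(e_now):
            raise RefineError("non-finite energy during refinement")
        if e_now <= best_e:
            best_e = e_now
            best_x = res.x.reshape(n, 3)
        return Conformer(best_x, best_e)

    done_iter = 0
    chunk = 40
    while done_iter < max_iter:
        res = minimize(
            fun, best_x.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": chunk, "ftol": 1e-14, "gtol": 1e-10},
        )
        done_iter += max(res.nit, 1)
        e_now = float(res.fun)
        if not np.isfinite(e_now):
            raise RefineError("non-finite energy during refinement")
        if e_now <= best_e:
            best_e = e_now
            best_x = res.x.reshape(n, 3)
        if stop_criterion == "gradient_norm":
            if float(np.linalg.norm(res.jac)) <= stop_threshold:
                break
        else:
            if abs(e_prev - e_now) <= stop_threshold:
                break
        if res.nit < chunk:  # optimizer converged on its own terms
            break
        e_prev = e_now
    return Conformer(best_x, best_e)


# ---------------------------------------------------------------------------
# stereo validation


def check_stereo(mg: MoleculeGraph, coords: np.ndarray) -> dict:
    """Compare coordinate-derived stereo with the declared descriptors.

    Returns ``{("atom", idx): bool, ("bond", idx): bool}`` for every
    defined tetrahedral center and configured double bond; unspecified
    centers are skipped.
    """
    mol = mg.mol
    out = {}
    for center, nbrs, sign in tetrahedral_stereocenters(mol):
        quad = list(nbrs) if len(nbrs) == 4 else [center] + list(nbrs)
        vol = signed_volume(coords, quad)
        out[("atom", center)] = bool(np.sign(vol) == sign)
    for bidx, (ref_a, ref_b, is_cis) in _defined_double_bonds(mol).items():
        b = mol.GetBondWithIdx(bidx)
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        # controlling atoms are listed per bond end: ref_a flanks the lower
        # numbered end as reported by stereo perception
        phi = _measure_dihedral(coords, ref_a, i, j, ref_b)
        if abs(np.degrees(phi)) <= 90.0:
            got_cis = True
        else:
            got_cis = False
        out[("bond", bidx)] = got_cis == is_cis
    return out


def _measure_dihedral(x, i, j, k, l) -> float:
    b1 = x[j] - x[i]
    b2 = x[k] - x[j]
    b3 = x[l] - x[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / max(np.linalg.norm(b2), 1e-12))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def stereo_ok(mg: MoleculeGraph, coords: np.ndarray) -> bool:
    return all(check_stereo(mg, coords).values())


def _partial_stereo_ok(mg: MoleculeGraph, coords, placed) -> bool:
    """Stereo check restricted to centers whose atoms are all placed."""
    mol = mg.mol
    for center, nbrs, sign in tetrahedral_stereocenters(mol):
        quad = list(nbrs) if len(nbrs) == 4 else [center] + list(nbrs)
        if not all(placed[q] for q in quad):
            continue
        if np.sign(signed_volume(coords, quad)) != sign:
            return False
    for bidx, (ref_a, ref_b, is_cis) in _defined_double_bonds(mol).items():
        b = mol.GetBondWithIdx(bidx)
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if not all(placed[q] for q in (ref_a, i, j, ref_b)):
            continue
        phi = _measure_dihedral(coords, ref_a, i, j, ref_b)
        if (abs(np.degrees(phi)) <= 90.0) != is_cis:
            return False
    return True


# ---------------------------------------------------------------------------
# full workflow


class RandomConformerGenerator:
    """Reusable random conformer generator for one molecule.

    Precomputes the constraint system once; every :meth:`generate` call
    runs the embed / hydrogen placement / refine / stereo-check loop with
    fresh random initial positions.
    """

    def __init__(
        self,
        mg: MoleculeGraph,
        param: ff.ForceFieldParametrization,
        settings: Optional[DGSettings] = None,
        td: Optional[np.ndarray] = None,
    ):
        self.mg = mg
        self.param = param
        self.settings = settings or DGSettings()
        self.bounds, self.embedded = build_distance_bounds(mg, param, td=td)
        self.volumes = build_volume_constraints(mg, embed_atoms=self.embedded)
        self.n_atoms = mg.n_atoms

    def generate(self, rng: np.random.Generator) -> Conformer:
        s = self.settings
        init_range = max(s.init_factor * self.n_atoms, 3.0)
        last_err: Exception = GenerationError("no trials run")
        for _ in range(s.trials):
            try:
                local = embed(
                    self.bounds, self.volumes, rng, init_range,
                    tol=s.embed_tol, max_iter=s.max_embed_iter,
                )
            except EmbedError as exc:
                last_err = exc
                continue
            coords = np.zeros((self.n_atoms, 3))
            placed = np.zeros(self.n_atoms, dtype=bool)
            coords[self.embedded] = local
            placed[self.embedded] = True
            if not _partial_stereo_ok(self.mg, coords, placed):
                last_err = StereoError("raw embedding violates declared stereo")
                continue
            full = place_hydrogens(self.mg, self.param, coords, placed)
            try:
                conf = refine(
                    self.param, full,
                    stop_criterion=s.stop_criterion,
                    stop_threshold=s.stop_threshold,
                    max_iter=s.max_refine_iter,
                )
            except RefineError as exc:
                last_err = exc
                continue
            if not stereo_ok(self.mg, conf.coords):
                last_err = StereoError("refined structure violates declared stereo")
                continue
            return conf
        raise GenerationError(
            f"no valid conformer in {s.trials} trials (last: {last_err})"
        )


def generate_random_conformer(
    mg: MoleculeGraph,
    param: ff.ForceFieldParametrization,
    settings: Optional[DGSettings] = None,
    rng: Optional[np.random.Generator] = None,
) -> Conformer:
    """One-shot convenience wrapper around :class:`RandomConformerGenerator`."""
    rng = rng if rng is not None else np.random.default_rng()
    return RandomConformerGenerator(mg, param, settings).generate(rng)
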