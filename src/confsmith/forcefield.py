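"""Decomposed MMFF94(s) energies and gradients.

Parameters (atom types, charges, force constants, reference geometries) are
taken from RDKit's validated MMFF94 implementation; what this module adds is
the *per-interaction* representation required elsewhere in the package:

* distance-geometry bound construction needs individual reference bond
  lengths and equilibrium angles,
* fragment-tree torsion driving needs interaction terms grouped by atom
  subsets so conformer energies can be built up incrementally,
* conformer ranking needs category-resolved totals.

Functional forms and unit conversion constants follow the MMFF94 papers;
energies are in kcal/mol, coordinates and lengths in Angstrom, angles in
degrees.  Supported parametrization variants: MMFF94 / MMFF94s (static,
the default), optional exclusion of all electrostatic interactions, and an
optional refined-torsion override table keyed by MMFF atom types.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .molprep import MoleculeGraph

__all__ = [
    "ForceFieldParametrization",
    "EnergyBreakdown",
    "TermSelection",
    "ParametrizationError",
    "parametrize",
    "energy",
    "gradient",
    "energy_and_gradient",
    "load_torsion_overrides",
]

# unit conversion: mdyn*A -> kcal/mol, degrees -> radians
_K = 143.9325
_D = np.pi / 180.0
_ANG = 0.5 * _K * _D * _D       # angle-bend prefactor (per deg^2)
_CB = -0.4 * _D                 # cubic-bend constant (per deg)
_SB = _K * _D                   # stretch-bend prefactor
_CS = -2.0                      # cubic-stretch constant (per A)
_ELE = 332.0716                 # electrostatic constant
_ELE_BUF = 0.05                 # distance buffering (A)
_R_MIN = 1e-3                   # coincident-atom guard (A)

# MMFF atom types whose bond angles are linear (sp carbon, sp nitrogens)
_LINEAR_TYPES = frozenset({4, 42, 53, 61})


class ParametrizationError(ValueError):
    """An atom falls outside MMFF94 coverage (or typing failed)."""


@dataclass
class EnergyBreakdown:
    """Category-resolved MMFF94 energy (kcal/mol)."""

    stretching: float = 0.0
    bending: float = 0.0
    stretch_bend: float = 0.0
    out_of_plane: float = 0.0
    torsion: float = 0.0
    vdw: float = 0.0
    electrostatic: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.stretching
            + self.bending
            + self.stretch_bend
            + self.out_of_plane
            + self.torsion
            + self.vdw
            + self.electrostatic
        )


@dataclass
class TermSelection:
    """Index arrays selecting a subset of parametrized interactions.

    ``None`` means "all terms of that category"; an empty array selects
    nothing.  Used by the fragment-tree machinery to assign every
    interaction to exactly one tree node.
    """

    bonds: Optional[np.ndarray] = None
    angles: Optional[np.ndarray] = None
    stretch_bends: Optional[np.ndarray] = None
    oops: Optional[np.ndarray] = None
    torsions: Optional[np.ndarray] = None
    vdws: Optional[np.ndarray] = None
    eles: Optional[np.ndarray] = None


@dataclass
class ForceFieldParametrization:
    """Typed and parametrized MMFF94 interaction lists for one molecule."""

    n_atoms: int
    variant: str
    electrostatics: bool
    atom_types: np.ndarray
    charges: np.ndarray

    bond_idx: np.ndarray      # (nb, 2)
    bond_kb: np.ndarray
    bond_r0: np.ndarray

    angle_idx: np.ndarray     # (na, 3) i-j-k, j central
    angle_ka: np.ndarray
    angle_t0: np.ndarray      # degrees
    angle_linear: np.ndarray  # bool

    sb_idx: np.ndarray        # (ns, 3)
    sb_kba_ijk: np.ndarray
    sb_kba_kji: np.ndarray
    sb_r0_ij: np.ndarray
    sb_r0_kj: np.ndarray
    sb_t0: np.ndarray

    oop_idx: np.ndarray       # (no, 4) i-j-k;l with j central, l out of plane
    oop_k: np.ndarray

    tor_idx: np.ndarray       # (nt, 4)
    tor_v1: np.ndarray
    tor_v2: np.ndarray
    tor_v3: np.ndarray

    vdw_idx: np.ndarray       # (nv, 2), TD >= 3 pairs
    vdw_rstar: np.ndarray
    vdw_eps: np.ndarray

    ele_idx: np.ndarray       # (ne, 2)
    ele_qq: np.ndarray        # 332.0716 * qi * qj * scale

    _r0_map: dict = field(default_factory=dict, repr=False)
    _t0_map: dict = field(default_factory=dict, repr=False)

    def ref_bond_length(self, i: int, j: int) -> float:
        return self._r0_map[(min(i, j), max(i, j))]

    def ref_angle(self, i: int, j: int, k: int) -> Optional[float]:
        return self._t0_map.get((j, min(i, k), max(i, k)))


def load_torsion_overrides(path: str) -> dict:
    """Read a refined-torsion override table.

    Plain-text lines ``t1 t2 t3 t4 V1 V2 V3`` (MMFF numeric atom types);
    blank lines and ``#`` comments are ignored.  The table is empty by
    default - overrides replace the stock V1-V3 for matching type quadruples
    (in either direction).
    """
    table: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"malformed torsion override line: {line!r}")
            t = tuple(int(x) for x in parts[:4])
            v = tuple(float(x) for x in parts[4:])
            table[t] = v
            table[t[::-1]] = v
    return table


def parametrize(
    mg: MoleculeGraph,
    variant: str = "MMFF94s",
    electrostatics: bool = True,
    torsion_overrides: Optional[dict] = None,
    td: Optional[np.ndarray] = None,
) -> ForceFieldParametrization:
    """Perceive and parametrize all MMFF94 interactions of a molecule.

    Raises :class:`ParametrizationError` naming the offending atom when the
    molecule contains chemistry outside MMFF94 coverage.
    """
    mol = Chem.Mol(mg.mol)
    if variant not in ("MMFF94", "MMFF94s"):
        raise ValueError(f"unknown MMFF variant {variant!r}")
    props = AllChem.MMFFGetMoleculeProperties(mol, mmffVariant=variant)
    if props is None:
        raise ParametrizationError(
            f"molecule {mg.name!r} could not be typed by MMFF94 "
            f"(atom environment outside force-field coverage)"
        )
    n = mol.GetNumAtoms()
    if td is None:
        td = np.asarray(Chem.GetDistanceMatrix(mol), dtype=float)

    atom_types = np.array([props.GetMMFFAtomType(i) for i in range(n)], dtype=int)
    charges = np.array([props.GetMMFFPartialCharge(i) for i in range(n)], dtype=float)

    bond_rows, r0_map = [], {}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        params = props.GetMMFFBondStretchParams(mol, i, j)
        if params is None:
            raise ParametrizationError(
                f"no bond-stretch parameters for atoms {i}-{j} in {mg.name!r}"
            )
        _, kb, r0 = params
        bond_rows.append((i, j, kb, r0))
        r0_map[(min(i, j), max(i, j))] = r0

    angle_rows, sb_rows, t0_map = [], [], {}
    for a in mol.GetAtoms():
        j = a.GetIdx()
        nbrs = [x.GetIdx() for x in a.GetNeighbors()]
        linear = int(atom_types[j]) in _LINEAR_TYPES
        for i, k in itertools.combinations(nbrs, 2):
            params = props.GetMMFFAngleBendParams(mol, i, j, k)
            if params is None:
                raise ParametrizationError(
                    f"no angle-bend parameters for atoms {i}-{j}-{k} in {mg.name!r}"
                )
            _, ka, t0 = params
            angle_rows.append((i, j, k, ka, t0, linear))
            t0_map[(j, min(i, k), max(i, k))] = t0
            if not linear:
                sb = props.GetMMFFStretchBendParams(mol, i, j, k)
                if sb is not None:
                    _, kba_ijk, kba_kji = sb
                    sb_rows.append(
                        (i, j, k, kba_ijk, kba_kji,
                         r0_map[(min(i, j), max(i, j))],
                         r0_map[(min(k, j), max(k, j))], t0)
                    )

    oop_rows = []
    for a in mol.GetAtoms():
        j = a.GetIdx()
        nbrs = [x.GetIdx() for x in a.GetNeighbors()]
        if len(nbrs) != 3:
            continue
        i, k, l = nbrs
        for (p, q, r) in ((i, k, l), (i, l, k), (k, l, i)):
            params = props.GetMMFFOopBendParams(mol, p, j, q, r)
            if params is None:
                continue
            oop_rows.append((p, j, q, r, params))

    tor_rows = []
    for b in mol.GetBonds():
        j, k = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        for i in (x.GetIdx() for x in mol.GetAtomWithIdx(j).GetNeighbors()):
            if i == k:
                continue
            for l in (x.GetIdx() for x in mol.GetAtomWithIdx(k).GetNeighbors()):
                if l == j or l == i:
                    continue
                params = props.GetMMFFTorsionParams(mol, i, j, k, l)
                if params is None:
                    continue
                _, v1, v2, v3 = params
                if torsion_overrides:
                    key = tuple(int(atom_types[x]) for x in (i, j, k, l))
                    if key in torsion_overrides:
                        v1, v2, v3 = torsion_overrides[key]
                tor_rows.append((i, j, k, l, v1, v2, v3))

    vdw_rows, ele_rows = [], []
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu.tolist(), ju.tolist()):
        if td[i, j] < 3:
            continue
        rs = props.GetMMFFVdWParams(i, j)
        vdw_rows.append((i, j, rs[2], rs[3]))
        if electrostatics:
            scale = 0.75 if td[i, j] == 3 else 1.0
            qq = _ELE * charges[i] * charges[j] * scale
            if qq != 0.0:
                ele_rows.append((i, j, qq))

    # canonical term ordering: summation order (and with it the exact
    # floating-point results) must be a pure function of the labelled
    # graph, independent of input atom/bond enumeration order
    bond_rows.sort(key=lambda r: (min(r[0], r[1]), max(r[0], r[1])))
    angle_rows = [
        (min(i, k), j, max(i, k), ka, t0, lin)
        for (i, j, k, ka, t0, lin) in angle_rows
    ]
    angle_rows.sort(key=lambda r: (r[1], r[0], r[2]))
    sb_rows = [
        (i, j, k, k1, k2, r1, r2, t0) if i < k else (k, j, i, k2, k1, r2, r1, t0)
        for (i, j, k, k1, k2, r1, r2, t0) in sb_rows
    ]
    sb_rows.sort(key=lambda r: (r[1], r[0], r[2]))
    oop_rows = [
        (min(p, q), j, max(p, q), r, ko)
        for (p, j, q, r, ko) in oop_rows
    ]
    oop_rows.sort(key=lambda r: (r[1], r[0], r[2], r[3]))
    oop_rows = [(p, j, q, r, ko) for (p, j, q, r, ko) in oop_rows]
    tor_rows = [
        r if (r[0], r[1], r[2], r[3]) <= (r[3], r[2], r[1], r[0])
        else (r[3], r[2], r[1], r[0], r[4], r[5], r[6])
        for r in tor_rows
    ]
    tor_rows.sort(key=lambda r: r[:4])

    def _arr(rows, cols, dtype=float):
        if not rows:
            return [np.zeros((0, c) if c > 1 else 0, dtype=d) for c, d in cols]
        data = list(zip(*rows))
        out = []
        pos = 0
        for c, d in cols:
            if c > 1:
                out.append(np.array(list(zip(*data[pos:pos + c])), dtype=d))
            else:
                out.append(np.array(data[pos], dtype=d))
            pos += c
        return out

    b_idx, b_kb, b_r0 = _arr(bond_rows, [(2, int), (1, float), (1, float)])
    a_idx, a_ka, a_t0, a_lin = _arr(
        angle_rows, [(3, int), (1, float), (1, float), (1, bool)]
    )
    s_idx, s_k1, s_k2, s_r1, s_r2, s_t0 = _arr(
        sb_rows, [(3, int), (1, float), (1, float), (1, float), (1, float), (1, float)]
    )
    o_idx, o_k = _arr(oop_rows, [(4, int), (1, float)])
    t_idx, t_v1, t_v2, t_v3 = _arr(
        tor_rows, [(4, int), (1, float), (1, float), (1, float)]
    )
    v_idx, v_rs, v_eps = _arr(vdw_rows, [(2, int), (1, float), (1, float)])
    e_idx, e_qq = _arr(ele_rows, [(2, int), (1, float)])

    return ForceFieldParametrization(
        n_atoms=n,
        variant=variant,
        electrostatics=electrostatics,
        atom_types=atom_types,
        charges=charges,
        bond_idx=b_idx, bond_kb=b_kb, bond_r0=b_r0,
        angle_idx=a_idx, angle_ka=a_ka, angle_t0=a_t0, angle_linear=a_lin,
        sb_idx=s_idx, sb_kba_ijk=s_k1, sb_kba_kji=s_k2,
        sb_r0_ij=s_r1, sb_r0_kj=s_r2, sb_t0=s_t0,
        oop_idx=o_idx, oop_k=o_k,
        tor_idx=t_idx, tor_v1=t_v1, tor_v2=t_v2, tor_v3=t_v3,
        vdw_idx=v_idx, vdw_rstar=v_rs, vdw_eps=v_eps,
        ele_idx=e_idx, ele_qq=e_qq,
        _r0_map=r0_map, _t0_map=t0_map,
    )


# ---------------------------------------------------------------------------
# geometry helpers (vectorized over terms)


def _norm(v, axis=-1):
    return np.sqrt(np.sum(v * v, axis=axis))


def _sel(idx_arr, sel):
    return idx_arr if sel is None else idx_arr[sel]


def _gather(param: ForceFieldParametrization, cat: str, sel: TermSelection | None):
    s = None if sel is None else getattr(sel, cat)
    if cat == "bonds":
        return (_sel(param.bond_idx, s), _sel(param.bond_kb, s), _sel(param.bond_r0, s))
    if cat == "angles":
        return (_sel(param.angle_idx, s), _sel(param.angle_ka, s),
                _sel(param.angle_t0, s), _sel(param.angle_linear, s))
    if cat == "stretch_bends":
        return (_sel(param.sb_idx, s), _sel(param.sb_kba_ijk, s),
                _sel(param.sb_kba_kji, s), _sel(param.sb_r0_ij, s),
                _sel(param.sb_r0_kj, s), _sel(param.sb_t0, s))
    if cat == "oops":
        return (_sel(param.oop_idx, s), _sel(param.oop_k, s))
    if cat == "torsions":
        return (_sel(param.tor_idx, s), _sel(param.tor_v1, s),
                _sel(param.tor_v2, s), _sel(param.tor_v3, s))
    if cat == "vdws":
        return (_sel(param.vdw_idx, s), _sel(param.vdw_rstar, s), _sel(param.vdw_eps, s))
    if cat == "eles":
        return (_sel(param.ele_idx, s), _sel(param.ele_qq, s))
    raise KeyError(cat)


def energy(
    param: ForceFieldParametrization,
    coords: np.ndarray,
    selection: Optional[TermSelection] = None,
) -> EnergyBreakdown:
    """Evaluate the (optionally term-selected) MMFF94 energy breakdown."""
    x = np.asarray(coords, dtype=float).reshape(param.n_atoms, 3)
    out = EnergyBreakdown()

    idx, kb, r0 = _gather(param, "bonds", selection)
    if len(kb):
        dr = _norm(x[idx[:, 0]] - x[idx[:, 1]]) - r0
        out.stretching = float(
            np.sum(0.5 * _K * kb * dr**2 * (1.0 + _CS * dr + 7.0 / 12.0 * _CS**2 * dr**2))
        )

    idx, ka, t0, lin = _gather(param, "angles", selection)
    if len(ka):
        u = x[idx[:, 0]] - x[idx[:, 1]]
        v = x[idx[:, 2]] - x[idx[:, 1]]
        cu = np.maximum(_norm(u), _R_MIN)
        cvn = np.maximum(_norm(v), _R_MIN)
        cos = np.clip(np.sum(u * v, axis=1) / (cu * cvn), -1.0, 1.0)
        theta = np.degrees(np.arccos(cos))
        dt = theta - t0
        e_nl = _ANG * ka * dt**2 * (1.0 + _CB * dt)
        e_l = _K * ka * (1.0 + cos)
        out.bending = float(np.sum(np.where(lin, e_l, e_nl)))

    idx, k1, k2, r01, r02, t0 = _gather(param, "stretch_bends", selection)
    if len(k1):
        u = x[idx[:, 0]] - x[idx[:, 1]]
        v = x[idx[:, 2]] - x[idx[:, 1]]
        ru = np.maximum(_norm(u), _R_MIN)
        rv = np.maximum(_norm(v), _R_MIN)
        cos = np.clip(np.sum(u * v, axis=1) / (ru * rv), -1.0, 1.0)
        dt = np.degrees(np.arccos(cos)) - t0
        out.stretch_bend = float(
            np.sum(_SB * (k1 * (ru - r01) + k2 * (rv - r02)) * dt)
        )

    idx, ko = _gather(param, "oops", selection)
    if len(ko):
        chi = _wilson(x, idx)
        out.out_of_plane = float(np.sum(0.5 * _K * ko * chi**2))

    idx, v1, v2, v3 = _gather(param, "torsions", selection)
    if len(v1):
        phi = _dihedral(x, idx)
        out.torsion = float(
            np.sum(0.5 * (v1 * (1 + np.cos(phi)) + v2 * (1 - np.cos(2 * phi))
                          + v3 * (1 + np.cos(3 * phi))))
        )

    idx, rs, eps = _gather(param, "vdws", selection)
    if len(eps):
        r = np.maximum(_norm(x[idx[:, 0]] - x[idx[:, 1]]), _R_MIN)
        t = 1.07 * rs / (r + 0.07 * rs)
        u7 = 1.12 * rs**7 / (r**7 + 0.12 * rs**7)
        out.vdw = float(np.sum(eps * t**7 * (u7 - 2.0)))

    idx, qq = _gather(param, "eles", selection)
    if len(qq):
        r = np.maximum(_norm(x[idx[:, 0]] - x[idx[:, 1]]), _R_MIN)
        out.electrostatic = float(np.sum(qq / (r + _ELE_BUF)))

    return out


def _wilson(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Wilson out-of-plane angle chi (radians) for quadruples i-j-k;l."""
    a = x[idx[:, 0]] - x[idx[:, 1]]
    b = x[idx[:, 2]] - x[idx[:, 1]]
    c = x[idx[:, 3]] - x[idx[:, 1]]
    nvec = np.cross(a, b)
    nn = np.maximum(_norm(nvec), 1e-12)
    cn = np.maximum(_norm(c), 1e-12)
    s = np.clip(np.sum(nvec * c, axis=1) / (nn * cn), -1.0, 1.0)
    return np.arcsin(s)


def _dihedral(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Signed dihedral (radians) for quadruples i-j-k-l."""
    b1 = x[idx[:, 1]] - x[idx[:, 0]]
    b2 = x[idx[:, 2]] - x[idx[:, 1]]
    b3 = x[idx[:, 3]] - x[idx[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.maximum(_norm(b2), 1e-12)[:, None]
    m1 = np.cross(n1, b2n)
    return np.arctan2(np.sum(m1 * n2, axis=1), np.sum(n1 * n2, axis=1))


# ---------------------------------------------------------------------------
# analytic gradient


def gradient(
    param: ForceFieldParametrization,
    coords: np.ndarray,
    selection: Optional[TermSelection] = None,
) -> np.ndarray:
    """Analytic gradient dE/dx (kcal/mol/A), shape (n_atoms, 3)."""
    return energy_and_gradient(param, coords, selection)[1]


def _acc(g, idx_col, contrib):
    np.add.at(g, idx_col, contrib)


def energy_and_gradient(
    param: ForceFieldParametrization,
    coords: np.ndarray,
    selection: Optional[TermSelection] = None,
) -> tuple[float, np.ndarray]:
    x = np.asarray(coords, dtype=float).reshape(param.n_atoms, 3)
    g = np.zeros_like(x)
    e = 0.0

    # --- bond stretching
    idx, kb, r0 = _gather(param, "bonds", selection)
    if len(kb):
        d = x[idx[:, 0]] - x[idx[:, 1]]
        r = np.maximum(_norm(d), _R_MIN)
        dr = r - r0
        e += float(np.sum(0.5 * _K * kb * dr**2 * (1 + _CS * dr + 7 / 12 * _CS**2 * dr**2)))
        dEdr = 0.5 * _K * kb * (2 * dr + 3 * _CS * dr**2 + 7 / 3 * _CS**2 * dr**3)
        f = (dEdr / r)[:, None] * d
        _acc(g, idx[:, 0], f)
        _acc(g, idx[:, 1], -f)

    # --- angle bending (+ shared machinery for stretch-bend)
    def _angle_geom(idx):
        u = x[idx[:, 0]] - x[idx[:, 1]]
        v = x[idx[:, 2]] - x[idx[:, 1]]
        ru = np.maximum(_norm(u), _R_MIN)
        rv = np.maximum(_norm(v), _R_MIN)
        uh = u / ru[:, None]
        vh = v / rv[:, None]
        cos = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        sin = np.sqrt(np.maximum(1.0 - cos**2, 1e-12))
        # d(theta)/dri = -(vh - cos*uh) / (ru * sin) etc. (theta in radians)
        dth_di = -(vh - cos[:, None] * uh) / (ru * sin)[:, None]
        dth_dk = -(uh - cos[:, None] * vh) / (rv * sin)[:, None]
        return ru, rv, uh, vh, cos, sin, dth_di, dth_dk

    idx, ka, t0, lin = _gather(param, "angles", selection)
    if len(ka):
        ru, rv, uh, vh, cos, sin, dth_di, dth_dk = _angle_geom(idx)
        theta = np.degrees(np.arccos(cos))
        dt = theta - t0
        nl = ~lin
        if np.any(nl):
            e += float(np.sum(_ANG * ka[nl] * dt[nl]**2 * (1 + _CB * dt[nl])))
            # dE/dtheta_deg -> dE/dtheta_rad via 1/D
            dEdth = (_ANG * ka * (2 * dt + 3 * _CB * dt**2)) / _D
            dEdth = np.where(nl, dEdth, 0.0)
            fi = dEdth[:, None] * dth_di
            fk = dEdth[:, None] * dth_dk
            _acc(g, idx[:, 0], fi)
            _acc(g, idx[:, 2], fk)
            _acc(g, idx[:, 1], -(fi + fk))
        if np.any(lin):
            kl = np.where(lin, ka, 0.0)
            e += float(np.sum(_K * kl * (1 + cos)))
            # dE = K*ka*dcos; dcos/dri = (vh - cos*uh)/ru
            dcos_di = (vh - cos[:, None] * uh) / ru[:, None]
            dcos_dk = (uh - cos[:, None] * vh) / rv[:, None]
            fi = (_K * kl)[:, None] * dcos_di
            fk = (_K * kl)[:, None] * dcos_dk
            _acc(g, idx[:, 0], fi)
            _acc(g, idx[:, 2], fk)
            _acc(g, idx[:, 1], -(fi + fk))

    # --- stretch-bend
    idx, k1, k2, r01, r02, t0 = _gather(param, "stretch_bends", selection)
    if len(k1):
        ru, rv, uh, vh, cos, sin, dth_di, dth_dk = _angle_geom(idx)
        dt = np.degrees(np.arccos(cos)) - t0
        dr1 = ru - r01
        dr2 = rv - r02
        e += float(np.sum(_SB * (k1 * dr1 + k2 * dr2) * dt))
        # dE = SB * [ (k1 dr1 + k2 dr2) * ddt + (k1 ddr1 + k2 ddr2) * dt ]
        common = _SB * (k1 * dr1 + k2 * dr2) / _D  # per radian
        fi = common[:, None] * dth_di + (_SB * k1 * dt)[:, None] * uh
        fk = common[:, None] * dth_dk + (_SB * k2 * dt)[:, None] * vh
        _acc(g, idx[:, 0], fi)
        _acc(g, idx[:, 2], fk)
        _acc(g, idx[:, 1], -(fi + fk))

    # --- out-of-plane bending
    idx, ko = _gather(param, "oops", selection)
    if len(ko):
        a = x[idx[:, 0]] - x[idx[:, 1]]
        b = x[idx[:, 2]] - x[idx[:, 1]]
        c = x[idx[:, 3]] - x[idx[:, 1]]
        nvec = np.cross(a, b)
        nn = np.maximum(_norm(nvec), 1e-12)
        cn = np.maximum(_norm(c), 1e-12)
        nh = nvec / nn[:, None]
        ch = c / cn[:, None]
        s = np.clip(np.sum(nh * ch, axis=1), -1.0, 1.0)
        chi = np.arcsin(s)
        e += float(np.sum(0.5 * _K * ko * chi**2))
        dEds = _K * ko * chi / np.sqrt(np.maximum(1 - s**2, 1e-12))
        # s = (n.c)/(|n||c|); dN and dD pieces per atom
        bxc = np.cross(b, c)
        cxa = np.cross(c, a)
        bxnh = np.cross(b, nh)
        nhxa = np.cross(nh, a)
        inv = 1.0 / (nn * cn)
        # ds/da = (b x c)/(|n||c|) - s * (b x nh)/|n|, and cyclic analogues
        da = (bxc * inv[:, None]) - (s / nn)[:, None] * bxnh
        db = (cxa * inv[:, None]) - (s / nn)[:, None] * nhxa
        dc = (nvec * inv[:, None]) - (s / cn)[:, None] * ch
        fa = dEds[:, None] * da
        fb = dEds[:, None] * db
        fc = dEds[:, None] * dc
        _acc(g, idx[:, 0], fa)
        _acc(g, idx[:, 2], fb)
        _acc(g, idx[:, 3], fc)
        _acc(g, idx[:, 1], -(fa + fb + fc))

    # --- torsions
    idx, v1, v2, v3 = _gather(param, "torsions", selection)
    if len(v1):
        b1 = x[idx[:, 1]] - x[idx[:, 0]]
        b2 = x[idx[:, 2]] - x[idx[:, 1]]
        b3 = x[idx[:, 3]] - x[idx[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2l = np.maximum(_norm(b2), 1e-12)
        phi = np.arctan2(
            np.sum(np.cross(n1, b2 / b2l[:, None]) * n2, axis=1),
            np.sum(n1 * n2, axis=1),
        )
        e += float(np.sum(0.5 * (v1 * (1 + np.cos(phi)) + v2 * (1 - np.cos(2 * phi))
                                 + v3 * (1 + np.cos(3 * phi)))))
        dEdphi = 0.5 * (-v1 * np.sin(phi) + 2 * v2 * np.sin(2 * phi)
                        - 3 * v3 * np.sin(3 * phi))
        n1sq = np.maximum(np.sum(n1 * n1, axis=1), 1e-12)
        n2sq = np.maximum(np.sum(n2 * n2, axis=1), 1e-12)
        c12 = np.sum(b1 * b2, axis=1)
        c32 = np.sum(b3 * b2, axis=1)
        # Blondel-Karplus dihedral derivatives (adapted to this sign convention)
        dphi_d1 = (b2l / n1sq)[:, None] * n1
        dphi_d4 = -(b2l / n2sq)[:, None] * n2
        dphi_d2 = (-(b2l + c12 / b2l) / n1sq)[:, None] * n1 \
            - (c32 / (n2sq * b2l))[:, None] * n2
        dphi_d3 = ((b2l + c32 / b2l) / n2sq)[:, None] * n2 \
            + (c12 / (n1sq * b2l))[:, None] * n1
        for col, dphi in ((0, dphi_d1), (1, dphi_d2), (2, dphi_d3), (3, dphi_d4)):
            _acc(g, idx[:, col], dEdphi[:, None] * dphi)

    # --- van der Waals (buffered 14-7)
    idx, rs, eps = _gather(param, "vdws", selection)
    if len(eps):
        d = x[idx[:, 0]] - x[idx[:, 1]]
        r = np.maximum(_norm(d), _R_MIN)
        t = 1.07 * rs / (r + 0.07 * rs)
        u7 = 1.12 * rs**7 / (r**7 + 0.12 * rs**7)
        e += float(np.sum(eps * t**7 * (u7 - 2.0)))
        dt_dr = -1.07 * rs / (r + 0.07 * rs) ** 2
        du7_dr = -1.12 * rs**7 * 7 * r**6 / (r**7 + 0.12 * rs**7) ** 2
        dEdr = eps * (7 * t**6 * dt_dr * (u7 - 2.0) + t**7 * du7_dr)
        f = (dEdr / r)[:, None] * d
        _acc(g, idx[:, 0], f)
        _acc(g, idx[:, 1], -f)

    # --- electrostatics (buffered coulomb)
    idx, qq = _gather(param, "eles", selection)
    if len(qq):
        d = x[idx[:, 0]] - x[idx[:, 1]]
        r = np.maximum(_norm(d), _R_MIN)
        e += float(np.sum(qq / (r + _ELE_BUF)))
        dEdr = -qq / (r + _ELE_BUF) ** 2
        f = (dEdr / r)[:, None] * d
        _acc(g, idx[:, 0], f)
        _acc(g, idx[:, 1], -f)

    return e, g
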