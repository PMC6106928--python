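"""Torsion-angle geometry for RNA chains.

This module provides the low-level geometric machinery shared by the rest of
the package: signed dihedral angles (IUPAC convention), circular-angle
statistics (MCQ, the Mean of Circular Quantities), coordinate RMSD in a
shared frame, and torsion-driven atom placement via the natural extension
reference frame (NeRF) construction.

All angles are degrees in the half-open interval (-180, 180] unless a
function documents otherwise.  Undefined angles -- missing atoms at chain
termini, degenerate geometry -- are represented by ``None`` rather than by
exceptions wherever absence is an expected value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeometryError",
    "InternalCoordinate",
    "TorsionProfile",
    "TORSION_NAMES",
    "dihedral_angle",
    "bond_angle",
    "circular_difference",
    "mcq",
    "rmsd",
    "nerf_place",
    "measure_internal",
    "compute_torsions",
    "wrap_angle",
    "kabsch_transform",
    "local_frame",
    "reconstruct_residue",
]

#: Canonical order of the per-residue torsion angles handled by this package.
#: alpha..zeta are the sugar-phosphate backbone torsions, tau0..tau4 the five
#: endocyclic ribose ring torsions, chi the glycosidic torsion, and eta/theta
#: the coarse P/C4' pseudotorsions.
TORSION_NAMES = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta",
    "tau0", "tau1", "tau2", "tau3", "tau4",
    "chi", "eta", "theta",
)

#: The 12 angles stored per library conformer (pseudotorsions are inter-residue
#: descriptors and are not conformer properties).
CONFORMER_TORSIONS = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta",
    "tau0", "tau1", "tau2", "tau3", "tau4", "chi",
)


class GeometryError(ValueError):
    """Raised for degenerate geometric input (collinear frames, empty sets)."""


def wrap_angle(a: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = math.fmod(a, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, IUPAC sign convention.

    The angle is measured between the half-plane spanned by (p1, p2, p3) and
    the half-plane spanned by (p2, p3, p4), looking down the p2->p3 axis;
    clockwise rotations are positive.  Raises :class:`GeometryError` when
    either atom triple is collinear (the angle is then undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-9 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("dihedral undefined for collinear or coincident points")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    ang = math.degrees(math.atan2(y, x))
    return wrap_angle(ang)


def bond_angle(p1, p2, p3) -> float:
    """Planar angle p1-p2-p3 in degrees, in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        raise GeometryError("bond angle undefined for coincident points")
    c = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def circular_difference(a: float, b: float) -> float:
    """Unsigned circular distance between two angles, degrees in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def mcq(angles_a: Iterable[float | None], angles_b: Iterable[float | None]) -> float:
    """Mean of Circular Quantities between two matched angle lists, degrees.

    Pairs where either side is ``None`` are skipped.  The result is the
    circular mean of the per-pair unsigned differences,
    ``atan2(mean sin d_i, mean cos d_i)``, and lies in [0, 180].

    Raises :class:`GeometryError` when no comparable pair remains.
    """
    sins = []
    coss = []
    for a, b in zip(angles_a, angles_b):
        if a is None or b is None:
            continue
        d = math.radians(circular_difference(a, b))
        sins.append(math.sin(d))
        coss.append(math.cos(d))
    if not sins:
        raise GeometryError("MCQ undefined: no comparable angle pairs")
    val = math.degrees(math.atan2(sum(sins) / len(sins), sum(coss) / len(coss)))
    # differences are in [0, 180] so the circular mean is too; guard rounding
    return abs(val)


def rmsd(coords_a: Sequence, coords_b: Sequence) -> float:
    """Root-mean-square deviation between matched coordinates, in Angstrom.

    No superposition is performed: both coordinate sets are expected to live
    in the same frame (here, the shared fixed-backbone frame).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise GeometryError("RMSD needs two equal, non-empty coordinate sets")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


@dataclass(frozen=True)
class InternalCoordinate:
    """Placement recipe for one atom relative to three reference atoms.

    The new atom ``name`` is placed at distance ``bond_length`` from reference
    atom ``c``, forming angle ``bond_angle`` with ``b``-``c`` and torsion
    ``torsion`` with the ``a``-``b``-``c`` plane.
    """

    name: str
    ref_a: str
    ref_b: str
    ref_c: str
    bond_length: float
    bond_angle: float
    torsion: float

    def __post_init__(self):
        if self.bond_length <= 0:
            raise ValueError("bond length must be positive")
        if not (0.0 < self.bond_angle < 180.0):
            raise ValueError("bond angle must be in (0, 180)")


def nerf_place(a, b, c, bond_length: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom ``d`` from frame atoms ``a``, ``b``, ``c`` (NeRF construction).

    Returns the unique point ``d`` with ``|c-d| = bond_length``,
    ``angle(b,c,d) = angle_deg`` and ``dihedral(a,b,c,d) = torsion_deg``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    bc = c - b
    nbc = np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nbc < 1e-9 or nn < 1e-9:
        raise GeometryError("NeRF frame is collinear")
    bc /= nbc
    n /= nn
    m = np.cross(n, bc)
    theta = math.radians(angle_deg)
    tau = math.radians(torsion_deg)
    d_local = bond_length * np.array(
        [-math.cos(theta), math.sin(theta) * math.cos(tau), math.sin(theta) * math.sin(tau)]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def measure_internal(name: str, a, b, c, d, *, ref_names=("a", "b", "c")) -> InternalCoordinate:
    """Measure the internal coordinate of point ``d`` relative to frame (a,b,c)."""
    d = np.asarray(d, dtype=float)
    c_arr = np.asarray(c, dtype=float)
    return InternalCoordinate(
        name=name,
        ref_a=ref_names[0],
        ref_b=ref_names[1],
        ref_c=ref_names[2],
        bond_length=float(np.linalg.norm(d - c_arr)),
        bond_angle=bond_angle(b, c, d),
        torsion=dihedral_angle(a, b, c, d),
    )


@dataclass
class TorsionProfile:
    """Per-residue torsion angles of a chain.

    ``angles[i][name]`` is the value in degrees or ``None`` when the angle is
    undefined for residue ``i`` (missing atoms, chain terminus, or a break in
    the sugar-phosphate backbone).
    """

    angles: list[dict[str, float | None]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.angles)

    def get(self, index: int, name: str) -> float | None:
        return self.angles[index].get(name)

    def vector(self, index: int, names: Sequence[str]) -> list[float | None]:
        rec = self.angles[index]
        return [rec.get(n) for n in names]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (residue, angle, value); absent angles are NaN."""
        rows = []
        for i, rec in enumerate(self.angles):
            for name in TORSION_NAMES:
                v = rec.get(name)
                rows.append({"residue": i + 1, "angle": name,
                             "value": float("nan") if v is None else v})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# torsion measurement on chains
# ---------------------------------------------------------------------------

#: maximum O3'(i-1)--P(i) distance for two residues to count as covalently
#: linked; beyond this the backbone is treated as broken (e.g. between the
#: concatenated chains of a multi-chain input) and inter-residue torsions are
#: left undefined.
BACKBONE_LINK_CUTOFF = 2.5

_PURINES = {"A", "G"}


def _coord(residue, name):
    atom = residue.atoms.get(name)
    return None if atom is None else atom.coord


def _dihedral_or_none(*points):
    if any(p is None for p in points):
        return None
    try:
        return dihedral_angle(*points)
    except GeometryError:
        return None


def _linked(prev, curr) -> bool:
    o3 = _coord(prev, "O3'")
    p = _coord(curr, "P")
    if o3 is None or p is None:
        return False
    return float(np.linalg.norm(np.asarray(o3) - np.asarray(p))) < BACKBONE_LINK_CUTOFF


def compute_torsions(chain) -> TorsionProfile:
    """Compute the full torsion profile of an :class:`~nucleofit.structure.RnaChain`.

    Backbone torsions follow the standard RNA definitions::

        alpha:   O3'(i-1)-P-O5'-C5'      epsilon: C4'-C3'-O3'-P(i+1)
        beta:    P-O5'-C5'-C4'           zeta:    C3'-O3'-P(i+1)-O5'(i+1)
        gamma:   O5'-C5'-C4'-C3'         chi:     O4'-C1'-N9-C4 (purines)
        delta:   C5'-C4'-C3'-O3'                  O4'-C1'-N1-C2 (pyrimidines)

    tau0..tau4 are the endocyclic ribose torsions starting at C4'-O4'-C1'-C2',
    and eta/theta the C4'/P pseudotorsions.  Any angle whose atoms are missing
    (or whose residues are not covalently linked) is ``None``.
    """
    residues = chain.residues
    n = len(residues)
    profile = TorsionProfile([{} for _ in range(n)])
    for i, res in enumerate(residues):
        prev = residues[i - 1] if i > 0 else None
        nxt = residues[i + 1] if i < n - 1 else None
        prev_ok = prev is not None and _linked(prev, res)
        next_ok = nxt is not None and _linked(res, nxt)
        rec = profile.angles[i]

        p = _coord(res, "P")
        o5 = _coord(res, "O5'")
        c5 = _coord(res, "C5'")
        c4 = _coord(res, "C4'")
        c3 = _coord(res, "C3'")
        o3 = _coord(res, "O3'")
        o4 = _coord(res, "O4'")
        c1 = _coord(res, "C1'")
        c2 = _coord(res, "C2'")

        rec["alpha"] = _dihedral_or_none(_coord(prev, "O3'") if prev_ok else None, p, o5, c5)
        rec["beta"] = _dihedral_or_none(p, o5, c5, c4)
        rec["gamma"] = _dihedral_or_none(o5, c5, c4, c3)
        rec["delta"] = _dihedral_or_none(c5, c4, c3, o3)
        rec["epsilon"] = _dihedral_or_none(c4, c3, o3, _coord(nxt, "P") if next_ok else None)
        rec["zeta"] = _dihedral_or_none(
            c3, o3,
            _coord(nxt, "P") if next_ok else None,
            _coord(nxt, "O5'") if next_ok else None,
        )

        rec["tau0"] = _dihedral_or_none(c4, o4, c1, c2)
        rec["tau1"] = _dihedral_or_none(o4, c1, c2, c3)
        rec["tau2"] = _dihedral_or_none(c1, c2, c3, c4)
        rec["tau3"] = _dihedral_or_none(c2, c3, c4, o4)
        rec["tau4"] = _dihedral_or_none(c3, c4, o4, c1)

        if res.base_type in _PURINES:
            rec["chi"] = _dihedral_or_none(o4, c1, _coord(res, "N9"), _coord(res, "C4"))
        else:
            rec["chi"] = _dihedral_or_none(o4, c1, _coord(res, "N1"), _coord(res, "C2"))

        rec["eta"] = _dihedral_or_none(
            _coord(prev, "C4'") if prev_ok else None, p, c4,
            _coord(nxt, "P") if next_ok else None,
        )
        rec["theta"] = _dihedral_or_none(
            p, c4,
            _coord(nxt, "P") if next_ok else None,
            _coord(nxt, "C4'") if next_ok else None,
        )
    return profile


# ---------------------------------------------------------------------------
# rigid-body helpers and residue reconstruction
# ---------------------------------------------------------------------------

def kabsch_transform(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) with ``R @ m + t ~ target``.

    Proper rotation only (no reflection); both inputs are (n, 3) arrays of
    matched points, n >= 3.
    """
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = moving.mean(axis=0)
    tc = target.mean(axis=0)
    h = (moving - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def local_frame(c5, c4, c3) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal frame (rotation, origin) anchored on the C5'/C4'/C3' triad.

    The conformer library stores coordinates in this frame so that library
    entries from different structures are directly comparable: origin at C4',
    x along C4'->C3', the C5' atom in the xy-plane at positive y.
    Returns ``(rows, origin)`` with ``local = rows @ (p - origin)``.
    """
    c5 = np.asarray(c5, dtype=float)
    c4 = np.asarray(c4, dtype=float)
    c3 = np.asarray(c3, dtype=float)
    x = c3 - c4
    nx = np.linalg.norm(x)
    v = c5 - c4
    z = np.cross(x, v)
    nz = np.linalg.norm(z)
    if nx < 1e-9 or nz < 1e-9:
        raise GeometryError("degenerate C5'/C4'/C3' frame")
    x /= nx
    z /= nz
    y = np.cross(z, x)
    return np.vstack([x, y, z]), c4


def _conformer_ic(conformer, name: str, refs: tuple[str, str, str]):
    """Internal coordinate of atom ``name`` measured on the conformer itself."""
    cc = conformer.atom_coords
    for r in (*refs, name):
        if r not in cc:
            raise GeometryError(f"conformer {conformer.id}: missing atom {r}")
    return measure_internal(name, cc[refs[0]], cc[refs[1]], cc[refs[2]], cc[name],
                            ref_names=refs)


# NeRF placement recipes for the remodeled sugar atoms (nucleoside mode):
# frames use only atoms that are fixed in that mode.  The sugar is rebuilt
# along two branches -- C4'->O4'->C1' and C3'->C2'->O2' -- and the implied
# C1'-C2' ring-closure bond is checked afterwards rather than enforced.
_SUGAR_REBUILD = (
    ("O4'", ("O5'", "C5'", "C4'")),
    ("C1'", ("C5'", "C4'", "O4'")),
    ("C2'", ("C5'", "C4'", "C3'")),
    ("O2'", ("C4'", "C3'", "C2'")),
)

#: tolerance for reporting (not rejecting) ring-closure deviation, Angstrom
RING_CLOSURE_TOL = 0.2


def reconstruct_residue(residue, conformer, mode: str):
    """Rebuild the remodeled atoms of one residue from a library conformer.

    In nucleoside mode the four sugar atoms O4', C1', C2', O2' are placed by
    NeRF from the fixed backbone frame using internal coordinates measured on
    the conformer, then the base is attached; in nucleobase mode the sugar is
    already fixed and only the base is placed.  The base ring is copied as a
    rigid body (superposed on its C1'/N/C-ref attachment triad) so its
    internal geometry is exactly the conformer's; the glycosidic torsion chi
    comes from the conformer's torsion record.

    Returns ``(rebuilt, closure_dev)`` where ``rebuilt`` maps atom name to
    coordinates for every newly placed atom and ``closure_dev`` is the
    C1'-C2' ring-closure deviation in Angstrom (0.0 in nucleobase mode).
    Fixed atoms are never touched.
    """
    from . import _chem  # local import to keep this module standalone

    if conformer.base_type != residue.base_type:
        raise GeometryError(
            f"conformer type {conformer.base_type} does not match residue "
            f"{residue.label} of type {residue.base_type}")
    if mode not in ("nucleobase", "nucleoside"):
        raise GeometryError(f"unknown mode {mode!r}")

    coords: dict[str, np.ndarray] = {
        name: residue.atoms[name].coord for name in _chem.FIXED_ATOMS[mode]
        if name in residue.atoms
    }
    for name in _chem.REQUIRED_ATOMS[mode]:
        if name not in coords:
            raise GeometryError(f"residue {residue.label}: missing frame atom {name}")

    rebuilt: dict[str, np.ndarray] = {}
    closure_dev = 0.0
    if mode == "nucleoside":
        for name, refs in _SUGAR_REBUILD:
            ic = _conformer_ic(conformer, name, refs)
            pos = nerf_place(coords[refs[0]], coords[refs[1]], coords[refs[2]],
                             ic.bond_length, ic.bond_angle, ic.torsion)
            coords[name] = pos
            rebuilt[name] = pos
        implied = float(np.linalg.norm(coords["C1'"] - coords["C2'"]))
        stored = conformer.bond_lengths.get("C1'-C2'", implied)
        closure_dev = abs(implied - stored)

    n_name, ref_name = _chem.GLYCOSIDIC[residue.base_type]
    ic_n = _conformer_ic(conformer, n_name, ("C4'", "O4'", "C1'"))
    coords[n_name] = nerf_place(coords["C4'"], coords["O4'"], coords["C1'"],
                                ic_n.bond_length, ic_n.bond_angle, ic_n.torsion)
    rebuilt[n_name] = coords[n_name]
    ic_ref = _conformer_ic(conformer, ref_name, ("O4'", "C1'", n_name))
    coords[ref_name] = nerf_place(coords["O4'"], coords["C1'"], coords[n_name],
                                  ic_ref.bond_length, ic_ref.bond_angle,
                                  conformer.torsions["chi"])
    rebuilt[ref_name] = coords[ref_name]

    # remaining base atoms ride rigidly on the attachment triad
    triad = ("C1'", n_name, ref_name)
    rot, t = kabsch_transform(
        np.array([conformer.atom_coords[a] for a in triad]),
        np.array([coords[a] for a in triad]))
    for name in _chem.BASE_ATOMS[residue.base_type]:
        if name in rebuilt:
            continue
        rebuilt[name] = rot @ conformer.atom_coords[name] + t
    return rebuilt, closure_dev
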