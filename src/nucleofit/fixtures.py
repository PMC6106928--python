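"""Self-contained synthetic RNA structures for development and testing.

Everything here is generated from code -- no external structure files are
ever needed.  The generator builds full-atom chains by torsion-driven NeRF
placement from an idealized nucleotide template (frozen internal-coordinate
constants below), with an A-form-like default torsion preset.  Duplexes add
the reverse-complement strand positioned by rigid superposition onto planted
Watson-Crick pair geometry.

The module also builds abstract "packing instances" -- random energy tables
with controlled interaction-graph topology plus their brute-force optimum --
used to exercise the combinatorial optimizer against an exhaustive oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from . import _chem
from .geometry import kabsch_transform, nerf_place, wrap_angle
from .structure import Atom, Residue, RnaChain

__all__ = [
    "FixtureSpec",
    "A_FORM_PRESET",
    "generate_chain",
    "perturb",
    "strip",
    "make_packing_instance",
    "PackingInstance",
]

# ---------------------------------------------------------------------------
# idealized nucleotide template
# ---------------------------------------------------------------------------
# Internal coordinates of an idealized ribonucleotide: ring geometry from a
# least-squares fit of a C3'-endo ribose (pseudorotation phase 18 deg,
# amplitude 38 deg) with standard bond lengths and angles; base geometry and
# branch handedness from idealized residue definitions.  These are generic
# structural-biology reference values, deliberately independent of any
# particular deposited structure.

#: default torsion preset: A-form-like backbone with C3'-endo sugar, anti
#: base; backbone values refined so that two strands generated with this
#: preset close ideal Watson-Crick pairs in the duplex construction below
A_FORM_PRESET = {
    "alpha": -74.35, "beta": 178.96, "gamma": 62.0, "delta": 75.21,
    "epsilon": -147.9, "zeta": -70.57, "chi": -155.97,
    "tau0": 0.26, "tau1": -22.67, "tau2": 35.73, "tau3": -36.38, "tau4": 22.70,
}

# each entry: (atom, (ref_a, ref_b, ref_c), bond, angle, driver, offset)
# a trailing '-' on a reference name means "previous residue's atom"; the
# torsion applied is preset[driver] + offset, with '-' drivers read from the
# previous residue's preset record.
_SUGAR_TEMPLATE = (
    ("P",   ("C4'-", "C3'-", "O3'-"), 1.607, 119.7, "epsilon-", 0.0),
    ("O5'", ("C3'-", "O3'-", "P"),    1.593, 104.0, "zeta-",    0.0),
    ("OP1", ("C3'-", "O3'-", "P"),    1.485, 107.9, "zeta-",  120.0),
    ("OP2", ("C3'-", "O3'-", "P"),    1.485, 107.9, "zeta-", -120.0),
    ("C5'", ("O3'-", "P", "O5'"),     1.440, 120.9, "alpha",    0.0),
    ("C4'", ("P", "O5'", "C5'"),      1.508, 111.5, "beta",     0.0),
    ("C3'", ("O5'", "C5'", "C4'"),    1.502, 116.0, "gamma",    0.0),
    ("O3'", ("C5'", "C4'", "C3'"),    1.423, 113.0, "delta",    0.0),
    ("O4'", ("O5'", "C5'", "C4'"),    1.452, 109.8, "gamma", -117.64),
    ("C1'", ("C3'", "C4'", "O4'"),    1.427, 110.0, "tau4",     0.0),
    ("C2'", ("C4'", "O4'", "C1'"),    1.538, 106.5, "tau0",     0.0),
    ("O2'", ("O4'", "C1'", "C2'"),    1.413, 108.4, "tau1",   120.23),
)

#: per-type glycosidic attachment: (bond C1'-N, angle O4'-C1'-N, offset of the
#: N branch torsion from tau0, bond N-Cref, angle C1'-N-Cref)
_GLYCOSIDIC_GEOM = {
    "A": (1.471, 108.2, -122.26, 1.372, 126.3),
    "G": (1.471, 108.2, -122.26, 1.368, 126.4),
    "C": (1.471, 108.2, -122.26, 1.344, 119.8),
    "U": (1.471, 108.2, -122.26, 1.343, 119.7),
}

# planar base skeletons past the chi-defining reference atom, measured from
# idealized residue geometry: (atom, (ref_a, ref_b, ref_c), bond, angle, torsion)
_BASE_TEMPLATE = {
    "A": (
        ("N3", ("C1'", "N9", "C4"), 1.328, 134.94, 0.0),
        ("C5", ("C1'", "N9", "C4"), 1.405, 106.00, 180.0),
        ("C8", ("C5", "C4", "N9"), 1.363, 107.42, 0.0),
        ("N7", ("C4", "N9", "C8"), 1.301, 109.98, 0.0),
        ("C6", ("N9", "C4", "C5"), 1.405, 118.15, 180.0),
        ("N1", ("C4", "C5", "C6"), 1.328, 118.50, 0.0),
        ("C2", ("C5", "C6", "N1"), 1.320, 121.12, 0.0),
        ("N6", ("C4", "C5", "C6"), 1.384, 120.74, 180.0),
    ),
    "G": (
        ("N3", ("C1'", "N9", "C4"), 1.338, 134.18, 0.0),
        ("C5", ("C1'", "N9", "C4"), 1.399, 106.15, 180.0),
        ("C8", ("C5", "C4", "N9"), 1.365, 107.47, 0.0),
        ("N7", ("C4", "N9", "C8"), 1.301, 109.83, 0.0),
        ("C6", ("N9", "C4", "C5"), 1.414, 118.62, 180.0),
        ("N1", ("C4", "C5", "C6"), 1.351, 118.34, 0.0),
        ("C2", ("C5", "C6", "N1"), 1.362, 120.32, 0.0),
        ("O6", ("C4", "C5", "C6"), 1.219, 120.80, 180.0),
        ("N2", ("C6", "N1", "C2"), 1.372, 119.03, 180.0),
    ),
    "C": (
        ("O2", ("C1'", "N1", "C2"), 1.220, 119.50, 0.0),
        ("N3", ("C1'", "N1", "C2"), 1.332, 121.10, 180.0),
        ("C4", ("N1", "C2", "N3"), 1.326, 120.66, 0.0),
        ("C5", ("C2", "N3", "C4"), 1.410, 119.62, 0.0),
        ("C6", ("N3", "C4", "C5"), 1.354, 118.99, 0.0),
        ("N4", ("C2", "N3", "C4"), 1.375, 120.20, 180.0),
    ),
    "U": (
        ("O2", ("C1'", "N1", "C2"), 1.215, 119.58, 0.0),
        ("N3", ("C1'", "N1", "C2"), 1.347, 120.90, 180.0),
        ("C4", ("N1", "C2", "N3"), 1.348, 120.25, 0.0),
        ("C5", ("C2", "N3", "C4"), 1.415, 119.37, 0.0),
        ("C6", ("N3", "C4", "C5"), 1.350, 119.15, 0.0),
        ("O4", ("C2", "N3", "C4"), 1.218, 120.27, 180.0),
    ),
}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class FixtureSpec:
    """Recipe for a synthetic structure.

    ``torsion_preset`` maps torsion names to degrees (defaults to the A-form
    preset); ``perturbations`` are (residue index, torsion name, delta in
    degrees) applied to the driving torsions of single residues before
    generation.
    """

    sequence: str
    form: str = "single_strand"
    torsion_preset: dict = field(default_factory=lambda: dict(A_FORM_PRESET))
    perturbations: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set(_chem.BASE_TYPES):
            raise ValueError("sequence must contain only A, C, G, U")
        if self.form not in ("single_strand", "duplex"):
            raise ValueError("form must be single_strand or duplex")
        for idx, name, _ in self.perturbations:
            if not 0 <= idx < len(self.sequence):
                raise ValueError(f"perturbation index {idx} out of range")
            if name not in self.torsion_preset:
                raise ValueError(f"unknown torsion {name!r} in perturbation")


# ---------------------------------------------------------------------------
# chain generation
# ---------------------------------------------------------------------------

def _residue_presets(spec: FixtureSpec) -> list[dict]:
    presets = [dict(spec.torsion_preset) for _ in spec.sequence]
    for idx, name, delta in spec.perturbations:
        presets[idx][name] = wrap_angle(presets[idx][name] + delta)
    return presets


def _build_strand(sequence: str, presets: list[dict], chain_id: str) -> list[Residue]:
    residues: list[Residue] = []
    coords_prev: dict[str, np.ndarray] | None = None
    for i, base in enumerate(sequence):
        preset = presets[i]
        preset_prev = presets[i - 1] if i > 0 else None
        coords: dict[str, np.ndarray] = {}
        if i == 0:
            # seed the first residue without a 5'-phosphate
            coords["O5'"] = np.zeros(3)
            coords["C5'"] = np.array([1.440, 0.0, 0.0])
            ang = math.radians(180.0 - 111.5)
            coords["C4'"] = coords["C5'"] + 1.508 * np.array(
                [math.cos(ang), math.sin(ang), 0.0])
        for entry in _SUGAR_TEMPLATE:
            name, refs, bond, angle, driver, offset = entry
            if name in coords:
                continue
            if i == 0 and driver.endswith("-"):
                continue  # no upstream residue
            ref_coords = []
            ok = True
            for r in refs:
                if r.endswith("-"):
                    val = coords_prev.get(r[:-1]) if coords_prev else None
                else:
                    val = coords.get(r)
                if val is None:
                    ok = False
                    break
                ref_coords.append(val)
            if not ok:
                continue
            src = preset_prev if driver.endswith("-") else preset
            torsion = wrap_angle(src[driver.rstrip("-")] + offset)
            coords[name] = nerf_place(*ref_coords, bond, angle, torsion)
        _attach_base(coords, base, preset["chi"], preset["tau0"])
        residues.append(_as_residue(coords, base, chain_id, i + 1))
        coords_prev = coords
    return residues


def _attach_base(coords: dict, base: str, chi: float, tau0: float) -> None:
    bond_n, ang_n, off_n, bond_ref, ang_ref = _GLYCOSIDIC_GEOM[base]
    n_name, ref_name = _chem.GLYCOSIDIC[base]
    coords[n_name] = nerf_place(coords["C4'"], coords["O4'"], coords["C1'"],
                                bond_n, ang_n, wrap_angle(tau0 + off_n))
    coords[ref_name] = nerf_place(coords["O4'"], coords["C1'"], coords[n_name],
                                  bond_ref, ang_ref, chi)
    for name, refs, bond, angle, torsion in _BASE_TEMPLATE[base]:
        coords[name] = nerf_place(*(coords[r] for r in refs), bond, angle, torsion)


def _as_residue(coords: dict, base: str, chain_id: str, number: int) -> Residue:
    res = Residue(chain_id=chain_id, seq_number=number, base_type=base)
    for name in _chem.residue_atoms(base):
        if name in coords:
            res.atoms[name] = Atom(name=name, element=_chem.element_of(name),
                                   coord=coords[name])
    return res


def generate_chain(spec: FixtureSpec) -> RnaChain:
    """Build a full-atom chain (or duplex) from a :class:`FixtureSpec`.

    Deterministic: the same spec always yields the same coordinates.  For
    duplexes the second strand carries the reverse complement sequence,
    chain id "B", and is positioned so that every planted Watson-Crick pair
    satisfies canonical hydrogen-bonding geometry.
    """
    presets = _residue_presets(spec)
    residues = _build_strand(spec.sequence, presets, "A")
    chain = RnaChain(residues=residues, source_id=f"fixture-{spec.sequence}")
    if spec.form == "duplex":
        chain.residues.extend(_build_partner_strand(chain.residues, spec))
    _renumber(chain)
    return chain


def _renumber(chain: RnaChain) -> None:
    serial = 0
    for res in chain.residues:
        for name in _chem.residue_atoms(res.base_type):
            atom = res.atoms.get(name)
            if atom is not None:
                serial += 1
                atom.serial = serial


# -- duplex construction ----------------------------------------------------

# In-plane Watson-Crick pair geometry: for each pair class X-Y the glycosidic
# attachment of both residues in the pair plane, parameterized by the
# C1'-C1' span, the angles between the C1'->N bonds and the C1'-C1' line
# (lambda), and the in-plane orientation of the N->Cref bond (phi, measured
# from the +x axis toward the partner).  Values fitted once against canonical
# hydrogen-bond lengths (N1-N3/N6-O4 for A-U, N1-N3/O6-N4/N2-O2 for G-C).
_WC_PARAMS = {
    # pair: (c1'-c1' distance, lambda_1, phi_1, lambda_2, phi_2, propeller);
    # the purine is residue 1 (left) in the stored convention
    "AU": (10.742, 56.425, -3.609, 50.045, -4.797, -6.26),
    "GC": (10.742, 57.985, -6.439, 51.605, -5.997, -6.26),
}


def _pair_template(base1: str) -> dict:
    """Coordinates of (C1', N, Cref) for both residues of a planted WC pair.

    The template is built in the mean pair plane; ``propeller`` rotates each
    base about its own glycosidic bond (opposite senses on the two sides),
    mimicking the propeller twist of stacked helical base pairs.
    """
    base2 = _COMPLEMENT[base1]
    key = "AU" if {base1, base2} == {"A", "U"} else "GC"
    span, lam1, phi1, lam2, phi2, propeller = _WC_PARAMS[key]
    if base1 in ("U", "C"):
        lam1, phi1, lam2, phi2 = lam2, phi2, lam1, phi1
        # parameters are stored for the purine on the left; swap for pyrimidine
    out = {}
    for tag, base, sign, lam, phi in (("1", base1, +1, lam1, phi1),
                                      ("2", base2, -1, lam2, phi2)):
        bond_n, _, _, bond_ref, ang_ref = _GLYCOSIDIC_GEOM[base]
        c1 = np.array([-sign * span / 2.0, 0.0, 0.0])
        u = np.array([sign * math.cos(math.radians(lam)),
                      math.sin(math.radians(lam)), 0.0])
        n = c1 + bond_n * u
        # Cref in the pair plane, direction phi from the +x axis, then tilted
        # out of plane by the propeller rotation about the glycosidic bond
        phi_rad = math.radians(phi if sign > 0 else 180.0 - phi)
        v = np.array([math.cos(phi_rad), math.sin(phi_rad), 0.0])
        cref = n + bond_ref * v
        if propeller:
            rot = _axis_rotation(u, math.radians(propeller))
            cref = n + rot @ (cref - n)
        out[tag] = {"C1'": c1, "N": n, "Cref": cref, "base": base}
    return out


def _residue_triad(res: Residue) -> np.ndarray:
    n_name, ref_name = _chem.GLYCOSIDIC[res.base_type]
    return np.array([res.coord("C1'"), res.coord(n_name), res.coord(ref_name)])


def _build_partner_strand(strand1: list[Residue], spec: FixtureSpec) -> list[Residue]:
    n = len(strand1)
    rev_comp = "".join(_COMPLEMENT[b] for b in reversed(spec.sequence))
    presets = [dict(spec.torsion_preset) for _ in range(n)]
    strand2 = _build_strand(rev_comp, presets, "B")

    # target triads: map the pair template onto each strand-1 residue
    targets = np.zeros((n, 3, 3))
    for i, res in enumerate(strand1):
        tpl = _pair_template(res.base_type)
        src = np.array([tpl["1"]["C1'"], tpl["1"]["N"], tpl["1"]["Cref"]])
        rot, t = kabsch_transform(src, _residue_triad(res))
        partner = np.array([tpl["2"]["C1'"], tpl["2"]["N"], tpl["2"]["Cref"]])
        targets[n - 1 - i] = partner @ rot.T + t

    moving = np.array([_residue_triad(r) for r in strand2])
    rot, t = kabsch_transform(moving.reshape(-1, 3), targets.reshape(-1, 3))
    for res in strand2:
        for atom in res.atoms.values():
            atom.coord = rot @ atom.coord + t
        res.seq_number += n
    return strand2


# ---------------------------------------------------------------------------
# perturbation and stripping
# ---------------------------------------------------------------------------

def perturb(chain: RnaChain, residue_index: int, angle: str, delta: float) -> RnaChain:
    """Return a copy with one torsion rotated by ``delta`` degrees.

    Only the glycosidic torsion ``chi`` is rotatable here (the base swings as
    a rigid body about the C1'-N bond; all other residues and all backbone
    atoms are untouched).  This is how clash scenarios are injected into
    otherwise clean fixtures.
    """
    if angle != "chi":
        raise ValueError(f"torsion {angle!r} is not rotatable in fixtures (only chi)")
    out = chain.copy()
    res = out.residues[residue_index]
    n_name, _ = _chem.GLYCOSIDIC[res.base_type]
    if "C1'" not in res.atoms or n_name not in res.atoms:
        raise ValueError(f"residue {res.label} lacks the glycosidic bond atoms")
    origin = res.coord("C1'")
    axis = res.coord(n_name) - origin
    axis = axis / np.linalg.norm(axis)
    rot = _axis_rotation(axis, math.radians(delta))
    for name in _chem.BASE_ATOMS[res.base_type]:
        atom = res.atoms.get(name)
        if atom is not None and name != n_name:
            atom.coord = origin + rot @ (atom.coord - origin)
    return out


def _axis_rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues), right-handed."""
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle_rad) * k + (1 - math.cos(angle_rad)) * (k @ k)


def strip(chain: RnaChain, mode: str) -> RnaChain:
    """Retain exactly the mode's fixed atom set in every residue (idempotent)."""
    keep = set(_chem.FIXED_ATOMS[mode])
    out = chain.copy()
    for res in out.residues:
        for name in list(res.atoms):
            if name not in keep:
                del res.atoms[name]
    return out


# ---------------------------------------------------------------------------
# abstract packing instances
# ---------------------------------------------------------------------------

@dataclass
class PackingInstance:
    """Random energy tables with known exhaustive optimum."""

    n_residues: int
    candidate_counts: list[int]
    e_fixed: dict
    e_pair: dict
    edges: list[tuple[int, int]]
    optimum_energy: float
    optimum_assignment: tuple[int, ...]

    def energy_of(self, assignment) -> float:
        total = sum(self.e_fixed[(i, c)] for i, c in enumerate(assignment))
        for i, j in self.edges:
            total += self.e_pair.get(((i, assignment[i]), (j, assignment[j])), 0.0)
        return total


_TOPOLOGIES = ("path", "star", "cycle", "two_blocks", "random")


def make_packing_instance(n_residues: int, n_candidates: int, topology: str = "random",
                          seed: int = 0) -> PackingInstance:
    """Build a random packing instance and its brute-force optimum.

    ``topology`` controls the interaction-graph shape: a path, a star, a
    cycle, two triangles sharing an articulation node (``two_blocks``), or an
    Erdos-Renyi random graph.  Self energies mix signs; pairwise energies are
    steric (zero or repulsive), matching the engine's decomposition rule that
    only positive interactions couple residues -- so the block-cut-tree solve
    is provably exact for these instances and can be checked against the
    brute force bit for bit.  The total combination count must stay small
    enough for exhaustive enumeration.
    """
    if n_candidates ** n_residues > 10 ** 6:
        raise ValueError("combination count too large for the exhaustive oracle")
    if topology not in _TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}")
    rng = np.random.default_rng(seed)
    counts = [int(rng.integers(1, n_candidates + 1)) for _ in range(n_residues)]

    if topology == "path":
        edges = [(i, i + 1) for i in range(n_residues - 1)]
    elif topology == "star":
        edges = [(0, i) for i in range(1, n_residues)]
    elif topology == "cycle":
        edges = [(i, (i + 1) % n_residues) for i in range(n_residues)]
        if n_residues < 3:
            edges = [(0, 1)] if n_residues == 2 else []
    elif topology == "two_blocks":
        if n_residues < 5:
            raise ValueError("two_blocks topology needs >= 5 residues")
        m = n_residues // 2
        tri1 = list(itertools.combinations(range(m + 1), 2))
        tri2 = list(itertools.combinations(range(m, n_residues), 2))
        edges = sorted(set(tri1) | set(tri2))
    else:
        edges = [(i, j) for i, j in itertools.combinations(range(n_residues), 2)
                 if rng.random() < 0.5]
    edges = sorted(set(tuple(sorted(e)) for e in edges if e[0] != e[1]))

    e_fixed = {(i, c): float(rng.normal(0.0, 3.0))
               for i in range(n_residues) for c in range(counts[i])}
    e_pair = {}
    for i, j in edges:
        for ci in range(counts[i]):
            for cj in range(counts[j]):
                u = rng.random()
                if u < 0.3:
                    val = float(rng.uniform(2.0, 40.0))   # hard clash
                elif u < 0.7:
                    val = float(rng.uniform(0.0, 1.5))    # mild overlap
                else:
                    val = 0.0                             # no contact
                e_pair[((i, ci), (j, cj))] = val
                e_pair[((j, cj), (i, ci))] = val

    best_e = math.inf
    best_a: tuple[int, ...] = ()
    for combo in itertools.product(*(range(c) for c in counts)):
        total = sum(e_fixed[(i, c)] for i, c in enumerate(combo))
        for i, j in edges:
            total += e_pair[((i, combo[i]), (j, combo[j]))]
        if total < best_e - 1e-12:
            best_e = total
            best_a = combo
    return PackingInstance(n_residues=n_residues, candidate_counts=counts,
                           e_fixed=e_fixed, e_pair=e_pair, edges=edges,
                           optimum_energy=best_e, optimum_assignment=best_a)
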