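"""Torsion-space conformer libraries: extraction, clustering, serialization.

A conformer library is the discrete conformational space searched during
remodeling.  It is built from any collection of RNA structures by a
two-stage clustering protocol applied per residue type: stage 1 groups
residues on the six backbone torsions (alpha..zeta), stage 2 refines each
group on the glycosidic torsion chi.  Either neural-gas or k-medoids
clustering can be used, under a wrap-aware Euclidean distance or the MCQ
circular mean.  Every stored prototype is a real residue (the subcluster
medoid), carrying its full 12-torsion vector, atom coordinates in a
canonical backbone frame, and covalent bond lengths.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import _chem
from .geometry import (
    CONFORMER_TORSIONS,
    circular_difference,
    compute_torsions,
    local_frame,
    mcq,
    wrap_angle,
)

__all__ = [
    "Conformer",
    "ConformerLibrary",
    "LibraryError",
    "extract_annotated_residues",
    "euclidean_angle_distance",
    "mcq_distance",
    "neural_gas",
    "k_medoids",
    "build_library",
    "save_library",
    "load_library",
    "builtin_library",
]

log = logging.getLogger(__name__)

#: angles used by the two clustering stages
STAGE1_ANGLES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")
STAGE2_ANGLES = ("chi",)

LIBRARY_FORMAT = "nucleofit-library"
LIBRARY_VERSION = 1


class LibraryError(ValueError):
    """Raised for invalid library content or serialization problems."""


@dataclass
class Conformer:
    """One library entry: a representative residue geometry.

    ``atom_coords`` live in the canonical local frame anchored on the
    C5'/C4'/C3' backbone triad (see :func:`nucleofit.geometry.local_frame`),
    so conformers extracted from different structures are directly
    comparable and can be superposed onto any fixed backbone.
    """

    id: str
    base_type: str
    torsions: dict[str, float]
    atom_coords: dict[str, np.ndarray]
    bond_lengths: dict[str, float]
    group_id: int = -1
    sub_id: int = -1

    def __post_init__(self):
        if self.base_type not in _chem.BASE_TYPES:
            raise LibraryError(f"conformer {self.id}: bad base type {self.base_type!r}")
        missing = [n for n in CONFORMER_TORSIONS
                   if self.torsions.get(n) is None]
        if missing:
            raise LibraryError(
                f"conformer {self.id}: undefined torsion(s) {', '.join(missing)}")
        need = set(_chem.SUGAR_ATOMS) | set(_chem.BASE_ATOMS[self.base_type])
        lost = sorted(need - set(self.atom_coords))
        if lost:
            raise LibraryError(
                f"conformer {self.id}: incomplete atom set, missing {', '.join(lost)}")
        self.atom_coords = {k: np.asarray(v, dtype=float)
                            for k, v in self.atom_coords.items()}

    def torsion_vector(self, names) -> list[float]:
        return [self.torsions[n] for n in names]


@dataclass
class ConformerLibrary:
    """Two-level hierarchy of conformers, queried by residue type."""

    name: str
    distance: str
    algorithm: str
    conformers: list[Conformer] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.conformers:
            raise LibraryError("a conformer library must not be empty")

    def by_type(self, base_type: str) -> list[Conformer]:
        return [c for c in self.conformers if c.base_type == base_type]

    def summary(self) -> dict:
        out: dict[str, dict] = {}
        for t in _chem.BASE_TYPES:
            members = self.by_type(t)
            out[t] = {
                "conformers": len(members),
                "groups": len({c.group_id for c in members}),
            }
        out["total"] = {"conformers": len(self.conformers)}
        return out


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_annotated_residues(chains) -> list[Conformer]:
    """Collect conformer precursors from parsed chains.

    One record is produced per residue that (a) carries every heavy atom of
    its type and (b) has all 12 torsions defined -- in practice the interior
    residues of unbroken strands.  Incomplete residues are skipped and
    counted in the module log.
    """
    out: list[Conformer] = []
    skipped = 0
    for chain in chains:
        profile = compute_torsions(chain)
        for i, res in enumerate(chain.residues):
            needed = set(_chem.residue_atoms(res.base_type))
            if not needed <= set(res.atoms):
                skipped += 1
                continue
            torsions = {n: profile.get(i, n) for n in CONFORMER_TORSIONS}
            if any(v is None for v in torsions.values()):
                skipped += 1
                continue
            rows, origin = local_frame(res.coord("C5'"), res.coord("C4'"),
                                       res.coord("C3'"))
            atom_coords = {name: rows @ (atom.coord - origin)
                           for name, atom in res.atoms.items()}
            bond_lengths = {
                f"{a}-{b}": float(np.linalg.norm(res.coord(a) - res.coord(b)))
                for a, b in _chem.residue_bonds(res.base_type)
                if a in res.atoms and b in res.atoms
            }
            out.append(Conformer(
                id=f"{chain.source_id}/{res.label}",
                base_type=res.base_type,
                torsions=torsions,
                atom_coords=atom_coords,
                bond_lengths=bond_lengths,
            ))
    if skipped:
        log.info("extract_annotated_residues: skipped %d incomplete residue(s)", skipped)
    return out


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def euclidean_angle_distance(u, v) -> float:
    """Wrap-aware Euclidean distance between two angle vectors (degrees).

    Each component difference is taken on the circle before squaring, so
    179 and -179 are 2 degrees apart, not 358.
    """
    if len(u) != len(v):
        raise LibraryError("angle vectors must have equal length")
    return float(np.sqrt(sum(circular_difference(a, b) ** 2 for a, b in zip(u, v))))


def mcq_distance(u, v) -> float:
    """MCQ (circular-mean) distance between two angle vectors, degrees."""
    return mcq(u, v)


_DISTANCES = {"euclidean": euclidean_angle_distance, "mcq": mcq_distance}


def get_distance(name: str):
    try:
        return _DISTANCES[name]
    except KeyError:
        raise LibraryError(f"unknown distance {name!r} (choose from "
                           f"{', '.join(sorted(_DISTANCES))})") from None


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def neural_gas(points, k: int, distance: str = "euclidean", epochs: int = 30,
               seed: int = 0) -> np.ndarray:
    """Neural-gas prototype learning on circular angle vectors.

    Prototypes start at ``k`` distinct data points chosen by the seeded RNG.
    Every epoch presents all samples in random order; for each sample the
    prototypes are ranked by distance and updated with step
    ``eps * exp(-rank / lam) * delta`` where ``delta`` is the wrapped signed
    angle difference, and ``eps``/``lam`` anneal geometrically from
    (0.5, k/2) to (0.005, 0.01) over the run.  Deterministic given the seed.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if not 1 <= k <= n:
        raise LibraryError(f"neural_gas: k={k} outside [1, {n}]")
    dist = get_distance(distance)
    rng = np.random.default_rng(seed)
    proto = pts[rng.choice(n, size=k, replace=False)].copy()

    eps0, epsf = 0.5, 0.005
    lam0, lamf = max(k / 2.0, 1e-6), 0.01
    total = max(epochs * n - 1, 1)
    step = 0
    for _ in range(epochs):
        for idx in rng.permutation(n):
            frac = step / total
            eps = eps0 * (epsf / eps0) ** frac
            lam = lam0 * (lamf / lam0) ** frac
            x = pts[idx]
            order = np.argsort([dist(x, w) for w in proto], kind="stable")
            for rank, pi in enumerate(order):
                h = eps * np.exp(-rank / lam)
                if h < 1e-12:
                    break
                delta = np.array([_signed_diff(a, b) for a, b in zip(x, proto[pi])])
                proto[pi] = np.array([wrap_angle(v) for v in proto[pi] + h * delta])
            step += 1
    return proto


def _signed_diff(a: float, b: float) -> float:
    """Signed circular difference a - b wrapped into (-180, 180]."""
    return wrap_angle(a - b)


def k_medoids(points, k: int, distance: str = "euclidean", seed: int = 0) -> list[int]:
    """PAM-style k-medoids; returns indices of the medoid data points.

    Starts from a seeded random selection and greedily applies the best
    improving (medoid, non-medoid) swap until no single swap lowers the
    total within-cluster distance -- a local minimum of the PAM objective.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if not 1 <= k <= n:
        raise LibraryError(f"k_medoids: k={k} outside [1, {n}]")
    dist = get_distance(distance)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = dist(pts[i], pts[j])

    rng = np.random.default_rng(seed)
    medoids = sorted(int(i) for i in rng.choice(n, size=k, replace=False))

    def cost(meds):
        return float(dmat[:, meds].min(axis=1).sum())

    current = cost(medoids)
    improved = True
    while improved:
        improved = False
        best = (current, None)
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in med_set:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1:])
                c = cost(trial)
                if c < best[0] - 1e-12:
                    best = (c, trial)
        if best[1] is not None:
            current, medoids = best
            improved = True
    return medoids


def _assign(points, centers, dist) -> list[int]:
    """Index of the nearest center for every point (ties to the first)."""
    out = []
    for p in points:
        ds = [dist(p, c) for c in centers]
        out.append(int(np.argmin(ds)))
    return out


def _medoid_index(points, members, dist) -> int:
    """Member index minimizing total distance to the other members."""
    best = None
    for i in members:
        total = sum(dist(points[i], points[j]) for j in members)
        if best is None or total < best[0] - 1e-12:
            best = (total, i)
    return best[1]


# ---------------------------------------------------------------------------
# library construction
# ---------------------------------------------------------------------------

def build_library(precursors, algorithm: str = "neural_gas",
                  distance: str = "euclidean", k1: int = 3, k2: int = 2,
                  seed: int = 0, name: str = "library",
                  provenance=()) -> ConformerLibrary:
    """Two-stage clustering of precursor residues into a conformer library.

    Residues are clustered per base type: stage 1 on the backbone 6-vector
    (alpha..zeta) into at most ``k1`` groups, stage 2 within each group on
    chi into at most ``k2`` subclusters.  Each subcluster is represented by
    its medoid, stored with the residue's real coordinates and bond lengths.
    Types with no precursor are absent from the library (with a warning).
    """
    if algorithm not in ("neural_gas", "k_medoids"):
        raise LibraryError(f"unknown algorithm {algorithm!r}")
    if k1 < 1 or k2 < 1:
        raise LibraryError("k1 and k2 must be positive")
    precursors = list(precursors)
    if not precursors:
        raise LibraryError("no precursor residues to cluster")
    dist = get_distance(distance)

    selected: list[Conformer] = []
    for t_i, base_type in enumerate(_chem.BASE_TYPES):
        members = [c for c in precursors if c.base_type == base_type]
        if not members:
            log.warning("build_library: no precursors of type %s", base_type)
            continue
        back = np.array([c.torsion_vector(STAGE1_ANGLES) for c in members])
        groups = _cluster(back, min(k1, len(members)), algorithm, distance,
                          seed + 17 * t_i)
        group_no = 0
        for g_members in groups:
            chi = np.array([[members[i].torsions["chi"]] for i in g_members])
            subs = _cluster(chi, min(k2, len(g_members)), algorithm, distance,
                            seed + 17 * t_i + 1 + group_no)
            for s_no, s_members in enumerate(subs):
                abs_members = [g_members[i] for i in s_members]
                for i in abs_members:
                    members[i].group_id = group_no
                    members[i].sub_id = s_no
                chosen = _medoid_index(
                    [[members[i].torsions["chi"]] for i in range(len(members))],
                    abs_members, dist)
                selected.append(members[chosen])
            group_no += 1
    return ConformerLibrary(name=name, distance=distance, algorithm=algorithm,
                            conformers=selected, provenance=list(provenance))


def _cluster(vectors: np.ndarray, k: int, algorithm: str, distance: str,
             seed: int) -> list[list[int]]:
    """Cluster row vectors into <= k non-empty member-index lists."""
    dist = get_distance(distance)
    if len(vectors) == 1 or k == 1:
        return [list(range(len(vectors)))]
    if algorithm == "neural_gas":
        centers = neural_gas(vectors, k, distance, seed=seed)
    else:
        centers = vectors[k_medoids(vectors, k, distance, seed=seed)]
    labels = _assign(vectors, centers, dist)
    groups = [[i for i, l in enumerate(labels) if l == g] for g in range(k)]
    return [g for g in groups if g]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_library(lib: ConformerLibrary) -> str:
    """Serialize a library to its JSON schema (lossless round-trip)."""
    doc = {
        "format": LIBRARY_FORMAT,
        "version": LIBRARY_VERSION,
        "name": lib.name,
        "distance": lib.distance,
        "algorithm": lib.algorithm,
        "provenance": lib.provenance,
        "conformers": [
            {
                "id": c.id,
                "base_type": c.base_type,
                "group_id": c.group_id,
                "sub_id": c.sub_id,
                "torsions": {k: round(v, 3) for k, v in c.torsions.items()},
                "atom_coords": {k: [round(float(x), 4) for x in v]
                                for k, v in c.atom_coords.items()},
                "bond_lengths": {k: round(v, 4) for k, v in c.bond_lengths.items()},
            }
            for c in lib.conformers
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def load_library(text: str) -> ConformerLibrary:
    """Parse library JSON, naming the offending field on schema errors."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise LibraryError(f"library file is not valid JSON: {exc}") from exc
    for key in ("format", "version", "name", "distance", "algorithm", "conformers"):
        if key not in doc:
            raise LibraryError(f"library schema violation: missing field {key!r}")
    if doc["format"] != LIBRARY_FORMAT:
        raise LibraryError(f"library schema violation: field 'format' is "
                           f"{doc['format']!r}, expected {LIBRARY_FORMAT!r}")
    if doc["version"] != LIBRARY_VERSION:
        raise LibraryError(f"library schema violation: unsupported version "
                           f"{doc['version']!r}")
    conformers = []
    for i, rec in enumerate(doc["conformers"]):
        for key in ("id", "base_type", "torsions", "atom_coords", "bond_lengths"):
            if key not in rec:
                raise LibraryError(
                    f"library schema violation: conformer #{i} missing {key!r}")
        try:
            conformers.append(Conformer(
                id=rec["id"], base_type=rec["base_type"],
                torsions=rec["torsions"], atom_coords=rec["atom_coords"],
                bond_lengths=rec["bond_lengths"],
                group_id=rec.get("group_id", -1), sub_id=rec.get("sub_id", -1)))
        except LibraryError as exc:
            raise LibraryError(f"library schema violation in conformer #{i}: {exc}") from exc
    return ConformerLibrary(name=doc["name"], distance=doc["distance"],
                            algorithm=doc["algorithm"], conformers=conformers,
                            provenance=list(doc.get("provenance", [])))


# ---------------------------------------------------------------------------
# built-in miniature library
# ---------------------------------------------------------------------------

def builtin_library() -> ConformerLibrary:
    """Miniature library generated from ideal-geometry synthetic strands.

    Covers all four residue types with a handful of chi rotamers around the
    A-form anti orientation plus a syn variant.  Useful for smoke tests and
    as a default when no user library is given; real applications should
    build a library from a representative structure collection.
    """
    from .fixtures import A_FORM_PRESET, FixtureSpec, generate_chain

    chains = []
    for chi_shift in (0.0, -40.0, 40.0, 145.0):
        preset = dict(A_FORM_PRESET)
        preset["chi"] = wrap_angle(preset["chi"] + chi_shift)
        chains.append(generate_chain(FixtureSpec(
            sequence="ACGUACGU", torsion_preset=preset)))
    precursors = extract_annotated_residues(chains)
    return build_library(precursors, algorithm="neural_gas", distance="euclidean",
                         k1=1, k2=4, seed=0, name="builtin",
                         provenance=["ideal-geometry synthetic strands"])
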