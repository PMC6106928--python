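"""Model quality assessment: clashes, RMSD subsets, MCQ, base pairs, INF.

These are deliberately lightweight, self-contained analogues of the
assessment tools commonly used around RNA model building (MolProbity-style
clash counting, secondary-structure annotation, Interaction Network
Fidelity).  The clash score here counts heavy-atom overlaps only -- absolute
values are not comparable with hydrogen-aware MolProbity scores, but
before/after trends on the same structure are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _chem
from .geometry import GeometryError, compute_torsions, mcq
from .structure import RnaChain

__all__ = [
    "ClashReport",
    "BasePairSet",
    "detect_clashes",
    "rmsd_subset",
    "mcq_compare",
    "annotate_canonical_pairs",
    "inf_score",
    "RMSD_ATOMS",
]

#: atom-name subsets for mode-specific RMSD: base heavy atoms for nucleobase
#: comparisons, base plus sugar (never the phosphate) for nucleoside ones
RMSD_ATOMS = {
    "nucleobase": ("C2", "C4", "C5", "C6", "C8", "N1", "N2", "N3", "N4",
                   "N6", "N7", "N9", "O2", "O4", "O6"),
    "nucleoside": ("O4'", "C1'", "C2'", "O2'", "C3'", "C4'",
                   "C2", "C4", "C5", "C6", "C8", "N1", "N2", "N3", "N4",
                   "N6", "N7", "N9", "O2", "O4", "O6"),
}

#: key donor/acceptor atom pairs per canonical pair class, (purine, pyrimidine)
_HBOND_ATOMS = {
    ("A", "U"): (("N1", "N3"), ("N6", "O4")),
    ("G", "C"): (("N1", "N3"), ("O6", "N4")),
    ("G", "U"): (("O6", "N3"), ("N1", "O2")),
}

_LINK_CUTOFF = 2.5

#: covalent neighbourhood excluded from contact scoring, in bonds; pairs up
#: to 1-4 never count as clashes (their separations are set by bond geometry,
#: not packing -- e.g. O4'-C8 sits near 2.8 A in every anti purine)
EXCLUDE_BONDS = 3


@dataclass
class ClashReport:
    """Steric clash inventory: overlapping non-bonded heavy-atom pairs."""

    clashes: list[tuple] = field(default_factory=list)
    n_atoms: int = 0
    threshold: float = 0.4

    @property
    def score(self) -> float:
        """Clashes per 1000 atoms in scope (0 for an empty scope)."""
        return 1000.0 * len(self.clashes) / self.n_atoms if self.n_atoms else 0.0

    def __len__(self) -> int:
        return len(self.clashes)


@dataclass
class BasePairSet:
    """Unordered canonical base-pair partners over residue indices (0-based)."""

    pairs: set = field(default_factory=set)
    n_residues: int = 0

    def __post_init__(self):
        self.pairs = {frozenset(p) for p in self.pairs}
        seen: set = set()
        for p in self.pairs:
            if seen & p:
                raise ValueError("a residue may appear in at most one canonical pair")
            seen |= p

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self.pairs

    def to_dot_bracket(self) -> str:
        """Dot-bracket string; crossing (pseudoknotted) pairs are left out."""
        chars = ["."] * self.n_residues
        kept: list[tuple[int, int]] = []
        for i, j in sorted(tuple(sorted(p)) for p in self.pairs):
            if any(a < i < b < j for a, b in kept):
                continue
            kept.append((i, j))
            chars[i], chars[j] = "(", ")"
        return "".join(chars)


# ---------------------------------------------------------------------------
# clashes
# ---------------------------------------------------------------------------

def detect_clashes(chain: RnaChain, threshold: float = 0.4,
                   scope=None) -> ClashReport:
    """Find non-bonded heavy-atom pairs overlapping by >= ``threshold``.

    A clash is a pair with ``r_i + r_j - d >= threshold`` that is neither a
    covalent neighbour (within :data:`EXCLUDE_BONDS` bonds, including across
    the backbone linkage of consecutive residues) nor a same-residue
    base-base pair.
    ``scope`` optionally restricts attention to a set of
    ``(residue_index, atom_name)`` tuples: a clash is reported when at least
    one participant is in scope, and the per-1000-atom score is normalized
    by the scope size.
    """
    entries = []
    for idx, res in enumerate(chain.residues):
        for name, atom in res.atoms.items():
            entries.append((idx, name, atom.coord, _chem.VDW_RADII[atom.element]))
    in_scope = (lambda i, n: True) if scope is None else (
        lambda i, n: (i, n) in scope)
    n_atoms = sum(1 for i, n, _, _ in entries if in_scope(i, n))

    coords = np.array([e[2] for e in entries])
    radii = np.array([e[3] for e in entries])
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    overlap = radii[:, None] + radii[None, :] - dist

    linked = _linked_pairs(chain)
    base_sets = [frozenset(_chem.BASE_ATOMS[r.base_type]) for r in chain.residues]
    bonded = [_chem.bonded_within(r.base_type, EXCLUDE_BONDS)
              for r in chain.residues]

    clashes = []
    for a, b in zip(*np.nonzero(np.triu(overlap >= threshold, k=1))):
        ia, na = entries[a][0], entries[a][1]
        ib, nb = entries[b][0], entries[b][1]
        if not (in_scope(ia, na) or in_scope(ib, nb)):
            continue
        if ia == ib:
            if frozenset((na, nb)) in bonded[ia]:
                continue
            if na in base_sets[ia] and nb in base_sets[ia]:
                continue
        elif frozenset((ia, ib)) in linked:
            lo, hi = (ia, ib) if ia < ib else (ib, ia)
            n_lo, n_hi = (na, nb) if ia < ib else (nb, na)
            excl = _chem.linked_excluded_pairs(
                chain.residues[lo].base_type, chain.residues[hi].base_type,
                EXCLUDE_BONDS)
            if (n_lo, n_hi) in excl:
                continue
        d = float(dist[a, b])
        clashes.append(((ia, na), (ib, nb), round(d, 3), round(float(overlap[a, b]), 3)))
    clashes.sort()
    return ClashReport(clashes=clashes, n_atoms=n_atoms, threshold=threshold)


def _linked_pairs(chain: RnaChain) -> set:
    """Residue index pairs joined by a plausible O3'-P backbone bond."""
    out = set()
    for i in range(len(chain) - 1):
        a, b = chain.residues[i], chain.residues[i + 1]
        if "O3'" in a.atoms and "P" in b.atoms:
            if np.linalg.norm(a.coord("O3'") - b.coord("P")) < _LINK_CUTOFF:
                out.add(frozenset((i, i + 1)))
    return out


# ---------------------------------------------------------------------------
# RMSD and MCQ comparisons
# ---------------------------------------------------------------------------

def rmsd_subset(model_a: RnaChain, model_b: RnaChain, mode: str) -> float:
    """RMSD over the mode's atom subset, matched by (residue, atom name).

    Both models must share sequence and residue order; no superposition is
    applied (the models are expected to share the fixed backbone frame).
    Atoms present in only one model are skipped.
    """
    if model_a.sequence != model_b.sequence:
        raise ValueError("models differ in sequence; cannot compare")
    names = set(RMSD_ATOMS[mode])
    deltas = []
    for res_a, res_b in zip(model_a.residues, model_b.residues):
        for name in names & set(res_a.atoms) & set(res_b.atoms):
            deltas.append(res_a.coord(name) - res_b.coord(name))
    if not deltas:
        raise GeometryError("no matched atoms in the requested subset")
    deltas = np.array(deltas)
    return float(np.sqrt(np.mean(np.sum(deltas ** 2, axis=1))))


def mcq_compare(model_a: RnaChain, model_b: RnaChain, angles=("chi",)) -> float:
    """MCQ over matched per-residue torsions of two models, degrees.

    Pairs where either model leaves the angle undefined (termini, missing
    atoms) are skipped, mirroring the behaviour of the underlying circular
    mean.
    """
    if len(model_a) != len(model_b):
        raise ValueError("models differ in length; cannot compare")
    prof_a = compute_torsions(model_a)
    prof_b = compute_torsions(model_b)
    va, vb = [], []
    for i in range(len(model_a)):
        for name in angles:
            va.append(prof_a.get(i, name))
            vb.append(prof_b.get(i, name))
    return mcq(va, vb)


# ---------------------------------------------------------------------------
# base pairs and INF
# ---------------------------------------------------------------------------

def annotate_canonical_pairs(chain: RnaChain,
                             c1_range=(8.9, 11.9),
                             hbond_max: float = 3.5,
                             plane_max: float = 30.0) -> BasePairSet:
    """Detect canonical (A-U, G-C, G-U wobble) pairs from geometry.

    A residue pair qualifies when the base types are complementary, the
    C1'-C1' distance falls in ``c1_range``, both key donor-acceptor
    distances for the pair class are below ``hbond_max`` and the base planes
    are within ``plane_max`` degrees of parallel.  Conflicts (a residue
    matching several partners) are resolved greedily by smallest mean
    hydrogen-bond distance.
    """
    candidates = []
    n = len(chain)
    for i in range(n):
        for j in range(i + 1, n):
            res_i, res_j = chain.residues[i], chain.residues[j]
            cls = _pair_class(res_i.base_type, res_j.base_type)
            if cls is None:
                continue
            pur, pyr = (res_i, res_j) if res_i.base_type in _chem.PURINES else (res_j, res_i)
            if "C1'" not in res_i.atoms or "C1'" not in res_j.atoms:
                continue
            d_c1 = float(np.linalg.norm(res_i.coord("C1'") - res_j.coord("C1'")))
            if not c1_range[0] <= d_c1 <= c1_range[1]:
                continue
            dists = []
            ok = True
            for a, b in _HBOND_ATOMS[cls]:
                if a not in pur.atoms or b not in pyr.atoms:
                    ok = False
                    break
                d = float(np.linalg.norm(pur.coord(a) - pyr.coord(b)))
                if d >= hbond_max:
                    ok = False
                    break
                dists.append(d)
            if not ok:
                continue
            angle = _plane_angle(res_i, res_j)
            if angle is None or angle >= plane_max:
                continue
            candidates.append((sum(dists) / len(dists), i, j))

    candidates.sort()
    used: set = set()
    pairs = set()
    for _, i, j in candidates:
        if i in used or j in used:
            continue
        pairs.add(frozenset((i, j)))
        used |= {i, j}
    return BasePairSet(pairs=pairs, n_residues=n)


def _pair_class(a: str, b: str):
    for pur, pyr in _HBOND_ATOMS:
        if {a, b} == {pur, pyr} and not (a in _chem.PURINES and b in _chem.PURINES):
            return (pur, pyr)
    return None


def _plane_angle(res_a, res_b):
    """Angle between the two base planes in degrees, or None if undefined."""
    normals = []
    for res in (res_a, res_b):
        pts = np.array([res.coord(n) for n in _chem.BASE_ATOMS[res.base_type]
                        if n in res.atoms])
        if len(pts) < 3:
            return None
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        normals.append(vt[2])
    c = abs(float(np.dot(normals[0], normals[1])))
    return math.degrees(math.acos(min(1.0, c)))


def inf_score(reference: BasePairSet, model: BasePairSet) -> float:
    """Interaction Network Fidelity between two base-pair sets.

    ``INF = sqrt(PPV * STY)`` with PPV = TP/(TP+FP) and STY = TP/(TP+FN)
    over the pair sets.  Two empty sets score 1.0 (nothing to restore,
    nothing spurious); exactly one empty set scores 0.0.
    """
    ref, mod = reference.pairs, model.pairs
    if not ref and not mod:
        return 1.0
    if not ref or not mod:
        return 0.0
    tp = len(ref & mod)
    if tp == 0:
        return 0.0
    ppv = tp / len(mod)
    sty = tp / len(ref)
    return math.sqrt(ppv * sty)
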