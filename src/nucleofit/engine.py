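"""Fixed-backbone remodeling engine.

Orchestrates the eight-step optimization that assigns one library conformer
to every remodeled residue:

1. candidate search by backbone-torsion similarity (MCQ),
2. reduction to the most promising candidates by reconstruction RMSD,
3. steric energies (Lennard-Jones 12-6 approximation) against the fixed
   structure and between candidate pairs,
4. Goldstein dead-end elimination,
5. residue-residue interaction graph over positive pair energies,
6. connected components,
7. block-cut-tree decomposition,
8. branch-and-bound over each component.

Steps 4-8 live in :mod:`nucleofit.packing`; this module supplies the
geometry: rebuilding candidates on the fixed backbone and scoring atom-atom
repulsion.  If every residue is down to a single candidate after step 1, 2
or 4, the remaining steps are skipped.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _chem, packing
from .geometry import GeometryError, compute_torsions, mcq, reconstruct_residue
from .library import ConformerLibrary, local_frame
from .structure import Atom, RemodelTask, RnaChain, StructureError, clean_and_validate

__all__ = [
    "EngineConfig",
    "Candidate",
    "EngineError",
    "lj_energy",
    "find_candidates",
    "prune_to_promising",
    "compute_energies",
    "remodel",
]

log = logging.getLogger(__name__)


class EngineError(RuntimeError):
    """Raised when the optimization cannot proceed (e.g. no candidates)."""


#: covalent neighbourhood (in bonds) excluded from steric scoring
EXCLUDE_BONDS = 3


def _linked_indices(chain: RnaChain) -> set:
    """Consecutive residue index pairs joined by a plausible O3'-P bond."""
    out = set()
    for i in range(len(chain) - 1):
        a, b = chain.residues[i], chain.residues[i + 1]
        if "O3'" in a.atoms and "P" in b.atoms:
            if np.linalg.norm(a.coord("O3'") - b.coord("P")) < 2.5:
                out.add(frozenset((i, i + 1)))
    return out


@dataclass
class EngineConfig:
    """Tunable knobs of the engine.

    Energies are in arbitrary units -- only ordering and sign matter to the
    optimizer.  The Lennard-Jones zero crossing sits at the sum of the van
    der Waals radii, so positive energy means steric overlap.
    """

    max_candidates: int = 10          # step-2 cap, "up to ten promising"
    mcq_window: float = 15.0          # step-1 retention band above best MCQ, deg
    lj_epsilon: float = 1.0           # LJ well depth, energy units
    vdw_radii: dict = field(default_factory=lambda: dict(_chem.VDW_RADII))
    pair_cutoff: float = 8.0          # Angstrom; no energy beyond this
    energy_cap: float = 100.0         # per atom pair, tames the r^-12 pole
    dee_max_rounds: int = 100
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.vdw_radii.values()):
            raise ValueError("van der Waals radii must be positive")
        if self.pair_cutoff <= 2 * max(self.vdw_radii.values()):
            raise ValueError("pair cutoff must exceed the largest contact distance")


@dataclass
class Candidate:
    """A library conformer rebuilt on one residue's fixed backbone."""

    conformer: object
    match_mcq: float
    coords: dict[str, np.ndarray] | None = None   # rebuilt atoms, set in step 2
    rebuild_rmsd: float = math.nan
    closure_dev: float = 0.0


# ---------------------------------------------------------------------------
# Step 1: candidate conformers by MCQ over comparable backbone angles
# ---------------------------------------------------------------------------

#: angles compared per mode: with a fixed sugar (nucleobase mode) the ring
#: torsions add signal, with a remodeled sugar only the backbone is fixed
MATCH_ANGLES = {
    "nucleoside": ("alpha", "beta", "gamma", "delta", "epsilon", "zeta"),
    "nucleobase": ("alpha", "beta", "gamma", "delta", "epsilon", "zeta",
                   "tau0", "tau1", "tau2", "tau3", "tau4"),
}


def find_candidates(residue, index: int, profile, library: ConformerLibrary,
                    mode: str, config: EngineConfig) -> list[Candidate]:
    """Score every library conformer of the residue's type by backbone MCQ.

    Only angle pairs defined on both sides enter the MCQ (chain termini have
    fewer angles -- that is fine).  All conformers within
    ``config.mcq_window`` degrees of the best match are retained, sorted by
    (MCQ, conformer id).
    """
    pool = library.by_type(residue.base_type)
    if not pool:
        raise EngineError(f"library has no conformer of type {residue.base_type} "
                          f"for residue {residue.label}")
    names = MATCH_ANGLES[mode]
    own = [profile.get(index, n) for n in names]
    if all(v is None for v in own):
        raise EngineError(f"residue {residue.label}: no comparable backbone angles")
    scored = []
    for conf in pool:
        score = mcq(own, [conf.torsions[n] for n in names])
        scored.append(Candidate(conformer=conf, match_mcq=score))
    scored.sort(key=lambda c: (c.match_mcq, c.conformer.id))
    best = scored[0].match_mcq
    return [c for c in scored if c.match_mcq <= best + config.mcq_window]


# ---------------------------------------------------------------------------
# Step 2: promising candidates by reconstruction RMSD
# ---------------------------------------------------------------------------

def prune_to_promising(residue, candidates: list[Candidate], mode: str,
                       config: EngineConfig) -> list[Candidate]:
    """Rebuild each candidate and keep the best ``max_candidates`` by RMSD.

    The RMSD compares the atoms rebuilt on the fixed backbone with the same
    atoms of the conformer rigidly superposed via its canonical C5'/C4'/C3'
    frame -- it measures how much the conformer had to distort to fit this
    backbone.  Ties break by (MCQ, conformer id).
    """
    rows, origin = local_frame(residue.coord("C5'"), residue.coord("C4'"),
                               residue.coord("C3'"))
    inv = rows.T
    survivors = []
    for cand in candidates:
        try:
            rebuilt, closure = reconstruct_residue(residue, cand.conformer, mode)
        except GeometryError as exc:
            log.debug("candidate %s rejected at rebuild: %s", cand.conformer.id, exc)
            continue
        ref = {name: inv @ c + origin
               for name, c in cand.conformer.atom_coords.items()}
        names = sorted(rebuilt)
        a = np.array([rebuilt[n] for n in names])
        b = np.array([ref[n] for n in names])
        cand.coords = rebuilt
        cand.rebuild_rmsd = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
        cand.closure_dev = closure
        survivors.append(cand)
    if not survivors:
        raise EngineError(f"residue {residue.label}: every candidate failed "
                          "reconstruction")
    survivors.sort(key=lambda c: (c.rebuild_rmsd, c.match_mcq, c.conformer.id))
    return survivors[:config.max_candidates]


# ---------------------------------------------------------------------------
# Step 3: Lennard-Jones energies
# ---------------------------------------------------------------------------

def lj_energy(d: float, r_i: float, r_j: float, config: EngineConfig) -> float:
    """12-6 Lennard-Jones energy of one atom pair at distance ``d``.

    ``sigma`` is the sum of the van der Waals radii, so the energy crosses
    zero exactly at contact, is negative (attractive) beyond contact with a
    minimum of ``-lj_epsilon`` at ``2^(1/6) sigma``, and rises steeply on
    overlap, capped at ``energy_cap``.  Zero beyond the pair cutoff.
    """
    if d <= 0:
        raise ValueError("distance must be positive")
    if d >= config.pair_cutoff:
        return 0.0
    sr6 = ((r_i + r_j) / d) ** 6
    e = 4.0 * config.lj_epsilon * (sr6 * sr6 - sr6)
    return min(e, config.energy_cap)


def _lj_array(dist: np.ndarray, sigma: np.ndarray, config: EngineConfig) -> np.ndarray:
    """Vectorized counterpart of :func:`lj_energy` (same conventions)."""
    with np.errstate(divide="ignore", over="ignore"):
        sr6 = (sigma / dist) ** 6
        e = 4.0 * config.lj_epsilon * (sr6 * sr6 - sr6)
    e = np.minimum(e, config.energy_cap)
    e[dist >= config.pair_cutoff] = 0.0
    return e


def compute_energies(chain: RnaChain, candidates: dict[int, list[Candidate]],
                     config: EngineConfig) -> packing.EnergyTables:
    """Fill the E_fixed / E_pair tables for all rebuilt candidates.

    ``E_fixed`` sums LJ terms between a candidate's rebuilt atoms and every
    fixed atom of the structure, excluding covalent neighbours within three
    bonds (same residue, or across the O3'-P linkage of consecutive
    residues): the rebuilt atoms attach to the fixed frame, and separations
    set by bond geometry must not register as steric energy.  ``E_pair``
    sums terms between the rebuilt atoms of candidates at two different
    residues and is stored symmetrically whenever any atom pair falls inside
    the cutoff.
    """
    radii = config.vdw_radii
    fixed_coords = []
    fixed_radii = []
    fixed_owner = []
    fixed_names = []
    for idx, res in enumerate(chain.residues):
        for name, atom in res.atoms.items():
            fixed_coords.append(atom.coord)
            fixed_radii.append(radii[atom.element])
            fixed_owner.append(idx)
            fixed_names.append(name)
    fixed_coords = np.array(fixed_coords)
    fixed_radii = np.array(fixed_radii)
    fixed_owner = np.array(fixed_owner)

    tables = packing.EnergyTables(cutoff=config.pair_cutoff)
    linked = _linked_indices(chain)
    for idx, cands in candidates.items():
        res = chain.residues[idx]
        excluded = _chem.bonded_within(res.base_type, EXCLUDE_BONDS)
        for m, cand in enumerate(cands):
            names = sorted(cand.coords)
            coords = np.array([cand.coords[n] for n in names])
            crad = np.array([radii[_chem.element_of(n)] for n in names])
            dist = np.linalg.norm(coords[:, None, :] - fixed_coords[None, :, :],
                                  axis=-1)
            energies = _lj_array(dist, crad[:, None] + fixed_radii[None, :], config)
            for a, name in enumerate(names):
                for b in np.nonzero(fixed_owner == idx)[0]:
                    if frozenset((name, fixed_names[b])) in excluded:
                        energies[a, b] = 0.0
                for other in (idx - 1, idx + 1):
                    if frozenset((idx, other)) not in linked:
                        continue
                    lo_t = chain.residues[min(idx, other)].base_type
                    hi_t = chain.residues[max(idx, other)].base_type
                    excl = _chem.linked_excluded_pairs(lo_t, hi_t, EXCLUDE_BONDS)
                    for b in np.nonzero(fixed_owner == other)[0]:
                        pair = ((name, fixed_names[b]) if idx < other
                                else (fixed_names[b], name))
                        if pair in excl:
                            energies[a, b] = 0.0
            tables.e_fixed[(idx, m)] = float(energies.sum())

    flagged = sorted(candidates)
    for i, j in itertools.combinations(flagged, 2):
        for m, cm in enumerate(candidates[i]):
            am = np.array([cm.coords[n] for n in sorted(cm.coords)])
            rm = np.array([radii[_chem.element_of(n)] for n in sorted(cm.coords)])
            for n, cn in enumerate(candidates[j]):
                an = np.array([cn.coords[k] for k in sorted(cn.coords)])
                rn = np.array([radii[_chem.element_of(k)] for k in sorted(cn.coords)])
                dist = np.linalg.norm(am[:, None, :] - an[None, :, :], axis=-1)
                if dist.min() >= config.pair_cutoff:
                    continue
                e = float(_lj_array(dist, rm[:, None] + rn[None, :], config).sum())
                tables.e_pair[((i, m), (j, n))] = e
                tables.e_pair[((j, n), (i, m))] = e
    return tables


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def remodel(chain: RnaChain, task: RemodelTask, library: ConformerLibrary,
            config: EngineConfig | None = None) -> tuple[RnaChain, dict]:
    """Run the full eight-step pipeline on a validated chain.

    Returns the remodeled chain (fixed atoms bit-identical to the input,
    rebuilt atoms from the chosen conformers) and a log dict recording the
    candidate counts after every step, the interaction-graph decomposition,
    and the final energy.
    """
    config = config or EngineConfig()
    cleaned, report = clean_and_validate(chain, task)
    if not report.ok:
        raise StructureError("; ".join(report.errors))
    flagged = [i for i, f in enumerate(task.flags) if f]
    logbook: dict = {"mode": task.mode, "flagged": flagged, "steps": {}}
    if task.minimize:
        log.warning("energy minimization was requested but is an external "
                    "post-processing hook; skipping")
        logbook["minimize"] = "requested, skipped (external hook)"

    profile = compute_torsions(cleaned)

    # step 1
    cands = {i: find_candidates(cleaned.residues[i], i, profile, library,
                                task.mode, config) for i in flagged}
    logbook["steps"]["1_candidates"] = {i: len(c) for i, c in cands.items()}

    # step 2
    cands = {i: prune_to_promising(cleaned.residues[i], c, task.mode, config)
             for i, c in cands.items()}
    logbook["steps"]["2_promising"] = {i: len(c) for i, c in cands.items()}

    if all(len(c) == 1 for c in cands.values()):
        chosen = {i: 0 for i in flagged}
        logbook["early_exit"] = "after step 2"
        energy = None
    else:
        # step 3
        tables = compute_energies(cleaned, cands, config)
        logbook["steps"]["3_energies"] = {
            "e_fixed_entries": len(tables.e_fixed),
            "e_pair_entries": len(tables.e_pair) // 2,
        }
        index_space = {i: list(range(len(c))) for i, c in cands.items()}
        result = packing.solve(index_space, tables,
                               dee_max_rounds=config.dee_max_rounds)
        chosen = result.assignment
        energy = result.energy
        logbook["steps"]["4_dee_pruned"] = result.n_pruned_by_dee
        logbook["steps"]["6_components"] = [list(c) for c in result.components]

    out = cleaned.copy()
    picks = {}
    for i in flagged:
        cand = cands[i][chosen[i]]
        res = out.residues[i]
        for name, coord in cand.coords.items():
            res.atoms[name] = Atom(name=name, element=_chem.element_of(name),
                                   coord=np.array(coord))
        picks[i] = {
            "conformer": cand.conformer.id,
            "mcq": round(cand.match_mcq, 3),
            "rmsd": round(cand.rebuild_rmsd, 4),
            "closure_dev": round(cand.closure_dev, 4),
        }
    logbook["chosen"] = picks
    logbook["total_energy"] = energy
    return out, logbook
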