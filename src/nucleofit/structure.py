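"""Reading, validating, cleaning and writing RNA structures in PDB format.

The in-memory model is deliberately small: an :class:`RnaChain` is an ordered
list of :class:`Residue` objects (one or more PDB chains concatenated in file
order, 5'->3'), each holding named heavy :class:`Atom` records.  Parsing and
serialization go through :mod:`gemmi`; this module adds the RNA-specific
validation the remodeling engine relies on -- required atom sets per mode,
the three-residue minimum, and the case-encoded task sequence.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import _chem

__all__ = [
    "Atom",
    "Residue",
    "RnaChain",
    "RemodelTask",
    "ValidationReport",
    "StructureError",
    "MODES",
    "parse_pdb",
    "clean_and_validate",
    "parse_task_sequence",
    "write_pdb",
]

MODES = ("nucleobase", "nucleoside")

_RNA_RESNAMES = {"A": "A", "C": "C", "G": "G", "U": "U",
                 "RA": "A", "RC": "C", "RG": "G", "RU": "U"}


class StructureError(ValueError):
    """Raised for unreadable or invalid structural input."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    serial: int = 0
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be a finite 3-vector")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    base_type: str
    atoms: dict[str, Atom] = field(default_factory=dict)
    insertion_code: str = ""

    def __post_init__(self):
        if self.base_type not in _chem.BASE_TYPES:
            raise ValueError(f"unsupported residue type {self.base_type!r}")

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.base_type}{self.seq_number}{self.insertion_code}"

    def coord(self, name: str) -> np.ndarray:
        return self.atoms[name].coord


@dataclass
class RnaChain:
    """Ordered residues of one RNA molecule (multi-chain inputs concatenated)."""

    residues: list[Residue] = field(default_factory=list)
    source_id: str = ""
    #: (residue label, atom-or-residue name, reason) records of everything the
    #: parser dropped: waters/ions/protein, hydrogens, extra altlocs
    parse_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.base_type for r in self.residues)

    def copy(self) -> "RnaChain":
        return copy.deepcopy(self)

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


@dataclass
class RemodelTask:
    """What to remodel: mode, per-residue flags, and the task sequence."""

    mode: str
    flags: list[bool]
    sequence: str
    library_id: str = "builtin"
    minimize: bool = False

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if len(self.flags) != len(self.sequence):
            raise ValueError("flags and sequence lengths differ")
        if not any(self.flags):
            raise ValueError("at least one residue must be flagged for remodeling")


@dataclass
class ValidationReport:
    removed_atoms: list[tuple[str, str, str]] = field(default_factory=list)
    missing_required: list[tuple[str, str]] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_pdb(text: str, chain_filter: list[str] | None = None,
              source_id: str = "") -> RnaChain:
    """Parse PDB-format text into an :class:`RnaChain`.

    Standard RNA residues (A, C, G, U) are kept with all their heavy atoms;
    waters, ions, protein and other residues, hydrogens, and alternate
    locations other than the first are dropped.  Multi-chain inputs are
    concatenated in file order.  ``chain_filter`` restricts parsing to the
    named PDB chains.
    """
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi message
        raise StructureError(f"unreadable PDB input: {exc}") from exc
    if len(st) == 0:
        raise StructureError("no model found in PDB input")
    model = st[0]
    if chain_filter is not None:
        known = [ch.name for ch in model]
        missing = [c for c in chain_filter if c not in known]
        if missing:
            raise StructureError(f"chain(s) not found in input: {', '.join(missing)}")

    chain = RnaChain(source_id=source_id or st.name or "input")
    for ch in model:
        if chain_filter is not None and ch.name not in chain_filter:
            continue
        for res in ch:
            base = _RNA_RESNAMES.get(res.name.strip())
            if base is None:
                chain.parse_log.append(
                    (f"{ch.name}/{res.name}{res.seqid.num}", res.name, "non-RNA residue"))
                continue
            residue = Residue(chain_id=ch.name, seq_number=res.seqid.num,
                              base_type=base, insertion_code=(res.seqid.icode or "").strip())
            for atom in res:
                name = atom.name.strip()
                if atom.element.is_hydrogen:
                    chain.parse_log.append((residue.label, name, "hydrogen"))
                    continue
                if name in residue.atoms:
                    # gemmi keeps file order, so the first altloc wins
                    chain.parse_log.append((residue.label, name, "alternate location"))
                    continue
                residue.atoms[name] = Atom(
                    name=name,
                    element=atom.element.name,
                    coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    serial=atom.serial,
                    occupancy=atom.occ,
                    b_factor=atom.b_iso,
                )
            if residue.atoms:
                chain.residues.append(residue)
    if not chain.residues:
        raise StructureError("no RNA residues found in input")
    return chain


# ---------------------------------------------------------------------------
# validation / cleaning
# ---------------------------------------------------------------------------

def clean_and_validate(chain: RnaChain, task: RemodelTask) -> tuple[RnaChain, ValidationReport]:
    """Strip remodeled atoms and check the hard input rules.

    For every flagged residue, atoms outside the mode's fixed set are removed
    (they will be rebuilt).  Errors are raised into the report for: chains
    shorter than 3 residues, sequence/chain length mismatch, and flagged
    residues missing a required fixed atom.  Unflagged residues are never
    touched.
    """
    report = ValidationReport()
    if len(chain) < 3:
        report.errors.append(
            f"input has {len(chain)} residues; fewer than the minimum of 3")
    if len(task.flags) != len(chain):
        report.errors.append(
            f"task length {len(task.flags)} does not match chain length {len(chain)}")
        return chain.copy(), report

    fixed_set = set(_chem.FIXED_ATOMS[task.mode])
    required = _chem.REQUIRED_ATOMS[task.mode]
    cleaned = chain.copy()
    for i, (res, flag) in enumerate(zip(cleaned.residues, task.flags)):
        if not flag:
            continue
        for name in required:
            if name not in res.atoms:
                report.missing_required.append((res.label, name))
                report.errors.append(
                    f"residue {res.label}: required fixed atom {name} is missing")
        for name in list(res.atoms):
            if name not in fixed_set:
                del res.atoms[name]
                report.removed_atoms.append((res.label, name, "remodeled"))
    return cleaned, report


_VALID_LETTERS = set("acguACGU")


def parse_task_sequence(raw: str, chain: RnaChain, mode: str,
                        library_id: str = "builtin",
                        minimize: bool = False) -> RemodelTask:
    """Parse a case-encoded task sequence against a chain.

    Uppercase letters mark residues to remodel, lowercase letters residues to
    keep fixed.  Each letter must match the chain's residue type at that
    position (case-insensitively).  The alphabet is a/c/g/u in either case;
    anything else -- including T and modified-residue codes -- is rejected.
    """
    if not raw:
        raise StructureError("task sequence must be non-empty")
    bad = sorted(set(raw) - _VALID_LETTERS)
    if bad:
        raise StructureError(
            f"illegal character(s) in task sequence: {', '.join(map(repr, bad))} "
            "(allowed: a, c, g, u in upper or lower case)")
    if len(raw) != len(chain):
        raise StructureError(
            f"task sequence length {len(raw)} does not match chain length {len(chain)}")
    flags = []
    for i, (letter, res) in enumerate(zip(raw, chain.residues)):
        if letter.upper() != res.base_type:
            raise StructureError(
                f"position {i + 1}: sequence letter {letter!r} conflicts with "
                f"residue type {res.base_type} ({res.label})")
        flags.append(letter.isupper())
    if not any(flags):
        raise StructureError("task sequence flags no residue for remodeling "
                             "(all letters lowercase)")
    return RemodelTask(mode=mode, flags=flags, sequence=raw.upper(),
                       library_id=library_id, minimize=minimize)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_pdb(chain: RnaChain) -> str:
    """Serialize a chain back to PDB-format text.

    Original chain identifiers and residue numbering are preserved;
    coordinates are printed with the standard three decimals, so atoms whose
    coordinates were never touched round-trip exactly.
    """
    if not chain.residues:
        raise StructureError("cannot write an empty chain")
    st = gemmi.Structure()
    st.name = chain.source_id or "nucleofit"
    model = gemmi.Model("1")
    current = None
    serial = 0
    for res in chain.residues:
        if current is None or current.name != res.chain_id:
            current = gemmi.Chain(res.chain_id)
            model.add_chain(current)
            current = model[-1]
        g_res = gemmi.Residue()
        g_res.name = res.base_type
        g_res.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
        for atom in _ordered_atoms(res):
            g_atom = gemmi.Atom()
            g_atom.name = atom.name
            g_atom.element = gemmi.Element(atom.element)
            g_atom.pos = gemmi.Position(*atom.coord)
            serial += 1
            g_atom.serial = serial
            g_atom.occ = atom.occupancy
            g_atom.b_iso = atom.b_factor
            g_res.add_atom(g_atom)
        current.add_residue(g_res)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True, numbered_ter=False))


def _ordered_atoms(res: Residue):
    order = {name: i for i, name in enumerate(_chem.residue_atoms(res.base_type))}
    return sorted(res.atoms.values(), key=lambda a: order.get(a.name, len(order)))
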