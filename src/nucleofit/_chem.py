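"""Chemical reference tables for standard ribonucleotides.

Atom inventories, covalent-bond graphs, van der Waals radii and the
glycosidic attachment atoms for the four standard residue types A, C, G, U.
Hydrogens are outside the scope of this package; all tables are heavy-atom
only.
"""

from __future__ import annotations

from functools import lru_cache

BASE_TYPES = ("A", "C", "G", "U")
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}

PHOSPHATE_ATOMS = ("P", "OP1", "OP2")
SUGAR_ATOMS = ("O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'")

BASE_ATOMS = {
    "A": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6", "N6"),
    "G": ("N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6", "O6", "N2"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
}

#: glycosidic nitrogen and its in-base torsion reference atom (chi is
#: O4'-C1'-N9-C4 for purines, O4'-C1'-N1-C2 for pyrimidines)
GLYCOSIDIC = {
    "A": ("N9", "C4"),
    "G": ("N9", "C4"),
    "C": ("N1", "C2"),
    "U": ("N1", "C2"),
}

#: atoms that remain inviolable in each remodeling mode
FIXED_ATOMS = {
    "nucleoside": ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'"),
    "nucleobase": ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'",
                   "O4'", "C1'", "C2'", "O2'"),
}

#: atoms that MUST be present in a flagged residue for each mode (the
#: phosphate group is kept when present but not required -- 5'-terminal
#: residues routinely lack it)
REQUIRED_ATOMS = {
    "nucleoside": ("O5'", "C5'", "C4'", "C3'", "O3'"),
    "nucleobase": ("O5'", "C5'", "C4'", "C3'", "O3'", "O4'", "C1'", "C2'", "O2'"),
}

#: heavy-atom van der Waals radii, Angstrom
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80}

_BACKBONE_BONDS = (
    ("P", "OP1"), ("P", "OP2"), ("P", "O5'"),
    ("O5'", "C5'"), ("C5'", "C4'"), ("C4'", "C3'"), ("C4'", "O4'"),
    ("C3'", "O3'"), ("C3'", "C2'"), ("C2'", "C1'"), ("C2'", "O2'"),
    ("C1'", "O4'"),
)

_BASE_BONDS = {
    "A": (("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C4"), ("C4", "N9"),
          ("C4", "N3"), ("N3", "C2"), ("C2", "N1"), ("N1", "C6"), ("C6", "C5"),
          ("C6", "N6")),
    "G": (("N9", "C8"), ("C8", "N7"), ("N7", "C5"), ("C5", "C4"), ("C4", "N9"),
          ("C4", "N3"), ("N3", "C2"), ("C2", "N1"), ("N1", "C6"), ("C6", "C5"),
          ("C6", "O6"), ("C2", "N2")),
    "C": (("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C5", "C6"),
          ("C6", "N1"), ("C2", "O2"), ("C4", "N4")),
    "U": (("N1", "C2"), ("C2", "N3"), ("N3", "C4"), ("C4", "C5"), ("C5", "C6"),
          ("C6", "N1"), ("C2", "O2"), ("C4", "O4")),
}


def residue_atoms(base_type: str) -> tuple[str, ...]:
    """Full heavy-atom inventory of a standard residue, 5'-phosphate included."""
    return PHOSPHATE_ATOMS + SUGAR_ATOMS + BASE_ATOMS[base_type]


def residue_bonds(base_type: str) -> tuple[tuple[str, str], ...]:
    """Intra-residue covalent bonds, glycosidic bond included."""
    n_gly = GLYCOSIDIC[base_type][0]
    return _BACKBONE_BONDS + (("C1'", n_gly),) + _BASE_BONDS[base_type]


@lru_cache(maxsize=None)
def bonded_within(base_type: str, max_bonds: int = 2) -> frozenset[frozenset]:
    """Atom-name pairs of a residue separated by <= ``max_bonds`` covalent bonds."""
    adj: dict[str, set[str]] = {}
    for a, b in residue_bonds(base_type):
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    pairs = set()
    for start in adj:
        frontier = {start}
        seen = {start}
        for _ in range(max_bonds):
            frontier = {n for f in frontier for n in adj.get(f, ())} - seen
            seen |= frontier
        for other in seen - {start}:
            pairs.add(frozenset((start, other)))
    return frozenset(pairs)


@lru_cache(maxsize=None)
def linked_excluded_pairs(base_a: str, base_b: str,
                          max_bonds: int = 3) -> frozenset[tuple[str, str]]:
    """Cross-residue atom pairs within ``max_bonds`` of the O3'(a)-P(b) linkage.

    Returned as (atom in 5' residue, atom in 3' residue) name tuples; these
    covalent neighbours must not be scored as steric contacts.
    """
    adj: dict[tuple, set] = {}

    def add(x, y):
        adj.setdefault(x, set()).add(y)
        adj.setdefault(y, set()).add(x)

    for x, y in residue_bonds(base_a):
        add(("a", x), ("a", y))
    for x, y in residue_bonds(base_b):
        add(("b", x), ("b", y))
    add(("a", "O3'"), ("b", "P"))
    out = set()
    for start in [n for n in adj if n[0] == "a"]:
        frontier = {start}
        seen = {start}
        for _ in range(max_bonds):
            frontier = {m for f in frontier for m in adj.get(f, ())} - seen
            seen |= frontier
        for other in seen:
            if other[0] == "b":
                out.add((start[1], other[1]))
    return frozenset(out)


def element_of(atom_name: str) -> str:
    """Chemical element of a standard RNA heavy atom from its PDB name."""
    lead = atom_name.strip()[0]
    if lead not in "CNOP":
        raise ValueError(f"unsupported atom name {atom_name!r}")
    return lead
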