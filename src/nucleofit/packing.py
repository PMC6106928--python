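"""Combinatorial optimization of conformer assignments.

This module is the abstract core of the fitting engine: it knows nothing
about geometry, only about candidate lists and energy tables.  Given
per-residue candidates with self energies (``e_fixed``) and symmetric
pairwise energies (``e_pair``, absent entries meaning zero), it finds the
global-minimum-energy assignment by

1. Goldstein dead-end elimination (provably safe pruning of candidates that
   can never be part of the optimum),
2. committing residues left with a single candidate and folding their pair
   energies into their neighbours' self energies,
3. building the residue-residue interaction graph (edge wherever some
   candidate pair has positive energy),
4. decomposing each connected component into its block-cut tree of
   biconnected components, and
5. solving the blocks by depth-first branch-and-bound, collapsing leaf
   blocks into their articulation points until a single block remains.

Graph machinery (connected/biconnected components, articulation points)
comes from :mod:`networkx`; the tests cross-check it against brute-force
definitions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "EnergyTables",
    "BlockCutTree",
    "PackingResult",
    "goldstein_prune",
    "positive_edges",
    "connected_components",
    "block_cut_tree",
    "solve",
]


@dataclass
class EnergyTables:
    """Self and pairwise energies over (residue, candidate) labels.

    ``e_fixed[(i, m)]`` is the energy of candidate ``m`` at residue ``i``
    against the fixed structure; ``e_pair[((i, m), (j, n))]`` the pairwise
    energy of two candidates at different residues.  ``e_pair`` is stored
    symmetrically and sparsely: a missing entry is zero.
    """

    e_fixed: dict = field(default_factory=dict)
    e_pair: dict = field(default_factory=dict)
    cutoff: float = 8.0

    def pair(self, i, m, j, n) -> float:
        return self.e_pair.get(((i, m), (j, n)), 0.0)

    def validate_symmetry(self) -> None:
        for ((a, b)), v in self.e_pair.items():
            if abs(self.e_pair.get((b, a), math.nan) - v) > 1e-9:
                raise ValueError(f"e_pair asymmetric at {a}, {b}")


@dataclass
class BlockCutTree:
    """Biconnected decomposition of a connected graph.

    ``blocks`` are the node sets of the biconnected components,
    ``articulation_points`` the nodes shared by two or more blocks, and
    ``adjacency`` maps each articulation point to the indices of the blocks
    containing it (the block-cut tree edges).
    """

    blocks: list[frozenset]
    articulation_points: set
    adjacency: dict

    def leaf_blocks(self) -> list[int]:
        """Indices of blocks containing at most one articulation point."""
        return [bi for bi, block in enumerate(self.blocks)
                if len(block & self.articulation_points) <= 1]


# ---------------------------------------------------------------------------
# Step 4: dead-end elimination (Goldstein criterion)
# ---------------------------------------------------------------------------

def goldstein_prune(candidates: dict, tables: EnergyTables,
                    max_rounds: int = 100) -> tuple[dict, list]:
    """Prune candidates that provably cannot be in the global optimum.

    Candidate ``m`` at residue ``i`` is eliminated when some competitor
    ``n`` at the same residue satisfies::

        E_fixed(m) - E_fixed(n)
          + sum_j min_c [E_pair(m, c) - E_pair(n, c)]  >  0

    i.e. ``n`` beats ``m`` no matter which candidates the other residues
    adopt.  Rounds repeat until a fixed point (or ``max_rounds``).  Only
    residues with two or more candidates participate, so every residue
    always keeps at least one candidate.

    Returns ``(surviving, log)`` where ``surviving`` maps residue to its
    remaining candidate list and ``log`` records ``(round, residue,
    pruned_candidate, dominating_candidate)`` tuples.
    """
    surviving = {i: list(cands) for i, cands in candidates.items()}
    others = {i: [j for j in surviving if j != i] for i in surviving}
    log = []
    for round_no in range(max_rounds):
        changed = False
        for i in sorted(surviving):
            cands = surviving[i]
            if len(cands) < 2:
                continue
            doomed = set()
            for m in cands:
                if m in doomed:
                    continue
                for n in cands:
                    if n == m or n in doomed:
                        continue
                    margin = tables.e_fixed[(i, m)] - tables.e_fixed[(i, n)]
                    for j in others[i]:
                        margin += min(
                            tables.pair(i, m, j, c) - tables.pair(i, n, j, c)
                            for c in surviving[j])
                    if margin > 1e-12:
                        doomed.add(m)
                        log.append((round_no, i, m, n))
                        break
            if doomed:
                surviving[i] = [c for c in cands if c not in doomed]
                changed = True
        if not changed:
            break
    return surviving, log


# ---------------------------------------------------------------------------
# Steps 5-7: interaction graph and its decomposition
# ---------------------------------------------------------------------------

def positive_edges(candidates: dict, tables: EnergyTables) -> list[tuple]:
    """Residue pairs with at least one positive pairwise candidate energy.

    Only residues with two or more candidates become nodes; the caller is
    expected to have committed and folded single-candidate residues first.
    """
    multi = sorted(i for i, c in candidates.items() if len(c) >= 2)
    edges = []
    for i, j in itertools.combinations(multi, 2):
        if any(tables.pair(i, m, j, n) > 0.0
               for m in candidates[i] for n in candidates[j]):
            edges.append((i, j))
    return edges


def connected_components(nodes, edges) -> list[list]:
    """Maximal connected node sets, ordered by smallest member."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])


def block_cut_tree(nodes, edges) -> BlockCutTree:
    """Biconnected decomposition of one connected component."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    if g.number_of_edges() == 0:
        blocks = [frozenset([n]) for n in sorted(g.nodes)]
    else:
        blocks = [frozenset(b) for b in nx.biconnected_components(g)]
        covered = set().union(*blocks) if blocks else set()
        blocks += [frozenset([n]) for n in sorted(set(g.nodes) - covered)]
    blocks.sort(key=lambda b: sorted(b))
    arts = set(nx.articulation_points(g))
    adjacency = {a: [bi for bi, b in enumerate(blocks) if a in b] for a in arts}
    return BlockCutTree(blocks=blocks, articulation_points=arts,
                        adjacency=adjacency)


# ---------------------------------------------------------------------------
# Step 8: branch-and-bound over the block-cut tree
# ---------------------------------------------------------------------------

@dataclass
class PackingResult:
    assignment: dict
    energy: float
    components: list
    n_pruned_by_dee: int = 0


def _bnb_block(nodes, candidates, e_self, tables, context) -> tuple[dict, float]:
    """Exact minimum over a block by depth-first branch-and-bound.

    ``e_self[i][m]`` holds the (possibly augmented) self energy; ``context``
    maps already-fixed residues to their chosen candidate -- their pair
    energies with block nodes are charged here, their self energies are not.
    Ties break toward lexicographically smallest candidate choices because
    candidates are explored in index order and only strict improvements
    replace the incumbent.
    """
    order = sorted(nodes)
    ctx = sorted(context.items())

    # admissible per-node and per-pair lower bounds for the unassigned suffix
    suffix_node_min = {}
    for pos, v in enumerate(order):
        suffix_node_min[v] = min(
            e_self[v][m] + sum(tables.pair(v, m, u, cu) for u, cu in ctx)
            for m in candidates[v])
    pair_min = {}
    for a, b in itertools.combinations(order, 2):
        pair_min[(a, b)] = min(tables.pair(a, m, b, n)
                               for m in candidates[a] for n in candidates[b])

    best_energy = math.inf
    best_assign: dict = {}

    def bound_tail(pos):
        total = 0.0
        for q in range(pos, len(order)):
            total += suffix_node_min[order[q]]
            for r in range(q + 1, len(order)):
                total += pair_min[(order[q], order[r])]
        return total

    def descend(pos, acc, partial):
        nonlocal best_energy, best_assign
        if pos == len(order):
            if acc < best_energy:
                best_energy = acc
                best_assign = dict(partial)
            return
        if acc + bound_tail(pos) > best_energy:
            return
        v = order[pos]
        for m in candidates[v]:
            e = e_self[v][m]
            e += sum(tables.pair(v, m, u, cu) for u, cu in ctx)
            e += sum(tables.pair(v, m, u, cu) for u, cu in partial.items())
            partial[v] = m
            descend(pos + 1, acc + e, partial)
            del partial[v]

    descend(0, 0.0, {})
    return best_assign, best_energy


def _solve_component(comp_nodes, edges, candidates, tables) -> dict:
    """Optimal assignment for one connected component via block collapse."""
    work = set(comp_nodes)
    e_self = {i: {m: tables.e_fixed[(i, m)] for m in candidates[i]}
              for i in comp_nodes}
    collapse_log = []  # (articulation, {cand: partial assignment})

    while True:
        sub_edges = [(a, b) for a, b in edges if a in work and b in work]
        tree = block_cut_tree(sorted(work), sub_edges)
        if len(tree.blocks) <= 1:
            assign, _ = _bnb_block(sorted(work), candidates, e_self, tables, {})
            break
        leaf_idx = next(bi for bi in tree.leaf_blocks()
                        if len(tree.blocks[bi] & tree.articulation_points) == 1)
        block = tree.blocks[leaf_idx]
        art = next(iter(block & tree.articulation_points))
        others = sorted(block - {art})
        table = {}
        for c in candidates[art]:
            sub_assign, sub_e = _bnb_block(others, candidates, e_self, tables,
                                           {art: c})
            table[c] = (sub_assign, sub_e)
        for c, (_, sub_e) in table.items():
            e_self[art][c] += sub_e
        collapse_log.append((art, table))
        work -= set(others)

    for art, table in reversed(collapse_log):
        assign.update(table[assign[art]][0])
    return assign


def solve(candidates: dict, tables: EnergyTables,
          dee_max_rounds: int = 100) -> PackingResult:
    """Minimum-energy assignment over the full candidate space.

    Runs DEE, commits single-candidate residues (folding their pair energies
    into the remaining residues' self energies), decomposes the interaction
    graph, and solves each component exactly.  The reported energy is
    recomputed from the original tables over the final assignment.
    """
    surviving, dee_log = goldstein_prune(candidates, tables, dee_max_rounds)

    assignment = {}
    singles = {i: cands[0] for i, cands in surviving.items() if len(cands) == 1}
    assignment.update(singles)
    multi = {i: cands for i, cands in surviving.items() if len(cands) >= 2}

    # fold committed residues' pair energies into the remaining self energies
    folded = EnergyTables(e_fixed=dict(tables.e_fixed), e_pair=tables.e_pair,
                          cutoff=tables.cutoff)
    for i, cands in multi.items():
        for m in cands:
            extra = sum(tables.pair(i, m, j, c) for j, c in singles.items())
            if extra:
                folded.e_fixed[(i, m)] = folded.e_fixed[(i, m)] + extra

    components = []
    if multi:
        edges = positive_edges(multi, folded)
        components = connected_components(sorted(multi), edges)
        for comp in components:
            assignment.update(_solve_component(comp, edges, multi, folded))

    energy = total_energy(assignment, tables)
    return PackingResult(assignment=assignment, energy=energy,
                         components=components, n_pruned_by_dee=len(dee_log))


def total_energy(assignment: dict, tables: EnergyTables) -> float:
    """Energy of a complete assignment under the original tables."""
    total = sum(tables.e_fixed[(i, m)] for i, m in assignment.items())
    for i, j in itertools.combinations(sorted(assignment), 2):
        total += tables.pair(i, assignment[i], j, assignment[j])
    return total
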