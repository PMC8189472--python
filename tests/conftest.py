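"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's scoring code paths: tree
length and ancestral-state questions are answered by exhaustively enumerating
internal-node labelings, and topology questions by exhaustively enumerating
trees built from nested tuples.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import numpy as np
import pytest

from morphosig.matrix import MISSING, CharacterMatrix
from morphosig.trees import Tree


# ---------------------------------------------------------------------------
# random matrices
# ---------------------------------------------------------------------------


def random_matrix(
    rng: np.random.Generator,
    n_taxa: int,
    n_chars: int,
    n_states: int = 3,
    missing_frac: float = 0.0,
    poly_frac: float = 0.0,
) -> CharacterMatrix:
    taxa = [f"T{i}" for i in range(n_taxa)]
    rows = []
    for _ in range(n_taxa):
        row = []
        for _ in range(n_chars):
            r = rng.random()
            if r < missing_frac:
                row.append(MISSING)
            elif r < missing_frac + poly_frac and n_states >= 2:
                pair = rng.choice(n_states, size=2, replace=False)
                row.append(frozenset(int(x) for x in pair))
            else:
                row.append(frozenset({int(rng.integers(n_states))}))
        rows.append(row)
    return CharacterMatrix(taxa, rows)


# ---------------------------------------------------------------------------
# exhaustive topology enumeration (nested-tuple construction)
# ---------------------------------------------------------------------------


def _insertions(struct, leaf):
    yield (struct, leaf)
    if isinstance(struct, tuple):
        a, b = struct
        for ai in _insertions(a, leaf):
            yield (ai, b)
        for bi in _insertions(b, leaf):
            yield (a, bi)


def all_unrooted_topologies(names: list[str]):
    """Every unrooted binary topology, returned rooted at names[0]."""
    assert len(names) >= 3
    structs = [names[1]]
    for leaf in names[2:]:
        structs = [ins for s in structs for ins in _insertions(s, leaf)]
    return [Tree.from_nested((names[0], s)) for s in structs]


# ---------------------------------------------------------------------------
# brute-force labeling oracles
# ---------------------------------------------------------------------------


def _edge_cost(parent_state: int, cell: frozenset) -> int:
    if not cell:  # missing leaf: free
        return 0
    return 0 if parent_state in cell else 1


def oracle_char_length(tree: Tree, column: dict[str, frozenset], states) -> int:
    """Minimum changes for one character by enumerating all internal labelings."""
    internal = [n for n in tree.postorder() if tree.children.get(n)]
    best = None
    for combo in itertools.product(states, repeat=len(internal)):
        assign = dict(zip(internal, combo))
        cost = 0
        for n in tree.postorder():
            if n == tree.root:
                continue
            p_state = assign[tree.parent[n]]
            if tree.children.get(n):
                cost += p_state != assign[n]
            else:
                cost += _edge_cost(p_state, column[tree.labels[n]])
        if best is None or cost < best:
            best = cost
    return best


def sankoff_char_length(tree: Tree, column: dict[str, frozenset], states) -> int:
    """Unit-cost Sankoff dynamic program (test-local, list-based)."""
    big = 10**6
    cost: dict[int, list[int]] = {}
    for n in tree.postorder():
        kids = tree.children.get(n, ())
        if not kids:
            cell = column[tree.labels[n]]
            cost[n] = [0 if (not cell or s in cell) else big for s in states]
        else:
            vec = [0] * len(states)
            for c in kids:
                child = cost[c]
                floor = min(child) + 1
                vec = [
                    vec[i] + min(child[i], floor) for i in range(len(states))
                ]
            cost[n] = vec
    return min(cost[tree.root])


def sankoff_matrix_length(tree: Tree, matrix: CharacterMatrix) -> int:
    total = 0
    for cid in matrix.char_ids:
        column = {t: matrix.cell(t, cid) for t in matrix.taxa if t in tree.leaf_names}
        states = sorted(set().union(*column.values()) or {0})
        total += sankoff_char_length(tree, column, states)
    return total


def oracle_matrix_length(tree: Tree, matrix: CharacterMatrix) -> int:
    total = 0
    for cid in matrix.char_ids:
        column = {t: matrix.cell(t, cid) for t in matrix.taxa if t in tree.leaf_names}
        states = sorted(set().union(*[c for c in column.values()]) or {0})
        total += oracle_char_length(tree, column, states)
    return total


def oracle_mpr_sets(tree: Tree, column: dict[str, frozenset], states):
    """States each internal node takes in some optimal labeling."""
    internal = [n for n in tree.postorder() if tree.children.get(n)]
    costs = []
    for combo in itertools.product(states, repeat=len(internal)):
        assign = dict(zip(internal, combo))
        cost = 0
        for n in tree.postorder():
            if n == tree.root:
                continue
            p_state = assign[tree.parent[n]]
            if tree.children.get(n):
                cost += p_state != assign[n]
            else:
                cost += _edge_cost(p_state, column[tree.labels[n]])
        costs.append((cost, assign))
    best = min(c for c, _ in costs)
    sets: dict[int, set] = {n: set() for n in internal}
    for c, assign in costs:
        if c == best:
            for n, s in assign.items():
                sets[n].add(s)
    return {n: frozenset(s) for n, s in sets.items()}, best


def oracle_stem_changes(tree: Tree, column, states, node: int):
    """(always_changes_to, sometimes_changes_to) for the branch above ``node``
    by enumerating optimal labelings; leaves are assigned explicitly too."""
    internal = [n for n in tree.postorder() if tree.children.get(n)]
    leaves = [n for n in tree.postorder() if not tree.children.get(n)]
    best = None
    optima = []
    for combo in itertools.product(states, repeat=len(internal) + len(leaves)):
        assign = dict(zip(internal + leaves, combo))
        cost = 0
        ok = True
        for n in leaves:
            cell = column[tree.labels[n]]
            if cell and assign[n] not in cell:
                ok = False
                break
        if not ok:
            continue
        for n in tree.postorder():
            if n == tree.root:
                continue
            cost += assign[tree.parent[n]] != assign[n]
        if best is None or cost < best:
            best, optima = cost, [assign]
        elif cost == best:
            optima.append(assign)
    parent = tree.parent[node]
    derived = [
        (a[node] if a[parent] != a[node] else None) for a in optima
    ]
    sometimes = {d for d in derived if d is not None}
    always = derived[0] if all(d == derived[0] and d is not None for d in derived) else None
    return always, sometimes, best


# ---------------------------------------------------------------------------
# shared fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def tiny_matrix():
    """4 taxa x 3 binary characters with one homoplastic character."""
    return CharacterMatrix(
        ["A", "B", "C", "D"],
        [
            [frozenset({0}), frozenset({0}), frozenset({0})],
            [frozenset({0}), frozenset({1}), frozenset({1})],
            [frozenset({1}), frozenset({1}), frozenset({1})],
            [frozenset({1}), frozenset({0}), frozenset({1})],
        ],
    )
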