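"""Fitch parsimony for unordered, equally weighted discrete characters.

State sets are packed as uint8 bitmasks (states 0..7), so a whole matrix is
scored on a tree with a handful of vectorised set operations per internal
node.  Missing cells are initialised to the character's full observed
alphabet, which is equivalent to ignoring them for unordered parsimony.

Besides tree length the module provides the classical per-character bounds:
``min_steps`` (m_i, the fewest steps on any tree) and ``max_steps`` (g_i, the
most steps any tree can force), and the ensemble consistency index
CI = sum(m_i)/S and retention index RI = (sum(g_i) - S)/(sum(g_i) - sum(m_i)).

A unit-cost dynamic program (`state_cost_vectors`, `constrained_length`)
complements the bitmask pass; it supports forced node states and is the basis
of exact most-parsimonious-reconstruction queries in the synapomorphy mapper.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .matrix import MISSING, CharacterMatrix
from .trees import Tree

MAX_STATES = 8
INF = 10**6


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------


def encode_matrix(matrix: CharacterMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Pack a matrix into (n_taxa, n_chars) uint8 bitmasks.

    Missing cells receive the character's observed alphabet mask (or the
    dummy state 0 for characters with no observations, which then contribute
    zero steps everywhere).
    """
    n_t, n_c = matrix.n_taxa, matrix.n_chars
    data = np.zeros((n_t, n_c), dtype=np.uint8)
    alph = np.zeros(n_c, dtype=np.uint8)
    for j in range(n_c):
        mask = 0
        for cell in matrix.column(j + 1):
            for s in cell:
                if s >= MAX_STATES:
                    raise ValueError(
                        f"character {j + 1}: state {s} exceeds supported maximum "
                        f"{MAX_STATES - 1}"
                    )
                mask |= 1 << s
        alph[j] = mask if mask else 1
    for i in range(n_t):
        for j, cell in enumerate(matrix.rows[i]):
            m = 0
            for s in cell:
                m |= 1 << s
            data[i, j] = m if m else alph[j]
    return data, alph


def _mask_to_set(mask: int) -> frozenset:
    return frozenset(s for s in range(MAX_STATES) if mask >> s & 1)


# ---------------------------------------------------------------------------
# tree length
# ---------------------------------------------------------------------------


def _tree_arrays(tree: Tree, matrix: CharacterMatrix):
    """Map a binary rooted Tree to postorder (node, left, right) index triples.

    Leaf slots are matrix row indices; internal nodes follow.  Returns
    (triples, index_of_node, n_slots).
    """
    if not tree.is_binary():
        raise ValueError("parsimony scoring requires a binary tree")
    missing = tree.leaf_names - set(matrix.taxa)
    if missing:
        raise KeyError(f"leaves absent from matrix: {sorted(missing)}")
    idx: dict[int, int] = {}
    nxt = [matrix.n_taxa]
    triples: list[tuple[int, int, int]] = []
    for n in tree.postorder():
        kids = tree.children.get(n, ())
        if not kids:
            idx[n] = matrix.row_index(tree.labels[n])
        else:
            idx[n] = nxt[0]
            nxt[0] += 1
            triples.append((idx[n], idx[kids[0]], idx[kids[1]]))
    return triples, idx, nxt[0]


def fitch_per_char_steps(tree: Tree, matrix: CharacterMatrix) -> np.ndarray:
    """Exact minimum changes per character on a fixed binary topology."""
    data, _ = encode_matrix(matrix)
    triples, _, n_slots = _tree_arrays(tree, matrix)
    sets = np.zeros((n_slots, matrix.n_chars), dtype=np.uint8)
    sets[: matrix.n_taxa] = data
    steps = np.zeros(matrix.n_chars, dtype=np.int64)
    for node, left, right in triples:
        inter = sets[left] & sets[right]
        empty = inter == 0
        sets[node] = np.where(empty, sets[left] | sets[right], inter)
        steps += empty
    return steps


@dataclass
class ParsimonyScores:
    """Tree length with per-character step decomposition and ensemble indices."""

    total_steps: int
    per_char_steps: np.ndarray
    min_steps: np.ndarray
    max_steps: np.ndarray

    @property
    def ci(self) -> float | None:
        return float(self.min_steps.sum() / self.total_steps) if self.total_steps else None

    @property
    def ri(self) -> float | None:
        g, m, s = self.max_steps.sum(), self.min_steps.sum(), self.total_steps
        if g == m:
            return None
        return float((g - s) / (g - m))


def fitch_length(tree: Tree, matrix: CharacterMatrix) -> ParsimonyScores:
    """Score a tree: total and per-character steps plus the m_i/g_i bounds."""
    steps = fitch_per_char_steps(tree, matrix)
    m = np.array([min_steps(matrix, c) for c in matrix.char_ids])
    g = np.array([max_steps(matrix, c) for c in matrix.char_ids])
    return ParsimonyScores(int(steps.sum()), steps, m, g)


# ---------------------------------------------------------------------------
# per-character bounds
# ---------------------------------------------------------------------------


def min_steps(matrix: CharacterMatrix, char_id: int) -> int:
    """Fewest steps on any topology: smallest state set hitting every scored
    cell, minus one (polymorphisms resolved favourably)."""
    cells = [c for c in matrix.column(char_id) if c is not MISSING and c]
    if not cells:
        return 0
    alphabet = sorted(set().union(*cells))
    for k in range(1, len(alphabet) + 1):
        for combo in combinations(alphabet, k):
            chosen = set(combo)
            if all(cell & chosen for cell in cells):
                return k - 1
    raise AssertionError("unreachable")


def max_steps(matrix: CharacterMatrix, char_id: int) -> int:
    """Most steps any topology can force: scored taxa minus the best
    achievable frequency of a single state (polymorphisms resolved
    favourably)."""
    cells = [c for c in matrix.column(char_id) if c]
    if not cells:
        return 0
    alphabet = set().union(*cells)
    best = max(sum(1 for cell in cells if s in cell) for s in alphabet)
    return len(cells) - best


def ensemble_indices(
    trees: Sequence[Tree],
    matrix: CharacterMatrix,
    include_uninformative: bool = True,
) -> tuple[float | None, float | None]:
    """Ensemble (CI, RI) over a set of equally parsimonious trees.

    All trees must score the same length.  With
    ``include_uninformative=False`` characters with g_i == m_i are dropped
    from the sums (the alternative convention some programs use).
    """
    if not trees:
        raise ValueError("at least one tree required")
    lengths = [fitch_per_char_steps(t, matrix) for t in trees]
    totals = {int(l.sum()) for l in lengths}
    if len(totals) > 1:
        raise ValueError(f"trees are not equally parsimonious: lengths {sorted(totals)}")
    steps = lengths[0]
    m = np.array([min_steps(matrix, c) for c in matrix.char_ids])
    g = np.array([max_steps(matrix, c) for c in matrix.char_ids])
    if not include_uninformative:
        keep = g > m
        steps, m, g = steps[keep], m[keep], g[keep]
    s = int(steps.sum())
    ci = float(m.sum() / s) if s else None
    ri = float((g.sum() - s) / (g.sum() - m.sum())) if g.sum() > m.sum() else None
    return ci, ri


# ---------------------------------------------------------------------------
# unit-cost dynamic program (supports forced node states)
# ---------------------------------------------------------------------------


def _leaf_cost(cell: frozenset, alphabet: Sequence[int]) -> list[int]:
    if not cell:
        return [0] * len(alphabet)
    return [0 if s in cell else INF for s in alphabet]


def state_cost_vectors(
    tree: Tree,
    matrix: CharacterMatrix,
    char_id: int,
    constraints: Mapping[int, int] | None = None,
):
    """Subtree ("down") and rest-of-tree ("up") unit-cost vectors per node.

    ``down[v][s]`` is the minimum number of changes within the subtree at v
    given that v is in state s; ``up[v][s]`` the minimum in the remainder of
    the tree.  ``constraints`` forces nodes to given states.  Returns
    ``(alphabet, down, up, L)`` where L is the (constrained) tree length.
    Polymorphic leaves are satisfied by any member state; missing leaves by
    any state.
    """
    alphabet = sorted(matrix.state_alphabet(char_id)) or [0]
    k = len(alphabet)
    state_pos = {s: i for i, s in enumerate(alphabet)}
    cons = constraints or {}

    def clamp(node: int, vec: list[int]) -> list[int]:
        if node in cons:
            s = cons[node]
            if s not in state_pos:
                return [INF] * k
            return [vec[i] if i == state_pos[s] else INF for i in range(k)]
        return vec

    down: dict[int, list[int]] = {}
    for n in tree.postorder():
        kids = tree.children.get(n, ())
        if not kids:
            vec = _leaf_cost(matrix.cell(tree.labels[n], char_id), alphabet)
        else:
            vec = [0] * k
            for c in kids:
                dc = down[c]
                floor = min(dc) + 1
                vec = [vec[i] + min(dc[i], floor) for i in range(k)]
        down[n] = clamp(n, vec)

    # rest[v][t]: cost of the whole tree minus subtree(v), given parent(v)=t.
    # up[v][s] = min_t rest[v][t] + w(t, s).
    up: dict[int, list[int]] = {tree.root: [0] * k}
    rest: dict[int, list[int]] = {}
    for n in tree.preorder():
        kids = tree.children.get(n, ())
        for v in kids:
            vec = list(up[n])
            for sib in kids:
                if sib is v:
                    continue
                ds = down[sib]
                floor = min(ds) + 1
                vec = [vec[i] + min(ds[i], floor) for i in range(k)]
            vec = clamp(n, vec)
            rest[v] = vec
            floor = min(vec) + 1
            up[v] = [min(vec[i], floor) for i in range(k)]

    length = min(down[tree.root])
    return alphabet, down, up, rest, length


def constrained_length(
    tree: Tree,
    matrix: CharacterMatrix,
    char_id: int,
    constraints: Mapping[int, int] | None = None,
) -> int:
    """Minimum changes for one character given forced node states.

    Returns a value >= :data:`INF` when the constraints are unsatisfiable
    (e.g. a state outside the character's alphabet forced on a scored leaf).
    """
    _, down, _, _, length = state_cost_vectors(tree, matrix, char_id, constraints)
    return length
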