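"""Ancestral state sets and unambiguous synapomorphies on parsimonious trees.

All quantities are computed exactly from unit-cost subtree/rest-of-tree cost
vectors (no sampling of reconstructions): a node's MPR set is the states that
appear at that node in at least one most-parsimonious reconstruction, and a
change to a derived state on a branch is *unambiguous* when every MPR of every
supplied tree places it there — equivalently, the child's MPR set is the
single derived state and the parent's MPR set excludes it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .fitch import state_cost_vectors
from .matrix import CharacterMatrix
from .trees import Tree

_INF_GUARD = 10**5


@dataclass(frozen=True)
class SynapomorphyRecord:
    """A state change assigned to a clade's stem branch."""

    clade: frozenset
    char_id: int
    derived_state: int
    status: str  # "unambiguous" | "ambiguous"
    n_trees_supporting: int

    def notation(self) -> str:
        """The conventional C<char>^<state> rendering."""
        return f"C{self.char_id}^{self.derived_state}"


def mpr_state_sets(
    tree: Tree, matrix: CharacterMatrix, char_id: int
) -> dict[int, frozenset]:
    """Per-node set of states attainable in some most-parsimonious
    reconstruction.  Leaves keep their observed sets (missing = full
    alphabet)."""
    alphabet, down, up, _, L = state_cost_vectors(tree, matrix, char_id)
    alph_set = frozenset(alphabet)
    out: dict[int, frozenset] = {}
    for n in tree.postorder():
        if not tree.children.get(n):
            cell = matrix.cell(tree.labels[n], char_id)
            out[n] = cell if cell else alph_set
        else:
            out[n] = frozenset(
                s
                for i, s in enumerate(alphabet)
                if down[n][i] + up[n][i] == L
            )
    return out


def _stem_changes(
    tree: Tree, matrix: CharacterMatrix, char_id: int, node: int
) -> tuple[int | None, set[int]]:
    """States gained on the branch above ``node``.

    Returns ``(unambiguous_state, possible_states)``: ``possible_states`` are
    derived states s for which some MPR places a change to s on the branch;
    ``unambiguous_state`` is set when every MPR does.
    """
    parent = tree.parent.get(node)
    if parent is None:
        return None, set()
    alphabet, down, up, rest, L = state_cost_vectors(tree, matrix, char_id)
    if L == 0 or L >= _INF_GUARD:
        return None, set()
    k = len(alphabet)
    mpr_child = [i for i in range(k) if down[node][i] + up[node][i] == L]

    # far[t]: optimal cost of everything on the far side of this branch given
    # the far endpoint is in state t.  A binary root is only a midpoint of the
    # outgroup edge, so for a root child the far endpoint is the sibling node
    # itself (the two root branches are one unrooted edge; a change must not
    # be called ambiguous just because it could sit on the edge's other half).
    root_kids = tree.children.get(tree.root, ())
    if parent == tree.root and len(root_kids) == 2:
        sib = root_kids[0] if root_kids[1] == node else root_kids[1]
        far = down[sib]
    else:
        far = rest[node]

    possible: set[int] = set()
    for i in mpr_child:
        # some MPR with child=s, far side=t != s: far[t] + 1 + down[s] == L
        for j in range(k):
            if j != i and far[j] + 1 + down[node][i] == L:
                possible.add(alphabet[i])
                break
    unamb = None
    if len(mpr_child) == 1:
        i = mpr_child[0]
        s = alphabet[i]
        no_change_possible = far[i] + down[node][i] == L
        if s in possible and not no_change_possible:
            unamb = s
    return unamb, possible


def stem_changes(
    tree: Tree, matrix: CharacterMatrix, clade: Iterable[str]
) -> tuple[dict[int, int], dict[int, set[int]]]:
    """(unambiguous, possible) changes on the stem branch of ``clade`` in one
    tree, keyed by character id."""
    want = frozenset(clade)
    sets = tree.clade_leafsets()
    node = next((n for n, s in sets.items() if s == want), None)
    if node is None:
        raise KeyError(f"clade not present in tree: {sorted(want)}")
    unambiguous: dict[int, int] = {}
    possible: dict[int, set[int]] = {}
    for cid in matrix.char_ids:
        u, p = _stem_changes(tree, matrix, cid, node)
        if u is not None:
            unambiguous[cid] = u
        if p:
            possible[cid] = p
    return unambiguous, possible


def unambiguous_synapomorphies(
    trees: Iterable[Tree],
    matrix: CharacterMatrix,
    clade: Iterable[str],
) -> list[SynapomorphyRecord]:
    """Character changes on a clade's stem branch across a set of MPTs.

    A record is *unambiguous* when the change to its derived state occurs
    under every most-parsimonious reconstruction of every tree that contains
    the clade; changes occurring in some but not all reconstructions are
    *ambiguous*.  Trees lacking the clade are tolerated (the consensus node
    may not resolve in every MPT) but at least one tree must contain it.
    Records are ordered by character id.
    """
    want = frozenset(clade)
    tree_list = list(trees)
    with_clade = [t for t in tree_list if want in t.clades(include_trivial=True)]
    if not with_clade:
        raise KeyError(f"clade absent from all supplied trees: {sorted(want)}")

    per_tree = [stem_changes(t, matrix, want) for t in with_clade]
    unamb_sets = [
        {(cid, s) for cid, s in u.items()} for u, _ in per_tree
    ]
    possible_sets = [
        {(cid, s) for cid, states in p.items() for s in states}
        for _, p in per_tree
    ]
    always = set.intersection(*unamb_sets) if unamb_sets else set()
    sometimes = set.union(*possible_sets) if possible_sets else set()

    records = []
    for cid, s in sorted(always):
        n_sup = sum(1 for u in unamb_sets if (cid, s) in u)
        records.append(SynapomorphyRecord(want, cid, s, "unambiguous", n_sup))
    for cid, s in sorted(sometimes - always):
        n_sup = sum(1 for u in unamb_sets if (cid, s) in u)
        records.append(SynapomorphyRecord(want, cid, s, "ambiguous", n_sup))
    records.sort(key=lambda r: (r.char_id, r.derived_state))
    return records


def synapomorphy_report(
    trees: Iterable[Tree],
    matrix: CharacterMatrix,
    named_clades: dict[str, Iterable[str]],
) -> str:
    """Text report in the C<id>^<state> notation, grouped by node."""
    lines = []
    for name, clade in named_clades.items():
        try:
            recs = unambiguous_synapomorphies(trees, matrix, clade)
        except KeyError:
            lines.append(f"{name}: clade not recovered")
            continue
        unamb = [r.notation() for r in recs if r.status == "unambiguous"]
        amb = [r.notation() for r in recs if r.status == "ambiguous"]
        lines.append(f"{name}: " + (", ".join(unamb) if unamb else "(none)"))
        if amb:
            lines.append(f"{name} (ambiguous): " + ", ".join(amb))
    return "\n".join(lines)
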