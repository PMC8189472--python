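"""Heuristic maximum-parsimony tree search.

Random-addition-sequence starting trees followed by branch swapping
(TBR/SPR/NNI), holding up to k equally parsimonious trees per replicate and
pooling deduplicated best trees across replicates.

The engine works on unrooted trees kept as adjacency maps with leaves indexed
by matrix row.  Scoring uses the edge-rooted Fitch decomposition: for a
fragment F and an edge e of F, ``set(e)`` is the Fitch root set obtained by
rooting F on e, and joining fragments F1 (on edge e1) and F2 (on edge e2)
costs ``L(F1) + L(F2) + #{characters with set(e1) and set(e2) disjoint}``.
This makes the cost of every reconnection of a bisected tree (and of every
placement of the next taxon during stepwise addition) a single vectorised
comparison, instead of a full-matrix rescore per neighbour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fitch import encode_matrix, state_cost_vectors
from .matrix import CharacterMatrix
from .trees import Tree

logger = logging.getLogger(__name__)

Adjacency = dict  # node id -> list of neighbour ids


@dataclass
class SearchConfig:
    """Search effort and reproducibility settings.

    The defaults are a desk-scale profile (50 random-addition replicates with
    early stopping); the published protocol of 1000 replicates holding 10
    trees is obtained with ``n_replicates=1000, early_stop_after=None``.
    """

    n_replicates: int = 50
    hold_per_replicate: int = 10
    swap: str = "tbr"  # one of {"nni", "spr", "tbr"}
    seed: int = 0
    max_pool: int = 500
    collapse_rule: str = "min"  # "min" (TNT rule-1-like) or "none"
    early_stop_after: int | None = 20

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.hold_per_replicate < 1:
            raise ValueError("n_replicates and hold_per_replicate must be >= 1")
        if self.swap not in {"nni", "spr", "tbr"}:
            raise ValueError(f"unknown swap mode {self.swap!r}")


@dataclass
class TreeSet:
    """Equally parsimonious trees found by a search.

    ``trees`` are binary most-parsimonious trees; ``collapsed`` (when the
    search used a collapse rule) are the same trees after contracting
    zero-minimum-length branches and deduplicating, which is what consensus
    and support calculations should summarise.
    """

    trees: list[Tree]
    best_length: int
    n_found: int
    replicate_log: list = field(default_factory=list)
    collapsed: list | None = None

    def consensus_input(self) -> list[Tree]:
        return self.collapsed if self.collapsed else self.trees

    def __iter__(self):
        return iter(self.trees)

    def __len__(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


class ParsimonyEngine:
    """Vectorised Fitch machinery over one encoded matrix."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        self.enc, self.alph = encode_matrix(matrix)
        self.n_taxa = matrix.n_taxa
        self.n_chars = matrix.n_chars

    # -- scoring ------------------------------------------------------------
    def _orient(self, adj: Adjacency, root: int):
        """(postorder nodes, parent map) for ``adj`` hung from ``root``."""
        parent = {root: -1}
        order = [root]
        stack = [root]
        while stack:
            n = stack.pop()
            for nb in adj[n]:
                if nb != parent[n]:
                    parent[nb] = n
                    order.append(nb)
                    stack.append(nb)
        order.reverse()
        return order, parent

    def length(self, adj: Adjacency) -> int:
        """Fitch length of an unrooted tree (leaves = matrix row indices)."""
        leaves = [n for n in adj if n < self.n_taxa]
        if len(leaves) == 1:
            return 0
        root = leaves[0]
        order, parent = self._orient(adj, root)
        down: dict[int, np.ndarray] = {}
        steps = 0
        for n in order:
            kids = [nb for nb in adj[n] if nb != parent[n]]
            vals = [down[k] for k in kids]
            if n < self.n_taxa:
                vals.append(self.enc[n])
            cur = vals[0]
            for v in vals[1:]:
                inter = cur & v
                empty = inter == 0
                steps += int(np.count_nonzero(empty))
                cur = np.where(empty, cur | v, inter)
            down[n] = cur
        return steps

    def edge_sets(self, adj: Adjacency, virtual_at: int | None = None):
        """Fitch root set for every edge rooting of the tree.

        Returns ``(edges, sets, length, virtual_index)``: edges as (parent,
        child) pairs keyed on an arbitrary internal orientation, ``sets`` the
        matching (n_edges, n_chars) uint8 array, and the tree length.  With
        ``virtual_at`` = a suppressed node id, ``virtual_index`` points at the
        edge that replaced it (used by SPR to pin a pruned fragment's root).
        """
        leaves = [n for n in adj if n < self.n_taxa]
        if len(leaves) == 1:
            only = leaves[0]
            return [(-1, only)], self.enc[only : only + 1], 0, 0
        root = leaves[0]
        order, parent = self._orient(adj, root)
        down: dict[int, np.ndarray] = {}
        steps = 0
        for n in order:
            kids = [nb for nb in adj[n] if nb != parent[n]]
            vals = [down[k] for k in kids]
            if n < self.n_taxa:
                vals.append(self.enc[n])
            cur = vals[0]
            for v in vals[1:]:
                inter = cur & v
                empty = inter == 0
                steps += int(np.count_nonzero(empty))
                cur = np.where(empty, cur | v, inter)
            down[n] = cur

        def combine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            inter = a & b
            return np.where(inter == 0, a | b, inter)

        rest: dict[int, np.ndarray] = {}
        edges: list[tuple[int, int]] = []
        sets: list[np.ndarray] = []
        virtual_index = None
        for n in reversed(order):  # preorder
            kids = [nb for nb in adj[n] if nb != parent[n]]
            for v in kids:
                r = rest[n] if n != root else self.enc[root]
                for sib in kids:
                    if sib != v:
                        r = combine(r, down[sib])
                if n != root and n < self.n_taxa:
                    r = combine(r, self.enc[n])
                rest[v] = r
                edges.append((n, v))
                sets.append(combine(down[v], r))
        # note: every non-root node contributes its parent edge; 2T-3 total
        if virtual_at is not None:
            # the edge joining the suppressed node's former neighbours
            for i, (p, c) in enumerate(edges):
                if {p, c} == virtual_at:
                    virtual_index = i
                    break
        return edges, np.array(sets), steps, virtual_index

    # -- neighbourhood scan ---------------------------------------------------
    def neighborhood(self, adj: Adjacency, bound: int, mode: str = "tbr"):
        """All branch-swap moves with resulting length <= ``bound``.

        Returns ``(best_score, moves)`` where each move is
        ``(score, cut_edge, edge_in_rest, edge_in_pruned)``; edges are frozensets
        of node ids, with ``None`` for a single-leaf fragment or an SPR-pinned
        root.  ``best_score`` is the minimum over the full neighbourhood even
        when above ``bound``.
        """
        moves: list[tuple[int, frozenset, frozenset | None, frozenset | None]] = []
        best = np.iinfo(np.int64).max
        seen_cuts = set()
        for a in list(adj):
            for b in adj[a]:
                cut = frozenset((a, b))
                if cut in seen_cuts:
                    continue
                seen_cuts.add(cut)
                sideA = self._split_fragment(adj, a, b)
                sideB = self._split_fragment(adj, b, a)
                eA, sA, lA, vA = self.edge_sets(*sideA)
                eB, sB, lB, vB = self.edge_sets(*sideB)
                if mode == "spr":
                    variants = []
                    if vB is not None or len(eB) == 1:
                        iB = vB if vB is not None else 0
                        variants.append((eA, sA, [eB[iB]], sB[iB : iB + 1]))
                    if vA is not None or len(eA) == 1:
                        iA = vA if vA is not None else 0
                        variants.append(([eA[iA]], sA[iA : iA + 1], eB, sB))
                elif mode == "nni" and vA is not None and vB is not None:
                    adjA = [i for i, (p, c) in enumerate(eA) if sideA[1] and ({p, c} & sideA[1])]
                    adjB = [i for i, (p, c) in enumerate(eB) if sideB[1] and ({p, c} & sideB[1])]
                    variants = [
                        (
                            [eA[i] for i in adjA],
                            sA[adjA],
                            [eB[j] for j in adjB],
                            sB[adjB],
                        )
                    ]
                elif mode == "nni":
                    variants = []
                else:  # tbr
                    variants = [(eA, sA, eB, sB)]
                base = lA + lB
                for edA, setsA, edB, setsB in variants:
                    if len(edA) == 0 or len(edB) == 0:
                        continue
                    disjoint = (
                        (setsA[:, None, :] & setsB[None, :, :]) == 0
                    ).sum(axis=2)
                    scores = base + disjoint
                    local_min = int(scores.min())
                    if local_min < best:
                        best = local_min
                    hits = np.argwhere(scores <= bound)
                    for i, j in hits:
                        moves.append(
                            (
                                int(scores[i, j]),
                                cut,
                                frozenset(edA[i]) if edA[i][0] != -1 else None,
                                frozenset(edB[j]) if edB[j][0] != -1 else None,
                            )
                        )
        return best, moves

    def _split_fragment(self, adj: Adjacency, start: int, banned: int):
        """Fragment adjacency on ``start``'s side of edge (start, banned).

        The cut endpoint is suppressed if it becomes degree-2.  Returns
        (fragment_adj, virtual_pair_or_None) suitable for :meth:`edge_sets`.
        """
        frag: Adjacency = {}
        stack = [start]
        seen = {start}
        while stack:
            n = stack.pop()
            nbs = [nb for nb in adj[n] if not (n == start and nb == banned)]
            frag[n] = nbs
            for nb in nbs:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        virtual = None
        if len(frag[start]) == 2:  # suppress the old junction
            u, v = frag[start]
            frag[u] = [x if x != start else v for x in frag[u]]
            frag[v] = [x if x != start else u for x in frag[v]]
            del frag[start]
            virtual = frozenset((u, v))
        return frag, virtual

    # -- applying a move -------------------------------------------------------
    def apply_move(
        self,
        adj: Adjacency,
        cut: frozenset,
        edge_rest: frozenset | None,
        edge_pruned: frozenset | None,
    ) -> Adjacency:
        """Reconnect the two fragments of a bisection at the chosen edges."""
        a, b = tuple(cut)
        fragA, _ = self._split_fragment(adj, a, b)
        fragB, _ = self._split_fragment(adj, b, a)
        free = sorted(set(adj) - set(fragA) - set(fragB))  # suppressed junctions
        new: Adjacency = {n: list(nbs) for frag in (fragA, fragB) for n, nbs in frag.items()}

        # match each reconnection edge to the fragment that contains it (the
        # cut is an unordered pair, so fragA/fragB order is arbitrary)
        def side(edge: frozenset | None) -> int | None:
            if edge is None:
                return None
            return 0 if next(iter(edge)) in fragA else 1

        sa, sb = side(edge_rest), side(edge_pruned)
        if sa is None and sb is None:
            sa, sb = (0, 1) if len(fragA) == 1 else (1, 0)
        elif sa is None:
            sa = 1 - sb
        elif sb is None:
            sb = 1 - sa
        if sa == sb:
            raise ValueError("reconnection edges lie in the same fragment")
        frags = (fragA, fragB)

        def junction(frag: Adjacency, edge: frozenset | None) -> int:
            if edge is None:  # single-leaf fragment: connect the leaf itself
                (leaf,) = frag
                return leaf
            u, v = tuple(edge)
            p = free.pop()
            new[u] = [x if x != v else p for x in new[u]]
            new[v] = [x if x != u else p for x in new[v]]
            new[p] = [u, v]
            return p

        ja = junction(frags[sa], edge_rest)
        jb = junction(frags[sb], edge_pruned)
        new[ja].append(jb)
        new[jb].append(ja)
        return new

    # -- stepwise addition -----------------------------------------------------
    def addition_tree(self, order: Sequence[int]) -> Adjacency:
        """Stepwise addition in the given taxon-row order, each taxon at the
        attachment of minimum incremental Fitch length (ties: first edge in
        deterministic enumeration order)."""
        if len(order) < 3:
            raise ValueError("stepwise addition requires at least 3 taxa")
        hub = 2 * self.n_taxa  # temporary star centre for the first triple
        a, b, c = order[:3]
        adj: Adjacency = {a: [hub], b: [hub], c: [hub], hub: [a, b, c]}
        next_internal = self.n_taxa
        for x in order[3:]:
            edges, sets, _, _ = self.edge_sets(adj)
            delta = ((sets & self.enc[x]) == 0).sum(axis=1)
            best = int(delta.argmin())
            u, v = edges[best]
            p = next_internal
            next_internal += 1
            adj[u] = [y if y != v else p for y in adj[u]]
            adj[v] = [y if y != u else p for y in adj[v]]
            adj[p] = [u, v, x]
            adj[x] = [p]
        # binarise the starting star hub
        if len(adj[hub]) == 3:
            u, v, w = adj[hub]
            # hub is already a proper internal node; just renumber it
            p = next_internal
            next_internal += 1
            for y in (u, v, w):
                adj[y] = [z if z != hub else p for z in adj[y]]
            adj[p] = [u, v, w]
            del adj[hub]
        return adj

    # -- hill climbing -----------------------------------------------------------
    def swap_to_optimum(
        self, adj: Adjacency, hold: int, mode: str = "tbr"
    ) -> tuple[int, list[Adjacency]]:
        """Branch swapping with steepest descent, then collect up to ``hold``
        equally best trees by plateau exploration."""
        cur = self.length(adj)
        while True:
            best, moves = self.neighborhood(adj, bound=cur - 1, mode=mode)
            if best < cur:
                move = next(m for m in moves if m[0] == best)
                adj = self.apply_move(adj, move[1], move[2], move[3])
                cur = best
            else:
                break
        pool: dict[frozenset, Adjacency] = {self.topology_key(adj): adj}
        frontier = [adj]
        while frontier and len(pool) < hold:
            t = frontier.pop(0)
            best, moves = self.neighborhood(t, bound=cur, mode=mode)
            if best < cur:  # plateau walking found an improvement
                move = next(m for m in moves if m[0] == best)
                adj = self.apply_move(t, move[1], move[2], move[3])
                return self.swap_to_optimum(adj, hold, mode)
            for score, cutE, eR, eP in moves:
                if len(pool) >= hold:
                    break
                cand = self.apply_move(t, cutE, eR, eP)
                key = self.topology_key(cand)
                if key not in pool:
                    pool[key] = cand
                    frontier.append(cand)
        return cur, list(pool.values())

    # -- identity / conversion -----------------------------------------------
    def topology_key(self, adj: Adjacency) -> frozenset:
        """Canonical unrooted-topology key: frozenset of nontrivial splits,
        each as the leaf-index side not containing leaf 0 of the tree."""
        leaves = sorted(n for n in adj if n < self.n_taxa)
        ref = leaves[0]
        order, parent = self._orient(adj, ref)
        below: dict[int, frozenset] = {}
        splits = set()
        for n in order:
            kids = [nb for nb in adj[n] if nb != parent[n]]
            s = frozenset([n]) if n < self.n_taxa and n != ref else frozenset()
            for k in kids:
                s |= below[k]
            below[n] = s
            if 2 <= len(s) <= len(leaves) - 2:
                splits.add(s)
        return frozenset(splits)

    def to_tree(self, adj: Adjacency, outgroup_row: int) -> Tree:
        """Root an unrooted adjacency on the outgroup's terminal edge."""
        root_id = max(adj) + 1
        (nbr,) = [n for n in adj[outgroup_row]]
        children: dict[int, list[int]] = {root_id: [outgroup_row, nbr]}
        labels = {}
        stack = [(outgroup_row, root_id), (nbr, root_id)]
        parent = {outgroup_row: root_id, nbr: root_id}
        while stack:
            n, p = stack.pop()
            if n == outgroup_row:
                kids = []
            else:
                kids = [x for x in adj[n] if x != p and not (n == nbr and x == outgroup_row)]
            children[n] = kids
            if not kids:
                labels[n] = self.matrix.taxa[n]
            for k in kids:
                parent[k] = n
                stack.append((k, n))
        return Tree(children, labels, root_id)

    def from_tree(self, tree: Tree) -> Adjacency:
        """Unrooted adjacency (leaves renumbered to matrix rows) from a Tree."""
        mapping: dict[int, int] = {}
        nxt = [self.n_taxa]
        adj: Adjacency = {}

        def nid(n: int) -> int:
            if n not in mapping:
                if tree.children.get(n):
                    mapping[n] = nxt[0]
                    nxt[0] += 1
                else:
                    mapping[n] = self.matrix.row_index(tree.labels[n])
                adj[mapping[n]] = []
            return mapping[n]

        for n in tree.postorder():
            for c in tree.children.get(n, ()):
                adj[nid(n)].append(nid(c))
                adj[nid(c)].append(nid(n))
        # suppress a degree-2 root
        r = mapping[tree.root]
        if len(adj[r]) == 2:
            u, v = adj[r]
            adj[u] = [x if x != r else v for x in adj[u]]
            adj[v] = [x if x != r else u for x in adj[v]]
            del adj[r]
        return adj


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def random_addition_tree(
    matrix: CharacterMatrix, order_seed: int, outgroup: str | None = None
) -> Tree:
    """Stepwise-addition starting tree for a seeded random taxon order."""
    if matrix.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    engine = ParsimonyEngine(matrix)
    rng = np.random.default_rng(order_seed)
    order = list(rng.permutation(matrix.n_taxa))
    adj = engine.addition_tree(order)
    og = matrix.row_index(outgroup) if outgroup else 0
    return engine.to_tree(adj, og)


def tbr_swap(
    tree: Tree,
    matrix: CharacterMatrix,
    hold_k: int = 10,
    mode: str = "tbr",
    outgroup: str | None = None,
) -> TreeSet:
    """Branch swapping from a starting tree down to a local optimum.

    The result length never exceeds the input length; up to ``hold_k``
    equally shortest trees are retained.
    """
    engine = ParsimonyEngine(matrix)
    adj = engine.from_tree(tree)
    og = matrix.row_index(outgroup) if outgroup else 0
    length, pool = engine.swap_to_optimum(adj, hold_k, mode)
    trees = [engine.to_tree(a, og) for a in pool]
    return TreeSet(trees, length, len(trees))


def heuristic_search(
    matrix: CharacterMatrix,
    config: SearchConfig | None = None,
    outgroup: str | None = None,
) -> TreeSet:
    """Replicated random-addition + branch-swapping search.

    Pools and deduplicates equally best trees across replicates (unrooted
    topology identity, after zero-minimum-length branch collapsing when
    ``collapse_rule='min'``); reports the best length, the deduplicated tree
    count and a per-replicate convergence log.
    """
    if matrix.n_taxa < 4:
        raise ValueError("heuristic search requires at least 4 taxa")
    config = config or SearchConfig()
    engine = ParsimonyEngine(matrix)
    og = matrix.row_index(outgroup) if outgroup else 0
    rng = np.random.default_rng(config.seed)

    best_len: int | None = None
    pool: dict[frozenset, Adjacency] = {}
    log: list[tuple[int, int, int]] = []
    since_improvement = 0
    for rep in range(config.n_replicates):
        order = list(rng.permutation(matrix.n_taxa))
        adj = engine.addition_tree(order)
        length, found = engine.swap_to_optimum(
            adj, config.hold_per_replicate, config.swap
        )
        log.append((rep, length, len(found)))
        if best_len is None or length < best_len:
            best_len = length
            pool = {}
            since_improvement = 0
        elif length == best_len:
            since_improvement += 1
        else:
            since_improvement += 1
        if length == best_len:
            for a in found:
                if len(pool) >= config.max_pool:
                    break
                pool.setdefault(engine.topology_key(a), a)
        if (
            config.early_stop_after is not None
            and since_improvement >= config.early_stop_after
        ):
            break

    trees = [engine.to_tree(a, og) for a in pool.values()]
    collapsed = None
    n_found = len(trees)
    if config.collapse_rule == "min":
        dedup: dict[frozenset, Tree] = {}
        for t in trees:
            c = collapse_zero_length_branches(t, matrix)
            dedup.setdefault(frozenset(c.bipartitions()), c)
        collapsed = list(dedup.values())
        n_found = len(collapsed)
    return TreeSet(trees, int(best_len), n_found, log, collapsed)


def exhaustive_search(matrix: CharacterMatrix, outgroup: str | None = None) -> TreeSet:
    """Enumerate every unrooted topology (feasible for <= ~9 taxa) and return
    all most-parsimonious trees."""
    n = matrix.n_taxa
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if n > 9:
        raise ValueError("exhaustive enumeration is limited to 9 taxa")
    engine = ParsimonyEngine(matrix)
    og = matrix.row_index(outgroup) if outgroup else 0

    base: Adjacency = {0: [n], 1: [n], 2: [n], n: [0, 1, 2]}
    stack: list[tuple[Adjacency, int, int]] = [(base, 3, n + 1)]
    best: int | None = None
    winners: list[Adjacency] = []
    while stack:
        adj, k, nxt = stack.pop()
        if k == n:
            length = engine.length(adj)
            if best is None or length < best:
                best, winners = length, [adj]
            elif length == best:
                winners.append(adj)
            continue
        edges = set()
        for a in adj:
            for b in adj[a]:
                edges.add(frozenset((a, b)))
        for e in edges:
            u, v = tuple(e)
            new = {x: list(y) for x, y in adj.items()}
            p = nxt
            new[u] = [y if y != v else p for y in new[u]]
            new[v] = [y if y != u else p for y in new[v]]
            new[p] = [u, v, k]
            new[k] = [p]
            stack.append((new, k + 1, nxt + 1))
    trees = [engine.to_tree(a, og) for a in winners]
    return TreeSet(trees, int(best), len(trees))


def collapse_zero_length_branches(tree: Tree, matrix: CharacterMatrix) -> Tree:
    """Collapse internal branches whose minimum length over all
    most-parsimonious reconstructions is zero (TNT rule-1-like)."""
    forced = {n: False for n in tree.postorder()}
    root_kids = tree.children.get(tree.root, ())
    for cid in matrix.char_ids:
        _, down, _, rest, L = state_cost_vectors(tree, matrix, cid)
        for v in tree.postorder():
            if v == tree.root or not tree.children.get(v):
                continue
            if forced[v]:
                continue
            # for a root child of a binary root, the far side of the branch is
            # the sibling subtree itself (the root is only an edge midpoint)
            if tree.parent[v] == tree.root and len(root_kids) == 2:
                sib = root_kids[0] if root_kids[1] == v else root_kids[1]
                far = down[sib]
            else:
                far = rest[v]
            k = len(down[v])
            no_change = min(down[v][i] + far[i] for i in range(k))
            if no_change > L:
                forced[v] = True
    keep = {
        tree.clade_leafsets()[v]
        for v in tree.postorder()
        if v != tree.root and tree.children.get(v) and forced[v]
    }
    out = tree_from_clades_rooted(tree, keep)
    return out


def tree_from_clades_rooted(tree: Tree, clades: set) -> Tree:
    from .trees import tree_from_clades

    return tree_from_clades(tree.leaf_names, clades)
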