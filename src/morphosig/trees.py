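"""Rooted phylogenetic trees over taxon labels.

Nodes are opaque integer ids; leaves carry labels.  Trees from parsimony
searches are binary and rooted so that the designated outgroup is the first
child of the root; strict consensus trees may be polytomous.  Newick parsing
is delegated to dendropy; serialisation is our own.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import dendropy


class Tree:
    """A rooted tree with integer node ids and leaf labels."""

    __slots__ = ("children", "parent", "root", "labels", "blen", "_clades")

    def __init__(
        self,
        children: Mapping[int, Sequence[int]],
        labels: Mapping[int, str],
        root: int,
        blen: Mapping[int, float] | None = None,
    ):
        self.children: dict[int, tuple[int, ...]] = {
            n: tuple(c) for n, c in children.items()
        }
        self.labels: dict[int, str] = dict(labels)
        self.root = root
        self.blen: dict[int, float] = dict(blen) if blen else {}
        self.parent: dict[int, int] = {}
        for n, kids in self.children.items():
            for c in kids:
                self.parent[c] = n
        self._clades: dict[int, frozenset] | None = None
        # sanity: labels only on leaves, every non-root reachable
        for n, kids in self.children.items():
            if kids and n in self.labels:
                raise ValueError(f"internal node {n} carries a leaf label")
        seen = set(self.postorder())
        if len(seen) != len(set(self.labels) | set(self.children) | {self.root}):
            raise ValueError("tree contains unreachable nodes")
        names = list(self.labels.values())
        if len(set(names)) != len(names):
            raise ValueError("repeated leaf labels")

    # -- construction -------------------------------------------------------
    @classmethod
    def from_nested(cls, nested) -> "Tree":
        """Build a tree from nested tuples of leaf names, e.g. ``("O",("A","B"))``."""
        children: dict[int, list[int]] = {}
        labels: dict[int, str] = {}
        counter = [0]

        def build(obj) -> int:
            nid = counter[0]
            counter[0] += 1
            if isinstance(obj, str):
                labels[nid] = obj
                children[nid] = []
            else:
                children[nid] = []
                for sub in obj:
                    # reserve id first so ids are preorder
                    children[nid].append(build(sub))
            return nid

        root = build(nested)
        return cls(children, labels, root)

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        children: dict[int, list[int]] = {}
        labels: dict[int, str] = {}
        blen: dict[int, float] = {}
        ids: dict = {}
        for i, nd in enumerate(dtree.preorder_node_iter()):
            ids[nd] = i
            children[i] = []
            if nd.parent_node is not None:
                children[ids[nd.parent_node]].append(i)
                if nd.edge.length is not None:
                    blen[i] = float(nd.edge.length)
            if nd.is_leaf():
                labels[i] = (
                    nd.taxon.label.replace(" ", "_") if nd.taxon else f"leaf_{i}"
                )
        return cls(children, labels, ids[dtree.seed_node], blen)

    # -- traversal ----------------------------------------------------------
    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(self.children.get(n, ()))
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def leaves(self) -> list[int]:
        return [n for n in self.postorder() if not self.children.get(n)]

    @property
    def leaf_names(self) -> frozenset:
        return frozenset(self.labels.values())

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def is_binary(self) -> bool:
        return all(
            len(kids) == 2 for n, kids in self.children.items() if kids
        )

    # -- clades and bipartitions ---------------------------------------------
    def clade_leafsets(self) -> dict[int, frozenset]:
        """Leaf-name set below every node."""
        if self._clades is None:
            clades: dict[int, frozenset] = {}
            for n in self.postorder():
                kids = self.children.get(n, ())
                if not kids:
                    clades[n] = frozenset({self.labels[n]})
                else:
                    s: frozenset = frozenset()
                    for c in kids:
                        s |= clades[c]
                    clades[n] = s
            self._clades = clades
        return self._clades

    def clades(self, include_trivial: bool = False) -> set:
        """Leaf sets of all non-root nodes (clades of the rooted tree)."""
        sets = self.clade_leafsets()
        out = set()
        for n, s in sets.items():
            if n == self.root:
                continue
            if not include_trivial and len(s) < 2:
                continue
            out.add(s)
        return out

    def bipartitions(self) -> set:
        """Nontrivial unrooted splits, each as the side not containing the
        lexicographically smallest leaf name."""
        all_leaves = self.leaf_names
        ref = min(all_leaves)
        n = len(all_leaves)
        out = set()
        for s in self.clade_leafsets().values():
            side = all_leaves - s if ref in s else s
            if 2 <= len(side) <= n - 2:
                out.add(side)
        return out

    def mrca(self, names: Iterable[str]) -> int:
        """Most recent common ancestor of a set of leaf names."""
        want = frozenset(names)
        missing = want - self.leaf_names
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        sets = self.clade_leafsets()
        best, best_size = self.root, len(self.leaf_names) + 1
        for n, s in sets.items():
            if want <= s and len(s) < best_size:
                best, best_size = n, len(s)
        return best

    # -- editing --------------------------------------------------------------
    def copy(self) -> "Tree":
        return Tree(self.children, self.labels, self.root, self.blen)

    def restrict(self, names: Iterable[str]) -> "Tree":
        """Induced tree on a subset of leaves (unary nodes suppressed)."""
        keep = frozenset(names)
        missing = keep - self.leaf_names
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        clades = {s & keep for s in self.clades(include_trivial=False)}
        clades = {s for s in clades if len(s) >= 2 and s != keep}
        return tree_from_clades(keep, clades)

    def reroot_at_leaf(self, name: str) -> "Tree":
        """Reroot the unrooted topology so that leaf ``name`` is the first
        child of a new binary root (the usual outgroup orientation)."""
        adj: dict[int, set[int]] = {n: set() for n in self.postorder()}
        for c, p in self.parent.items():
            adj[c].add(p)
            adj[p].add(c)
        # suppress an old degree-2 root
        if len(self.children.get(self.root, ())) == 2 and self.root in adj:
            a, b = self.children[self.root]
            adj[a].discard(self.root)
            adj[b].discard(self.root)
            adj[a].add(b)
            adj[b].add(a)
            del adj[self.root]
        leaf = next(n for n, lbl in self.labels.items() if lbl == name)
        new_root = max(adj) + 1
        (nbr,) = adj[leaf]
        adj[leaf] = {new_root}
        adj[nbr].discard(leaf)
        adj[nbr].add(new_root)
        adj[new_root] = {leaf, nbr}
        children: dict[int, list[int]] = {}
        stack = [(new_root, -1)]
        while stack:
            node, par = stack.pop()
            kids = sorted(adj[node] - {par})
            if node == new_root:
                kids = [leaf] + [k for k in kids if k != leaf]
            children[node] = kids
            for k in kids:
                stack.append((k, node))
        return Tree(children, self.labels, new_root)

    # -- serialisation ---------------------------------------------------------
    def to_newick(self, annotations: Mapping[int, str] | None = None) -> str:
        ann = annotations or {}

        def render(n: int) -> str:
            kids = self.children.get(n, ())
            if not kids:
                core = self.labels[n]
            else:
                core = "(" + ",".join(render(c) for c in kids) + ")" + ann.get(n, "")
            if n in self.blen:
                core += f":{self.blen[n]:g}"
            return core

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.n_leaves} leaves)"

    # topological identity (rooted)
    def same_topology(self, other: "Tree") -> bool:
        return (
            self.leaf_names == other.leaf_names
            and self.clades(include_trivial=False)
            == other.clades(include_trivial=False)
        )


def tree_from_clades(leaves: Iterable[str], clades: Iterable[frozenset]) -> Tree:
    """Build the rooted tree realising a nested family of leaf-name clades.

    ``clades`` must be pairwise compatible (nested or disjoint); the full leaf
    set and singletons are implicit.
    """
    leaves = frozenset(leaves)
    fam = sorted(
        {frozenset(c) for c in clades if 2 <= len(c) < len(leaves)},
        key=lambda s: (-len(s), sorted(s)),
    )
    children: dict[int, list[int]] = {0: []}
    labels: dict[int, str] = {}
    node_of: dict[frozenset, int] = {leaves: 0}
    nxt = 1
    # parent of each clade = smallest strictly containing clade seen so far
    ordered_sets = [leaves] + fam
    for s in fam:
        parent = min(
            (t for t in ordered_sets if s < t and t in node_of),
            key=len,
        )
        node_of[s] = nxt
        children[nxt] = []
        children[node_of[parent]].append(nxt)
        nxt += 1
    for name in sorted(leaves):
        s = frozenset({name})
        parent = min((t for t in ordered_sets if name in t), key=len)
        labels[nxt] = name
        children[nxt] = []
        children[node_of[parent]].append(nxt)
        nxt += 1
    return Tree(children, labels, 0)
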