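"""Synthetic morphological matrices with known ground truth.

Characters are discrete, unordered, and evolve on a known rooted tree by a
simple change-per-branch process: every character receives one primary
derived-state change on a designated or randomly drawn branch (so it marks a
clade of its generating tree), plus extra changes drawn per branch with
probability ``1 - exp(-branch_length * homoplasy_rate)``.  This keeps the true
number of changes per character exact in the ground-truth record, which is
what the parsimony machinery needs for calibration; it deliberately is not a
full continuous-time Mk process.

The conflict scenario mirrors a partition-signal experiment: a "postcranial"
partition evolves on a tree where a focal clade sits inside the crown group,
a "cranial" partition on a tree where the same clade sits next to the basal
anchors, so masking the postcranial cells of the focal taxa flips the clade's
recovered placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .experiment import CladeDefinition
from .matrix import MISSING, CharacterMatrix, Partition
from .trees import Tree

MAX_STATES = 8


@dataclass
class SimulationParams:
    """Configuration of one simulated matrix.

    ``n_chars`` maps partition name -> character count; ``homoplasy_rate``
    scales the probability of extra (homoplastic) changes per unit branch
    length (0 = every character changes exactly once); ``missing_fraction``
    is per taxon (scalar = all taxa), emulating fragmentary fossils;
    ``conflict_topology``/``conflict_partitions`` route selected partitions
    onto a second generating tree over the same leaves.
    """

    tree: Tree
    n_chars: Mapping[str, int]
    n_states: int = 2
    homoplasy_rate: float | Mapping[str, float] = 0.0
    missing_fraction: float | Mapping[str, float] = 0.0
    conflict_topology: Tree | None = None
    conflict_partitions: frozenset = frozenset()
    marker_clades: Mapping[str, list] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_states <= MAX_STATES:
            raise ValueError(f"n_states must be in 2..{MAX_STATES}")
        for p, n in self.n_chars.items():
            if n < 1:
                raise ValueError(f"partition {p!r}: n_chars must be >= 1")
        if self.conflict_topology is not None:
            if self.conflict_topology.leaf_names != self.tree.leaf_names:
                raise ValueError("conflict topology must share the leaf set")
            if self.tree.n_leaves < 4:
                raise ValueError("conflict scenarios require >= 4 leaves")

    def rate(self, partition: str) -> float:
        if isinstance(self.homoplasy_rate, Mapping):
            return float(self.homoplasy_rate.get(partition, 0.0))
        return float(self.homoplasy_rate)

    def missing_for(self, taxon: str) -> float:
        if isinstance(self.missing_fraction, Mapping):
            return float(self.missing_fraction.get(taxon, 0.0))
        return float(self.missing_fraction)


@dataclass
class CharTruth:
    partition: str
    generating_tree: str  # "base" | "conflict"
    marker_clade: frozenset  # leaves below the primary change
    n_changes: int  # realised changes (primary + extra)


@dataclass
class GroundTruth:
    base_tree: Tree
    conflict_tree: Tree | None
    partitions: dict
    chars: list  # CharTruth per character, 0-based order = char_id - 1
    masked_cells: set  # (taxon, char_id)

    def partition_object(self, name: str) -> Partition:
        return self.partitions[name]


def random_tree(
    names: Iterable[str], seed: int = 0, mean_branch_length: float = 0.3
) -> Tree:
    """Random binary rooted tree by sequential pairing, exponential branch
    lengths."""
    rng = np.random.default_rng(seed)
    names = list(names)
    if len(names) < 2:
        raise ValueError("need at least two taxa")
    nodes: list = list(names)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    tree = Tree.from_nested(nodes[0])
    blen = {
        n: float(rng.exponential(mean_branch_length))
        for n in tree.postorder()
        if n != tree.root
    }
    tree.blen = blen
    return tree


def _branch_nodes(tree: Tree) -> list[int]:
    """Nodes identifying branches (every node except the root)."""
    return [n for n in tree.postorder() if n != tree.root]


def _evolve_char(
    tree: Tree,
    rng: np.random.Generator,
    n_states: int,
    rate: float,
    marker_node: int | None,
) -> tuple[dict[str, int], frozenset, int]:
    """One character on a tree: primary change on ``marker_node``'s branch
    (random branch when None), extra changes at ``rate``.  Returns (leaf
    states, marked clade leafset, total changes)."""
    branches = _branch_nodes(tree)
    if marker_node is None:
        lens = np.array([tree.blen.get(n, 1.0) for n in branches])
        probs = lens / lens.sum()
        marker_node = branches[int(rng.choice(len(branches), p=probs))]
    state: dict[int, int] = {tree.root: 0}
    n_changes = 0
    for n in tree.preorder():
        if n == tree.root:
            continue
        s = state[tree.parent[n]]
        if n == marker_node:
            s = 1 if s != 1 else (2 if n_states > 2 else 0)
            n_changes += 1
        elif rate > 0:
            bl = tree.blen.get(n, 1.0)
            if rng.random() < 1.0 - np.exp(-bl * rate):
                others = [x for x in range(n_states) if x != s]
                s = int(others[int(rng.integers(len(others)))])
                n_changes += 1
        state[n] = s
    leaf_states = {lbl: state[n] for n, lbl in tree.labels.items()}
    clade = tree.clade_leafsets()[marker_node]
    return leaf_states, clade, n_changes


def simulate_matrix(params: SimulationParams) -> tuple[CharacterMatrix, GroundTruth]:
    """Generate a matrix and its ground truth; fully determined by the seed."""
    rng = np.random.default_rng(params.seed)
    base = params.tree
    taxa = sorted(base.leaf_names)
    columns: list[dict[str, int]] = []
    char_truths: list[CharTruth] = []
    partitions: dict[str, set] = {}

    node_of_clade = {}
    for tree_name, tree in (("base", base), ("conflict", params.conflict_topology)):
        if tree is None:
            continue
        node_of_clade[tree_name] = {
            s: n for n, s in tree.clade_leafsets().items() if n != tree.root
        }

    cid = 0
    for pname in sorted(params.n_chars):
        n = params.n_chars[pname]
        tree_name = "conflict" if pname in params.conflict_partitions else "base"
        tree = params.conflict_topology if tree_name == "conflict" else base
        rate = params.rate(pname)
        markers = list(params.marker_clades.get(pname, []))
        members = set()
        for i in range(n):
            marker_node = None
            if i < len(markers):
                clade = frozenset(markers[i])
                marker_node = node_of_clade[tree_name].get(clade)
                if marker_node is None:
                    raise ValueError(
                        f"marker clade {sorted(clade)} is not a clade of the "
                        f"{tree_name} tree"
                    )
            leaf_states, clade, changes = _evolve_char(
                tree, rng, params.n_states, rate if i >= len(markers) else 0.0,
                marker_node,
            )
            columns.append(leaf_states)
            char_truths.append(CharTruth(pname, tree_name, clade, changes))
            cid += 1
            members.add(cid)
        partitions[pname] = members

    masked: set = set()
    rows = []
    for t in taxa:
        frac = params.missing_for(t)
        row = []
        for j, col in enumerate(columns):
            if frac > 0 and rng.random() < frac:
                row.append(MISSING)
                masked.add((t, j + 1))
            else:
                row.append(frozenset({col[t]}))
        rows.append(row)
    matrix = CharacterMatrix(taxa, rows)
    truth = GroundTruth(
        base,
        params.conflict_topology,
        {p: Partition(p, frozenset(m)) for p, m in partitions.items()},
        char_truths,
        masked,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# the conflict scenario
# ---------------------------------------------------------------------------


@dataclass
class ConflictTruth:
    matrix_truth: GroundTruth
    focal: CladeDefinition
    crown_clade: frozenset  # focal position in the base tree
    basal_clade: frozenset  # focal position in the conflict tree
    expected_full: str
    expected_masked: str


def _ladder(names: list[str]):
    nested = names[0]
    for n in names[1:]:
        nested = (nested, n)
    return nested


def make_conflict_scenario(
    n_taxa: int = 16,
    focal_size: int = 3,
    signal_strengths: tuple[int, int] = (6, 1),
    seed: int = 0,
    n_chars: tuple[int, int] = (25, 40),
    missing_fraction_focal: float = 0.0,
    homoplasy_rate: float = 0.08,
) -> tuple[CharacterMatrix, ConflictTruth]:
    """Two-partition matrix with conflicting placement signal for a focal clade.

    The taxon set comprises an outgroup, a basal (hylaeochampsid-like) pair, a
    gavialoid-like pair, crown (brevirostres-like) taxa, and ``focal_size``
    focal taxa.  The base tree places the focal clade sister to the crown
    taxa; the conflict tree places it sister to the basal pair.  The
    "postcranial" partition (``n_chars[0]`` characters) evolves on the base
    tree with ``signal_strengths[0]`` extra markers on the focal attachment
    clade; the "cranial" partition (``n_chars[1]``) evolves on the conflict
    tree with ``signal_strengths[1]`` extra attachment markers.  With
    ``signal_strengths[1] == 0`` the cranial partition evolves on the base
    tree too (the no-conflict negative control).
    """
    if focal_size < 2:
        raise ValueError("focal_size must be >= 2")
    n_crown = n_taxa - 1 - 2 - 2 - focal_size
    if n_crown < 2:
        raise ValueError("n_taxa too small for the scenario backbone")

    out = "Outgroup"
    hyl = ["Hylaeo_1", "Hylaeo_2"]
    gav = ["Gavialoid_1", "Gavialoid_2"]
    crown = [f"Crown_{i + 1}" for i in range(n_crown)]
    focal = [f"Focal_{i + 1}" for i in range(focal_size)]

    focal_nest = _ladder(focal)
    crown_nest = _ladder(crown)
    base_nested = (
        out,
        ((hyl[0], hyl[1]), ((gav[0], gav[1]), (focal_nest, crown_nest))),
    )
    conflict_nested = (
        out,
        (((hyl[0], hyl[1]), focal_nest), ((gav[0], gav[1]), crown_nest)),
    )
    base = Tree.from_nested(base_nested)
    conflict = Tree.from_nested(conflict_nested)
    for t in (base, conflict):
        t.blen = {n: 0.3 for n in t.postorder() if n != t.root}

    focal_set = frozenset(focal)
    crown_clade = focal_set | frozenset(crown)  # attachment clade, base tree
    basal_clade = focal_set | frozenset(hyl)  # attachment clade, conflict tree

    s_post, s_cran = signal_strengths
    conflicting = s_cran > 0

    def clade_markers(
        tree: Tree, extra_on: frozenset, n_extra: int, per_clade: int = 1
    ) -> list:
        clades = sorted(
            (
                s
                for n, s in tree.clade_leafsets().items()
                if n != tree.root and len(s) >= 2 and len(s) < tree.n_leaves - 1
            ),
            key=lambda s: (len(s), sorted(s)),
        )
        return clades * per_clade + [extra_on] * n_extra

    # the cranial partition is the larger, backbone-carrying one (as in real
    # morphological matrices): two markers per clade so backbone resolution
    # survives masking plus fossil-style missingness in the focal taxa
    post_markers = clade_markers(base, crown_clade, s_post)
    if conflicting:
        cran_markers = clade_markers(conflict, basal_clade, s_cran, per_clade=2)
    else:
        cran_markers = clade_markers(base, crown_clade, 0, per_clade=2)

    n_post, n_cran = n_chars
    if n_post < len(post_markers) or n_cran < len(cran_markers):
        raise ValueError(
            "character counts too small for one marker per generating-tree clade"
        )

    params = SimulationParams(
        tree=base,
        n_chars={"postcranial": n_post, "cranial": n_cran},
        n_states=2,
        homoplasy_rate=homoplasy_rate,
        missing_fraction={t: missing_fraction_focal for t in focal},
        conflict_topology=conflict if conflicting else None,
        conflict_partitions=frozenset({"cranial"}) if conflicting else frozenset(),
        marker_clades={"postcranial": post_markers, "cranial": cran_markers},
        seed=seed,
    )
    matrix, truth = simulate_matrix(params)
    focal_def = CladeDefinition(
        name="focal",
        member_tips=focal_set,
        reference_tips={
            "gavialoids": frozenset(gav),
            "brevirostres": frozenset(crown[:2]),
            "hylaeochampsids": frozenset(hyl),
        },
    )
    return matrix, ConflictTruth(
        truth,
        focal_def,
        crown_clade,
        basal_clade,
        expected_full="crown_crocodylian",
        expected_masked="basal_eusuchian" if conflicting else "crown_crocodylian",
    )
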