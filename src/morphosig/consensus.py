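"""Strict consensus, bootstrap frequencies and Bremer (decay) support."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import CharacterMatrix
from .search import ParsimonyEngine, SearchConfig, TreeSet, heuristic_search
from .trees import Tree, tree_from_clades

logger = logging.getLogger(__name__)


def strict_consensus(trees: TreeSet | list[Tree]) -> Tree:
    """The tree containing exactly the clades present in every input tree.

    All inputs must share a leaf set and a rooting (searches root on the
    outgroup); disagreements become polytomies.
    """
    if isinstance(trees, TreeSet):
        tree_list = list(trees.consensus_input())
    else:
        tree_list = list(trees)
    if not tree_list:
        raise ValueError("at least one tree required")
    ref = tree_list[0]
    for t in tree_list[1:]:
        if t.leaf_names != ref.leaf_names:
            missing = sorted(t.leaf_names ^ ref.leaf_names)
            raise ValueError(f"trees differ in their leaf sets: {missing}")
    common = ref.clades(include_trivial=False)
    for t in tree_list[1:]:
        common &= t.clades(include_trivial=False)
    return tree_from_clades(ref.leaf_names, common)


def bootstrap_support(
    matrix: CharacterMatrix,
    config: SearchConfig | None = None,
    clades: list[frozenset] | None = None,
    n_bootstrap: int = 100,
    seed: int = 0,
    outgroup: str | None = None,
) -> pd.DataFrame:
    """Clade frequencies over character-resampled pseudoreplicates.

    Each pseudoreplicate resamples columns with replacement to the original
    character count, runs :func:`heuristic_search` with the (typically
    reduced-effort) ``config`` and takes the strict consensus.  Reported for
    each queried clade (default: the clades of the original search's strict
    consensus) as a percentage of pseudoreplicates whose consensus contains
    it.  Fully seeded and reproducible.
    """
    config = config or SearchConfig(n_replicates=10, hold_per_replicate=5)
    rng = np.random.default_rng(seed)
    if clades is None:
        base = heuristic_search(matrix, config, outgroup=outgroup)
        clades = sorted(
            strict_consensus(base).clades(include_trivial=False),
            key=lambda s: (len(s), sorted(s)),
        )
    # clade presence is judged on unrooted splits, so the queried tip sets are
    # canonicalised the same way Tree.bipartitions() does
    all_tips = frozenset(matrix.taxa)
    ref = min(all_tips)

    def canonical(tips: frozenset) -> frozenset:
        return all_tips - tips if ref in tips else frozenset(tips)

    counts = {frozenset(c): 0 for c in clades}
    trivial = {
        c for c in counts if not 2 <= len(canonical(c)) <= len(all_tips) - 2
    }
    for _ in range(n_bootstrap):
        cols = rng.integers(0, matrix.n_chars, size=matrix.n_chars)
        rows = [[row[j] for j in cols] for row in matrix.rows]
        pseudo = CharacterMatrix(list(matrix.taxa), rows)
        rep_cfg = SearchConfig(
            n_replicates=config.n_replicates,
            hold_per_replicate=config.hold_per_replicate,
            swap=config.swap,
            seed=int(rng.integers(0, 2**31 - 1)),
            max_pool=config.max_pool,
            collapse_rule=config.collapse_rule,
            early_stop_after=config.early_stop_after,
        )
        result = heuristic_search(pseudo, rep_cfg, outgroup=outgroup)
        present = strict_consensus(result).bipartitions()
        for c in counts:
            if c in trivial or canonical(c) in present:
                counts[c] += 1
    return pd.DataFrame(
        {
            "clade": [",".join(sorted(c)) for c in counts],
            "n_tips": [len(c) for c in counts],
            "frequency_pct": [100.0 * v / n_bootstrap for v in counts.values()],
        }
    )


def bremer_support(
    matrix: CharacterMatrix,
    mpts: TreeSet,
    max_extra: int = 5,
    pool_cap: int = 2000,
) -> pd.DataFrame:
    """Decay index for each strict-consensus clade.

    Starting from the most-parsimonious trees, branch swapping retains every
    distinct topology of length <= best + ``max_extra`` (up to ``pool_cap``
    trees); a clade's Bremer value is the smallest extra length at which some
    retained tree lacks it.  Clades surviving the whole pool are reported as
    censored (``> max_extra``).
    """
    if max_extra < 1:
        raise ValueError("max_extra must be >= 1")
    engine = ParsimonyEngine(matrix)
    best = mpts.best_length
    threshold = best + max_extra

    all_tips = frozenset(matrix.taxa)
    ref = min(all_tips)

    def canonical(tips: frozenset) -> frozenset:
        return all_tips - tips if ref in tips else frozenset(tips)

    pool: dict[frozenset, tuple[int, frozenset]] = {}
    frontier: list = []
    for t in mpts:
        adj = engine.from_tree(t)
        key = engine.topology_key(adj)
        if key not in pool:
            pool[key] = (best, frozenset(t.bipartitions()))
            frontier.append(adj)
    while frontier and len(pool) < pool_cap:
        adj = frontier.pop()
        _, moves = engine.neighborhood(adj, bound=threshold)
        for score, cut, e_rest, e_pruned in moves:
            if len(pool) >= pool_cap:
                break
            cand = engine.apply_move(adj, cut, e_rest, e_pruned)
            key = engine.topology_key(cand)
            if key not in pool:
                og = min(n for n in cand if n < engine.n_taxa)
                tr = engine.to_tree(cand, og)
                pool[key] = (score, frozenset(tr.bipartitions()))
                frontier.append(cand)
    if len(pool) >= pool_cap:
        logger.warning("Bremer pool hit its cap (%d trees); values are upper bounds", pool_cap)

    consensus = strict_consensus(mpts)
    records = []
    for clade in sorted(consensus.clades(include_trivial=False), key=lambda s: (len(s), sorted(s))):
        split = canonical(clade)
        if not 2 <= len(split) <= len(all_tips) - 2:
            continue  # trivial split: present in every tree, no decay defined
        decay = None
        for length, splits in pool.values():
            if split not in splits:
                d = length - best
                decay = d if decay is None else min(decay, d)
        records.append(
            {
                "clade": ",".join(sorted(clade)),
                "n_tips": len(clade),
                "bremer": decay if decay is not None else max_extra,
                "censored": decay is None,
            }
        )
    return pd.DataFrame(records)


def annotate_consensus(
    consensus: Tree,
    bootstrap: pd.DataFrame | None = None,
    bremer: pd.DataFrame | None = None,
) -> str:
    """Newick with ``bootstrap/bremer`` internal node labels."""
    boot = {}
    if bootstrap is not None:
        boot = dict(zip(bootstrap["clade"], bootstrap["frequency_pct"]))
    brem = {}
    if bremer is not None:
        brem = {
            row.clade: (f">{row.bremer}" if row.censored else str(int(row.bremer)))
            for row in bremer.itertuples()
        }
    ann = {}
    for node, leafset in consensus.clade_leafsets().items():
        if node == consensus.root or not consensus.children.get(node):
            continue
        key = ",".join(sorted(leafset))
        parts = []
        if key in boot:
            parts.append(f"{boot[key]:.0f}")
        if key in brem:
            parts.append(brem[key])
        if parts:
            ann[node] = "/".join(parts)
    return consensus.to_newick(annotations=ann)
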