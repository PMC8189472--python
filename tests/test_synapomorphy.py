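"""MPR state sets and synapomorphy enumeration against labeling oracles."""

import numpy as np
import pytest

from morphosig.fitch import fitch_per_char_steps
from morphosig.matrix import MISSING, CharacterMatrix
from morphosig.simulate import SimulationParams, random_tree, simulate_matrix
from morphosig.synapomorphy import (
    mpr_state_sets,
    stem_changes,
    unambiguous_synapomorphies,
)
from morphosig.trees import Tree
from conftest import (
    all_unrooted_topologies,
    oracle_mpr_sets,
    oracle_stem_changes,
    random_matrix,
)


def test_constant_character_has_singleton_mpr_everywhere():
    m = CharacterMatrix(["A", "B", "C", "D"], [[frozenset({1})]] * 4)
    t = Tree.from_nested((("A", "B"), ("C", "D")))
    sets = mpr_state_sets(t, m, 1)
    assert all(s == frozenset({1}) for s in sets.values())


def test_autapomorphy_is_confined_to_its_leaf_branch():
    m = CharacterMatrix(
        ["A", "B", "C", "D"],
        [[frozenset({0})], [frozenset({0})], [frozenset({0})], [frozenset({1})]],
    )
    t = Tree.from_nested(("A", ("B", ("C", "D"))))
    sets = mpr_state_sets(t, m, 1)
    for node in t.postorder():
        if t.labels.get(node) == "D":
            continue
        assert sets[node] == frozenset({0})


@pytest.mark.parametrize("trial_block", [0, 1])
def test_mpr_sets_match_exhaustive_labeling_oracle(trial_block):
    rng = np.random.default_rng(500 + trial_block)
    for _ in range(40):
        m = random_matrix(rng, 6, 1, n_states=3, missing_frac=0.15, poly_frac=0.1)
        topo = all_unrooted_topologies(m.taxa)
        t = topo[int(rng.integers(len(topo)))]
        column = {x: m.cell(x, 1) for x in m.taxa}
        states = sorted(set().union(*column.values()) or {0})
        expected, _ = oracle_mpr_sets(t, column, states)
        got = mpr_state_sets(t, m, 1)
        for node, exp in expected.items():
            assert got[node] == exp, f"node {node}: {got[node]} != {exp}"


def test_stem_changes_match_labeling_oracle():
    rng = np.random.default_rng(71)
    checked = 0
    while checked < 25:
        m = random_matrix(rng, 5, 1, n_states=2, missing_frac=0.1)
        topo = all_unrooted_topologies(m.taxa)
        t = topo[int(rng.integers(len(topo)))]
        column = {x: m.cell(x, 1) for x in m.taxa}
        states = sorted(set().union(*column.values()) or {0})
        if len(states) < 2:
            continue
        internal = [
            n
            for n in t.postorder()
            if t.children.get(n) and n != t.root and t.parent.get(n) != t.root
        ]
        if not internal:
            continue
        node = internal[0]
        clade = t.clade_leafsets()[node]
        unamb, possible = stem_changes(t, m, clade)
        o_always, o_sometimes, _ = oracle_stem_changes(t, column, states, node)
        assert possible.get(1, set()) == o_sometimes
        assert unamb.get(1) == o_always
        checked += 1


def test_planted_markers_recovered_without_false_negatives():
    """Zero-homoplasy generator: each planted clade marker must surface as an
    unambiguous synapomorphy of its clade, with state 1."""
    tree = random_tree([f"T{i}" for i in range(10)], seed=21)
    clades = sorted(
        (s for s in tree.clades(include_trivial=False) if len(s) <= 8),
        key=lambda s: (len(s), sorted(s)),
    )
    matrix, truth = simulate_matrix(
        SimulationParams(tree=tree, n_chars={"all": len(clades)}, marker_clades={"all": clades}, seed=21)
    )
    for cid, clade in enumerate(clades, start=1):
        recs = unambiguous_synapomorphies([tree], matrix, clade)
        mine = [r for r in recs if r.char_id == cid]
        assert len(mine) == 1
        assert mine[0].status == "unambiguous"
        assert mine[0].derived_state == 1
        assert mine[0].notation() == f"C{cid}^1"


def test_character_missing_across_clade_is_never_reported():
    tree = Tree.from_nested((("A", "B"), (("C", "D"), "E")))
    clade = frozenset({"C", "D"})
    m = CharacterMatrix(
        ["A", "B", "C", "D", "E"],
        [
            [frozenset({0})],
            [frozenset({0})],
            [MISSING],
            [MISSING],
            [frozenset({1})],
        ],
    )
    recs = unambiguous_synapomorphies([tree], m, clade)
    assert recs == []


def test_reversal_appears_as_second_change_on_nested_branch():
    # state 1 arises on the (C,D,E,F) stem and unambiguously reverts to 0 in
    # the deeply nested F (stem gain + one loss is the unique optimum)
    tree = Tree.from_nested(("A", ("B", ("C", ("D", ("E", "F"))))))
    m = CharacterMatrix(
        ["A", "B", "C", "D", "E", "F"],
        [
            [frozenset({0})],
            [frozenset({0})],
            [frozenset({1})],
            [frozenset({1})],
            [frozenset({1})],
            [frozenset({0})],
        ],
    )
    big = frozenset({"C", "D", "E", "F"})
    recs = unambiguous_synapomorphies([tree], m, big)
    assert any(r.derived_state == 1 and r.status == "unambiguous" for r in recs)
    reversal = unambiguous_synapomorphies([tree], m, frozenset({"F"}))
    assert any(r.derived_state == 0 and r.status == "unambiguous" for r in reversal)


def test_forced_changes_never_exceed_character_length():
    rng = np.random.default_rng(91)
    for _ in range(10):
        m = random_matrix(rng, 6, 4, n_states=2, missing_frac=0.1)
        topo = all_unrooted_topologies(m.taxa)
        t = topo[int(rng.integers(len(topo)))]
        steps = fitch_per_char_steps(t, m)
        forced_per_char = {cid: 0 for cid in m.char_ids}
        root_kids = t.children[t.root]
        for node in t.postorder():
            # the two root branches are halves of one unrooted edge: count once
            if node == t.root or node == root_kids[0]:
                continue
            clade = t.clade_leafsets()[node]
            unamb, _ = stem_changes(t, m, clade)
            for cid in unamb:
                forced_per_char[cid] += 1
        for cid in m.char_ids:
            assert forced_per_char[cid] <= steps[cid - 1]


def test_clade_absent_from_all_trees_raises():
    tree = Tree.from_nested((("A", "B"), ("C", "D")))
    m = CharacterMatrix(["A", "B", "C", "D"], [[frozenset({0})]] * 4)
    with pytest.raises(KeyError):
        unambiguous_synapomorphies([tree], m, frozenset({"A", "C"}))
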