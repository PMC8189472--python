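"""Fitch scoring against exhaustive labeling oracles; step bounds; indices."""

import numpy as np
import pytest

from morphosig.fitch import (
    constrained_length,
    ensemble_indices,
    fitch_length,
    fitch_per_char_steps,
    max_steps,
    min_steps,
)
from morphosig.matrix import MISSING, CharacterMatrix
from morphosig.trees import Tree
from conftest import (
    all_unrooted_topologies,
    oracle_char_length,
    oracle_matrix_length,
    random_matrix,
)


def test_constant_character_scores_zero():
    m = CharacterMatrix(["A", "B", "C", "D"], [[frozenset({1})]] * 4)
    t = Tree.from_nested((("A", "B"), ("C", "D")))
    assert fitch_length(t, m).total_steps == 0


def test_missing_leaf_error_names_leaf():
    m = CharacterMatrix(["A", "B", "C"], [[frozenset({0})]] * 3)
    t = Tree.from_nested((("A", "B"), ("C", "Zed")))
    with pytest.raises(KeyError, match="Zed"):
        fitch_length(t, m)


@pytest.mark.parametrize("n_taxa,n_trials", [(5, 60), (6, 60), (7, 30)])
def test_fitch_equals_exhaustive_labeling_oracle(n_taxa, n_trials):
    """Tree length matches brute-force minimisation over all internal
    labelings, including missing and polymorphic cells."""
    rng = np.random.default_rng(100 + n_taxa)
    for trial in range(n_trials):
        m = random_matrix(
            rng, n_taxa, 5, n_states=3, missing_frac=0.1, poly_frac=0.1
        )
        topo = all_unrooted_topologies(m.taxa)
        t = topo[int(rng.integers(len(topo)))]
        assert fitch_length(t, m).total_steps == oracle_matrix_length(t, m)


def test_root_invariance():
    rng = np.random.default_rng(7)
    m = random_matrix(rng, 7, 12, n_states=3, missing_frac=0.1)
    topo = all_unrooted_topologies(m.taxa)
    t = topo[40]
    base = fitch_length(t, m).total_steps
    for name in m.taxa:
        assert fitch_length(t.reroot_at_leaf(name), m).total_steps == base


def test_masking_never_increases_length():
    rng = np.random.default_rng(11)
    m = random_matrix(rng, 8, 15, n_states=3)
    t = Tree.from_nested(
        (("T0", ("T1", "T2")), (("T3", "T4"), ("T5", ("T6", "T7"))))
    )
    base = fitch_length(t, m).total_steps
    masked = m.with_cells(
        {(f"T{i}", c): MISSING for i in (1, 4, 6) for c in (1, 5, 9)}
    )
    assert fitch_length(t, masked).total_steps <= base


def test_min_steps_basics():
    col = lambda cells: CharacterMatrix(
        [f"T{i}" for i in range(len(cells))], [[c] for c in cells]
    )
    assert min_steps(col([frozenset({0}), frozenset({1})]), 1) == 1
    assert min_steps(col([MISSING, MISSING, MISSING]), 1) == 0
    assert min_steps(col([frozenset({0}), frozenset({1}), frozenset({2})]), 1) == 2
    # polymorphism resolvable to a single state
    assert min_steps(col([frozenset({0, 1}), frozenset({1})]), 1) == 0


def test_max_steps_basics_and_against_topology_enumeration():
    col = lambda cells: CharacterMatrix(
        [f"T{i}" for i in range(len(cells))], [[c] for c in cells]
    )
    assert max_steps(col([frozenset({0})] * 4), 1) == 0
    assert (
        max_steps(
            col([frozenset({0}), frozenset({0}), frozenset({1}), frozenset({1})]), 1
        )
        == 2
    )
    rng = np.random.default_rng(42)
    taxa = [f"T{i}" for i in range(6)]
    topologies = all_unrooted_topologies(taxa)
    for _ in range(25):
        m = random_matrix(rng, 6, 1, n_states=3, missing_frac=0.15, poly_frac=0.1)
        column = {t: m.cell(t, 1) for t in m.taxa}
        states = sorted(set().union(*column.values()) or {0})
        worst = max(
            oracle_char_length(t, column, states) for t in topologies
        )
        assert max_steps(m, 1) == worst


def test_bounds_bracket_observed_steps():
    rng = np.random.default_rng(3)
    for _ in range(10):
        m = random_matrix(rng, 7, 8, n_states=3, missing_frac=0.1, poly_frac=0.05)
        topo = all_unrooted_topologies(m.taxa)
        t = topo[int(rng.integers(len(topo)))]
        sc = fitch_length(t, m)
        assert all(sc.min_steps <= sc.per_char_steps)
        assert all(sc.per_char_steps <= sc.max_steps)


def test_ensemble_indices_no_homoplasy_gives_ci_one():
    # characters each marking a clade of the tree exactly once
    t = Tree.from_nested((("A", "B"), (("C", "D"), "E")))
    m = CharacterMatrix(
        ["A", "B", "C", "D", "E"],
        [
            [frozenset({1}), frozenset({0})],
            [frozenset({1}), frozenset({0})],
            [frozenset({0}), frozenset({1})],
            [frozenset({0}), frozenset({1})],
            [frozenset({0}), frozenset({0})],
        ],
    )
    ci, ri = ensemble_indices([t], m)
    assert ci == 1.0
    assert ri == 1.0


def test_ensemble_indices_match_hand_computation():
    rng = np.random.default_rng(9)
    m = random_matrix(rng, 6, 10, n_states=3, missing_frac=0.1)
    topo = all_unrooted_topologies(m.taxa)
    t = topo[3]
    steps = fitch_per_char_steps(t, m)
    S = int(steps.sum())
    msum = sum(min_steps(m, c) for c in m.char_ids)
    gsum = sum(max_steps(m, c) for c in m.char_ids)
    ci, ri = ensemble_indices([t], m)
    assert ci == pytest.approx(msum / S)
    assert ri == pytest.approx((gsum - S) / (gsum - msum))
    # trees of unequal length are rejected
    other = next(
        x for x in topo if fitch_per_char_steps(x, m).sum() != S
    )
    with pytest.raises(ValueError, match="equally parsimonious"):
        ensemble_indices([t, other], m)


def test_constrained_length_matches_oracle_with_forced_root():
    rng = np.random.default_rng(17)
    for _ in range(20):
        m = random_matrix(rng, 5, 1, n_states=3, missing_frac=0.1)
        topo = all_unrooted_topologies(m.taxa)
        t = topo[int(rng.integers(len(topo)))]
        column = {x: m.cell(x, 1) for x in m.taxa}
        states = sorted(set().union(*column.values()) or {0})
        free = constrained_length(t, m, 1)
        assert free == oracle_char_length(t, column, states)
        # forcing the root to each state costs at least the free optimum
        for s in states:
            forced = constrained_length(t, m, 1, {t.root: s})
            assert forced >= free
        assert min(
            constrained_length(t, m, 1, {t.root: s}) for s in states
        ) == free
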