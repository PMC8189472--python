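"""Matrix masking/transfer, placement classification, monophyly, RF, and the
full analysis battery."""

import dendropy
import networkx as nx
import numpy as np
import pytest

from morphosig.consensus import strict_consensus
from morphosig.experiment import (
    CladeDefinition,
    ExperimentConfig,
    classify_placement,
    mask_partition,
    monophyly_status,
    rf_distance,
    run_experiment,
    transfer_scores,
)
from morphosig.matrix import MISSING, CharacterMatrix, Partition
from morphosig.search import SearchConfig
from morphosig.simulate import make_conflict_scenario, random_tree
from morphosig.trees import Tree
from conftest import all_unrooted_topologies, random_matrix


# ---------------------------------------------------------------------------
# masking and transfer
# ---------------------------------------------------------------------------


def test_mask_partition_is_idempotent_and_local():
    rng = np.random.default_rng(1)
    m = random_matrix(rng, 6, 10)
    part = Partition("p", frozenset({2, 5, 9}))
    masked = mask_partition(m, {"T1", "T3"}, part)
    assert mask_partition(masked, {"T1", "T3"}, part) == masked
    for taxon in m.taxa:
        for cid in m.char_ids:
            expected = (
                MISSING
                if taxon in {"T1", "T3"} and cid in part.members
                else m.cell(taxon, cid)
            )
            assert masked.cell(taxon, cid) == expected
    with pytest.raises(KeyError):
        mask_partition(m, {"nope"}, part)
    with pytest.raises(KeyError):
        mask_partition(m, {"T1"}, Partition("bad", frozenset({99})))


def test_empty_partition_mask_is_identity():
    rng = np.random.default_rng(2)
    m = random_matrix(rng, 5, 8)
    assert mask_partition(m, {"T0"}, Partition("empty", frozenset())) == m


def test_transfer_single_donor_and_conflict_union(caplog):
    part = Partition("p", frozenset({1, 2}))
    m = CharacterMatrix(
        ["D1", "D2", "R"],
        [
            [frozenset({0}), frozenset({1})],
            [frozenset({1}), frozenset({1})],
            [MISSING, MISSING],
        ],
    )
    out = transfer_scores(m, ["D1"], "R", part)
    assert out.cell("R", 1) == frozenset({0})
    assert out.cell("R", 2) == frozenset({1})
    both = transfer_scores(m, ["D1", "D2"], "R", part)
    assert both.cell("R", 1) == frozenset({0, 1})  # conflicting donors
    assert both.cell("R", 2) == frozenset({1})
    dropped = transfer_scores(m, ["D1"], "R", part, drop_donors=True)
    assert dropped.taxa == ["D2", "R"]


def test_transfer_respects_scored_recipient_unless_forced():
    part = Partition("p", frozenset({1}))
    m = CharacterMatrix(
        ["D", "R"], [[frozenset({1})], [frozenset({0})]]
    )
    kept = transfer_scores(m, ["D"], "R", part)
    assert kept.cell("R", 1) == frozenset({0})
    forced = transfer_scores(m, ["D"], "R", part, force=True)
    assert forced.cell("R", 1) == frozenset({1})
    empty_donor = CharacterMatrix(["D", "R"], [[MISSING], [MISSING]])
    with pytest.raises(ValueError):
        transfer_scores(empty_donor, ["D"], "R", part)


def test_transfer_then_mask_equals_mask_alone():
    rng = np.random.default_rng(3)
    m = random_matrix(rng, 6, 10, missing_frac=0.2)
    part = Partition("p", frozenset({1, 4, 7}))
    recipient = "T5"
    cleared = mask_partition(m, {recipient}, part)
    transferred = transfer_scores(cleared, ["T0", "T1"], recipient, part)
    assert mask_partition(transferred, {recipient}, part) == cleared


# ---------------------------------------------------------------------------
# placement classification
# ---------------------------------------------------------------------------


def _anchors():
    return {
        "gavialoids": frozenset({"Gav1", "Gav2"}),
        "brevirostres": frozenset({"Brev1", "Brev2"}),
        "hylaeochampsids": frozenset({"Hyl1", "Hyl2"}),
    }


def test_classify_placement_on_hand_built_trees():
    focal = CladeDefinition("focal", frozenset({"F1", "F2"}), _anchors())
    crown = Tree.from_nested(
        ("Out", (("Hyl1", "Hyl2"), (("Gav1", "Gav2"), (("F1", "F2"), ("Brev1", "Brev2")))))
    )
    assert classify_placement(crown, focal) == "crown_crocodylian"
    basal = Tree.from_nested(
        ("Out", ((("Hyl1", "Hyl2"), ("F1", "F2")), (("Gav1", "Gav2"), ("Brev1", "Brev2"))))
    )
    assert classify_placement(basal, focal) == "basal_eusuchian"
    # polytomy joining focal, gavialoids and brevirostres -> unresolved
    unresolved = Tree.from_nested(
        ("Out", (("Hyl1", "Hyl2"), (("Gav1", "Gav2"), ("F1", "F2"), ("Brev1", "Brev2"))))
    )
    assert classify_placement(unresolved, focal) == "unresolved"
    with pytest.raises(KeyError):
        classify_placement(crown.restrict(crown.leaf_names - {"Gav1"}), focal)


def test_classify_placement_invariant_to_outgroup_rerooting():
    focal = CladeDefinition("focal", frozenset({"F1", "F2"}), _anchors())
    crown = Tree.from_nested(
        ("Out", (("Hyl1", "Hyl2"), (("Gav1", "Gav2"), (("F1", "F2"), ("Brev1", "Brev2")))))
    )
    rerooted = crown.reroot_at_leaf("Out")
    assert classify_placement(rerooted, focal) == "crown_crocodylian"


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------


def test_monophyly_basic_cases():
    t = Tree.from_nested((("A", "B"), (("C", "D"), "E")))
    assert monophyly_status(t, {"C", "D"}) == "monophyletic"
    assert monophyly_status(t, {"C", "D", "A"}) == "polyphyletic"
    t2 = Tree.from_nested(("A", ("B", ("C", ("D", "E")))))
    # B..E minus D: complement {D} hangs inside -> paraphyletic
    assert monophyly_status(t2, {"B", "C", "E"}) == "paraphyletic"
    with pytest.raises(ValueError):
        monophyly_status(t, {"C"})
    with pytest.raises(KeyError):
        monophyly_status(t, {"C", "Zed"})


def _oracle_monophyly(tree: Tree, tips: frozenset) -> str:
    """Brute-force convexity via networkx Steiner subtrees."""
    g = nx.Graph()
    for child, parent in tree.parent.items():
        g.add_edge(child, parent)
    leaf_node = {lbl: n for n, lbl in tree.labels.items()}
    sets = tree.clade_leafsets()
    mrca = tree.mrca(tips)
    if sets[mrca] == tips:
        return "monophyletic"
    complement = sets[mrca] - tips

    def steiner(names):
        nodes = set()
        names = sorted(names)
        for x in names:
            for y in names:
                nodes |= set(nx.shortest_path(g, leaf_node[x], leaf_node[y]))
        return nodes

    if steiner(tips) & steiner(complement):
        return "polyphyletic"
    return "paraphyletic"


def test_monophyly_matches_connectivity_oracle_on_random_trees():
    from itertools import combinations

    for seed in range(4):
        tree = random_tree([f"T{i}" for i in range(8)], seed=seed)
        names = sorted(tree.leaf_names)
        rng = np.random.default_rng(seed)
        tipsets = [frozenset(c) for k in (2, 3, 4) for c in combinations(names, k)]
        picks = [tipsets[i] for i in rng.choice(len(tipsets), size=40, replace=False)]
        for tips in picks:
            assert monophyly_status(tree, tips) == _oracle_monophyly(tree, tips)


# ---------------------------------------------------------------------------
# RF distance
# ---------------------------------------------------------------------------


def test_rf_identity_and_nni():
    t1 = Tree.from_nested((("A", "B"), (("C", "D"), ("E", "F"))))
    t2 = Tree.from_nested((("A", "B"), (("C", "E"), ("D", "F"))))
    assert rf_distance(t1, t1) == 0
    assert rf_distance(t1, t2) == 4  # two splits lost, two gained
    t3 = Tree.from_nested((("A", "B"), ((("C", "D"), "E"), "F")))
    nni = Tree.from_nested((("A", "B"), ((("C", "E"), "D"), "F")))
    assert rf_distance(t3, nni) == 2  # classic single-NNI distance
    with pytest.raises(ValueError):
        rf_distance(t1, t3.restrict(frozenset("ABCDE")))


def test_rf_matches_dendropy_on_random_pairs():
    rng = np.random.default_rng(13)
    taxa = [f"T{i}" for i in range(10)]
    tns = dendropy.TaxonNamespace()
    for seed in range(10):
        a = random_tree(taxa, seed=seed)
        b = random_tree(taxa, seed=seed + 100)
        da = dendropy.Tree.get(data=a.to_newick(), schema="newick", taxon_namespace=tns)
        db = dendropy.Tree.get(data=b.to_newick(), schema="newick", taxon_namespace=tns)
        expected = dendropy.calculate.treecompare.symmetric_difference(da, db)
        assert rf_distance(a, b) == expected


# ---------------------------------------------------------------------------
# the analysis battery
# ---------------------------------------------------------------------------


def test_run_experiment_reports_placement_flip_on_conflict_scenario():
    matrix, truth = make_conflict_scenario(seed=42)
    cfg = ExperimentConfig(
        matrix=matrix,
        partition=truth.matrix_truth.partitions["postcranial"],
        masked_taxa=truth.focal.member_tips,
        focal=truth.focal,
        outgroup="Outgroup",
        control_drop=frozenset({"Focal_3"}),
        monophyly_queries={"focal": truth.focal.member_tips},
        search=SearchConfig(n_replicates=3, hold_per_replicate=10, early_stop_after=None),
        seed=42,
    )
    report = run_experiment(cfg)
    assert set(report.analyses) == {"control", "full", "masked"}
    assert report.analyses["full"].placement == truth.expected_full
    assert report.analyses["masked"].placement == truth.expected_masked
    assert report.analyses["full"].placement != report.analyses["masked"].placement
    assert report.analyses["full"].monophyly["focal"] == "monophyletic"
    assert ("full", "masked") in report.rf_between or ("masked", "full") in report.rf_between
    assert "placement=" in report.summary()
    for a in report.analyses.values():
        assert a.best_length > 0 and a.ci is not None


def test_run_experiment_empty_partition_masked_equals_full():
    matrix, truth = make_conflict_scenario(seed=7)
    cfg = ExperimentConfig(
        matrix=matrix,
        partition=Partition("none", frozenset()),
        masked_taxa=truth.focal.member_tips,
        focal=truth.focal,
        outgroup="Outgroup",
        search=SearchConfig(n_replicates=2, hold_per_replicate=5, early_stop_after=None),
        seed=3,
    )
    report = run_experiment(cfg)
    full, masked = report.analyses["full"], report.analyses["masked"]
    assert full.best_length == masked.best_length
    assert report.rf_between[("full", "masked")] == 0


def test_transfer_analysis_included_when_configured():
    matrix, truth = make_conflict_scenario(seed=9)
    part = truth.matrix_truth.partitions["postcranial"]
    donors = ("Focal_1", "Focal_2")
    recipient = "Crown_1"
    m2 = mask_partition(matrix, {recipient}, part)
    cfg = ExperimentConfig(
        matrix=m2,
        partition=part,
        masked_taxa=truth.focal.member_tips,
        focal=truth.focal,
        outgroup="Outgroup",
        donors=donors,
        recipients=(recipient,),
        search=SearchConfig(n_replicates=2, hold_per_replicate=5, early_stop_after=None),
        seed=5,
    )
    report = run_experiment(cfg)
    assert "transferred" in report.analyses
    # donors dropped from the transferred analysis
    assert report.analyses["transferred"].consensus.leaf_names == (
        frozenset(matrix.taxa) - set(donors)
    )
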