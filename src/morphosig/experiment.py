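"""Partition masking / score-transfer experiments and topology queries.

This is the analysis layer that tests whether a character partition (for the
motivating study, the postcranial skeleton of allodaposuchid crocodylians)
carries its own phylogenetic signal: run a search on the full matrix, on a
variant with the partition masked to missing in a focal taxon set, and on a
variant where the partition scores of a few well-preserved donors are
transferred to a poorly known recipient; then compare the focal clade's
placement and the consensus topologies across analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .consensus import strict_consensus
from .fitch import ensemble_indices
from .matrix import MISSING, CharacterMatrix, Partition
from .search import SearchConfig, heuristic_search
from .trees import Tree

logger = logging.getLogger(__name__)

PLACEMENTS = ("crown_crocodylian", "basal_eusuchian", "unresolved")


# ---------------------------------------------------------------------------
# matrix surgery
# ---------------------------------------------------------------------------


def mask_partition(
    matrix: CharacterMatrix, taxa: Iterable[str], partition: Partition
) -> CharacterMatrix:
    """Copy of the matrix with every (taxon in taxa, character in partition)
    cell set to missing.  Idempotent."""
    taxa = set(taxa)
    unknown = taxa - set(matrix.taxa)
    if unknown:
        raise KeyError(f"taxa not in matrix: {sorted(unknown)}")
    bad = [c for c in partition.members if not 1 <= c <= matrix.n_chars]
    if bad:
        raise KeyError(f"character ids out of range: {sorted(bad)}")
    out = matrix.copy()
    for taxon in taxa:
        i = out.row_index(taxon)
        for cid in partition.members:
            out.rows[i][cid - 1] = MISSING
    return out


def transfer_scores(
    matrix: CharacterMatrix,
    donors: Iterable[str],
    recipient: str,
    partition: Partition,
    force: bool = False,
    drop_donors: bool = False,
) -> CharacterMatrix:
    """Give ``recipient`` the union of the donors' states on the partition.

    Conflicting donor states become polymorphisms (logged).  The recipient's
    partition cells are expected to be missing; scored cells are only
    overwritten with ``force=True`` (otherwise a warning is emitted and the
    cell is left alone).  ``drop_donors`` removes the donor rows afterwards.
    """
    donors = list(donors)
    for t in donors + [recipient]:
        if t not in matrix.taxa:
            raise KeyError(f"taxon {t!r} not in matrix")
    out = matrix.copy()
    ri = out.row_index(recipient)
    scored_any = False
    for cid in sorted(partition.members):
        union: set = set()
        seen = []
        for d in donors:
            cell = matrix.cell(d, cid)
            if cell:
                union |= cell
                seen.append((d, cell))
        if not union:
            continue
        scored_any = True
        if len({c for _, c in seen}) > 1:
            logger.info(
                "character %d: conflicting donor states %s -> polymorphism %s",
                cid,
                seen,
                sorted(union),
            )
        existing = matrix.cell(recipient, cid)
        if existing and not force:
            logger.warning(
                "recipient %s already scored for character %d; not overwriting "
                "(use force=True)",
                recipient,
                cid,
            )
            continue
        out.rows[ri][cid - 1] = frozenset(union)
    if not scored_any:
        raise ValueError("no donor carries any scored state in the partition")
    if drop_donors:
        out = out.drop_taxa(donors)
    return out


# ---------------------------------------------------------------------------
# topology queries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CladeDefinition:
    """A focal clade plus the anchor tip sets used to classify its placement.

    ``reference_tips`` maps anchor-group names to tip sets; the classifier
    uses ``gavialoids``, ``brevirostres`` and ``hylaeochampsids``, and treats
    any further groups (e.g. ``borealosuchus``, ``planocraniids``) as extra
    crown-crocodylian anchors.
    """

    name: str
    member_tips: frozenset
    reference_tips: Mapping[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_tips", frozenset(self.member_tips))
        object.__setattr__(
            self,
            "reference_tips",
            {k: frozenset(v) for k, v in self.reference_tips.items()},
        )
        for name, tips in self.reference_tips.items():
            if tips & self.member_tips:
                raise ValueError(
                    f"anchor set {name!r} overlaps the focal clade members"
                )


def classify_placement(consensus: Tree, focal: CladeDefinition) -> str:
    """Crown or basal placement of the focal clade on a (possibly polytomous)
    rooted consensus tree.

    ``crown_crocodylian``: the smallest clade containing the focal tips and
    the brevirostres anchors excludes every gavialoid anchor — the focal
    group is crownward of the gavialoid divergence.  ``basal_eusuchian``: the
    smallest clade containing focal tips and hylaeochampsid anchors excludes
    all crown (crocodylian) anchors, or the focal group attaches wholly
    outside the clade spanned by the crocodylian anchors.  Polytomies that
    prevent either call yield ``unresolved``.
    """
    tips = consensus.leaf_names
    needed = set(focal.member_tips)
    for key in ("gavialoids", "brevirostres", "hylaeochampsids"):
        needed |= set(focal.reference_tips.get(key, ()))
    absent = sorted(needed - tips)
    if absent:
        raise KeyError(f"tips absent from tree: {absent}")

    sets = consensus.clade_leafsets()
    gav = focal.reference_tips.get("gavialoids", frozenset())
    brevi = focal.reference_tips.get("brevirostres", frozenset())
    hylaeo = focal.reference_tips.get("hylaeochampsids", frozenset())
    crown_anchors = gav | brevi
    for name, extra in focal.reference_tips.items():
        if name not in {"gavialoids", "brevirostres", "hylaeochampsids"}:
            crown_anchors |= extra

    m1 = sets[consensus.mrca(focal.member_tips | brevi)]
    if gav and not (m1 & gav):
        return "crown_crocodylian"
    if hylaeo:
        m2 = sets[consensus.mrca(focal.member_tips | hylaeo)]
        if not (m2 & crown_anchors):
            return "basal_eusuchian"
    m3 = sets[consensus.mrca(crown_anchors)]
    if not (m3 & focal.member_tips):
        return "basal_eusuchian"
    return "unresolved"


def _steiner_vertices(tree: Tree, tips: frozenset) -> set:
    """Vertices of the minimal subtree connecting a set of leaf names
    (the union of the tip-to-MRCA paths)."""
    mrca = tree.mrca(tips)
    leaf_node = {lbl: n for n, lbl in tree.labels.items()}
    nodes = {mrca}
    for t in tips:
        n = leaf_node[t]
        while n not in nodes:
            nodes.add(n)
            n = tree.parent[n]
    return nodes


def monophyly_status(tree: Tree, tipset: Iterable[str]) -> str:
    """monophyletic / paraphyletic / polyphyletic under the standard convexity
    definition on the rooted tree."""
    tips = frozenset(tipset)
    if len(tips) < 2:
        raise ValueError("tipset must contain at least 2 tips")
    missing = tips - tree.leaf_names
    if missing:
        raise KeyError(f"tips not in tree: {sorted(missing)}")
    sets = tree.clade_leafsets()
    mrca = tree.mrca(tips)
    if sets[mrca] == tips:
        return "monophyletic"
    complement = sets[mrca] - tips
    green = _steiner_vertices(tree, tips)
    red = _steiner_vertices(tree, complement)
    return "paraphyletic" if not (green & red) else "polyphyletic"


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Unrooted Robinson-Foulds distance (symmetric bipartition difference)."""
    if t1.leaf_names != t2.leaf_names:
        raise ValueError(
            f"leaf sets differ: {sorted(t1.leaf_names ^ t2.leaf_names)}"
        )
    return len(t1.bipartitions() ^ t2.bipartitions())


# ---------------------------------------------------------------------------
# the three-analysis battery
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    matrix: CharacterMatrix
    partition: Partition
    masked_taxa: frozenset
    focal: CladeDefinition
    outgroup: str | None = None
    control_drop: frozenset = frozenset()  # taxa absent from the control run
    donors: tuple = ()
    recipients: tuple = ()
    drop_donors_after_transfer: bool = True
    monophyly_queries: Mapping[str, frozenset] = field(default_factory=dict)
    search: SearchConfig = field(default_factory=SearchConfig)
    seed: int = 0


@dataclass
class AnalysisResult:
    name: str
    best_length: int
    n_trees: int
    consensus: Tree
    ci: float | None
    ri: float | None
    placement: str
    monophyly: dict = field(default_factory=dict)


@dataclass
class ExperimentReport:
    analyses: dict
    rf_between: dict
    config: ExperimentConfig

    def summary(self) -> str:
        lines = []
        for name, a in self.analyses.items():
            ci = f"{a.ci:.2f}" if a.ci is not None else "NA"
            ri = f"{a.ri:.2f}" if a.ri is not None else "NA"
            lines.append(
                f"{name}: length={a.best_length} trees={a.n_trees} "
                f"CI={ci} RI={ri} placement={a.placement}"
            )
            for q, status in a.monophyly.items():
                lines.append(f"  {q}: {status}")
        for (a, b), d in self.rf_between.items():
            lines.append(f"RF({a}, {b}) = {d}")
        return "\n".join(lines)


def _analyse(
    name: str,
    matrix: CharacterMatrix,
    cfg: ExperimentConfig,
    seed: int,
) -> AnalysisResult:
    search_cfg = SearchConfig(
        n_replicates=cfg.search.n_replicates,
        hold_per_replicate=cfg.search.hold_per_replicate,
        swap=cfg.search.swap,
        seed=seed,
        max_pool=cfg.search.max_pool,
        collapse_rule=cfg.search.collapse_rule,
        early_stop_after=cfg.search.early_stop_after,
    )
    result = heuristic_search(matrix, search_cfg, outgroup=cfg.outgroup)
    cons = strict_consensus(result)
    ci, ri = ensemble_indices(result.trees, matrix)
    focal = cfg.focal
    present = focal.member_tips | set().union(*focal.reference_tips.values()) if focal.reference_tips else focal.member_tips
    if present <= cons.leaf_names:
        placement = classify_placement(cons, focal)
    else:
        placement = "unresolved"
        logger.info("%s: focal/anchor tips missing; placement not classified", name)
    mono = {}
    for qname, tips in cfg.monophyly_queries.items():
        if frozenset(tips) <= cons.leaf_names:
            mono[qname] = monophyly_status(cons, tips)
    return AnalysisResult(
        name, result.best_length, result.n_found, cons, ci, ri, placement, mono
    )


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Run the analysis battery: control (focal additions removed), full,
    partition-masked, and (when donors/recipients are configured)
    score-transferred; classify the focal placement in each and compare the
    consensus topologies."""
    analyses: dict[str, AnalysisResult] = {}
    variants: list[tuple[str, CharacterMatrix]] = []

    if cfg.control_drop:
        variants.append(("control", cfg.matrix.drop_taxa(cfg.control_drop)))
    variants.append(("full", cfg.matrix))
    variants.append(
        ("masked", mask_partition(cfg.matrix, cfg.masked_taxa, cfg.partition))
    )
    if cfg.donors and cfg.recipients:
        m = cfg.matrix
        for r in cfg.recipients:
            m = transfer_scores(m, cfg.donors, r, cfg.partition)
        if cfg.drop_donors_after_transfer:
            m = m.drop_taxa(cfg.donors)
        variants.append(("transferred", m))

    for i, (name, matrix) in enumerate(variants):
        try:
            analyses[name] = _analyse(name, matrix, cfg, seed=cfg.seed + i)
        except Exception as exc:
            raise RuntimeError(f"analysis {name!r} failed: {exc}") from exc

    rf_between = {}
    names = list(analyses)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = analyses[names[i]], analyses[names[j]]
            common = a.consensus.leaf_names & b.consensus.leaf_names
            if len(common) >= 4:
                rf_between[(names[i], names[j])] = rf_distance(
                    a.consensus.restrict(common), b.consensus.restrict(common)
                )
    return ExperimentReport(analyses, rf_between, cfg)
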