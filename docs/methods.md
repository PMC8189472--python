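# Methods

## Scope and data model

`morphosig` analyses matrices of discrete, unordered, equally weighted
morphological characters. A cell is a set of integer states (0–7): a
singleton for an ordinary observation, a multi-state set for a polymorphic
terminal, and the empty set for missing data. Both `?` and `-` map to
missing on input, the convention of the TNT program for unordered parsimony,
and matrices declaring ordered (additive) or differentially weighted
characters are rejected rather than silently reinterpreted. Character
numbering is 1-based everywhere a user sees it.

## Tree length

On a binary tree, each character is scored with the Fitch pass on bitmask
state sets: leaves are initialised to their observed sets (missing = the
character's full observed alphabet), an internal node takes the intersection
of its children's sets, or their union at the cost of one step when the
intersection is empty. The whole matrix is scored simultaneously as uint8
vectors, one set operation per internal node. A missing leaf can never force
a step, so this is equivalent to ignoring missing entries. Polymorphic
terminals are "satisfied by any member state": the terminal branch costs a
step only if the ancestral state lies outside the observed set. Tree length
is invariant to root placement (asserted by test).

Per-character bounds are computed combinatorially: the minimum `m_i` over all
topologies is (size of the smallest state set hitting every scored cell) − 1,
and the maximum `g_i` is the number of scored cells minus the best achievable
frequency of any single state; both resolve polymorphisms favourably, and
both were verified against exhaustive enumeration over all 6-taxon
topologies. The ensemble consistency index CI = Σm/S and retention index
RI = (Σg − S)/(Σg − Σm) include parsimony-uninformative characters by
default, the convention of the common parsimony programs; a flag computes the
informative-only variant since published values do not always state which
convention produced them. Characters with no observations contribute zero to
all three sums; RI is reported as undefined when Σg = Σm.

## Heuristic search

Starting trees are built by stepwise addition in a seeded random taxon order.
The incremental cost of attaching the next taxon to an edge is exact, not a
heuristic: rooting a tree on an edge e gives a Fitch root set `set(e)`, and
joining a leaf x there adds one step per character with `set(e)` disjoint
from x's set. All edge sets are obtained in one down-pass plus one rest-pass,
so an addition step is O(edges × characters) vector work. Ties go to the
first edge in a deterministic enumeration, so a seed fully determines the
tree.

Branch swapping generalises the same identity: bisecting the tree at any
edge yields two fragments whose lengths are rooting-invariant, and
reconnecting fragment edges e1 and e2 costs
`L1 + L2 + #{characters with set(e1), set(e2) disjoint}`. One broadcasted
comparison therefore scores the entire reconnection table of a bisection.
TBR enumerates all bisections and all edge pairs; SPR pins the pruned
fragment's root at its original cut; NNI restricts reconnection to edges
adjacent to the cut. Descent is steepest-first; when no neighbour improves,
up to `hold_per_replicate` equally short trees are collected by walking the
plateau, and a shorter tree found during that walk restarts the descent.
Replicates are pooled, deduplicated by unrooted topology, and optionally
condensed.

Exhaustive enumeration (`exhaustive_search`, ≤ 9 taxa) exists as a reference
implementation; on every tested instance the heuristic search reaches its
optimum, and with hold ≥ 10 a single TBR descent did too.

### Branch collapsing and tree counts

MPT counts are not comparable across programs: they depend on the collapsing
rule, the hold limit and swap order. The default rule here contracts internal
branches whose minimum length over all most-parsimonious reconstructions is
zero (akin to TNT's rule 1), and the search reports both the binary MPTs (for
scoring and synapomorphy work) and the condensed, deduplicated trees (what
consensus and support summarise). Consensus over condensed trees avoids
reporting splits that no character supports merely because a binary
representative had to resolve them somehow.

## Consensus and support

Strict consensus intersects the clade sets of the (condensed) input trees;
the result may be polytomous. Bootstrap support resamples characters with
replacement, re-runs a reduced-effort search per pseudoreplicate and counts
the fraction of pseudoreplicate consensus trees containing each queried
split; presence is judged on unrooted bipartitions so the rooting of the
query cannot bias the count, and trivial splits score 100 by construction.
Bremer (decay) values come from suboptimal-retention swapping: starting at
the MPTs, every distinct topology within `max_extra` steps of the optimum is
retained (capped, with a warning when the cap binds), and a clade's decay is
the smallest extra length among retained trees lacking it; clades that
survive the whole pool are reported censored (`> max_extra`). On small
instances the decay values match exhaustive enumeration of all topologies.

## Ancestral states and synapomorphies

For one character, a unit-cost dynamic program gives `down[v][s]` (minimum
changes in the subtree at v given v = s) and `rest[v][t]` (minimum in the
remainder given the far end of v's branch is t). The MPR set of a node — the
states it takes in at least one most-parsimonious reconstruction — is
`{s : down[v][s] + up[v][s] = L}`. A change to state s on the branch above v
occurs in some reconstruction iff `rest[v][t] + 1 + down[v][s] = L` for some
t ≠ s, and in every reconstruction iff additionally the MPR set of v is
exactly {s} and no-change (`rest[v][s] + down[v][s] = L`) is impossible.
One subtlety: a binary root is only a midpoint of the outgroup's terminal
edge, so for a root child the "far side" is the sibling subtree itself;
otherwise a change on that edge would be mis-scored as ambiguous because it
could formally sit on the edge's other half. All of this is exact (verified
against brute-force enumeration of labelings) — no ACCTRAN/DELTRAN sampling
is involved. Synapomorphies of a clade are aggregated over all supplied MPTs:
*unambiguous* if the change is forced in every reconstruction of every tree
containing the clade, *ambiguous* if it occurs in some reconstruction;
reversals nested inside the clade surface as additional records on the inner
branches.

## The partition experiment

`mask_partition` sets a character partition to missing in a chosen taxon set;
`transfer_scores` gives one taxon the union of several donors' states on a
partition (conflicts become logged polymorphisms; scored cells are preserved
unless forced). `run_experiment` chains the analyses — control (focal
additions removed), full, masked, and optionally transferred — and reports
per analysis the best length, consensus, CI/RI, the focal clade's placement
and any monophyly queries, plus pairwise RF distances between consensus trees
restricted to shared taxa.

Placement classification works on anchor tip sets: *crown* if the smallest
clade containing the focal tips and the brevirostres anchors excludes every
gavialoid anchor; *basal* if the smallest clade containing the focal tips and
the hylaeochampsid anchors excludes all crown anchors, or the focal tips fall
wholly outside the clade spanned by the crown anchors; *unresolved* when
polytomies prevent either call. Monophyly uses the standard convexity
test on the rooted tree: a non-monophyletic tip set is paraphyletic when the
minimal subtrees spanning the tips and spanning their complement within the
MRCA clade are vertex-disjoint, polyphyletic otherwise.

## The simulator

Characters evolve on a known rooted tree by a change-per-branch process:
every character receives exactly one primary change on a designated branch
(so it marks a clade of its generating tree; the branch is drawn
length-weighted when not designated), and additional changes occur per branch
with probability 1 − exp(−branch length × homoplasy rate), with a uniformly
drawn new state. This is intentionally simpler than a continuous-time Mk
process: the realised number of changes per character is recorded exactly in
the ground truth, which is what calibrating a parsimony pipeline needs. At
homoplasy 0 every character is a clean clade marker (CI = 1 on the
generating tree). Missingness is applied per cell with a per-taxon fraction,
emulating fragmentary fossil taxa. What passing tests on these matrices do
*not* show: robustness to correlated characters, rate heterogeneity across
branches, or coding practices (inapplicable states, composite characters)
found in real morphological data.

The conflict scenario builds two trees over one taxon set — an outgroup, a
basal pair, a gavialoid-like pair, crown taxa and a focal clade — differing
only in the focal attachment (sister to the crown taxa vs. sister to the
basal pair). The "postcranial" partition (default 25 characters) evolves on
the crown-placement tree, the "cranial" partition (default 40) on the
basal-placement tree; each partition carries one marker per clade of its
generating tree (two per clade for the larger cranial partition, which plays
the backbone-resolving role the cranial characters play in real matrices),
plus extra markers on the attachment clade set by `signal_strengths`
(defaults 6 crown / 1 basal, giving the full analysis a parsimony margin of
several steps in favour of the crown placement) and homoplastic fillers at
rate 0.08 per unit branch length. Setting the conflicting partition's signal
to zero routes it onto the base tree — the negative control. Focal-taxon
missingness defaults to zero in this scenario so that the control isolates
partition conflict; fossil-style missingness is exercised through
`simulate_matrix` directly.

## Problem sizes and numerics

Self-contained tests and the acceptance script use 16-taxon scenarios, 50
replicates per rate estimate, and ≤ 7-taxon instances wherever an exhaustive
oracle is the comparator; these sizes keep the whole suite under a minute
while leaving the oracles exact. States are capped at 8 per character (uint8
bitmasks); beyond that the encoder raises. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical seeds
reproduce identical matrices, searches and reports. Tie-breaking is
deterministic everywhere (ordered edge enumeration, sorted clade
construction).

## Known limitations

- Ordered/Wagner characters, step matrices, implied weighting and continuous
  characters are out of scope by design.
- Bootstrap values depend on the per-pseudoreplicate search effort; they are
  sampling estimates, not exact quantities.
- The Bremer pool is capped; censored values are lower bounds when the cap
  binds (a warning is emitted).
- Counts of most-parsimonious trees are not a stable quantity across
  programs and are deliberately not treated as a result.
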