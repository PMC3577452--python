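# Methods

## The time-sliced species tree

The species tree S is rooted and binary. Construction of the scaffold S₀
adds an auxiliary outgroup leaf d\* as a sibling of the original root under a
new root R, and a root tube d₀ entering R from above. Tubes are subdivided
into segments so that any two consecutive tubes lie in consecutive *time
slices*; d₀ forms its own topmost slice, and every slice below it contains
exactly one segment of the outgroup tube (all segments denoted d\*).
Horizontal transfers are permitted only between tubes of one slice, which is
what makes minimal-cost reconciliation polynomial.

Two slicing modes exist. In **auto** mode all leaves (including d\*) are
pushed to the common depth h = the maximum root-to-leaf edge depth, leaf
tubes absorbing the extra segments; internal tubes get one segment per
depth unit, so the number of slices is h + 1. In **explicit** mode the
integer branch "lengths" of the input Newick give per-tube segment counts;
every root-to-leaf path must then cross the same number of slices
(validated), and the outgroup tube is cut to match. The auto rule is the
package's own reading of the depth-based slicing convention: the only hard
constraints honoured are that consecutive tubes change slice, each slice has
one d\* segment, and the three-leaf caterpillar configuration yields four
slices; equalizing leaf depths is the simplest rule satisfying all three.

Aggregation back to the original ("old") tubes sums any per-segment
statistic over the segments of each tube of S.

## The event model and the dynamic program

Thirty-five elementary event types describe what a gene-tree edge e can do
inside a tube d: terminate (cohered leaf/tube; terminal transfer; terminal
gain), pass a slice boundary, speciate with or without losing one copy,
enter or bypass the root (the root tube treats the outgroup side specially),
duplicate, transfer one copy with retention, transfer without retention onto
a passing/forking/duplicating receiver, the symmetric gain family acting
from the outgroup tube (a gain is a transfer from "outside"), fall asleep
(move into d\*, whence it may later be re-gained), the origin of the whole
family (big gain, root edge at d\* only), and double transfers.

Each type has an applicability predicate over the pair ⟨e, d⟩ and a cost
rule: the sum of the child-cell values it references plus a local increment
built from seven elementary cost parameters (dimensionless units):

| parameter | default | role |
|---|---|---|
| loss | 1 | loss of one copy at a speciation or after a transfer |
| dupl | 2 | one duplication (also Phase I's c_d) |
| gain | 3 | gain from the outgroup tube |
| tr_with | 3 | transfer with retention in the donor |
| tr_without | 3 | transfer without retention |
| sleep | 1 | the gene falls dormant (moves into d\*) |
| gain_big | 0 | origin of the family below the root |

The defaults are a package choice — losses cheapest, transfers and gains
costlier, the family origin free so that late origination is not penalized —
and every interface accepts overrides; results quoted anywhere in the
documentation use these values unless stated otherwise.

The DP fills c_min(e, d) = min_i c(e, d, i) visiting gene edges from the
deepest level upward and tubes from the deepest slice upward. Within a slice
the outgroup segment is visited first for every edge except the root edge
e₀ (whose big-gain event refers to same-slice cells of e₀ itself, so d\* is
visited last for it). Three cell variants exist at d₀ — unconstrained, the
minimum over the two "leave through the outgroup" events, and the minimum
over everything else — because the duplication events at d₀ constrain their
copies through exactly these variants (an ordinary duplication forbids the
outgroup exit in both copies; the free pre-root duplication requires it in
at least one).

Transfer/gain targets d′ range over same-slice in-group tubes other than d;
ties among equally cheap targets are broken by the tube closest to d
(distance = path length between the tubes' upper vertices), then by
enumeration order; equal-cost event rows resolve to the lowest row index.
Double-transfer events minimize over ordered pairs of distinct targets
(d″ ≠ d′, both in-group) with the tie broken by the distance sum. The whole
gain family — including the gain-with-fork events — acts from d = d\* only:
a gain from an in-group tube would abandon the resident copy without a loss
charge, so the model forbids it.

Two entry points implement the same recurrences. `compute_cost_matrix`
retains per-cell candidate lists and backpointers (needed for scenarios);
`reconcile_cost` computes the cost alone, with per-(edge, slice)
best/second/third-best precomputation so that every "minimize over d′
excluding d" query is O(1) — this keeps the supertree search (thousands of
reconciliations) fast. The test suite cross-checks the two against each
other and against a naive brute-force expansion of the event table on
hundreds of random instances.

Degenerate inputs: a cell with no applicable event keeps cost +∞ (normal for
e.g. a non-leaf edge in a dormant tube with no same-slice receiver); only an
infinite root cell is an error. Gene trees must be binary (binarize first)
and every gene species must appear in the species tree.

## Scenarios

The **event tree** T is recovered by backtracking from ⟨e₀, d₀⟩; its cost
equals c_min(e₀, d₀) and also the sum of local increments along T (both
identities are asserted in tests). The mapping **β** lists, per gene edge,
the tubes of its T-vertices in root-to-leaf order plus the final event; the
path is connected in S₀ (consecutive tubes are parent/child, same-slice
donor/acceptor, or the acceptor's child).

The **k-best DAG** keeps, at every reachable cell, the k cheapest applicable
alternatives, each with conditional probability p_i given by a Boltzmann
softmin over the retained alternatives, temperature τ defaulting to the
mean elementary cost. The exact probability rule is a design decision of
this package: the model only requires that p_i decreases with cost and that
k = 1 is deterministic, and the softmin satisfies both (τ → 0 sharpens
toward the event tree, τ → ∞ flattens toward uniform over the k best).
Cohered leaf cells are sinks; non-cohered leaf cells have a single forced
alternative (terminal transfer or terminal gain) with p = 1. Unconditional
masses propagate from the root (mass 1); a binary edge forwards its full
mass to both termini, so masses are *expected inclusion counts* and may
exceed 1 after duplications — reports keep the traditional name
"probability" with this caveat.

Expectations follow the tag-triplet table: each event row emits tags
(gain, gain_big, dupl, loss, sleep, tr±o, tr±i, loss⁻) attached to an edge
and a tube. f(I, u) sums the masses of triplets with tag in I and tube u;
g(I, T) matches against a marked edge set instead; cf/cg weight each triplet
with its tag's elementary cost (tr+i/tr−i are priced as tr_with/tr_without —
the receiving-side view of the same physical event). In the composite
references of the double-transfer rows (d′&d″, e₁&e₂) each matching member
contributes half, so per-tube halves always add back to the full mass. The
second-scenario cost is the sum of cf(I, u) over all tubes with the default
tag set {gain, gain_big, dupl, loss, tr−o, tr+o, loss⁻}; note it prices
bookkeeping tags (e.g. loss⁻) separately and therefore exceeds c(G, S) even
at k = 1 whenever transfers occur.

## Supertree amalgamation

Phase I orders the clade family P by cardinality and computes, per basic
set V, the best partition cost
c(V) = c(V₁) + c(V₂) + c_d·(|R(V₁)|+|R(V₂)|−|R(V)|−|r(V₁,V₂)|)
     + c_l·(|R(V₁)|+|R(V₂)|−2|r(V₁,V₂)|),
the basic tree S(V), the second-best partition cost c(V′) and the weight
w(V) = 1 + (c/(a·m))·(c(V′)−c(V))/c(V′) (c = 10 by default, a = leaves of
S(V), m = total species; w(V) = 1 when no second partition exists or
c(V′) = 0, including exact ties). Good vertices use the parent-clade rule on
binary trees and the child-based rule on polytomous ones (different sets,
equal cardinality on binary trees — property-tested). Partition enumeration
scans V₁ ∈ P inside V with symmetric pairs deduplicated; equal-cost
partitions resolve to the lexicographically smallest V₁. Basic trees with
fewer than three leaves are excluded from Phase II. If V₀ is not basic a
warning is issued and Phase II proceeds on the available basic trees.

One sharpening of the exactness statement emerged during verification: the
clade DP never charges duplications occurring *inside terminal tubes*
(within-species paralog clusters), because those are invariant across all
candidate topologies. Hence c(V₀) equals the exhaustive constrained minimum
of the total duplication-loss cost minus that constant — and equals it
verbatim whenever no gene tree contains a same-species paralog cluster. The
acceptance test asserts the corrected identity on random forests (m ≤ 6,
against full topology enumeration) and the verbatim one when the constant
vanishes. Relatedly, the duplication-loss limit of the tube model charges
losses from the species root down to the family's origination vertex (a
family confined to a subtree must have been lost on the stem unless gained),
which the independent LCA-mapping oracle reproduces.

Phase II seeds with the cheapest rooted triplet (all 3-subsets × 3
topologies), then repeatedly inserts the (species, position) pair minimizing
Σ w(V)·c(S′(V), T) over eligible basic trees, where S′(V) is S(V) pruned to
the candidate's species and the cost is the tube-model reconciliation cost
(the weighting is on by default; the insertion is jointly greedy over
species and position). Ties fall back to enumeration order, so the whole
pipeline is deterministic. Pruned basic trees with fewer than two leaves
contribute zero.

## The simulator

`simulate` emulates gene families evolving along S₀: one lineage starts in
the in-group root tube; per tube traversal it duplicates with p_dup (both
copies redo the tube step), dies with p_loss, or jumps to a uniform
same-slice non-outgroup tube with p_tr (without retention), otherwise
following speciation. Defaults (p_dup = p_loss = 0.02, p_tr = 0.01, n = 50
trees) describe a low-event regime in which most gene trees are congruent
with the species tree — the regime in which supertree recovery experiments
are meaningful. Families extinct everywhere or surviving as a single leaf
are redrawn.

What the simulator does *not* emulate: gene sequences and reconstruction
error (input trees are error-free), rate heterogeneity among families,
within-tube event timing (at most one event per lineage per tube step,
except repeated duplication), transfers with retention, and gains from
outside the species set. Passing recovery tests therefore show that the
pipeline inverts its own generative model at realistic event densities, not
that it is robust to phylogenetic reconstruction noise.

With zero rates every simulated tree reconciles at cost 0 against the
generating tree (tested). With 8 species, 50 trees and default rates, the
full pipeline recovers the generating topology in ≈ 95% of seeded
replicates; the Phase II functional occasionally (≈ 1 replicate in 20)
genuinely prefers an alternative topology on noisy forests — Phase I alone
recovered the truth in every replicate observed.

## Problem sizes and numerics

The test suite and the acceptance script run on one CPU in a few minutes:
brute-force cross-validation uses instances with ≤ 4 species and ≤ 4 gene
leaves (500 instances), Phase I enumeration uses m ≤ 6 (≤ 945 topologies),
and recovery uses m = 8, n = 50 with 20 replicates. Costs are floats;
equality tie-breaks use exact comparison (deterministic because tied
alternatives are sums of identical literals); probability conservation is
asserted to 1e−12 and cost identities to 1e−9. Seeds control every random
draw; identical inputs and seeds give byte-identical outputs.

## Known limitations

* Unrooted-tree rooting and polytomy resolution are this package's own
  greedy, cost-driven rules; other implementations of the model may resolve
  differently.
* The DAG probability rule (softmin) and its temperature are package
  choices; expectation *values* at k > 1 are therefore comparable only
  within this package, although the k = 1 limit and all conservation
  properties are rule-independent.
* Phase II is a greedy heuristic; it can return a local optimum of its
  scoring functional (and the functional itself is not the total
  reconciliation cost it is ultimately judged by).
* Non-binary species trees, calibrated (chronogram) slicing, NEXUS/PhyloXML
  dialects, branch-length-aware rooting and MPI parallelism are out of
  scope.
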