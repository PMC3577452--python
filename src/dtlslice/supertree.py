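"""Supertree amalgamation over a fixed clade family P.

Phase I is a dynamic program over P (ordered by cardinality): a set V is
*basic* if it is a singleton or splits into two disjoint basic sets from P.
For each basic V the best partition <V1, V2> minimizes

    c(V) = c(V1) + c(V2) + C_d + C_l

where the duplication and loss totals on the corresponding tube are counted
through the *good vertex* sets R(V) of the gene trees:

    C_d = c_d (|R(V1)| + |R(V2)| - |R(V)| - |r(V1, V2)|)
    C_l = c_l (|R(V1)| + |R(V2)| - 2 |r(V1, V2)|)

A vertex is good w.r.t. V when its clade fits inside V but its parent's does
not (the root: when its clade fits); r(V1, V2) are vertices speciating
exactly across the partition. When only duplications and losses are charged
and the full species set V_0 is basic, c(V_0) is the exact global minimum of
the total reconciliation cost over all species trees whose clades lie in P.

Phase II greedily assembles the supertree S*: seed with the cheapest rooted
triplet, then repeatedly insert the (species, position) pair minimizing the
total (optionally weight w(V)-multiplied) cost of reconciling the pruned
basic trees into the candidate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .events import EventCosts
from .reconcile import reconcile_cost, total_cost
from .timeslice import SpNode, attach_outgroup, build_slices
from .treeio import Forest, GeneNode, GeneTree


# ---------------------------------------------------------------------------
# The clade family P


@dataclass
class CladeSet:
    sets: list[frozenset[str]]          # ordered by ascending cardinality
    provenance: dict[frozenset[str], str]

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, V) -> bool:
        return V in self.provenance

    def __len__(self) -> int:
        return len(self.sets)


def build_clade_set(forest: Forest, with_transfer_sets: bool = False) -> CladeSet:
    """Standard P: all clades of all gene trees plus V_0; optionally the
    transfer-difference sets of overlapping noncomparable clades."""
    if not len(forest):
        raise ValueError("forest is empty")
    prov: dict[frozenset[str], str] = {}
    for tree in forest:
        for node in tree.nodes:
            prov.setdefault(node.clade, "clade")
    V0 = forest.species_universe()
    if V0 not in prov:
        prov[V0] = "V0"
    if with_transfer_sets:
        for tree in forest:
            nodes = tree.nodes
            ancestors: dict[int, set[int]] = {}

            def walk(n: GeneNode, anc: tuple) -> None:
                ancestors[n.index] = set(anc)
                for c in n.children:
                    walk(c, anc + (n.index,))

            walk(tree.root, ())
            for v1, v2 in itertools.combinations(nodes, 2):
                if v1.index in ancestors[v2.index] or v2.index in ancestors[v1.index]:
                    continue
                inter = v1.clade & v2.clade
                if not inter:
                    continue
                for vi, vj in ((v1, v2), (v2, v1)):
                    diff = vi.clade - inter
                    if diff:
                        prov.setdefault(diff, "transfer")
                    # ancestors of vi that are not ancestors of vj
                    for anc in nodes:
                        if (anc.index in ancestors[vi.index]
                                and anc.index not in ancestors[vj.index]):
                            d2 = anc.clade - vi.clade
                            if d2:
                                prov.setdefault(d2, "transfer")
    ordered = sorted(prov, key=lambda s: (len(s), tuple(sorted(s))))
    return CladeSet(ordered, prov)


# ---------------------------------------------------------------------------
# Good vertices


def good_vertices(tree: GeneTree, V: frozenset[str],
                  rule: str = "auto") -> set[int]:
    """Indices of the good vertices of one gene tree w.r.t. V.

    Binary trees: a non-root vertex is good when its clade fits inside V but
    its parent's does not; the root when its clade fits. Polytomous trees: a
    vertex is good when at least one child's clade fits inside V while the
    vertex's own does not; the super-root (index -1) when the root clade fits
    (the two definitions give differing sets of equal cardinality on binary
    trees). ``rule`` forces one of the two definitions ("binary" /
    "polytomous"); "auto" selects by the tree's shape.
    """
    if rule not in ("auto", "binary", "polytomous"):
        raise ValueError(f"unknown rule {rule!r}")
    out: set[int] = set()
    use_binary = tree.is_binary() if rule == "auto" else rule == "binary"
    if use_binary:
        for node in tree.nodes:
            if node.parent is None:
                if node.clade <= V:
                    out.add(node.index)
            elif node.clade <= V and not (node.parent.clade <= V):
                out.add(node.index)
    else:
        # super-root: index -1
        if tree.root.clade <= V:
            out.add(-1)
        for node in tree.nodes:
            if node.clade <= V:
                continue
            if any(c.clade <= V for c in node.children):
                out.add(node.index)
    return out


def _good_child_sets(tree: GeneTree, V: frozenset[str]) -> set[int]:
    """Vertices obeying the child condition: clade inside V, parent's not
    (root counts when its clade fits). Used to build r(V1, V2)."""
    out: set[int] = set()
    for node in tree.nodes:
        if node.parent is None:
            if node.clade <= V:
                out.add(node.index)
        elif node.clade <= V and not (node.parent.clade <= V):
            out.add(node.index)
    return out


def pair_vertices(tree: GeneTree, V1: frozenset[str], V2: frozenset[str],
                  good1: Optional[set[int]] = None,
                  good2: Optional[set[int]] = None) -> set[int]:
    """r(V1, V2) in one tree: vertices with one child good for V1 and another
    good for V2 (for polytomies: at least one child obeying each condition)."""
    if V1 & V2:
        raise ValueError("V1 and V2 must be disjoint")
    if good1 is None:
        good1 = _good_child_sets(tree, V1)
    if good2 is None:
        good2 = _good_child_sets(tree, V2)
    out: set[int] = set()
    for node in tree.nodes:
        if not node.children:
            continue
        has1 = any(c.index in good1 for c in node.children)
        has2 = any(c.index in good2 for c in node.children)
        if has1 and has2:
            out.add(node.index)
    return out


# ---------------------------------------------------------------------------
# Phase I


@dataclass
class BasicRecord:
    V: frozenset[str]
    basic: bool
    cost: float = 0.0
    partition: Optional[tuple[frozenset, frozenset]] = None
    second_cost: Optional[float] = None
    tree: Optional[SpNode] = None
    weight: float = 1.0
    eligible: bool = False  # >= 3 leaves, enters Phase II

    @property
    def newick(self) -> Optional[str]:
        return self.tree.newick() if self.tree is not None else None


@dataclass
class Phase1Result:
    records: dict[frozenset, BasicRecord]
    v0: frozenset
    condition_star: bool

    def basic_trees(self) -> list[BasicRecord]:
        return [r for r in self.records.values() if r.basic and r.eligible]


def _leaf_tree(species: str) -> SpNode:
    return SpNode(species)


def _join_trees(t1: SpNode, t2: SpNode) -> SpNode:
    root = SpNode()
    root.add(t1.copy())
    root.add(t2.copy())
    return root


def phase1(forest: Forest, P: Optional[CladeSet] = None,
           costs: Optional[EventCosts] = None,
           weight_c: float = 10.0) -> Phase1Result:
    """Bottom-up construction of the basic trees S(V), costs c(V), weights."""
    if costs is None:
        costs = EventCosts()
    if P is None:
        P = build_clade_set(forest)
    c_d, c_l = costs.dupl, costs.loss
    v0 = forest.species_universe()
    m = len(v0)

    # |R(V)| and per-tree good-child sets, cached per member of P
    trees = list(forest)
    good_cache: dict[frozenset, list[set[int]]] = {}
    R_size: dict[frozenset, int] = {}
    for V in P:
        gsets = [_good_child_sets(t, V) for t in trees]
        good_cache[V] = gsets
        R_size[V] = sum(len(good_vertices(t, V)) for t in trees)

    records: dict[frozenset, BasicRecord] = {}
    members = list(P)
    member_set = set(members)
    for V in members:
        if len(V) == 1:
            (s,) = V
            rec = BasicRecord(V, True, 0.0, None, None, _leaf_tree(s), 1.0)
            records[V] = rec
            continue
        best = None          # (cost, key, V1, V2)
        second = None
        seen_partitions = set()
        for V1 in members:
            if len(V1) >= len(V) or not (V1 < V):
                continue
            V2 = V - V1
            if V2 not in member_set:
                continue
            r1, r2 = records.get(V1), records.get(V2)
            if r1 is None or r2 is None or not r1.basic or not r2.basic:
                continue
            lo, hi = sorted((V1, V2), key=lambda s: tuple(sorted(s)))
            if (lo, hi) in seen_partitions:
                continue
            seen_partitions.add((lo, hi))
            r_size = sum(
                len(pair_vertices(t, V1, V2, good_cache[V1][i], good_cache[V2][i]))
                for i, t in enumerate(trees)
            )
            C_d = c_d * (R_size[V1] + R_size[V2] - R_size[V] - r_size)
            C_l = c_l * (R_size[V1] + R_size[V2] - 2 * r_size)
            cost = records[V1].cost + records[V2].cost + C_d + C_l
            key = (cost, tuple(sorted(lo)))
            cand = (cost, key, lo, hi)
            if best is None or key < best[1]:
                if best is not None:
                    second = best if second is None or best[1] < second[1] else second
                best = cand
            elif second is None or key < second[1]:
                second = cand
        if best is None:
            records[V] = BasicRecord(V, False)
            continue
        cost, _, V1, V2 = best
        tree = _join_trees(records[V1].tree, records[V2].tree)
        a = len(V)
        if second is None or second[0] <= 0:
            w = 1.0
        else:
            w = 1.0 + (weight_c / (a * m)) * (second[0] - cost) / second[0]
        rec = BasicRecord(V, True, cost, (V1, V2),
                          None if second is None else second[0], tree, w)
        records[V] = rec

    for rec in records.values():
        if rec.basic and rec.tree is not None and len(rec.V) >= 3:
            rec.eligible = True

    star = v0 in records and records[v0].basic
    if not star:
        warnings.warn(
            "the full species set V_0 is not basic (condition (*) fails); "
            "Phase II will run on the available basic trees", stacklevel=2)
    return Phase1Result(records, v0, star)


# ---------------------------------------------------------------------------
# Phase II


def _prune_species_tree(node: SpNode, keep: frozenset[str]) -> Optional[SpNode]:
    if node.is_leaf:
        return SpNode(node.name) if node.name in keep else None
    kept = [c for c in (_prune_species_tree(ch, keep) for ch in node.children) if c]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    out = SpNode(node.name)
    for c in kept:
        out.add(c)
    return out


def _as_gene_tree(sp: SpNode) -> GeneTree:
    def rec(n: SpNode) -> GeneNode:
        if n.is_leaf:
            return GeneNode(n.name, "0")
        g = GeneNode()
        for c in n.children:
            g.add(rec(c))
        return g

    return GeneTree(rec(sp))


def basic_tree_cost(SV: SpNode, S: SpNode, costs: Optional[EventCosts] = None,
                    S0=None) -> float:
    """Cost of mapping the basic tree S(V), pruned to the leaf species of S,
    into the sliced version of S. Pruned trees with < 2 leaves cost 0."""
    if costs is None:
        costs = EventCosts()
    W = frozenset(l.name for l in S.leaves())
    pruned = _prune_species_tree(SV, W)
    if pruned is None or pruned.is_leaf:
        return 0.0
    if S0 is None:
        S0 = build_slices(attach_outgroup(S.copy()))
    return reconcile_cost(_as_gene_tree(pruned), S0, costs)


@dataclass
class SupertreeResult:
    tree: SpNode
    steps: list[str] = field(default_factory=list)
    weighted_basic_cost: float = 0.0
    total_cost: Optional[float] = None

    @property
    def newick(self) -> str:
        return self.tree.newick()


def _candidate_positions(root: SpNode) -> list[Optional[SpNode]]:
    """Insertion positions: above the root (None) plus every edge (its lower
    vertex), in preorder. The root's own "edge" is the above-root position."""
    return [None] + [n for n in root.preorder() if n is not root]


def _insert(root: SpNode, position: Optional[SpNode], species: str) -> SpNode:
    """New tree with a vertex a on the given edge joining the new species."""
    marker = position

    def rec(n: SpNode) -> SpNode:
        m = SpNode(n.name, n.segments)
        for c in n.children:
            cc = rec(c)
            if c is marker:
                a = SpNode()
                a.add(cc)
                a.add(SpNode(species))
                m.add(a)
            else:
                m.add(cc)
        return m

    new_root = rec(root)
    if position is None:
        a = SpNode()
        a.add(new_root)
        a.add(SpNode(species))
        return a
    return new_root


def _score_candidate(T: SpNode, basics: Sequence[tuple[SpNode, float]],
                     costs: EventCosts) -> float:
    S0 = build_slices(attach_outgroup(T.copy()))
    W = frozenset(l.name for l in T.leaves())
    total = 0.0
    cache: dict[str, float] = {}
    for SV, w in basics:
        pruned = _prune_species_tree(SV, W)
        if pruned is None or pruned.is_leaf:
            continue
        key = pruned.newick()
        if key not in cache:
            cache[key] = reconcile_cost(_as_gene_tree(pruned), S0, costs)
        total += w * cache[key]
    return total


def phase2(result: Phase1Result, costs: Optional[EventCosts] = None,
           use_weights: bool = True) -> SupertreeResult:
    """Greedy assembly of the supertree from the weighted basic trees."""
    if costs is None:
        costs = EventCosts()
    v0 = sorted(result.v0)
    basics = [(r.tree, r.weight if use_weights else 1.0)
              for r in result.basic_trees()]
    steps: list[str] = []

    if len(v0) <= 2:
        if len(v0) == 1:
            tree = SpNode(v0[0])
        else:
            tree = _join_trees(SpNode(v0[0]), SpNode(v0[1]))
        return SupertreeResult(tree, ["trivial seed"],
                               _score_candidate(tree, basics, costs)
                               if len(v0) == 2 else 0.0)

    # seed: the cheapest rooted triplet over all 3-subsets and topologies
    best = None
    for trio in itertools.combinations(v0, 3):
        a, b, c = trio
        for out_sp, pair in ((c, (a, b)), (b, (a, c)), (a, (b, c))):
            cand = _join_trees(_join_trees(SpNode(pair[0]), SpNode(pair[1])),
                               SpNode(out_sp))
            score = _score_candidate(cand, basics, costs)
            if best is None or score < best[0]:
                best = (score, cand, trio)
    score, tree, trio = best
    steps.append(f"seed {tree.newick()} cost {score:g}")
    placed = set(trio)

    while len(placed) < len(v0):
        best = None
        order = 0
        for s in v0:
            if s in placed:
                continue
            for pos in _candidate_positions(tree):
                cand = _insert(tree, pos, s)
                sc = _score_candidate(cand, basics, costs)
                if best is None or sc < best[0]:
                    best = (sc, cand, s, order)
                order += 1
        sc, tree, s, _ = best
        placed.add(s)
        steps.append(f"insert {s} -> {tree.newick()} cost {sc:g}")

    return SupertreeResult(tree, steps, _score_candidate(tree, basics, costs))


def amalgamation_cost(forest: Forest, S: SpNode,
                      costs: Optional[EventCosts] = None) -> float:
    """Total reconciliation cost of the forest against S (sliced on the fly)."""
    if costs is None:
        costs = EventCosts()
    S0 = build_slices(attach_outgroup(S.copy()))
    return total_cost(forest, S0, costs)


def build_supertree(forest: Forest, costs: Optional[EventCosts] = None,
                    p_min: int = 0, with_transfer_sets: bool = False,
                    use_weights: bool = True, weight_c: float = 10.0
                    ) -> tuple[Phase1Result, SupertreeResult]:
    """Full pipeline: optional pruning, Phase I, Phase II, total cost."""
    from .treeio import prune_rare_species

    if costs is None:
        costs = EventCosts()
    if p_min > 0:
        forest = prune_rare_species(forest, p_min)
    if not len(forest):
        raise ValueError("no gene trees left after pruning")
    P = build_clade_set(forest, with_transfer_sets)
    ph1 = phase1(forest, P, costs, weight_c)
    ph2 = phase2(ph1, costs, use_weights)
    ph2.total_cost = amalgamation_cost(forest, ph2.tree, costs)
    return ph1, ph2
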