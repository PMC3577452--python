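"""Second scenario: a random process on the k-best event DAG.

Instead of keeping only the minimal event at every pair <e, d>, the k
cheapest applicable alternatives are retained and weighted with a Boltzmann
softmin: p_i ∝ exp(-(c_i - c_min)/tau). At k = 1 the DAG degenerates to the
event tree with all probabilities in {0, 1}. The unconditional mass p(e, d, i)
of a DAG edge is the expected number of times the branching process includes
that edge (a binary edge forwards its full mass to both termini, so masses
may exceed 1 after duplications).

Expectations of event counts and costs are taken over the tag triplets of
the event-definition table: f(I, u) counts events with tags in I inside tube
u, g(I, T) counts events with tags in I on a marked edge set T, and cf / cg
are the cost-weighted versions. The second-scenario cost is the sum of
cf(I, u) over all tubes for the default tag set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .events import (DEFAULT_SCENARIO_TAGS, EventCosts, TAG_TABLE, TAGS,
                     tag_cost)
from .reconcile import ALL, Candidate, CostMatrix, compute_cost_matrix
from .timeslice import SlicedSpeciesTree
from .treeio import Forest, GeneNode, GeneTree


@dataclass
class DagEdge:
    row: int
    cost: float
    params: dict
    termini: tuple  # of vertex keys
    p: float = 0.0      # conditional probability
    mass: float = 0.0   # unconditional p(e, d, i)


@dataclass
class DagVertex:
    e: GeneNode
    d: int
    mode: str
    edges: list[DagEdge] = field(default_factory=list)
    mass: float = 0.0


class ScenarioDAG:
    def __init__(self, G: GeneTree, S0: SlicedSpeciesTree, costs: EventCosts,
                 k: int, tau: float):
        self.G = G
        self.S0 = S0
        self.costs = costs
        self.k = k
        self.tau = tau
        self.vertices: dict[tuple[int, int, str], DagVertex] = {}
        self.root_key = (G.root.index, S0.d0, ALL)

    def topological(self) -> list[DagVertex]:
        """Root-first order (every edge goes from earlier to later)."""
        seen: set[tuple[int, int, str]] = set()
        order: list[tuple[int, int, str]] = []

        def rec(key) -> None:
            if key in seen:
                return
            seen.add(key)
            for edge in self.vertices[key].edges:
                for t in edge.termini:
                    rec(t)
            order.append(key)

        rec(self.root_key)
        return [self.vertices[k] for k in reversed(order)]


def _mode_filter(cands: Sequence[Candidate], d: int, d0: int, mode: str):
    if d != d0:
        return list(cands)
    if mode == "out":
        return [c for c in cands if c.row in (10, 11)]
    if mode == "noout":
        return [c for c in cands if c.row not in (10, 11)]
    return list(cands)


def build_dag(G: GeneTree, S0: SlicedSpeciesTree,
              costs: Optional[EventCosts] = None, k: int = 10,
              tau: Optional[float] = None,
              matrix: Optional[CostMatrix] = None) -> ScenarioDAG:
    """Construct the k-best DAG rooted at <e_0, d_0> and assign p_i."""
    if costs is None:
        costs = EventCosts()
    if k < 1:
        raise ValueError("ramification degree k must be >= 1")
    if tau is None:
        tau = costs.mean() or 1.0
    if tau <= 0:
        raise ValueError("softmin temperature tau must be > 0")
    if matrix is None:
        matrix = compute_cost_matrix(G, S0, costs)
    dag = ScenarioDAG(G, S0, costs, k, tau)
    node_of = {n.index: n for n in G.nodes}

    def rec(key) -> None:
        if key in dag.vertices:
            return
        ei, d, mode = key
        v = DagVertex(node_of[ei], d, mode)
        dag.vertices[key] = v
        cands = _mode_filter(matrix.cands[(ei, d)], d, S0.d0, mode)
        cands = sorted(cands, key=lambda c: (c.cost, c.row))[:k]
        if len(cands) == 1 and cands[0].row == 0:
            return  # cohered leaf pair: sink
        if not cands:
            return
        cmin = cands[0].cost
        weights = [math.exp(-(c.cost - cmin) / tau) for c in cands]
        z = sum(weights)
        for c, w in zip(cands, weights):
            termini = tuple((te.index, td, tmode) for (te, td, tmode) in c.termini)
            v.edges.append(DagEdge(c.row, c.cost, c.params, termini, p=w / z))
            for t in termini:
                rec(t)

    rec(dag.root_key)
    return dag


def propagate_mass(dag: ScenarioDAG) -> ScenarioDAG:
    """Unconditional masses: root = 1; edge mass = vertex mass x p_i; binary
    edges deliver their full mass to both termini."""
    for v in dag.vertices.values():
        v.mass = 0.0
    order = dag.topological()
    dag.vertices[dag.root_key].mass = 1.0
    for v in order:
        for edge in v.edges:
            edge.mass = v.mass * edge.p
            for t in edge.termini:
                dag.vertices[t].mass += edge.mass
    return dag


# ---------------------------------------------------------------------------
# Tag triplet instantiation and expectations


def _resolve_tube(ref: str, v_d: int, params: dict, S0: SlicedSpeciesTree):
    if ref == "d":
        return v_d
    if ref in ("d1", "d2"):
        return S0.children[v_d][0 if ref == "d1" else 1]
    if ref == "d'":
        return params["dp"]
    if ref == "d''":
        return params["dpp"]
    if ref in ("d'1", "d'2"):
        return S0.children[params["dp"]][0 if ref == "d'1" else 1]
    if ref == "x":
        return params["x"]
    if ref == "d'&d''":
        return (params["dp"], params["dpp"])
    raise ValueError(f"unknown tube reference {ref!r}")


def _resolve_edge(ref: str, e: GeneNode):
    if ref == "e":
        return e
    if ref == "e1":
        return e.children[0]
    if ref == "e2":
        return e.children[1]
    if ref == "e1&e2":
        return (e.children[0], e.children[1])
    raise ValueError(f"unknown edge reference {ref!r}")


def iter_tagged(dag: ScenarioDAG):
    """Yield (tag, edge-or-pair, tube-or-pair, mass, elementary cost) for
    every tag triplet of every DAG edge."""
    for v in dag.vertices.values():
        for edge in v.edges:
            for (tag, eref, dref) in TAG_TABLE[edge.row]:
                yield (tag, _resolve_edge(eref, v.e),
                       _resolve_tube(dref, v.d, edge.params, dag.S0),
                       edge.mass, tag_cost(tag, dag.costs))


def _check_tags(I: Iterable[str]) -> frozenset:
    I = frozenset(I)
    unknown = I - TAGS
    if unknown:
        raise ValueError(f"unknown event tags: {sorted(unknown)}")
    return I


def _tube_weight(tube_ref, u: int) -> float:
    if isinstance(tube_ref, tuple):  # composite d'&d'': halved per member
        return 0.5 * ((tube_ref[0] == u) + (tube_ref[1] == u))
    return 1.0 if tube_ref == u else 0.0


def _edge_weight(edge_ref, T: frozenset) -> float:
    if isinstance(edge_ref, tuple):  # composite e1&e2: halved per member
        return 0.5 * ((edge_ref[0] in T) + (edge_ref[1] in T))
    return 1.0 if edge_ref in T else 0.0


def expect_in_tube(dags: Sequence[ScenarioDAG], I: Iterable[str], u: int,
                   weighted: bool = False) -> float:
    """f(I, u): expected number of I-tagged events in tube u (cf(I, u) when
    *weighted*, i.e. each event weighted with its elementary cost)."""
    I = _check_tags(I)
    total = 0.0
    for dag in dags:
        for tag, _eref, dref, mass, c in iter_tagged(dag):
            if tag in I:
                w = _tube_weight(dref, u)
                if w:
                    total += w * mass * (c if weighted else 1.0)
    return total


def marked_edge_set(G: GeneTree, marked_leaves: Iterable[str]) -> frozenset:
    """Edges of G all of whose descendant leaves carry marked labels."""
    marked = set(marked_leaves)
    out: set[GeneNode] = set()

    def rec(n: GeneNode) -> bool:
        if n.is_leaf:
            ok = n.label in marked
        else:
            oks = [rec(c) for c in n.children]
            ok = all(oks)
        if ok:
            out.add(n)
        return ok

    rec(G.root)
    return frozenset(out)


def expect_on_edges(dags: Sequence[ScenarioDAG], I: Iterable[str],
                    T: Iterable[GeneNode], weighted: bool = False) -> float:
    """g(I, T): expected number of I-tagged events on the marked edges T
    (cg(I, T) when *weighted*)."""
    I = _check_tags(I)
    T = frozenset(T)
    total = 0.0
    for dag in dags:
        for tag, eref, _dref, mass, c in iter_tagged(dag):
            if tag in I:
                w = _edge_weight(eref, T)
                if w:
                    total += w * mass * (c if weighted else 1.0)
    return total


def expect_costs(dags: Sequence[ScenarioDAG], I: Iterable[str], *,
                 u: Optional[int] = None, T: Optional[Iterable] = None) -> float:
    """cf(I, u) or cg(I, T): cost-weighted expectations."""
    if (u is None) == (T is None):
        raise ValueError("provide exactly one of u (a tube) or T (edges)")
    if u is not None:
        return expect_in_tube(dags, I, u, weighted=True)
    return expect_on_edges(dags, I, T, weighted=True)


def scenario_cost(dags: Sequence[ScenarioDAG],
                  I: Optional[Iterable[str]] = None) -> float:
    """Cost of the second scenario: sum of cf(I, u) over all tubes u."""
    I = _check_tags(DEFAULT_SCENARIO_TAGS if I is None else I)
    total = 0.0
    for dag in dags:
        for tag, _eref, _dref, mass, c in iter_tagged(dag):
            if tag in I:
                total += mass * c
    return total


def per_tube_table(dags: Sequence[ScenarioDAG], I: Iterable[str]):
    """f and cf per tube, as {tube index: (f, cf)}."""
    I = _check_tags(I)
    if not dags:
        return {}
    S0 = dags[0].S0
    table = {d: [0.0, 0.0] for d in range(S0.n_tubes)}
    for dag in dags:
        for tag, _eref, dref, mass, c in iter_tagged(dag):
            if tag not in I:
                continue
            refs = dref if isinstance(dref, tuple) else (dref,)
            w = 0.5 if isinstance(dref, tuple) else 1.0
            for r in refs:
                table[r][0] += w * mass
                table[r][1] += w * mass * c
    return {d: tuple(v) for d, v in table.items()}


def forest_dags(forest: Forest, S0: SlicedSpeciesTree,
                costs: Optional[EventCosts] = None, k: int = 10,
                tau: Optional[float] = None) -> list[ScenarioDAG]:
    """Build and mass-propagate one DAG per gene tree."""
    return [propagate_mass(build_dag(G, S0, costs, k, tau)) for G in forest]


# ---------------------------------------------------------------------------
# Deterministic event counting on an event tree (first scenario side)


def event_tree_tags(T) -> list[tuple[str, object, object, float]]:
    """Tag triplets of a first-scenario event tree, each with weight 1
    (same resolution rules as the DAG; used for reports and for the k = 1
    collapse checks)."""
    S0 = T.matrix.S0
    out = []
    for node in T.walk():
        for (tag, eref, dref) in TAG_TABLE[node.row]:
            out.append((tag, _resolve_edge(eref, node.e),
                        _resolve_tube(dref, node.d, node.params, S0),
                        tag_cost(tag, T.matrix.costs)))
    return out


def count_in_tube(T, I: Iterable[str], u: int, weighted: bool = False) -> float:
    I = _check_tags(I)
    total = 0.0
    for tag, _e, dref, c in event_tree_tags(T):
        if tag in I:
            total += _tube_weight(dref, u) * (c if weighted else 1.0)
    return total


def count_on_edges(T, I: Iterable[str], edges, weighted: bool = False) -> float:
    I = _check_tags(I)
    edges = frozenset(edges)
    total = 0.0
    for tag, eref, _d, c in event_tree_tags(T):
        if tag in I:
            total += _edge_weight(eref, edges) * (c if weighted else 1.0)
    return total
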