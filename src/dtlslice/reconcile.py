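"""Reconciliation of a binary gene tree into a time-sliced species tree.

The conditional cost c_min(e, d) — the cost of an optimal scenario that
starts with gene edge e entering tube d — is computed by dynamic programming
over the 35 elementary event types. Edges are visited from the deepest level
of the gene tree upwards, tubes from the deepest time slice upwards; within a
slice the outgroup segment d* is visited first for every edge except the root
edge e_0, for which it is visited last (the big-gain event refers to
same-slice cells of e_0 itself). The value c_min(e_0, d_0) is the
reconciliation cost c(G, S).

Three special cell variants exist at the root tube d_0: the unconstrained
minimum, the minimum over the two "gene leaves the root through the
outgroup" events (out_l / out_r), and the minimum over everything else.
The duplication events at d_0 constrain their children through these
variants (an ordinary duplication forbids out in both copies; the free
pre-root duplication requires out in at least one).

Two entry points are provided: :func:`compute_cost_matrix` fills the full
matrix with backpointers and per-cell candidate lists (used for scenario
construction), and :func:`reconcile_cost` computes the cost alone with
per-(edge, slice) best/second-best precomputation, which keeps the supertree
search fast. The two are cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .events import EventCosts, EVENT_NAMES, row_increment
from .timeslice import SlicedSpeciesTree
from .treeio import Forest, GeneNode, GeneTree

INF = math.inf

ALL, OUT, NOOUT = "all", "out", "noout"


class ReconciliationError(ValueError):
    pass


def _check_species(G: GeneTree, S0: SlicedSpeciesTree) -> None:
    missing = sorted(G.species_set() - set(S0.terminal_tube))
    if missing:
        raise ReconciliationError(
            "gene-tree species absent from the species tree: " + ", ".join(missing)
        )


def _eval_order(G: GeneTree) -> list[GeneNode]:
    depth = {G.root.index: 0}
    for node in G.nodes:
        for ch in node.children:
            depth[ch.index] = depth[node.index] + 1
    return sorted(G.nodes, key=lambda n: -depth[n.index])


# ---------------------------------------------------------------------------
# Full matrix with backpointers


@dataclass
class Candidate:
    cost: float
    row: int
    params: dict
    termini: tuple  # of (GeneNode, tube index, mode)

    @property
    def name(self) -> str:
        return EVENT_NAMES[self.row]


class CostMatrix:
    """c_min(e, d) for every gene edge x tube, with winning events."""

    def __init__(self, G: GeneTree, S0: SlicedSpeciesTree, costs: EventCosts):
        self.G = G
        self.S0 = S0
        self.costs = costs
        n, m = len(G.nodes), S0.n_tubes
        self.c = [[INF] * m for _ in range(n)]
        self.c_out = [INF] * n
        self.c_noout = [INF] * n
        # (e index, d index, mode) -> Candidate
        self.bp: dict[tuple[int, int, str], Candidate] = {}
        # (e index, d index) -> list[Candidate] (all applicable alternatives)
        self.cands: dict[tuple[int, int], list[Candidate]] = {}

    @property
    def cost(self) -> float:
        return self.c[self.G.root.index][self.S0.d0]

    def value(self, e: GeneNode, d: int, mode: str = ALL) -> float:
        if d == self.S0.d0:
            if mode == OUT:
                return self.c_out[e.index]
            if mode == NOOUT:
                return self.c_noout[e.index]
        return self.c[e.index][d]


def _argmin_tube(entries, d, S0):
    """Pick (cost, tube, payload) minimizing cost; ties resolved by the tube
    closest to d, then by enumeration order. entries yield (cost, tube, payload)."""
    best = None
    best_dist = None
    for cost, tube, payload in entries:
        if best is None or cost < best[0]:
            best = (cost, tube, payload)
            best_dist = S0.tube_distance(tube, d)
        elif cost == best[0]:
            dist = S0.tube_distance(tube, d)
            if dist < best_dist:
                best = (cost, tube, payload)
                best_dist = dist
    return best


def _argmin_pair(A, B, d, partners, S0):
    """Minimize A[t1] + B[t2] over ordered pairs of distinct partners; ties by
    total distance to d, then enumeration order. A, B map tube -> cost."""
    best = None
    best_dist = None
    for t1 in partners:
        a = A[t1]
        if a == INF:
            continue
        for t2 in partners:
            if t2 == t1:
                continue
            cost = a + B[t2]
            if cost == INF:
                continue
            if best is None or cost < best[0]:
                best = (cost, t1, t2)
                best_dist = S0.tube_distance(t1, d) + S0.tube_distance(t2, d)
            elif cost == best[0]:
                dist = S0.tube_distance(t1, d) + S0.tube_distance(t2, d)
                if dist < best_dist:
                    best = (cost, t1, t2)
                    best_dist = dist
    return best


def _cell_candidates(M: CostMatrix, e: GeneNode, d: int) -> list[Candidate]:
    """All applicable events at the pair <e, d> with their minimal parameters."""
    S0, costs = M.S0, M.costs
    out: list[Candidate] = []
    add = out.append

    eb = len(e.children) == 2
    el = not e.children
    e1 = e.children[0] if eb else None
    e2 = e.children[1] if eb else None
    dch = S0.children[d]
    ddstar = S0.is_out[d]
    dd0 = d == S0.d0
    is_e0 = e is M.G.root
    s = S0.slice_of[d]
    partners = [t for t in S0.ingroup_by_slice[s] if t != d]
    unary = [t for t in S0.unary_by_slice[s] if t != d]
    binary = [t for t in S0.binary_by_slice[s] if t != d]

    def val(en: GeneNode, dn: int) -> float:
        return M.c[en.index][dn]

    if el and not dch:  # rows 0-2: evolution terminates
        if S0.species[d] == e.species:
            add(Candidate(0.0, 0, {}, ()))
        else:
            x = S0.terminal_tube[e.species]
            if not ddstar:
                add(Candidate(costs.tr_without, 1, {"x": x}, ((e, x, ALL),)))
            else:
                add(Candidate(costs.gain, 2, {"x": x}, ((e, x, ALL),)))

    if len(dch) == 1:  # row 3: pass to the next slice
        add(Candidate(val(e, dch[0]), 3, {}, ((e, dch[0], ALL),)))

    if len(dch) == 2:
        d1, d2 = dch
        if eb:  # rows 4-5: speciation forks
            add(Candidate(val(e1, d1) + val(e2, d2), 4, {},
                          ((e1, d1, ALL), (e2, d2, ALL))))
            add(Candidate(val(e2, d1) + val(e1, d2), 5, {},
                          ((e2, d1, ALL), (e1, d2, ALL))))
        if not dd0:  # rows 6-7: speciation with a loss in one branch
            add(Candidate(val(e, d1) + costs.loss, 6, {}, ((e, d1, ALL),)))
            add(Candidate(val(e, d2) + costs.loss, 7, {}, ((e, d2, ALL),)))
        else:  # rows 8-11: the root tube (one child is the outgroup tube)
            if S0.is_out[d2]:
                add(Candidate(val(e, d1), 8, {}, ((e, d1, ALL),)))
                add(Candidate(val(e, d2), 11, {}, ((e, d2, ALL),)))
            else:
                add(Candidate(val(e, d2), 9, {}, ((e, d2, ALL),)))
                add(Candidate(val(e, d1), 10, {}, ((e, d1, ALL),)))

    if eb and not ddstar:  # row 12: duplication
        if dd0:
            add(Candidate(
                M.c_noout[e1.index] + M.c_noout[e2.index] + costs.dupl, 12, {},
                ((e1, d, NOOUT), (e2, d, NOOUT))))
        else:
            add(Candidate(val(e1, d) + val(e2, d) + costs.dupl, 12, {},
                          ((e1, d, ALL), (e2, d, ALL))))

    if eb and dd0:  # row 13: free pre-root duplication, one copy leaves
        v1 = M.c_out[e1.index] + M.c[e2.index][d]
        v2 = M.c[e1.index][d] + M.c_out[e2.index]
        if v1 <= v2:
            add(Candidate(v1, 13, {}, ((e1, d, OUT), (e2, d, ALL))))
        else:
            add(Candidate(v2, 13, {}, ((e1, d, ALL), (e2, d, OUT))))

    if eb and ddstar:  # row 14: duplication inside the outgroup tube
        add(Candidate(val(e1, d) + val(e2, d), 14, {},
                      ((e1, d, ALL), (e2, d, ALL))))

    if eb and not ddstar and not dd0 and partners:  # rows 15-16: transfer w/ retention
        b = _argmin_tube(((val(e1, t), t, None) for t in partners), d, S0)
        add(Candidate(b[0] + val(e2, d) + costs.tr_with, 15, {"dp": b[1]},
                      ((e1, b[1], ALL), (e2, d, ALL))))
        b = _argmin_tube(((val(e2, t), t, None) for t in partners), d, S0)
        add(Candidate(b[0] + val(e1, d) + costs.tr_with, 16, {"dp": b[1]},
                      ((e2, b[1], ALL), (e1, d, ALL))))

    if eb and ddstar and partners:  # rows 17-18: gain of one copy
        b = _argmin_tube(((val(e1, t), t, None) for t in partners), d, S0)
        add(Candidate(b[0] + val(e2, d) + costs.gain, 17, {"dp": b[1]},
                      ((e1, b[1], ALL), (e2, d, ALL))))
        b = _argmin_tube(((val(e2, t), t, None) for t in partners), d, S0)
        add(Candidate(b[0] + val(e1, d) + costs.gain, 18, {"dp": b[1]},
                      ((e2, b[1], ALL), (e1, d, ALL))))

    if not is_e0 and not ddstar and not dd0 and dch:  # row 19: gene falls asleep
        ds = S0.dstar_of_slice[s]
        add(Candidate(M.c[e.index][ds] + costs.sleep, 19, {}, ((e, ds, ALL),)))

    if is_e0 and ddstar and partners:  # row 20: origin of the whole family
        b = _argmin_tube(((M.c[e.index][t], t, None) for t in partners), d, S0)
        add(Candidate(b[0] + costs.gain_big, 20, {"dp": b[1]}, ((e, b[1], ALL),)))

    if not ddstar and not dd0 and unary:  # row 21: transfer w/o retention, pass
        b = _argmin_tube(
            ((M.c[e.index][S0.children[t][0]], t, None) for t in unary), d, S0)
        add(Candidate(b[0] + costs.tr_without, 21, {"dp": b[1]},
                      ((e, S0.children[b[1]][0], ALL),)))

    if not is_e0 and ddstar and unary:  # row 22: gain into a passing tube
        b = _argmin_tube(
            ((M.c[e.index][S0.children[t][0]], t, None) for t in unary), d, S0)
        add(Candidate(b[0] + costs.gain, 22, {"dp": b[1]},
                      ((e, S0.children[b[1]][0], ALL),)))

    if eb and not ddstar and not dd0 and binary:  # rows 23-24: transfer + fork
        b = _argmin_tube(
            ((val(e1, S0.children[t][0]) + val(e2, S0.children[t][1]), t, None)
             for t in binary), d, S0)
        c1, c2 = S0.children[b[1]]
        add(Candidate(b[0] + costs.tr_without, 23, {"dp": b[1]},
                      ((e1, c1, ALL), (e2, c2, ALL))))
        b = _argmin_tube(
            ((val(e1, S0.children[t][1]) + val(e2, S0.children[t][0]), t, None)
             for t in binary), d, S0)
        c1, c2 = S0.children[b[1]]
        add(Candidate(b[0] + costs.tr_without, 24, {"dp": b[1]},
                      ((e1, c2, ALL), (e2, c1, ALL))))

    if eb and not is_e0 and ddstar and binary:  # rows 25-26: gain + fork
        b = _argmin_tube(
            ((val(e1, S0.children[t][0]) + val(e2, S0.children[t][1]), t, None)
             for t in binary), d, S0)
        c1, c2 = S0.children[b[1]]
        add(Candidate(b[0] + costs.gain, 25, {"dp": b[1]},
                      ((e1, c1, ALL), (e2, c2, ALL))))
        b = _argmin_tube(
            ((val(e1, S0.children[t][1]) + val(e2, S0.children[t][0]), t, None)
             for t in binary), d, S0)
        c1, c2 = S0.children[b[1]]
        add(Candidate(b[0] + costs.gain, 26, {"dp": b[1]},
                      ((e1, c2, ALL), (e2, c1, ALL))))

    if not ddstar and not dd0 and binary:  # rows 27-28: transfer + fork with loss
        b = _argmin_tube(
            ((M.c[e.index][S0.children[t][0]], t, None) for t in binary), d, S0)
        add(Candidate(b[0] + costs.tr_without + costs.loss, 27, {"dp": b[1]},
                      ((e, S0.children[b[1]][0], ALL),)))
        b = _argmin_tube(
            ((M.c[e.index][S0.children[t][1]], t, None) for t in binary), d, S0)
        add(Candidate(b[0] + costs.tr_without + costs.loss, 28, {"dp": b[1]},
                      ((e, S0.children[b[1]][1], ALL),)))

    if not is_e0 and ddstar and binary:  # rows 29-30: gain + fork with loss
        b = _argmin_tube(
            ((M.c[e.index][S0.children[t][0]], t, None) for t in binary), d, S0)
        add(Candidate(b[0] + costs.gain + costs.loss, 29, {"dp": b[1]},
                      ((e, S0.children[b[1]][0], ALL),)))
        b = _argmin_tube(
            ((M.c[e.index][S0.children[t][1]], t, None) for t in binary), d, S0)
        add(Candidate(b[0] + costs.gain + costs.loss, 30, {"dp": b[1]},
                      ((e, S0.children[b[1]][1], ALL),)))

    if eb and not ddstar and not dd0 and partners:  # row 31: transfer + duplication
        b = _argmin_tube(((val(e1, t) + val(e2, t), t, None) for t in partners),
                         d, S0)
        add(Candidate(b[0] + costs.tr_without + costs.dupl, 31, {"dp": b[1]},
                      ((e1, b[1], ALL), (e2, b[1], ALL))))

    if eb and not is_e0 and ddstar and partners:  # row 32: gain + duplication
        b = _argmin_tube(((val(e1, t) + val(e2, t), t, None) for t in partners),
                         d, S0)
        add(Candidate(b[0] + costs.gain + costs.dupl, 32, {"dp": b[1]},
                      ((e1, b[1], ALL), (e2, b[1], ALL))))

    if eb and not ddstar and not dd0 and len(partners) >= 2:  # row 33
        A = {t: val(e1, t) for t in partners}
        B = {t: val(e2, t) for t in partners}
        b = _argmin_pair(A, B, d, partners, S0)
        if b is not None:
            add(Candidate(b[0] + costs.tr_without + costs.tr_with, 33,
                          {"dp": b[1], "dpp": b[2]},
                          ((e1, b[1], ALL), (e2, b[2], ALL))))

    if eb and not is_e0 and ddstar and len(partners) >= 2:  # row 34
        A = {t: val(e1, t) for t in partners}
        B = {t: val(e2, t) for t in partners}
        b = _argmin_pair(A, B, d, partners, S0)
        if b is not None:
            add(Candidate(b[0] + costs.gain + costs.tr_with, 34,
                          {"dp": b[1], "dpp": b[2]},
                          ((e1, b[1], ALL), (e2, b[2], ALL))))

    return [c for c in out if c.cost < INF]


def compute_cost_matrix(
    G: GeneTree, S0: SlicedSpeciesTree, costs: Optional[EventCosts] = None
) -> CostMatrix:
    """Fill the full cost matrix with backpointers and candidate lists."""
    if costs is None:
        costs = EventCosts()
    if not G.is_binary():
        raise ReconciliationError("gene tree must be binary (binarize first)")
    _check_species(G, S0)
    M = CostMatrix(G, S0, costs)
    S0_, d0 = S0, S0.d0
    for e in _eval_order(G):
        is_e0 = e is G.root
        for s in range(S0_.n_slices - 1, 0, -1):
            tubes = list(S0_.ingroup_by_slice[s])
            ds = S0_.dstar_of_slice[s]
            order = tubes + [ds] if is_e0 else [ds] + tubes
            for d in order:
                cands = _cell_candidates(M, e, d)
                M.cands[(e.index, d)] = cands
                if cands:
                    best = min(cands, key=lambda c: (c.cost, c.row))
                    M.c[e.index][d] = best.cost
                    M.bp[(e.index, d, ALL)] = best
        # root tube
        cands = _cell_candidates(M, e, d0)
        M.cands[(e.index, d0)] = cands
        out = [c for c in cands if c.row in (10, 11)]
        noout = [c for c in cands if c.row not in (10, 11)]
        if out:
            b = min(out, key=lambda c: (c.cost, c.row))
            M.c_out[e.index] = b.cost
            M.bp[(e.index, d0, OUT)] = b
        if noout:
            b = min(noout, key=lambda c: (c.cost, c.row))
            M.c_noout[e.index] = b.cost
            M.bp[(e.index, d0, NOOUT)] = b
        if cands:
            b = min(cands, key=lambda c: (c.cost, c.row))
            M.c[e.index][d0] = b.cost
            M.bp[(e.index, d0, ALL)] = b
    if M.cost == INF:
        raise ReconciliationError(
            f"no scenario exists for <e_0, d_0> of tree {G.newick()}"
        )
    return M


# ---------------------------------------------------------------------------
# Optimized cost-only evaluation


def _best3(pairs):
    """Top three (value, tube) by value, enumeration order kept among ties."""
    b = []
    for v, t in pairs:
        if len(b) < 3:
            b.append((v, t))
            b.sort(key=lambda x: x[0])
        elif v < b[-1][0]:
            b[-1] = (v, t)
            b.sort(key=lambda x: x[0])
    return b


def _q1(b, excl):
    for v, t in b:
        if t != excl:
            return v
    return INF


def _qpair(bA, bB, excl):
    best = INF
    for va, ta in bA:
        if ta == excl:
            continue
        for vb, tb in bB:
            if tb == excl or tb == ta:
                continue
            if va + vb < best:
                best = va + vb
    return best


def reconcile_cost(
    G: GeneTree, S0: SlicedSpeciesTree, costs: Optional[EventCosts] = None
) -> float:
    """Reconciliation cost c(G, S) = c_min(e_0, d_0), cost only.

    Same recurrences as :func:`compute_cost_matrix` but the minimizations
    over the transfer/gain target d' use per-(edge, slice) best/second-best
    values so each cell costs O(1) beyond the slice set-up.
    """
    if costs is None:
        costs = EventCosts()
    if not G.is_binary():
        raise ReconciliationError("gene tree must be binary (binarize first)")
    _check_species(G, S0)

    closs, cdup, cgain = costs.loss, costs.dupl, costs.gain
    ctrw, ctrwo = costs.tr_with, costs.tr_without
    csleep, cbig = costs.sleep, costs.gain_big

    n, m = len(G.nodes), S0.n_tubes
    C = [[INF] * m for _ in range(n)]
    c_out = [INF] * n
    c_noout = [INF] * n
    d0 = S0.d0
    children = S0.children
    is_out_t = S0.is_out
    species_t = S0.species

    for e in _eval_order(G):
        ei = e.index
        eb = len(e.children) == 2
        el = not e.children
        is_e0 = e is G.root
        if eb:
            r1 = C[e.children[0].index]
            r2 = C[e.children[1].index]
        row = C[ei]
        for s in range(S0.n_slices - 1, 0, -1):
            partners = S0.ingroup_by_slice[s]
            unary = S0.unary_by_slice[s]
            binary = S0.binary_by_slice[s]
            ds = S0.dstar_of_slice[s]
            # per-slice trackers
            if eb:
                A1 = _best3((r1[t], t) for t in partners)
                A2 = _best3((r2[t], t) for t in partners)
                DD = _best3((r1[t] + r2[t], t) for t in partners)
                F = _best3((r1[children[t][0]] + r2[children[t][1]], t)
                           for t in binary)
                Fx = _best3((r1[children[t][1]] + r2[children[t][0]], t)
                            for t in binary)
            U = _best3((row[children[t][0]], t) for t in unary)
            B1 = _best3((row[children[t][0]], t) for t in binary)
            B2 = _best3((row[children[t][1]], t) for t in binary)

            def cell(d: int, ddstar: bool) -> float:
                best = INF
                dch = children[d]
                ndch = len(dch)
                if el and ndch == 0:  # rows 0-2
                    if species_t[d] == e.species:
                        return 0.0
                    best = cgain if ddstar else ctrwo
                if ndch == 1:  # row 3
                    v = row[dch[0]]
                    if v < best:
                        best = v
                elif ndch == 2:
                    d1, d2 = dch
                    if eb:  # rows 4-5
                        v = r1[d1] + r2[d2]
                        if v < best:
                            best = v
                        v = r2[d1] + r1[d2]
                        if v < best:
                            best = v
                    v = row[d1] + closs  # rows 6-7 (d != d0 here)
                    if v < best:
                        best = v
                    v = row[d2] + closs
                    if v < best:
                        best = v
                if not ddstar:
                    if eb:  # row 12
                        v = r1[d] + r2[d] + cdup
                        if v < best:
                            best = v
                        # rows 15-16
                        v = _q1(A1, d)
                        if v + r2[d] + ctrw < best:
                            best = v + r2[d] + ctrw
                        v = _q1(A2, d)
                        if v + r1[d] + ctrw < best:
                            best = v + r1[d] + ctrw
                        # rows 23-24
                        v = _q1(F, d) + ctrwo
                        if v < best:
                            best = v
                        v = _q1(Fx, d) + ctrwo
                        if v < best:
                            best = v
                        # row 31
                        v = _q1(DD, d) + ctrwo + cdup
                        if v < best:
                            best = v
                        # row 33
                        v = _qpair(A1, A2, d) + ctrwo + ctrw
                        if v < best:
                            best = v
                    if not is_e0 and ndch:  # row 19
                        v = row[ds] + csleep
                        if v < best:
                            best = v
                    # row 21
                    v = _q1(U, d) + ctrwo
                    if v < best:
                        best = v
                    # rows 27-28
                    v = _q1(B1, d) + ctrwo + closs
                    if v < best:
                        best = v
                    v = _q1(B2, d) + ctrwo + closs
                    if v < best:
                        best = v
                else:  # d = d*
                    if eb:
                        v = r1[d] + r2[d]  # row 14
                        if v < best:
                            best = v
                        # rows 17-18
                        v = _q1(A1, d) + r2[d] + cgain
                        if v < best:
                            best = v
                        v = _q1(A2, d) + r1[d] + cgain
                        if v < best:
                            best = v
                        if not is_e0:
                            # rows 25-26
                            v = _q1(F, d) + cgain
                            if v < best:
                                best = v
                            v = _q1(Fx, d) + cgain
                            if v < best:
                                best = v
                            # row 32
                            v = _q1(DD, d) + cgain + cdup
                            if v < best:
                                best = v
                            # row 34
                            v = _qpair(A1, A2, d) + cgain + ctrw
                            if v < best:
                                best = v
                    if not is_e0:
                        # row 22
                        v = _q1(U, d) + cgain
                        if v < best:
                            best = v
                        # rows 29-30
                        v = _q1(B1, d) + cgain + closs
                        if v < best:
                            best = v
                        v = _q1(B2, d) + cgain + closs
                        if v < best:
                            best = v
                    else:  # row 20
                        v = min((row[t] for t in partners), default=INF) + cbig
                        if v < best:
                            best = v
                return best

            if is_e0:
                for d in partners:
                    row[d] = cell(d, False)
                row[ds] = cell(ds, True)
            else:
                row[ds] = cell(ds, True)
                for d in partners:
                    row[d] = cell(d, False)

        # root tube d_0
        d1, d2 = children[d0]
        ig, og = (d1, d2) if is_out_t[d2] else (d2, d1)
        best_noout = row[ig]  # rows 8/9
        if eb:
            v = r1[d1] + r2[d2]  # rows 4-5
            if v < best_noout:
                best_noout = v
            v = r2[d1] + r1[d2]
            if v < best_noout:
                best_noout = v
            i1, i2 = e.children[0].index, e.children[1].index
            v = c_noout[i1] + c_noout[i2] + cdup  # row 12
            if v < best_noout:
                best_noout = v
            v = min(c_out[i1] + C[i2][d0], C[i1][d0] + c_out[i2])  # row 13
            if v < best_noout:
                best_noout = v
        c_noout[ei] = best_noout
        c_out[ei] = row[og]  # rows 10/11
        row[d0] = min(best_noout, c_out[ei])

    result = C[G.root.index][d0]
    if result == INF:
        raise ReconciliationError(
            f"no scenario exists for <e_0, d_0> of tree {G.newick()}"
        )
    return result


def total_cost(
    forest: Forest, S0: SlicedSpeciesTree, costs: Optional[EventCosts] = None
) -> float:
    """Weighted total reconciliation cost of a forest against S_0."""
    if costs is None:
        costs = EventCosts()
    return sum(t.weight * reconcile_cost(t, S0, costs) for t in forest)


# ---------------------------------------------------------------------------
# First scenario: the event tree and the beta mapping


@dataclass
class EventNode:
    e: GeneNode
    d: int
    row: int
    params: dict
    children: list["EventNode"] = field(default_factory=list)

    @property
    def name(self) -> str:
        return EVENT_NAMES[self.row]


class EventTree:
    """The first scenario: minimal events recovered by backtracking."""

    def __init__(self, root: EventNode, matrix: CostMatrix):
        self.root = root
        self.matrix = matrix

    def walk(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def cost(self) -> float:
        return self.matrix.cost

    def local_cost(self) -> float:
        """Sum of the local event-cost increments over the tree (must equal
        the matrix root cell; asserted in tests)."""
        return sum(row_increment(n.row, self.matrix.costs) for n in self.walk())

    def format(self) -> str:
        S0 = self.matrix.S0
        lines = []

        def rec(n: EventNode, indent: int) -> None:
            tube = S0.old_id[n.d]
            label = n.e.label or f"edge#{n.e.index}"
            lines.append("  " * indent + f"<{label}, {tube}> {n.name}")
            for c in n.children:
                rec(c, indent + 1)

        rec(self.root, 0)
        return "\n".join(lines)


def build_event_tree(M: CostMatrix) -> EventTree:
    """Backward run from <e_0, d_0>, following the winning events."""

    def rec(e: GeneNode, d: int, mode: str) -> EventNode:
        cand = M.bp[(e.index, d, mode if d == M.S0.d0 else ALL)]
        node = EventNode(e, d, cand.row, cand.params)
        for (te, td, tmode) in cand.termini:
            node.children.append(rec(te, td, tmode))
        return node

    return EventTree(rec(M.G.root, M.S0.d0, ALL), M)


def beta_mapping(T: EventTree) -> dict[GeneNode, tuple[list[int], int]]:
    """β(e) = the ordered tube path of edge e, plus its final event row."""
    beta: dict[GeneNode, tuple[list[int], int]] = {}

    def rec(n: EventNode) -> None:
        tubes, _ = beta.setdefault(n.e, ([], -1))
        tubes.append(n.d)
        beta[n.e] = (tubes, n.row)
        for c in n.children:
            rec(c)

    rec(T.root)
    return beta
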