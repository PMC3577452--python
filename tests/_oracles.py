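"""Independent oracles used by the test suite.

``oracle_cost`` re-derives the reconciliation cost by naive recursive
expansion of the event-type table, enumerating every applicable event and
every admissible parameter tube directly (no ordering tricks, no
best/second-best precomputation, no backpointers). It is written against the
table itself and shares no code with the package's dynamic program.

``dl_stem_cost`` is the classical duplication-loss reconciliation cost via
the LCA mapping, with losses additionally charged from the species root down
to the gene family's origination vertex (in the tube model every family
enters at the root unless gained or transferred, so a family spanning only a
subtree pays one loss per speciation passed on the way down).

``all_rooted_topologies`` enumerates every rooted binary topology over a
species set (for exhaustive supertree minima at small m).
"""

from __future__ import annotations

import itertools
from math import inf

from dtlslice.timeslice import SlicedSpeciesTree, SpNode
from dtlslice.treeio import GeneTree


def oracle_cost(G: GeneTree, S0: SlicedSpeciesTree, costs) -> float:
    """Minimal scenario cost by exhaustive expansion of the event table."""
    d0 = S0.d0
    memo: dict = {}

    def leafq(d):
        return not S0.children[d]

    def same_slice(d):
        s = S0.slice_of[d]
        return [t for t in range(S0.n_tubes)
                if S0.slice_of[t] == s and t != d and t != d0]

    def cmin(e, d, mode="all"):
        key = (e.index, d, mode)
        if key in memo:
            return memo[key]
        memo[key] = inf  # placeholder; the recursion has no cycles
        opts = []
        eb = len(e.children) == 2
        el = not e.children
        e1, e2 = (e.children[0], e.children[1]) if eb else (None, None)
        dstar = S0.is_out[d]
        dd0 = d == d0
        is_e0 = e.parent is None
        dch = S0.children[d]
        outgoing = [t for t in same_slice(d) if not S0.is_out[t]]

        if mode in ("all", "noout"):
            # 0-2: terminal events
            if el and leafq(d):
                if S0.species[d] == e.species:
                    opts.append(0.0)
                elif not dstar:
                    opts.append(costs.tr_without)
                else:
                    opts.append(costs.gain)
            # 3: pass
            if len(dch) == 1:
                opts.append(cmin(e, dch[0]))
            if len(dch) == 2:
                da, db = dch
                # 4-5: forks
                if eb:
                    opts.append(cmin(e1, da) + cmin(e2, db))
                    opts.append(cmin(e2, da) + cmin(e1, db))
                if not dd0:
                    # 6-7: speciation with loss
                    opts.append(cmin(e, da) + costs.loss)
                    opts.append(cmin(e, db) + costs.loss)
                else:
                    # 8-9: gene present in the root
                    ig = da if S0.is_out[db] else db
                    opts.append(cmin(e, ig))
            # 12: duplication
            if eb and not dstar:
                if dd0:
                    opts.append(cmin(e1, d, "noout") + cmin(e2, d, "noout")
                                + costs.dupl)
                else:
                    opts.append(cmin(e1, d) + cmin(e2, d) + costs.dupl)
            # 13: pre-root duplication, one copy leaves through the outgroup
            if eb and dd0:
                opts.append(cmin(e1, d, "out") + cmin(e2, d, "all"))
                opts.append(cmin(e1, d, "all") + cmin(e2, d, "out"))
            # 14: duplication inside the outgroup tube
            if eb and dstar:
                opts.append(cmin(e1, d) + cmin(e2, d))
            # 15-16: transfer with retention
            if eb and not dstar and not dd0:
                for t in outgoing:
                    opts.append(cmin(e1, t) + cmin(e2, d) + costs.tr_with)
                    opts.append(cmin(e2, t) + cmin(e1, d) + costs.tr_with)
            # 17-18: gain of one copy
            if eb and dstar:
                for t in outgoing:
                    opts.append(cmin(e1, t) + cmin(e2, d) + costs.gain)
                    opts.append(cmin(e2, t) + cmin(e1, d) + costs.gain)
            # 19: sleep
            if not is_e0 and not dstar and not dd0 and dch:
                ds = S0.dstar_of_slice[S0.slice_of[d]]
                opts.append(cmin(e, ds) + costs.sleep)
            # 20: origin of the family
            if is_e0 and dstar:
                for t in outgoing:
                    opts.append(cmin(e, t) + costs.gain_big)
            # 21: transfer onto a passing tube
            if not dstar and not dd0:
                for t in outgoing:
                    if len(S0.children[t]) == 1:
                        opts.append(cmin(e, S0.children[t][0]) + costs.tr_without)
            # 22: gain onto a passing tube
            if not is_e0 and dstar:
                for t in outgoing:
                    if len(S0.children[t]) == 1:
                        opts.append(cmin(e, S0.children[t][0]) + costs.gain)
            # 23-26: transfer/gain onto a forking tube
            if eb and not dstar and not dd0:
                for t in outgoing:
                    if len(S0.children[t]) == 2:
                        ta, tb = S0.children[t]
                        opts.append(cmin(e1, ta) + cmin(e2, tb) + costs.tr_without)
                        opts.append(cmin(e1, tb) + cmin(e2, ta) + costs.tr_without)
            if eb and not is_e0 and dstar:
                for t in outgoing:
                    if len(S0.children[t]) == 2:
                        ta, tb = S0.children[t]
                        opts.append(cmin(e1, ta) + cmin(e2, tb) + costs.gain)
                        opts.append(cmin(e1, tb) + cmin(e2, ta) + costs.gain)
            # 27-30: transfer/gain onto a forking tube with a loss
            if not dstar and not dd0:
                for t in outgoing:
                    if len(S0.children[t]) == 2:
                        ta, tb = S0.children[t]
                        opts.append(cmin(e, ta) + costs.tr_without + costs.loss)
                        opts.append(cmin(e, tb) + costs.tr_without + costs.loss)
            if not is_e0 and dstar:
                for t in outgoing:
                    if len(S0.children[t]) == 2:
                        ta, tb = S0.children[t]
                        opts.append(cmin(e, ta) + costs.gain + costs.loss)
                        opts.append(cmin(e, tb) + costs.gain + costs.loss)
            # 31-32: transfer/gain then duplication
            if eb and not dstar and not dd0:
                for t in outgoing:
                    opts.append(cmin(e1, t) + cmin(e2, t)
                                + costs.tr_without + costs.dupl)
            if eb and not is_e0 and dstar:
                for t in outgoing:
                    opts.append(cmin(e1, t) + cmin(e2, t)
                                + costs.gain + costs.dupl)
            # 33-34: double transfers
            if eb and not dstar and not dd0:
                for t1 in outgoing:
                    for t2 in outgoing:
                        if t1 != t2:
                            opts.append(cmin(e1, t1) + cmin(e2, t2)
                                        + costs.tr_without + costs.tr_with)
            if eb and not is_e0 and dstar:
                for t1 in outgoing:
                    for t2 in outgoing:
                        if t1 != t2:
                            opts.append(cmin(e1, t1) + cmin(e2, t2)
                                        + costs.gain + costs.tr_with)
        if mode in ("all", "out") and dd0:
            # 10-11: gene absent in the root, continues in the outgroup tube
            da, db = S0.children[d]
            og = da if S0.is_out[da] else db
            opts.append(cmin(e, og))

        val = min(opts, default=inf)
        memo[key] = val
        return val

    return cmin(G.root, d0)


# ---------------------------------------------------------------------------
# Classical duplication-loss cost with root origination


def dl_stem_cost(G: GeneTree, S: SpNode, c_d: float, c_l: float) -> float:
    """LCA-mapping duplication-loss cost of a gene tree against a plain
    species tree, charging losses from the species root down to the family's
    origination vertex."""
    parent = {}
    depth = {}
    leaf_of = {}

    def walk(n: SpNode, d: int) -> None:
        depth[id(n)] = d
        if n.is_leaf:
            leaf_of[n.name] = n
        for c in n.children:
            parent[id(c)] = n
            walk(c, d + 1)

    walk(S, 0)

    def lca(a: SpNode, b: SpNode) -> SpNode:
        while a is not b:
            if depth[id(a)] >= depth[id(b)]:
                a = parent[id(a)]
            else:
                b = parent[id(b)]
        return a

    alpha = {}
    dups = 0
    losses = 0
    for g in G.root.postorder():
        if g.is_leaf:
            alpha[g.index] = leaf_of[g.species]
        else:
            a = alpha[g.children[0].index]
            for c in g.children[1:]:
                a = lca(a, alpha[c.index])
            alpha[g.index] = a
            dup = any(alpha[c.index] is a for c in g.children)
            if dup:
                dups += 1
            for c in g.children:
                k = depth[id(alpha[c.index])] - depth[id(a)]
                losses += k if dup else k - 1
    losses += depth[id(alpha[G.root.index])]  # stem: root down to origination
    return c_d * dups + c_l * losses


# ---------------------------------------------------------------------------
# Exhaustive rooted topologies


def all_rooted_topologies(species: list[str]):
    """Yield every rooted binary topology (as SpNode) over the species."""
    if len(species) == 1:
        yield SpNode(species[0])
        return
    first, rest = species[0], species[1:]
    for k in range(0, len(rest)):
        for combo in itertools.combinations(rest, k):
            left = [first, *combo]
            right = [s for s in rest if s not in combo]
            if not right:
                continue
            for lt in all_rooted_topologies(left):
                for rt in all_rooted_topologies(right):
                    root = SpNode()
                    root.add(lt.copy())
                    root.add(rt.copy())
                    yield root


def tree_clades(root: SpNode) -> set[frozenset]:
    out = set()

    def rec(n: SpNode) -> frozenset:
        if n.is_leaf:
            cl = frozenset([n.name])
        else:
            cl = frozenset()
            for c in n.children:
                cl |= rec(c)
        out.add(cl)
        return cl

    rec(root)
    return out
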