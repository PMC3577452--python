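"""Shared helpers for the test suite."""

from __future__ import annotations

import random

from dtlslice import EventCosts, GeneNode, GeneTree, SpNode
from dtlslice.simulate import generate_species_tree


def random_gene_tree(species: list[str], n_leaves: int,
                     rng: random.Random) -> GeneTree:
    """Random binary gene tree; species drawn with replacement (paralogs)."""
    nodes = [GeneNode(rng.choice(species), str(i + 1)) for i in range(n_leaves)]
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        p = GeneNode()
        p.add(a)
        p.add(b)
        nodes.append(p)
    return GeneTree(nodes[0])


def random_costs(rng: random.Random, low: float = 0.1,
                 high: float = 4.0) -> EventCosts:
    u = lambda: rng.uniform(low, high)
    return EventCosts(loss=u(), dupl=u(), gain=u(), tr_with=u(),
                      tr_without=u(), sleep=u(), gain_big=u())


def random_instance(rng: random.Random, max_species: int = 4,
                    max_leaves: int = 4):
    """Random (gene tree, sliced species tree, costs) triple."""
    from dtlslice import build_slices

    m = rng.randint(2, max_species)
    S = generate_species_tree(m, seed=rng.randrange(2**31))
    S0 = build_slices(S)
    species = sorted(S0.species_names())
    G = random_gene_tree(species, rng.randint(2, max_leaves), rng)
    return G, S0, random_costs(rng)


def species_clades(root: SpNode) -> set[frozenset]:
    out: set[frozenset] = set()

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


def same_topology(a: SpNode, b: SpNode) -> bool:
    return species_clades(a) == species_clades(b)
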