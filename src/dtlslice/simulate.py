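"""Forward simulation of gene trees along a time-sliced species tree.

A gene starts as a single lineage in the in-group root tube. Traversing a
tube, the lineage duplicates with probability p_dup (both copies restart the
tube step), dies with p_loss, jumps to a uniformly chosen same-slice
non-outgroup tube with p_tr (without retention in the donor), and otherwise
follows the tube to its lower vertex, where it either speciates into both
child tubes, passes into the single child segment, or terminates as a leaf.
Genes extinct everywhere are discarded and redrawn, as are genes surviving
in fewer than two lineages (single-leaf families carry no topology).

The simulation mirrors the event model of the reconciler — losses happen at
tube granularity and transfers stay within a slice — so a zero-rate forest
reconciles against its generating tree at cost zero.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass
from typing import Optional

from .timeslice import (SlicedSpeciesTree, SpNode, SpeciesTree,
                        attach_outgroup, build_slices)
from .treeio import Forest, GeneNode, GeneTree


@dataclass(frozen=True)
class SimParams:
    p_dup: float = 0.02
    p_loss: float = 0.02
    p_tr: float = 0.01
    n_trees: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_dup", "p_loss", "p_tr"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.p_dup + self.p_loss + self.p_tr >= 1:
            raise ValueError("p_dup + p_loss + p_tr must be < 1")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def species_names(m: int) -> list[str]:
    if m <= 26:
        return list(string.ascii_uppercase[:m])
    return [f"S{i + 1}" for i in range(m)]


def generate_species_tree(m: int, seed: int = 0) -> SpeciesTree:
    """Random rooted binary tree over m species by uniform sequential joins,
    with the auxiliary outgroup attached."""
    if m < 2:
        raise ValueError("need at least two species")
    rng = random.Random(seed)
    nodes = [SpNode(name) for name in species_names(m)]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        parent = SpNode()
        parent.add(a)
        parent.add(b)
        nodes.append(parent)
    return attach_outgroup(nodes[0])


def _simulate_one(S0: SlicedSpeciesTree, params: SimParams,
                  rng: random.Random, gene_counter: list[int],
                  counts: Optional[dict] = None) -> Optional[GeneNode]:
    p_d, p_l, p_t = params.p_dup, params.p_loss, params.p_tr
    if counts is None:
        counts = {}
    counts.update(dup=0, loss=0, transfer=0)

    def in_tube(d: int) -> Optional[GeneNode]:
        r = rng.random()
        if r < p_l:
            counts["loss"] += 1
            return None
        if r < p_l + p_d:
            counts["dup"] += 1
            a = in_tube(d)
            b = in_tube(d)
            if a is None:
                return b
            if b is None:
                return a
            node = GeneNode()
            node.add(a)
            node.add(b)
            return node
        if r < p_l + p_d + p_t:
            partners = S0.same_slice_partners(d)
            if partners:
                counts["transfer"] += 1
                d = partners[rng.randrange(len(partners))]
            # transferred copy continues from the bottom of the target tube
        return at_bottom(d)

    def at_bottom(d: int) -> Optional[GeneNode]:
        kids = S0.children[d]
        if not kids:
            gene_counter[0] += 1
            return GeneNode(S0.species[d], str(gene_counter[0]))
        subs = [in_tube(c) for c in kids]
        subs = [s for s in subs if s is not None]
        if not subs:
            return None
        if len(subs) == 1:
            return subs[0]
        node = GeneNode()
        for s in subs:
            node.add(s)
        return node

    # root tube of the in-group (the non-outgroup child of d_0)
    d1, d2 = S0.children[S0.d0]
    start = d2 if S0.is_out[d1] else d1
    return in_tube(start)


def generate_gene_trees(S0: SlicedSpeciesTree, params: SimParams,
                        stats: Optional[list[dict]] = None) -> Forest:
    """Simulate a forest of rooted binary gene trees along S_0.

    When *stats* is a list, a ``{"dup": ..., "loss": ..., "transfer": ...}``
    event-count dict is appended per accepted tree (counts of redrawn
    attempts are dropped with their trees).
    """
    rng = random.Random(params.seed)
    trees = []
    counter = [0]
    while len(trees) < params.n_trees:
        counts: dict = {}
        root = _simulate_one(S0, params, rng, counter, counts)
        if root is None or root.is_leaf:
            continue  # extinct or single-leaf family: redraw
        trees.append(GeneTree(root))
        if stats is not None:
            stats.append(counts)
    return Forest(trees)


def simulate_forest(m: int, params: SimParams):
    """Species tree + sliced tree + forest in one call (seeded)."""
    S = generate_species_tree(m, params.seed)
    S0 = build_slices(S)
    forest = generate_gene_trees(S0, params)
    return S, S0, forest
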