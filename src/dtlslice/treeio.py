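"""Gene-tree input/output and preprocessing.

Gene trees are rooted, possibly polytomous, with leaves labelled
``species-gene`` (the separator is configurable; paralogs allowed). Every
tree carries an implicit *super-root* above its root: the edge between the
super-root and the root is the root edge e_0, identified (like every other
edge) with its lower vertex, so the root vertex *is* e_0.

Newick text is parsed with dendropy and converted to the package's own
lightweight structures, which carry clades and the super-root semantics.
"""

from __future__ import annotations

import io
from typing import Iterable, Iterator, Optional, Sequence

import dendropy


class ParseError(ValueError):
    pass


class GeneNode:
    __slots__ = ("children", "parent", "species", "gene", "clade", "index")

    def __init__(self, species=None, gene=None):
        self.children: list[GeneNode] = []
        self.parent: Optional[GeneNode] = None
        self.species: Optional[str] = species
        self.gene: Optional[str] = gene
        self.clade: frozenset[str] = frozenset()
        self.index: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def label(self) -> str:
        return f"{self.species}-{self.gene}" if self.is_leaf else ""

    def add(self, child: "GeneNode") -> None:
        child.parent = self
        self.children.append(child)

    def preorder(self) -> Iterator["GeneNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["GeneNode"]:
        out = list(self.preorder())
        return reversed(out)


class GeneTree:
    """Rooted gene tree with super-root edge e_0 (= the root vertex)."""

    def __init__(self, root: GeneNode, weight: float = 1.0, separator: str = "-"):
        self.root = root
        self.weight = weight
        self.separator = separator
        self._finalize()

    def _finalize(self) -> None:
        self.nodes: list[GeneNode] = []
        for i, node in enumerate(self.root.preorder()):
            node.index = i
            self.nodes.append(node)
        for node in self.root.postorder():
            if node.is_leaf:
                node.clade = frozenset([node.species])
            else:
                cl: set[str] = set()
                for ch in node.children:
                    cl.update(ch.clade)
                node.clade = frozenset(cl)

    @property
    def e0(self) -> GeneNode:
        return self.root

    def leaves(self) -> list[GeneNode]:
        return [n for n in self.nodes if n.is_leaf]

    def species_set(self) -> frozenset[str]:
        return self.root.clade

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.nodes)

    def newick(self) -> str:
        def rec(n: GeneNode) -> str:
            if n.is_leaf:
                return f"{n.species}{self.separator}{n.gene}"
            return "(" + ",".join(rec(c) for c in n.children) + ")"

        return rec(self.root) + ";"

    def copy(self) -> "GeneTree":
        def rec(n: GeneNode) -> GeneNode:
            m = GeneNode(n.species, n.gene)
            for c in n.children:
                m.add(rec(c))
            return m

        return GeneTree(rec(self.root), self.weight, self.separator)


class Forest:
    """Ordered collection of gene trees; index j identifies a tree."""

    def __init__(self, trees: Sequence[GeneTree]):
        self.trees = list(trees)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[GeneTree]:
        return iter(self.trees)

    def __getitem__(self, j: int) -> GeneTree:
        return self.trees[j]

    def species_universe(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.trees:
            out.update(t.species_set())
        return frozenset(out)


def _split_label(label: str, separator: str) -> tuple[str, str]:
    if separator not in label:
        raise ParseError(
            f"leaf label {label!r} lacks the species{separator}gene separator"
        )
    species, gene = label.split(separator, 1)
    if not species or not gene:
        raise ParseError(f"leaf label {label!r} has an empty species or gene part")
    return species, gene


def _dendropy_parse(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise ParseError(f"cannot parse Newick: {exc}") from exc
    if tree.seed_node is None or (
        tree.seed_node.is_leaf() and tree.seed_node.taxon is None
    ):
        raise ParseError("empty tree")
    return tree


def _convert(dnode, separator: str) -> GeneNode:
    children = dnode.child_nodes()
    if not children:
        label = dnode.taxon.label if dnode.taxon is not None else (dnode.label or "")
        species, gene = _split_label(label, separator)
        return GeneNode(species, gene)
    node = GeneNode()
    for ch in children:
        node.add(_convert(ch, separator))
    return node


def parse_gene_tree(text: str, separator: str = "-", weight: float = 1.0) -> GeneTree:
    """Parse a single rooted Newick statement into a :class:`GeneTree`.

    Polytomies are preserved; leaf labels split at the first *separator*.
    """
    tree = _dendropy_parse(text)
    root = _convert(tree.seed_node, separator)
    if root.is_leaf and root.species is None:
        raise ParseError("empty tree")
    return GeneTree(root, weight=weight, separator=separator)


def parse_forest(text: str, separator: str = "-") -> Forest:
    """Parse one Newick gene tree per non-empty line."""
    trees = []
    for line in io.StringIO(text):
        line = line.strip()
        if line:
            trees.append(parse_gene_tree(line, separator))
    return Forest(trees)


def write_forest(forest: Forest) -> str:
    return "".join(t.newick() + "\n" for t in forest)


# ---------------------------------------------------------------------------
# Pruning of rare species (step before supertree construction)

def species_occurrences(forest: Forest) -> dict[str, int]:
    """Count occurrences of each species.

    An occurrence of species *s* in a tree is an inextensible subtree all of
    whose leaves belong to *s* (so a cherry of two paralogs of *s* is one
    occurrence, not two).
    """
    counts: dict[str, int] = {}
    for tree in forest:
        for node in tree.nodes:
            if len(node.clade) == 1 and (
                node.parent is None or len(node.parent.clade) > 1
            ):
                (s,) = node.clade
                counts[s] = counts.get(s, 0) + 1
    return counts


def _filter_leaves(node: GeneNode, keep: frozenset[str]) -> Optional[GeneNode]:
    """Copy of the subtree with leaves outside *keep* removed and unary
    vertices suppressed (pendant edges removed together with their origins)."""
    if node.is_leaf:
        if node.species in keep:
            return GeneNode(node.species, node.gene)
        return None
    kept = [c for c in (_filter_leaves(ch, keep) for ch in node.children) if c]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    out = GeneNode()
    for c in kept:
        out.add(c)
    return out


def prune_rare_species(forest: Forest, p_min: int) -> Forest:
    """Remove every species occurring fewer than *p_min* times in the forest.

    Trees that become empty or single-species are dropped. Dropping trees can
    make further species rare, so the pass is repeated until stable (which
    makes the operation idempotent). Returns a new forest; the input is not
    modified.
    """
    if p_min < 0:
        raise ValueError("p_min must be >= 0")
    while True:
        counts = species_occurrences(forest)
        keep = frozenset(s for s, c in counts.items() if c >= p_min)
        trees = []
        for tree in forest:
            root = _filter_leaves(tree.root, keep)
            if root is None:
                continue
            new = GeneTree(root, tree.weight, tree.separator)
            if len(new.species_set()) >= 2:
                trees.append(new)
        out = Forest(trees)
        if species_occurrences(out) == counts and len(out) == len(forest):
            return out
        forest = out


# ---------------------------------------------------------------------------
# Binarization and rooting

def _subtree_cost(node: GeneNode, reference, costs) -> float:
    from .reconcile import reconcile_cost

    def rec(n: GeneNode) -> GeneNode:
        m = GeneNode(n.species, n.gene)
        for c in n.children:
            m.add(rec(c))
        return m

    return reconcile_cost(GeneTree(rec(node)), reference, costs)


def binarize(tree: GeneTree, reference=None, costs=None) -> GeneTree:
    """Resolve polytomies by greedy agglomeration.

    At each polytomous vertex the child pair whose join reconciles most
    cheaply against *reference* (a sliced species tree) is joined first; ties
    fall back to enumeration order. Without a reference the pair minimizing
    the symmetric clade distance is joined. Binary input is returned as an
    identical copy.
    """
    from .events import EventCosts

    if costs is None:
        costs = EventCosts()

    def clade(n: GeneNode) -> frozenset:
        if n.is_leaf:
            return frozenset([n.species])
        out: set = set()
        for c in n.children:
            out.update(clade(c))
        return frozenset(out)

    def score(a: GeneNode, b: GeneNode) -> float:
        if reference is None:
            return float(len(clade(a) ^ clade(b)))
        joined = GeneNode()
        joined.add(a)
        joined.add(b)
        val = _subtree_cost(joined, reference, costs)
        a.parent = b.parent = None
        return val

    def rec(n: GeneNode) -> GeneNode:
        if n.is_leaf:
            return GeneNode(n.species, n.gene)
        kids = [rec(c) for c in n.children]
        while len(kids) > 2:
            best = None
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    s = score(kids[i], kids[j])
                    if best is None or s < best[0]:
                        best = (s, i, j)
            _, i, j = best
            joined = GeneNode()
            joined.add(kids[i])
            joined.add(kids[j])
            kids = [k for t, k in enumerate(kids) if t not in (i, j)]
            kids.append(joined)
        if len(kids) == 1:
            return kids[0]
        out = GeneNode()
        for k in kids:
            out.add(k)
        return out

    return GeneTree(rec(tree.root), tree.weight, tree.separator)


def root_unrooted(text: str, reference, costs=None, separator: str = "-") -> GeneTree:
    """Root an unrooted Newick gene tree against a sliced reference tree.

    Every edge is tried as the root position; the rooting with the minimal
    reconciliation cost wins (ties: first edge in enumeration order). Input
    whose basal vertex is already binary is treated as rooted and returned
    unchanged.
    """
    from .events import EventCosts
    from .reconcile import reconcile_cost

    if costs is None:
        costs = EventCosts()

    dtree = _dendropy_parse(text)
    seed = dtree.seed_node
    if len(seed.child_nodes()) == 2:
        return parse_gene_tree(text, separator)

    # Undirected adjacency over dendropy nodes.
    nodes = list(dtree.preorder_node_iter())
    adj: dict[int, list] = {id(n): [] for n in nodes}
    edges = []  # (u, v) in deterministic preorder
    for n in nodes:
        for ch in n.child_nodes():
            adj[id(n)].append(ch)
            adj[id(ch)].append(n)
            edges.append((n, ch))

    missing = set()
    ref_species = reference.species_names()
    for n in nodes:
        if not n.child_nodes():
            label = n.taxon.label if n.taxon else (n.label or "")
            sp, _ = _split_label(label, separator)
            if sp not in ref_species:
                missing.add(sp)
    if missing:
        raise ValueError(
            "species absent from the reference tree: " + ", ".join(sorted(missing))
        )

    def orient(node, came_from) -> GeneNode:
        neighbours = [x for x in adj[id(node)] if x is not came_from]
        if not neighbours:
            label = node.taxon.label if node.taxon else (node.label or "")
            sp, gene = _split_label(label, separator)
            return GeneNode(sp, gene)
        out = GeneNode()
        for nb in neighbours:
            out.add(orient(nb, node))
        return out

    best = None
    for u, v in edges:
        root = GeneNode()
        root.add(orient(v, u))
        root.add(orient(u, v))
        cand = GeneTree(root, separator=separator)
        if not cand.is_binary():
            cand = binarize(cand, reference, costs)
        c = reconcile_cost(cand, reference, costs)
        if best is None or c < best[0]:
            best = (c, cand)
    if best is None:
        raise ParseError("tree has no edges to root on")
    return best[1]
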