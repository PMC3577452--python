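"""Time-sliced species trees.

The species tree S is rooted and binary. An auxiliary outgroup leaf d* is
attached as a sibling of the original root under a new root R, and the root
tube d_0 enters R from above. Tubes (species-tree edges) are subdivided into
segments so that consecutive tubes always lie in consecutive *time slices*;
horizontal transfers are permitted only between tubes of one slice. d_0 forms
its own topmost slice (index 0), and every slice below it contains exactly
one segment of the outgroup tube (all denoted d*).

Tubes in the sliced tree S_0 are identified with their lower vertices and
indexed by integers; the structure below stores flat arrays per tube.
"""

from __future__ import annotations

from typing import Iterable, Optional

import dendropy

OUTGROUP = "d*"


class SpNode:
    """Vertex of the (unsliced) species tree; ``segments`` is the integer
    number of slice segments of the incoming tube."""

    __slots__ = ("children", "parent", "name", "segments")

    def __init__(self, name: str = "", segments: int = 1):
        self.children: list[SpNode] = []
        self.parent: Optional[SpNode] = None
        self.name = name
        self.segments = segments

    def add(self, child: "SpNode") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self):
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self):
        return [n for n in self.preorder() if n.is_leaf]

    def newick(self, lengths: bool = False) -> str:
        def rec(n: SpNode) -> str:
            if n.is_leaf:
                s = n.name
            else:
                s = "(" + ",".join(rec(c) for c in n.children) + ")" + n.name
            return f"{s}:{n.segments}" if lengths else s

        return rec(self) + ";"

    def copy(self) -> "SpNode":
        m = SpNode(self.name, self.segments)
        for c in self.children:
            m.add(c.copy())
        return m


class SpeciesTree:
    """Species tree with the outgroup leaf d* and root tube d_0 attached.

    ``root`` is the new root R whose children are the original root and d*.
    """

    def __init__(self, root: SpNode):
        self.root = root

    @property
    def ingroup_root(self) -> SpNode:
        return self.root.children[0]

    @property
    def outgroup_leaf(self) -> SpNode:
        return self.root.children[1]

    def species_names(self) -> frozenset[str]:
        return frozenset(
            n.name for n in self.ingroup_root.preorder() if n.is_leaf
        )


def parse_species_tree(text: str) -> SpNode:
    """Parse a rooted binary species tree in the integer-length dialect.

    The branch "length" of each vertex is the number of slice segments of its
    incoming tube (default 1).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"cannot parse species tree: {exc}") from exc

    counter = [0]

    def conv(dnode) -> SpNode:
        if dnode.child_nodes():
            counter[0] += 1
            node = SpNode(dnode.label or f"_n{counter[0]}")
            for ch in dnode.child_nodes():
                node.add(conv(ch))
        else:
            node = SpNode(dnode.taxon.label if dnode.taxon else dnode.label)
        if dnode.edge.length is not None:
            seg = int(dnode.edge.length)
            if seg != dnode.edge.length or seg < 1:
                raise ValueError(
                    f"tube length of {node.name!r} must be a positive integer"
                )
            node.segments = seg
        return node

    root = conv(tree.seed_node)
    for n in root.preorder():
        if n.children and len(n.children) != 2:
            raise ValueError("species tree must be binary")
    return root


def attach_outgroup(ingroup_root: SpNode) -> SpeciesTree:
    """Create the root R with children (original root, d*) and the tube d_0."""
    names = {n.name for n in ingroup_root.preorder() if n.is_leaf}
    if OUTGROUP in names:
        raise ValueError(f"reserved outgroup label {OUTGROUP!r} already present")
    root = SpNode("_R")
    root.add(ingroup_root)
    root.add(SpNode(OUTGROUP))
    return SpeciesTree(root)


class SlicedSpeciesTree:
    """Flat-array representation of S_0.

    Tube *i* is the edge entering vertex *i*; ``d0`` is the root tube. Arrays:
    ``parent``, ``children``, ``slice_of``, ``is_out`` (outgroup segment),
    ``species`` (terminal tubes), ``old_id`` (name of the original tube of S
    that the segment belongs to).
    """

    def __init__(self) -> None:
        self.parent: list[Optional[int]] = []
        self.children: list[tuple[int, ...]] = []
        self.slice_of: list[int] = []
        self.is_out: list[bool] = []
        self.species: list[Optional[str]] = []
        self.old_id: list[str] = []
        self.d0: int = 0
        self.n_slices: int = 0

    # -- construction -------------------------------------------------------

    def _new_tube(self, parent, s, is_out, species, old_id) -> int:
        i = len(self.parent)
        self.parent.append(parent)
        self.children.append(())
        self.slice_of.append(s)
        self.is_out.append(is_out)
        self.species.append(species)
        self.old_id.append(old_id)
        return i

    def _finalize(self) -> None:
        n = len(self.parent)
        kids: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p is not None:
                kids[p].append(i)
        self.children = [tuple(k) for k in kids]
        self.n_slices = max(self.slice_of) + 1
        self.ingroup_by_slice: list[list[int]] = [[] for _ in range(self.n_slices)]
        self.dstar_of_slice: list[Optional[int]] = [None] * self.n_slices
        for i in range(n):
            s = self.slice_of[i]
            if self.is_out[i]:
                self.dstar_of_slice[s] = i
            elif i != self.d0:
                self.ingroup_by_slice[s].append(i)
        self.terminal_tube = {
            self.species[i]: i for i in range(n) if self.species[i] is not None
        }
        # per-slice partner sublists (in-group only, enumeration order kept)
        self.unary_by_slice = [
            [d for d in tubes if len(self.children[d]) == 1]
            for tubes in self.ingroup_by_slice
        ]
        self.binary_by_slice = [
            [d for d in tubes if len(self.children[d]) == 2]
            for tubes in self.ingroup_by_slice
        ]
        self._distances()

    def _distances(self) -> None:
        # distance between tubes = path length between their parent vertices
        # (vertex == lower end of a tube; the parent vertex of tube i is
        # vertex parent[i]).
        n = len(self.parent)
        adj: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p is not None:
                adj[i].append(p)
                adj[p].append(i)
        INF = float("inf")
        self.vdist = [[INF] * n for _ in range(n)]
        for src in range(n):
            row = self.vdist[src]
            row[src] = 0
            queue = [src]
            while queue:
                nxt = []
                for u in queue:
                    for v in adj[u]:
                        if row[v] is INF or row[v] > row[u] + 1:
                            row[v] = row[u] + 1
                            nxt.append(v)
                queue = nxt

    def tube_distance(self, d1: int, d2: int) -> float:
        p1 = self.parent[d1] if self.parent[d1] is not None else d1
        p2 = self.parent[d2] if self.parent[d2] is not None else d2
        return self.vdist[p1][p2]

    # -- queries ------------------------------------------------------------

    @property
    def n_tubes(self) -> int:
        return len(self.parent)

    def same_slice_partners(self, d: int) -> list[int]:
        """In-group tubes sharing d's slice, excluding d itself and d*."""
        return [t for t in self.ingroup_by_slice[self.slice_of[d]] if t != d]

    def is_terminal(self, d: int) -> bool:
        return not self.children[d]

    def species_names(self) -> frozenset[str]:
        return frozenset(s for s in self.species if s is not None and s != OUTGROUP)


def build_slices(S: SpeciesTree, mode: str = "auto") -> SlicedSpeciesTree:
    """Build S_0 from a species tree with outgroup attached.

    auto mode: leaf tubes are subdivided so that all leaves (including d*)
    lie at the common depth h below R; internal tubes get one segment per
    unit depth. explicit mode: the ``segments`` attributes of the in-group
    tubes are honoured; every root-to-leaf path must cross the same number of
    slices, and the outgroup tube is cut into that many segments.
    """
    if mode not in ("auto", "explicit"):
        raise ValueError(f"unknown slicing mode {mode!r}")
    ingroup = S.ingroup_root

    if mode == "auto":
        depth: dict[int, int] = {}

        def walk(n: SpNode, d: int) -> None:
            depth[id(n)] = d
            for c in n.children:
                walk(c, d + 1)

        walk(ingroup, 1)
        h = max(depth[id(l)] for l in ingroup.leaves())
        seg_of = {}
        for n in ingroup.preorder():
            seg_of[id(n)] = (h - depth[id(n)] + 1) if n.is_leaf else 1
    else:
        sums = []

        def walk2(n: SpNode, acc: int) -> None:
            acc += n.segments
            if n.is_leaf:
                sums.append(acc)
            for c in n.children:
                walk2(c, acc)

        walk2(ingroup, 0)
        h = sums[0]
        if any(x != h for x in sums):
            raise ValueError(
                "inconsistent explicit tube lengths: root-to-leaf paths cross "
                f"different numbers of slices ({sorted(set(sums))})"
            )
        seg_of = {id(n): n.segments for n in ingroup.preorder()}

    S0 = SlicedSpeciesTree()
    S0.d0 = S0._new_tube(None, 0, False, None, "d0")

    def emit(n: SpNode, parent_tube: int, s: int) -> None:
        segs = seg_of[id(n)]
        old = n.name
        cur = parent_tube
        for k in range(segs):
            last = k == segs - 1
            species = n.name if (n.is_leaf and last) else None
            cur = S0._new_tube(cur, s + k + 1, False, species, old)
        for c in n.children:
            emit(c, cur, s + segs)

    emit(ingroup, S0.d0, 0)
    # the outgroup tube: one segment per slice 1..h, terminal at the bottom
    cur = S0.d0
    for k in range(h):
        species = OUTGROUP if k == h - 1 else None
        cur = S0._new_tube(cur, k + 1, True, species, OUTGROUP)
    S0._finalize()
    return S0


def slice_species_tree(newick: str, mode: str = "auto") -> SlicedSpeciesTree:
    """Convenience: parse, attach the outgroup and slice in one call."""
    return build_slices(attach_outgroup(parse_species_tree(newick)), mode)


def aggregate_by_old_tube(
    S0: SlicedSpeciesTree, values: dict[int, float]
) -> dict[str, float]:
    """Sum a per-(new)tube statistic over the segments of each original tube."""
    missing = [d for d in range(S0.n_tubes) if d not in values]
    if missing:
        raise KeyError(f"values missing for tubes {missing}")
    out: dict[str, float] = {}
    for d in range(S0.n_tubes):
        key = S0.old_id[d]
        out[key] = out.get(key, 0.0) + values[d]
    return out
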