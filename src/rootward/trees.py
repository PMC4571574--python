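"""Rooted phylogenetic trees, newick I/O, clades and root splits.

Under stationary, reversible substitution models the likelihood does not
depend on where a tree is rooted, so most phylogenetic software works with
unrooted topologies.  The models in this package *are* informative about the
root, which makes the rooted tree the central data structure: a binary tree
whose root has exactly two children, with a strictly positive branch length
(expected substitutions per site) on every edge.

Edges are identified with their child node, and node identifiers are stable
across :meth:`RootedTree.copy` and across the topology operations
(:func:`rooted_nni`, :func:`reroot_at_edge`).  This is what lets branch-level
parameters (the per-branch composition vectors of the HB model) "travel" with
their physical edge while the sampler rearranges the topology.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import dendropy

__all__ = [
    "TreeError",
    "Node",
    "RootedTree",
    "RootSplit",
    "Clade",
    "parse_newick",
    "root_split_of",
    "enumerate_rootings",
    "unroot",
    "reroot_at_edge",
    "rooted_nni",
    "random_rooted_tree",
    "MERGED_EDGE",
]

#: sentinel marking, in :class:`RerootInfo.edge_origin`, the physical edge that
#: results from suppressing the old root (its two root-adjacent half-edges fused).
MERGED_EDGE = -1


class TreeError(ValueError):
    """Malformed newick input or an invalid tree operation."""


class Node:
    """A tree node; the edge *above* a node carries ``length``."""

    __slots__ = ("id", "label", "length", "parent", "children")

    def __init__(self, node_id: int, label: Optional[str] = None,
                 length: Optional[float] = None) -> None:
        self.id = node_id
        self.label = label
        self.length = length
        self.parent: Optional["Node"] = None
        self.children: List["Node"] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.id}, label={self.label!r})"


class RootedTree:
    """A rooted phylogeny with stable integer node/edge identifiers.

    The root normally has two children (a rooted binary tree).  A root with
    three children is tolerated as the representation of an *unrooted* binary
    tree (the basal trifurcation of unrooted newick); such trees are only
    accepted by :func:`enumerate_rootings` and :func:`reroot_at_edge`.
    """

    def __init__(self, root: Node, nodes: Dict[int, Node], next_id: int) -> None:
        self.root = root
        self._nodes = nodes
        self._next_id = next_id

    # ------------------------------------------------------------------ access

    def node(self, node_id: int) -> Node:
        return self._nodes[node_id]

    def nodes(self) -> Iterator[Node]:
        return iter(self._nodes.values())

    def postorder(self) -> List[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        out.reverse()
        return out

    def preorder(self) -> List[Node]:
        out: List[Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(reversed(nd.children))
        return out

    def leaves(self) -> List[Node]:
        return [nd for nd in self.postorder() if nd.is_leaf]

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(nd.label for nd in self.leaves())

    @property
    def n_leaves(self) -> int:
        return sum(1 for nd in self._nodes.values() if nd.is_leaf)

    def edges(self) -> List[Node]:
        """All edges, as their child nodes (every node except the root)."""
        return [nd for nd in self.postorder() if nd.parent is not None]

    @property
    def is_rooted_binary(self) -> bool:
        return len(self.root.children) == 2

    def clade(self, node: Node) -> frozenset:
        """Leaf-label set of the subtree below ``node``."""
        if node.is_leaf:
            return frozenset((node.label,))
        out = []
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                out.append(nd.label)
            else:
                stack.extend(nd.children)
        return frozenset(out)

    def clade_set(self) -> frozenset:
        """All clades (one per node below the root); identifies the rooted topology."""
        return frozenset(self.clade(nd) for nd in self.edges())

    # ------------------------------------------------------------------- edit

    def _claim_id(self) -> int:
        nid = self._next_id
        self._next_id += 1
        return nid

    def copy(self) -> "RootedTree":
        nodes: Dict[int, Node] = {}

        def rec(nd: Node) -> Node:
            new = Node(nd.id, nd.label, nd.length)
            nodes[nd.id] = new
            for ch in nd.children:
                new.add_child(rec(ch))
            return new

        return RootedTree(rec(self.root), nodes, self._next_id)

    # -------------------------------------------------------------- validation

    def validate(self) -> None:
        """Raise :class:`TreeError` unless this is a valid rooted binary tree."""
        if len(self.root.children) != 2:
            raise TreeError(
                f"root must have exactly 2 children, found {len(self.root.children)}")
        labels = []
        n_edges = 0
        n_internal = 0
        for nd in self.postorder():
            if nd.parent is not None:
                n_edges += 1
                if nd.length is None or not (nd.length > 0) or nd.length != nd.length:
                    raise TreeError(
                        f"edge above node {nd.label or nd.id} has invalid length {nd.length}")
            if nd.is_leaf:
                if not nd.label:
                    raise TreeError("leaf with empty label")
                labels.append(nd.label)
            else:
                n_internal += 1
                if nd.parent is not None and len(nd.children) != 2:
                    raise TreeError(
                        f"internal node {nd.id} has {len(nd.children)} children (must be 2)")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dup}")
        n = len(labels)
        if n_edges != 2 * n - 2 or n_internal != n - 1:
            raise TreeError(
                f"tree with {n} leaves has {n_edges} edges / {n_internal} internal nodes")

    # ------------------------------------------------------------------ output

    def newick(self, include_supports: bool = False, digits: int = 10) -> str:
        """Newick string with branch lengths always written (``%.10g``).

        Internal node ``label`` attributes (used for posterior supports on
        consensus trees) are emitted only when ``include_supports`` is set.
        """

        def fmt(nd: Node) -> str:
            if nd.is_leaf:
                s = nd.label
            else:
                s = "(" + ",".join(fmt(c) for c in nd.children) + ")"
                if include_supports and nd.label is not None:
                    s += str(nd.label)
            if nd.parent is not None:
                s += ":" + ("%.*g" % (digits, nd.length))
            return s

        return fmt(self.root) + ";"

    def canonical_newick(self) -> str:
        """Newick with children sorted by smallest descendant label (stable form)."""

        def key(nd: Node):
            return min(self.clade(nd)) if not nd.is_leaf else nd.label

        def fmt(nd: Node) -> str:
            if nd.is_leaf:
                s = nd.label
            else:
                s = "(" + ",".join(fmt(c) for c in sorted(nd.children, key=key)) + ")"
            if nd.parent is not None:
                s += ":" + ("%.10g" % nd.length)
            return s

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"RootedTree({self.newick()})"


# ---------------------------------------------------------------------- splits


@dataclass(frozen=True)
class RootSplit:
    """The taxon bipartition induced by deleting the root.

    Canonical form: ``sides[0]`` contains the lexicographically smallest label,
    which makes the split hashable and stable as a table key.
    """

    sides: Tuple[frozenset, frozenset]

    @classmethod
    def from_sets(cls, a, b) -> "RootSplit":
        a, b = frozenset(a), frozenset(b)
        if not a or not b:
            raise TreeError("root split sides must be non-empty")
        if a & b:
            raise TreeError("root split sides must be disjoint")
        if min(a) > min(b):
            a, b = b, a
        return cls((a, b))

    def __str__(self) -> str:
        fmt = lambda s: ",".join(sorted(s))
        return fmt(self.sides[0]) + "|" + fmt(self.sides[1])

    @classmethod
    def from_string(cls, s: str) -> "RootSplit":
        left, right = s.split("|")
        return cls.from_sets(left.split(","), right.split(","))


@dataclass(frozen=True)
class Clade:
    """A leaf-label subset with its posterior support."""

    labels: frozenset
    support: float

    def __post_init__(self):
        if not self.labels:
            raise TreeError("empty clade")
        if not 0.0 <= self.support <= 1.0:
            raise TreeError(f"support {self.support} outside [0, 1]")


def root_split_of(tree: RootedTree) -> RootSplit:
    """Bipartition of the leaf set induced by deleting the root."""
    c0 = tree.clade(tree.root.children[0])
    rest = tree.leaf_labels - c0
    return RootSplit.from_sets(c0, rest)


# --------------------------------------------------------------------- parsing


def parse_newick(text: str) -> RootedTree:
    """Parse a newick string into a :class:`RootedTree`.

    The root may be bifurcating (rooted tree) or trifurcating (unrooted tree;
    pass it to :func:`enumerate_rootings` or :func:`reroot_at_edge` to root
    it).  Branch lengths are mandatory and must be positive; labels are kept
    verbatim (underscores preserved, no sanitization).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeError(f"newick parse error: {exc}") from None

    nodes: Dict[int, Node] = {}
    counter = [0]

    def conv(dnode, is_root: bool) -> Node:
        nid = counter[0]
        counter[0] += 1
        label = dnode.taxon.label if dnode.taxon is not None else None
        nd = Node(nid, label=label)
        nodes[nid] = nd
        if not is_root:
            bl = dnode.edge.length
            if bl is None:
                raise TreeError(
                    f"missing branch length above {label or 'an internal node'}")
            if not (bl > 0):
                raise TreeError(
                    f"non-positive branch length {bl} above {label or 'an internal node'}")
            nd.length = float(bl)
        for dchild in dnode.child_nodes():
            nd.add_child(conv(dchild, False))
        if nd.children and len(nd.children) != 2 and not is_root:
            raise TreeError(f"non-binary internal node with {len(nd.children)} children")
        if is_root and len(nd.children) not in (2, 3) and nd.children:
            raise TreeError(f"root must have 2 or 3 children, found {len(nd.children)}")
        return nd

    root = conv(dtree.seed_node, True)
    tree = RootedTree(root, nodes, counter[0])
    labels = [nd.label for nd in tree.leaves()]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate leaf labels: {dup}")
    if any(not l for l in labels):
        raise TreeError("leaf with empty label")
    if len(labels) < 2:
        raise TreeError("a tree needs at least 2 leaves")
    return tree


# -------------------------------------------------------------------- rooting


def unroot(tree: RootedTree) -> RootedTree:
    """Suppress a binary root, yielding the trifurcating-base representation.

    The two root-adjacent edges fuse into one (lengths added), attached below
    whichever root child is internal.
    """
    if len(tree.root.children) == 3:
        return tree.copy()
    if tree.n_leaves < 3:
        raise TreeError("cannot unroot a tree with fewer than 3 leaves")
    t = tree.copy()
    c1, c2 = t.root.children
    base = c1 if not c1.is_leaf else c2
    other = c2 if base is c1 else c1
    other.length = c1.length + c2.length
    base.children.append(other)
    other.parent = base
    base.parent = None
    base.length = None
    del t._nodes[t.root.id]
    t.root = base
    return t


@dataclass
class RerootInfo:
    """Bookkeeping for :func:`reroot_at_edge`, needed by the MCMC root move.

    ``edge_origin`` maps each new-tree edge (child id) to the physical edge it
    came from in the input tree (old child id), with :data:`MERGED_EDGE`
    marking the fused former root edge.
    """

    split_child_id: int
    split_length: float
    edge_origin: Dict[int, int] = field(default_factory=dict)
    merged_child_id: Optional[int] = None
    merged_length: Optional[float] = None
    old_root_child_ids: Tuple[int, ...] = ()
    slide: bool = False


def reroot_at_edge(tree: RootedTree, node_id: int,
                   fraction: float = 0.5) -> Tuple[RootedTree, RerootInfo]:
    """Place the root on the edge above ``node_id``, at ``fraction`` of its length.

    Works on rooted trees (the old root is suppressed first) and on
    trifurcating-base unrooted trees.  Returns a new tree plus a
    :class:`RerootInfo` describing how physical edges map between the two,
    which the HB sampler uses to carry per-branch compositions across the move.
    """
    if not (0.0 < fraction < 1.0):
        raise TreeError(f"fraction must lie in (0,1), got {fraction}")
    t = tree.copy()
    x = t.node(node_id)
    if x.parent is None:
        raise TreeError("cannot reroot on the root node itself")
    old_root = t.root
    binary_root = len(old_root.children) == 2

    if binary_root and x.parent is old_root:
        # Sliding the root along its current edge: just re-partition lengths.
        sib = next(c for c in old_root.children if c is not x)
        total = x.length + sib.length
        x.length = fraction * total
        sib.length = total - x.length
        info = RerootInfo(
            split_child_id=x.id, split_length=total,
            edge_origin={nd.id: nd.id for nd in t.edges()},
            merged_length=total,
            old_root_child_ids=tuple(c.id for c in old_root.children),
            slide=True)
        return t, info

    # Undirected adjacency with per-edge (length, physical origin id).
    adj: Dict[Node, List[Tuple[Node, float, int]]] = defaultdict(list)
    for nd in list(t.nodes()):
        if nd.parent is None:
            continue
        if binary_root and nd.parent is old_root:
            continue
        adj[nd.parent].append((nd, nd.length, nd.id))
        adj[nd].append((nd.parent, nd.length, nd.id))

    old_root_child_ids: Tuple[int, ...] = ()
    if binary_root:
        r1, r2 = old_root.children
        old_root_child_ids = (r1.id, r2.id)
        fused = r1.length + r2.length
        adj[r1].append((r2, fused, MERGED_EDGE))
        adj[r2].append((r1, fused, MERGED_EDGE))
        new_root = old_root            # reuse the node (and its id)
    else:
        new_root = Node(t._claim_id())
        t._nodes[new_root.id] = new_root

    # Split the edge above x.
    p = x.parent
    lx = x.length
    adj[x] = [e for e in adj[x] if e[0] is not p]
    adj[p] = [e for e in adj[p] if e[0] is not x]
    adj[new_root] = [(x, fraction * lx, x.id), (p, (1.0 - fraction) * lx, x.id)]
    adj[x].append((new_root, fraction * lx, x.id))
    adj[p].append((new_root, (1.0 - fraction) * lx, x.id))

    # Re-orient everything away from the new root.
    for nd in t.nodes():
        nd.children = []
        nd.parent = None
        if nd is not new_root:
            nd.length = None
    new_root.length = None
    edge_origin: Dict[int, int] = {}
    merged_child_id = None
    seen = {new_root}
    queue = deque([new_root])
    while queue:
        nd = queue.popleft()
        for nbr, length, origin in adj[nd]:
            if nbr in seen:
                continue
            seen.add(nbr)
            nd.add_child(nbr)
            nbr.length = length
            edge_origin[nbr.id] = origin
            if origin == MERGED_EDGE:
                merged_child_id = nbr.id
            queue.append(nbr)
    t.root = new_root
    info = RerootInfo(
        split_child_id=x.id, split_length=lx, edge_origin=edge_origin,
        merged_child_id=merged_child_id,
        merged_length=(fused if binary_root else None),
        old_root_child_ids=old_root_child_ids, slide=False)
    return t, info


def enumerate_rootings(tree: RootedTree) -> List[RootedTree]:
    """All 2n−3 rooted trees obtained by rooting each edge of an unrooted tree.

    Accepts a trifurcating-base unrooted tree or a rooted binary tree (which
    is unrooted first).  The root is inserted at the midpoint of each edge —
    a neutral initialization convention; a sampler moves it afterwards.
    """
    if tree.n_leaves < 3:
        raise TreeError("need at least 3 leaves to enumerate rootings")
    base = unroot(tree) if len(tree.root.children) == 2 else tree
    out = []
    for nd in base.edges():
        rooted, _ = reroot_at_edge(base, nd.id, 0.5)
        rooted.validate()
        out.append(rooted)
    return out


# -------------------------------------------------------------------- editing


def rooted_nni(tree: RootedTree, v_id: int, which_child: int) -> RootedTree:
    """Rooted nearest-neighbour interchange around internal node ``v_id``.

    Swaps child ``which_child`` of v with v's sibling.  Branch lengths (and,
    by id-stability, any per-edge parameters) travel with their subtrees.
    The move is an involution: applying it twice restores the input.
    """
    t = tree.copy()
    v = t.node(v_id)
    if v.parent is None or v.is_leaf:
        raise TreeError("NNI requires an internal, non-root node")
    p = v.parent
    w = next(c for c in p.children if c is not v)
    c = v.children[which_child]
    p.children[p.children.index(w)] = c
    v.children[which_child] = w
    c.parent = p
    w.parent = v
    return t


def nni_candidates(tree: RootedTree) -> List[Tuple[int, int]]:
    """All (v_id, which_child) pairs eligible for :func:`rooted_nni`."""
    out = []
    for nd in tree.postorder():
        if nd.parent is not None and not nd.is_leaf:
            out.extend([(nd.id, 0), (nd.id, 1)])
    return out


def random_rooted_tree(labels: Sequence[str], rng,
                       mean_branch_length: float = 0.1) -> RootedTree:
    """Uniform random rooted binary topology via sequential leaf insertion.

    Leaf k+1 attaches to one of the current 2k−2 edges or above the root
    (2k−1 equiprobable choices), which yields the uniform distribution over
    the (2n−3)!! labelled rooted topologies.  Branch lengths are iid
    Exponential with the given mean.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise TreeError("need at least 2 labels")
    if len(set(labels)) != len(labels):
        raise TreeError("duplicate labels")

    def bl() -> float:
        # clip away underflow-tiny draws; lengths must be strictly positive
        return max(rng.exponential(mean_branch_length), 1e-9)

    nodes: Dict[int, Node] = {}
    nid = [0]

    def new_node(label=None, length=None):
        nd = Node(nid[0], label=label, length=length)
        nodes[nd.id] = nd
        nid[0] += 1
        return nd

    root = new_node()
    a = new_node(labels[0], bl())
    b = new_node(labels[1], bl())
    root.add_child(a)
    root.add_child(b)
    tree = RootedTree(root, nodes, 0)
    tree._next_id = nid[0]

    for label in labels[2:]:
        edges = tree.edges()
        k = rng.integers(0, len(edges) + 1)
        leaf = Node(tree._claim_id(), label=label, length=bl())
        tree._nodes[leaf.id] = leaf
        knot = Node(tree._claim_id())
        tree._nodes[knot.id] = knot
        if k == len(edges):      # new root above the old one
            knot.add_child(tree.root)
            tree.root.length = bl()
            knot.add_child(leaf)
            tree.root = knot
        else:
            target = edges[k]
            parent = target.parent
            parent.children[parent.children.index(target)] = knot
            knot.parent = parent
            knot.length = target.length * 0.5
            target.length *= 0.5
            knot.add_child(target)
            knot.add_child(leaf)
    tree.validate()
    return tree
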