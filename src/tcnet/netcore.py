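"""Rooted binary phylogenetic network data structure and elementary surgery.

A :class:`PhyloNetwork` is a leaf-labeled directed acyclic graph with

* a unique indegree-0 node of outdegree 1 (the root),
* labeled leaves of indegree 1 and outdegree 0, labels forming a bijection
  with ``{1..n}``,
* internal *tree nodes* (indegree 1, outdegree 2) and *reticulate nodes*
  (indegree 2, outdegree 1),
* no parallel edges.

Nodes are referenced by opaque integers (``NodeRef``) allocated by a
per-network monotone counter; edges by ``(parent, child)`` pairs
(``EdgeRef``).  NodeRefs are only meaningful within the network that
allocated them — isomorphism never depends on them.

This module also provides the elementary surgery used by the rearrangement
operations: edge subdivision, leaf deletion with smoothing, and copying.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional, Tuple

from .errors import (
    LabelError,
    MissingEdgeError,
    MissingNodeError,
    MissingTaxonError,
    ParameterError,
    StructuralError,
)

NodeRef = int
EdgeRef = Tuple[int, int]


class PhyloNetwork:
    """Mutable rooted phylogenetic network.

    The mutating methods perform only local bookkeeping; global structural
    invariants are checked by :func:`validate`.  Construction code (and the
    rearrange module) may therefore pass through transiently invalid states,
    but every public operation of the library returns networks for which
    ``validate`` reports no violations.
    """

    __slots__ = ("_children", "_parents", "leaf_label", "_label_node", "root",
                 "_next_id", "_cache")

    def __init__(self) -> None:
        self._children: Dict[int, List[int]] = {}
        self._parents: Dict[int, List[int]] = {}
        #: NodeRef -> taxon (partial map; exactly the leaves are labeled)
        self.leaf_label: Dict[int, int] = {}
        self._label_node: Dict[int, int] = {}
        self.root: Optional[int] = None
        self._next_id = 0
        self._cache: Dict[str, object] = {}

    # -- construction -----------------------------------------------------

    def new_node(self) -> int:
        """Allocate a fresh node and return its NodeRef."""
        v = self._next_id
        self._next_id += 1
        self._children[v] = []
        self._parents[v] = []
        self._cache.clear()
        return v

    def add_edge(self, u: int, v: int) -> None:
        """Add the directed edge ``u -> v``.

        Parallel edges are *not* rejected here; :func:`validate` reports
        them, which lets tests build deliberately broken networks.
        """
        if u not in self._children:
            raise MissingNodeError(u)
        if v not in self._children:
            raise MissingNodeError(v)
        self._children[u].append(v)
        self._parents[v].append(u)
        self._cache.clear()

    def remove_edge(self, u: int, v: int) -> None:
        try:
            self._children[u].remove(v)
            self._parents[v].remove(u)
        except (KeyError, ValueError):
            raise MissingEdgeError((u, v)) from None
        self._cache.clear()

    def remove_node(self, v: int) -> None:
        """Remove ``v`` together with all incident edges and its label."""
        if v not in self._children:
            raise MissingNodeError(v)
        for c in list(self._children[v]):
            self.remove_edge(v, c)
        for p in list(self._parents[v]):
            self.remove_edge(p, v)
        del self._children[v]
        del self._parents[v]
        taxon = self.leaf_label.pop(v, None)
        if taxon is not None:
            del self._label_node[taxon]
        if self.root == v:
            self.root = None
        self._cache.clear()

    def set_leaf_label(self, v: int, taxon: int) -> None:
        if v not in self._children:
            raise MissingNodeError(v)
        if taxon in self._label_node:
            raise LabelError(f"taxon {taxon} is already used")
        old = self.leaf_label.pop(v, None)
        if old is not None:
            del self._label_node[old]
        self.leaf_label[v] = taxon
        self._label_node[taxon] = v
        self._cache.clear()

    # -- queries ----------------------------------------------------------

    def nodes(self) -> List[int]:
        return list(self._children)

    def num_nodes(self) -> int:
        return len(self._children)

    def edges(self) -> Iterator[EdgeRef]:
        for u, cs in self._children.items():
            for c in cs:
                yield (u, c)

    def sorted_edges(self) -> List[EdgeRef]:
        return sorted(self.edges())

    def num_edges(self) -> int:
        return sum(len(cs) for cs in self._children.values())

    def has_edge(self, u: int, v: int) -> bool:
        return u in self._children and v in self._children[u]

    def children(self, v: int) -> Tuple[int, ...]:
        try:
            return tuple(self._children[v])
        except KeyError:
            raise MissingNodeError(v) from None

    def parents(self, v: int) -> Tuple[int, ...]:
        try:
            return tuple(self._parents[v])
        except KeyError:
            raise MissingNodeError(v) from None

    def indegree(self, v: int) -> int:
        try:
            return len(self._parents[v])
        except KeyError:
            raise MissingNodeError(v) from None

    def outdegree(self, v: int) -> int:
        try:
            return len(self._children[v])
        except KeyError:
            raise MissingNodeError(v) from None

    def is_leaf(self, v: int) -> bool:
        return v in self.leaf_label

    def is_reticulate(self, v: int) -> bool:
        return len(self._parents[v]) == 2

    def is_tree_node(self, v: int) -> bool:
        return (v != self.root and v not in self.leaf_label
                and len(self._parents[v]) == 1)

    def n_taxa(self) -> int:
        return len(self.leaf_label)

    def taxa(self) -> List[int]:
        return sorted(self._label_node)

    def reticulation_count(self) -> int:
        return sum(1 for ps in self._parents.values() if len(ps) == 2)

    def leaf_with_label(self, taxon: int) -> int:
        try:
            return self._label_node[taxon]
        except KeyError:
            raise MissingTaxonError(taxon) from None

    # -- copying ----------------------------------------------------------

    def copy(self) -> "PhyloNetwork":
        """Independent deep copy.

        NodeRefs keep their numeric values (the structure-preserving map is
        the identity on ids), but the copy shares no mutable state with the
        original; NodeRef equality across networks carries no meaning.
        """
        M = PhyloNetwork.__new__(PhyloNetwork)
        M._children = {v: list(cs) for v, cs in self._children.items()}
        M._parents = {v: list(ps) for v, ps in self._parents.items()}
        M.leaf_label = dict(self.leaf_label)
        M._label_node = dict(self._label_node)
        M.root = self.root
        M._next_id = self._next_id
        M._cache = {}
        return M

    def relabeled(self, mapping: Optional[Dict[int, int]] = None) -> "PhyloNetwork":
        """Return a copy with NodeRefs remapped through ``mapping``.

        Used by tests to certify that structural predicates and canonical
        codes do not depend on node-id allocation order.  The default
        mapping reverses the id order.
        """
        ids = sorted(self._children)
        if mapping is None:
            m = len(ids)
            mapping = {v: ids[m - 1 - i] for i, v in enumerate(ids)}
        if sorted(mapping) != ids or len(set(mapping.values())) != len(mapping):
            raise ParameterError("mapping must be a bijection on the node set")
        M = PhyloNetwork()
        for v in sorted(mapping.values()):
            M._children[v] = []
            M._parents[v] = []
        M._next_id = max(mapping.values()) + 1
        for u, v in self.sorted_edges():
            M.add_edge(mapping[u], mapping[v])
        for v, t in self.leaf_label.items():
            M.set_leaf_label(mapping[v], t)
        M.root = mapping[self.root] if self.root is not None else None
        return M

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"<PhyloNetwork n={self.n_taxa()} k={self.reticulation_count()} "
                f"|V|={self.num_nodes()} |E|={self.num_edges()}>")


# -- base networks --------------------------------------------------------

def base_network(n_taxa: int) -> PhyloNetwork:
    """The unique phylogenetic tree on one or two taxa.

    These two networks are the generation bases: every tree, tree-child
    network and normal network on more taxa is produced from them by the
    rearrange operations.
    """
    if n_taxa not in (1, 2):
        raise ParameterError(f"base_network requires n_taxa in {{1, 2}}, got {n_taxa}")
    N = PhyloNetwork()
    root = N.new_node()
    N.root = root
    if n_taxa == 1:
        leaf = N.new_node()
        N.add_edge(root, leaf)
        N.set_leaf_label(leaf, 1)
    else:
        t = N.new_node()
        a = N.new_node()
        b = N.new_node()
        N.add_edge(root, t)
        N.add_edge(t, a)
        N.add_edge(t, b)
        N.set_leaf_label(a, 1)
        N.set_leaf_label(b, 2)
    return N


# -- validation -----------------------------------------------------------

def topological_order(N: PhyloNetwork) -> Optional[List[int]]:
    """Kahn topological order of the nodes, or None if the digraph is cyclic."""
    indeg = {v: len(N._parents[v]) for v in N._children}
    stack = [v for v, d in indeg.items() if d == 0]
    order: List[int] = []
    while stack:
        v = stack.pop()
        order.append(v)
        for c in N._children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if len(order) != len(indeg):
        return None
    return order


def validate(N: PhyloNetwork) -> List[str]:
    """Check all structural invariants; return a list of violations (empty iff valid)."""
    out: List[str] = []
    nodes = N._children
    if not nodes:
        return ["network has no nodes"]
    sources = [v for v in nodes if len(N._parents[v]) == 0]
    if N.root is None or N.root not in nodes:
        out.append("root is unset or not a node of the network")
    if len(sources) != 1:
        out.append(f"expected exactly one indegree-0 node, found {len(sources)}")
    elif N.root is not None and sources[0] != N.root:
        out.append(f"indegree-0 node {sources[0]} is not the designated root {N.root}")
    if N.root in nodes and len(N._children[N.root]) != 1:
        out.append(f"root must have outdegree 1, has {len(N._children[N.root])}")

    labels = sorted(N.leaf_label.values())
    if labels != list(range(1, len(labels) + 1)):
        out.append(f"leaf labels {labels} are not a bijection with 1..n")
    for v, t in N.leaf_label.items():
        if len(N._children[v]) != 0 or len(N._parents[v]) != 1:
            out.append(f"labeled node {v} (taxon {t}) must have indegree 1 and outdegree 0")

    for v in nodes:
        if v == N.root or v in N.leaf_label:
            continue
        sig = (len(N._parents[v]), len(N._children[v]))
        if sig not in ((1, 2), (2, 1)):
            out.append(f"node {v} has degree signature in/out = {sig}; "
                       "expected tree node (1,2) or reticulate node (2,1)")

    for v, cs in N._children.items():
        if len(cs) != len(set(cs)):
            dup = sorted(c for c in set(cs) if cs.count(c) > 1)
            out.append(f"parallel edges from node {v} to {dup}")

    if topological_order(N) is None:
        out.append("the digraph contains a directed cycle")
    return out


# -- accessors ------------------------------------------------------------

def leaves(N: PhyloNetwork) -> List[int]:
    return sorted(N.leaf_label)


def reticulate_nodes(N: PhyloNetwork) -> List[int]:
    return sorted(v for v in N._children if len(N._parents[v]) == 2)


def tree_nodes(N: PhyloNetwork) -> List[int]:
    return sorted(v for v in N._children
                  if v != N.root and v not in N.leaf_label
                  and len(N._parents[v]) == 1)


def tree_edges(N: PhyloNetwork) -> List[EdgeRef]:
    """Edges whose head is a tree node or a leaf, sorted for determinism.

    A tree-child network with n leaves and k reticulations has exactly
    ``2n + k - 1`` of them.
    """
    return sorted((u, v) for u, v in N.edges() if len(N._parents[v]) != 2)


def reticulate_edges(N: PhyloNetwork) -> List[EdgeRef]:
    return sorted((u, v) for u, v in N.edges() if len(N._parents[v]) == 2)


# -- elementary surgery ---------------------------------------------------

def _subdivide_inplace(N: PhyloNetwork, e: EdgeRef) -> int:
    u, v = e
    if not N.has_edge(u, v):
        raise MissingEdgeError(e)
    w = N.new_node()
    N.remove_edge(u, v)
    N.add_edge(u, w)
    N.add_edge(w, v)
    return w


def subdivide(N: PhyloNetwork, e: EdgeRef) -> Tuple[PhyloNetwork, int]:
    """Replace ``e = (u, v)`` by ``(u, w), (w, v)`` with a fresh node ``w``.

    Returns ``(copy_of_N, w)``.  The result is transiently invalid (``w``
    has degree signature (1,1)); the caller must attach a second child or a
    second parent to ``w`` to restore validity.
    """
    M = N.copy()
    w = _subdivide_inplace(M, e)
    return M, w


def delete_leaf_smooth(N: PhyloNetwork, taxon: int) -> PhyloNetwork:
    """Remove a labeled leaf and suppress its (tree-node) parent.

    The parent's remaining neighbours are joined by a new edge.  If the
    leaf's parent is reticulate, or if the suppression would create a
    parallel edge, a :class:`StructuralError` is raised — those
    configurations must be undone through the reverse reduction in the
    rearrange module instead.
    """
    M = N.copy()
    leaf = M.leaf_with_label(taxon)
    parents = M.parents(leaf)
    if len(parents) != 1:
        raise StructuralError(f"leaf of taxon {taxon} has indegree {len(parents)}")
    p = parents[0]
    if p == M.root:
        raise StructuralError("cannot delete the only leaf of a one-taxon network")
    if M.indegree(p) == 2:
        raise StructuralError(
            f"parent of leaf {taxon} is a reticulate node; "
            "smoothing does not apply (use the reverse reduction)")
    g = M.parents(p)[0]
    others = [c for c in M.children(p) if c != leaf]
    if len(others) != 1:
        raise StructuralError(f"parent of leaf {taxon} does not have exactly one other child")
    c = others[0]
    M.remove_node(leaf)
    M.remove_node(p)
    if M.has_edge(g, c):
        raise StructuralError(
            f"suppressing node {p} would create a parallel edge {g}->{c}")
    M.add_edge(g, c)
    bad = validate(M)
    if bad:
        raise StructuralError("leaf deletion left an invalid network: " + "; ".join(bad))
    return M
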