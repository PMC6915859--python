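"""Leaf-label-preserving isomorphism and canonical codes.

Two routes are provided on purpose:

* :func:`are_isomorphic` — a backtracking search for a node bijection that
  preserves edges and fixes every leaf label.  It makes no use of the
  canonical code.
* :func:`canonical_code` — a total invariant built from the multiset of
  per-node path-count vectors (the number of directed paths from each node
  to each labeled leaf).  Equal codes are *necessary* for isomorphism by
  construction; that they are also sufficient on tree-child networks is
  certified empirically by the test suite against the backtracking route.

The enumeration module uses the code for duplicate detection; the tests
use both routes against each other.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from . import classify, netcore
from .errors import ContractError, UnsupportedClassError
from .netcore import PhyloNetwork

CanonicalCode = bytes


# -- canonical code -------------------------------------------------------

def path_count_vectors(N: PhyloNetwork) -> Dict[int, Tuple[int, ...]]:
    """Per-node vector of directed path counts to each leaf (taxon order)."""
    order = netcore.topological_order(N)
    if order is None:
        raise ContractError("path_count_vectors requires an acyclic network")
    taxa = N.taxa()
    idx = {t: i for i, t in enumerate(taxa)}
    zero = (0,) * len(taxa)
    vec: Dict[int, Tuple[int, ...]] = {}
    children = N._children
    label = N.leaf_label
    for v in reversed(order):
        cs = children[v]
        if not cs:
            t = label.get(v)
            if t is None:
                vec[v] = zero
            else:
                row = list(zero)
                row[idx[t]] = 1
                vec[v] = tuple(row)
        elif len(cs) == 1:
            vec[v] = vec[cs[0]]
        else:
            acc = list(vec[cs[0]])
            for c in cs[1:]:
                w = vec[c]
                for i in range(len(acc)):
                    acc[i] += w[i]
            vec[v] = tuple(acc)
    return vec


def canonical_key(N: PhyloNetwork) -> Tuple:
    """Hashable isomorphism invariant (no validity / class checking).

    Internal fast path used by enumeration verification and by the tests;
    :func:`canonical_code` wraps it with the contract checks and a byte
    serialization.
    """
    vec = path_count_vectors(N)
    return (tuple(N.taxa()), tuple(sorted(vec.values())))


def canonical_code(N: PhyloNetwork) -> CanonicalCode:
    """Byte-string canonical code of a tree-child network.

    Raises :class:`UnsupportedClassError` on non-tree-child input: the
    code's completeness is only certified for the tree-child class.
    """
    if not classify.is_tree_child(N):
        raise UnsupportedClassError(
            "canonical_code is only certified for tree-child networks")
    taxa, rows = canonical_key(N)
    parts = [",".join(map(str, taxa))]
    parts.extend("|" + ",".join(map(str, row)) for row in rows)
    return "".join(parts).encode("ascii")


# -- backtracking isomorphism --------------------------------------------

def _quick_signature(N: PhyloNetwork) -> Tuple:
    sig = N._cache.get("iso_sig")
    if sig is None:
        degrees = sorted((N.indegree(v), N.outdegree(v)) for v in N._children)
        leaf_ctx = sorted(
            (t, N.indegree(N.parents(v)[0]), N.outdegree(N.parents(v)[0]))
            for v, t in N.leaf_label.items() if N.parents(v))
        sig = (N.num_nodes(), N.num_edges(), tuple(N.taxa()),
               tuple(degrees), tuple(leaf_ctx))
        N._cache["iso_sig"] = sig
    return sig


def are_isomorphic(N1: PhyloNetwork, N2: PhyloNetwork) -> bool:
    """Existence of a node bijection preserving edges and fixing leaf labels.

    Backtracking seeded by the forced leaf correspondence; nodes of N1 are
    processed children-before-parents so each internal node's image is
    constrained by the (already mapped) images of its children.
    """
    if _quick_signature(N1) != _quick_signature(N2):
        return False

    order = netcore.topological_order(N1)
    order2 = netcore.topological_order(N2)
    if order is None or order2 is None:
        raise ContractError("are_isomorphic requires acyclic networks")
    rev = list(reversed(order))  # children before parents

    # index N2's internal nodes by their frozenset of children
    by_children: Dict[frozenset, List[int]] = {}
    for v in N2._children:
        if N2._children[v]:
            by_children.setdefault(frozenset(N2._children[v]), []).append(v)
    sig2 = {v: (N2.indegree(v), N2.outdegree(v)) for v in N2._children}

    mapping: Dict[int, int] = {}
    used: set = set()

    def assign(i: int) -> bool:
        if i == len(rev):
            return True
        u = rev[i]
        t = N1.leaf_label.get(u)
        if t is not None:
            v = N2._label_node.get(t)
            if v is None or v in used:
                return False
            mapping[u] = v
            used.add(v)
            if assign(i + 1):
                return True
            used.discard(v)
            del mapping[u]
            return False
        image = frozenset(mapping[c] for c in N1._children[u])
        usig = (N1.indegree(u), N1.outdegree(u))
        for v in by_children.get(image, ()):
            if v in used or sig2[v] != usig:
                continue
            mapping[u] = v
            used.add(v)
            if assign(i + 1):
                return True
            used.discard(v)
            del mapping[u]
        return False

    return assign(0)


def find_isomorphism(N1: PhyloNetwork, N2: PhyloNetwork) -> Optional[Dict[int, int]]:
    """Like :func:`are_isomorphic` but returns one witness mapping (or None)."""
    # small duplicated driver kept separate so are_isomorphic stays allocation-light
    if not are_isomorphic(N1, N2):
        return None
    # re-run recording the mapping
    order = list(reversed(netcore.topological_order(N1)))
    by_children: Dict[frozenset, List[int]] = {}
    for v in N2._children:
        if N2._children[v]:
            by_children.setdefault(frozenset(N2._children[v]), []).append(v)
    sig2 = {v: (N2.indegree(v), N2.outdegree(v)) for v in N2._children}
    mapping: Dict[int, int] = {}
    used: set = set()

    def assign(i: int) -> bool:
        if i == len(order):
            return True
        u = order[i]
        t = N1.leaf_label.get(u)
        if t is not None:
            v = N2._label_node.get(t)
            if v is None or v in used:
                return False
            cands = [v]
        else:
            image = frozenset(mapping[c] for c in N1._children[u])
            usig = (N1.indegree(u), N1.outdegree(u))
            cands = [v for v in by_children.get(image, ())
                     if v not in used and sig2[v] == usig]
        for v in cands:
            mapping[u] = v
            used.add(v)
            if assign(i + 1):
                return True
            used.discard(v)
            del mapping[u]
        return False

    assign(0)
    return mapping
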