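"""Structural predicates: ancestry, incomparability, class membership.

Ancestry is *reflexive*: a node is an ancestor of itself (the defining
root-to-v path contains v).  Consequently an edge is never incomparable
with itself, and a single edge paired with itself counts as a comparable
pair.

The incomparable-pair statistic :func:`u_of` is computed over **all** edge
pairs by default; the variant restricted to tree edges (the one the
counting recurrence for k >= 2 actually needs — see the counting module)
is obtained with ``edge_scope="tree_only"``.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Tuple

from . import netcore
from .errors import ContractError, MissingEdgeError, MissingNodeError, ParameterError
from .netcore import EdgeRef, PhyloNetwork

AncestryIndex = Dict[int, FrozenSet[int]]


def descendant_sets(N: PhyloNetwork) -> AncestryIndex:
    """Reflexive reachability closure: node -> frozenset of descendants.

    Recomputed from scratch on demand (networks are tiny at desk scale)
    and memoized on the network until its next mutation.
    """
    cached = N._cache.get("desc")
    if cached is not None:
        return cached
    order = netcore.topological_order(N)
    if order is None:
        raise ContractError("descendant_sets requires an acyclic network")
    desc: Dict[int, FrozenSet[int]] = {}
    for v in reversed(order):
        s = {v}
        for c in N.children(v):
            s.update(desc[c])
        desc[v] = frozenset(s)
    N._cache["desc"] = desc
    return desc


def is_ancestor(N: PhyloNetwork, u: int, v: int) -> bool:
    """True iff some root-to-v path contains u (including u == v)."""
    if u not in N._children:
        raise MissingNodeError(u)
    if v not in N._children:
        raise MissingNodeError(v)
    return v in descendant_sets(N)[u]


def incomparable_nodes(N: PhyloNetwork, u: int, v: int) -> bool:
    """True iff neither node is an ancestor of the other."""
    if u not in N._children:
        raise MissingNodeError(u)
    if v not in N._children:
        raise MissingNodeError(v)
    desc = descendant_sets(N)
    return v not in desc[u] and u not in desc[v]


def _require_valid(N: PhyloNetwork, what: str) -> None:
    bad = netcore.validate(N)
    if bad:
        raise ContractError(f"{what} requires a valid network: " + "; ".join(bad))


def is_tree_child(N: PhyloNetwork) -> bool:
    """True iff every non-leaf node has at least one tree-node or leaf child."""
    _require_valid(N, "is_tree_child")
    for v in N._children:
        if v in N.leaf_label:
            continue
        if not any(N.indegree(c) == 1 for c in N.children(v)):
            return False
    return True


def is_normal(N: PhyloNetwork) -> bool:
    """True iff N is tree-child and each reticulate node has incomparable parents."""
    _require_valid(N, "is_normal")
    if not is_tree_child(N):
        return False
    desc = descendant_sets(N)
    for r in N._children:
        if N.indegree(r) == 2:
            p, q = N.parents(r)
            if q in desc[p] or p in desc[q]:
                return False
    return True


def edge_incomparable(N: PhyloNetwork, e1: EdgeRef, e2: EdgeRef) -> bool:
    """Incomparability of two edges, judged on their head nodes.

    An edge is never incomparable with itself (reflexive ancestry).
    """
    if not N.has_edge(*e1):
        raise MissingEdgeError(e1)
    if not N.has_edge(*e2):
        raise MissingEdgeError(e2)
    desc = descendant_sets(N)
    v1, v2 = e1[1], e2[1]
    return v2 not in desc[v1] and v1 not in desc[v2]


def u_of(N: PhyloNetwork, edge_scope: str = "all") -> int:
    """Number of unordered pairs of distinct incomparable edges in N.

    ``edge_scope`` is ``"all"`` (the defining statistic) or ``"tree_only"``
    (pairs of tree edges only; coincides with "all" when k = 0).
    """
    _require_valid(N, "u_of")
    return _u_of_unchecked(N, edge_scope)


def _u_of_unchecked(N: PhyloNetwork, edge_scope: str = "all") -> int:
    if edge_scope == "all":
        edges = N.sorted_edges()
    elif edge_scope == "tree_only":
        edges = netcore.tree_edges(N)
    else:
        raise ParameterError(f"unknown edge_scope {edge_scope!r}")
    desc = descendant_sets(N)
    heads = [e[1] for e in edges]
    count = 0
    m = len(heads)
    for i in range(m):
        di = desc[heads[i]]
        hi = heads[i]
        for j in range(i + 1, m):
            hj = heads[j]
            if hj not in di and hi not in desc[hj]:
                count += 1
    return count


def comparable_pairs(N: PhyloNetwork, edge_scope: str = "all") -> int:
    """Unordered pairs of distinct comparable edges (complement of u_of)."""
    _require_valid(N, "comparable_pairs")
    if edge_scope == "all":
        m = N.num_edges()
    else:
        m = len(netcore.tree_edges(N))
    return m * (m - 1) // 2 - _u_of_unchecked(N, edge_scope)
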