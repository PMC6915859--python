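"""The three generation operations and their reverse reduction.

* :func:`leaf_insert`   — subdivide a tree edge and hang a new labeled leaf.
* :func:`ret_insert`    — subdivide one or two tree edges, join the two
  subdivision nodes to a new reticulate node whose child is a new leaf.
* :func:`c_rotate`      — at a reticulate node r with tree-node parent u not
  ancestral to the other parent, swap r's child with u's other child.
* :func:`reduce_last`   — classify how the largest-labeled leaf was produced
  and return the unique predecessor network.

All public operations copy their input, check their preconditions, and
return validated networks.  The ``_fast`` variants skip the validation for
the enumeration inner loop; they are correct by construction there and the
test suite validates the enumeration output exhaustively at small sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from . import classify, netcore
from .errors import (
    ContractError,
    LabelError,
    OperationDomainError,
    RotationInadmissibleError,
)
from .netcore import EdgeRef, PhyloNetwork, _subdivide_inplace

CASE_RET_PARENT = "ret_parent"
CASE_TREE_PARENT_TREE_SIB = "tree_parent_tree_sib"
CASE_TREE_PARENT_RET_SIB = "tree_parent_ret_sib"


@dataclass(frozen=True)
class GenerationRecord:
    """Provenance of one enumeration step.

    ``op`` is one of ``leaf_insert``, ``ret_insert``,
    ``ret_insert_rotated_1`` (rotation at the node subdividing the first
    edge) or ``ret_insert_rotated_2``; ``edges`` are tree EdgeRefs of the
    parent network.
    """

    parent: PhyloNetwork
    op: str
    edges: Tuple[EdgeRef, ...]
    inserted_taxon: int

    @property
    def parent_code(self) -> bytes:
        from .isocheck import canonical_code

        return canonical_code(self.parent)


# -- checked public operations -------------------------------------------

def _check_tree_edge(N: PhyloNetwork, e: EdgeRef, opname: str) -> None:
    if not N.has_edge(*e):
        raise OperationDomainError(f"{opname}: edge {e} is not in the network")
    if N.indegree(e[1]) == 2:
        raise OperationDomainError(f"{opname}: edge {e} is a reticulate edge")


def _check_fresh_taxon(N: PhyloNetwork, taxon: int, opname: str) -> None:
    if taxon in N._label_node:
        raise LabelError(f"{opname}: taxon {taxon} already labels a leaf")


def _validated(M: PhyloNetwork, opname: str) -> PhyloNetwork:
    bad = netcore.validate(M)
    if bad:
        raise ContractError(f"{opname} produced an invalid network: " + "; ".join(bad))
    return M


def leaf_insert(N: PhyloNetwork, e: EdgeRef, taxon: int) -> PhyloNetwork:
    """Attach a new leaf below a fresh node subdividing the tree edge e."""
    _check_tree_edge(N, e, "leaf_insert")
    _check_fresh_taxon(N, taxon, "leaf_insert")
    return _validated(_leaf_insert_fast(N, e, taxon), "leaf_insert")


def _leaf_insert_fast(N: PhyloNetwork, e: EdgeRef, taxon: int) -> PhyloNetwork:
    M = N.copy()
    w = _subdivide_inplace(M, e)
    leaf = M.new_node()
    M.add_edge(w, leaf)
    M.set_leaf_label(leaf, taxon)
    return M


def ret_insert(N: PhyloNetwork, e1: EdgeRef, e2: EdgeRef, taxon: int) -> PhyloNetwork:
    """Insert a reticulate node straddling tree edges e1 and e2.

    The edges need not be distinct.  When ``e1 == e2 == (u, v)`` the edge is
    subdivided twice and, by convention, the *first* subdivision node sits
    above the second (u -> w1 -> w2 -> v), which fixes the output
    deterministically.
    """
    _check_tree_edge(N, e1, "ret_insert")
    _check_tree_edge(N, e2, "ret_insert")
    _check_fresh_taxon(N, taxon, "ret_insert")
    M, _r, _w1, _w2 = _ret_insert_parts(N, e1, e2, taxon)
    return _validated(M, "ret_insert")


def _ret_insert_parts(
    N: PhyloNetwork, e1: EdgeRef, e2: EdgeRef, taxon: int
) -> Tuple[PhyloNetwork, int, int, int]:
    """Unchecked core of ret_insert; returns (network, r, w1, w2)."""
    M = N.copy()
    w1 = _subdivide_inplace(M, e1)
    if e1 == e2:
        w2 = _subdivide_inplace(M, (w1, e1[1]))
    else:
        w2 = _subdivide_inplace(M, e2)
    r = M.new_node()
    M.add_edge(w1, r)
    M.add_edge(w2, r)
    leaf = M.new_node()
    M.add_edge(r, leaf)
    M.set_leaf_label(leaf, taxon)
    return M, r, w1, w2


def c_rotate(N: PhyloNetwork, u: int, r: int) -> PhyloNetwork:
    """Child rotation at reticulate node r and its tree-node parent u.

    Precondition (checked here, not trusted to callers): u is a parent of
    r, u is a tree node, and u is not an ancestor of r's other parent.
    """
    if N.indegree(r) != 2:
        raise OperationDomainError(f"c_rotate: node {r} is not reticulate")
    ps = N.parents(r)
    if u not in ps:
        raise OperationDomainError(f"c_rotate: node {u} is not a parent of {r}")
    if not N.is_tree_node(u):
        raise OperationDomainError(f"c_rotate: parent {u} is not a tree node")
    v = ps[0] if ps[1] == u else ps[1]
    if classify.is_ancestor(N, u, v):
        raise RotationInadmissibleError(
            f"c_rotate: parent {u} is an ancestor of the other parent {v}")
    return _validated(_c_rotate_fast(N, u, r), "c_rotate")


def _c_rotate_fast(N: PhyloNetwork, u: int, r: int) -> PhyloNetwork:
    M = N.copy()
    z = M.children(r)[0]
    w = next(c for c in M.children(u) if c != r)
    M.remove_edge(r, z)
    M.remove_edge(u, w)
    M.add_edge(u, z)
    M.add_edge(r, w)
    return M


# -- reverse reduction ----------------------------------------------------

def reduce_last(N: PhyloNetwork, taxon: int) -> Tuple[str, PhyloNetwork]:
    """One step of the reverse map for the largest-labeled leaf.

    Classifies the leaf's surroundings and returns ``(case, M)`` where M is
    the unique predecessor network:

    * ``ret_parent`` — the leaf's parent is reticulate; M (one taxon fewer)
      is the network the leaf was reticulation-inserted into.
    * ``tree_parent_tree_sib`` — plain leaf insertion; M is the smoothed
      network (one taxon fewer).
    * ``tree_parent_ret_sib`` — a child rotation was applied last; M (same
      taxa) is the un-rotated network, whose own reduction falls into the
      ``ret_parent`` case.
    """
    if not classify.is_tree_child(N):
        raise ContractError("reduce_last requires a tree-child network")
    if taxon != max(N.taxa()):
        raise ContractError(f"taxon {taxon} is not the largest leaf label")
    leaf = N.leaf_with_label(taxon)
    p = N.parents(leaf)[0]
    if N.indegree(p) == 2:
        return CASE_RET_PARENT, _undo_ret_insert(N, leaf, p)
    siblings = [c for c in N.children(p) if c != leaf]
    if len(siblings) != 1:
        raise ContractError("leaf parent does not have exactly one other child")
    sib = siblings[0]
    if N.indegree(sib) == 2:
        # invert the rotation: the same (p, sib) rotation is its own inverse
        return CASE_TREE_PARENT_RET_SIB, c_rotate(N, p, sib)
    return CASE_TREE_PARENT_TREE_SIB, netcore.delete_leaf_smooth(N, taxon)


def _undo_ret_insert(N: PhyloNetwork, leaf: int, r: int) -> PhyloNetwork:
    """Remove leaf, its reticulate parent r, and r's two (tree-node) parents."""
    M = N.copy()
    u1, u2 = sorted(M.parents(r))
    # orient so that if the parents are adjacent, u1 is the upper one
    if u1 in M.parents(u2):
        pass
    elif u2 in M.parents(u1):
        u1, u2 = u2, u1
    adjacent = u1 in M.parents(u2)
    w1 = M.parents(u1)[0]
    v2 = next(c for c in M.children(u2) if c != r)
    if adjacent:
        M.remove_node(leaf)
        M.remove_node(r)
        M.remove_node(u1)
        M.remove_node(u2)
        M.add_edge(w1, v2)
    else:
        w2 = M.parents(u2)[0]
        v1 = next(c for c in M.children(u1) if c != r)
        M.remove_node(leaf)
        M.remove_node(r)
        M.remove_node(u1)
        M.remove_node(u2)
        M.add_edge(w1, v1)
        M.add_edge(w2, v2)
    return _validated(M, "reduce_last")


def reduce_fully(N: PhyloNetwork, taxon: int) -> Tuple[Tuple[str, ...], PhyloNetwork]:
    """Apply :func:`reduce_last` until the taxon is removed.

    At most two steps are ever needed: after undoing a rotation the leaf's
    parent is reticulate.  Returns the tuple of visited cases and the final
    network (one taxon fewer than N).
    """
    case, M = reduce_last(N, taxon)
    if case != CASE_TREE_PARENT_RET_SIB:
        return (case,), M
    case2, M2 = reduce_last(M, taxon)
    if case2 != CASE_RET_PARENT:
        raise ContractError(
            "after undoing a rotation the leaf's parent must be reticulate")
    return (case, case2), M2
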