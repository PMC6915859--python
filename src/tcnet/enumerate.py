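"""Isomorphism-free exhaustive generation of trees, TCNs and normal networks.

Networks with k reticulations on {1..n} are produced from the one- and
two-taxon base trees by a depth-first recursion over the (n', k') lattice:

* route (i): insert leaf n into every tree edge of every network with the
  same k on {1..n-1};
* route (ii): from every network with k-1 reticulations on {1..n-1},
  perform a reticulation insertion on every single tree edge and every
  unordered pair of tree edges, followed by every admissible child rotation
  at the inserted parents (one rotation for a same-edge or comparable pair,
  two for an incomparable pair).

For the normal class, route (ii) runs only over *incomparable* pairs of
distinct tree edges, and a rotation is skipped when some reticulate edge
(x, y) of the pre-insertion network N satisfies, with (e1, e2) the chosen
pair and the rotation pulling v_i under the new reticulation:
y below v_i, x not an ancestor of v_i, and x an ancestor of the other head.
All three ancestry conditions are evaluated in N.

Production mode trusts the uniqueness of this generation scheme and
streams; ``verify_unique=True`` additionally keeps a set of canonical
codes and raises :class:`DuplicateNetworkError` on a collision.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Iterator, List, Optional, Tuple

from . import classify, netcore
from .errors import DuplicateNetworkError, ParameterError
from .isocheck import canonical_key
from .netcore import EdgeRef, PhyloNetwork, base_network
from .rearrange import (
    GenerationRecord,
    _c_rotate_fast,
    _leaf_insert_fast,
    _ret_insert_parts,
)

CLASS_TREE = "tree"
CLASS_TCN = "tcn"
CLASS_NORMAL = "normal"
_CLASSES = (CLASS_TREE, CLASS_TCN, CLASS_NORMAL)

#: materialized parent levels, keyed (n, k, net_class)
_LEVEL_CACHE: Dict[Tuple[int, int, str], List[PhyloNetwork]] = {}


def clear_cache() -> None:
    """Drop all memoized generation levels (mainly for memory-bound runs)."""
    _LEVEL_CACHE.clear()


def _check_spec(n: int, k: int, net_class: str) -> None:
    if net_class not in _CLASSES:
        raise ParameterError(f"unknown network class {net_class!r}")
    if n < 1:
        raise ParameterError(f"need n >= 1, got n={n}")
    if k < 0 or k > n - 1:
        raise ParameterError(f"need 0 <= k <= n-1, got (n, k) = ({n}, {k})")
    if net_class == CLASS_TREE and k != 0:
        raise ParameterError("trees have k = 0")


def _level(n: int, k: int, net_class: str) -> List[PhyloNetwork]:
    key = (n, k, net_class)
    cached = _LEVEL_CACHE.get(key)
    if cached is None:
        cached = [N for N, _rec in _generate(n, k, net_class)]
        _LEVEL_CACHE[key] = cached
    return cached


def incomparable_tree_edge_pairs(N: PhyloNetwork) -> List[Tuple[EdgeRef, EdgeRef]]:
    """All unordered pairs of distinct, mutually incomparable tree edges."""
    desc = classify.descendant_sets(N)
    tes = netcore.tree_edges(N)
    out = []
    for e1, e2 in combinations(tes, 2):
        h1, h2 = e1[1], e2[1]
        if h2 not in desc[h1] and h1 not in desc[h2]:
            out.append((e1, e2))
    return out


def _normal_rotation_excluded(
    N: PhyloNetwork,
    desc: Dict[int, frozenset],
    ret_edges: List[EdgeRef],
    v_rot: int,
    v_other: int,
) -> bool:
    """Exclusion test for the rotation pulling v_rot under the new reticulation.

    True iff some reticulate edge (x, y) of the pre-insertion network has
    y below v_rot, x not an ancestor of v_rot, and x a *proper* ancestor of
    v_other.  (x = v_other gains no new descendants from the rotation, so
    the ancestor condition must be read strictly there; the reflexive
    reading over-excludes and loses normal networks.)
    """
    dv = desc[v_rot]
    for x, y in ret_edges:
        if y in dv and v_rot not in desc[x] and v_other in desc[x] and x != v_other:
            return True
    return False


def _generate(
    n: int, k: int, net_class: str
) -> Iterator[Tuple[PhyloNetwork, Optional[GenerationRecord]]]:
    if k < 0 or k > n - 1:
        return
    if n == 1:
        yield base_network(1), None
        return
    if n == 2 and k == 0:
        yield base_network(2), None
        return

    # route (i): leaf insertion from networks with the same k on n-1 taxa
    for M in _level(n - 1, k, net_class):
        for e in netcore.tree_edges(M):
            yield (_leaf_insert_fast(M, e, n),
                   GenerationRecord(M, "leaf_insert", (e,), n))

    if net_class == CLASS_TREE or k == 0:
        return

    # route (ii): reticulation insertion (+ rotations) from k-1 on n-1 taxa
    for M in _level(n - 1, k - 1, net_class):
        desc = classify.descendant_sets(M)
        tes = netcore.tree_edges(M)
        ret_edges = netcore.reticulate_edges(M) if net_class == CLASS_NORMAL else []
        if net_class == CLASS_NORMAL:
            pairs = []
            for e1, e2 in combinations(tes, 2):
                if e2[1] not in desc[e1[1]] and e1[1] not in desc[e2[1]]:
                    pairs.append((e1, e2))
        else:
            pairs = [(e, e) for e in tes]
            pairs.extend(combinations(tes, 2))
            pairs.sort()
        for e1, e2 in pairs:
            net, r, w1, w2 = _ret_insert_parts(M, e1, e2, n)
            yield net, GenerationRecord(M, "ret_insert", (e1, e2), n)
            # admissible rotations, decided in the parent (heads of tree
            # edges are distinct, so head comparability in M equals the
            # ancestor relation between the inserted parents)
            if e1 == e2:
                admissible = (2,)
            else:
                h1, h2 = e1[1], e2[1]
                admissible = tuple(
                    i for i, cond in ((1, h2 not in desc[h1]),
                                      (2, h1 not in desc[h2])) if cond)
            for i in admissible:
                if net_class == CLASS_NORMAL:
                    v_rot = e1[1] if i == 1 else e2[1]
                    v_other = e2[1] if i == 1 else e1[1]
                    if _normal_rotation_excluded(M, desc, ret_edges, v_rot, v_other):
                        continue
                w = w1 if i == 1 else w2
                yield (_c_rotate_fast(net, w, r),
                       GenerationRecord(M, f"ret_insert_rotated_{i}", (e1, e2), n))


def _stream(
    n: int,
    k: int,
    net_class: str,
    verify_unique: bool,
    with_records: bool,
) -> Iterator:
    seen = set() if verify_unique else None
    for net, rec in _generate(n, k, net_class):
        if seen is not None:
            key = canonical_key(net)
            if key in seen:
                raise DuplicateNetworkError(
                    f"duplicate network in {net_class} generation at (n, k) = ({n}, {k})")
            seen.add(key)
        yield (net, rec) if with_records else net


def enumerate_trees(
    n: int, *, verify_unique: bool = False, with_records: bool = False
) -> Iterator:
    """Yield all (2n-3)!! phylogenetic trees on {1..n}, each exactly once."""
    _check_spec(n, 0, CLASS_TREE)
    return _stream(n, 0, CLASS_TREE, verify_unique, with_records)


def enumerate_tcn(
    n: int, k: int, *, verify_unique: bool = False, with_records: bool = False
) -> Iterator:
    """Yield every tree-child network with k reticulations on {1..n} once."""
    _check_spec(n, k, CLASS_TCN)
    return _stream(n, k, CLASS_TCN, verify_unique, with_records)


def enumerate_normal(
    n: int, k: int, *, verify_unique: bool = False, with_records: bool = False
) -> Iterator:
    """Yield every normal network with k reticulations on {1..n} once.

    Empty for k = n - 1 (a known impossibility, reproduced rather than
    special-cased by the generation scheme).
    """
    _check_spec(n, k, CLASS_NORMAL)
    return _stream(n, k, CLASS_NORMAL, verify_unique, with_records)


def enumerate_class(
    net_class: str, n: int, k: int, **kw
) -> Iterator:
    """Dispatch by class name (CLI convenience)."""
    if net_class == CLASS_TREE:
        if k != 0:
            raise ParameterError("trees have k = 0")
        return enumerate_trees(n, **kw)
    if net_class == CLASS_TCN:
        return enumerate_tcn(n, k, **kw)
    if net_class == CLASS_NORMAL:
        return enumerate_normal(n, k, **kw)
    raise ParameterError(f"unknown network class {net_class!r}")


def cross_validate_normal(n: int, k: int) -> bool:
    """True iff filtering the TCN enumeration through is_normal equals the
    direct normal enumeration, as multisets of canonical keys."""
    lhs = sorted(canonical_key(N) for N in enumerate_tcn(n, k)
                 if classify.is_normal(N))
    rhs = sorted(canonical_key(N) for N in enumerate_normal(n, k))
    return lhs == rhs
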