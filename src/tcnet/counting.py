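"""Exact-integer counting: recurrences, closed forms, enumeration backing.

Everything here is integer arithmetic (counts reach 11 digits); division is
always exact and performed with ``//`` after verifying divisibility via the
factorial factorizations used below.

Notation (all on taxa {1..n}):

* ``a(n, k)`` — number of tree-child networks with k reticulations,
* ``b(n, k)`` — number of normal networks with k reticulations,
* ``u(n, k)`` — total incomparable-edge-pair count over all TCNs at (n, k),
* ``c(n)``    — total comparable-pair count over all trees on n taxa.

The recurrence for ``a`` consumes ``u(n-1, k-1)``.  For k = 1 that is the
closed tree formula; for k >= 2 the statistic is obtained by enumeration,
restricted to pairs of *tree* edges.  The restriction matters: the
generation scheme applies extra rotations once per incomparable pair of
tree edges, so only the tree-edge-scoped total makes the recurrence agree
with direct enumeration (the all-edge variant overcounts; both are exposed
and the test suite pins the disagreement down).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from typing import Callable, Dict, Optional, Tuple

from . import classify
from .enumerate import enumerate_normal, enumerate_tcn, enumerate_trees
from .errors import ParameterError, ResourceLimitError

#: default ceiling on enumeration-backed counts
DEFAULT_SIZE_GUARD = 10 ** 6


def _exact_div(num: int, den: int) -> int:
    q, r = divmod(num, den)
    if r:
        raise ArithmeticError(f"non-exact division {num}/{den}")
    return q


def num_trees(n: int) -> int:
    """(2n-3)!! phylogenetic trees on n taxa, via (2n-2)!/(2^(n-1) (n-1)!)."""
    if n < 1:
        raise ParameterError(f"need n >= 1, got {n}")
    return _exact_div(factorial(2 * n - 2), 2 ** (n - 1) * factorial(n - 1))


def u_trees_closed(n: int) -> int:
    """Closed form for the incomparable-pair total over all trees on n taxa:
    (n+1)(2n)!/(2^n n!) - 2^n n!."""
    if n < 1:
        raise ParameterError(f"need n >= 1, got {n}")
    return _exact_div((n + 1) * factorial(2 * n), 2 ** n * factorial(n)) \
        - 2 ** n * factorial(n)


def c_trees(n: int) -> int:
    """Comparable-pair total over all trees on n taxa, by the recurrence
    c_2 = 2,  c_m = 2 m c_{m-1} + 2 (2m-2)! / (2^(m-1) (m-1)!)."""
    if n < 2:
        raise ParameterError(f"need n >= 2, got {n}")
    c = 2
    for m in range(3, n + 1):
        c = 2 * m * c + _exact_div(2 * factorial(2 * m - 2),
                                   2 ** (m - 1) * factorial(m - 1))
    return c


def c_trees_closed(n: int) -> int:
    """Terminal closed form of the same quantity: 2^n n! - (2n)!/(2^(n-1) n!)."""
    if n < 2:
        raise ParameterError(f"need n >= 2, got {n}")
    return 2 ** n * factorial(n) - _exact_div(factorial(2 * n),
                                              2 ** (n - 1) * factorial(n))


def u_total(n: int, k: int, edge_scope: str = "all",
            limit: int = DEFAULT_SIZE_GUARD) -> int:
    """Sum of the per-network incomparable-pair statistic over all TCNs at (n, k).

    ``edge_scope`` is ``"all"`` or ``"tree_only"`` (see module docstring).
    Raises :class:`ResourceLimitError` if more than ``limit`` networks would
    be enumerated.
    """
    total = 0
    count = 0
    for N in enumerate_tcn(n, k):
        count += 1
        if count > limit:
            raise ResourceLimitError(
                f"u_total({n}, {k}) exceeds the size guard of {limit} networks")
        total += classify._u_of_unchecked(N, edge_scope)
    return total


UProvider = Callable[[int, int], int]


def _default_u_provider(n: int, k: int) -> int:
    if k == 0:
        return u_trees_closed(n)
    return u_total(n, k, edge_scope="tree_only")


def a_recurrence(n: int, k: int, u_provider: Optional[UProvider] = None) -> int:
    """Number of TCNs with k reticulations on n taxa, by the recurrence

        a(n, k) = (2n+k-3) { a(n-1, k) + (2n+k-4) a(n-1, k-1) } + u(n-1, k-1)

    with a(n, 0) the tree count (a(1, 0) = a(2, 0) = 1) and zero outside
    0 <= k <= n-1.  ``u_provider(n', k')`` supplies the incomparable-pair
    totals; the default uses the closed tree formula for k' = 0 and
    tree-edge-scoped enumeration otherwise.
    """
    if n < 1:
        raise ParameterError(f"need n >= 1, got {n}")
    provider = u_provider or _default_u_provider
    memo: Dict[Tuple[int, int], int] = {}

    def a(m: int, j: int) -> int:
        if j < 0 or j > m - 1:
            return 0
        if j == 0:
            return num_trees(m)
        got = memo.get((m, j))
        if got is None:
            got = (2 * m + j - 3) * (a(m - 1, j) + (2 * m + j - 4) * a(m - 1, j - 1)) \
                + provider(m - 1, j - 1)
            memo[(m, j)] = got
        return got

    return a(n, k)


def a_one_ret_closed(n: int) -> int:
    """Closed form (2n)!/(2^n (n-1)!) - 2^(n-1) n! for TCNs with one
    reticulation; also the count of *all* rooted binary phylogenetic
    networks with one reticulate node."""
    if n < 2:
        raise ParameterError(f"need n >= 2, got {n}")
    return _exact_div(factorial(2 * n), 2 ** n * factorial(n - 1)) \
        - 2 ** (n - 1) * factorial(n)


def b_one_ret_recurrence(n: int) -> int:
    """Normal networks with one reticulation via
    b(2, 1) = 0,  b(m, 1) = (2m-2) b(m-1, 1) + 3 u(m-1, 0)."""
    if n < 2:
        raise ParameterError(f"need n >= 2, got {n}")
    b = 0
    for m in range(3, n + 1):
        b = (2 * m - 2) * b + 3 * u_trees_closed(m - 1)
    return b


def b_one_ret_closed(n: int) -> int:
    """Closed form (n+2)(2n)!/(2^n n!) - 3 * 2^(n-1) n! for normal networks
    with one reticulation."""
    if n < 2:
        raise ParameterError(f"need n >= 2, got {n}")
    return _exact_div((n + 2) * factorial(2 * n), 2 ** n * factorial(n)) \
        - 3 * 2 ** (n - 1) * factorial(n)


def b_by_enumeration(n: int, k: int, limit: int = DEFAULT_SIZE_GUARD) -> int:
    """|enumerate_normal(n, k)|, guarded by ``limit``."""
    count = 0
    for _ in enumerate_normal(n, k):
        count += 1
        if count > limit:
            raise ResourceLimitError(
                f"b_by_enumeration({n}, {k}) exceeds the size guard of {limit}")
    return count


def a_by_enumeration(n: int, k: int, limit: int = DEFAULT_SIZE_GUARD) -> int:
    """|enumerate_tcn(n, k)|, guarded by ``limit``."""
    count = 0
    for _ in enumerate_tcn(n, k):
        count += 1
        if count > limit:
            raise ResourceLimitError(
                f"a_by_enumeration({n}, {k}) exceeds the size guard of {limit}")
    return count


def trees_by_enumeration(n: int, limit: int = DEFAULT_SIZE_GUARD) -> int:
    count = 0
    for _ in enumerate_trees(n):
        count += 1
        if count > limit:
            raise ResourceLimitError(
                f"trees_by_enumeration({n}) exceeds the size guard of {limit}")
    return count


@dataclass
class CountTable:
    """Exact-integer table of the four counting families with provenance.

    Provenance per cell is one of ``closed_form``, ``recurrence`` or
    ``enumeration``.
    """

    a: Dict[Tuple[int, int], int] = field(default_factory=dict)
    b: Dict[Tuple[int, int], int] = field(default_factory=dict)
    u: Dict[Tuple[int, int], int] = field(default_factory=dict)
    c: Dict[int, int] = field(default_factory=dict)
    provenance: Dict[Tuple[str, Tuple], str] = field(default_factory=dict)

    def record(self, family: str, key, value: int, provenance: str) -> None:
        if value < 0:
            raise ParameterError("counts are non-negative")
        getattr(self, family)[key] = value
        self.provenance[(family, key if isinstance(key, tuple) else (key,))] = provenance


def normal_table(max_n: int, limit: int = DEFAULT_SIZE_GUARD) -> CountTable:
    """b(n, k) for 3 <= n <= max_n, 1 <= k <= n-1, by enumeration
    (recurrence for the guard-exceeding k = 1 cells)."""
    t = CountTable()
    for n in range(3, max_n + 1):
        for k in range(1, n):
            try:
                t.record("b", (n, k), b_by_enumeration(n, k, limit), "enumeration")
            except ResourceLimitError:
                if k == 1:
                    t.record("b", (n, k), b_one_ret_recurrence(n), "recurrence")
                else:
                    raise
    return t


def tcn_table(max_n: int) -> CountTable:
    """a(n, k) for 2 <= n <= max_n by the recurrence."""
    t = CountTable()
    for n in range(2, max_n + 1):
        for k in range(0, n):
            t.record("a", (n, k), a_recurrence(n, k), "recurrence")
    return t
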