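# tcnet

Generation, classification, exact counting and serialization of **rooted
binary tree-child and normal phylogenetic networks**.

A rooted binary phylogenetic network is an acyclic digraph with a unique
outdegree-1 root, labeled indegree-1 leaves, tree nodes (in 1, out 2) and
reticulate nodes (in 2, out 1), and no parallel edges.  It is *tree-child*
if every non-leaf node has a child that is a tree node or a leaf, and
*normal* if additionally the two parents of every reticulate node are
incomparable.

The package implements a generation algebra of three operations — leaf
insertion, reticulation insertion, and child rotation — under which every
tree-child (resp. normal) network with `k` reticulations on `n` taxa is
produced **exactly once** from the networks on `n-1` taxa with `k` or
`k-1` reticulations.  On top of it sit:

* `tcnet.netcore` — the network data structure, validity checking, and
  elementary surgery (subdivision, leaf deletion with smoothing);
* `tcnet.classify` — ancestry/incomparability predicates, tree-child and
  normal membership, and the incomparable-edge-pair statistic `u(N)`;
* `tcnet.rearrange` — the three operations with checked preconditions and
  the reverse reduction that recovers the unique predecessor network;
* `tcnet.enumerate` — isomorphism-free streaming enumeration of trees,
  tree-child networks and normal networks (with an optional
  canonical-code uniqueness verification pass);
* `tcnet.isocheck` — leaf-label-preserving backtracking isomorphism and a
  canonical code built from per-node path-count vectors;
* `tcnet.counting` — exact-integer recurrences and closed forms: tree
  counts, incomparable/comparable pair totals, tree-child counts
  `a(n, k)`, and normal counts `b(n, 1)` (closed) / `b(n, k)`
  (enumeration-backed);
* `tcnet.ionet` — extended Newick (with `#H` hybrid tags) and edge-list
  readers/writers, plus the CLI.

## CLI

```sh
# enumerate: one eNewick string per line
tcnet enumerate --n 5 --k 2 --class normal --verify-unique
tcnet enumerate --n 6 --k 3 --class normal --count-only

# exact counts: enumeration, recurrence, or closed form
tcnet count --n 8 --k 1 --class normal --method recurrence   # 4787370
tcnet count --n 5 --k 1 --class tcn --method closed          # 2805

# the full normal-network count table as TSV
tcnet table --max-n 6 --class normal

# structural facts about a serialized network
tcnet classify --in net.nwk --format enewick
tcnet validate --in net.tsv --format edgelist

# re-derive one enumeration level and check validity, uniqueness and the
# reverse reduction of every generated network
tcnet verify --n 4 --k 2 --class normal
```

All commands accept `--seed` for interface uniformity; every algorithm is
deterministic and the value is ignored.

## Notes

* eNewick dialect: the outdegree-1 root is serialized explicitly (the
  two-taxon tree is `((1,2));`), hybrid tags are numbered in traversal
  order, children are ordered canonically, and `:length` annotations are
  parsed and discarded.
* The recurrence for `a(n, k)` consumes incomparable-pair totals
  restricted to pairs of **tree** edges.  The unrestricted statistic
  agrees for `k - 1 = 0` (the only case feeding the closed formulas) but
  overcounts for deeper recursion levels; both scopes are exposed
  (`u_of(N, edge_scope=...)`, `u_total(..., edge_scope=...)`) and the
  test suite pins down the disagreement (42 vs 46 at `n = 3, k = 2`).
* Canonical codes are certified against the backtracking isomorphism
  route empirically by the test suite; codes are only issued for
  tree-child networks.
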