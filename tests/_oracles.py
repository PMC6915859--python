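"""Independent test oracles.

These deliberately avoid the library's own ancestry/isomorphism code paths:
reachability goes through networkx, and isomorphism through exhaustive
permutation search.  They are only usable at tiny sizes.
"""

from itertools import permutations, product

import networkx as nx


def to_networkx(N):
    G = nx.DiGraph()
    G.add_nodes_from(N.nodes())
    G.add_edges_from(N.edges())
    return G


def nx_descendants(N):
    """node -> reflexive descendant set, via networkx."""
    G = to_networkx(N)
    return {v: nx.descendants(G, v) | {v} for v in G.nodes}


def nx_is_ancestor(N, u, v):
    return v in nx_descendants(N)[u]


def nx_u_of(N, tree_only=False):
    """Unordered incomparable edge pairs, by brute double loop over edges."""
    desc = nx_descendants(N)
    edges = sorted(N.edges())
    if tree_only:
        edges = [e for e in edges if N.indegree(e[1]) != 2]
    count = 0
    for i in range(len(edges)):
        for j in range(i + 1, len(edges)):
            v1, v2 = edges[i][1], edges[j][1]
            if v1 not in desc[v2] and v2 not in desc[v1]:
                count += 1
    return count


def brute_force_isomorphic(N1, N2):
    """Exhaustive search for a leaf-label-fixing, edge-preserving bijection.

    Leaves are forced by label; the remaining nodes are grouped by degree
    signature and every signature-respecting bijection is tried.  Only
    usable for networks with a handful of internal nodes.
    """
    if sorted(N1.leaf_label.values()) != sorted(N2.leaf_label.values()):
        return False
    if N1.num_nodes() != N2.num_nodes() or N1.num_edges() != N2.num_edges():
        return False

    fixed = {N1.leaf_with_label(t): N2.leaf_with_label(t)
             for t in N1.leaf_label.values()}

    def groups(N):
        g = {}
        for v in N.nodes():
            if v in N.leaf_label:
                continue
            g.setdefault((N.indegree(v), N.outdegree(v)), []).append(v)
        return {sig: sorted(vs) for sig, vs in g.items()}

    g1, g2 = groups(N1), groups(N2)
    if sorted(g1) != sorted(g2):
        return False
    if any(len(g1[s]) != len(g2[s]) for s in g1):
        return False

    sigs = sorted(g1)
    edges2 = set(N2.edges())
    if len(edges2) != N2.num_edges():
        raise ValueError("oracle requires no parallel edges")
    for perms in product(*[permutations(g2[s]) for s in sigs]):
        mapping = dict(fixed)
        for s, perm in zip(sigs, perms):
            mapping.update(zip(g1[s], perm))
        if all((mapping[u], mapping[v]) in edges2 for u, v in N1.edges()):
            return True
    return False
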