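"""Unit tests for the core network structure and elementary surgery."""

import pytest

from tcnet import netcore
from tcnet.enumerate import enumerate_tcn, enumerate_trees
from tcnet.errors import (
    MissingEdgeError,
    MissingTaxonError,
    ParameterError,
    StructuralError,
)
from tcnet.isocheck import are_isomorphic
from tcnet.netcore import (
    base_network,
    delete_leaf_smooth,
    reticulate_edges,
    subdivide,
    tree_edges,
    tree_nodes,
    validate,
)
from tcnet.rearrange import leaf_insert, ret_insert

from ._oracles import brute_force_isomorphic


class TestBaseNetwork:
    def test_two_taxon_base(self, base2):
        assert validate(base2) == []
        assert base2.num_edges() == 3
        assert base2.reticulation_count() == 0
        assert base2.taxa() == [1, 2]

    def test_one_taxon_base(self, base1):
        assert validate(base1) == []
        assert base1.num_edges() == 1
        assert base1.taxa() == [1]

    @pytest.mark.parametrize("bad", [0, 3, -1])
    def test_parameter_error(self, bad):
        with pytest.raises(ParameterError):
            base_network(bad)


class TestValidate:
    def test_parallel_edge_reported(self, base2):
        N = base2.copy()
        N.add_edge(1, 2)  # second copy of an existing edge
        assert any("parallel" in v for v in validate(N))

    def test_cycle_reported(self):
        N = netcore.PhyloNetwork()
        root = N.new_node()
        a = N.new_node()
        b = N.new_node()
        leaf = N.new_node()
        N.root = root
        for u, v in [(root, a), (a, b), (b, a), (a, leaf)]:
            N.add_edge(u, v)
        N.set_leaf_label(leaf, 1)
        assert any("cycle" in v for v in validate(N))

    def test_two_sources_reported(self, base2):
        N = base2.copy()
        extra = N.new_node()
        N.add_edge(extra, 1)
        assert any("indegree-0" in v for v in validate(N))

    def test_bad_degree_reported(self, base2):
        N = base2.copy()
        dangling = N.new_node()
        N.add_edge(1, dangling)  # internal node of outdegree 3, sink unlabeled
        msgs = "; ".join(validate(N))
        assert "degree signature" in msgs

    def test_label_gap_reported(self, base1):
        N = base1.copy()
        N.set_leaf_label(1, 5)  # relabel the single leaf as taxon 5
        assert any("bijection" in v for v in validate(N))

    def test_root_outdegree(self, base2):
        N = base2.copy()
        leaf3 = N.new_node()
        N.add_edge(0, leaf3)
        N.set_leaf_label(leaf3, 3)
        assert any("root" in v for v in validate(N))


class TestSubdivide:
    def test_one_edge_network_becomes_path(self, base1):
        M, w = subdivide(base1, (0, 1))
        assert M.num_edges() == 2
        assert M.children(0) == (w,)
        assert M.children(w) == (1,)

    def test_edge_count_increases_by_one(self, cherry3):
        for e in cherry3.sorted_edges():
            M, _ = subdivide(cherry3, e)
            assert M.num_edges() == cherry3.num_edges() + 1

    def test_missing_edge(self, base2):
        with pytest.raises(MissingEdgeError):
            subdivide(base2, (2, 3))

    def test_three_insertions_give_three_distinct_trees(self, base2):
        trees = [leaf_insert(base2, e, 3) for e in tree_edges(base2)]
        assert len(trees) == 3
        for i in range(3):
            assert validate(trees[i]) == []
            for j in range(i + 1, 3):
                assert not brute_force_isomorphic(trees[i], trees[j])


class TestDeleteLeafSmooth:
    def test_round_trip_all_tree_edges_small_tcns(self):
        pops = [list(enumerate_trees(3)), list(enumerate_tcn(3, 1))]
        for pop in pops:
            for N in pop:
                m = N.n_taxa() + 1
                for e in tree_edges(N):
                    M = delete_leaf_smooth(leaf_insert(N, e, m), m)
                    assert are_isomorphic(M, N)

    def test_cherry_reduces_to_base(self, cherry3, base2):
        assert are_isomorphic(delete_leaf_smooth(cherry3, 3), base2)

    def test_missing_taxon(self, base2):
        with pytest.raises(MissingTaxonError):
            delete_leaf_smooth(base2, 7)

    def test_reticulate_parent_is_structural_error(self, ret12):
        # leaf 2 hangs below the reticulate node: smoothing does not apply
        with pytest.raises(StructuralError):
            delete_leaf_smooth(ret12, 2)

    def test_only_leaf_is_structural_error(self, base1):
        with pytest.raises(StructuralError):
            delete_leaf_smooth(base1, 1)


class TestCopyAndAccessors:
    def test_copy_is_independent_and_isomorphic(self, ret12):
        M = ret12.copy()
        assert are_isomorphic(M, ret12)
        M.remove_edge(*M.sorted_edges()[0])
        assert M.num_edges() == ret12.num_edges() - 1

    def test_relabeled_is_isomorphic(self, ret12):
        assert are_isomorphic(ret12.relabeled(), ret12)

    def test_base2_edge_partition(self, base2):
        assert len(tree_edges(base2)) == 3
        assert reticulate_edges(base2) == []

    def test_degree_census_over_generated_networks(self):
        # for a TCN with n leaves and k reticulations:
        #   #tree nodes = n + k - 1, |E| = 2n + 3k - 1, #tree edges = 2n + k - 1
        for (n, k) in [(2, 0), (2, 1), (3, 0), (3, 1), (3, 2), (4, 1), (4, 2)]:
            for N in enumerate_tcn(n, k):
                assert len(tree_nodes(N)) == n + k - 1
                assert N.num_edges() == 2 * n + 3 * k - 1
                assert len(tree_edges(N)) == 2 * n + k - 1
                assert len(reticulate_edges(N)) == 2 * k

    def test_tcn_3_1_has_six_tree_edges(self):
        for N in enumerate_tcn(3, 1):
            assert len(tree_edges(N)) == 2 * 3 + 1 - 1
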