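import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import squareform

from ohcpipe.cluster import (
    OverlapClustering,
    cut_tree,
    distance_matrix,
    overlap_distance,
    to_newick,
    ward_agglomerate,
)
from ohcpipe.genesets import GeneSet
from ohcpipe.io import DistanceMatrix


def _gs(name, members):
    return GeneSet(name, frozenset(members))


class TestOverlapDistance:
    def test_identical_nonempty_sets(self):
        assert overlap_distance(_gs("a", {"p1"}), _gs("b", {"p1"})) == 0.0

    def test_disjoint_nonempty_sets(self):
        assert overlap_distance({"p1"}, {"p2"}) == 1.0

    def test_direct_formula(self):
        assert overlap_distance({"p1", "p2", "p3"}, {"p2", "p3", "p4"}) == 0.5

    def test_both_empty_convention_zero(self):
        assert overlap_distance(set(), set()) == 0.0

    def test_exactly_one_empty_is_one(self):
        assert overlap_distance(set(), {"p1"}) == 1.0

    sets = st.frozensets(st.integers(0, 15), max_size=12)

    @given(sets, sets, sets)
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_metric_properties(self, a, b, c):
        dab = overlap_distance(a, b)
        assert 0.0 <= dab <= 1.0
        assert dab == overlap_distance(b, a)
        assert (dab == 0.0) == (a == b)
        # Jaccard distance satisfies the triangle inequality
        assert dab <= overlap_distance(a, c) + overlap_distance(c, b) + 1e-12


class TestDistanceMatrix:
    def test_identical_sets_all_zero(self):
        dm = distance_matrix([_gs(f"a{i}", {"p1", "p2"}) for i in range(3)])
        assert dm.values.sum() == 0.0

    def test_formula_values(self):
        dm = distance_matrix([_gs("a", {1, 2}), _gs("b", {2, 3}), _gs("c", {5, 6})])
        np.testing.assert_allclose(dm.values[0, 1], 1 - 1 / 3)
        assert dm.values[0, 2] == 1.0 and dm.values[1, 2] == 1.0

    def test_single_set_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            distance_matrix([_gs("a", {1})])

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            distance_matrix([_gs("a", {1}), _gs("a", {2})])


def _random_dm(rng, n):
    v = rng.uniform(0.05, 1.0, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix([f"l{j}" for j in range(n)], v)


class TestWardAgglomerate:
    def test_two_leaves_merge_at_their_distance(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.37], [0.37, 0]]))
        Z = ward_agglomerate(dm)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.37)
        assert Z[0, 3] == 2

    def test_three_leaf_lance_williams_hand_oracle(self):
        # D(1,2)=0.1, D(1,3)=D(2,3)=1.0. First merge (1,2) at 0.1. Second:
        # squared variant works on w = d^2; the Lance-Williams Ward update is
        # w(3,{12}) = ((1+1)*1 + (1+1)*1 - 1*0.01) / 3 = 3.99/3, height sqrt.
        values = np.array([[0, 0.1, 1.0], [0.1, 0, 1.0], [1.0, 1.0, 0]])
        dm = DistanceMatrix(["a", "b", "c"], values)
        Z = ward_agglomerate(dm, variant="squared")
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(np.sqrt(3.99 / 3))
        # unsquared variant: w(3,{12}) = (2*1 + 2*1 - 1*0.1)/3 = 3.9/3 = 1.3
        Zu = ward_agglomerate(dm, variant="unsquared")
        assert Zu[1, 2] == pytest.approx(1.3)

    def test_agrees_with_scipy_reference_on_random_matrices(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 13))
            dm = _random_dm(rng, n)
            Z = ward_agglomerate(dm)
            Zs = sch.linkage(squareform(dm.values), method="ward")
            for step in range(n - 1):
                assert {int(Z[step, 0]), int(Z[step, 1])} == {
                    int(Zs[step, 0]), int(Zs[step, 1])
                }
            np.testing.assert_allclose(Z[:, 2], Zs[:, 2], rtol=1e-10)
            np.testing.assert_array_equal(Z[:, 3], Zs[:, 3])

    def test_heights_non_decreasing(self, rng):
        for _ in range(10):
            Z = ward_agglomerate(_random_dm(rng, 10))
            assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_deterministic_under_exact_ties(self):
        # four equidistant leaves: merges follow lowest (i, j) label order
        v = np.ones((4, 4)) - np.eye(4)
        Z1 = ward_agglomerate(DistanceMatrix(list("abcd"), v))
        Z2 = ward_agglomerate(DistanceMatrix(list("abcd"), v))
        np.testing.assert_array_equal(Z1, Z2)
        assert {int(Z1[0, 0]), int(Z1[0, 1])} == {0, 1}


class TestCutTree:
    @pytest.fixture
    def fitted(self, rng):
        return OverlapClustering.from_distance_matrix(_random_dm(rng, 6)).fit()

    def test_k_equals_n_every_leaf_alone(self, fitted):
        assert fitted.cut(6).nunique() == 6

    def test_k_one_single_cluster(self, fitted):
        assert fitted.cut(1).nunique() == 1

    def test_k_out_of_range(self, fitted):
        with pytest.raises(ValueError):
            fitted.cut(0)
        with pytest.raises(ValueError):
            fitted.cut(7)

    def test_planted_two_group_partition_recovered(self):
        sets = [_gs(f"g1_{i}", {1, 2, 3}) for i in range(3)] + [
            _gs(f"g2_{i}", {7, 8, 9}) for i in range(3)
        ]
        res = OverlapClustering(sets).fit()
        labels = res.cut(2)
        assert labels[:3].nunique() == 1 and labels[3:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]


class TestNewick:
    def test_single_merge_midpoint_convention(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]]))
        Z = ward_agglomerate(dm)
        assert to_newick(Z, ["a", "b"]) == "(a:0.2,b:0.2);"

    def test_three_leaf_tree_nested(self):
        values = np.array([[0, 0.1, 1.0], [0.1, 0, 1.0], [1.0, 1.0, 0]])
        Z = ward_agglomerate(DistanceMatrix(["a", "b", "c"], values))
        nwk = to_newick(Z, ["a", "b", "c"])
        assert nwk.count("(") == 2 and nwk.endswith(";")

    def test_round_trip_parse_recovers_leaves(self, rng):
        import dendropy

        dm = _random_dm(rng, 7)
        res = OverlapClustering.from_distance_matrix(dm).fit()
        tree = dendropy.Tree.get(data=res.to_newick(), schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == set(dm.labels)


def test_results_summary_and_linkage_table(rng):
    res = OverlapClustering.from_distance_matrix(_random_dm(rng, 5)).fit()
    tbl = res.summary()
    assert list(tbl.columns) == ["merge", "cluster_i", "cluster_j", "height", "size"]
    assert len(tbl) == 4
    assert tbl["size"].iloc[-1] == 5
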