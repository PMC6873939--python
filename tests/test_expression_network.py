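"""Geometric-mean cluster profiles, distances, and the cluster graph."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st

import scdiversity as sd
from scdiversity.expression_network import ClusterExpressionProfile


def make_matrix(dense, barcodes=None, genes=None):
    dense = np.asarray(dense)
    genes = genes or tuple(f"g{i}" for i in range(dense.shape[0]))
    barcodes = barcodes or tuple(f"BC{i}-1" for i in range(dense.shape[1]))
    return sd.ExpressionMatrix(genes, barcodes, sp.csc_matrix(dense))


def make_table(barcodes, clusters, conditions=None):
    conditions = conditions or ["c"] * len(barcodes)
    return sd.CellAnnotationTable(
        pd.DataFrame(
            {
                "barcode": barcodes,
                "sample_id": "S1",
                "condition": conditions,
                "cluster": clusters,
            }
        )
    )


class TestClusterProfiles:
    def test_plain_geometric_mean_in_small_pseudocount_limit(self):
        m = make_matrix([[2, 8]])
        t = make_table(m.barcodes, [1, 1])
        (prof,) = sd.cluster_profiles(m, t, pseudocount=1e-9)
        assert prof.values[0] == pytest.approx(4.0, abs=1e-6)
        assert prof.n_cells == 2

    def test_pseudocount_rule_with_zero_counts(self):
        # counts (0, 3), c = 1: exp((ln 1 + ln 4) / 2) - 1 = 1
        m = make_matrix([[0, 3]])
        t = make_table(m.barcodes, [1, 1])
        (prof,) = sd.cluster_profiles(m, t, pseudocount=1.0)
        assert prof.values[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("pc", [0.5, 1.0, 7.0])
    def test_identical_cells_recover_their_counts_for_any_pseudocount(self, pc):
        col = np.array([[3], [0], [11]])
        m = make_matrix(np.hstack([col, col, col]))
        t = make_table(m.barcodes, [1, 1, 1])
        (prof,) = sd.cluster_profiles(m, t, pseudocount=pc)
        assert np.allclose(prof.values, col.ravel(), atol=1e-9)

    def test_all_zero_gene_stays_zero(self):
        m = make_matrix([[0, 0], [1, 3]])
        t = make_table(m.barcodes, [1, 1])
        (prof,) = sd.cluster_profiles(m, t, pseudocount=1.0)
        assert prof.values[0] == 0.0

    def test_one_gene_scaling_property(self):
        # multiplying all counts of a one-gene cluster by a constant scales
        # the pseudocount-free geometric mean by that constant
        base = np.array([[2, 8, 4]])
        m1 = make_matrix(base)
        m3 = make_matrix(base * 3)
        t = make_table(m1.barcodes, [1, 1, 1])
        (p1,) = sd.cluster_profiles(m1, t, pseudocount=1e-10)
        (p3,) = sd.cluster_profiles(m3, t, pseudocount=1e-10)
        assert p3.values[0] == pytest.approx(3 * p1.values[0], rel=1e-6)

    def test_barcode_mismatch_raises(self):
        m = make_matrix([[1, 2]])
        t = make_table(["BC0-1", "MISSING-1"], [1, 1])
        with pytest.raises(ValueError, match="absent"):
            sd.cluster_profiles(m, t)

    def test_invalid_pseudocount_rejected(self):
        m = make_matrix([[1]])
        t = make_table(m.barcodes, [1])
        with pytest.raises(ValueError):
            sd.cluster_profiles(m, t, pseudocount=0.0)


class TestDistanceMatrix:
    def test_identical_profiles_at_zero_distance(self):
        p = ClusterExpressionProfile(1, np.array([1.0, 2.0]), 5)
        q = ClusterExpressionProfile(2, np.array([1.0, 2.0]), 3)
        mat = sd.cluster_distance_matrix([p, q])
        assert mat.loc[1, 2] == 0.0

    def test_three_four_five_triangle(self):
        p = ClusterExpressionProfile(1, np.array([0.0, 0.0]), 1)
        q = ClusterExpressionProfile(2, np.array([3.0, 4.0]), 1)
        mat = sd.cluster_distance_matrix([p, q])
        assert mat.loc[1, 2] == pytest.approx(5.0)
        assert np.allclose(mat.values, mat.values.T)

    @given(
        vals=st.lists(
            st.tuples(*[st.floats(0, 50) for _ in range(3)]),
            min_size=3,
            max_size=3,
        )
    )
    def test_triangle_inequality_on_random_profiles(self, vals):
        profs = [
            ClusterExpressionProfile(i, np.array(v, dtype=float), 1)
            for i, v in enumerate(vals)
        ]
        mat = sd.cluster_distance_matrix(profs).values
        assert mat[0, 1] <= mat[0, 2] + mat[2, 1] + 1e-9

    def test_gene_order_mismatch_rejected(self):
        p = ClusterExpressionProfile(1, np.zeros(3), 1)
        q = ClusterExpressionProfile(2, np.zeros(4), 1)
        with pytest.raises(ValueError, match="gene"):
            sd.cluster_distance_matrix([p, q])


class TestClusterGraph:
    def _graph(self):
        barcodes = [f"B{i}-1" for i in range(10)]
        clusters = [1] * 5 + [2] * 5
        conditions = ["healthy"] * 3 + ["aml"] * 2 + ["healthy", "aml", "aml", "aml", "aml"]
        table = make_table(barcodes, clusters, conditions)
        profs = [
            ClusterExpressionProfile(1, np.array([0.0, 0.0]), 5),
            ClusterExpressionProfile(2, np.array([3.0, 4.0]), 5),
        ]
        return sd.build_cluster_graph(sd.cluster_distance_matrix(profs), table), table

    def test_composition_and_majority(self):
        g, _ = self._graph()
        node = g.nodes[1]
        assert node["condition_composition"] == pytest.approx(
            {"healthy": 0.6, "aml": 0.4}
        )
        assert node["majority_condition"] == "healthy"

    def test_tie_breaks_to_lexicographically_smallest(self):
        table = make_table(
            ["A-1", "B-1", "C-1", "D-1"], [1, 1, 2, 2],
            ["healthy", "aml", "aml", "healthy"],
        )
        profs = [
            ClusterExpressionProfile(1, np.zeros(2), 2),
            ClusterExpressionProfile(2, np.ones(2), 2),
        ]
        g = sd.build_cluster_graph(sd.cluster_distance_matrix(profs), table)
        assert g.nodes[1]["majority_condition"] == "aml"

    def test_node_sizes_conserve_cells_and_compositions_sum_to_one(self):
        g, table = self._graph()
        assert sum(d["size"] for _, d in g.nodes(data=True)) == len(table)
        for _, d in g.nodes(data=True):
            assert sum(d["condition_composition"].values()) == pytest.approx(1.0)

    def test_edges_carry_distance_and_inverse_layout_weight(self):
        g, _ = self._graph()
        e = g.edges[1, 2]
        assert e["distance"] == pytest.approx(5.0)
        assert e["layout_weight"] == pytest.approx(1 / (5.0 + 1e-6))

    def test_cluster_set_disagreement_rejected(self):
        _, table = self._graph()
        profs = [
            ClusterExpressionProfile(1, np.zeros(2), 5),
            ClusterExpressionProfile(7, np.ones(2), 5),
        ]
        with pytest.raises(ValueError, match="disagree"):
            sd.build_cluster_graph(sd.cluster_distance_matrix(profs), table)

    def test_graph_tables_written(self, tmp_path):
        g, _ = self._graph()
        nodes_path, edges_path = sd.write_graph_tables(g, tmp_path)
        nodes = pd.read_csv(nodes_path)
        edges = pd.read_csv(edges_path)
        assert set(nodes["cluster"]) == {1, 2}
        assert {"prop_aml", "prop_healthy"} <= set(nodes.columns)
        assert edges.loc[0, "distance"] == pytest.approx(5.0)


class TestExpressionMatrixValidation:
    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sd.ExpressionMatrix(("g1",), ("b1", "b2"), sp.csc_matrix(np.ones((1, 3))))

    def test_negative_and_fractional_counts_rejected(self):
        with pytest.raises(ValueError):
            make_matrix([[-1, 2]])
        with pytest.raises(ValueError):
            make_matrix([[0.5, 2]])
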