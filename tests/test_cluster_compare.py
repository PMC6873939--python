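"""Occupancy construction and discrete KS comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import scdiversity as sd
from scdiversity.cluster_compare import AlignmentError


def dist(counts, ids=None):
    counts = np.asarray(counts)
    ids = tuple(range(1, counts.size + 1)) if ids is None else tuple(ids)
    return sd.ClusterDistribution(ids, counts)


class TestOccupancy:
    def test_direct_tally_with_zero_padding(self, tiny_table):
        d = sd.occupancy(tiny_table, "H1", cluster_space=(1, 2, 3))
        assert d.cluster_ids == (1, 2, 3)
        assert list(d.counts) == [3, 1, 0]
        assert d.n_cells == 4

    def test_condition_pooling_sums_sample_counts(self, tiny_table):
        space = tiny_table.cluster_space
        pooled = sd.occupancy(tiny_table, "healthy", cluster_space=space)
        per_sample = sd.occupancy(tiny_table, "H1", cluster_space=space)
        # healthy condition has exactly one sample here
        assert np.array_equal(pooled.counts, per_sample.counts)

    def test_pooling_two_samples_is_elementwise_sum(self):
        rows = []
        for i, (sample, clusters) in enumerate(
            [("S1", [1, 1, 2]), ("S2", [2, 3, 3])], start=1
        ):
            rows += [
                (f"BC{i}{j}-{i}", sample, "cond", c) for j, c in enumerate(clusters)
            ]
        table = sd.CellAnnotationTable(
            pd.DataFrame(rows, columns=["barcode", "sample_id", "condition", "cluster"])
        )
        space = table.cluster_space
        pooled = sd.occupancy(table, "cond", cluster_space=space, by="condition")
        summed = (
            sd.occupancy(table, "S1", cluster_space=space).counts
            + sd.occupancy(table, "S2", cluster_space=space).counts
        )
        assert np.array_equal(pooled.counts, summed)

    def test_unknown_group_and_inconsistent_space_raise(self, tiny_table):
        with pytest.raises(KeyError):
            sd.occupancy(tiny_table, "nope")
        with pytest.raises(AlignmentError):
            sd.occupancy(tiny_table, "A1", cluster_space=(1, 2))  # cluster 3 observed


class TestKSDistance:
    def test_identical_distributions_have_zero_distance(self):
        a = dist([2, 3, 5])
        assert sd.ks_distance(a, dist([2, 3, 5])) == 0.0
        # proportions matter, not raw counts
        assert sd.ks_distance(a, dist([4, 6, 10])) == pytest.approx(0.0, abs=1e-15)

    def test_disjoint_support_has_distance_one(self):
        assert sd.ks_distance(dist([5, 0]), dist([0, 5])) == pytest.approx(1.0)

    def test_hand_computed_cdf_maximum(self):
        # p = (0.2, 0.3, 0.5) vs (0.4, 0.4, 0.2): CDFs (0.2, 0.5, 1) vs
        # (0.4, 0.8, 1); the maximum gap is 0.3 at the second cluster
        a, b = dist([2, 3, 5]), dist([4, 4, 2])
        assert sd.ks_distance(a, b) == pytest.approx(0.3, abs=1e-12)
        # brute force over all prefixes
        brute = max(
            abs(a.proportions[: k + 1].sum() - b.proportions[: k + 1].sum())
            for k in range(3)
        )
        assert sd.ks_distance(a, b) == pytest.approx(brute, abs=1e-15)

    def test_zero_padding_invariance(self):
        a, b = dist([2, 3, 5]), dist([4, 4, 2])
        a_pad = dist([2, 3, 5, 0, 0], ids=range(1, 6))
        b_pad = dist([4, 4, 2, 0, 0], ids=range(1, 6))
        assert sd.ks_distance(a_pad, b_pad) == pytest.approx(
            sd.ks_distance(a, b), abs=1e-15
        )

    def test_mismatched_cluster_spaces_raise(self):
        with pytest.raises(AlignmentError):
            sd.ks_distance(dist([1, 2]), dist([1, 2, 3]))
        with pytest.raises(AlignmentError):
            sd.ks_distance(dist([1, 2]), dist([1, 2], ids=(2, 3)))

    @given(
        data=st.lists(
            st.tuples(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)),
            min_size=2,
            max_size=10,
        ).filter(lambda rows: all(sum(col) > 0 for col in zip(*rows)))
    )
    def test_metric_axioms(self, data):
        cols = list(zip(*data))
        ids = tuple(range(1, len(data) + 1))
        a, b, c = (dist(np.array(col), ids=ids) for col in cols)
        dab = sd.ks_distance(a, b)
        assert 0 <= dab <= 1
        assert dab == sd.ks_distance(b, a)
        assert sd.ks_distance(a, a) == 0.0
        if not np.allclose(a.proportions, b.proportions):
            assert dab > 0
        assert dab <= sd.ks_distance(a, c) + sd.ks_distance(c, b) + 1e-12


class TestPairwiseKS:
    def test_matrix_shape_symmetry_and_consistency(self, tiny_table):
        mat = sd.pairwise_ks(tiny_table, by="sample")
        assert mat.shape == (2, 2)
        assert np.allclose(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 0)
        space = tiny_table.cluster_space
        expected = sd.ks_distance(
            sd.occupancy(tiny_table, "A1", cluster_space=space),
            sd.occupancy(tiny_table, "H1", cluster_space=space),
        )
        assert mat.loc["A1", "H1"] == pytest.approx(expected)

    def test_identical_samples_have_zero_offdiagonal(self):
        rows = [
            ("X1-1", "S1", "c", 1), ("X2-1", "S1", "c", 2),
            ("Y1-2", "S2", "c", 1), ("Y2-2", "S2", "c", 2),
        ]
        table = sd.CellAnnotationTable(
            pd.DataFrame(rows, columns=["barcode", "sample_id", "condition", "cluster"])
        )
        mat = sd.pairwise_ks(table, by="sample")
        assert mat.loc["S1", "S2"] == 0.0

    def test_single_group_rejected(self, tiny_table):
        healthy_only = tiny_table.subset(
            (tiny_table.df["condition"] == "healthy").to_numpy().nonzero()[0]
        )
        with pytest.raises(ValueError):
            sd.pairwise_ks(healthy_only, by="condition")


class TestAnnotationTableValidation:
    def test_duplicate_barcodes_rejected(self):
        rows = [("A-1", "S", "c", 1), ("A-1", "S", "c", 2)]
        with pytest.raises(ValueError, match="duplicate"):
            sd.CellAnnotationTable(
                pd.DataFrame(
                    rows, columns=["barcode", "sample_id", "condition", "cluster"]
                )
            )

    def test_non_integer_clusters_rejected(self):
        df = pd.DataFrame(
            [("A-1", "S", "c", 1.5)],
            columns=["barcode", "sample_id", "condition", "cluster"],
        )
        with pytest.raises(ValueError, match="integer"):
            sd.CellAnnotationTable(df)
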