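import numpy as np
import pytest

from wmcpm import connectome as cn
from wmcpm.core import ConnectivityMatrix, NetworkMask, NodeTimeSeries

from conftest import random_mask, random_z_matrix


def brute_force_parcellate(voxels, labels, kept):
    """Voxel-loop oracle for parcel averaging."""
    T = voxels.shape[3]
    out = np.zeros((T, len(kept)))
    for k, label in enumerate(kept):
        coords = np.argwhere(labels == label)
        for t in range(T):
            out[t, k] = np.mean([voxels[x, y, z, t] for x, y, z in coords])
    return out


class TestParcellate:
    def test_single_label_is_global_mean(self, rng):
        voxels = rng.normal(size=(3, 3, 3, 8))
        labels = np.ones((3, 3, 3), dtype=int)
        # pad with a second single-voxel parcel so N >= 2
        labels[0, 0, 0] = 2
        ts, missing = cn.parcellate(voxels, labels)
        rest = voxels[labels == 1]
        np.testing.assert_allclose(ts.values[:, 0], rest.mean(axis=0))
        assert missing == set()

    def test_one_voxel_parcels_are_verbatim(self, rng):
        voxels = rng.normal(size=(2, 1, 1, 6))
        labels = np.array([[[1]], [[2]]])
        ts, _ = cn.parcellate(voxels, labels)
        np.testing.assert_allclose(ts.values[:, 0], voxels[0, 0, 0])
        np.testing.assert_allclose(ts.values[:, 1], voxels[1, 0, 0])

    def test_matches_voxel_loop_oracle(self, rng):
        voxels = rng.normal(size=(4, 4, 4, 20))
        labels = rng.integers(0, 6, size=(4, 4, 4))
        present = sorted(int(v) for v in np.unique(labels) if v > 0)
        ts, _ = cn.parcellate(voxels, labels)
        np.testing.assert_allclose(
            ts.values, brute_force_parcellate(voxels, labels, present), atol=1e-12
        )

    def test_absent_label_reported_missing(self, rng):
        voxels = rng.normal(size=(2, 2, 2, 5))
        labels = rng.integers(1, 3, size=(2, 2, 2))
        ts, missing = cn.parcellate(voxels, labels, atlas_labels=[1, 2, 3])
        assert missing == {3}
        assert ts.node_ids == (1, 2)

    def test_no_parcels_is_error(self):
        with pytest.raises(ValueError, match="no nonzero"):
            cn.parcellate(np.zeros((2, 2, 2, 4)), np.zeros((2, 2, 2), dtype=int))


class TestCorrelationMatrix:
    def test_identical_and_negated_columns(self, rng):
        base = rng.normal(size=50)
        ts = NodeTimeSeries(
            np.column_stack([base, base, -base + 1]), node_ids=(1, 2, 3)
        )
        m = cn.correlation_matrix(ts)
        assert m.values[0, 1] == pytest.approx(1.0)
        assert m.values[0, 2] == pytest.approx(-1.0)
        assert np.all(np.diag(m.values) == 0.0)

    def test_matches_two_pass_formula_oracle(self, rng):
        x = rng.normal(size=(50, 5))
        m = cn.correlation_matrix(NodeTimeSeries(x, node_ids=tuple(range(1, 6))))
        for i in range(5):
            for j in range(i + 1, 5):
                xi, xj = x[:, i] - x[:, i].mean(), x[:, j] - x[:, j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert m.values[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_column_names_node(self, rng):
        x = rng.normal(size=(20, 3))
        x[:, 1] = 2.5
        with pytest.raises(ValueError, match=r"\[7\]"):
            cn.correlation_matrix(NodeTimeSeries(x, node_ids=(3, 7, 9)))

    def test_converges_to_generating_correlation(self):
        from wmcpm.synth import gen_time_series

        target = np.eye(6)
        ts = gen_time_series(target, 10000, seed=5)
        m = cn.correlation_matrix(NodeTimeSeries(ts, node_ids=tuple(range(1, 7))))
        off = m.values[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.05  # ~ 2 / sqrt(T) sampling bound


class TestAverageAndFisher:
    def test_mean_is_idempotent_and_identity(self, rng):
        m = cn.correlation_matrix(
            NodeTimeSeries(rng.normal(size=(30, 4)), node_ids=(1, 2, 3, 4))
        )
        np.testing.assert_allclose(cn.average_runs([m, m]).values, m.values)
        np.testing.assert_allclose(cn.average_runs([m]).values, m.values)

    def test_mean_checked_entrywise(self, rng):
        ms = [
            cn.correlation_matrix(
                NodeTimeSeries(rng.normal(size=(25, 3)), node_ids=(1, 2, 3))
            )
            for _ in range(2)
        ]
        avg = cn.average_runs(ms)
        for i in range(3):
            for j in range(3):
                assert avg.values[i, j] == pytest.approx(
                    (ms[0].values[i, j] + ms[1].values[i, j]) / 2
                )

    def test_node_mismatch_is_error(self, rng):
        a = cn.correlation_matrix(
            NodeTimeSeries(rng.normal(size=(20, 3)), node_ids=(1, 2, 3))
        )
        b = cn.correlation_matrix(
            NodeTimeSeries(rng.normal(size=(20, 3)), node_ids=(1, 2, 4))
        )
        with pytest.raises(ValueError, match="node ids"):
            cn.average_runs([a, b])

    def test_fisher_z_closed_form(self):
        values = np.array([[0.0, 0.5], [0.5, 0.0]])
        z = cn.fisher_z(ConnectivityMatrix(values, scale="r", node_ids=(1, 2)))
        assert z.scale == "z"
        assert z.values[0, 1] == pytest.approx(0.5493, abs=5e-5)  # atanh(0.5)

    def test_fisher_z_is_odd_and_monotone(self, rng):
        r = np.sort(rng.uniform(-0.95, 0.95, size=9))
        n = len(r) + 1
        values = np.zeros((n, n))
        values[0, 1:] = r
        values[1:, 0] = r
        m = ConnectivityMatrix(values, scale="r", node_ids=tuple(range(1, n + 1)))
        z = cn.fisher_z(m).values[0, 1:]
        neg = ConnectivityMatrix(-values, scale="r", node_ids=m.node_ids)
        np.testing.assert_allclose(cn.fisher_z(neg).values[0, 1:], -z, atol=1e-12)
        assert np.all(np.diff(z) > 0)

    def test_unit_correlation_is_error(self):
        values = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="infinite"):
            cn.fisher_z(ConnectivityMatrix(values, scale="r", node_ids=(1, 2)))

    def test_average_then_z_differs_from_z_then_average(self):
        """Heterogeneous runs: the pipeline's order (average on r, then z)
        is not interchangeable with z-then-average."""
        ids = (1, 2)
        r1 = ConnectivityMatrix(np.array([[0, 0.2], [0.2, 0]]), scale="r", node_ids=ids)
        r2 = ConnectivityMatrix(np.array([[0, 0.8], [0.8, 0]]), scale="r", node_ids=ids)
        avg_then_z = cn.fisher_z(cn.average_runs([r1, r2])).values[0, 1]
        z_then_avg = (cn.fisher_z(r1).values[0, 1] + cn.fisher_z(r2).values[0, 1]) / 2
        assert avg_then_z == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert abs(avg_then_z - z_then_avg) > 0.05


class TestHarmonize:
    def test_union_of_missing_removed_everywhere(self, rng):
        mats = [random_z_matrix(rng, 5, f"s{i}") for i in range(2)]
        reduced, kept = cn.harmonize_nodes(mats, [{2}, {5}])
        assert kept == (1, 3, 4)
        assert all(m.values.shape == (3, 3) for m in reduced)
        # entries survive at the right positions
        np.testing.assert_allclose(reduced[0].values[0, 1], mats[0].values[0, 2])

    def test_no_missing_is_identity(self, rng):
        mats = [random_z_matrix(rng, 4)]
        reduced, kept = cn.harmonize_nodes(mats)
        assert kept == (1, 2, 3, 4)
        np.testing.assert_allclose(reduced[0].values, mats[0].values)

    def test_all_missing_is_error(self, rng):
        mats = [random_z_matrix(rng, 3)]
        with pytest.raises(ValueError, match="empty cohort"):
            cn.harmonize_nodes(mats, [{1, 2, 3}])


class TestRestrictMask:
    def test_complete_graph_drop_one_node(self):
        edges = [(i, j) for i in range(1, 6) for j in range(i + 1, 6)]
        mask = NetworkMask(edges=frozenset(edges), polarity="high", atlas_size=5)
        restricted, count = cn.restrict_mask(mask, kept={1, 2, 3, 4})
        assert count == 6  # C(4, 2)

    def test_full_node_set_is_identity(self, rng):
        mask = random_mask(rng, 10, 15)
        restricted, count = cn.restrict_mask(mask, kept=range(1, 11))
        assert restricted.edges == mask.edges and count == 15

    def test_matches_membership_loop_oracle(self, rng):
        mask = random_mask(rng, 20, 60)
        kept = set(rng.choice(np.arange(1, 21), size=17, replace=False).tolist())
        restricted, count = cn.restrict_mask(mask, kept)
        expected = {e for e in mask.edges if e[0] in kept and e[1] in kept}
        assert restricted.edges == frozenset(expected)
        assert count == len(expected)


def test_permutation_invariance_of_strength(rng):
    """Reordering nodes consistently leaves mask strength unchanged."""
    from wmcpm.strength import network_strength

    m = random_z_matrix(rng, 8)
    mask = random_mask(rng, 8, 10)
    perm = rng.permutation(8)
    permuted = ConnectivityMatrix(
        values=m.values[np.ix_(perm, perm)],
        scale="z",
        node_ids=tuple(np.array(m.node_ids)[perm]),
    )
    # rebuild in sorted order, as loaders do
    order = np.argsort(permuted.node_ids)
    sorted_m = ConnectivityMatrix(
        values=permuted.values[np.ix_(order, order)],
        scale="z",
        node_ids=tuple(sorted(permuted.node_ids)),
    )
    assert network_strength(sorted_m, mask) == pytest.approx(
        network_strength(m, mask), abs=1e-12
    )
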