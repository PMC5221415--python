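"""Common representation space: pooled ECDF, rank transform, MMD^2_SF."""

import numpy as np
import pytest

from connktst import (
    BrainGraph,
    EdgeWeightECDF,
    LabeledGraphDataset,
    Modality,
    common_space_mmds,
    mmd_sf_test,
    pooled_ecdf,
    shared_null_reference,
    transform_graphs,
)
from connktst.simulate import SimulationParams, simulate_dataset

from conftest import random_dataset


class TestEdgeWeightECDF:
    def test_direct_counting(self):
        ecdf = EdgeWeightECDF(np.array([10.0, 20, 30, 40]), Modality.STRUCTURAL)
        assert ecdf.evaluate(10) == 0.25
        assert ecdf.evaluate(25) == 0.5
        assert ecdf.evaluate(40) == 1.0
        assert ecdf.evaluate(5) == 0.0

    def test_ties_counted_with_leq(self):
        ecdf = EdgeWeightECDF(np.array([1.0, 2, 2, 3]), Modality.STRUCTURAL)
        assert ecdf.evaluate(2) == 0.75

    def test_nondecreasing_with_unit_max(self, rng):
        vals = rng.gamma(2, 10, size=200)
        ecdf = EdgeWeightECDF(vals, Modality.STRUCTURAL)
        grid = np.linspace(vals.min() - 1, vals.max() + 1, 300)
        out = ecdf.evaluate(grid)
        assert np.all(np.diff(out) >= 0)
        assert ecdf.evaluate(vals.max()) == 1.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            EdgeWeightECDF(np.array([]), Modality.STRUCTURAL)


class TestPooledEcdf:
    def test_pool_size_fully_dense(self, rng):
        """16 dense graphs over 50 nodes pool 16 x 1225 nonzero weights."""
        labels = tuple(f"v{i}" for i in range(50))
        iu = np.triu_indices(50, k=1)
        graphs = []
        for i in range(16):
            w = np.zeros((50, 50))
            w[iu] = rng.uniform(1, 100, len(iu[0]))
            graphs.append(
                BrainGraph.from_matrix(labels, w + w.T, "structural", f"s{i}")
            )
        ds = LabeledGraphDataset(
            tuple(graphs), ("A",) * 8 + ("B",) * 8, labels
        )
        assert len(pooled_ecdf(ds)) == 16 * 1225

    def test_zeros_excluded_from_pool(self):
        labels = ("a", "b", "c")
        w = np.array([[0.0, 5, 0], [5, 0, 7], [0, 7, 0]])
        g = BrainGraph.from_matrix(labels, w, "structural", "s")
        ds = LabeledGraphDataset((g, g), ("A", "B"), labels)
        ecdf = pooled_ecdf(ds)
        assert len(ecdf) == 4  # two graphs x two nonzero upper-tri edges
        np.testing.assert_array_equal(ecdf.sorted_weights, [5, 5, 7, 7])


class TestTransformGraphs:
    def test_rank_identity_all_distinct(self, rng):
        """With all-distinct weights the pooled transformed weights are
        exactly the multiset {1/N, ..., N/N}."""
        ds = random_dataset(rng, l=6, n=6)
        ecdf = pooled_ecdf(ds)
        transformed = transform_graphs(ds, ecdf)
        iu = np.triu_indices(6, k=1)
        pooled = np.concatenate(
            [np.asarray(g.weights)[iu] for g in transformed]
        )
        pooled = np.sort(pooled[pooled != 0])
        N = len(ecdf)
        np.testing.assert_allclose(pooled, np.arange(1, N + 1) / N, rtol=0,
                                   atol=1e-15)

    def test_max_weight_maps_to_one(self, rng):
        ds = random_dataset(rng, l=5, n=4)
        ecdf = pooled_ecdf(ds)
        out = transform_graphs(ds, ecdf)
        m = max(np.max(g.weights) for g in out)
        assert m == 1.0

    def test_monotone(self, rng):
        ds = random_dataset(rng, l=5, n=4)
        ecdf = pooled_ecdf(ds)
        out = transform_graphs(ds, ecdf)
        for g_raw, g_t in zip(ds.graphs, out.graphs):
            raw = np.asarray(g_raw.weights).ravel()
            t = np.asarray(g_t.weights).ravel()
            order = np.argsort(raw)
            assert np.all(np.diff(t[order]) >= -1e-15)

    def test_zeros_stay_zero_sparsity_preserved(self, rng):
        ds = random_dataset(rng, l=6, n=4, density=0.5)
        out = transform_graphs(ds, pooled_ecdf(ds))
        for g_raw, g_t in zip(ds.graphs, out.graphs):
            np.testing.assert_array_equal(
                np.asarray(g_raw.weights) == 0, np.asarray(g_t.weights) == 0
            )

    def test_modality_mismatch_rejected(self, rng, small_functional):
        ds = random_dataset(rng, l=6, n=4)
        with pytest.raises(ValueError, match="cannot transform"):
            transform_graphs(small_functional, pooled_ecdf(ds))

    def test_strictly_monotone_raw_rescaling_is_invisible(self, rng):
        """x -> x^3 on raw weights leaves the transformed dataset
        bit-identical when weights are distinct (rank invariance)."""
        ds = random_dataset(rng, l=6, n=6)
        cubed = LabeledGraphDataset(
            tuple(
                BrainGraph.from_matrix(
                    g.node_labels,
                    np.asarray(g.weights) ** 3,
                    g.modality,
                    g.subject_id,
                )
                for g in ds.graphs
            ),
            ds.class_labels,
            ds.shared_node_labels,
        )
        t1 = transform_graphs(ds, pooled_ecdf(ds))
        t2 = transform_graphs(cubed, pooled_ecdf(cubed))
        for g1, g2 in zip(t1.graphs, t2.graphs):
            np.testing.assert_array_equal(g1.weights, g2.weights)


class TestCommonSpaceMmds:
    def test_rank_invariance_of_statistics(self):
        ds, df = simulate_dataset(SimulationParams(seed=11))
        cubed = LabeledGraphDataset(
            tuple(
                BrainGraph.from_matrix(
                    g.node_labels,
                    np.asarray(g.weights) ** 3,
                    g.modality,
                    g.subject_id,
                )
                for g in ds.graphs
            ),
            ds.class_labels,
            ds.shared_node_labels,
        )
        m_s1, m_f1, sig1 = common_space_mmds(ds, df)
        m_s2, m_f2, sig2 = common_space_mmds(cubed, df)
        assert m_s1 == pytest.approx(m_s2, abs=1e-12)
        assert m_f1 == pytest.approx(m_f2, abs=1e-12)
        assert sig1 == pytest.approx(sig2, abs=1e-12)

    def test_structural_effect_dominates_when_present(self):
        ds, df = simulate_dataset(
            SimulationParams(delta_s=0.8, delta_f=0.0, seed=21)
        )
        m_s, m_f, sigma = common_space_mmds(ds, df)
        assert m_s > m_f
        assert sigma > 0

    def test_modality_order_enforced(self):
        ds, df = simulate_dataset(SimulationParams(seed=2))
        with pytest.raises(ValueError, match="structural"):
            common_space_mmds(df, ds)


class TestMmdSfTest:
    def test_positive_differential_with_structural_effect(self):
        ds, df = simulate_dataset(SimulationParams(seed=5))
        res = mmd_sf_test(ds, df, T=1000, seed=9)
        assert res.mmd2_sf == res.mmd2_s - res.mmd2_f
        assert res.mmd2_sf > 0
        assert res.p_value <= 0.05
        assert res.group_sizes == (8, 8, 10, 10)

    def test_antisymmetry_under_modality_exchange(self):
        """Swapping the roles of the datasets negates the observed
        statistic (checked through the component statistics, since the
        test itself enforces the structural-first signature)."""
        ds, df = simulate_dataset(SimulationParams(seed=5))
        res = mmd_sf_test(ds, df, T=10, seed=1)
        assert -(res.mmd2_f - res.mmd2_s) == res.mmd2_sf

    def test_deterministic_under_seed(self):
        ds, df = simulate_dataset(SimulationParams(seed=5))
        r1 = mmd_sf_test(ds, df, T=300, seed=4)
        r2 = mmd_sf_test(ds, df, T=300, seed=4)
        assert r1.mmd2_sf == r2.mmd2_sf
        np.testing.assert_array_equal(r1.null_sample, r2.null_sample)
        assert r1.p_value == r2.p_value

    def test_two_sided_at_least_one_sided(self):
        ds, df = simulate_dataset(SimulationParams(seed=5))
        r1 = mmd_sf_test(ds, df, T=500, seed=4)
        r2 = mmd_sf_test(ds, df, T=500, seed=4, two_sided=True)
        assert r2.p_value >= r1.p_value

    def test_per_modality_sigma_reported_as_pair(self):
        ds, df = simulate_dataset(SimulationParams(seed=5))
        res = mmd_sf_test(ds, df, T=50, seed=4, per_modality_sigma=True)
        assert isinstance(res.sigma, tuple) and len(res.sigma) == 2


class TestSharedNullReference:
    def test_deterministic_under_seed(self):
        ds, df = simulate_dataset(SimulationParams(seed=5))
        n1 = shared_null_reference(ds, df, T=40, seed=3)
        n2 = shared_null_reference(ds, df, T=40, seed=3)
        np.testing.assert_array_equal(n1, n2)
        assert len(n1) == 40

    def test_h0_statistics_fall_inside_null(self):
        """With no effect anywhere, both common-space statistics sit well
        inside the shared reference null."""
        ds, df = simulate_dataset(
            SimulationParams(delta_s=0.0, delta_f=0.0, seed=13)
        )
        null = shared_null_reference(ds, df, T=400, seed=3)
        m_s, m_f, _ = common_space_mmds(ds, df)
        lo, hi = np.quantile(null, [0.005, 0.995])
        assert lo <= m_s <= hi
        assert lo <= m_f <= hi
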