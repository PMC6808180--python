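"""Batch SOM: grid geometry, PCA init, batch updates, training properties."""

from collections import deque
from dataclasses import replace

import numpy as np
import pytest

from phenosom.cohort import CohortGenConfig, generate_scores
from phenosom.som import (SOMConfig, batch_cycle, find_bmu, grid_coords,
                          grid_distances, grid_positions, init_weights_pca,
                          map_bmus, neighborhood_schedule, train_som)


def bfs_hop_counts(adj):
    """Independent BFS oracle for link distances."""
    n = len(adj)
    out = np.full((n, n), np.inf)
    for s in range(n):
        out[s, s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in np.flatnonzero(adj[u]):
                if out[s, v] == np.inf:
                    out[s, v] = out[s, u] + 1
                    q.append(v)
    return out


class TestGridDistances:
    def test_two_node_rectangular_link(self):
        d = grid_distances(SOMConfig(grid_rows=1, grid_cols=2,
                                     topology="rectangular"))
        assert d[0, 1] == 1 and d[1, 0] == 1 and d[0, 0] == 0

    def test_3x3_chebyshev_corner_to_corner(self):
        d = grid_distances(SOMConfig(grid_rows=3, grid_cols=3,
                                     topology="rectangular",
                                     grid_metric="chebyshev"))
        assert d[0, 8] == 2

    def test_hexagonal_link_equals_bfs_oracle(self):
        cfg = SOMConfig(grid_rows=10, grid_cols=10)
        # oracle: hexagonal adjacency from explicit row-parity offsets
        rc = grid_coords(cfg)
        idx = {(r, c): i for i, (r, c) in enumerate(map(tuple, rc))}
        n = len(rc)
        adj = np.zeros((n, n), dtype=bool)
        for (r, c), i in idx.items():
            even = [(-1, -1), (-1, 0), (0, -1), (0, 1), (1, -1), (1, 0)]
            odd = [(-1, 0), (-1, 1), (0, -1), (0, 1), (1, 0), (1, 1)]
            for dr, dc in (odd if r % 2 else even):
                j = idx.get((r + dr, c + dc))
                if j is not None:
                    adj[i, j] = True
        oracle = bfs_hop_counts(adj)
        assert np.array_equal(grid_distances(cfg), oracle)

    def test_symmetric_zero_diagonal_triangle_inequality(self):
        for metric in ("link", "euclidean"):
            cfg = SOMConfig(grid_rows=4, grid_cols=5, grid_metric=metric)
            d = grid_distances(cfg)
            assert np.allclose(d, d.T)
            assert np.allclose(np.diag(d), 0)
            n = len(d)
            viol = d[:, :, None] + d[None, :, :] - d[:, None, :].repeat(n, 1)
            assert viol.min() > -1e-9

    def test_unknown_topology_rejected(self):
        with pytest.raises(ValueError, match="topology"):
            grid_distances(SOMConfig(topology="toroidal"))


class TestPCAInit:
    def test_planar_data_stays_on_plane(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((2, 5))
        X = rng.standard_normal((40, 2)) @ basis + 3.0
        W = init_weights_pca(X, SOMConfig(grid_rows=4, grid_cols=4))
        centered = W - X.mean(axis=0)
        # residual after projecting onto the data plane
        q, _ = np.linalg.qr(basis.T)
        resid = centered - (centered @ q) @ q.T
        assert np.abs(resid).max() < 1e-10

    def test_grand_mean_equals_data_mean(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 7))
        W = init_weights_pca(X, SOMConfig())
        assert np.allclose(W.mean(axis=0), X.mean(axis=0), atol=1e-10)

    def test_span_ratio_is_sqrt_eigenvalue_ratio(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((500, 2)) * [3.0, 1.0]
        evals = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        cfg = SOMConfig(grid_rows=6, grid_cols=6)
        W = init_weights_pca(X, cfg)
        _, evecs = np.linalg.eigh(np.cov(X, rowvar=False))
        pc1, pc2 = evecs[:, -1], evecs[:, -2]
        r1 = np.ptp((W - X.mean(0)) @ pc1)
        r2 = np.ptp((W - X.mean(0)) @ pc2)
        assert r1 / r2 == pytest.approx(np.sqrt(evals[0] / evals[1]), abs=1e-8)

    def test_rank_deficient_falls_back_with_warning(self):
        X = np.outer(np.arange(10.0), [1.0, 2.0])  # rank 1
        with pytest.warns(UserWarning, match="rank-deficient"):
            W = init_weights_pca(X, SOMConfig(grid_rows=3, grid_cols=3))
        assert np.isfinite(W).all()


class TestFindBMU:
    def test_exact_match_and_tie_rule(self):
        rng = np.random.default_rng(3)
        W = rng.standard_normal((20, 4))
        assert find_bmu(W, W[7]) == 7
        W2 = np.zeros((3, 2))
        W2[0] = [1, 0]
        W2[1] = [-1, 0]  # nodes 0 and 1 equidistant from origin
        W2[2] = [5, 5]
        assert find_bmu(W2, np.zeros(2)) == 0

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(4)
        W = rng.standard_normal((100, 7))
        for _ in range(1000):
            x = rng.standard_normal(7)
            dists = [np.linalg.norm(W[i] - x) for i in range(100)]
            assert find_bmu(W, x) == int(np.argmin(dists))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            find_bmu(np.zeros((5, 3)), np.zeros(4))


class TestBatchCycle:
    def test_single_node_mean(self):
        W = np.array([[0.0]])
        out = batch_cycle(W, np.array([[1.0], [3.0]]), 0,
                          np.zeros((1, 1)))
        assert out[0, 0] == 2.0

    def test_constant_data_fixed_point(self):
        cfg = SOMConfig(grid_rows=3, grid_cols=3)
        gd = grid_distances(cfg)
        rng = np.random.default_rng(5)
        W = rng.standard_normal((9, 2))
        v = np.array([1.5, -2.0])
        X = np.tile(v, (10, 1))
        out = batch_cycle(W, X, 1.0, gd)
        bmu = map_bmus(W, X)
        occupied = gd[:, bmu[0]] <= 1.0
        assert np.allclose(out[occupied], v)

    def test_2x2_nd1_matches_hand_enumerated_buffer_average(self):
        cfg = SOMConfig(grid_rows=2, grid_cols=2, topology="rectangular")
        gd = grid_distances(cfg)
        W = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        X = np.array([[0.1, 0.0], [0.9, 0.1], [0.0, 1.1], [1.2, 0.9]])
        # hand oracle: BMUs then explicit neighborhood means
        bmu = [int(np.argmin([np.linalg.norm(w - x) for w in W])) for x in X]
        expect = W.copy()
        for i in range(4):
            neigh = [j for j in range(4) if gd[i, j] <= 1]
            members = [x for x, b in zip(X, bmu) if b in neigh]
            if members:
                expect[i] = np.mean(members, axis=0)
        out = batch_cycle(W, X, 1.0, gd)
        assert np.allclose(out, expect)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            batch_cycle(np.zeros((2, 1)), np.empty((0, 1)), 1,
                        np.zeros((2, 2)))


class TestSchedule:
    def test_default_ordering_values(self):
        nds = neighborhood_schedule(SOMConfig())
        assert nds[:5] == pytest.approx([3.4, 2.8, 2.2, 1.6, 1.0])

    @pytest.mark.parametrize("ins", [1.0, 2.5, 7.0])
    def test_endpoint_is_one_for_any_ins(self, ins):
        cfg = SOMConfig(initial_neighborhood=ins, ordering_steps=4)
        nds = neighborhood_schedule(cfg)
        assert nds[3] == pytest.approx(1.0)

    def test_finetune_entries_below_one(self):
        nds = neighborhood_schedule(SOMConfig(finetune_steps=3))
        assert all(nd < 1 for nd in nds[-3:])


class TestTraining:
    def test_identical_children_collapse_to_their_vector(self):
        v = np.array([0.5, -1.0, 2.0])
        X = np.tile(v, (20, 1))
        with pytest.warns(UserWarning, match="no variance"):
            som = train_som(X, SOMConfig(grid_rows=3, grid_cols=3))
        assert len(set(som.bmu)) == 1
        assert np.allclose(som.weights[som.bmu[0]], v)

    def test_separated_clouds_get_disjoint_contiguous_map_regions(self):
        # each cloud's BMUs are disjoint and fall inside that cloud's map
        # region (nodes nearer its centroid in weight space), and the two
        # regions are grid-contiguous; BMU multisets themselves may leave
        # unoccupied holes, so contiguity is a property of the regions
        rng = np.random.default_rng(6)
        a = rng.standard_normal((60, 3)) + [6, 0, 0]
        b = rng.standard_normal((60, 3)) - [6, 0, 0]
        X = np.vstack([a, b])
        cfg = SOMConfig(seed=1)
        som = train_som(X, cfg)
        set_a = set(som.bmu[:60])
        set_b = set(som.bmu[60:])
        assert set_a.isdisjoint(set_b)
        gd = grid_distances(cfg)
        da = np.linalg.norm(som.weights - a.mean(axis=0), axis=1)
        db = np.linalg.norm(som.weights - b.mean(axis=0), axis=1)
        region_a = set(np.flatnonzero(da < db))
        region_b = set(np.flatnonzero(db <= da))
        assert set_a <= region_a and set_b <= region_b
        for nodes in (region_a, region_b):
            nodes = sorted(nodes)
            seen = {nodes[0]}
            frontier = [nodes[0]]
            while frontier:
                u = frontier.pop()
                for v in nodes:
                    if v not in seen and gd[u, v] <= 1:
                        seen.add(v)
                        frontier.append(v)
            assert seen == set(nodes)

    def test_topographic_ordering_over_seeded_cohorts(self):
        near, far = [], []
        for seed in range(20):
            cfg = CohortGenConfig(cluster_sizes=[40, 30, 35, 35], seed=seed)
            cohort, _ = generate_scores(cfg)
            som = train_som(cohort, SOMConfig(seed=seed))
            X = cohort.values_for()
            from scipy.spatial.distance import pdist, squareform
            dd = squareform(pdist(X))
            gd = squareform(pdist(som.bmu_coords.astype(float)))
            iu = np.triu_indices(len(X), 1)
            order = np.argsort(dd[iu])
            m = max(1, len(order) // 20)
            near.append(gd[iu][order[:m]].mean())
            far.append(gd[iu][order[-m:]].mean())
        assert np.mean(near) < np.mean(far)

    def test_quantization_error_nonincreasing_in_ordering_phase(self):
        for seed in (0, 1, 2):
            cfg = CohortGenConfig(cluster_sizes=[40, 30, 35, 35], seed=seed)
            cohort, _ = generate_scores(cfg)
            som = train_som(cohort, SOMConfig(seed=seed))
            qe = som.quantization_errors[:5]
            assert all(a >= b - 1e-12 for a, b in zip(qe, qe[1:]))

    def test_full_determinism(self, cognitive_matrix):
        cfg = SOMConfig(seed=123, init_jitter_sd=0.05)
        a = train_som(cognitive_matrix, cfg)
        b = train_som(cognitive_matrix, cfg)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.bmu, b.bmu)
        assert a.schedule_trace == b.schedule_trace


class TestLloydEquivalence:
    def lloyd_step(self, centroids, X):
        """Independent Lloyd update oracle (plain loops)."""
        out = centroids.copy()
        assign = []
        for x in X:
            d = [np.dot(x - c, x - c) for c in centroids]
            assign.append(int(np.argmin(d)))
        for i in range(len(centroids)):
            members = [x for x, a in zip(X, assign) if a == i]
            if members:
                out[i] = np.mean(members, axis=0)
        return out

    def test_nd_zero_batch_cycle_is_lloyd_update(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n_nodes = rng.integers(2, 8)
            n_obs = rng.integers(3, 15)
            dim = rng.integers(1, 4)
            W = rng.standard_normal((n_nodes, dim))
            X = rng.standard_normal((n_obs, dim))
            gd = np.where(np.eye(n_nodes, dtype=bool), 0.0, np.inf)
            assert np.allclose(batch_cycle(W, X, 0.0, gd),
                               self.lloyd_step(W, X), atol=1e-12)


class TestWeightPlanes:
    def test_reshape_roundtrip_and_counts(self, trained_som):
        planes = trained_som.weight_planes()
        assert len(planes) == trained_som.weights.shape[1]
        for j, name in enumerate(trained_som.measures):
            assert np.array_equal(planes[name].ravel(),
                                  trained_som.weights[:, j])

    def test_correlation_extremes_and_undefined(self):
        from phenosom.som import TrainedSOM

        rng = np.random.default_rng(8)
        col = rng.standard_normal(12)
        W = np.column_stack([col, col, -col, np.zeros(12)])
        som = TrainedSOM(config=SOMConfig(grid_rows=3, grid_cols=4),
                         node_coords=np.zeros((12, 2), dtype=int),
                         weights=W, schedule_trace=[], bmu=np.zeros(1, int))
        corr = som.weight_plane_correlations()
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)
        assert np.isnan(corr[0, 3]) and np.isnan(corr[3, 3])

    def test_shared_profiles_correlate_higher_than_orthogonal(self):
        # measures A and B share the cluster-mean profile, C is orthogonal
        import pandas as pd

        means = pd.DataFrame({"a": [1, -1, 1, -1], "b": [1, -1, 1, -1],
                              "c": [1, 1, -1, -1]}, dtype=float)
        shared, ortho = [], []
        for seed in range(20):
            cfg = CohortGenConfig(cluster_sizes=[30] * 4, cluster_means=means,
                                  within_cluster_corr=np.eye(3), seed=seed)
            cohort, _ = generate_scores(cfg)
            som = train_som(cohort, SOMConfig(seed=seed))
            corr = som.weight_plane_correlations()
            shared.append(corr[0, 1])
            ortho.append(corr[0, 2])
        assert np.mean(shared) > np.mean(ortho)
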