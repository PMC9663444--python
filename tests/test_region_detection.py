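import numpy as np
import pytest

from mist.io_st import STData
from mist.region_detection import (
    ISOLATED,
    Embedding,
    RegionAssignment,
    SpatialGraph,
    build_weighted_graph,
    default_min_region_size,
    detect_regions,
    embed_pca,
    pc_correlations,
    prune_and_components,
    region_objective,
    select_hvg,
)
from mist.synthetic_data import generate_lattice

from oracles import objective_double_loop, union_find_components


def _data_from_counts(counts, normalized=True):
    m = counts.shape[0]
    side = int(np.ceil(np.sqrt(m)))
    coords = np.array([[i // side, i % side] for i in range(m)])
    return STData(
        counts,
        coords,
        [f"g{j}" for j in range(counts.shape[1])],
        [f"s{i}" for i in range(m)],
        normalized=normalized,
    )


class TestSelectHvg:
    def test_fraction_one_returns_all(self, quad_cpm):
        cpm, _ = quad_cpm
        assert len(select_hvg(cpm, 1.0)) == cpm.n_genes

    def test_top_80_percent_of_ten(self):
        rng = np.random.default_rng(0)
        counts = rng.gamma(2.0, 50.0, (20, 10))
        data = _data_from_counts(counts)
        assert len(select_hvg(data, 0.8)) == 8

    def test_constant_gene_ranked_last(self):
        rng = np.random.default_rng(1)
        counts = rng.gamma(2.0, 50.0, (20, 5))
        counts[:, 2] = 7.0
        data = _data_from_counts(counts)
        assert 2 not in select_hvg(data, 0.8)

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_bad_fraction_fatal(self, quad_cpm, fraction):
        with pytest.raises(ValueError):
            select_hvg(quad_cpm[0], fraction)


class TestEmbedPca:
    def test_exact_low_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        u = rng.gamma(2.0, 1.0, (30, 2))
        v = rng.gamma(2.0, 1.0, (2, 12))
        counts = 5.0 + u @ v  # centered matrix has rank <= 2
        data = _data_from_counts(counts)
        emb = embed_pca(data, np.arange(12), p=2, log1p=False)
        centered = counts - counts.mean(axis=0)
        # two components capture all variance of a centered rank-2 matrix
        assert np.linalg.norm(centered, "fro") == pytest.approx(
            np.linalg.norm(emb.pcs, "fro"), rel=1e-8
        )

    def test_explained_variance_non_increasing(self, quad_cpm):
        cpm, _ = quad_cpm
        emb = embed_pca(cpm, select_hvg(cpm), p=10, log1p=False)
        assert np.all(np.diff(emb.explained_variance) <= 1e-9)

    def test_p_too_large_fatal(self):
        data = _data_from_counts(np.abs(np.random.default_rng(0).normal(size=(5, 4))))
        with pytest.raises(ValueError, match="p="):
            embed_pca(data, np.arange(4), p=5)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        counts = rng.gamma(2.0, 10.0, (25, 8))
        data = _data_from_counts(counts)
        a = embed_pca(data, np.arange(8), p=3)
        b = embed_pca(data, np.arange(8), p=3)
        np.testing.assert_array_equal(a.pcs, b.pcs)


class TestBuildWeightedGraph:
    def test_identical_vectors_weight_one(self):
        pcs = np.tile([1.0, 2.0, -1.0, 0.5], (4, 1))
        emb = Embedding(pcs=pcs, p=4)
        data = _data_from_counts(np.ones((4, 3)))
        g = build_weighted_graph(data, emb)
        np.testing.assert_allclose(g.weights, 1.0)

    def test_anticorrelated_vectors_weight_minus_one(self):
        pcs = np.array([[1.0, 0.0, -1.0], [-1.0, 0.0, 1.0]])
        emb = Embedding(pcs=pcs, p=3)
        data = STData(np.ones((2, 2)), np.array([[0, 0], [0, 1]]),
                      ["g1", "g2"], ["a", "b"], normalized=True)
        g = build_weighted_graph(data, emb)
        np.testing.assert_allclose(g.weights, -1.0)

    def test_3x3_square4_has_12_edges(self):
        coords = generate_lattice(3, 3)
        data = STData(np.ones((9, 2)), coords, ["g1", "g2"],
                      [f"s{i}" for i in range(9)], normalized=True)
        emb = Embedding(pcs=np.random.default_rng(0).normal(size=(9, 3)), p=3)
        g = build_weighted_graph(data, emb)
        assert g.edges.shape[0] == 12  # 2*r*c - r - c

    def test_zero_variance_vector_warns_and_zeroes(self):
        pcs = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        emb = Embedding(pcs=pcs, p=3)
        data = STData(np.ones((2, 2)), np.array([[0, 0], [0, 1]]),
                      ["g1", "g2"], ["a", "b"], normalized=True)
        with pytest.warns(UserWarning, match="zero-variance"):
            g = build_weighted_graph(data, emb)
        np.testing.assert_allclose(g.weights, 0.0)


def _two_block_graph():
    """3x4 lattice: left 2 columns vs right 2 columns, planted weights."""
    coords = generate_lattice(3, 4)
    n = 12
    from mist.lattice import adjacent_pairs

    edges = adjacent_pairs(coords, "square4")
    block = coords[:, 1] >= 2
    weights = np.array(
        [
            0.1 if block[i] != block[j] else 0.9
            for i, j in edges
        ]
    )
    return SpatialGraph(n_nodes=n, edges=edges, weights=weights), block


class TestPruneAndComponents:
    def test_epsilon_above_max_all_isolated(self):
        g, _ = _two_block_graph()
        a = prune_and_components(g, 0.95, 1)
        assert a.n_regions == 0
        assert np.all(a.labels == ISOLATED)

    def test_epsilon_below_min_single_region(self):
        g, _ = _two_block_graph()
        a = prune_and_components(g, 0.05, 1)
        assert a.n_regions == 1
        assert a.regions[0].size == 12

    def test_two_planted_blocks_recovered(self):
        g, block = _two_block_graph()
        a = prune_and_components(g, 0.5, 1)
        assert a.n_regions == 2
        detected = {frozenset(r.tolist()) for r in a.regions}
        expected = {
            frozenset(np.flatnonzero(block).tolist()),
            frozenset(np.flatnonzero(~block).tolist()),
        }
        assert detected == expected

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(5)
        coords = generate_lattice(6, 6)
        from mist.lattice import adjacent_pairs

        edges = adjacent_pairs(coords, "square4")
        weights = rng.uniform(-1, 1, edges.shape[0])
        g = SpatialGraph(n_nodes=36, edges=edges, weights=weights)
        for eps in (0.0, 0.2, 0.5, 0.8):
            a = prune_and_components(g, eps, 1)
            kept = edges[weights >= eps]
            oracle = {
                frozenset(c) for c in union_find_components(36, kept) if len(c) > 1
            }
            detected = {frozenset(r.tolist()) for r in a.regions}
            assert detected == oracle

    def test_strict_comparison_keeps_equal_weight(self):
        edges = np.array([[0, 1]])
        g = SpatialGraph(n_nodes=2, edges=edges, weights=np.array([0.5]))
        a = prune_and_components(g, 0.5, 1)
        assert a.n_regions == 1  # weight == epsilon is kept

    def test_region_ids_by_decreasing_size(self):
        coords = generate_lattice(3, 4)
        from mist.lattice import adjacent_pairs

        edges = adjacent_pairs(coords, "square4")
        # cut the lattice into column groups {0,1}, {2}, {3}
        group = np.minimum(coords[:, 1], 2) - (coords[:, 1] == 3)
        group = np.array([0 if c <= 1 else (1 if c == 2 else 2) for c in coords[:, 1]])
        weights = np.array(
            [0.9 if group[i] == group[j] else 0.0 for i, j in edges]
        )
        g = SpatialGraph(n_nodes=12, edges=edges, weights=weights)
        a = prune_and_components(g, 0.5, 1)
        assert [r.size for r in a.regions] == [6, 3, 3]
        assert a.labels[coords[:, 1] <= 1].tolist() == [0] * 6


class TestRegionObjective:
    def test_closed_form_two_regions(self):
        pcs = np.array(
            [[1.0, 0.0, -1.0]] * 3 + [[-1.0, 0.0, 1.0]] * 3
        )
        emb = Embedding(pcs=pcs, p=3)
        labels = np.array([0, 0, 0, 1, 1, 1])
        regions = [np.array([0, 1, 2]), np.array([3, 4, 5])]
        a = RegionAssignment(labels=labels, regions=regions, threshold=0.5)
        assert region_objective(a, emb, sigma=0.1) == pytest.approx(2.1)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        pcs = rng.normal(size=(30, 6))
        labels = np.array([0] * 12 + [1] * 10 + [ISOLATED] * 8)
        regions = [np.arange(12), np.arange(12, 22)]
        a = RegionAssignment(labels=labels, regions=regions, threshold=0.3)
        emb = Embedding(pcs=pcs, p=6)
        assert region_objective(a, emb, sigma=0.1) == pytest.approx(
            objective_double_loop(labels, pcs, 0.1), abs=1e-10
        )

    def test_invariant_to_relabeling_and_permutation(self):
        rng = np.random.default_rng(9)
        pcs = rng.normal(size=(20, 5))
        labels = np.array([0] * 8 + [1] * 8 + [ISOLATED] * 4)
        regions = [np.arange(8), np.arange(8, 16)]
        emb = Embedding(pcs=pcs, p=5)
        a = RegionAssignment(labels=labels, regions=regions, threshold=0.3)
        base = region_objective(a, emb)
        swapped = RegionAssignment(
            labels=np.where(labels == 0, 1, np.where(labels == 1, 0, labels)),
            regions=[regions[1], regions[0]],
            threshold=0.3,
        )
        assert region_objective(swapped, emb) == pytest.approx(base, abs=1e-12)
        perm = rng.permutation(20)
        inv = np.empty(20, dtype=int)
        inv[perm] = np.arange(20)
        permuted = RegionAssignment(
            labels=labels[perm],
            regions=[np.sort(inv[regions[0]]) for _ in range(1)] + [np.sort(inv[regions[1]])],
            threshold=0.3,
        )
        permuted = RegionAssignment(
            labels=labels[perm],
            regions=[np.sort(inv[r]) for r in regions],
            threshold=0.3,
        )
        emb_perm = Embedding(pcs=pcs[perm], p=5)
        assert region_objective(permuted, emb_perm) == pytest.approx(base, abs=1e-12)

    def test_zero_regions_minus_inf(self):
        emb = Embedding(pcs=np.random.default_rng(0).normal(size=(4, 3)), p=3)
        a = RegionAssignment(labels=np.full(4, ISOLATED), regions=[], threshold=0.9)
        assert region_objective(a, emb) == -np.inf

    def test_single_region_inter_term_zero(self):
        pcs = np.tile([1.0, 2.0, 3.0], (4, 1)) + np.random.default_rng(1).normal(
            scale=0.01, size=(4, 3)
        )
        emb = Embedding(pcs=pcs, p=3)
        a = RegionAssignment(
            labels=np.zeros(4, dtype=int), regions=[np.arange(4)], threshold=0.1
        )
        obj = region_objective(a, emb, sigma=0.1)
        c = pc_correlations(emb)
        intra = (c.sum() - np.trace(c)) / (4 * 3)
        assert obj == pytest.approx(intra + 0.1, abs=1e-12)

    def test_full_coverage_term_equals_sigma(self):
        pcs = np.vstack([np.tile([1.0, 0.0, -1.0], (3, 1)),
                         np.tile([-1.0, 0.0, 1.0], (3, 1))])
        emb = Embedding(pcs=pcs, p=3)
        a = RegionAssignment(
            labels=np.array([0] * 3 + [1] * 3),
            regions=[np.arange(3), np.arange(3, 6)],
            threshold=0.5,
        )
        with_sigma = region_objective(a, emb, sigma=0.4)
        without = region_objective(a, emb, sigma=0.0)
        assert with_sigma - without == pytest.approx(0.4, abs=1e-12)


class TestDetectRegions:
    def test_default_q_by_platform(self):
        assert default_min_region_size(500) == 40
        assert default_min_region_size(499) == 20

    def test_requires_normalized(self, quad_fixture):
        data, _ = quad_fixture
        with pytest.raises(ValueError, match="normalized"):
            detect_regions(data)

    def test_quadrants_recovered(self, quad_cpm):
        cpm, truth = quad_cpm
        a = detect_regions(cpm, log1p=False)
        keep = ~truth.boundary
        from mist.evaluation import adjusted_rand_index

        ari = adjusted_rand_index(a.labels[keep], truth.region_labels[keep])
        assert ari >= 0.75  # strong recovery even at 30% dropout

    def test_objective_self_consistent(self, quad_cpm):
        cpm, _ = quad_cpm
        a = detect_regions(cpm, log1p=False)
        genes = select_hvg(cpm)
        emb = embed_pca(cpm, genes, p=min(30, cpm.n_spots, genes.size), log1p=False)
        assert region_objective(a, emb, sigma=0.1) == pytest.approx(
            a.objective, abs=1e-10
        )

    def test_monotone_components_in_epsilon(self, quad_cpm):
        cpm, _ = quad_cpm
        genes = select_hvg(cpm)
        emb = embed_pca(cpm, genes, p=30, log1p=False)
        g = build_weighted_graph(cpm, emb)
        prev_edges = np.inf
        prev_components = 0
        for eps in np.arange(0.1, 0.95, 0.05):
            kept = int((g.weights >= eps).sum())
            comps = len(
                union_find_components(g.n_nodes, g.edges[g.weights >= eps])
            )
            assert kept <= prev_edges
            assert comps >= prev_components
            prev_edges, prev_components = kept, comps

    def test_no_region_fatal_with_diagnostic(self):
        rng = np.random.default_rng(0)
        counts = rng.gamma(2.0, 100.0, (16, 10))
        data = _data_from_counts(counts / counts.sum(1, keepdims=True) * 1e6)
        with pytest.raises(ValueError, match="distribution"):
            detect_regions(data, q=15, log1p=False)


class TestHexLayout:
    def test_detection_on_hex_lattice(self):
        import warnings as _w
        from mist.io_st import normalize_cpm
        from mist.synthetic_data import generate_synthetic_st

        data, truth = generate_synthetic_st(
            14, 14, 80, n_regions=4, rank=3, dropout_rate=0.02, seed=1,
            layout="hex6", coherence=6.0, within_noise=0.2,
        )
        cpm = normalize_cpm(data)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            a = detect_regions(cpm, layout="hex6", log1p=False)
        from mist.evaluation import adjusted_rand_index

        keep = ~truth.boundary
        ari = adjusted_rand_index(a.labels[keep], truth.region_labels[keep])
        assert ari >= 0.75
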