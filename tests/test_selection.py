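import numpy as np
import pytest
import scipy.linalg

from sparselap import (
    InputError,
    ScanConfig,
    fit_sparse_loadings,
    genome_scan,
    normalize,
    pca_marker_scores,
    qr_prune,
    rank_markers,
    select_top,
    simulate_discrete_pops,
    sparse_eigenfunctions,
)
from sparselap.graph import embed_normalized
from sparselap.selection import elastic_net_objective, lambda_max, tune_lambda1
from .conftest import make_genotypes


def prox_gradient_enet(X, y, lam1, lam2, n_iter=20000):
    """Independent proximal-gradient (ISTA) solver for
    ||y - Xv||^2 + lam1 ||v||_1 + lam2 ||v||_2^2."""
    L = 2 * (np.linalg.norm(X, 2) ** 2 + lam2)
    v = np.zeros(X.shape[1])
    for _ in range(n_iter):
        grad = -2 * X.T @ (y - X @ v) + 2 * lam2 * v
        z = v - grad / L
        v_new = np.sign(z) * np.maximum(np.abs(z) - lam1 / L, 0)
        if np.max(np.abs(v_new - v)) < 1e-12:
            return v_new
        v = v_new
    return v


@pytest.fixture(scope="module")
def rand_problem():
    rng = np.random.default_rng(20)
    X = rng.normal(size=(20, 30))
    phi = rng.normal(size=20)
    return X, phi


class TestElasticNet:
    def test_large_lambda1_kills_all_loadings(self, rand_problem):
        X, phi = rand_problem
        lam = lambda_max(X, phi) * 1.001
        V = fit_sparse_loadings(X, phi, lam, 0.0).V
        assert np.all(V == 0)

    def test_unpenalized_limit_is_ols(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 6))
        phi = rng.normal(size=15)
        V = fit_sparse_loadings(X, phi, 0.0, 0.0).V[:, 0]
        ols = np.linalg.solve(X.T @ X, X.T @ phi)
        np.testing.assert_allclose(V, ols, atol=1e-8)

    def test_orthonormal_design_soft_threshold(self):
        rng = np.random.default_rng(9)
        Q, _ = np.linalg.qr(rng.normal(size=(8, 4)))
        Phi = rng.normal(size=(8, 2))
        lam1 = 0.3
        V = fit_sparse_loadings(Q, Phi, lam1, 0.0).V
        z = Q.T @ Phi
        want = np.sign(z) * np.maximum(np.abs(z) - lam1 / 2, 0)
        np.testing.assert_allclose(V, want, atol=1e-7)

    @pytest.mark.parametrize("lam1,lam2", [
        (0.0, 0.5), (0.5, 0.0), (0.5, 0.5), (2.0, 0.1), (0.05, 2.0),
    ])
    def test_agrees_with_proximal_gradient_oracle(self, rand_problem, lam1, lam2):
        X, phi = rand_problem
        v_pkg = fit_sparse_loadings(X, phi, lam1, lam2).V[:, 0]
        v_ref = prox_gradient_enet(X, phi, lam1, lam2)
        obj_pkg = elastic_net_objective(X, phi, v_pkg, lam1, lam2)
        obj_ref = elastic_net_objective(X, phi, v_ref, lam1, lam2)
        assert obj_pkg <= obj_ref + 1e-5

    def test_solution_beats_trivial_candidates(self, rand_problem):
        X, phi = rand_problem
        ols, *_ = np.linalg.lstsq(X, phi, rcond=None)
        for lam1, lam2 in [(0.1, 0.1), (1.0, 0.5), (3.0, 0.0)]:
            v = fit_sparse_loadings(X, phi, lam1, lam2).V[:, 0]
            obj = elastic_net_objective(X, phi, v, lam1, lam2)
            assert obj <= elastic_net_objective(X, phi, np.zeros_like(v), lam1, lam2)
            assert obj <= elastic_net_objective(X, phi, ols, lam1, lam2) + 1e-10

    def test_sparsity_path_monotone(self, rand_problem):
        X, phi = rand_problem
        lams = np.geomspace(lambda_max(X, phi), 1e-3, 10)
        nnz = [int((fit_sparse_loadings(X, phi, lam, 0.0).V != 0).sum())
               for lam in lams]
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))

    def test_stored_zeros_are_exact(self, rand_problem):
        X, phi = rand_problem
        V = fit_sparse_loadings(X, phi, 1.0, 1.0).V
        assert np.all((V == 0) | (np.abs(V) > 1e-12))

    def test_tune_lambda_reaches_target(self, rand_problem):
        X, phi = rand_problem
        lam, loadings = tune_lambda1(X, phi, target_nonzero=5)
        assert (loadings.V != 0).sum() >= 5
        direct = fit_sparse_loadings(X, phi, lam, lam)
        np.testing.assert_allclose(loadings.V, direct.V, atol=1e-6)


class TestRanking:
    def test_hand_computation(self):
        V = np.array([[1.0, 0], [0, 2], [1, 1]])
        rk = rank_markers(V, weights=np.array([0.7, 0.3]))
        np.testing.assert_allclose(rk.scores, [0.7, 1.2, 1.0])
        np.testing.assert_array_equal(rk.order, [1, 2, 0])

    def test_zero_row_ranks_last(self):
        V = np.array([[0.5], [0.0], [1.0]])
        rk = rank_markers(V)
        assert rk.scores[1] == 0
        assert rk.order[-1] == 1
        assert rk.zero_fraction == pytest.approx(1 / 3)

    def test_single_eigenfunction_reduces_to_squared_loading(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(12, 1))
        rk = rank_markers(v)
        np.testing.assert_allclose(rk.scores, v[:, 0] ** 2)
        np.testing.assert_array_equal(rk.order, np.argsort(-np.abs(v[:, 0]),
                                                           kind="stable"))

    def test_eigen_variance_weights(self):
        V = np.ones((4, 2))
        rk = rank_markers(V, weights="eigen_variance", eigenvalues=[0.1, 0.4])
        w = np.array([1 / 1.1, 1 / 1.4])
        np.testing.assert_allclose(rk.weights_used, w / w.sum())

    def test_ties_broken_by_marker_index(self):
        V = np.array([[1.0], [1.0], [2.0], [1.0]])
        rk = rank_markers(V)
        np.testing.assert_array_equal(rk.order, [2, 0, 1, 3])

    def test_select_top_truncates_to_positive_scores(self, caplog):
        rk = rank_markers(np.array([[1.0], [0.0], [0.5]]))
        got = select_top(rk, 3)
        np.testing.assert_array_equal(got, [0, 2])

    def test_select_top_full_and_errors(self):
        rk = rank_markers(np.array([[1.0], [0.5], [0.2]]))
        np.testing.assert_array_equal(select_top(rk, 3), rk.order)
        with pytest.raises(InputError):
            select_top(rk, 0)


class TestSparseEigenfunctions:
    def test_full_panel_reproduces_embedding_exactly(self, two_pop_sim):
        G = two_pop_sim.genotypes
        X = normalize(G)
        full, _ = embed_normalized(X, K=2, epsilon="connect")
        again = sparse_eigenfunctions(G, np.arange(G.n_markers), K=2,
                                      epsilon="connect")
        np.testing.assert_array_equal(full.coords, again.coords)
        assert again.source == "sparse"

    def test_empty_panel_raises(self, two_pop_sim):
        with pytest.raises(InputError):
            sparse_eigenfunctions(two_pop_sim.genotypes, [])


@pytest.fixture(scope="module")
def scan_inputs(small_ring):
    from sparselap.genotypes import prepare

    Gq, X = prepare(small_ring.genotypes)
    emb, _ = embed_normalized(X, K=2, epsilon=("quantile", 0.4))
    return Gq, X, emb.coords


class TestGenomeScan:
    def test_single_group_equals_direct(self, scan_inputs):
        Gq, X, Phi = scan_inputs
        lam = 0.2
        cfg = ScanConfig(group_size=X.n_markers + 1, seed=3)
        scanned = genome_scan(X, Phi, cfg, Gq.markers, lam, lam)
        direct = rank_markers(fit_sparse_loadings(X, Phi, lam, lam))
        np.testing.assert_allclose(scanned.scores, direct.scores, atol=1e-10)
        np.testing.assert_array_equal(scanned.order, direct.order)

    def test_deterministic_given_seed(self, scan_inputs):
        Gq, X, Phi = scan_inputs
        cfg = ScanConfig(group_size=400, keep_fraction=0.3, seed=5)
        r1 = genome_scan(X, Phi, cfg, Gq.markers, 0.2, 0.2)
        r2 = genome_scan(X, Phi, cfg, Gq.markers, 0.2, 0.2)
        np.testing.assert_array_equal(r1.order, r2.order)
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_overlap_with_direct_ranking(self, scan_inputs):
        Gq, X, Phi = scan_inputs
        # proportions mirror a 10k-marker scan with groups of 2.5k, 20% kept
        # per round and the top-100 compared: the kept-per-group count stays
        # well above the compared slice
        lam, _ = tune_lambda1(X, Phi, target_nonzero=80)
        cfg = ScanConfig(group_size=400, keep_fraction=0.2, seed=5)
        scanned = genome_scan(X, Phi, cfg, Gq.markers, lam, lam)
        direct = rank_markers(fit_sparse_loadings(X, Phi, lam, lam))
        top = 12
        overlap = len(set(scanned.order[:top]) & set(direct.order[:top]))
        assert overlap >= 0.8 * top

    def test_ld_aware_splits_duplicated_markers(self):
        rng = np.random.default_rng(14)
        g = rng.choice([0.0, 0.5, 1.0], size=(30, 40))
        g[:, 1] = g[:, 0]  # adjacent exact duplicates
        G = make_genotypes(g)
        from sparselap.selection import _partition

        groups = _partition(np.arange(40), G.markers, group_size=20,
                            ld_aware=True, rng=np.random.default_rng(0))
        ga = [i for i, grp in enumerate(groups) if 0 in grp]
        gb = [i for i, grp in enumerate(groups) if 1 in grp]
        assert ga != gb


class TestPCAComparator:
    def test_constant_marker_scores_zero(self):
        g = np.array([[0.5, 0.0], [0.5, 1.0], [0.5, 0.5], [0.5, 0.0]])
        rk = pca_marker_scores(make_genotypes(g), n_pcs=1)
        assert rk.scores[0] == pytest.approx(0.0, abs=1e-20)

    def test_duplicated_markers_score_identically(self):
        rng = np.random.default_rng(3)
        g = rng.choice([0.0, 0.5, 1.0], size=(25, 6))
        g[:, 3] = g[:, 0]
        rk = pca_marker_scores(make_genotypes(g), n_pcs=2)
        assert rk.scores[0] == pytest.approx(rk.scores[3], rel=1e-10)

    def test_top_marker_has_largest_frequency_difference(self):
        sim = simulate_discrete_pops(n_pops=2, fst=0.3, samples_per_pop=100,
                                     n_loci=50, seed=2)
        rk = pca_marker_scores(sim.genotypes, n_pcs=1)
        g = sim.genotypes.genotypes
        lab = sim.deme_labels
        diff = np.abs(g[lab == 0].mean(0) - g[lab == 1].mean(0))
        assert rk.order[0] == int(np.argmax(diff))

    def test_n_pcs_bounds(self, two_pop_sim):
        with pytest.raises(InputError):
            pca_marker_scores(two_pop_sim.genotypes, n_pcs=10_000)


class TestQRPrune:
    def test_duplicate_deferred(self):
        rng = np.random.default_rng(6)
        g = rng.choice([0.0, 0.5, 1.0], size=(40, 10))
        g[:, 1] = g[:, 0]
        G = make_genotypes(g)
        kept = qr_prune(G, np.arange(10), 9)
        assert not {0, 1} <= set(kept)

    def test_full_rank_full_keep_is_permutation(self):
        rng = np.random.default_rng(15)
        g = rng.choice([0.0, 0.5, 1.0], size=(50, 8))
        G = make_genotypes(g)
        kept = qr_prune(G, np.arange(8), 8)
        assert sorted(kept) == list(range(8))

    def test_pruning_reduces_max_pairwise_r2(self, ld_block_sim):
        G, labels, block_of = ld_block_sim
        rk = pca_marker_scores(G, n_pcs=2)
        top100 = rk.order[:100]
        pruned = qr_prune(G, rk.order[:500], 100)

        def max_r2(panel):
            sub = G.genotypes[:, panel]
            r = np.corrcoef(sub.T)
            np.fill_diagonal(r, 0)
            return (r ** 2).max()

        assert max_r2(pruned) <= max_r2(top100)


class TestLDRedundancyContrast:
    def test_sparse_panel_has_fewer_within_block_pairs_than_pca(self, ld_block_sim):
        from itertools import combinations

        from sparselap import SparseLaplacianEigenmap

        G, labels, block_of = ld_block_sim
        n_blocks = int(block_of.max()) + 1
        model = SparseLaplacianEigenmap(G, n_components=1, epsilon="connect",
                                        qc=False)
        res = model.fit(lambda1="auto", target_nonzero=100)
        q = n_blocks

        def within_block_pairs(panel):
            blocks = block_of[np.asarray(panel)]
            return sum(1 for a, b in combinations(blocks, 2)
                       if a == b and a >= 0)

        slap_panel = res.ranking.order[:q]
        pca_panel = pca_marker_scores(G, n_pcs=1).order[:q]
        assert within_block_pairs(slap_panel) < within_block_pairs(pca_panel)
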