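"""NMF contracts, consensus stability, splitting, hyperparameter search."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.decomposition import NMF as SklearnNMF
from sklearn.metrics import adjusted_rand_score

from sanmf import factorization as fz


def block_matrix(rng, sizes=(20, 15), features=(12, 10), scale=5.0):
    """Block-diagonal nonnegative matrix with the given block shapes."""
    blocks = [rng.uniform(1.0, scale, size=(n, m)) for n, m in zip(sizes, features)]
    X = np.zeros((sum(sizes), sum(features)))
    r = c = 0
    labels = []
    for g, b in enumerate(blocks):
        X[r:r + b.shape[0], c:c + b.shape[1]] = b
        labels += [g] * b.shape[0]
        r += b.shape[0]
        c += b.shape[1]
    return X, np.array(labels)


class TestFitNMF:
    def test_rank_one_exactness(self, rng):
        u = rng.uniform(0.5, 2.0, size=30)
        v = rng.uniform(0.5, 2.0, size=40)
        X = np.outer(u, v)
        f = fz.fit_nmf(X, fz.NMFConfig(k=1, max_iter=500, tol=1e-12, seed=0))
        rel = f.objective / np.linalg.norm(X)
        assert rel < 1e-6

    def test_block_recovery(self, rng):
        X, labels = block_matrix(rng)
        f = fz.fit_nmf(X, fz.NMFConfig(k=2, max_iter=500, seed=0))
        assert adjusted_rand_score(labels, f.W.argmax(axis=1)) == 1.0

    def test_negative_entry_reported_with_location(self):
        X = np.ones((3, 3))
        X[1, 2] = -1.0
        with pytest.raises(ValueError, match=r"\(1, 2\)"):
            fz.fit_nmf(X, fz.NMFConfig(k=2))

    def test_objective_monotone_nonincreasing(self, rng):
        X = rng.uniform(0, 3.0, size=(25, 30))
        f = fz.fit_nmf(X, fz.NMFConfig(k=3, max_iter=200, tol=1e-12, seed=1))
        diffs = np.diff(f.trajectory)
        assert (diffs <= 1e-8 * (1 + f.trajectory[:-1])).all()

    def test_factors_nonnegative(self, rng):
        X = sp.random(30, 40, density=0.3, random_state=1, format="csr") * 10
        f = fz.fit_nmf(X, fz.NMFConfig(k=4, seed=2))
        assert (f.W >= 0).all() and (f.H >= 0).all()

    def test_objective_comparable_to_sklearn(self, rng):
        """Independent cross-check: same loss, same rank, similar optimum."""
        X = rng.uniform(0, 5.0, size=(40, 50))
        ours = fz.fit_nmf(X, fz.NMFConfig(k=3, max_iter=500, tol=1e-9, seed=0))
        ref = SklearnNMF(3, init="random", solver="mu", max_iter=2000,
                         tol=1e-9, random_state=0).fit(X)
        ref_obj = np.linalg.norm(X - ref.transform(X) @ ref.components_)
        assert ours.objective <= ref_obj * 1.02

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            fz.fit_nmf(np.zeros((3, 3)), fz.NMFConfig(k=2))


class TestAssignMembership:
    def test_argmax(self):
        labels, unassigned = fz.assign_membership(np.array([[0.1, 0.9, 0.3]]))
        assert labels == {0: 2} and unassigned == []

    def test_tie_breaks_to_lowest_component(self):
        labels, _ = fz.assign_membership(np.array([[0.5, 0.5, 0.0]]))
        assert labels == {0: 1}

    def test_zero_row_unassigned(self):
        labels, unassigned = fz.assign_membership(np.array([[0.0, 0.0], [1.0, 0.0]]))
        assert labels == {1: 1} and unassigned == [0]

    def test_label_equivariance_under_row_permutation(self, rng):
        X, labels = block_matrix(rng)
        perm = rng.permutation(X.shape[0])
        f1 = fz.fit_nmf(X, fz.NMFConfig(k=2, seed=0))
        f2 = fz.fit_nmf(X[perm], fz.NMFConfig(k=2, seed=0))
        assert adjusted_rand_score(f1.W.argmax(1)[perm], f2.W.argmax(1)) == 1.0


class TestConsensus:
    def test_perfect_blocks_give_rho_one(self, rng):
        X, _ = block_matrix(rng)
        res = fz.consensus_cophenetic(X, k=2, n_runs=5, seed=0)
        assert res.cophenetic_rho == pytest.approx(1.0)
        assert set(np.unique(res.consensus)) <= {0.0, 1.0}

    def test_diagonal_always_one(self, rng):
        X = rng.uniform(0, 2, size=(15, 20))
        res = fz.consensus_cophenetic(X, k=3, n_runs=3, seed=1)
        assert (np.diag(res.consensus) == 1.0).all()
        assert np.allclose(res.consensus, res.consensus.T)

    def test_rho_stable_when_doubling_runs(self, rng):
        X, _ = block_matrix(rng, sizes=(25, 20), features=(15, 12))
        a = fz.consensus_cophenetic(X, k=2, n_runs=5, seed=3).cophenetic_rho
        b = fz.consensus_cophenetic(X, k=2, n_runs=10, seed=3).cophenetic_rho
        assert abs(a - b) < 0.05

    def test_best_factors_is_lowest_objective(self, rng):
        X = rng.uniform(0, 2, size=(20, 25))
        res = fz.consensus_cophenetic(X, k=2, n_runs=4, seed=0)
        assert res.best_factors is not None
        solo = fz.fit_nmf(X, fz.NMFConfig(k=2, seed=0))
        assert res.best_factors.objective <= solo.objective * 1.01

    def test_single_run_rejected(self, rng):
        with pytest.raises(ValueError):
            fz.consensus_cophenetic(rng.uniform(0, 1, (5, 5)), k=2, n_runs=1, seed=0)


class TestDistinctiveness:
    def test_disjoint_sets_fully_distinct(self):
        H = np.array([[3.0, 2.0, 0.0, 0.0], [0.0, 0.0, 3.0, 2.0]])
        assert fz.distinctiveness(H, top_n=2) == 1.0

    def test_identical_sets_zero(self):
        H = np.array([[3.0, 2.0, 0.1, 0.0], [3.0, 2.0, 0.0, 0.1]])
        assert fz.distinctiveness(H, top_n=2) == 0.0

    def test_partial_overlap_jaccard(self):
        # top-2 sets {a,b} and {b,c}: Jaccard 1/3, distinctiveness 2/3
        H = np.array([[3.0, 2.0, 0.5, 0.1], [0.5, 3.0, 2.0, 0.1]])
        assert fz.distinctiveness(H, top_n=2) == pytest.approx(2 / 3)

    def test_top_n_larger_than_vocabulary_uses_all(self):
        H = np.array([[1.0, 2.0], [2.0, 1.0]])
        assert fz.distinctiveness(H, top_n=100) == 0.0

    def test_requires_two_components(self):
        with pytest.raises(ValueError):
            fz.distinctiveness(np.array([[1.0, 2.0]]))


class TestSplitCohort:
    def test_stratified_counts_n10(self):
        ids = [f"p{i}" for i in range(10)]
        mortality = {p: i < 2 for i, p in enumerate(ids)}
        train, test = fz.split_cohort(ids, mortality, ratio=0.8, seed=0)
        assert len(train) == 8 and len(test) == 2
        # largest remainder: deaths 2*0.8=1.6 -> 2, survivors 8*0.8=6.4 -> 6
        assert sum(mortality[p] for p in train) == 2
        assert sum(mortality[p] for p in test) == 0

    def test_deterministic(self):
        ids = [f"p{i}" for i in range(20)]
        mortality = {p: i % 4 == 0 for i, p in enumerate(ids)}
        assert fz.split_cohort(ids, mortality, seed=5) == fz.split_cohort(
            ids, mortality, seed=5)

    def test_full_ratio_rejected(self):
        ids = ["a", "b", "c", "d"]
        mortality = {"a": True, "b": True, "c": False, "d": False}
        with pytest.raises(ValueError):
            fz.split_cohort(ids, mortality, ratio=1.0)

    def test_single_class_rejected(self):
        ids = ["a", "b", "c"]
        with pytest.raises(ValueError):
            fz.split_cohort(ids, {p: False for p in ids})

    def test_tiny_stratum_rejected(self):
        ids = ["a", "b", "c", "d"]
        mortality = {"a": True, "b": False, "c": False, "d": False}
        with pytest.raises(ValueError, match="fewer than 2"):
            fz.split_cohort(ids, mortality)


class TestHyperparameterSearch:
    def test_single_cell_grid_returned(self, rng):
        X, _ = block_matrix(rng)
        builders = {(6.0, 5): lambda: sp.csr_matrix(X)}
        best, table = fz.select_hyperparameters(builders, k_grid=(2,), n_runs=3, seed=0)
        assert (best.interval, best.min_support, best.k) == (6.0, 5, 2)
        assert len(table) == 1

    def test_empty_cell_scored_minus_inf(self, rng):
        X, _ = block_matrix(rng)
        builders = {
            (6.0, 5): lambda: sp.csr_matrix(X),
            (24.0, 100): lambda: sp.csr_matrix((X.shape[0], 0)),
        }
        best, table = fz.select_hyperparameters(builders, k_grid=(2,), n_runs=3, seed=0)
        assert best.min_support == 5
        empty_rows = table[table["min_support"] == 100]
        assert (empty_rows["cophenetic_rho"] == -np.inf).all()


class TestRefitValidation:
    def test_identical_split_perfectly_stable(self, rng):
        corpus_matrix, _ = block_matrix(rng, sizes=(20, 20), features=(10, 10))
        from sanmf.mining import Subgraph, SubgraphCountMatrix

        subs = [Subgraph("v", (i, i)) for i in range(corpus_matrix.shape[1])]
        m = SubgraphCountMatrix(
            patients=[f"p{i}" for i in range(corpus_matrix.shape[0])],
            subgraphs=subs, counts=sp.csr_matrix(corpus_matrix),
            support=np.ones(corpus_matrix.shape[1], dtype=int),
        )
        report = fz.refit_validation(m, m, fz.NMFConfig(k=2, seed=0), n_runs=3)
        assert report["rho_difference"] == pytest.approx(0.0)
        assert report["weight_rank_correlation"] == pytest.approx(1.0)

    def test_disjoint_vocabulary_flagged(self, rng):
        from sanmf.mining import Subgraph, SubgraphCountMatrix

        X = rng.uniform(0.1, 1.0, size=(12, 6))
        def make(prefix):
            subs = [Subgraph(prefix, (i, i)) for i in range(6)]
            return SubgraphCountMatrix(
                patients=[f"p{i}" for i in range(12)], subgraphs=subs,
                counts=sp.csr_matrix(X), support=np.ones(6, dtype=int))
        report = fz.refit_validation(make("a"), make("b"),
                                     fz.NMFConfig(k=2, seed=0), n_runs=2)
        assert report["shared_subgraphs"] == 0
        assert report["weight_rank_correlation"] is None
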