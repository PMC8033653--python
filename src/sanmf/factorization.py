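"""Nonnegative matrix factorization of the patient x subgraph count matrix.

The count matrix X (patients x subgraphs) is factorized as X ~ W H with W, H
elementwise nonnegative: W rows are patient group coefficients, H rows are
trend-group subgraph coefficients. The Frobenius objective is minimized by
multiplicative updates (Lee-Seung), which keep the objective monotone
non-increasing — the trajectory is recorded so the contract can be asserted.

Rank selection follows consensus clustering: many seeded fits, a connectivity
matrix per fit (1 iff two patients share the same W row-argmax), their mean as
the consensus matrix, and the cophenetic correlation between consensus
distances and their average-linkage hierarchical clustering as the stability
score. A distinctiveness score (1 - mean pairwise Jaccard overlap of the
components' top-n subgraph sets) breaks ties between equally stable
configurations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class NMFConfig:
    k: int = 3
    max_iter: int = 300
    tol: float = 1e-5
    n_consensus_runs: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class NMFFactors:
    W: np.ndarray                 # n_patients x k
    H: np.ndarray                 # k x n_subgraphs
    objective: float              # final Frobenius reconstruction error
    trajectory: np.ndarray        # objective after every iteration
    n_iter: int


@dataclass
class ConsensusResult:
    consensus: np.ndarray
    cophenetic_rho: float
    best_factors: "NMFFactors | None" = None  # lowest-objective run of the ensemble


def _as_csr(X) -> sp.csr_matrix:
    if sp.issparse(X):
        return X.tocsr().astype(float)
    return sp.csr_matrix(np.asarray(X, dtype=float))


def _check_nonnegative(X: sp.csr_matrix) -> None:
    if X.nnz and X.data.min() < 0:
        coo = X.tocoo()
        neg = int(np.flatnonzero(coo.data < 0)[0])
        raise ValueError(
            f"negative entry {coo.data[neg]} at ({coo.row[neg]}, {coo.col[neg]})"
        )


def fit_nmf(X, config: NMFConfig) -> NMFFactors:
    """Frobenius NMF via multiplicative updates with seeded random init.

    Stops when the relative decrease of the objective falls below
    ``config.tol`` or at ``config.max_iter``. The objective is recorded after
    every iteration and is monotone non-increasing up to floating-point noise.
    """
    config.validate()
    Xs = _as_csr(X)
    _check_nonnegative(Xs)
    n, m = Xs.shape
    if n == 0 or m == 0 or Xs.nnz == 0:
        raise ValueError("cannot factorize an empty or all-zero matrix")
    k = config.k
    rng = np.random.default_rng(config.seed)
    scale = np.sqrt(Xs.mean() / k)
    W = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, m)) * scale

    x_norm2 = float((Xs.data ** 2).sum())
    traj: list[float] = []
    prev = np.inf
    it = 0
    for it in range(1, config.max_iter + 1):
        # H update
        WtX = W.T @ Xs            # k x m
        WtW = W.T @ W
        H *= WtX / np.maximum(WtW @ H, _EPS)
        # W update
        XHt = Xs @ H.T            # n x k
        HHt = H @ H.T
        W *= XHt / np.maximum(W @ HHt, _EPS)
        # Frobenius objective without forming WH:
        # ||X - WH||^2 = ||X||^2 - 2<X H^T, W> + <W^T W, H H^T>
        XHt = Xs @ H.T
        WtW = W.T @ W
        HHt = H @ H.T
        obj2 = x_norm2 - 2.0 * float(np.sum(XHt * W)) + float(np.sum(WtW * HHt))
        obj = float(np.sqrt(max(obj2, 0.0)))
        traj.append(obj)
        if np.isfinite(prev) and prev > 0 and (prev - obj) / prev < config.tol:
            break
        prev = obj
    return NMFFactors(W=W, H=H, objective=traj[-1], trajectory=np.array(traj), n_iter=it)


def assign_membership(W: np.ndarray) -> tuple[dict[int, int], list[int]]:
    """Row-argmax phenotype labels (1..k), ties toward the lowest component.

    Returns (row index -> label, list of unassigned all-zero row indices).
    """
    labels: dict[int, int] = {}
    unassigned: list[int] = []
    for i, row in enumerate(np.asarray(W)):
        if np.all(row == 0):
            unassigned.append(i)
        else:
            labels[i] = int(np.argmax(row)) + 1
    if unassigned:
        logger.warning("%d patient(s) with all-zero coefficients left unassigned",
                       len(unassigned))
    return labels, unassigned


def _labels_array(W: np.ndarray) -> np.ndarray:
    # argmax with ties toward the lowest index; all-zero rows get label 0
    lab = np.argmax(W, axis=1) + 1
    lab[np.all(W == 0, axis=1)] = 0
    return lab


def consensus_cophenetic(X, k: int, n_runs: int, seed: int,
                         max_iter: int = 300, tol: float = 1e-5) -> ConsensusResult:
    """Consensus matrix over seeded NMF runs and its cophenetic correlation.

    Entry (i, j) of the consensus matrix is the fraction of runs in which
    patients i and j share the same W row-argmax. The cophenetic correlation
    is the Pearson correlation between the (1 - consensus) distances and the
    cophenetic distances of their average-linkage dendrogram; it is 1 when the
    consensus is perfectly block-structured.

    The lowest-objective run of the ensemble is kept as ``best_factors``;
    multiplicative updates occasionally settle in a poorer local optimum, and
    restart selection by objective is the standard cure.
    """
    if n_runs < 2:
        raise ValueError("n_consensus_runs must be >= 2")
    Xs = _as_csr(X)
    n = Xs.shape[0]
    consensus = np.zeros((n, n))
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2 ** 31)
    best: NMFFactors | None = None
    for s in seeds:
        factors = fit_nmf(Xs, NMFConfig(k=k, max_iter=max_iter, tol=tol, seed=int(s)))
        if best is None or factors.objective < best.objective:
            best = factors
        lab = _labels_array(factors.W)
        consensus += (lab[:, None] == lab[None, :]).astype(float)
    consensus /= n_runs
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = squareform(1.0 - consensus, checks=False)
    if np.allclose(dist, dist[0]):
        # degenerate: all pairwise distances equal (single consensus cluster)
        rho = 0.0
    else:
        linkage = average(dist)
        rho = float(cophenet(linkage, dist)[0])
        if not np.isfinite(rho):
            rho = 0.0
    return ConsensusResult(consensus=consensus, cophenetic_rho=rho,
                           best_factors=best)


def _top_sets(H: np.ndarray, top_n: int) -> list[frozenset[int]]:
    k, m = H.shape
    n = min(top_n, m)
    sets = []
    for comp in range(k):
        order = np.lexsort((np.arange(m), -H[comp]))
        sets.append(frozenset(order[:n].tolist()))
    return sets


def distinctiveness(H: np.ndarray, top_n: int = 100) -> float:
    """1 - mean pairwise Jaccard overlap of the components' top-n subgraph
    sets; 1 means the trend groups emphasize fully disjoint subgraphs."""
    H = np.asarray(H)
    if H.shape[0] < 2:
        raise ValueError("distinctiveness needs k >= 2")
    sets = _top_sets(H, top_n)
    overlaps = [
        len(a & b) / len(a | b) if a | b else 0.0
        for a, b in combinations(sets, 2)
    ]
    return 1.0 - float(np.mean(overlaps))


def split_cohort(
    patient_ids: Sequence[str],
    mortality: Mapping[str, bool],
    ratio: float = 0.8,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Mortality-stratified train/test split.

    |train| = round(ratio * n) exactly; per-stratum training counts are
    apportioned by largest remainder, so each stratum's mortality rate agrees
    between the splits to within one patient. Deterministic for a fixed seed.
    """
    ids = list(patient_ids)
    n = len(ids)
    n_train = int(round(ratio * n))
    if n_train >= n or n_train <= 0:
        raise ValueError("split ratio leaves an empty train or test set")
    strata: dict[bool, list[str]] = {}
    for pid in ids:
        strata.setdefault(bool(mortality[pid]), []).append(pid)
    if len(strata) < 2:
        raise ValueError("both mortality classes must be present")
    for flag, members in strata.items():
        if len(members) < 2:
            raise ValueError(f"mortality stratum {flag} has fewer than 2 patients")

    rng = np.random.default_rng(seed)
    keys = sorted(strata)
    ideal = {f: ratio * len(strata[f]) for f in keys}
    take = {f: int(np.floor(ideal[f])) for f in keys}
    # largest-remainder apportionment up to the exact train size
    while sum(take.values()) < n_train:
        f = max(keys, key=lambda f: (ideal[f] - take[f], -take[f]))
        take[f] += 1
    while sum(take.values()) > n_train:
        f = min(keys, key=lambda f: (ideal[f] - take[f], take[f]))
        take[f] -= 1
    train: list[str] = []
    test: list[str] = []
    for f in keys:
        members = list(strata[f])
        rng.shuffle(members)
        train.extend(members[: take[f]])
        test.extend(members[take[f]:])
    return sorted(train), sorted(test)


@dataclass
class GridScore:
    interval: float
    min_support: int
    k: int
    cophenetic_rho: float
    distinctiveness: float


def select_hyperparameters(
    matrix_builders: Mapping[tuple[float, int], Callable[[], object]],
    k_grid: Sequence[int] = (2, 3, 4, 5, 6),
    n_runs: int = 30,
    seed: int = 0,
    top_n: int = 100,
) -> tuple[GridScore, pd.DataFrame]:
    """Grid search over (interval, min_support) x k.

    ``matrix_builders`` maps an (interval, min_support) cell to a callable
    producing the training count matrix for that cell (built from the training
    split only). Cophenetic correlation is the primary score; distinctiveness
    breaks ties. Cells yielding an empty matrix score -inf and are logged.
    """
    rows: list[GridScore] = []
    for (interval, support), builder in matrix_builders.items():
        matrix = builder()
        X = getattr(matrix, "counts", matrix)
        if X is None or X.shape[1] == 0:
            logger.warning("grid cell (interval=%s, support=%s) yielded no subgraphs",
                           interval, support)
            for k in k_grid:
                rows.append(GridScore(interval, support, k, -np.inf, -np.inf))
            continue
        for k in k_grid:
            res = consensus_cophenetic(X, k=k, n_runs=n_runs, seed=seed)
            d = distinctiveness(res.best_factors.H, top_n=top_n) if k >= 2 else 0.0
            rows.append(GridScore(interval, support, k, res.cophenetic_rho, d))
    if not rows:
        raise ValueError("hyperparameter grid is empty")
    table = pd.DataFrame([vars(r) for r in rows])
    best = max(rows, key=lambda r: (r.cophenetic_rho, r.distinctiveness))
    return best, table


def refit_validation(
    train_matrix,
    test_matrix,
    config: NMFConfig,
    n_runs: int = 30,
) -> dict:
    """Refit the chosen configuration on the held-out matrix and compare.

    Reports the train-vs-test cophenetic correlation difference and a
    Spearman rank correlation of shared subgraphs' H weights (components
    aligned greedily by cosine similarity over the shared vocabulary).
    """
    rho_train = consensus_cophenetic(train_matrix.counts, config.k, n_runs,
                                     config.seed).cophenetic_rho
    rho_test = consensus_cophenetic(test_matrix.counts, config.k, n_runs,
                                    config.seed).cophenetic_rho
    fit_train = fit_nmf(train_matrix.counts, config)
    fit_test = fit_nmf(test_matrix.counts, config)

    train_cols = train_matrix.column_index()
    test_cols = test_matrix.column_index()
    shared = sorted(set(train_cols) & set(test_cols))
    if not shared:
        logger.warning("no shared subgraphs between the splits; "
                       "weight correlation undefined")
        rank_corr = None
    else:
        A = fit_train.H[:, [train_cols[s] for s in shared]]
        B = fit_test.H[:, [test_cols[s] for s in shared]]
        perm = _align_components(A, B)
        a = np.concatenate([A[i] for i in range(config.k)])
        b = np.concatenate([B[perm[i]] for i in range(config.k)])
        rank_corr = float(spearmanr(a, b).statistic)
    return {
        "rho_train": rho_train,
        "rho_test": rho_test,
        "rho_difference": abs(rho_train - rho_test),
        "shared_subgraphs": len(shared),
        "weight_rank_correlation": rank_corr,
    }


def _align_components(A: np.ndarray, B: np.ndarray) -> list[int]:
    """Best permutation of B's rows against A's by total cosine similarity."""
    k = A.shape[0]
    def cos(u, v):
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        return float(u @ v / (nu * nv)) if nu > 0 and nv > 0 else 0.0
    sim = np.array([[cos(A[i], B[j]) for j in range(k)] for i in range(k)])
    best, best_score = list(range(k)), -np.inf
    for perm in permutations(range(k)):
        score = sum(sim[i, perm[i]] for i in range(k))
        if score > best_score:
            best, best_score = list(perm), score
    return best
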