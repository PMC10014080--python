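"""Mutational-signature extraction by non-negative matrix factorization.

The input is a 96-row matrix of pyrimidine-centered trinucleotide mutation
types by (age bin x population) columns, each column normalized by the
number of SNPs in its bin so that columns sum to one. Factorizing
V ≈ W H with W (96 x K) signatures and H (K x columns) exposures uses the
classic multiplicative updates that minimize the generalized
Kullback-Leibler divergence

    D(V || WH) = sum_ij [ V_ij log(V_ij / (WH)_ij) − V_ij + (WH)_ij ]

Rank selection follows standard consensus practice: across random restarts,
each column is assigned to its dominant signature; the mean connectivity
matrix over restarts yields a cophenetic correlation coefficient (stability
of the clustering), and the chosen rank is the smallest one maximizing that
coefficient among ranks explaining at least a target fraction of variance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, check_random_state

from .classes import context96_labels

_EPS = np.finfo(float).tiny


def build_context_matrix(
    tables: dict[str, pd.DataFrame], populations: list[str] | None = None
) -> pd.DataFrame:
    """Assemble and column-normalize the 96 x (bins x populations) matrix.

    ``tables`` maps population label to a pseudo-count table whose rows are
    the 96 trinucleotide contexts (``A[C>T]G`` style) and whose columns are
    age bins. Each output column is divided by its bin's SNP total, so
    columns sum to one. Bins with zero SNPs raise.
    """
    populations = populations or list(tables)
    labels = context96_labels()
    blocks, names = [], []
    for pop in populations:
        t = tables[pop].reindex(labels).fillna(0.0)
        totals = t.sum(axis=0).to_numpy()
        if np.any(totals <= 0):
            raise ValueError(f"population {pop}: age bin with zero SNPs")
        blocks.append(t.to_numpy() / totals)
        names.extend(f"{pop}:bin{b}" for b in range(t.shape[1]))
    values = np.hstack(blocks)
    return pd.DataFrame(values, index=pd.Index(labels, name="context"),
                        columns=names)


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH)."""
    WH = W @ H
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS)))
    return float(div - V.sum() + WH.sum())


def _mu_step(V, W, H):
    """One round of KL multiplicative updates (brunet)."""
    WH = np.maximum(W @ H, _EPS)
    H = H * (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
    WH = np.maximum(W @ H, _EPS)
    W = W * ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
    return W, H


def _factorize_once(V, rank, rng, max_iter, tol):
    n, m = V.shape
    scale = np.sqrt(V.mean() / rank)
    W = rng.uniform(0.0, 2 * scale, size=(n, rank))
    H = rng.uniform(0.0, 2 * scale, size=(rank, m))
    history = [kl_divergence(V, W, H)]
    converged = False
    for _ in range(max_iter):
        W, H = _mu_step(V, W, H)
        history.append(kl_divergence(V, W, H))
        if abs(history[-2] - history[-1]) <= tol * max(abs(history[-2]), 1e-12):
            converged = True
            break
    return W, H, np.asarray(history), converged


def _normalize_factors(W, H):
    """Scale signatures to unit column sum, compensating in the exposures."""
    norms = np.maximum(W.sum(axis=0), _EPS)
    return W / norms, H * norms[:, None]


def variance_explained(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """1 − ||V − WH||_F^2 / ||V||_F^2."""
    resid = V - W @ H
    return float(1.0 - (resid**2).sum() / (V**2).sum())


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of average-linkage clustering of the consensus
    connectivity matrix (1 = perfectly stable column assignments)."""
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    if np.allclose(condensed, condensed[0]):
        return 1.0
    Z = hierarchy.linkage(condensed, method="average")
    coph, _ = hierarchy.cophenet(Z, condensed)
    return float(coph)


class KLNMF(BaseEstimator):
    """KL-divergence NMF with multiplicative updates and consensus restarts.

    Parameters
    ----------
    n_components : int, default=3
        Factorization rank K.
    n_runs : int, default=50
        Random restarts; the best-KL run is kept and all runs feed the
        consensus connectivity matrix.
    max_iter : int, default=2000
        Update iterations per run.
    tol : float, default=1e-9
        Relative KL improvement below which a run stops.
    random_state : int, RandomState or None

    Attributes
    ----------
    signatures_ : ndarray (n_features, K)
        Column-stochastic signature matrix of the best run.
    exposures_ : ndarray (K, n_columns)
    kl_divergence_ : float
    objective_history_ : ndarray
        KL value per iteration of the best run (non-increasing).
    variance_explained_ : float
    cophenetic_ : float
    consensus_ : ndarray (n_columns, n_columns)
    converged_ : bool
    """

    def __init__(self, n_components: int = 3, n_runs: int = 50,
                 max_iter: int = 2000, tol: float = 1e-9, random_state=None):
        self.n_components = n_components
        self.n_runs = n_runs
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.n_components < 1 or self.n_runs < 1:
            raise ValueError("n_components and n_runs must be >= 1")
        V = np.asarray(X, dtype=float)
        if np.any(V < 0):
            raise ValueError("matrix must be non-negative")
        rng = check_random_state(self.random_state)
        n_cols = V.shape[1]
        consensus = np.zeros((n_cols, n_cols))
        best = None
        any_converged = False
        for _ in range(self.n_runs):
            W, H, history, converged = _factorize_once(
                V, self.n_components, rng, self.max_iter, self.tol
            )
            any_converged = any_converged or converged
            assign = H.argmax(axis=0)
            consensus += assign[:, None] == assign[None, :]
            if best is None or history[-1] < best[2][-1]:
                best = (W, H, history)
        W, H, history = best
        W, H = _normalize_factors(W, H)
        self.signatures_, self.exposures_ = W, H
        self.kl_divergence_ = float(history[-1])
        self.objective_history_ = history
        self.variance_explained_ = variance_explained(V, W, H)
        self.consensus_ = consensus / self.n_runs
        self.cophenetic_ = (
            cophenetic_coefficient(self.consensus_) if n_cols > 2 else 1.0
        )
        self.converged_ = any_converged
        return self

    def transform(self, X=None):
        check_is_fitted(self, "exposures_")
        return self.exposures_


def nmf_factorize(matrix, rank: int, n_runs: int = 50, seed=None, **kwargs) -> KLNMF:
    """Functional wrapper around :class:`KLNMF`."""
    values = matrix.to_numpy() if isinstance(matrix, pd.DataFrame) else matrix
    return KLNMF(n_components=rank, n_runs=n_runs, random_state=seed,
                 **kwargs).fit(values)


def select_rank(
    matrix,
    ranks=range(2, 16),
    n_runs: int = 50,
    seed=None,
    variance_threshold: float = 0.99,
    **kwargs,
) -> tuple[int, pd.DataFrame]:
    """Smallest rank maximizing the cophenetic coefficient among ranks whose
    variance explained meets the threshold.

    Returns (selected rank, diagnostics table with one row per rank). Falls
    back to all ranks if none meets the variance threshold.
    """
    ranks = list(ranks)
    if not ranks:
        raise ValueError("ranks must be non-empty")
    rows = []
    for k in ranks:
        model = nmf_factorize(matrix, k, n_runs=n_runs, seed=seed, **kwargs)
        rows.append(
            {
                "rank": k,
                "cophenetic": model.cophenetic_,
                "variance_explained": model.variance_explained_,
                "kl_divergence": model.kl_divergence_,
            }
        )
    diag = pd.DataFrame(rows)
    eligible = diag[diag["variance_explained"] >= variance_threshold]
    if eligible.empty:
        eligible = diag
    best_coph = eligible["cophenetic"].max()
    selected = int(eligible.loc[
        np.isclose(eligible["cophenetic"], best_coph, atol=1e-12), "rank"
    ].min())
    return selected, diag


def cosine_similarity_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities between columns of A and columns of B."""
    A = A / np.maximum(np.linalg.norm(A, axis=0), _EPS)
    B = B / np.maximum(np.linalg.norm(B, axis=0), _EPS)
    return A.T @ B
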