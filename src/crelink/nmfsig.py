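"""Non-negative matrix factorization of link and omics matrices.

A matrix V (features x cells) is decomposed as V ~ W H with W >= 0
(features x K signatures) and H >= 0 (K x cells exposures) by
multiplicative updates minimizing the Frobenius loss.  Factorization is
repeated from several random initialisations; restart stability is
summarized by the mean Amari distance between restart W matrices, and
cell-clustering stability by the cophenetic correlation of the consensus
connectivity matrix (cells co-clustered when their H-column argmax
agrees).  The factorization rank K is chosen over a range (default 2..6)
to jointly minimize the Frobenius error (via its relative drop — an
elbow criterion, since the raw error always decreases with K) and the
mean Amari distance while maximizing the cophenetic coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import nnls
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE = (2, 6)
DEFAULT_N_RESTARTS = 20
DEFAULT_MAX_ITER = 1000
DEFAULT_TOL = 1e-6
_EPS = 1e-12


@dataclass
class NMFResult:
    """Best factorization at one rank plus restart/consensus diagnostics."""

    W: np.ndarray  # features x K
    H: np.ndarray  # K x cells
    rank: int
    restart_errors: np.ndarray  # relative Frobenius error per restart
    restart_Ws: list[np.ndarray] = field(repr=False, default_factory=list)
    consensus: np.ndarray | None = None  # cells x cells
    kept_rows: np.ndarray | None = None
    kept_cols: np.ndarray | None = None

    @property
    def frobenius_error(self) -> float:
        return float(self.restart_errors.min())

    @property
    def mean_amari(self) -> float:
        ws = self.restart_Ws
        if len(ws) < 2:
            return 0.0
        dists = [
            amari_distance(ws[i], ws[j])
            for i in range(len(ws))
            for j in range(i + 1, len(ws))
        ]
        return float(np.mean(dists))

    @property
    def cophenetic(self) -> float:
        if self.consensus is None:
            raise ValueError("no consensus matrix stored")
        return cophenetic_coefficient(self.consensus)

    def cell_clusters(self) -> np.ndarray:
        """Hard cell assignment: argmax over exposures."""
        return self.H.argmax(axis=0)


def _mu_factorize(
    V: np.ndarray, K: int, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    """One multiplicative-update run from a random initialisation.

    The Frobenius loss under these updates is non-increasing; this is
    asserted every 50 iterations.
    """
    n, m = V.shape
    scale = np.sqrt(V.mean() / K) if V.mean() > 0 else 1.0
    W = rng.uniform(0, 1, size=(n, K)) * scale + _EPS
    H = rng.uniform(0, 1, size=(K, m)) * scale + _EPS
    norm_v = np.linalg.norm(V)
    prev_checked = np.inf
    last_err = np.inf
    for it in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ H @ H.T + _EPS)
        if (it + 1) % 50 == 0 or it == max_iter - 1:
            err = np.linalg.norm(V - W @ H) / (norm_v + _EPS)
            if err > prev_checked + 1e-9:
                logger.warning("NMF loss increased at iteration %d", it + 1)
            if prev_checked - err < tol:
                last_err = err
                break
            prev_checked = err
            last_err = err
    return W, H, float(last_err)


def nmf_factorize(
    V: np.ndarray | pd.DataFrame,
    K: int,
    n_restarts: int = DEFAULT_N_RESTARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
) -> NMFResult:
    """Factorize V at rank K over several restarts; keep the best.

    All-zero rows/columns are dropped with a warning before factorization
    (their indices are recorded on the result).  Restart r uses the seeded
    generator ``seed + r``; a fixed seed makes the result reproducible.
    """
    Vd = V.to_numpy(dtype=float) if isinstance(V, pd.DataFrame) else np.asarray(V, dtype=float)
    if (Vd < 0).any():
        raise ValueError("NMF input must be non-negative")
    kept_rows = Vd.sum(axis=1) > 0
    kept_cols = Vd.sum(axis=0) > 0
    if not kept_rows.all() or not kept_cols.all():
        logger.warning(
            "nmf_factorize: dropping %d all-zero rows and %d all-zero columns",
            int((~kept_rows).sum()), int((~kept_cols).sum()),
        )
        Vd = Vd[kept_rows][:, kept_cols]
    if K >= min(Vd.shape) and K > 1:
        raise ValueError(f"rank {K} must be below min(matrix dims) {min(Vd.shape)}")

    best: tuple[np.ndarray, np.ndarray] | None = None
    errors = np.empty(n_restarts)
    restart_Ws: list[np.ndarray] = []
    connectivity_sum = np.zeros((Vd.shape[1], Vd.shape[1]))
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        W, H, err = _mu_factorize(Vd, K, max_iter, tol, rng)
        errors[r] = err
        restart_Ws.append(W)
        labels = H.argmax(axis=0)
        connectivity_sum += labels[:, None] == labels[None, :]
        if best is None or err < errors[: r].min(initial=np.inf):
            best = (W, H)
    assert best is not None
    consensus = connectivity_sum / n_restarts
    return NMFResult(
        W=best[0],
        H=best[1],
        rank=K,
        restart_errors=errors,
        restart_Ws=restart_Ws,
        consensus=consensus,
        kept_rows=kept_rows,
        kept_cols=kept_cols,
    )


def _amari_index(C: np.ndarray) -> float:
    C = np.abs(C)
    K = C.shape[0]
    row_term = (C.sum(axis=1) / C.max(axis=1) - 1).sum()
    col_term = (C.sum(axis=0) / C.max(axis=0) - 1).sum()
    return float((row_term + col_term) / (2 * K))


def amari_distance(W1: np.ndarray, W2: np.ndarray) -> float:
    """Amari index between two factor matrices with matching shapes.

    The cross-product ``pinv(W1) @ W2`` reduces to a scaled permutation
    matrix exactly when the column sets agree up to permutation and
    positive scaling, making the index zero in that case regardless of how
    correlated the individual columns are; the index is averaged over both
    directions so the distance is symmetric.
    """
    W1 = np.asarray(W1, dtype=float)
    W2 = np.asarray(W2, dtype=float)
    if W1.shape != W2.shape:
        raise ValueError("factor matrices must share a shape")
    if (np.linalg.norm(W1, axis=0) == 0).any() or (np.linalg.norm(W2, axis=0) == 0).any():
        raise ValueError("zero column in factor matrix")
    forward = _amari_index(np.linalg.pinv(W1) @ W2)
    backward = _amari_index(np.linalg.pinv(W2) @ W1)
    return 0.5 * (forward + backward)


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the consensus matrix.

    Average-linkage hierarchical clustering is run on 1 - consensus as a
    distance; the returned value is the Pearson correlation between the
    cophenetic distances of the dendrogram and the original distances.
    An all-identical consensus has no dispersion to correlate and returns
    1 by convention.
    """
    C = np.asarray(consensus, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("consensus must be square")
    if not np.allclose(C, C.T, atol=1e-9):
        raise ValueError("consensus must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-9):
        raise ValueError("consensus must have unit diagonal")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    if np.ptp(condensed) == 0:
        logger.warning("cophenetic_coefficient: degenerate consensus, returning 1 by convention")
        return 1.0
    Z = hierarchy.linkage(condensed, method="average")
    coeff, _ = hierarchy.cophenet(Z, condensed)
    return float(coeff)


def select_rank(
    V: np.ndarray | pd.DataFrame,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    n_restarts: int = DEFAULT_N_RESTARTS,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
) -> tuple[int, pd.DataFrame, dict[int, NMFResult]]:
    """Choose the factorization rank over ``k_range`` (inclusive).

    Each K is scored by three criteria: the relative Frobenius-error drop
    from the previous rank (larger is better — the elbow reading of
    "minimize the Frobenius error", since the raw error is monotone in K),
    the mean Amari distance over restarts (smaller is better) and the
    cophenetic coefficient of the consensus matrix (larger is better).
    Criteria are converted to ranks after rounding to three decimals, so
    differences below numerical noise count as ties rather than votes; the
    K with the best mean rank wins, ties resolved toward the smaller K.
    Returns the chosen K, the metrics table and the per-K factorizations.
    """
    k_min, k_max = k_range
    Vd = V.to_numpy(dtype=float) if isinstance(V, pd.DataFrame) else np.asarray(V, dtype=float)
    k_max = min(k_max, min(Vd.shape) - 1)
    if k_max < k_min:
        raise ValueError("rank range collapsed below its minimum")
    ks = list(range(k_min, k_max + 1))
    results: dict[int, NMFResult] = {}
    # baseline error at K-1 of the smallest rank, for the first drop
    prev_err = (
        nmf_factorize(Vd, k_min - 1, n_restarts, max_iter, tol, seed).frobenius_error
        if k_min >= 2
        else np.linalg.norm(Vd - Vd.mean()) / np.linalg.norm(Vd)
    )
    rows = []
    for K in ks:
        res = nmf_factorize(Vd, K, n_restarts, max_iter, tol, seed)
        results[K] = res
        drop = (prev_err - res.frobenius_error) / max(prev_err, _EPS)
        rows.append(
            {
                "K": K,
                "frobenius_error": res.frobenius_error,
                "frobenius_drop": drop,
                "mean_amari": res.mean_amari,
                "cophenetic": res.cophenetic,
            }
        )
        prev_err = res.frobenius_error
    table = pd.DataFrame(rows).set_index("K")
    rounded = table.round(3)
    score = (
        rounded["frobenius_drop"].rank(ascending=False)
        + rounded["mean_amari"].rank(ascending=True)
        + rounded["cophenetic"].rank(ascending=False)
    )
    best_k = int(score.idxmin())  # idxmin takes the first (smallest K) on ties
    return best_k, table, results


def extract_signature_features(
    W: np.ndarray, exclusivity: float = 0.75
) -> dict[int, list[int]]:
    """Features contributing (near-)exclusively to one signature.

    W rows are normalized to sum 1; feature f is assigned to signature s
    when its normalized weight on s is at least ``exclusivity``.  Features
    meeting the bar for no signature (including all-zero rows) stay
    unassigned.
    """
    W = np.asarray(W, dtype=float)
    sums = W.sum(axis=1, keepdims=True)
    out: dict[int, list[int]] = {s: [] for s in range(W.shape[1])}
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = np.where(sums > 0, W / sums, 0.0)
    for f in range(W.shape[0]):
        s = int(normed[f].argmax())
        if normed[f, s] >= exclusivity:
            out[s].append(f)
    return out


def rank_similarity(W_k: np.ndarray, W_k1: np.ndarray) -> np.ndarray:
    """Cross-rank signature similarity by normalized non-negative least squares.

    Every column of the higher-rank W is regressed onto the columns of the
    lower-rank W with NNLS; coefficient columns are normalized to sum 1.
    Returns a K x K' matrix (rows: signatures of ``W_k``).
    """
    W_k = np.asarray(W_k, dtype=float)
    W_k1 = np.asarray(W_k1, dtype=float)
    if W_k.shape[0] != W_k1.shape[0]:
        raise ValueError("factor matrices must share their feature rows")
    K, K1 = W_k.shape[1], W_k1.shape[1]
    coeffs = np.zeros((K, K1))
    for j in range(K1):
        coeffs[:, j], _ = nnls(W_k, W_k1[:, j])
    sums = coeffs.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sums > 0, coeffs / sums, 0.0)
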