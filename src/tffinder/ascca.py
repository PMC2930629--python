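"""Adaptive sparse canonical correlation analysis (first component).

The first sparse canonical pair (u, v) of a cross-correlation matrix K is
approximated by alternating power steps with adaptive soft-thresholding:
each coefficient's L1 threshold is scaled by the inverse of the matching
entry of the first SVD pair of K raised to gamma, so coefficients the SVD
deems weak are shrunk harder.  Penalties (lambda_u, lambda_v, gamma) are
selected on a grid by k-fold cross-validation of the held-out canonical
correlation.

Because columns are standardized, diag(Sigma_XX) = diag(Sigma_YY) = I and
the canonical vectors coincide with (u, v); all variates are formed as
X @ u and Y @ v directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix import (
    CrossCorrelationMatrix,
    ExpressionMatrix,
    cross_correlation,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AdaptiveWeights",
    "PenaltyParams",
    "SparseCanonicalPair",
    "CVResult",
    "svd_reference_vectors",
    "initial_vectors",
    "adaptive_soft_threshold",
    "ascca_iterate",
    "penalty_grid",
    "cv_select",
]

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500


@dataclass(frozen=True)
class AdaptiveWeights:
    """First singular-vector pair of K, used as adaptive penalty references."""

    u_svd: np.ndarray
    v_svd: np.ndarray

    def __post_init__(self) -> None:
        for name in ("u_svd", "v_svd"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(vec) - 1.0) > 1e-10:
                raise ValueError(f"{name} must have unit norm")
            object.__setattr__(self, name, vec)


@dataclass(frozen=True, order=True)
class PenaltyParams:
    """One (lambda_u, lambda_v, gamma) penalty triple."""

    lambda_u: float
    lambda_v: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.lambda_u, self.lambda_v, self.gamma) < 0:
            raise ValueError("penalty parameters must be nonnegative")


@dataclass(frozen=True)
class SparseCanonicalPair:
    """Converged sparse canonical vectors with their nonzero supports."""

    u: np.ndarray
    v: np.ndarray
    support_u: tuple[int, ...]
    support_v: tuple[int, ...]
    n_iterations: int
    converged: bool

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "support_u", tuple(np.flatnonzero(u)))
        object.__setattr__(self, "support_v", tuple(np.flatnonzero(v)))


@dataclass(frozen=True)
class CVResult:
    """Cross-validation outcome for one penalty triple."""

    params: PenaltyParams
    delta_cor: float
    fold_correlations: tuple[float, ...]

    def __post_init__(self) -> None:
        folds = tuple(float(c) for c in self.fold_correlations)
        object.__setattr__(self, "fold_correlations", folds)
        expect = float(np.mean(np.abs(folds))) if folds else 0.0
        if abs(self.delta_cor - expect) > 1e-12:
            raise ValueError("delta_cor must equal mean |fold correlation|")


def svd_reference_vectors(K: CrossCorrelationMatrix | np.ndarray) -> AdaptiveWeights:
    """First left/right singular vectors of K, sign-fixed.

    The sign is chosen so the largest-magnitude entry of the left vector is
    positive; the right vector is flipped together with it so the pair still
    corresponds to a positive singular value.
    """
    values = K.values if isinstance(K, CrossCorrelationMatrix) else np.asarray(K, float)
    if not np.any(values):
        raise ValueError("cannot take SVD reference vectors of an all-zero matrix")
    U, _, Vt = np.linalg.svd(values, full_matrices=False)
    u = U[:, 0]
    v = Vt[0]
    if u[np.argmax(np.abs(u))] < 0:
        u = -u
        v = -v
    return AdaptiveWeights(u_svd=u, v_svd=v)


def initial_vectors(
    K: CrossCorrelationMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalized row means (u0) and column means (v0) of K.

    Falls back to the SVD reference pair, with a warning, if either mean
    vector is identically zero.
    """
    values = K.values if isinstance(K, CrossCorrelationMatrix) else np.asarray(K, float)
    if not np.any(values):
        raise ValueError("cannot build initial vectors from an all-zero matrix")
    u0 = values.mean(axis=1)
    v0 = values.mean(axis=0)
    nu, nv = np.linalg.norm(u0), np.linalg.norm(v0)
    if nu == 0.0 or nv == 0.0:
        logger.warning(
            "row/column means of K are zero; falling back to SVD initialization"
        )
        weights = svd_reference_vectors(values)
        return weights.u_svd.copy(), weights.v_svd.copy()
    return u0 / nu, v0 / nv


def adaptive_soft_threshold(
    w: np.ndarray, ref: np.ndarray, lam: float, gamma: float
) -> np.ndarray:
    """Soft-threshold ``w`` at ``lam/2`` scaled by ``|ref|**-gamma`` per entry.

    ``out_j = max(|w_j| - lam / (2 |ref_j|**gamma), 0) * sign(w_j)``.

    With ``gamma = 0`` this is uniform soft-thresholding at ``lam/2``; a zero
    reference entry with ``gamma > 0`` yields an infinite threshold, so that
    coefficient is forced to zero (adaptive-lasso convention: variables the
    reference deems null are never resurrected).  ``lam = 0`` is the identity.
    """
    w = np.asarray(w, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if w.shape != ref.shape:
        raise ValueError("w and ref must have equal length")
    if lam == 0.0:
        return w.copy()
    with np.errstate(divide="ignore", over="ignore"):
        thresh = 0.5 * lam / np.abs(ref) ** gamma
    shrunk = np.abs(w) - thresh
    return np.where(shrunk > 0, shrunk, 0.0) * np.sign(w)


def _unit(x: np.ndarray) -> tuple[np.ndarray, bool]:
    norm = np.linalg.norm(x)
    if norm == 0.0:
        return x, False
    return x / norm, True


def ascca_iterate(
    K: CrossCorrelationMatrix | np.ndarray,
    params: PenaltyParams,
    weights: AdaptiveWeights,
    u0: np.ndarray,
    v0: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SparseCanonicalPair:
    """Alternate thresholded power steps on K until (u, v) stabilize.

    Each half-step is: multiply by K (or K'), normalize, adaptively
    soft-threshold, normalize again.  Iteration stops when the max-norm
    change of both vectors drops below ``tol``.  If either vector collapses
    to zero under heavy penalties, an empty non-converged pair is returned
    (the caller treats it as "nothing hooked").
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    Kv = K.values if isinstance(K, CrossCorrelationMatrix) else np.asarray(K, float)
    if not np.isfinite(Kv).all():
        raise ValueError("K contains non-finite values")
    p, q = Kv.shape

    u = np.asarray(u0, dtype=float).copy()
    v = np.asarray(v0, dtype=float).copy()
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        u_prev, v_prev = u, v

        u = Kv @ v
        u, ok = _unit(u)
        if not ok:
            return _degenerate_pair(p, q, iteration)
        u = adaptive_soft_threshold(u, weights.u_svd, params.lambda_u, params.gamma)
        u, ok = _unit(u)
        if not ok:
            return _degenerate_pair(p, q, iteration)

        v = Kv.T @ u
        v, ok = _unit(v)
        if not ok:
            return _degenerate_pair(p, q, iteration)
        v = adaptive_soft_threshold(v, weights.v_svd, params.lambda_v, params.gamma)
        v, ok = _unit(v)
        if not ok:
            return _degenerate_pair(p, q, iteration)

        delta = max(
            np.max(np.abs(u - u_prev), initial=0.0),
            np.max(np.abs(v - v_prev), initial=0.0),
        )
        if delta < tol:
            converged = True
            break

    return SparseCanonicalPair(
        u=u,
        v=v,
        support_u=(),
        support_v=(),
        n_iterations=iteration,
        converged=converged,
    )


def _degenerate_pair(p: int, q: int, iteration: int) -> SparseCanonicalPair:
    return SparseCanonicalPair(
        u=np.zeros(p),
        v=np.zeros(q),
        support_u=(),
        support_v=(),
        n_iterations=iteration,
        converged=False,
    )


def penalty_grid(
    lu_max: float = 0.4,
    lu_step: float = 0.01,
    lv_max: float = 0.4,
    lv_step: float = 0.01,
    g_max: float = 2.0,
    g_step: float = 0.1,
) -> list[PenaltyParams]:
    """Cartesian grid over lambda_u, lambda_v and gamma, endpoints included.

    Values are generated as ``i * step`` from integer indices so the grid is
    free of float-accumulation drift.  The defaults enumerate 41 * 41 * 21 =
    35301 triples.
    """
    for name, step in (("lu_step", lu_step), ("lv_step", lv_step), ("g_step", g_step)):
        if step <= 0:
            raise ValueError(f"{name} must be positive")

    def axis(vmax: float, step: float) -> list[float]:
        count = int(round(vmax / step)) + 1
        return [i * step for i in range(count)]

    return [
        PenaltyParams(lu, lv, g)
        for lu in axis(lu_max, lu_step)
        for lv in axis(lv_max, lv_step)
        for g in axis(g_max, g_step)
    ]


def _standardize_fold(
    train: np.ndarray, test: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize columns on training statistics, apply to the test block.

    Training columns that happen to be constant within a fold are centered
    and left at zero scale 1 (they then contribute nothing to K).
    """
    mean = train.mean(axis=0)
    std = train.std(axis=0, ddof=1)
    std = np.where(std == 0.0, 1.0, std)
    return (train - mean) / std, (test - mean) / std


def _grid_iterate(
    K: np.ndarray,
    weights: AdaptiveWeights,
    u0: np.ndarray,
    v0: np.ndarray,
    grid: list[PenaltyParams],
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the thresholded power iteration for every grid triple at once.

    Column g of the returned (p, G) and (q, G) arrays holds the fitted
    (u, v) for ``grid[g]``; columns that collapsed to zero stay zero.
    Mathematically identical to ``ascca_iterate`` per column — the update
    for one triple never mixes with another — but executed as batched
    matrix products for speed during cross-validation.
    """
    p, q = K.shape
    G = len(grid)
    lam_u = np.array([t.lambda_u for t in grid])
    lam_v = np.array([t.lambda_v for t in grid])
    gamma = np.array([t.gamma for t in grid])
    with np.errstate(divide="ignore"):
        # (p, G) / (q, G) per-coefficient thresholds; inf where ref is 0
        thr_u = 0.5 * lam_u[None, :] / np.abs(weights.u_svd)[:, None] ** gamma[None, :]
        thr_v = 0.5 * lam_v[None, :] / np.abs(weights.v_svd)[:, None] ** gamma[None, :]
    thr_u[:, lam_u == 0.0] = 0.0
    thr_v[:, lam_v == 0.0] = 0.0

    U = np.tile(u0[:, None], (1, G))
    V = np.tile(v0[:, None], (1, G))
    active = np.arange(G)  # columns still iterating; others are frozen

    def _norm_cols(M: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(M, axis=0)
        dead = norms == 0.0
        norms[dead] = 1.0
        M /= norms
        return dead

    for _ in range(max_iter):
        if active.size == 0:
            break
        Ua_prev = U[:, active]
        Va_prev = V[:, active]

        Ua = K @ Va_prev
        dead = _norm_cols(Ua)
        shrunk = np.abs(Ua) - thr_u[:, active]
        Ua = np.where(shrunk > 0, shrunk, 0.0) * np.sign(Ua)
        dead |= _norm_cols(Ua)

        Va = K.T @ Ua
        dead |= _norm_cols(Va)
        shrunk = np.abs(Va) - thr_v[:, active]
        Va = np.where(shrunk > 0, shrunk, 0.0) * np.sign(Va)
        dead |= _norm_cols(Va)

        Ua[:, dead] = 0.0
        Va[:, dead] = 0.0
        U[:, active] = Ua
        V[:, active] = Va
        delta = np.maximum(
            np.max(np.abs(Ua - Ua_prev), axis=0),
            np.max(np.abs(Va - Va_prev), axis=0),
        )
        active = active[~(dead | (delta < tol))]

    return U, V


def cv_select(
    X: ExpressionMatrix,
    Y: ExpressionMatrix,
    grid: list[PenaltyParams],
    k: int = 5,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[PenaltyParams, list[CVResult]]:
    """Pick the penalty triple maximizing mean held-out |canonical correlation|.

    Samples are shuffled with ``seed`` and split into ``k`` folds.  For each
    fold, columns are re-standardized on the training samples, K is rebuilt
    from training data, and every grid triple is fitted; the held-out
    variates ``X_test @ u`` and ``Y_test @ v`` score the triple by absolute
    Pearson correlation (0 if either variate is constant or the fit
    collapsed).  Ties are broken toward the smallest (lambda_u, lambda_v,
    gamma).
    """
    if not grid:
        raise ValueError("penalty grid must not be empty")
    if k < 2:
        raise ValueError("k must be >= 2")
    n = X.n_samples
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of samples n = {n}")
    if X.sample_ids != Y.sample_ids:
        raise ValueError("X and Y must share sample ids in the same order")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    cors = np.zeros((len(grid), k))
    for j, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx, assume_unique=True)
        Xtr, Xte = _standardize_fold(X.values[train_idx], X.values[test_idx])
        Ytr, Yte = _standardize_fold(Y.values[train_idx], Y.values[test_idx])
        K = (Xtr.T @ Ytr) / (len(train_idx) - 1)
        if not np.any(K):
            continue  # fold carries no signal at all; contributes 0
        weights = svd_reference_vectors(K)
        u0, v0 = initial_vectors(K)
        U, V = _grid_iterate(K, weights, u0, v0, grid, tol, max_iter)

        xv = Xte @ U  # (n_test, G) held-out canonical variates
        yv = Yte @ V
        xv = xv - xv.mean(axis=0)
        yv = yv - yv.mean(axis=0)
        sx = np.linalg.norm(xv, axis=0)
        sy = np.linalg.norm(yv, axis=0)
        ok = (sx > 0) & (sy > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.einsum("ij,ij->j", xv, yv) / (sx * sy)
        cors[ok, j] = r[ok]

    delta = np.mean(np.abs(cors), axis=1)
    results = [
        CVResult(params=t, delta_cor=float(d), fold_correlations=tuple(row))
        for t, d, row in zip(grid, delta, cors)
    ]
    best_score = delta.max()
    candidates = [t for t, d in zip(grid, delta) if d == best_score]
    best = min(candidates, key=lambda t: (t.lambda_u, t.lambda_v, t.gamma))
    return best, results


def fit_first_pair(
    X: ExpressionMatrix,
    Y: ExpressionMatrix,
    params: PenaltyParams,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SparseCanonicalPair:
    """Convenience: build K from standardized blocks and run one fit."""
    K = cross_correlation(X, Y)
    weights = svd_reference_vectors(K)
    u0, v0 = initial_vectors(K)
    return ascca_iterate(K, params, weights, u0, v0, tol=tol, max_iter=max_iter)
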