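"""Cross-area interaction via residual ridge prediction and CCA.

Single-trial spike counts (50-ms bins over the 250-ms presentation or
omission window) are residualized by subtracting the condition PSTH and
z-scoring per unit; the residual activity of a source area predicts the
partner area through ridge regression with the closed-form solution

    B = (X'X + lambda I)^{-1} X'Y

with lambda chosen by cross-validation.  Interaction strength per area
pair is the difference in held-out predictive R^2 between stimulus and
omission trials (positive: better prediction during the stimulus).
Canonical correlation analysis on the same matched-trial matrices gives
a complementary, coefficient-level view of shared variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

__all__ = [
    "residualize",
    "ridge_solve",
    "RidgeInteraction",
    "ridge_interaction",
    "interaction_difference",
    "CcaResult",
    "cca",
]

DEFAULT_LAMBDA_GRID = np.logspace(-2, 3, 10)


def residualize(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """PSTH-subtracted, unit-wise z-scored residuals.

    ``counts`` has shape (trials, bins, units).  The per-(bin, unit)
    mean across trials (the PSTH) is subtracted, then each unit is
    z-scored by its residual SD pooled over trials and bins.  Returns
    (residuals flattened to trials x (bins*units), kept-unit mask);
    zero-variance units are dropped with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 3:
        raise ValueError("counts must be trials x bins x units")
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    resid = counts - counts.mean(axis=0, keepdims=True)
    sd = resid.std(axis=(0, 1))
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} zero-variance unit(s)")
    resid = resid[:, :, keep] / sd[keep]
    T = resid.shape[0]
    return resid.reshape(T, -1), keep


def ridge_solve(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge coefficients (X'X + lambda I)^{-1} X'Y."""
    p = X.shape[1]
    return linalg.solve(X.T @ X + lam * np.eye(p), X.T @ Y, assume_a="pos")


def _pooled_r2(Y_true: np.ndarray, Y_pred: np.ndarray, Y_train_mean: np.ndarray) -> tuple[float, float]:
    sse = float(np.sum((Y_true - Y_pred) ** 2))
    sst = float(np.sum((Y_true - Y_train_mean) ** 2))
    return sse, sst


def _contiguous_split(T: int, folds: int):
    return np.array_split(np.arange(T), folds)


def _cv_ridge_r2(X, Y, lambda_grid, folds, rng) -> tuple[float, float]:
    """Held-out pooled R^2 with per-fold inner lambda selection.

    Returns (r2, chosen lambda median).
    """
    T = X.shape[0]
    if T < folds:
        warnings.warn("fewer trials than folds; reducing folds")
        folds = T
    order = rng.permutation(T)
    sse_tot = sst_tot = 0.0
    lams = []
    for test_idx in _contiguous_split(T, folds):
        te = order[test_idx]
        tr = np.setdiff1d(order, te)
        # inner selection on training trials
        inner_folds = min(10, max(2, len(tr) // 3))
        inner_splits = _contiguous_split(len(tr), inner_folds)
        best_lam, best_err = None, np.inf
        for lam in lambda_grid:
            err = 0.0
            for isp in inner_splits:
                ite = tr[isp]
                itr = np.setdiff1d(tr, ite)
                B = ridge_solve(X[itr], Y[itr], lam)
                err += float(np.sum((Y[ite] - X[ite] @ B) ** 2))
            if err < best_err:
                best_err, best_lam = err, lam
        B = ridge_solve(X[tr], Y[tr], best_lam)
        sse, sst = _pooled_r2(Y[te], X[te] @ B, Y[tr].mean(axis=0))
        sse_tot += sse
        sst_tot += sst
        lams.append(best_lam)
    r2 = 1.0 - sse_tot / sst_tot if sst_tot > 0 else float("nan")
    return r2, float(np.median(lams))


@dataclass
class RidgeInteraction:
    r2_stimulus: float
    r2_omission: float
    difference: float          # positive: better prediction during stimulus
    lambda_stimulus: float
    lambda_omission: float
    n_trials: int


def ridge_interaction(
    X_by_cond: dict,
    Y_by_cond: dict,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    folds: int = 10,
    seed: int = 0,
) -> RidgeInteraction:
    """Per-session interaction strength between a source and target area.

    ``X_by_cond`` / ``Y_by_cond`` map 'stimulus' / 'omission' to residual
    matrices (trials x features).  Trial counts are matched by randomly
    subsampling the more numerous condition (seed-controlled).
    """
    rng = np.random.default_rng(seed)
    T = min(X_by_cond[c].shape[0] for c in ("stimulus", "omission"))
    r2, lam = {}, {}
    for cond in ("stimulus", "omission"):
        X, Y = X_by_cond[cond], Y_by_cond[cond]
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must share trials")
        if X.shape[0] > T:
            sel = rng.choice(X.shape[0], size=T, replace=False)
            X, Y = X[sel], Y[sel]
        assert X.shape[0] == T
        r2[cond], lam[cond] = _cv_ridge_r2(X, Y, lambda_grid, folds, rng)
    return RidgeInteraction(
        r2["stimulus"], r2["omission"], r2["stimulus"] - r2["omission"],
        lam["stimulus"], lam["omission"], T,
    )


def interaction_difference(session_results: list[RidgeInteraction]):
    """Across-session summary: mean difference and rank-sum p of the per-
    session stimulus vs omission R^2 distributions."""
    stim = np.array([r.r2_stimulus for r in session_results])
    omit = np.array([r.r2_omission for r in session_results])
    p = float(stats.ranksums(stim, omit).pvalue)
    return float(np.mean(stim - omit)), p


@dataclass
class CcaResult:
    A: np.ndarray              # n_X x n_dims canonical coefficients
    B: np.ndarray              # n_Y x n_dims
    correlations: np.ndarray   # non-increasing, in [0, 1]
    regularized: bool = False


def cca(X: np.ndarray, Y: np.ndarray, n_dims: int = 3, reg: float | None = None) -> CcaResult:
    """Classical canonical correlation analysis with optional ridge loading.

    When the matched trial count T does not exceed n_X + n_Y the
    covariance blocks get a small diagonal loading (``reg`` defaults to
    1e-3 of the mean variance) so the whitening stays well-posed.
    Correlations are the Pearson correlations of the paired projections,
    sorted non-increasing.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must share trials")
    T, nx = X.shape
    ny = Y.shape[1]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    Sxx = Xc.T @ Xc / (T - 1)
    Syy = Yc.T @ Yc / (T - 1)
    Sxy = Xc.T @ Yc / (T - 1)
    regularized = False
    if reg is None:
        reg = 0.0
        if T <= nx + ny:
            reg = 1e-3 * 0.5 * (np.trace(Sxx) / nx + np.trace(Syy) / ny)
            regularized = True
    elif reg > 0:
        regularized = True
    Sxx = Sxx + reg * np.eye(nx)
    Syy = Syy + reg * np.eye(ny)
    Lx = linalg.cholesky(Sxx, lower=True)
    Ly = linalg.cholesky(Syy, lower=True)
    M = linalg.solve_triangular(Lx, Sxy, lower=True)
    M = linalg.solve_triangular(Ly, M.T, lower=True).T
    U, s, Vt = linalg.svd(M, full_matrices=False)
    k = min(n_dims, s.size)
    A = linalg.solve_triangular(Lx.T, U[:, :k], lower=False)
    B = linalg.solve_triangular(Ly.T, Vt[:k].T, lower=False)
    # report sample correlations of the projections
    corrs = np.empty(k)
    for i in range(k):
        u, v = Xc @ A[:, i], Yc @ B[:, i]
        corrs[i] = abs(float(np.corrcoef(u, v)[0, 1]))
    corrs = np.sort(np.clip(corrs, 0.0, 1.0))[::-1]
    return CcaResult(A, B, corrs, regularized)
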