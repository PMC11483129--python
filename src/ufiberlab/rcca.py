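"""Regularized canonical correlation between behavior and AFD matrices.

With many more vertices than subjects the sample covariance of the
vertex block is singular, so both block covariances are ridge-regularized
(Cxx + lambda_x I, Cyy + lambda_y I).  Only the first canonical pair is
modeled.  The regularizers are chosen by cross-validated grid search on
the out-of-fold correlation of the canonical variates: the in-sample
canonical correlation is degenerate (identically 1) whenever a block's
regularizer vanishes with more columns than subjects, so held-out
correlation is the meaningful objective.  Permutation nulls (rows of Y
shuffled, model refit) give per-variable 99% intervals for the loadings;
a variable is flagged when its observed loading falls outside its null
interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CCAResult", "fit_rcca", "grid_search_lambdas",
           "permutation_loading_cis", "default_lambda_grid"]


@dataclass
class CCAResult:
    lambda_x: float
    lambda_y: float
    canonical_corr: float
    u_weights: np.ndarray        # (p,) behavior-side weights
    v_weights: np.ndarray        # (q,) AFD-side weights
    U: np.ndarray                # (n,) behavioral variate, unit variance
    V: np.ndarray                # (n,) AFD variate, unit variance
    loadings_x: np.ndarray       # corr of each X column with U
    loadings_y: np.ndarray       # corr of each Y column with V
    n_perm: int = 0
    ci99_x: np.ndarray | None = None   # (p, 2) null intervals
    ci99_y: np.ndarray | None = None   # (q, 2)
    cv_corr: float = np.nan

    def flagged_x(self) -> np.ndarray:
        """Behavioral variables whose loading lies outside its null CI."""
        if self.ci99_x is None:
            raise ValueError("no permutation CIs computed")
        return ((self.loadings_x < self.ci99_x[:, 0])
                | (self.loadings_x > self.ci99_x[:, 1]))

    def flagged_y(self) -> np.ndarray:
        if self.ci99_y is None:
            raise ValueError("no permutation CIs computed")
        return ((self.loadings_y < self.ci99_y[:, 0])
                | (self.loadings_y > self.ci99_y[:, 1]))


def _standardize(M):
    M = np.asarray(M, float)
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (M - mu) / sd, mu, sd


def _inv_sqrt_apply(Zs: np.ndarray, lam: float, M: np.ndarray,
                    n: int) -> np.ndarray:
    """Apply (Z'Z/(n-1) + lam I)^(-1/2) to M without forming q x q matrices.

    Uses the thin SVD of Zs: the regularized covariance shares Z's right
    singular vectors, and directions orthogonal to them have eigenvalue
    exactly lam.
    """
    _, s, Vt = np.linalg.svd(Zs, full_matrices=False)
    ev = s**2 / (n - 1)
    if lam <= 0 and np.any(ev < 1e-10 * max(ev.max(initial=0.0), 1.0)):
        raise np.linalg.LinAlgError(
            "regularized covariance is singular; use a positive lambda")
    if lam <= 0 and Zs.shape[1] > len(s):
        raise np.linalg.LinAlgError(
            "covariance rank-deficient (more columns than subjects); "
            "use a positive lambda")
    d = 1.0 / np.sqrt(ev + lam)
    if lam > 0:
        tail = 1.0 / np.sqrt(lam)
        VtM = Vt @ M
        return tail * M + Vt.T @ ((d - tail)[:, None] * VtM)
    return Vt.T @ (d[:, None] * (Vt @ M))


def fit_rcca(X: np.ndarray, Y: np.ndarray, lambda_x: float = 0.0,
             lambda_y: float = 0.0) -> CCAResult:
    """First canonical pair of ridge-regularized CCA.

    Columns are standardized internally; missing values are not allowed.
    Sign convention: the behavioral weight of largest magnitude is
    positive (the joint sign of the pair is otherwise arbitrary).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching subject rows")
    if np.isnan(X).any() or np.isnan(Y).any():
        raise ValueError("missing values not supported; impute or drop first")
    n = X.shape[0]
    Xs, _, _ = _standardize(X)
    Ys, _, _ = _standardize(Y)

    # whitened cross-covariance: Kx Cxy Ky, SVD gives the first pair
    Cxy = Xs.T @ Ys / (n - 1)
    A = _inv_sqrt_apply(Xs, lambda_x, Cxy, n)          # Kx Cxy  (p x q)
    Bt = _inv_sqrt_apply(Ys, lambda_y, A.T, n)         # Ky (Kx Cxy)' (q x p)
    Uw, s, Vtw = np.linalg.svd(Bt.T, full_matrices=False)
    a, b = Uw[:, 0], Vtw[0]
    wx = _inv_sqrt_apply(Xs, lambda_x, a[:, None], n).ravel()
    wy = _inv_sqrt_apply(Ys, lambda_y, b[:, None], n).ravel()

    U = Xs @ wx
    V = Ys @ wy
    if U.std() > 0:
        U = U / U.std()
    if V.std() > 0:
        V = V / V.std()
    cc = float(np.corrcoef(U, V)[0, 1]) if U.std() > 0 and V.std() > 0 else 0.0
    if cc < 0:  # orient the pair so the canonical correlation is nonnegative
        wy, V, cc = -wy, -V, -cc
    i = int(np.argmax(np.abs(wx)))
    if wx[i] < 0:  # joint flip: largest behavioral weight positive
        wx, wy, U, V = -wx, -wy, -U, -V

    lx = _col_corr(Xs, U)
    ly = _col_corr(Ys, V)
    return CCAResult(lambda_x=float(lambda_x), lambda_y=float(lambda_y),
                     canonical_corr=min(abs(cc), 1.0),
                     u_weights=wx, v_weights=wy, U=U, V=V,
                     loadings_x=lx, loadings_y=ly)


def _col_corr(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    Mc = M - M.mean(axis=0)
    vc = v - v.mean()
    den = np.sqrt((Mc**2).sum(axis=0) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (Mc.T @ vc) / den
    return np.where(np.isfinite(out), out, 0.0)


def default_lambda_grid(X: np.ndarray, Y: np.ndarray, n_per_side: int = 6):
    """Log-spaced lambda pairs spanning [1e-3, 1e2] x mean covariance diag.

    Standardized columns have unit variance, so the scale anchor is 1.
    """
    vals = np.logspace(-3, 2, n_per_side)
    return [(float(a), float(b)) for a in vals for b in vals]


def grid_search_lambdas(X, Y, grid=None, k_folds: int = 5, seed: int = 0):
    """Pick the lambda pair maximizing out-of-fold variate correlation.

    Weights are fit on the training folds; the held-out correlation
    between X_test @ wx and Y_test @ wy is averaged over folds.  The
    reported ``cv_corr`` of the winner is re-estimated on a fresh fold
    split (selecting the maximum over the grid would otherwise bias it
    upward under the null).  Refits on all data at the winning pair.
    Returns ``(lambda_pair, CCAResult)``.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    if grid is None:
        grid = default_lambda_grid(X, Y)
    if len(grid) == 1:
        lam = grid[0]
        res = fit_rcca(X, Y, *lam)
        res.cv_corr = np.nan
        return lam, res
    if n // k_folds < 3:
        raise ValueError("each fold needs at least 3 subjects")

    def cv_score(lam, fold_seed):
        rng = np.random.default_rng(fold_seed)
        order = rng.permutation(n)
        folds = np.array_split(order, k_folds)
        scores = []
        for f in folds:
            tr = np.setdiff1d(order, f)
            try:
                res = fit_rcca(X[tr], Y[tr], *lam)
            except np.linalg.LinAlgError:
                return None
            u = X[f] @ res.u_weights
            v = Y[f] @ res.v_weights
            if u.std() == 0 or v.std() == 0:
                scores.append(0.0)
            else:
                scores.append(float(np.corrcoef(u, v)[0, 1]))
        return float(np.mean(scores))

    best, best_score = None, -np.inf
    for lam in grid:
        m = cv_score(lam, seed)
        if m is not None and m > best_score:
            best, best_score = lam, m
    if best is None:
        raise np.linalg.LinAlgError("no lambda pair in the grid was fittable")
    res = fit_rcca(X, Y, *best)
    held_out = cv_score(best, seed + 1)
    res.cv_corr = held_out if held_out is not None else best_score
    return best, res


def permutation_loading_cis(X, Y, lambdas, n_perm: int = 10_000,
                            level: float = 0.99, seed: int = 0) -> CCAResult:
    """Permutation null intervals for the loadings at fixed lambdas.

    Rows of Y are permuted, the model is refit, and the loadings are
    recorded; each variable's null interval is the central ``level`` mass
    of its null loading distribution.  ``n_perm = 0`` returns the point
    fit untouched; fewer than 100 permutations warns about instability.
    """
    import warnings
    res = fit_rcca(X, Y, *lambdas)
    if n_perm == 0:
        return res
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: unstable intervals",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y, float)
    n = Y.shape[0]
    null_x = np.empty((n_perm, X.shape[1]))
    null_y = np.empty((n_perm, Y.shape[1]))
    for i in range(n_perm):
        perm = rng.permutation(n)
        r = fit_rcca(X, Y[perm], *lambdas)
        null_x[i] = r.loadings_x
        null_y[i] = r.loadings_y
    lo = 100 * (1 - level) / 2
    hi = 100 - lo
    res.ci99_x = np.percentile(null_x, [lo, hi], axis=0).T
    res.ci99_y = np.percentile(null_y, [lo, hi], axis=0).T
    res.n_perm = n_perm
    return res
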