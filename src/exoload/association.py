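"""Single-marker linear mixed-model association in the kinship eigenbasis.

The model is ``y = W a + x b + g + e`` with ``g ~ N(0, sg^2 K)`` and
``e ~ N(0, se^2 I)``.  ``K`` is eigendecomposed once; the restricted
likelihood is profiled over ``lambda = sg^2 / se^2`` on a log10 grid with a
bounded 1-D refinement.  Per-marker Wald tests use the rotated weighted
regression; ``p3d`` mode reuses the null lambda, ``exact`` mode re-optimizes
it per marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "NullModel",
    "fit_null_lmm",
    "ols_null",
    "lmm_scan",
    "significance_thresholds",
    "reml_profile",
    "inflation_factor",
]

LOG10_LAMBDA_BOUNDS = (-5.0, 5.0)
_CHI2_95_HALF = stats.chi2.ppf(0.95, 1) / 2.0  # 1.9207


@dataclass
class NullModel:
    """Rotated null model: kinship spectrum plus REML lambda estimate."""

    U: np.ndarray  # (n, n) eigenvectors of K
    D: np.ndarray  # (n,) eigenvalues, clipped >= 0
    lambda0: float
    loglik: float
    covariates: np.ndarray  # (n, q) original-basis fixed effects (incl. intercept)
    y_rot: np.ndarray = field(repr=False, default=None)
    X_rot: np.ndarray = field(repr=False, default=None)
    boundary: bool = False


def _reml_loglik(log10_lam: float, D: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    """Profiled restricted log-likelihood (constant terms in lambda dropped)."""
    lam = 10.0**log10_lam
    delta = lam * D + 1.0
    w = 1.0 / delta
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yr)
    resid = yr - Xr @ beta
    rss = float((resid * resid * w).sum())
    n, p = Xr.shape
    df = n - p
    sigma2 = rss / df
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0 or not np.isfinite(logdet) or sigma2 <= 0:
        return -np.inf
    return -0.5 * (df * np.log(2.0 * np.pi * sigma2) + df
                   + float(np.log(delta).sum()) + logdet)


def _optimize_lambda(
    D: np.ndarray, yr: np.ndarray, Xr: np.ndarray,
    bounds: tuple[float, float] = LOG10_LAMBDA_BOUNDS, n_grid: int = 61,
) -> tuple[float, float, bool]:
    """Grid search plus bounded refinement; returns (log10_lam, loglik, boundary)."""
    grid = np.linspace(bounds[0], bounds[1], n_grid)
    lls = np.array([_reml_loglik(g, D, yr, Xr) for g in grid])
    if not np.any(np.isfinite(lls)):
        raise ValueError(f"non-finite restricted likelihood over lambda bracket {bounds}")
    ll_max = np.nanmax(lls)
    # flat or near-flat profiles (e.g. K = I) resolve to the smallest lambda
    tol = 1e-8 * max(1.0, abs(ll_max))
    best = int(np.flatnonzero(lls >= ll_max - tol)[0])
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, D, yr, Xr), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    boundary = best in (0, n_grid - 1)
    if -res.fun >= lls[best]:
        return float(res.x), float(-res.fun), boundary
    return float(grid[best]), float(lls[best]), boundary


def fit_null_lmm(
    y: np.ndarray,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    psd_tol: float = 1e-6,
) -> NullModel:
    """Eigendecompose ``K`` once and REML-fit lambda under the null.

    ``covariates`` (without intercept column requirement — an intercept is
    always prepended) enter as fixed effects.  Raises if ``K`` is not
    positive semi-definite beyond tolerance or the likelihood is non-finite.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K.shape != (n, n):
        raise ValueError("kinship shape does not match phenotype length")
    D, U = np.linalg.eigh((K + K.T) / 2.0)
    scale = max(float(D[-1]), 1.0)
    if D[0] < -psd_tol * scale:
        raise ValueError(f"kinship not positive semi-definite (min eigenvalue {D[0]:.3g})")
    D = np.clip(D, 0.0, None)
    W = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    yr = U.T @ y
    Xr = U.T @ W
    log10_lam, ll, boundary = _optimize_lambda(D, yr, Xr)
    return NullModel(U=U, D=D, lambda0=10.0**log10_lam, loglik=ll,
                     covariates=W, y_rot=yr, X_rot=Xr, boundary=boundary)


def ols_null(y: np.ndarray, covariates: np.ndarray | None = None) -> NullModel:
    """Degenerate null with no kinship correction (plain regression)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    W = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    return NullModel(U=np.eye(n), D=np.ones(n), lambda0=0.0, loglik=np.nan,
                     covariates=W, y_rot=y.copy(), X_rot=W.copy(), boundary=True)


def reml_profile(
    null: NullModel, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Restricted log-likelihood over a log10-lambda grid (for CI inversion)."""
    if grid is None:
        grid = np.linspace(*LOG10_LAMBDA_BOUNDS, 201)
    lls = np.array([_reml_loglik(g, null.D, null.y_rot, null.X_rot) for g in grid])
    return grid, lls


def _wald_scan_at_lambda(
    lam: float, D: np.ndarray, yr: np.ndarray, Wr: np.ndarray, Xr: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Vectorized per-column Wald tests at fixed lambda via partitioned WLS."""
    n, q = Wr.shape
    w = 1.0 / (lam * D + 1.0)
    sw = np.sqrt(w)
    A = Wr * sw[:, None]
    yw = yr * sw
    Xw = Xr * sw[:, None]
    Q, _ = np.linalg.qr(A)
    y_res = yw - Q @ (Q.T @ yw)
    X_res = Xw - Q @ (Q.T @ Xw)
    bxx = (X_res * X_res).sum(axis=0)
    bxy = X_res.T @ y_res
    yy = float(y_res @ y_res)
    df = n - q - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = bxy / bxx
        rss = yy - beta * bxy
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 / bxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    bad = bxx <= 1e-12 * max(yy, 1.0)
    beta[bad] = np.nan
    se[bad] = np.nan
    p[bad] = np.nan
    return beta, se, p, df


def lmm_scan(
    null: NullModel,
    y: np.ndarray,
    X: np.ndarray,
    mode: str = "p3d",
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
) -> pd.DataFrame:
    """Wald test of each predictor column of ``X`` (genotype dosage or
    methylation fraction, used as-is).

    ``p3d`` reuses the null-model lambda for every marker; ``exact``
    re-optimizes lambda per marker with the marker in the fixed effects.
    Constant predictors yield ``p = NaN`` with reason ``"constant"``.
    Returns a position-sorted data frame (chrom, pos, beta, se, p, lam, n).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, m = X.shape
    yr = null.U.T @ y
    Wr = null.X_rot
    Xr = null.U.T @ X

    if mode == "p3d":
        beta, se, p, df = _wald_scan_at_lambda(null.lambda0, null.D, yr, Wr, Xr)
        lam = np.full(m, null.lambda0)
    elif mode == "exact":
        beta = np.empty(m); se = np.empty(m); p = np.empty(m); lam = np.empty(m)
        for j in range(m):
            xj = Xr[:, j : j + 1]
            if np.ptp(X[:, j]) == 0:
                beta[j] = se[j] = p[j] = np.nan
                lam[j] = np.nan
                continue
            design = np.hstack([Wr, xj])
            log10_lam, _, _ = _optimize_lambda(null.D, yr, design)
            bj, sj, pj, _ = _wald_scan_at_lambda(10.0**log10_lam, null.D, yr, Wr, xj)
            beta[j], se[j], p[j] = bj[0], sj[0], pj[0]
            lam[j] = 10.0**log10_lam
    else:
        raise ValueError(f"unknown mode {mode!r}")

    reason = np.where(np.isnan(p), "constant", "")
    out = pd.DataFrame({
        "chrom": chrom if chrom is not None else np.repeat("NA", m),
        "pos": pos if pos is not None else np.arange(m),
        "beta": beta, "se": se, "p": p, "lambda": lam,
        "n": np.full(m, n), "reason": reason,
    })
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def significance_thresholds(n_unlinked: int, alpha: float = 0.05) -> tuple[float, float]:
    """(genome-wide Bonferroni over unlinked variants, fixed suggestive 1e-5)."""
    if n_unlinked < 1:
        raise ValueError("n_unlinked must be >= 1")
    return alpha / n_unlinked, 1e-5


def inflation_factor(p_values: np.ndarray) -> float:
    """Genomic inflation: median chi-square over its null median 0.4549."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, 1))
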