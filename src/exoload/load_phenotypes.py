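"""Depth-corrected load phenotypes and their genetic characterization.

The load phenotype is the residual of ``log(count + 1)`` regressed on
``log(dedup_total)`` by ordinary least squares.  Characterization covers
population variance decomposition, Welch's unequal-variance two-group test,
and single-component REML SNP heritability with a profile-likelihood CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .association import (
    LOG10_LAMBDA_BOUNDS,
    _CHI2_95_HALF,
    _reml_loglik,
    fit_null_lmm,
)
from .genotypes import scale_kinship

__all__ = [
    "LoadPhenotype",
    "HeritabilityEstimate",
    "normalize_load",
    "population_variance",
    "welch_test",
    "snp_heritability",
]


@dataclass
class LoadPhenotype:
    sample_ids: list[str]
    taxon: str
    residual: np.ndarray  # r_i, log-scale, sums to 0
    log_count: np.ndarray  # y_i = log(c_i + 1)
    log_depth: np.ndarray  # x_i = log(d_i)
    slope: float
    intercept: float


@dataclass
class HeritabilityEstimate:
    h2: float
    ci_low: float
    ci_high: float
    sigma_g2: float
    sigma_e2: float
    lam: float  # sigma_g2 / sigma_e2
    boundary: bool


def normalize_load(
    counts: np.ndarray,
    dedup_totals: np.ndarray,
    sample_ids: list[str] | None = None,
    taxon: str = "",
) -> LoadPhenotype:
    """OLS residuals of ``log(c+1) ~ log(d)`` with intercept."""
    counts = np.asarray(counts, dtype=float)
    depths = np.asarray(dedup_totals, dtype=float)
    if counts.shape != depths.shape:
        raise ValueError("counts and dedup_totals must have the same length")
    if np.any(counts < 0) or np.any(depths <= 0):
        raise ValueError("counts must be >= 0 and dedup_totals > 0")
    y = np.log(counts + 1.0)
    x = np.log(depths)
    if np.ptp(x) == 0:
        raise ValueError("all dedup_totals identical: depth regression is degenerate")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(len(y))]
    return LoadPhenotype(sample_ids=list(ids), taxon=taxon, residual=resid,
                         log_count=y, log_depth=x, slope=float(slope),
                         intercept=float(intercept))


def population_variance(
    loads: np.ndarray, population_labels: np.ndarray
) -> tuple[float, float, float]:
    """One-way variance decomposition: (R^2, F, p) with F(k-1, n-k)."""
    loads = np.asarray(loads, dtype=float)
    labels = np.asarray(population_labels)
    groups = [loads[labels == g] for g in np.unique(labels)]
    k, n = len(groups), len(loads)
    if k < 2:
        raise ValueError("need >= 2 populations")
    if not any(len(g) >= 2 for g in groups):
        raise ValueError("need at least one population with >= 2 samples")
    grand = loads.mean()
    ss_total = float(((loads - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    if ss_total == 0:
        return 0.0, 0.0, 1.0
    r2 = ss_between / ss_total
    ss_within = ss_total - ss_between
    df1, df2 = k - 1, n - k
    if ss_within <= 0:
        return r2, np.inf, 0.0
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return r2, float(f), p


def welch_test(loads: np.ndarray, binary_group: np.ndarray) -> tuple[float, float, float]:
    """Welch's t with Satterthwaite df; identical groups return (0, df, 1)."""
    loads = np.asarray(loads, dtype=float)
    group = np.asarray(binary_group).astype(bool)
    a, b = loads[group], loads[~group]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 samples")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        df = float(na + nb - 2)
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    df = max(df, 1.0)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def snp_heritability(
    loads: np.ndarray,
    kinship: np.ndarray,
    conf_level: float = 0.95,
) -> HeritabilityEstimate:
    """Single-component REML heritability with profile-likelihood CI.

    The kinship is rescaled to mean diagonal 1, so
    ``h2 = lambda / (lambda + 1)``.  The CI inverts the restricted profile
    likelihood at the chi-square(1) cutoff and is clipped to [0, 1];
    boundary estimates carry ``boundary=True``.
    """
    y = np.asarray(loads, dtype=float)
    K = scale_kinship(np.asarray(kinship, dtype=float))
    if len(y) < 20:
        warnings.warn("n < 20: heritability estimate will be unstable")
    null = fit_null_lmm(y, K)
    lam = null.lambda0
    h2 = lam / (lam + 1.0)

    # residual variance at the optimum, for reporting sigma_g2/sigma_e2
    delta = lam * null.D + 1.0
    w = 1.0 / delta
    Xr, yr = null.X_rot, null.y_rot
    beta = np.linalg.solve(Xr.T @ (Xr * w[:, None]), (Xr * w[:, None]).T @ yr)
    resid = yr - Xr @ beta
    sigma_e2 = float((resid * resid * w).sum() / (len(y) - Xr.shape[1]))
    sigma_g2 = lam * sigma_e2

    cutoff = stats.chi2.ppf(conf_level, 1) / 2.0
    target = null.loglik - cutoff

    def f(log10_lam: float) -> float:
        return _reml_loglik(log10_lam, null.D, yr, Xr) - target

    lo_bound, hi_bound = LOG10_LAMBDA_BOUNDS
    log10_hat = np.log10(lam) if lam > 0 else lo_bound
    ci_low = 0.0
    if f(lo_bound) < 0 and log10_hat > lo_bound:
        try:
            root = optimize.brentq(f, lo_bound, log10_hat, xtol=1e-8)
            ci_low = 10.0**root / (10.0**root + 1.0)
        except ValueError:
            ci_low = 0.0
    ci_high = 1.0
    if f(hi_bound) < 0 and log10_hat < hi_bound:
        try:
            root = optimize.brentq(f, log10_hat, hi_bound, xtol=1e-8)
            ci_high = 10.0**root / (10.0**root + 1.0)
        except ValueError:
            ci_high = 1.0
    ci_low = float(np.clip(ci_low, 0.0, h2))
    ci_high = float(np.clip(ci_high, h2, 1.0))
    return HeritabilityEstimate(h2=float(h2), ci_low=ci_low, ci_high=ci_high,
                                sigma_g2=sigma_g2, sigma_e2=sigma_e2, lam=float(lam),
                                boundary=null.boundary)
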