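"""Variant filtering, LD pruning and IBS kinship construction."""

from __future__ import annotations

import numpy as np

from .formats_io import VariantTable

__all__ = ["maf_filter", "compute_maf", "ld_prune", "ibs_kinship", "scale_kinship"]


def compute_maf(table: VariantTable) -> np.ndarray:
    """Minor allele frequency per variant, over non-missing calls."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(table.dosages, axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def maf_filter(table: VariantTable, min_maf: float = 0.04) -> VariantTable:
    """Keep variants with MAF >= ``min_maf`` (boundary kept)."""
    keep = np.flatnonzero(compute_maf(table) >= min_maf)
    return table.take(keep)


def _mean_impute(dosages: np.ndarray) -> np.ndarray:
    out = dosages.copy()
    col_means = np.nanmean(out, axis=0)
    col_means = np.nan_to_num(col_means)
    nan_r, nan_c = np.nonzero(np.isnan(out))
    out[nan_r, nan_c] = col_means[nan_c]
    return out


def ld_prune(
    table: VariantTable,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.8,
) -> np.ndarray:
    """Sliding-window LD pruning on dosage correlations, chromosome-local.

    Within each ``window``-variant window, while any retained pair has
    squared Pearson correlation > ``r2_max``, the member of the worst
    (highest-r2) pair with the lower MAF is removed (tie: larger position).
    Windows slide by ``step`` variants.  Returns the retained variant
    indices into ``table``.
    """
    dos = _mean_impute(table.dosages)
    maf = compute_maf(table)
    removed = np.zeros(table.n_variants, dtype=bool)
    for chrom in dict.fromkeys(table.chrom.tolist()):
        idx = np.flatnonzero(table.chrom == chrom)
        order = idx[np.argsort(table.pos[idx], kind="stable")]
        m = len(order)
        start = 0
        while start < m:
            win = order[start : start + window]
            win = win[~removed[win]]
            if len(win) > 1:
                x = dos[:, win]
                x = x - x.mean(axis=0)
                sd = x.std(axis=0)
                sd[sd == 0] = 1.0
                corr = (x / sd).T @ (x / sd) / x.shape[0]
                r2 = corr**2
                np.fill_diagonal(r2, 0.0)
                alive = np.ones(len(win), dtype=bool)
                while True:
                    sub = np.where(np.outer(alive, alive), r2, 0.0)
                    worst = np.unravel_index(np.argmax(sub), sub.shape)
                    if sub[worst] <= r2_max:
                        break
                    a, b = win[worst[0]], win[worst[1]]
                    if maf[a] < maf[b]:
                        victim = a
                    elif maf[b] < maf[a]:
                        victim = b
                    else:
                        victim = a if table.pos[a] > table.pos[b] else b
                    removed[victim] = True
                    alive[worst[0] if victim == a else worst[1]] = False
            if start + window >= m:
                break
            start += step
    return np.flatnonzero(~removed)


def ibs_kinship(table: VariantTable) -> np.ndarray:
    """IBS similarity: ``K_ij = mean_v (2 - |g_iv - g_jv|) / 2``.

    Missing dosages are mean-imputed per variant.  Entries are in [0, 1]
    with diagonal 1 for complete data.
    """
    if table.n_variants == 0:
        raise ValueError("cannot compute kinship from zero variants")
    dos = _mean_impute(table.dosages)
    n = table.n_samples
    K = np.empty((n, n))
    # pairwise mean absolute dosage difference, blocked over samples
    for i in range(n):
        diff = np.abs(dos - dos[i]).mean(axis=1)
        K[i] = (2.0 - diff) / 2.0
    return (K + K.T) / 2.0


def scale_kinship(K: np.ndarray) -> np.ndarray:
    """Rescale so the mean diagonal is 1 (heritability scale convention)."""
    d = float(np.mean(np.diag(K)))
    if d <= 0:
        raise ValueError("kinship has non-positive mean diagonal")
    return K / d
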