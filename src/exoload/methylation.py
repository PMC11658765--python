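"""Methylation filtering, extreme-group DMR calling and EWA preparation.

The DMR caller is a transparent seed-merge-test procedure: per context,
sites with a large high-vs-low group mean difference seed candidate regions,
nearby seeds merge, and each region is tested by Mann-Whitney U on
per-sample region means with Benjamini-Hochberg control across regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import CONTEXTS, IntervalSet, UnionBed

__all__ = [
    "DMR",
    "select_extreme_samples",
    "filter_union",
    "call_dmrs",
    "dmr_feature_density",
    "ewa_sites",
    "dmrs_to_bed_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class DMR:
    chrom: str
    start: int  # 0-based half-open
    end: int
    context: str
    n_sites: int
    delta: float  # mean(high) - mean(low), fraction units
    p: float
    q: float
    direction: str  # "hyper" | "hypo" w.r.t. the high-load group


def select_extreme_samples(
    loads: np.ndarray, sample_ids: list[str], n: int = 20
) -> tuple[list[str], list[str]]:
    """Top-n and bottom-n samples by load; ties broken by sample id."""
    if 2 * n > len(loads):
        raise ValueError(f"need >= {2 * n} samples, have {len(loads)}")
    order = sorted(range(len(loads)), key=lambda i: (loads[i], sample_ids[i]))
    low = sorted(sample_ids[i] for i in order[:n])
    high = sorted(sample_ids[i] for i in order[-n:])
    return high, low


def filter_union(
    ub: UnionBed,
    min_cov: int = 4,
    presence: float = 0.95,
    min_diff: float = 0.05,
    min_diff_samples: int = 2,
) -> UnionBed:
    """Keep sites covered >= min_cov in >= ``presence`` of samples with at
    least ``min_diff_samples`` samples deviating >= ``min_diff`` from the
    site median."""
    covered = ub.coverage >= min_cov
    presence_ok = covered.mean(axis=1) >= presence
    med = np.nanmedian(ub.fractions, axis=1)
    with np.errstate(invalid="ignore"):
        deviant = np.abs(ub.fractions - med[:, None]) >= min_diff
    diff_ok = np.nansum(deviant, axis=1) >= min_diff_samples
    return ub.take(np.flatnonzero(presence_ok & diff_ok))


def _bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, p[i] * m / rank_from_top)
        q[i] = prev
    return q


def call_dmrs(
    ub: UnionBed,
    high_ids: list[str],
    low_ids: list[str],
    min_cov: int = 4,
    seed_diff: float = 0.1,
    max_gap: int = 300,
    min_sites: int = 5,
    fdr: float = 0.2,
    group_presence: float = 0.8,
) -> list[DMR]:
    """Seed-merge-test DMR calling between two extreme-load groups.

    A site is usable when >= ``group_presence`` of each group is covered at
    >= ``min_cov``; it seeds a region when the group mean difference reaches
    ``seed_diff``.  Seeds within ``max_gap`` bp merge; regions with >=
    ``min_sites`` seed sites are tested (Mann-Whitney U on per-sample region
    means) and kept at BH ``q < fdr``.
    """
    if set(high_ids) & set(low_ids):
        raise ValueError("high and low groups overlap")
    hi_idx = [ub.samples.index(s) for s in high_ids]
    lo_idx = [ub.samples.index(s) for s in low_ids]
    dmrs: list[DMR] = []
    for ctx in CONTEXTS:
        sel = np.flatnonzero(ub.context == ctx)
        if len(sel) == 0:
            continue
        sub = ub.take(sel)
        order = np.lexsort((sub.pos, sub.chrom.astype(str)))
        sub = sub.take(order)
        fr_hi = sub.fractions[:, hi_idx]
        fr_lo = sub.fractions[:, lo_idx]
        cov_hi = sub.coverage[:, hi_idx] >= min_cov
        cov_lo = sub.coverage[:, lo_idx] >= min_cov
        usable = (cov_hi.mean(axis=1) >= group_presence) & (cov_lo.mean(axis=1) >= group_presence)
        with np.errstate(invalid="ignore"):
            mean_hi = np.nanmean(np.where(cov_hi, fr_hi, np.nan), axis=1)
            mean_lo = np.nanmean(np.where(cov_lo, fr_lo, np.nan), axis=1)
        diff = mean_hi - mean_lo
        seeds = np.flatnonzero(usable & (np.abs(diff) >= seed_diff))
        if len(seeds) == 0:
            continue
        # merge seeds separated by <= max_gap bp on the same chromosome
        regions: list[list[int]] = [[seeds[0]]]
        for s in seeds[1:]:
            prev = regions[-1][-1]
            if sub.chrom[s] == sub.chrom[prev] and sub.pos[s] - sub.pos[prev] <= max_gap:
                regions[-1].append(s)
            else:
                regions.append([s])
        tested: list[tuple[list[int], float, float]] = []
        for region in regions:
            if len(region) < min_sites:
                continue
            ridx = np.asarray(region)
            m_hi = np.where(cov_hi[ridx], fr_hi[ridx], np.nan)
            m_lo = np.where(cov_lo[ridx], fr_lo[ridx], np.nan)
            with np.errstate(invalid="ignore"):
                per_hi = np.nanmean(m_hi, axis=0)
                per_lo = np.nanmean(m_lo, axis=0)
            per_hi = per_hi[~np.isnan(per_hi)]
            per_lo = per_lo[~np.isnan(per_lo)]
            if len(per_hi) < 2 or len(per_lo) < 2:
                logger.info("region %s:%d-%d skipped: group too small after coverage masking",
                            sub.chrom[ridx[0]], sub.pos[ridx[0]], sub.pos[ridx[-1]])
                continue
            if np.ptp(np.concatenate([per_hi, per_lo])) == 0:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(per_hi, per_lo, alternative="two-sided").pvalue)
            delta = float(per_hi.mean() - per_lo.mean())
            tested.append((region, p, delta))
        if not tested:
            continue
        qs = _bh(np.array([t[1] for t in tested]))
        for (region, p, delta), q in zip(tested, qs):
            if q < fdr:
                ridx = np.asarray(region)
                dmrs.append(DMR(
                    chrom=str(sub.chrom[ridx[0]]), start=int(sub.pos[ridx[0]]),
                    end=int(sub.pos[ridx[-1]]) + 1, context=ctx, n_sites=len(region),
                    delta=delta, p=p, q=float(q),
                    direction="hyper" if delta > 0 else "hypo",
                ))
    return dmrs


def dmr_feature_density(
    dmrs: list[DMR],
    features: IntervalSet,
    genome_feature_mb: dict[str, float],
) -> dict[str, float]:
    """DMRs overlapping each feature class per Mb of that class.

    A DMR overlapping two feature classes counts in both.  Classes with zero
    Mb yield NaN.
    """
    counts = {fc: 0 for fc in genome_feature_mb}
    for d in dmrs:
        hit_classes = set()
        for i in range(len(features)):
            if (features.chrom[i] == d.chrom and features.start[i] < d.end
                    and d.start < features.end[i]):
                hit_classes.add(str(features.feature_class[i]))
        for fc in hit_classes:
            if fc in counts:
                counts[fc] += 1
    out: dict[str, float] = {}
    for fc, mb in genome_feature_mb.items():
        out[fc] = counts[fc] / mb if mb > 0 else float("nan")
    return out


def ewa_sites(ub: UnionBed, dmrs: list[DMR]) -> tuple[UnionBed, float]:
    """Restrict sites to DMR intervals of matching context; Bonferroni
    threshold ``0.05 / n_DMRs``.  Zero DMRs yield an empty table and a NaN
    threshold."""
    if not dmrs:
        return ub.take(np.empty(0, dtype=np.int64)), float("nan")
    keep = np.zeros(ub.n_sites, dtype=bool)
    for d in dmrs:
        keep |= ((ub.context == d.context) & (ub.chrom == d.chrom)
                 & (ub.pos >= d.start) & (ub.pos < d.end))
    return ub.take(np.flatnonzero(keep)), 0.05 / len(dmrs)


def dmrs_to_bed_frame(dmrs: list[DMR]) -> pd.DataFrame:
    """BED6+ layout: name=context, score=-log10 q, extra: delta, n_sites, direction."""
    return pd.DataFrame({
        "chrom": [d.chrom for d in dmrs],
        "start": [d.start for d in dmrs],
        "end": [d.end for d in dmrs],
        "name": [d.context for d in dmrs],
        "score": [-np.log10(max(d.q, 1e-300)) for d in dmrs],
        "strand": ["." for _ in dmrs],
        "delta": [d.delta for d in dmrs],
        "n_sites": [d.n_sites for d in dmrs],
        "direction": [d.direction for d in dmrs],
    })
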