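"""Candidate enrichment across significance thresholds with a rotation null.

A priori candidate variants (within a window of candidate genes) are tested
for over-representation among significant associations.  The null
distribution rotates candidate flags circularly against fixed p-values
within each chromosome, preserving the local correlation structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import IntervalSet

__all__ = [
    "EnrichmentResult",
    "RotationNull",
    "mark_candidates",
    "enrichment_curve",
    "rotation_test",
    "feature_enrichment",
]


@dataclass
class EnrichmentResult:
    thresholds: np.ndarray  # -log10 p, 0.5 increments
    n_significant: np.ndarray  # s(t)
    n_candidate_significant: np.ndarray  # a(t)
    enrichment: np.ndarray  # E(t), NaN where s(t) == 0
    fdr_upper: np.ndarray  # NaN where a(t) == 0
    total_variants: int  # S
    total_candidates: int  # A

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds, "s": self.n_significant,
            "a": self.n_candidate_significant, "enrichment": self.enrichment,
            "fdr_upper": self.fdr_upper,
        })


@dataclass
class RotationNull:
    observed: float
    null_enrichments: np.ndarray
    empirical_p: float
    n_perm: int
    seed: int


def mark_candidates(
    variant_chrom: np.ndarray,
    variant_pos: np.ndarray,
    candidate_genes: IntervalSet,
    window: int = 20_000,
) -> np.ndarray:
    """Flag variants within ``window`` bp of any candidate gene interval.

    Variant positions are 1-based (VCF convention); a variant is flagged iff
    its 0-based position falls in ``[start - window, end + window)``.
    Raises when no variant chromosome occurs among the candidate intervals
    (a naming-convention mismatch), listing the offending names.
    """
    v_chrom = np.asarray(variant_chrom)
    v_pos0 = np.asarray(variant_pos, dtype=np.int64) - 1
    iv_chroms = set(candidate_genes.chrom.tolist())
    offenders = sorted(set(v_chrom.tolist()) - iv_chroms)
    if len(offenders) == len(set(v_chrom.tolist())) and len(candidate_genes) > 0:
        raise ValueError(f"no shared chromosome names; variant chroms {offenders} "
                         f"absent from candidate intervals")
    flags = np.zeros(len(v_pos0), dtype=bool)
    for chrom in iv_chroms:
        sel = np.flatnonzero(candidate_genes.chrom == chrom)
        if len(sel) == 0:
            continue
        starts = candidate_genes.start[sel] - window
        ends = candidate_genes.end[sel] + window
        vmask = v_chrom == chrom
        pos = v_pos0[vmask]
        hit = np.zeros(len(pos), dtype=bool)
        for s, e in zip(starts, ends):
            hit |= (pos >= s) & (pos < e)
        flags[vmask] = hit
    return flags


def _curve_thresholds(p_values: np.ndarray, t_step: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        max_logp = float(np.max(-np.log10(np.maximum(p_values, 1e-300))))
    top = np.ceil(max_logp / t_step) * t_step
    return np.arange(0.0, top + t_step / 2, t_step)


def enrichment_curve(
    p_values: np.ndarray, flags: np.ndarray, t_step: float = 0.5
) -> EnrichmentResult:
    """Enrichment ``E(t) = [a(t)/s(t)] / [A/S]`` with an FDR upper bound.

    ``FDR_ub(t) = min(1, [(s-a) * A/(S-A)] / a)`` assumes candidate and
    non-candidate null rates are exchangeable.  Degenerate backgrounds
    (``A == 0`` or ``A == S``) raise.
    """
    p = np.asarray(p_values, dtype=float)
    f = np.asarray(flags, dtype=bool)
    if len(p) != len(f) or len(p) == 0:
        raise ValueError("p_values and flags must be equal-length and non-empty")
    S = len(p)
    A = int(f.sum())
    if A == 0 or A == S:
        raise ValueError(f"degenerate candidate background (A={A}, S={S})")
    ts = _curve_thresholds(p, t_step)
    logp = -np.log10(np.maximum(p, 1e-300))
    s = np.array([(logp >= t).sum() for t in ts])
    a = np.array([((logp >= t) & f).sum() for t in ts])
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.where(s > 0, (a / np.maximum(s, 1)) / (A / S), np.nan)
        fdr = np.where(a > 0, np.minimum(1.0, ((s - a) * A / (S - A)) / np.maximum(a, 1)), np.nan)
    return EnrichmentResult(thresholds=ts, n_significant=s, n_candidate_significant=a,
                            enrichment=E, fdr_upper=fdr, total_variants=S,
                            total_candidates=A)


def _enrichment_at(logp: np.ndarray, flags: np.ndarray, t: float, A: int, S: int) -> float:
    sig = logp >= t
    s = int(sig.sum())
    if s == 0:
        return 0.0
    a = int((sig & flags).sum())
    return (a / s) / (A / S)


def rotation_test(
    p_values: np.ndarray,
    flags: np.ndarray,
    chrom_of_variant: np.ndarray,
    test_threshold: float,
    n_perm: int = 10_000,
    seed: int = 0,
) -> RotationNull:
    """Genome-rotation permutation null for the enrichment at one threshold.

    Each permutation circularly shifts the candidate-flag vector within each
    chromosome by an independent uniform offset while p-values stay fixed in
    genomic order.  ``test_threshold`` is on the -log10 p scale.  Empirical
    p is ``(1 + #{null >= observed}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100: rotation null will be very coarse")
    p = np.asarray(p_values, dtype=float)
    f = np.asarray(flags, dtype=bool)
    chroms = np.asarray(chrom_of_variant)
    S = len(p)
    A = int(f.sum())
    if A == 0 or A == S:
        raise ValueError("degenerate candidate background")
    logp = -np.log10(np.maximum(p, 1e-300))
    observed = _enrichment_at(logp, f, test_threshold, A, S)

    rng = np.random.default_rng(seed)
    chrom_idx = [np.flatnonzero(chroms == c) for c in dict.fromkeys(chroms.tolist())]
    null = np.empty(n_perm)
    rotated = f.copy()
    for b in range(n_perm):
        for idx in chrom_idx:
            off = int(rng.integers(0, len(idx)))
            rotated[idx] = np.roll(f[idx], off)
        null[b] = _enrichment_at(logp, rotated, test_threshold, A, S)
    emp_p = (1.0 + float((null >= observed).sum())) / (n_perm + 1.0)
    return RotationNull(observed=observed, null_enrichments=null,
                        empirical_p=emp_p, n_perm=n_perm, seed=seed)


def feature_enrichment(
    p_values: np.ndarray,
    feature_label_per_site: np.ndarray,
    t_step: float = 0.5,
) -> pd.DataFrame:
    """Per-feature enrichment of significant sites over the background mix.

    For feature ``f`` at threshold ``t``:
    ``[frac of sites with -log10 p >= t in f] / [frac of all sites in f]``.
    Returns a tidy frame (feature, threshold, enrichment, background_fraction);
    thresholds with no significant sites give NaN, features with zero
    background sites are excluded upstream by construction.
    """
    p = np.asarray(p_values, dtype=float)
    labels = np.asarray(feature_label_per_site)
    if len(p) != len(labels) or len(p) == 0:
        raise ValueError("p_values and labels must be equal-length and non-empty")
    ts = _curve_thresholds(p, t_step)
    logp = -np.log10(np.maximum(p, 1e-300))
    features = list(dict.fromkeys(labels.tolist()))
    n = len(p)
    rows = []
    for t in ts:
        sig = logp >= t
        n_sig = int(sig.sum())
        for feat in features:
            in_f = labels == feat
            bg = in_f.sum() / n
            enr = ((sig & in_f).sum() / n_sig) / bg if n_sig > 0 else np.nan
            rows.append({"feature": feat, "threshold": t, "enrichment": enr,
                         "background_fraction": bg, "n_significant": n_sig})
    return pd.DataFrame(rows)
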