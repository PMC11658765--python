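"""Competitive mapping of exogenous reads against a SNP-only pseudo-reference.

Candidate marker sequences are aligned (externally or with the built-in
pairwise aligner), gap columns removed, and reads assigned to the unique
best-scoring candidate by an exact-seed ungapped extension mapper.  Ties and
misses are left unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import revcomp

__all__ = [
    "PseudoReference",
    "AssignmentResult",
    "build_pseudo_reference",
    "assign_reads",
    "candidate_proportions",
    "align_pair",
]


@dataclass
class PseudoReference:
    """Equal-length, gap-free candidate sequences plus diagnostic columns."""

    names: list[str]
    sequences: list[str]
    diagnostic_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len({len(s) for s in self.sequences}) > 1:
            raise ValueError("pseudo-reference sequences must be equal length")
        if any("-" in s for s in self.sequences):
            raise ValueError("pseudo-reference must be gap-free")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclass
class AssignmentResult:
    counts: dict[str, int]
    unassigned: int
    read_hits: dict[str, str] = field(default_factory=dict)  # read id -> candidate

    @property
    def proportions(self) -> dict[str, float]:
        return candidate_proportions(self.counts)


def build_pseudo_reference(aligned: dict[str, str]) -> PseudoReference:
    """Drop every alignment column containing a gap in any candidate.

    Remaining columns are concatenated per candidate.  Diagnostic columns
    (0-based, post-drop coordinates) are those where at least two candidates
    differ.  Raises on unequal aligned lengths or fewer than two candidates.
    """
    if len(aligned) < 2:
        raise ValueError("need at least 2 candidates")
    names = list(aligned)
    seqs = [aligned[n].upper() for n in names]
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("aligned candidate sequences differ in length")
    arr = np.array([list(s) for s in seqs])
    keep = ~(arr == "-").any(axis=0)
    arr = arr[:, keep]
    out = ["".join(row) for row in arr]
    diag = [j for j in range(arr.shape[1]) if len(set(arr[:, j])) > 1]
    if not diag:
        warnings.warn("candidates are identical after gap removal: no diagnostic columns")
    return PseudoReference(names=names, sequences=out, diagnostic_columns=diag)


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        idx.setdefault(seq[i : i + k], []).append(i)
    return idx


def _best_score(read: str, ref: str, index: dict[str, list[int]], k: int,
                max_mismatch_rate: float) -> int | None:
    """Best ungapped-extension score (matches - mismatches) over seed hits."""
    best: int | None = None
    seen_offsets: set[int] = set()
    for i in range(len(read) - k + 1):
        for hit in index.get(read[i : i + k], ()):  # exact seed
            offset = hit - i
            if offset in seen_offsets:
                continue
            seen_offsets.add(offset)
            lo = max(0, -offset)
            hi = min(len(read), len(ref) - offset)
            aligned_len = hi - lo
            if aligned_len <= 0:
                continue
            mism = sum(read[j] != ref[j + offset] for j in range(lo, hi))
            if mism / aligned_len > max_mismatch_rate:
                continue
            score = (aligned_len - mism) - mism
            if best is None or score > best:
                best = score
    return best


def assign_reads(
    reads: dict[str, str],
    pseudo_ref: PseudoReference,
    seed_k: int = 25,
    max_mismatch_rate: float = 0.05,
) -> AssignmentResult:
    """Assign each read to the strictly best candidate, both strands searched.

    A read with no passing hit, or whose best score is tied between
    candidates, is unassigned (unique mappings only).
    """
    if not pseudo_ref.sequences:
        raise ValueError("empty pseudo-reference")
    indexes = [_kmer_index(s, seed_k) for s in pseudo_ref.sequences]
    counts = {n: 0 for n in pseudo_ref.names}
    read_hits: dict[str, str] = {}
    unassigned = 0
    for rid, read in reads.items():
        read = read.upper()
        rc = revcomp(read)
        scores: list[int | None] = []
        for ref, idx in zip(pseudo_ref.sequences, indexes):
            cands = [
                s for s in (
                    _best_score(read, ref, idx, seed_k, max_mismatch_rate),
                    _best_score(rc, ref, idx, seed_k, max_mismatch_rate),
                ) if s is not None
            ]
            scores.append(max(cands) if cands else None)
        valid = [(s, n) for s, n in zip(scores, pseudo_ref.names) if s is not None]
        if not valid:
            unassigned += 1
            continue
        best = max(s for s, _ in valid)
        winners = [n for s, n in valid if s == best]
        if len(winners) != 1:
            unassigned += 1
            continue
        counts[winners[0]] += 1
        read_hits[rid] = winners[0]
    return AssignmentResult(counts=counts, unassigned=unassigned, read_hits=read_hits)


def candidate_proportions(counts: dict[str, int]) -> dict[str, float]:
    """Per-candidate fraction of assigned reads."""
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative counts")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no assigned reads")
    return {n: c / total for n, c in counts.items()}


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global pairwise alignment with unit costs (match +1, mismatch/gap -1).

    Intended only for near-identical marker sequences where a full MSA tool
    is unnecessary.
    """
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    score[:, 0] = -np.arange(n + 1)
    score[0, :] = -np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(np.frombuffer(a[i - 1].encode(), dtype="S1")
                       == np.frombuffer(b.encode(), dtype="S1"), 1, -1)
        for j in range(1, m + 1):
            score[i, j] = max(
                score[i - 1, j - 1] + sub[j - 1],
                score[i - 1, j] - 1,
                score[i, j - 1] - 1,
            )
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else -1):
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] - 1:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))
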