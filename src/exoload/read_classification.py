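"""Partition read pairs by mapping behavior and clean host alignments.

A read *pair* is the classification unit.  Pairs with both mates unmapped in
the host alignment (flag-12 semantics) are exogenous candidates; host-mapped
pairs that also map confidently to a pest reference are ambiguous and are
blacklisted from the host alignment before variant calling.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field

from .formats_io import AlignmentRecord, iter_sam_lines, read_sam_minimal

__all__ = ["ReadClassification", "classify_sample", "count_exogenous_by_taxon",
           "blacklist_ambiguous", "pileup_base_counts", "naive_allele_dosage"]


@dataclass
class ReadClassification:
    """Disjoint partition of one sample's read pairs.

    target | ambiguous | exogenous | other covers every pair seen in the
    host SAM.  ``pest_hits`` maps each pest name to the set of pair ids with
    a confident primary hit in that pest's alignment.
    """

    sample_id: str
    target: set[str]
    ambiguous: set[str]
    exogenous: set[str]
    other: set[str]
    pest_hits: dict[str, set[str]] = field(default_factory=dict)
    dedup_total: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.target) + len(self.ambiguous) + len(self.exogenous) + len(self.other)


def _pair_mates(records: list[AlignmentRecord]) -> dict[str, list[AlignmentRecord]]:
    pairs: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for rec in records:
        pairs[rec.read_id].append(rec)
    return pairs


def classify_sample(
    host_sam: str | os.PathLike,
    pest_sams: dict[str, str | os.PathLike],
    mapq_min: int = 20,
    sample_id: str | None = None,
    dedup_total: int | None = None,
) -> ReadClassification:
    """Classify each host-SAM read pair as target/ambiguous/exogenous/other.

    Secondary and supplementary records are dropped before any rule is
    applied; records flagged secondary never count as mapping evidence.
    A pest hit requires a primary, mapped record with ``mapq >= mapq_min``.
    Raises ``ValueError`` if a pest SAM contains a read id absent from the
    host SAM (the read universes differ).
    """
    host_records = [r for r in read_sam_minimal(host_sam) if r.is_primary]
    host_pairs = _pair_mates(host_records)

    pest_hits: dict[str, set[str]] = {}
    for pest, path in pest_sams.items():
        hits: set[str] = set()
        for rec in read_sam_minimal(path):
            if rec.read_id not in host_pairs:
                raise ValueError(
                    f"read {rec.read_id!r} in pest SAM {pest!r} absent from host SAM"
                )
            if rec.is_primary and not rec.is_unmapped and rec.mapq >= mapq_min:
                hits.add(rec.read_id)
        pest_hits[pest] = hits
    any_pest = set().union(*pest_hits.values()) if pest_hits else set()

    target: set[str] = set()
    ambiguous: set[str] = set()
    exogenous: set[str] = set()
    other: set[str] = set()
    for rid, mates in host_pairs.items():
        n_mapped = sum(not m.is_unmapped for m in mates)
        if n_mapped == 0:
            exogenous.add(rid)
        elif rid in any_pest:
            ambiguous.add(rid)
        elif n_mapped == len(mates) and len(mates) >= 2:
            target.add(rid)
        elif len(mates) == 1 and n_mapped == 1:
            # unpaired single-end record treated as fully host-mapped
            target.add(rid)
        else:
            other.add(rid)

    return ReadClassification(
        sample_id=sample_id or os.path.basename(os.fspath(host_sam)),
        target=target, ambiguous=ambiguous, exogenous=exogenous, other=other,
        pest_hits=pest_hits,
        dedup_total=dedup_total if dedup_total is not None else len(host_pairs),
    )


def count_exogenous_by_taxon(
    classification: ReadClassification,
    pest_sams: dict[str, str | os.PathLike],
    mapq_min: int = 20,
    dedupe: bool = True,
) -> dict[str, int]:
    """Count exogenous pairs confidently mapped to each pest reference.

    Only pairs classified exogenous are counted; hits must be primary with
    ``mapq >= mapq_min``.  With ``dedupe``, pairs sharing the signature
    (ref, pos, flag) of both mates collapse to one.  A pair hitting two
    references counts once per reference (the multi-reference pairs are also
    reported under the ``"__multi__"`` key).
    """
    per_pest_pairs: dict[str, dict[str, list[tuple[str, int, int]]]] = {}
    for pest, path in pest_sams.items():
        sigs: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
        for rec in read_sam_minimal(path):
            if (rec.read_id in classification.exogenous and rec.is_primary
                    and not rec.is_unmapped and rec.mapq >= mapq_min):
                sigs[rec.read_id].append((rec.ref_name, rec.pos, rec.flag))
        per_pest_pairs[pest] = sigs

    counts: dict[str, int] = {}
    assigned: dict[str, set[str]] = {}
    for pest, sigs in per_pest_pairs.items():
        if dedupe:
            uniq = {tuple(sorted(v)) for v in sigs.values()}
            counts[pest] = len(uniq)
        else:
            counts[pest] = len(sigs)
        assigned[pest] = set(sigs)
    multi = set()
    names = list(assigned)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            multi |= assigned[a] & assigned[b]
    counts["__multi__"] = len(multi)
    return counts


def blacklist_ambiguous(
    host_sam: str | os.PathLike,
    classification: ReadClassification,
    out_path: str | os.PathLike,
) -> int:
    """Write the host SAM without any record of an ambiguous pair.

    Non-ambiguous lines are copied byte-identically.  Returns the number of
    alignment lines removed.
    """
    removed = 0
    with open(out_path, "w") as out:
        for is_header, rid, line in iter_sam_lines(host_sam):
            if not is_header and rid in classification.ambiguous:
                removed += 1
                continue
            out.write(line + "\n")
    return removed


def pileup_base_counts(
    host_sam: str | os.PathLike, chrom: str, pos: int
) -> dict[str, int]:
    """Base counts at a 1-based position from primary, fully-matched records.

    Only ungapped alignments (CIGAR ``<n>M``) contribute; enough for the
    spurious-variant demonstration on simulated alignments.
    """
    counts: dict[str, int] = defaultdict(int)
    for rec in read_sam_minimal(host_sam):
        if (rec.is_unmapped or not rec.is_primary or rec.ref_name != chrom
                or rec.seq == "*" or not rec.cigar.endswith("M")
                or not rec.cigar[:-1].isdigit()):
            continue
        offset = pos - rec.pos
        if 0 <= offset < len(rec.seq):
            counts[rec.seq[offset]] += 1
    return dict(counts)


def naive_allele_dosage(
    base_counts: dict[str, int],
    ref_base: str,
    alt_base: str,
    min_depth: int = 2,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> float:
    """Crude genotype call from an allele pileup: 0/1/2 dosage or NaN.

    Alt fraction below the het band is homozygous reference, above it
    homozygous alternate, inside heterozygous; insufficient depth is NaN.
    """
    n_ref = base_counts.get(ref_base, 0)
    n_alt = base_counts.get(alt_base, 0)
    depth = n_ref + n_alt
    if depth < min_depth:
        return float("nan")
    frac = n_alt / depth
    if frac < het_band[0]:
        return 0.0
    if frac > het_band[1]:
        return 2.0
    return 1.0
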