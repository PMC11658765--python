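"""Minimal, strict readers and writers for the text formats used throughout.

Internal coordinate convention: **0-based half-open** for all intervals and
methylation site positions.  SAM and VCF positions are 1-based only at the
parse/serialize boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pysam

__all__ = [
    "AlignmentRecord",
    "VariantTable",
    "IntervalSet",
    "UnionBed",
    "read_sam_minimal",
    "iter_sam_lines",
    "read_vcf_biallelic",
    "write_vcf",
    "read_unionbed",
    "write_unionbed",
    "read_intervals",
    "write_bed",
    "read_fasta",
]

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class AlignmentRecord:
    """One SAM alignment line, parsed at read level (no CIGAR arithmetic)."""

    read_id: str
    flag: int
    ref_name: str  # "*" when unmapped
    pos: int  # 1-based; meaningless when unmapped
    mapq: int
    cigar: str = "*"
    seq: str = "*"

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def mate_unmapped(self) -> bool:
        return bool(self.flag & FLAG_MATE_UNMAPPED)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_primary(self) -> bool:
        return not (self.is_secondary or self.is_supplementary)

    @property
    def is_read1(self) -> bool:
        return bool(self.flag & FLAG_READ1)


def read_sam_minimal(path: str | os.PathLike) -> Iterator[AlignmentRecord]:
    """Yield one :class:`AlignmentRecord` per alignment line of a text SAM.

    Header lines (``@``) are skipped.  Raises ``ValueError`` naming the line
    number on malformed input.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=11 SAM fields, got {len(fields)}"
                )
            try:
                flag = int(fields[1])
                pos = int(fields[3])
                mapq = int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer SAM field: {exc}") from None
            yield AlignmentRecord(
                read_id=fields[0], flag=flag, ref_name=fields[2],
                pos=pos, mapq=mapq, cigar=fields[5], seq=fields[9],
            )


def iter_sam_lines(path: str | os.PathLike) -> Iterator[tuple[bool, str, str]]:
    """Yield ``(is_header, read_id, raw_line)`` preserving lines byte-exactly."""
    with open(path) as fh:
        for line in fh:
            stripped = line.rstrip("\n")
            if stripped.startswith("@"):
                yield True, "", stripped
            elif stripped:
                yield False, stripped.split("\t", 1)[0], stripped


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence mapping."""
    seqs: dict[str, list[str]] = {}
    name: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is None:
                raise ValueError(f"{path}: sequence data before first FASTA header")
            else:
                seqs[name].append(line)
    return {n: "".join(parts) for n, parts in seqs.items()}


# ---------------------------------------------------------------------------
# variants


@dataclass
class VariantTable:
    """Biallelic variants with a samples x variants dosage matrix.

    Dosages are ``float`` with ``NaN`` for missing calls; non-missing values
    are 0, 1 or 2 copies of the ALT allele.
    """

    chrom: np.ndarray  # (m,) str
    pos: np.ndarray  # (m,) int, 1-based
    ref: np.ndarray  # (m,) str
    alt: np.ndarray  # (m,) str
    dosages: np.ndarray  # (n, m) float, NaN = missing
    samples: list[str]

    def __post_init__(self) -> None:
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.pos):
            raise ValueError("dosage matrix not aligned with variant arrays")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def take(self, idx: np.ndarray) -> "VariantTable":
        idx = np.asarray(idx)
        return VariantTable(
            chrom=self.chrom[idx], pos=self.pos[idx], ref=self.ref[idx],
            alt=self.alt[idx], dosages=self.dosages[:, idx], samples=list(self.samples),
        )


def read_vcf_biallelic(path: str | os.PathLike, max_missing: float = 0.1) -> VariantTable:
    """Read a VCF, keeping biallelic variants with missingness <= ``max_missing``.

    GT "0/1" (any phasing) -> 1, "1/1" -> 2, "./." -> NaN.  Multi-allelic
    sites are dropped.  Raises ``ValueError`` when the VCF carries no GT
    FORMAT field.
    """
    vf = pysam.VariantFile(os.fspath(path))
    if "GT" not in vf.header.formats:
        raise ValueError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vf.header.samples)
    n = len(samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        dos = np.full(n, np.nan)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            dos[i] = float(sum(gt))
        if np.isnan(dos).mean() > max_missing:
            continue
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        refs.append(rec.ref)
        alts.append(rec.alts[0])
        cols.append(dos)
    dosages = np.column_stack(cols) if cols else np.empty((n, 0))
    return VariantTable(
        chrom=np.asarray(chroms, dtype=object), pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object), alt=np.asarray(alts, dtype=object),
        dosages=dosages, samples=samples,
    )


def write_vcf(table: VariantTable, path: str | os.PathLike) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype columns."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in dict.fromkeys(table.chrom.tolist()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j in range(table.n_variants):
            gts = [
                gt_map.get(table.dosages[i, j], "./.")
                if not np.isnan(table.dosages[i, j]) else "./."
                for i in range(table.n_samples)
            ]
            fh.write(
                f"{table.chrom[j]}\t{table.pos[j]}\t.\t{table.ref[j]}\t{table.alt[j]}"
                "\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# intervals

FEATURE_CLASSES = ("gene", "CDS", "promoter", "TE", "intergenic")


@dataclass
class IntervalSet:
    """Genomic intervals, 0-based half-open, with a feature-class label."""

    chrom: np.ndarray  # (k,) str
    start: np.ndarray  # (k,) int
    end: np.ndarray  # (k,) int
    feature_class: np.ndarray  # (k,) str
    name: np.ndarray  # (k,) str

    def __post_init__(self) -> None:
        if np.any(self.start >= self.end):
            bad = int(np.argmax(self.start >= self.end))
            raise ValueError(
                f"interval {self.name[bad]} has start >= end "
                f"({self.start[bad]} >= {self.end[bad]})"
            )

    def __len__(self) -> int:
        return len(self.start)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, f), getattr(other, f))
            for f in ("chrom", "start", "end", "feature_class", "name")
        )


def read_intervals(path: str | os.PathLike, dialect: str = "bed") -> IntervalSet:
    """Read BED (0-based half-open) or GFF3 (1-based closed) into one convention.

    GFF3 ``start=s, end=e`` becomes ``(s-1, e)``.  Raises on ``end <= start``
    after normalization.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    classes: list[str] = []
    names: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "bed":
                if len(fields) < 3:
                    raise ValueError(f"{path}: line {lineno}: BED needs >=3 columns")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"iv{lineno}"
                fclass = fields[6] if len(fields) > 6 else (
                    fields[3] if len(fields) > 3 and fields[3] in FEATURE_CLASSES else "gene"
                )
            elif dialect == "gff3":
                if len(fields) < 9:
                    raise ValueError(f"{path}: line {lineno}: GFF3 needs 9 columns")
                chrom, fclass = fields[0], fields[2]
                start, end = int(fields[3]) - 1, int(fields[4])
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                name = attrs.get("ID", attrs.get("Name", f"iv{lineno}"))
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end <= start after normalization")
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            classes.append(fclass)
            names.append(name)
    return IntervalSet(
        chrom=np.asarray(chroms, dtype=object),
        start=np.asarray(starts, dtype=np.int64),
        end=np.asarray(ends, dtype=np.int64),
        feature_class=np.asarray(classes, dtype=object),
        name=np.asarray(names, dtype=object),
    )


def write_bed(intervals: IntervalSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i in range(len(intervals)):
            fh.write(
                f"{intervals.chrom[i]}\t{intervals.start[i]}\t{intervals.end[i]}"
                f"\t{intervals.name[i]}\t0\t.\t{intervals.feature_class[i]}\n"
            )


# ---------------------------------------------------------------------------
# unionbed

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class UnionBed:
    """Multi-sample methylation table: one row per (chrom, pos, context).

    ``fractions[r, i]`` is NaN iff ``coverage[r, i] == 0``.  Positions are
    0-based (single-base sites).
    """

    chrom: np.ndarray  # (r,) str
    pos: np.ndarray  # (r,) int, 0-based
    context: np.ndarray  # (r,) str in CONTEXTS
    fractions: np.ndarray  # (r, n) float in [0,1], NaN = no coverage
    coverage: np.ndarray  # (r, n) int >= 0
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        frac = self.fractions
        with np.errstate(invalid="ignore"):
            if np.any((frac < 0) | (frac > 1)):
                raise ValueError("methylation fraction outside [0, 1]")
        zero_cov = self.coverage == 0
        if np.any(zero_cov != np.isnan(frac)):
            raise ValueError("fraction must be missing iff coverage is 0")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return self.fractions.shape[1]

    def take(self, idx: np.ndarray) -> "UnionBed":
        idx = np.asarray(idx)
        return UnionBed(
            chrom=self.chrom[idx], pos=self.pos[idx], context=self.context[idx],
            fractions=self.fractions[idx], coverage=self.coverage[idx],
            samples=list(self.samples),
        )


def write_unionbed(ub: UnionBed, path: str | os.PathLike) -> None:
    """Columns: chrom, pos, context, then ``<sample>.frac``/``<sample>.cov`` pairs."""
    with open(path, "w") as fh:
        header = ["chrom", "pos", "context"]
        for s in ub.samples:
            header += [f"{s}.frac", f"{s}.cov"]
        fh.write("\t".join(header) + "\n")
        for r in range(ub.n_sites):
            row = [str(ub.chrom[r]), str(ub.pos[r]), str(ub.context[r])]
            for i in range(ub.n_samples):
                cov = int(ub.coverage[r, i])
                frac = "NA" if cov == 0 else f"{ub.fractions[r, i]:.6g}"
                row += [frac, str(cov)]
            fh.write("\t".join(row) + "\n")


def read_unionbed(path: str | os.PathLike) -> UnionBed:
    """Read the unionbed dialect written by :func:`write_unionbed`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 5 or header[:3] != ["chrom", "pos", "context"]:
            raise ValueError(f"{path}: not a unionbed header")
        sample_cols = header[3:]
        if len(sample_cols) % 2 != 0:
            raise ValueError(f"{path}: odd number of sample columns")
        samples = [c[:-5] for c in sample_cols[::2]]
        n = len(samples)
        chroms, poss, ctxs = [], [], []
        fracs: list[list[float]] = []
        covs: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3 + 2 * n:
                raise ValueError(
                    f"{path}: line {lineno}: ragged row ({len(fields)} fields)"
                )
            chroms.append(fields[0])
            poss.append(int(fields[1]))
            ctxs.append(fields[2])
            frow, crow = [], []
            for i in range(n):
                fv, cv = fields[3 + 2 * i], int(fields[4 + 2 * i])
                f = np.nan if fv == "NA" else float(fv)
                if not np.isnan(f) and not 0.0 <= f <= 1.0:
                    raise ValueError(f"{path}: line {lineno}: fraction {f} outside [0, 1]")
                frow.append(f)
                crow.append(cv)
            fracs.append(frow)
            covs.append(crow)
        return UnionBed(
            chrom=np.asarray(chroms, dtype=object),
            pos=np.asarray(poss, dtype=np.int64),
            context=np.asarray(ctxs, dtype=object),
            fractions=np.asarray(fracs, dtype=float).reshape(-1, n),
            coverage=np.asarray(covs, dtype=np.int64).reshape(-1, n),
            samples=samples,
        )
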