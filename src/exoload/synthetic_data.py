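"""Synthetic toy datasets with recorded ground truth.

Generators for host/pest genomes sharing a conserved block, population
structured genotypes, depth-dependent pest read counts, paired-end alignment
files, and methylation matrices with load-linked differential regions.
Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .formats_io import UnionBed, VariantTable

__all__ = [
    "GenomeTruth",
    "LoadTruth",
    "AlignmentTruth",
    "MethylationTruth",
    "make_genomes",
    "make_population",
    "simulate_loads",
    "simulate_alignments",
    "simulate_methylation",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _seq_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# genomes


@dataclass
class GenomeTruth:
    """Coordinates of the conserved block shared between host and pests."""

    host_name: str
    host_len: int
    block_start: int  # 0-based half-open, in host coordinates
    block_end: int
    pest_block_start: dict[str, int]  # block start within each pest contig
    divergent_sites: dict[str, np.ndarray]  # block-relative offsets mutated per pest
    seed: int


def make_genomes(
    host_len: int,
    pest_specs: dict[str, int],
    conserved_len: int,
    divergence: float,
    seed: int,
) -> tuple[dict[str, str], GenomeTruth]:
    """Random host contig plus pest contigs each carrying a mutated copy of
    one host block.

    Each block base mutates independently with probability ``divergence``
    (always to a different base).  Returns sequences keyed by contig name
    (host is ``"host"``) and the truth record.
    """
    if conserved_len >= host_len:
        raise ValueError(f"conserved_len {conserved_len} must be < host_len {host_len}")
    if not 0.0 <= divergence <= 0.2:
        raise ValueError("divergence must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    host = _random_seq(rng, host_len)
    block_start = int(rng.integers(0, host_len - conserved_len + 1))
    block = host[block_start : block_start + conserved_len]

    seqs = {"host": _seq_str(host)}
    pest_block_start: dict[str, int] = {}
    divergent: dict[str, np.ndarray] = {}
    for name, plen in pest_specs.items():
        if plen < conserved_len:
            raise ValueError(f"pest {name} shorter than conserved block")
        pest = _random_seq(rng, plen)
        pstart = int(rng.integers(0, plen - conserved_len + 1))
        mut_block = block.copy()
        hits = np.flatnonzero(rng.random(conserved_len) < divergence)
        for h in hits:
            choices = _BASES[_BASES != mut_block[h]]
            mut_block[h] = choices[rng.integers(0, len(choices))]
        pest[pstart : pstart + conserved_len] = mut_block
        seqs[name] = _seq_str(pest)
        pest_block_start[name] = pstart
        divergent[name] = hits
    truth = GenomeTruth(
        host_name="host", host_len=host_len, block_start=block_start,
        block_end=block_start + conserved_len, pest_block_start=pest_block_start,
        divergent_sites=divergent, seed=seed,
    )
    return seqs, truth


# ---------------------------------------------------------------------------
# population genotypes


def make_population(
    n_samples: int,
    n_pops: int,
    fst: float,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    n_chroms: int = 2,
    spacing: int = 1000,
    family_size: int = 1,
    family_fst: float = 0.3,
) -> tuple[VariantTable, np.ndarray]:
    """Balding-Nichols style structured genotypes.

    Ancestral allele frequencies are uniform on ``maf_range``; each
    population draws its frequency from ``Beta(p(1-F)/F, (1-p)(1-F)/F)``;
    genotypes are ``Binomial(2, p_pop)``.  ``fst=0`` collapses to a single
    panmictic population.  Variants are laid out position-sorted over
    ``n_chroms`` chromosomes.

    With ``family_size > 1`` a second Balding-Nichols layer (parameter
    ``family_fst``) is nested within populations: samples come in related
    groups of ``family_size``, which spreads the kinship spectrum beyond
    the handful of population eigenvalues — needed for well-identified
    variance components at moderate n.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if n_pops < 1:
        raise ValueError("n_pops must be >= 1")
    if not 0.0 <= fst < 1.0:
        raise ValueError("fst must be in [0, 1)")
    rng = np.random.default_rng(seed)
    pop_labels = np.array([f"pop{i % n_pops}" for i in range(n_samples)], dtype=object)
    p_anc = rng.uniform(maf_range[0], maf_range[1], size=n_variants)
    dosages = np.empty((n_samples, n_variants))
    for k in range(n_pops):
        idx = np.flatnonzero(pop_labels == f"pop{k}")
        if fst > 0:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            p_pop = rng.beta(a, b)
        else:
            p_pop = p_anc
        if family_size <= 1:
            dosages[idx] = rng.binomial(2, p_pop, size=(len(idx), n_variants)).astype(float)
        else:
            for f0 in range(0, len(idx), family_size):
                fam = idx[f0 : f0 + family_size]
                pf = np.clip(p_pop, 1e-4, 1 - 1e-4)
                af = pf * (1 - family_fst) / family_fst
                bf = (1 - pf) * (1 - family_fst) / family_fst
                p_fam = rng.beta(af, bf)
                dosages[fam] = rng.binomial(
                    2, p_fam, size=(len(fam), n_variants)).astype(float)

    per_chrom = int(np.ceil(n_variants / n_chroms))
    chrom = np.array(
        [f"Chr{1 + j // per_chrom}" for j in range(n_variants)], dtype=object
    )
    pos = np.array(
        [spacing * (1 + j % per_chrom) for j in range(n_variants)], dtype=np.int64
    )
    refs = np.array(["A"] * n_variants, dtype=object)
    alts = np.array(["T"] * n_variants, dtype=object)
    table = VariantTable(
        chrom=chrom, pos=pos, ref=refs, alt=alts, dosages=dosages,
        samples=[f"s{i:03d}" for i in range(n_samples)],
    )
    return table, pop_labels


# ---------------------------------------------------------------------------
# loads


@dataclass
class LoadTruth:
    """Generative record for per-sample pest loads."""

    h2_true: float
    causal_idx: np.ndarray
    beta: np.ndarray
    liability: np.ndarray  # l_i
    genetic_value: np.ndarray  # standardized genetic component of l_i
    pop_labels: np.ndarray | None
    fraction: np.ndarray  # f_i, true per-sample pest fraction
    seed: int


def simulate_loads(
    genotypes: VariantTable,
    n_causal: int,
    h2: float,
    pop_effect_sd: float = 0.0,
    depth_lognorm_params: tuple[float, float] = (np.log(50_000.0), 0.3),
    seed: int = 0,
    pop_labels: np.ndarray | None = None,
    link: str = "exp",
    f_scale: float = 0.01,
    f_max: float = 0.5,
    genetic_model: str = "causal",
    kinship: np.ndarray | None = None,
    standardize: str = "model",
) -> tuple[np.ndarray, np.ndarray, LoadTruth]:
    """Draw counts ``c_i ~ Poisson(f_i d_i)`` with a heritable liability.

    Liability ``l_i = genetic_i + pop_i + e_i``.  With
    ``standardize="model"`` the component *model* variances are
    ``(h2, pop_effect_sd^2, 1 - h2 - pop_effect_sd^2)`` — the convention
    under which single-component REML heritability (kinship scaled to mean
    diagonal 1) targets ``h2``.  ``standardize="sample"`` rescales each
    component to its exact in-sample variance instead; note that in-sample
    rescaling of a kinship-drawn genetic value shifts the generative target
    away from the REML ``h2`` when the kinship spectrum is dominated by a
    few eigenvalues.

    The load-to-fraction link is ``f_i = min(f_scale * exp(l_i), f_max)``
    by default ("exp" keeps log-fraction affine in liability); a shifted
    softplus link ("softplus") is available for heavier left tails.

    ``genetic_model="causal"`` builds the genetic value from ``n_causal``
    variant effects (empirically scaled in either mode — its model variance
    is genotype-dependent); ``"kinship"`` draws it as a Gaussian with
    covariance proportional to ``kinship``, validating the REML estimator
    under its own model.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must be in [0, 1]")
    if n_causal > genotypes.n_variants:
        raise ValueError("n_causal exceeds number of variants")
    if pop_effect_sd**2 > 1.0 - h2 + 1e-12:
        raise ValueError("pop_effect_sd^2 must not exceed 1 - h2")
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples

    if standardize not in ("model", "sample"):
        raise ValueError(f"unknown standardize mode {standardize!r}")

    def _sample_scale(x: np.ndarray, sd: float) -> np.ndarray:
        x = x - x.mean()
        s = x.std()
        return x * (sd / s) if s > 0 and sd > 0 else np.zeros_like(x)

    if genetic_model == "kinship":
        if kinship is None:
            raise ValueError("kinship matrix required for genetic_model='kinship'")
        w, v = np.linalg.eigh(kinship)
        w = np.clip(w, 0.0, None)
        u = v @ (np.sqrt(w) * rng.standard_normal(n))
        causal_idx = np.empty(0, dtype=np.int64)
        beta = np.empty(0)
        u = u * np.sqrt(h2) if standardize == "model" else _sample_scale(u, np.sqrt(h2))
    elif genetic_model == "causal":
        causal_idx = np.sort(rng.choice(genotypes.n_variants, size=n_causal, replace=False))
        beta = rng.standard_normal(n_causal)
        g = np.nan_to_num(genotypes.dosages[:, causal_idx])
        # causal model variance is genotype-dependent: always sample-scaled
        u = _sample_scale(g @ beta, np.sqrt(h2))
    else:
        raise ValueError(f"unknown genetic_model {genetic_model!r}")

    if pop_labels is not None and pop_effect_sd > 0:
        uniq = np.unique(pop_labels)
        eff = rng.standard_normal(len(uniq)) * pop_effect_sd
        pop_term = np.array([eff[list(uniq).index(p)] for p in pop_labels], dtype=float)
        if standardize == "sample":
            pop_term = _sample_scale(pop_term, pop_effect_sd)
    else:
        pop_term = np.zeros(n)
    e_sd = np.sqrt(max(1.0 - h2 - pop_effect_sd**2, 0.0))
    e = rng.standard_normal(n) * e_sd
    if standardize == "sample":
        e = _sample_scale(e, e_sd)
    liability = u + pop_term + e

    if link == "exp":
        fraction = np.minimum(f_scale * np.exp(liability), f_max)
    elif link == "softplus":
        fraction = np.minimum(f_scale * np.log1p(np.exp(liability + 1.0)), f_max)
    else:
        raise ValueError(f"unknown link {link!r}")

    mu, sigma = depth_lognorm_params
    depths = np.maximum(rng.lognormal(mu, sigma, size=n), 1.0)
    counts = rng.poisson(fraction * depths).astype(np.int64)
    truth = LoadTruth(
        h2_true=h2, causal_idx=causal_idx, beta=beta, liability=liability,
        genetic_value=u, pop_labels=pop_labels, fraction=fraction, seed=seed,
    )
    return counts, depths, truth


# ---------------------------------------------------------------------------
# alignments


@dataclass
class AlignmentTruth:
    """Per-sample truth partition of simulated read pairs."""

    labels: dict[str, dict[str, str]]  # sample -> read_id -> target|ambiguous|exogenous
    pest_counts: dict[str, dict[str, int]]  # sample -> pest -> exogenous pair count
    contaminant_pairs: dict[str, int]  # sample -> pest-origin pairs mapped into host
    host_sam: dict[str, str]  # sample -> path
    pest_sams: dict[str, dict[str, str]]  # sample -> pest -> path
    seed: int


def _sam_header(name: str, length: int) -> str:
    return f"@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:{name}\tLN:{length}\n"


def _pair_lines(
    qname: str, ref: str, p1: int, p2: int, seq1: str, seq2: str, mapq: int
) -> list[str]:
    """Proper paired-end SAM lines, 1-based positions, ungapped."""
    rl1, rl2 = len(seq1), len(seq2)
    tlen = p2 + rl2 - p1
    return [
        f"{qname}\t99\t{ref}\t{p1}\t{mapq}\t{rl1}M\t=\t{p2}\t{tlen}\t{seq1}\t*",
        f"{qname}\t147\t{ref}\t{p2}\t{mapq}\t{rl2}M\t=\t{p1}\t{-tlen}\t{seq2}\t*",
    ]


def _unmapped_pair_lines(qname: str, seq1: str, seq2: str) -> list[str]:
    return [
        f"{qname}\t77\t*\t0\t0\t*\t*\t0\t0\t{seq1}\t*",
        f"{qname}\t141\t*\t0\t0\t*\t*\t0\t0\t{seq2}\t*",
    ]


def simulate_alignments(
    genomes: dict[str, str],
    genome_truth: GenomeTruth,
    sample_pest_counts: dict[str, dict[str, int]],
    ambiguous_fraction: float,
    out_dir: str | os.PathLike,
    seed: int = 0,
    n_host_pairs: int = 200,
    contamination_rate: float = 0.0,
    read_len: int = 100,
    frag_len: int = 300,
) -> AlignmentTruth:
    """Emit per-sample host and pest SAM files with truth labels.

    Three pair types are generated: host-only pairs (mapped in the host SAM
    only), pest-only pairs (flag-12 unmapped in the host SAM, mapped with
    mapq 60 in their pest SAM), and conserved-block pairs mapped in *both*
    the host SAM and a pest SAM (the ambiguous class).  With
    ``contamination_rate > 0``, additional pest-origin block pairs
    (``~Poisson(rate * pest count)``) are mapped into the host alignment
    carrying the pest's divergent bases — the source of spurious variants.
    """
    if not 0.0 <= ambiguous_fraction <= 1.0:
        raise ValueError("ambiguous_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    host_seq = genomes[genome_truth.host_name]
    pests = list(genome_truth.pest_block_start)
    block_len = genome_truth.block_end - genome_truth.block_start

    labels: dict[str, dict[str, str]] = {}
    pest_counts_out: dict[str, dict[str, int]] = {}
    contam_out: dict[str, int] = {}
    host_paths: dict[str, str] = {}
    pest_paths: dict[str, dict[str, str]] = {}

    def _draw_pair(seq: str, lo: int, hi: int) -> tuple[int, str, str]:
        """Fragment start (0-based) within [lo, hi - frag_len]."""
        start = int(rng.integers(lo, max(lo + 1, hi - frag_len)))
        s1 = seq[start : start + read_len]
        s2 = seq[start + frag_len - read_len : start + frag_len]
        return start, s1, s2

    for sample, pcounts in sample_pest_counts.items():
        lab: dict[str, str] = {}
        host_lines: list[str] = []
        pest_lines: dict[str, list[str]] = {p: [] for p in pests}
        ridx = 0

        n_amb = rng.binomial(n_host_pairs, ambiguous_fraction)
        n_plain = n_host_pairs - n_amb
        # host-only pairs, anywhere on the host contig
        for _ in range(n_plain):
            qname = f"{sample}:r{ridx:06d}"
            ridx += 1
            start, s1, s2 = _draw_pair(host_seq, 0, len(host_seq))
            host_lines += _pair_lines(qname, "host", start + 1,
                                      start + frag_len - read_len + 1, s1, s2, 60)
            lab[qname] = "target"
        # host-origin conserved-block pairs: map in host and in one pest
        for _ in range(n_amb):
            qname = f"{sample}:r{ridx:06d}"
            ridx += 1
            pest = pests[int(rng.integers(0, len(pests)))]
            off, s1, s2 = _draw_pair(
                host_seq, genome_truth.block_start,
                genome_truth.block_end,
            )
            host_lines += _pair_lines(qname, "host", off + 1,
                                      off + frag_len - read_len + 1, s1, s2, 60)
            poff = genome_truth.pest_block_start[pest] + (off - genome_truth.block_start)
            pest_lines[pest] += _pair_lines(qname, pest, poff + 1,
                                            poff + frag_len - read_len + 1, s1, s2, 60)
            lab[qname] = "ambiguous"
        # pest-only (exogenous) pairs, drawn outside the pest's block copy
        true_counts: dict[str, int] = {}
        for pest, c in pcounts.items():
            pseq = genomes[pest]
            pstart = genome_truth.pest_block_start[pest]
            true_counts[pest] = int(c)
            for _ in range(int(c)):
                qname = f"{sample}:r{ridx:06d}"
                ridx += 1
                # sample from the longer of the two non-block segments
                if pstart > len(pseq) - (pstart + block_len):
                    lo, hi = 0, pstart
                else:
                    lo, hi = pstart + block_len, len(pseq)
                if hi - lo < frag_len:
                    lo, hi = 0, len(pseq)
                off, s1, s2 = _draw_pair(pseq, lo, hi)
                host_lines += _unmapped_pair_lines(qname, s1, s2)
                pest_lines[pest] += _pair_lines(qname, pest, off + 1,
                                                off + frag_len - read_len + 1, s1, s2, 60)
                lab[qname] = "exogenous"
        # pest-origin contamination mapped into the host conserved block
        n_contam = 0
        if contamination_rate > 0:
            total_pest = sum(pcounts.values())
            n_contam = int(rng.poisson(contamination_rate * total_pest))
            for _ in range(n_contam):
                qname = f"{sample}:r{ridx:06d}"
                ridx += 1
                pest = pests[int(rng.integers(0, len(pests)))]
                pseq = genomes[pest]
                pstart = genome_truth.pest_block_start[pest]
                off, s1, s2 = _draw_pair(pseq, pstart, pstart + block_len)
                hoff = genome_truth.block_start + (off - pstart)
                host_lines += _pair_lines(qname, "host", hoff + 1,
                                          hoff + frag_len - read_len + 1, s1, s2, 60)
                pest_lines[pest] += _pair_lines(qname, pest, off + 1,
                                                off + frag_len - read_len + 1, s1, s2, 60)
                lab[qname] = "ambiguous"

        host_path = os.path.join(out_dir, f"{sample}.host.sam")
        with open(host_path, "w") as fh:
            fh.write(_sam_header("host", len(host_seq)))
            fh.write("\n".join(host_lines) + "\n")
        ppaths: dict[str, str] = {}
        for pest in pests:
            ppath = os.path.join(out_dir, f"{sample}.{pest}.sam")
            with open(ppath, "w") as fh:
                fh.write(_sam_header(pest, len(genomes[pest])))
                if pest_lines[pest]:
                    fh.write("\n".join(pest_lines[pest]) + "\n")
            ppaths[pest] = ppath
        labels[sample] = lab
        pest_counts_out[sample] = true_counts
        contam_out[sample] = n_contam
        host_paths[sample] = host_path
        pest_paths[sample] = ppaths

    return AlignmentTruth(
        labels=labels, pest_counts=pest_counts_out, contaminant_pairs=contam_out,
        host_sam=host_paths, pest_sams=pest_paths, seed=seed,
    )


def write_truth_manifest(truth: AlignmentTruth, path: str | os.PathLike) -> None:
    """Tab-separated truth labels: sample, read_id, label."""
    with open(path, "w") as fh:
        fh.write(f"#seed\t{truth.seed}\n")
        fh.write("sample\tread_id\tlabel\n")
        for sample in sorted(truth.labels):
            for rid in sorted(truth.labels[sample]):
                fh.write(f"{sample}\t{rid}\t{truth.labels[sample][rid]}\n")


# ---------------------------------------------------------------------------
# methylation


@dataclass
class MethylationTruth:
    """Spiked differential-region coordinates and effect sizes."""

    spiked: list[tuple[str, int, int, str]]  # (chrom, start, end, context) 0-based half-open
    dmr_effect: float
    load_z: np.ndarray
    seed: int
    site_means: dict[str, np.ndarray] = field(default_factory=dict)


_CONTEXT_BETA = {"CG": (7.0, 3.0), "CHG": (4.0, 6.0), "CHH": (1.5, 12.0)}


def simulate_methylation(
    n_sites_per_context: int,
    samples: list[str],
    loads: np.ndarray,
    n_dmr: int,
    dmr_effect: float,
    coverage_nb_params: tuple[float, float] = (10.0, 0.4),
    seed: int = 0,
    contexts: tuple[str, ...] = ("CG", "CHG", "CHH"),
    chrom: str = "Chr1",
    dmr_n_sites: int = 10,
    site_noise_sd: float = 0.05,
) -> tuple[UnionBed, MethylationTruth]:
    """Methylation matrix with ``n_dmr`` spiked load-linked regions per context.

    Baseline per-site methylation is Beta-distributed with context-specific
    means (CG high, CHH low).  Within spiked intervals the per-sample true
    fraction shifts by ``dmr_effect * z_i`` where ``z`` is the standardized
    load (negative effect = hypomethylation at high load).  Coverage is
    negative binomial; observed fractions are binomial draws given coverage.
    """
    if not -1.0 <= dmr_effect <= 1.0:
        raise ValueError("dmr_effect must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    loads = np.asarray(loads, dtype=float)
    n = len(samples)
    if len(loads) != n:
        raise ValueError("loads length must match samples")
    sd = loads.std()
    z = (loads - loads.mean()) / sd if sd > 0 else np.zeros(n)

    all_chrom, all_pos, all_ctx = [], [], []
    all_frac, all_cov = [], []
    spiked: list[tuple[str, int, int, str]] = []
    site_means: dict[str, np.ndarray] = {}
    r_nb, p_nb = coverage_nb_params

    for ctx in contexts:
        gaps = rng.integers(30, 120, size=n_sites_per_context)
        pos = np.cumsum(gaps) + 1000
        a, b = _CONTEXT_BETA[ctx]
        means = rng.beta(a, b, size=n_sites_per_context)
        effect = np.zeros(n_sites_per_context, dtype=bool)
        # spike n_dmr disjoint runs of consecutive sites
        if n_dmr > 0:
            max_start = n_sites_per_context - dmr_n_sites
            starts: list[int] = []
            tries = 0
            while len(starts) < n_dmr and tries < 1000:
                s = int(rng.integers(0, max_start))
                if all(abs(s - t) >= 2 * dmr_n_sites for t in starts):
                    starts.append(s)
                tries += 1
            for s in sorted(starts):
                effect[s : s + dmr_n_sites] = True
                spiked.append((chrom, int(pos[s]), int(pos[s + dmr_n_sites - 1]) + 1, ctx))
                # keep baseline mid-range so the shift is visible either way
                means[s : s + dmr_n_sites] = rng.uniform(0.4, 0.6, size=dmr_n_sites)

        true_frac = np.clip(
            means[:, None]
            + np.where(effect[:, None], dmr_effect * z[None, :], 0.0)
            + rng.normal(0.0, site_noise_sd, size=(n_sites_per_context, n)),
            0.0, 1.0,
        )
        cov = rng.negative_binomial(r_nb, p_nb, size=(n_sites_per_context, n))
        meth_reads = rng.binomial(cov, true_frac)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(cov > 0, meth_reads / np.maximum(cov, 1), np.nan)
        all_chrom += [chrom] * n_sites_per_context
        all_pos.append(pos)
        all_ctx += [ctx] * n_sites_per_context
        all_frac.append(frac)
        all_cov.append(cov)
        site_means[ctx] = means

    ub = UnionBed(
        chrom=np.asarray(all_chrom, dtype=object),
        pos=np.concatenate(all_pos).astype(np.int64),
        context=np.asarray(all_ctx, dtype=object),
        fractions=np.vstack(all_frac),
        coverage=np.vstack(all_cov).astype(np.int64),
        samples=list(samples),
    )
    truth = MethylationTruth(
        spiked=spiked, dmr_effect=dmr_effect, load_z=z, seed=seed, site_means=site_means
    )
    return ub, truth
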