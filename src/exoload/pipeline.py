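"""End-to-end orchestration: simulate -> classify -> quantify -> gwa/ewa ->
dmr -> enrich, driven by a validated configuration mapping.

A single global seed fans out to per-stage seeds by stable hashing of stage
names, so inserting a stage does not shift the random streams of the others.
Every produced file is listed in a manifest with its content hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import association, enrichment, genotypes, load_phenotypes, methylation
from . import read_classification as rc
from . import synthetic_data as synth
from .formats_io import read_intervals, read_unionbed, read_vcf_biallelic

logger = logging.getLogger("exoload")

STAGE_ORDER = ["simulate", "classify", "quantify", "heritability",
               "gwa", "dmr", "ewa", "enrich"]

# every key accepted by the config schema, per stage
_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "out_dir", "stages"},
    "simulate": {"n_samples", "n_pops", "fst", "n_variants", "n_causal", "h2",
                 "pop_effect_sd", "host_len", "conserved_len", "divergence",
                 "pests", "ambiguous_fraction", "n_host_pairs",
                 "contamination_rate", "n_sites_per_context", "n_dmr",
                 "dmr_effect", "contexts"},
    "classify": {"mapq_min"},
    "quantify": set(),
    "heritability": {"min_maf"},
    "gwa": {"min_maf", "mode", "alpha"},
    "dmr": {"n_extreme", "min_cov", "seed_diff", "max_gap", "min_sites", "fdr"},
    "ewa": {"min_cov", "presence", "min_diff", "min_diff_samples"},
    "enrich": {"window", "n_perm", "t_step"},
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: stage-name hash mixed with the global seed."""
    h = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return (int(global_seed) * 1_000_003 + h) % (2**31 - 1)


def validate_config(config: dict) -> dict:
    """Reject unknown keys anywhere in the config; fill stage defaults."""
    unknown = set(config) - _SCHEMA[""] - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages", STAGE_ORDER)
    for st in stages:
        if st not in STAGE_ORDER:
            raise ValueError(f"unknown stage {st!r}")
        extra = set(config.get(st, {}) or {}) - _SCHEMA[st]
        if extra:
            raise ValueError(f"unknown keys in stage {st!r}: {sorted(extra)}")
    out = dict(config)
    out.setdefault("seed", 0)
    out.setdefault("out_dir", "exoload_run")
    out["stages"] = list(stages)
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest mapping ``stage -> {path: sha256}``; also written
    to ``<out_dir>/manifest.json``.  Raises when a stage's upstream artifact
    is missing, naming the stage to run first.
    """
    cfg = validate_config(config)
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict[str, dict[str, str]] = {}
    logger.info("run: seed=%d out_dir=%s stages=%s", seed, out_dir, cfg["stages"])
    for st in cfg["stages"]:
        params = cfg.get(st, {}) or {}
        logger.info("stage %s: params=%s seed=%d", st, params, stage_seed(seed, st))

    def _require(stage: str, path: str) -> str:
        if not os.path.exists(path):
            raise FileNotFoundError(
                f"missing artifact {path!r}: run stage {stage!r} first")
        return path

    stages = [s for s in STAGE_ORDER if s in cfg["stages"]]
    for st in stages:
        p = cfg.get(st, {}) or {}
        outputs: dict[str, str] = {}
        if st == "simulate":
            outputs = _stage_simulate(p, out_dir, stage_seed(seed, st))
        elif st == "classify":
            _require("simulate", os.path.join(out_dir, "sim", "samples.tsv"))
            outputs = _stage_classify(p, out_dir)
        elif st == "quantify":
            _require("classify", os.path.join(out_dir, "counts.tsv"))
            outputs = _stage_quantify(out_dir)
        elif st == "heritability":
            _require("quantify", os.path.join(out_dir, "pheno.tsv"))
            _require("simulate", os.path.join(out_dir, "sim", "variants.vcf"))
            outputs = _stage_heritability(p, out_dir)
        elif st == "gwa":
            _require("quantify", os.path.join(out_dir, "pheno.tsv"))
            outputs = _stage_gwa(p, out_dir)
        elif st == "dmr":
            _require("quantify", os.path.join(out_dir, "pheno.tsv"))
            _require("simulate", os.path.join(out_dir, "sim", "methylation.unionbed"))
            outputs = _stage_dmr(p, out_dir)
        elif st == "ewa":
            _require("dmr", os.path.join(out_dir, "dmrs.bed"))
            outputs = _stage_ewa(p, out_dir)
        elif st == "enrich":
            _require("gwa", os.path.join(out_dir, "gwa.tsv"))
            outputs = _stage_enrich(p, out_dir, stage_seed(seed, st))
        manifest[st] = {path: _sha256(path) for path in sorted(outputs.values())}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(p: dict, out_dir: str, seed: int) -> dict[str, str]:
    sim_dir = os.path.join(out_dir, "sim")
    os.makedirs(sim_dir, exist_ok=True)
    n_samples = p.get("n_samples", 60)
    pests = p.get("pests", {"aphid": 6000, "mildew": 6000})
    genomes, gtruth = synth.make_genomes(
        host_len=p.get("host_len", 20_000), pest_specs=pests,
        conserved_len=p.get("conserved_len", 2000),
        divergence=p.get("divergence", 0.05), seed=seed,
    )
    synth.write_fasta(genomes, os.path.join(sim_dir, "genomes.fasta"))
    table, pops = synth.make_population(
        n_samples=n_samples, n_pops=p.get("n_pops", 2), fst=p.get("fst", 0.1),
        n_variants=p.get("n_variants", 500), seed=seed + 1,
    )
    from .formats_io import write_vcf
    write_vcf(table, os.path.join(sim_dir, "variants.vcf"))
    counts, depths, ltruth = synth.simulate_loads(
        table, n_causal=p.get("n_causal", 50), h2=p.get("h2", 0.4),
        pop_effect_sd=p.get("pop_effect_sd", 0.2), seed=seed + 2,
        pop_labels=pops, depth_lognorm_params=(np.log(2000.0), 0.4),
        f_scale=0.02,
    )
    samples = table.samples
    atruth = synth.simulate_alignments(
        genomes, gtruth,
        {s: {pest: int(counts[i]) // len(pests) for pest in pests}
         for i, s in enumerate(samples)},
        ambiguous_fraction=p.get("ambiguous_fraction", 0.05),
        out_dir=os.path.join(sim_dir, "sams"), seed=seed + 3,
        n_host_pairs=p.get("n_host_pairs", 150),
        contamination_rate=p.get("contamination_rate", 0.0),
    )
    synth.write_truth_manifest(atruth, os.path.join(sim_dir, "truth_labels.tsv"))
    loads0 = load_phenotypes.normalize_load(counts, depths, samples).residual
    ub, mtruth = synth.simulate_methylation(
        n_sites_per_context=p.get("n_sites_per_context", 600), samples=samples,
        loads=loads0, n_dmr=p.get("n_dmr", 3), dmr_effect=p.get("dmr_effect", -0.15),
        seed=seed + 4, contexts=tuple(p.get("contexts", ("CG",))),
    )
    from .formats_io import write_unionbed
    write_unionbed(ub, os.path.join(sim_dir, "methylation.unionbed"))
    meta = pd.DataFrame({"sample": samples, "population": pops,
                         "dedup_total": depths.astype(int),
                         "true_count": counts})
    meta.to_csv(os.path.join(sim_dir, "samples.tsv"), sep="\t", index=False)
    # candidate genes: intervals around a third of the causal variants
    cand_rows = []
    for k, j in enumerate(ltruth.causal_idx[::3]):
        pos0 = int(table.pos[j]) - 1
        cand_rows.append((table.chrom[j], max(pos0 - 500, 0), pos0 + 500, f"cand{k}"))
    with open(os.path.join(sim_dir, "candidates.bed"), "w") as fh:
        for c, s, e, n in cand_rows:
            fh.write(f"{c}\t{s}\t{e}\t{n}\n")
    paths = {
        "genomes": os.path.join(sim_dir, "genomes.fasta"),
        "vcf": os.path.join(sim_dir, "variants.vcf"),
        "truth": os.path.join(sim_dir, "truth_labels.tsv"),
        "unionbed": os.path.join(sim_dir, "methylation.unionbed"),
        "samples": os.path.join(sim_dir, "samples.tsv"),
        "candidates": os.path.join(sim_dir, "candidates.bed"),
    }
    return paths


def _read_meta(out_dir: str) -> pd.DataFrame:
    return pd.read_csv(os.path.join(out_dir, "sim", "samples.tsv"), sep="\t")


def _stage_classify(p: dict, out_dir: str) -> dict[str, str]:
    meta = _read_meta(out_dir)
    sam_dir = os.path.join(out_dir, "sim", "sams")
    rows = []
    for _, row in meta.iterrows():
        s = row["sample"]
        host = os.path.join(sam_dir, f"{s}.host.sam")
        pest_sams = {
            fn.split(".")[1]: os.path.join(sam_dir, fn)
            for fn in sorted(os.listdir(sam_dir))
            if fn.startswith(f"{s}.") and not fn.endswith(".host.sam")
            and fn.endswith(".sam")
        }
        cls = rc.classify_sample(host, pest_sams, mapq_min=p.get("mapq_min", 20),
                                 sample_id=s, dedup_total=int(row["dedup_total"]))
        taxon_counts = rc.count_exogenous_by_taxon(cls, pest_sams,
                                                   mapq_min=p.get("mapq_min", 20))
        for taxon, cnt in taxon_counts.items():
            if taxon == "__multi__":
                continue
            rows.append({"sample": s, "taxon": taxon, "raw_count": cnt,
                         "dedup_total": cls.dedup_total,
                         "n_target": len(cls.target), "n_ambiguous": len(cls.ambiguous),
                         "n_exogenous": len(cls.exogenous), "n_other": len(cls.other)})
        rc.blacklist_ambiguous(host, cls, os.path.join(sam_dir, f"{s}.host.clean.sam"))
    out = os.path.join(out_dir, "counts.tsv")
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return {"counts": out}


def _stage_quantify(out_dir: str) -> dict[str, str]:
    counts = pd.read_csv(os.path.join(out_dir, "counts.tsv"), sep="\t")
    frames = []
    for taxon, sub in counts.groupby("taxon"):
        pheno = load_phenotypes.normalize_load(
            sub["raw_count"].to_numpy(), sub["dedup_total"].to_numpy(),
            sub["sample"].tolist(), taxon=str(taxon),
        )
        frames.append(pd.DataFrame({
            "sample": pheno.sample_ids, "taxon": taxon,
            "raw_count": sub["raw_count"].to_numpy(),
            "dedup_total": sub["dedup_total"].to_numpy(),
            "residual": pheno.residual,
        }))
    out = os.path.join(out_dir, "pheno.tsv")
    pd.concat(frames).to_csv(out, sep="\t", index=False)
    return {"pheno": out}


def _load_pheno_kinship(p: dict, out_dir: str):
    pheno = pd.read_csv(os.path.join(out_dir, "pheno.tsv"), sep="\t")
    table = read_vcf_biallelic(os.path.join(out_dir, "sim", "variants.vcf"))
    table = genotypes.maf_filter(table, p.get("min_maf", 0.04))
    K = genotypes.scale_kinship(genotypes.ibs_kinship(table))
    return pheno, table, K


def _stage_heritability(p: dict, out_dir: str) -> dict[str, str]:
    pheno, table, K = _load_pheno_kinship(p, out_dir)
    rows = []
    for taxon, sub in pheno.groupby("taxon"):
        sub = sub.set_index("sample").loc[table.samples]
        est = load_phenotypes.snp_heritability(sub["residual"].to_numpy(), K)
        rows.append({"taxon": taxon, "h2": est.h2, "ci_low": est.ci_low,
                     "ci_high": est.ci_high, "boundary": est.boundary})
    out = os.path.join(out_dir, "heritability.tsv")
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return {"heritability": out}


def _stage_gwa(p: dict, out_dir: str) -> dict[str, str]:
    pheno, table, K = _load_pheno_kinship(p, out_dir)
    pruned = genotypes.ld_prune(table)
    gw_thr, sugg = association.significance_thresholds(len(pruned), p.get("alpha", 0.05))
    frames = []
    for taxon, sub in pheno.groupby("taxon"):
        sub = sub.set_index("sample").loc[table.samples]
        y = sub["residual"].to_numpy()
        null = association.fit_null_lmm(y, K)
        res = association.lmm_scan(null, y, table.dosages, mode=p.get("mode", "p3d"),
                                   chrom=table.chrom, pos=table.pos)
        res.insert(0, "taxon", taxon)
        frames.append(res)
    out = os.path.join(out_dir, "gwa.tsv")
    df = pd.concat(frames)
    df.attrs["genomewide_threshold"] = gw_thr
    df.to_csv(out, sep="\t", index=False)
    thr_path = os.path.join(out_dir, "gwa_thresholds.json")
    with open(thr_path, "w") as fh:
        json.dump({"genomewide_p": gw_thr, "suggestive_p": sugg,
                   "n_unlinked": int(len(pruned))}, fh)
    return {"gwa": out, "thresholds": thr_path}


def _stage_dmr(p: dict, out_dir: str) -> dict[str, str]:
    pheno = pd.read_csv(os.path.join(out_dir, "pheno.tsv"), sep="\t")
    ub = read_unionbed(os.path.join(out_dir, "sim", "methylation.unionbed"))
    taxon = sorted(pheno["taxon"].unique())[0]
    sub = pheno[pheno["taxon"] == taxon].set_index("sample").loc[ub.samples]
    n_extreme = p.get("n_extreme", max(5, len(ub.samples) // 4))
    high, low = methylation.select_extreme_samples(
        sub["residual"].to_numpy(), list(sub.index), n=n_extreme)
    dmrs = methylation.call_dmrs(
        ub, high, low, min_cov=p.get("min_cov", 4),
        seed_diff=p.get("seed_diff", 0.1), max_gap=p.get("max_gap", 300),
        min_sites=p.get("min_sites", 5), fdr=p.get("fdr", 0.2))
    out = os.path.join(out_dir, "dmrs.bed")
    methylation.dmrs_to_bed_frame(dmrs).to_csv(out, sep="\t", index=False, header=False)
    return {"dmrs": out}


def _stage_ewa(p: dict, out_dir: str) -> dict[str, str]:
    pheno = pd.read_csv(os.path.join(out_dir, "pheno.tsv"), sep="\t")
    ub = read_unionbed(os.path.join(out_dir, "sim", "methylation.unionbed"))
    ub = methylation.filter_union(
        ub, min_cov=p.get("min_cov", 4), presence=p.get("presence", 0.8),
        min_diff=p.get("min_diff", 0.05),
        min_diff_samples=p.get("min_diff_samples", 2))
    dmr_bed = pd.read_csv(os.path.join(out_dir, "dmrs.bed"), sep="\t", header=None)
    dmrs = [methylation.DMR(chrom=str(r[0]), start=int(r[1]), end=int(r[2]),
                            context=str(r[3]), n_sites=int(r[7]), delta=float(r[6]),
                            p=0.0, q=10.0 ** -float(r[4]), direction=str(r[8]))
            for r in dmr_bed.itertuples(index=False)] if len(dmr_bed) else []
    sites, bonf = methylation.ewa_sites(ub, dmrs)
    taxon = sorted(pheno["taxon"].unique())[0]
    sub = pheno[pheno["taxon"] == taxon].set_index("sample").loc[ub.samples]
    y = sub["residual"].to_numpy()
    table = read_vcf_biallelic(os.path.join(out_dir, "sim", "variants.vcf"))
    K = genotypes.scale_kinship(genotypes.ibs_kinship(genotypes.maf_filter(table, 0.04)))
    out = os.path.join(out_dir, "ewa.tsv")
    if sites.n_sites == 0:
        pd.DataFrame(columns=["chrom", "pos", "beta", "se", "p"]).to_csv(
            out, sep="\t", index=False)
        return {"ewa": out}
    X = sites.fractions.T.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    null = association.fit_null_lmm(y, K)
    res = association.lmm_scan(null, y, X, mode="p3d", chrom=sites.chrom, pos=sites.pos)
    res["bonferroni_p"] = bonf
    res.to_csv(out, sep="\t", index=False)
    return {"ewa": out}


def _stage_enrich(p: dict, out_dir: str, seed: int) -> dict[str, str]:
    gwa = pd.read_csv(os.path.join(out_dir, "gwa.tsv"), sep="\t")
    with open(os.path.join(out_dir, "gwa_thresholds.json")) as fh:
        thr = json.load(fh)
    cand = read_intervals(os.path.join(out_dir, "sim", "candidates.bed"), "bed")
    taxon = sorted(gwa["taxon"].unique())[0]
    sub = gwa[(gwa["taxon"] == taxon) & np.isfinite(gwa["p"])]
    flags = enrichment.mark_candidates(sub["chrom"].to_numpy(), sub["pos"].to_numpy(),
                                       cand, window=p.get("window", 20_000))
    if flags.sum() in (0, len(flags)):
        report = {"status": "degenerate candidate background"}
    else:
        curve = enrichment.enrichment_curve(sub["p"].to_numpy(), flags,
                                            t_step=p.get("t_step", 0.5))
        rot = enrichment.rotation_test(
            sub["p"].to_numpy(), flags, sub["chrom"].to_numpy(),
            test_threshold=-np.log10(thr["genomewide_p"]),
            n_perm=p.get("n_perm", 1000), seed=seed)
        curve.to_frame().to_csv(os.path.join(out_dir, "enrichment_curve.tsv"),
                                sep="\t", index=False)
        report = {"observed": rot.observed, "empirical_p": rot.empirical_p,
                  "n_perm": rot.n_perm, "seed": rot.seed}
    out = os.path.join(out_dir, "enrichment.json")
    with open(out, "w") as fh:
        json.dump(report, fh, indent=2)
    return {"enrichment": out}
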