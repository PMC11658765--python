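# exoload

Turn the non-target ("exogenous") reads of a host whole-genome sequencing
experiment into quantitative pest/microbe load phenotypes, and analyze those
phenotypes genetically and epigenetically:

- **Read classification** — partition each sample's read pairs by mapping
  behavior into *target* / *ambiguous* / *exogenous* / *other*, count
  exogenous pairs per pest reference (primary alignments, MAPQ ≥ 20,
  optional duplicate collapse), and blacklist ambiguous pairs from the host
  alignment before variant calling (they create spurious variants in
  conserved regions).
- **Species assignment** — competitive mapping of exogenous reads against a
  SNP-only pseudo-reference built from aligned candidate marker sequences;
  unique best hit wins, ties stay unassigned.
- **Load phenotypes** — residuals of `log(count+1) ~ log(deduplicated
  reads)`; population variance decomposition, Welch two-group contrast, and
  single-component REML SNP heritability with profile-likelihood CI.
- **Genotypes** — MAF filtering, sliding-window LD pruning, IBS kinship.
- **Association** — linear mixed-model scans (GWA on dosages, EWA on
  methylation fractions) in the kinship eigenbasis, `exact` or `p3d` modes,
  Bonferroni threshold over LD-pruned variant counts.
- **Enrichment** — a priori candidate enrichment across −log10 p thresholds
  with an FDR upper bound and a chromosome-local rotation permutation null;
  per-feature enrichment curves for EWA.
- **Methylation** — unionbed filtering, extreme-group selection, a
  transparent seed–merge–test DMR caller (Mann–Whitney + BH), DMR feature
  densities, and EWA site preparation.
- **Synthetic data** — generators for host/pest genomes sharing a conserved
  block, population- and family-structured genotypes, depth-dependent
  Poisson read counts with configurable heritability, paired-end SAM files,
  and methylation matrices with load-linked differential regions — all with
  recorded ground truth.

## CLI

Every stage is a subcommand of `exoload`:

```sh
exoload simulate --seed 1 --out-dir demo          # synthetic demo dataset
exoload classify --host-sam s.host.sam --pest-sam aphid=s.aphid.sam \
    --mapq-min 20 --out counts.tsv --blacklist s.clean.sam
exoload speciesid --msa aligned.fasta --reads exo.fasta --k 25 --out props.tsv
exoload quantify --counts counts.tsv --out pheno.tsv
exoload heritability --pheno pheno.tsv --vcf variants.vcf --out h2.tsv
exoload gwa --vcf variants.vcf --pheno pheno.tsv --mode p3d --out gwa.tsv
exoload ewa --unionbed meth.unionbed --vcf-kinship variants.vcf \
    --pheno pheno.tsv --out ewa.tsv
exoload dmr --unionbed meth.unionbed --pheno pheno.tsv --n 20 --out dmrs.bed
exoload enrich --results gwa.tsv --candidates candidates.bed \
    --test-threshold 4.0 --out enrichment.tsv
```

`exoload run --config config.yaml [--seed N]` executes configured stages in
dependency order (simulate → classify → quantify → heritability → gwa →
dmr → ewa → enrich), writes every output with a content hash into
`manifest.json`, and rejects configs with unknown keys.  A single global
seed fans out to per-stage seeds by stable hashing of stage names.

## Conventions

All internal intervals and methylation positions are 0-based half-open;
SAM/VCF positions are 1-based at the parse/serialize boundary only.
Kinship matrices are rescaled to mean diagonal 1, so heritability is
`lambda / (lambda + 1)` with `lambda = sigma_g^2 / sigma_e^2`.
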