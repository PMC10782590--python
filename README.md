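# protwas

A proteome-wide association study (PWAS) toolkit: build and validate
genetic prediction models of plasma protein abundance from cis + trans
SNPs, then test genetically predicted protein levels against GWAS
summary statistics with an LD-reference-panel Z statistic

```
Z = w'z / sqrt(w' Σ w)
```

where `w` are the trained per-SNP weights, `z` the GWAS z-scores of
those SNPs, and `Σ` their correlation matrix estimated from a reference
panel. A synthetic-data module generates LD-structured genotypes,
covariates, protein abundances with planted heritability, and GWAS
z-vectors, so the entire pipeline is exercisable (and testable) at desk
scale without access to the original cohort data.

## Pipeline stages

| stage | module | what it does |
|---|---|---|
| simulate | `protwas.simulate` | genotypes (blockwise AR(1) LD, calibrated dosage correlation), covariates, proteome with planted cis/trans h², GWAS z ~ MVN(μ, Σ), QC-violation planting |
| qc | `protwas.qc` | per-SNP MAF / missingness / exact Hardy-Weinberg test; filters: info ≥ 0.7, MAF ≥ 0.05, HWE p ≥ 5e-6, missing < 5%, reference-panel membership |
| prep | `protwas.prep` | log transform, OLS adjustment for age/sex/processing duration/3 PCs, Blom rank-inverse-normal transform |
| train | `protwas.train` | seed SNPs (cis BH FDR < 0.05 within 1 Mb of the TSS, trans p ≤ 5e-8), ±100 kb merged windows on a pseudo chromosome, four learners (top1 / LASSO / elastic net / BLUP-as-ridge), 5-fold out-of-fold R², retention gate R² ≥ 0.01 |
| validate | `protwas.validate` | apply weights to an independent cohort (allele flips handled), gate on predicted-vs-measured r ≥ 0.1 |
| assoc | `protwas.assoc` | harmonize model/sumstats alleles, skip models with >50% missing SNPs, panel LD with PSD repair, Z statistic, Bonferroni over tested models |
| report | `protwas.report` | counts and direction split, risk-SNP distance annotation, consistency checks of the packaged 69-row association fixture |

## CLI

Every stage is a subcommand of `protwas`:

```bash
protwas simulate --config sim.yaml --out data/ --seed 1
protwas qc       --geno data/train --out qc/
protwas prep     --proteins data/train.proteins.tsv --covars data/train.covariates.tsv --out pheno1.tsv
protwas train    --geno data/train --pheno pheno1.tsv --gene-meta data/aptamers.tsv \
                 --kept-snps qc/kept_snps.tsv --out models/ --seed 1
protwas validate --geno2 data/valid --pheno2 pheno2.tsv --models models/ --out validated/
protwas assoc    --models validated/ --sumstats data/sumstats.null.tsv --panel data/ref --out assoc.tsv
protwas report   --assoc assoc.tsv --out report/
```

`sim.yaml` holds a `SimConfig` mapping (`n_train`, `n_valid`, `n_ref`,
`n_snps`, `n_blocks`, `ld_rho`, `maf_range`, `seed`) plus an optional
`truth:` list of planted protein architectures; see
`tests/test_io_cli.py` for a complete example.

Genotypes use a plain-text two-file dialect: `<prefix>.dosage.tsv`
(sample_id + one column per SNP, dosages in [0, 2], empty = missing) and
`<prefix>.snps.tsv` (snp_id, chrom, pos, a1, a2, info, ...). Summary
statistics are 4-column TSV (`SNP A1 A2 Z`). Weight models are one TSV +
JSON sidecar per aptamer plus an index TSV.

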