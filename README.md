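# vprotqtl

Quantitative genetics of cell-to-cell protein expression variability, from
single-cell flow-cytometry events to variability-QTLs and causal inference:

1. **synthgen** — synthetic cohorts with known ground truth: LD-structured
   genotypes (haplotype copying model), MZ/DZ twin sharing, latent traits
   with additive-genetic / common-environment / unique-environment (A/C/E)
   components plus SNP effects, single-cell event tables with doublets, and
   two-sample MR summary statistics.
2. **cytometry** — event QC (< 1000 events per sample rejected),
   biexponential transform (defaults reproduce asinh), landmark
   (density-peak) normalization across individuals, rectangular gating,
   FSC-A/FSC-H doublet removal, cell volume = log10(FSC-A³), volume-normalized
   log10 fluorescence, and per-(individual, cell type, protein) summaries
   (n ≥ 100 cells, mean, CV²).
3. **variability** — the mean-adjusted variability statistic η_res: local
   polynomial (tricube LOESS) fit of log10(CV²) on log10(mean) across
   individuals; η_res is the standardized residual (mean 0, variance 1).
4. **twinvc** — twin ACE variance decomposition by maximum likelihood with
   path-coefficient (Cholesky-style) parametrization, 75%-of-pairs bootstrap
   SEs, and zygosity-permutation p-values using the formula
   p = 1 − (#{test > null} + 1)/(n_perm + 1).
5. **qtlmap** — variant QC (MAF < 1%, HWE p ≤ 1e-50), GCTA-style GRMs with
   leave-one-chromosome-out complements, REML linear mixed-model scans
   (MLMA-style per-SNP GLS), 1 Mb cis windows with beta-approximated
   permutation p-values, BH FDR, greedy LD clumping (250 kb, r² > 0.5),
   strand-aware TSS annotation, MAF-matched TSS-proximity enrichment, and
   down-sampling sensitivity analysis.
6. **mr** — two-sample Mendelian randomization: instrument selection
   (200 kb window, p ≤ 1e-5), allele harmonization, Wald ratio with
   delta-method SE, profile-ML estimator, MR-Egger, Cochran's Q, and an
   FDR-controlled screen across (exposure, outcome) pairs.
7. **cli / pipeline** — end-to-end orchestration with manifests and
   per-stage seeds.

## Test

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` contains the binding statistical contracts
(parameter recovery, oracle equivalences, calibration under the null,
clumping vs brute force, MR consistency).

## CLI

Run the bundled demo end to end (simulated cohort → η_res → ACE → QTL scan →
MR) into a run directory:

```bash
vprotqtl run --out runs/demo            # bundled demo config
vprotqtl run --config my_config.yaml --out runs/custom
```

Individual stages:

```bash
vprotqtl simulate --out runs/sim
vprotqtl cytometry --events-dir runs/sim/simulated/events --out runs/cyto \
    --min-events 1000 --min-cells 100 --doublet-band 0.8:1.3
vprotqtl variability --summaries runs/cyto/trait_summaries.tsv --out runs/var
vprotqtl heritability --matrix runs/var/eta_res.tsv \
    --pedigree runs/sim/simulated/pedigree.tsv --out runs/her
vprotqtl qtl scan --traits runs/var/eta_res.tsv \
    --genotypes runs/sim/simulated/genotypes.tsv --out assoc.tsv
vprotqtl qtl clump --assoc assoc.tsv \
    --genotypes runs/sim/simulated/genotypes.tsv --out clumps.tsv
vprotqtl qtl annotate --snps snps.tsv \
    --gene-models runs/sim/simulated/gene_models.tsv --out annotated.tsv
vprotqtl mr --exposure exposure.tsv --outcome outcome.tsv --out mr.tsv
```

Inputs are plain text: per-individual event CSVs (FSC-A, FSC-H, SSC-A plus
protein channels), genotype dosage TSV or VCF, pedigree TSV
(individual/family/zygosity), gene-model TSV (gene_id, chrom, start, end,
tss, strand), and summary-statistic TSVs for MR.

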