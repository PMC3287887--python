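# ebcoalesce

Gene-based rare-variant association in two stages:

1. **Supervised coalescing** — within each gene, SNPs are collapsed into a
   single gene-level marker by penalized orthogonal-components regression:
   sequential components with sparse unit-norm loadings, where sparsity comes
   from empirical Bayes posterior-median thresholding under a
   point-mass/Laplace mixture prior.  Markers are trained on one phenotype
   replicate and applied to the others to avoid overfitting.
2. **Empirical Bayes variable selection (EBVS)** — the gene markers plus
   environmental covariates (Age/Sex/Smoke style) enter a large-p, small-n
   linear model.  Coefficients are updated coordinate-wise as posterior
   medians; the mixture weight, Laplace scale and noise scale are refreshed
   from their full conditional modes each sweep, until convergence.  The
   posterior median is an exact-zero thresholding rule, so the fit is a
   genuine selection.

Selected genes are back-mapped to SNPs through the nonzero coalescing
coefficients, and results are aggregated across replicates into selection
frequencies, effect-size means/SDs, and false-positive/false-negative rates
(both a discovery/FDP convention and the classical convention are reported).

A bundled generator produces GAW17-like studies (fixed genotypes, ~13% common
SNPs, per-gene blocks, replicate phenotypes with known causal truth) so the
whole pipeline is testable without restricted data.

## Layout

| module | contents |
|---|---|
| `ebcoalesce.eb_threshold` | mixture prior, marginal density, posterior median/threshold, conditional modes |
| `ebcoalesce.ebvs` | design standardization, iterative sparse fit, OLS refit |
| `ebcoalesce.pocre` | per-gene component extraction, gene markers, study-wide coalescing |
| `ebcoalesce.pipeline` | study container, per-replicate runs, rates, frequency tables |
| `ebcoalesce.synthdata` | simulation configs, `gaw17_mini` preset, genotype/phenotype generators |
| `ebcoalesce.io_cli` | PLINK-`.raw`-style and TSV readers/writers, YAML config, CLI |

## CLI

```sh
# simulate a study (plain-text bundle: genotypes.raw, gene_map.tsv, ...)
ebcoalesce simulate --preset gaw17_mini --seed 7 --out study/

# stage by stage
ebcoalesce coalesce --study study/ --training-replicate 0 --out models.tsv
ebcoalesce select   --study study/ --models models.tsv --replicate 1 --out sel.tsv
ebcoalesce evaluate --study study/ --selections sel.tsv --min-frequency 1 --out reports/

# or everything at once
ebcoalesce pipeline --preset gaw17_mini --seed 7 --out reports/
```

Reports written by `evaluate`/`pipeline` (all TSV):

- `predictor_frequency.tsv` — predictor, kind, mean, sd, frequency (mean/SD of
  OLS estimates over the replicates where the predictor was selected).
- `snp_frequency.tsv` — snp_id, chrom, pos, gene_id, frequency, is_causal
  (frequency-by-position data).
- `rates_by_replicate.tsv` / `rate_summary.tsv` — gene- and SNP-level FPR/FNR
  per replicate and their mean ± SD, under both conventions.
- `selections.tsv` — replicate, item_type (gene|covariate|snp), item_id,
  estimate.

Exit codes: 0 success, 2 validation/usage error, 1 runtime failure.

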