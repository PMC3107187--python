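# epifit

Epistasis statistics and phenotype-to-fitness map fitting for single- and
double-mutant growth-rate assays.

Given replicate-level fitness measurements (doublings per hour) of a wild
type, a panel of single mutants, and double mutants built from pairs of
them, the package:

- reduces replicates to per-genotype means, SEs and effects relative to
  the wild type (`epifit.assay_io`);
- computes deviations from additivity (`epsilon = s_ij - s_i - s_j`),
  background-specific effects, mean-based epistasis categories, and
  one-sided Welch test batteries with Bonferroni correction
  (`epifit.epistasis_stats`);
- fits a unimodal gamma-shaped phenotype-to-fitness curve in which
  single-mutant phenotypes are latent and double-mutant phenotypes are
  additive, by iterative phenotype imputation plus nonlinear least
  squares, with SSE/SST/R²/F diagnostics (`epifit.gamma_map`,
  `epifit.gamma_fit`);
- performs leave-one-double-out prediction with significance flags on the
  number of residual SDs (`epifit.cross_validation`);
- simulates deviation-from-additivity distributions under the fitted
  gamma model and under a 2-D geometric model with a Gaussian fitness
  map, and compares the models by histogram-density likelihood and AIC
  (`epifit.landscape_sim`);
- generates synthetic replicate datasets with the exact statistical
  structure the fit assumes, and bundles the ID11 bacteriophage
  single/double-mutant dataset (`epifit.synthetic_data`).

## Command line

All subcommands take one data source: `--input FILE` (CSV/TSV with
columns `genotype,replicate,fitness`), `--fixture` (the bundled ID11
dataset), or `--synthetic` (the model-based generator; `--noise`,
`--seed`).

```sh
epifit stats   --fixture --out epsilon_table.csv       # per-pair epsilon table
epifit fit     --fixture --out fit_report.json         # gamma-map fit + diagnostics
epifit loo     --fixture --out loo_table.csv           # leave-one-out predictions
epifit compare --fixture --seed 1 --out compare.json   # AIC model comparison
epifit run     --fixture --seed 1 --out artifacts/     # full pipeline + manifest
```

`epifit run` writes the epsilon table, fit report, LOO table, model
comparison and a manifest; a failed stage leaves partial outputs plus a
`FAILED` marker and exits non-zero. Outputs are bit-reproducible for a
given seed.

## Notes on the model

The curve is `f(z) = shift + height * g(z)/g(z*)` with
`g(z) = z^(shape-1) exp(-z/scale)` and mode `z* = (shape-1)*scale`, so
the peak equals `shift + height` exactly. The phenotype scale is
arbitrary (a rescaling of `scale` absorbs it), so `scale` is fixed at 1
during fitting unless `--free-scale` is passed. The fitness shift is not
estimated by least squares: it is pinned to the largest integer strictly
below every observed fitness. Residual degrees of freedom count the
imputed phenotypes plus the three free curve parameters.
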