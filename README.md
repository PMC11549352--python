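# agequant

Quantitative pipelines for the statistical procedures used in cellular-ageing
assays, each exercised against seeded synthetic data with known ground truth:

| Module | What it does |
| --- | --- |
| `agequant.synth` | Seeded generators for every input type below, with ground-truth sidecars |
| `agequant.cls` | CFU concentration by Poisson maximum likelihood from serial-dilution counts, relative-viability lifespan curves, Kaplan–Meier / log-rank survival comparison |
| `agequant.growth` | Logistic / Gompertz / Richards growth-curve fitting (capacity A, max rate μ, lag λ), AIC model selection, ANOVA + Tukey HSD / Dunnett comparisons |
| `agequant.sga` | Colony-array genetic-interaction scoring: artefact filtering, moving-median + row/column spatial normalisation, 250-kb linkage exclusion, clipped log10 GIS, sign-consistent consensus calls |
| `agequant.polysome` | Polysome-profile segmentation and AUC metrics (P/M ratio, P+M ribosome content), per-fraction mRNA distribution from qPCR Ct values |
| `agequant.chirp` | RNA-pulldown protein enrichment: presence filter, impute-with-1, variance-stabilising normalisation, empirical-Bayes moderated t, BH FDR, stringent bound-protein calls |
| `agequant.qpcr` | Comparative-Ct (ΔΔCt) relative quantification with reference-gene normalisation |

## CLI

```sh
# synthetic datasets (TSV/CSV + truth sidecar); parameters via YAML config
agequant simulate colony_screen --seed 1 --out out/screen
agequant simulate lifespans --config params.yaml --seed 1 --out out/ls

# score a colony screen from a size table
agequant sga score --plates out/screen/colony_sizes.tsv --out scores.tsv

# polysome-profile metrics and fraction distributions
agequant polysome quant --trace trace.csv --out metrics.tsv
agequant polysome fractions --ct fraction_ct.tsv --out percents.tsv
```

## Notes

- Every generator in `agequant.synth` is deterministic given its seed and
  never touches global random state.
- Ground truth is returned/written separately from the simulated data, so
  downstream stages cannot see it.
- GIS values are clipped to [−2, +2]; hit calls need `|GIS| ≥ 0.1` with a
  consistent sign in ≥ 2 repeats by default.
- Undetected qPCR fractions contribute zero signal (no imputed Ct cap).
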