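# actimr

Two-sample Mendelian randomisation (MR) toolkit for GWAS summary
statistics, built around the accelerometer-measured physical-activity →
cancer-risk analysis design:

- **summary_stats** — summary-statistic data model, delimited-text I/O,
  allele harmonisation (strand/palindrome aware), and two packaged
  physical-activity instruments (`doherty5`, 5 genome-wide-significant
  SNPs; `klimentidis10`, 10-SNP extended instrument).
- **instrument_strength** — per-variant R² (simple `2pq·β²` and
  scale-invariant forms), F-statistics, binary-outcome power
  (non-centrality approximation) and minimum-detectable odds ratio.
- **mr_estimators** — per-SNP Wald ratios; IVW (fixed / multiplicative
  random effects / auto), MR-Egger with intercept-based pleiotropy test,
  weighted median with parametric-bootstrap SE; Cochran's Q / I²;
  subgroup-heterogeneity contrasts; SD rescaling (1 SD = 8.14
  milli-gravities of mean acceleration).
- **pleiotropy** — MR-PRESSO (global, outlier, distortion tests),
  leave-one-SNP-out, SNP-set exclusion (adiposity list included),
  multivariable IVW adjusting for a second exposure such as BMI.
- **simulate** — seeded generator of two-sample summary data with known
  causal effect and configurable pleiotropy regimes (balanced,
  directional, outlier, correlated/InSIDE-violating, BMI-mediated).
- **pipeline** — full analysis grid over instruments × outcomes,
  Benjamini–Hochberg FDR across the IVW family, report/plot-data export,
  YAML-configurable CLI.

## CLI

```sh
actimr strength --instrument klimentidis10
actimr power --n-total 228951 --cases 122977 --r2 0.002
actimr simulate --scenario causal --seed 7 --out sim/
actimr estimate --exposure sim/exposure.tsv --outcome sim/outcome.tsv \
    --method ivw,egger,wmedian --effects auto --seed 1
actimr presso --exposure sim/exposure.tsv --outcome sim/outcome.tsv --seed 1
actimr loo --exposure sim/exposure.tsv --outcome sim/outcome.tsv
actimr mvmr --file multi.tsv          # beta_pa/se_pa, beta_bmi/se_bmi, beta_out/se_out
actimr run --config analysis.yaml     # full grid + FDR + report files
```

An `analysis.yaml` looks like:

```yaml
instruments:
  - name: doherty5          # built-in; or name + path + exposure_unit
  - name: klimentidis10
outcomes:
  - label: breast_overall
    path: data/breast.tsv
methods: [ivw, egger, wmedian]
effects: auto
seed: 1
out_dir: out/
```

Outputs: `report.json` (full precision), `table1.csv` (2-significant-figure
summary), per-cell `ratios_<instrument>_<outcome>.tsv`, plus plot-data
export (`forest`, `funnel`, `scatter`, `loo`) via
`actimr.export_plot_data`.

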