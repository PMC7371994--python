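# tsmr

Two-sample Mendelian randomization (MR) from GWAS summary statistics:
instrument selection and allele harmonization, inverse-variance weighted
(IVW), weighted-median, and MR-Egger estimation, Cochran's Q heterogeneity,
Steiger directionality filtering, leave-one-out sensitivity analysis, a
Bonferroni pleiotropy screen, and a synthetic summary-statistic simulator
with known ground truth for calibration studies.

The package ships fixture tables for a published four-phenotype stroke →
Alzheimer's disease analysis (any stroke, any ischemic stroke, large-artery
stroke, cardio-embolic stroke, plus a SNP × trait pleiotropy p-value matrix)
so the entire pipeline runs and is verified offline.

## Layout

| Module | Purpose |
| --- | --- |
| `tsmr.summary_io` | `SnpAssociation` / `SummaryDataset` data model, OR→beta and CI→SE conversions, delimited-table I/O, packaged fixtures |
| `tsmr.harmonize` | allele orientation (incl. strand complements), palindromic detection, proxy substitution, the selection pipeline with a reasoned drop log |
| `tsmr.mr_estimators` | Wald ratios, IVW (fixed / multiplicative random effects), weighted median with seeded parametric-bootstrap SE, MR-Egger with intercept test, Cochran's Q |
| `tsmr.steiger` | p/n → variance explained, the directionality Z-test, and filtering |
| `tsmr.sensitivity` | leave-one-out re-estimation, single-SNP scans, Bonferroni pleiotropy screen |
| `tsmr.synthetic_data` | scenario simulator (balanced/directional pleiotropy, invalid-majority) and Monte-Carlo calibration (type-I error, bias, coverage) |
| `tsmr.study_runner` | `AnalysisConfig` / YAML configs, end-to-end `run_analysis`, the fixture reproduction suite, and the CLI |

Two estimator conventions are supported, mirroring the two software stacks
commonly used for such analyses. The primary arm uses simple
inverse-variance weighted-median weights `(beta_exp/se_out)^2`, normal
p-values, and an IVW variance model that is fixed-effects below four
instruments and multiplicative random-effects otherwise. The Steiger arm
uses full delta-method weighted-median weights, t-based Egger p-values, and
random-effects IVW at every instrument count. Both are plain options
(`weighting=`, `use_t=`, `variance_model=`).

## CLI

```sh
# run the packaged fixture suite and compare against the published values
tsmr reproduce --seed 0 --out results/

# run one configured analysis (fixture keys or file paths as sources)
tsmr run -c analysis.yaml --out results/

# simulate a paired exposure/outcome dataset with known truth
tsmr simulate --n-snps 50 --theta 0.1 --seed 7 --out scratch/sim

# write a documented config template for the reverse-direction analysis
tsmr reverse-template --out reverse.yaml
```

A minimal `analysis.yaml`:

```yaml
label: AIS
exposure_source: AIS:exposure      # or a path to a TSV
outcome_source: AIS:outcome
rules:
  exposure_p_max: 5.0e-8
  outcome_p_min: 0.05
  proxy_map: {rs6825454: rs56010410}
variance_model: default
n_boot: 1000
seed: 0
```

Input tables are delimited text with a configurable column mapping
(defaults: `snp, chr, gene, ea, nea, eaf, beta, se, pval`).

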