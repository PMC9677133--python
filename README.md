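# brainwas

Brain-wide imaging-genetics association analysis, packaged as a tested,
reusable pipeline. The scientific setting: a small panel of disease risk
variants — here the 17 loci known to drive genetic risk of idiopathic
pulmonary fibrosis (IPF) — is tested against a large array of
imaging-derived brain phenotypes (IDPs: regional cortical thickness,
white-matter microstructure indices, functional measures) in a
population-scale imaging cohort, and the resulting signals are
characterised by Bayesian colocalisation against the disease GWAS and by
mediation analysis through lung function.

The package is aimed at biostatisticians and imaging-genetics
researchers who need the full chain — cohort QC, confound modelling,
mass-univariate association, colocalisation, mediation — as composable,
unit-tested pieces, together with a synthetic-cohort generator that
reproduces the statistical structure of such a study for power analyses,
method checks and end-to-end testing.

## What it computes

- **QC / preprocessing** (`brainwas.preprocess`): per-IDP technical
  outlier flagging (|x − mean| > 5 SD), subject exclusion by outlier
  burden (> 10 flagged IDPs), maximally unrelated subject selection from
  KING kinship pairs (cut-off 0.0884, one representative per related
  group), rank-based inverse normal transformation
  y ↦ Φ⁻¹((r − 3/8)/(n + 1/4)), and an auditable exclusion ledger.
- **Confounds** (`brainwas.confounds`): augmented confound sets (raw,
  quantile-normalised, centred-squared; site indicators), scan-date
  drift components (low-rank imputation → median/MAD trimming → spline
  smoothing over scan date → top-10 PCA), and GLM deconfounding
  r = y − C C⁺y per IDP on its complete cases.
- **BWAS** (`brainwas.bwas`): for every variant g and IDP y, OLS of
  y ~ intercept + g + covariates under an additive dosage model (25
  standardised covariates: age/sex terms, body measures, blood
  pressures, 10 genetic PCs, smoking, alcohol units/week), with
  Bonferroni (α/M·N) and Benjamini–Hochberg FDR control.
- **Colocalisation** (`brainwas.coloc`): Wakefield approximate Bayes
  factors log ABF = ½[log(V/(V+W)) + z²W/(V+W)] per variant in a ±1 Mb
  window, combined into posterior probabilities PP0–PP4 of the five
  single-causal-variant hypotheses; PP4 ≥ 0.8 is read as a shared
  causal variant.
- **Mediation** (`brainwas.mediation`): paths a (X→M), b (M→Y|X),
  c (total), c′ (direct) from three OLS fits on a shared complete-case
  sample (so c = c′ + ab exactly), with the Sobel test
  z = ab/√(a²se_b² + b²se_a²) for the indirect effect.
- **Synthetic cohorts** (`brainwas.simulate`): LD-structured
  Hardy–Weinberg genotypes (latent AR(1) haplotype thresholding),
  IDPs with planted genetic effects, confound loadings and scan-date
  drift, a lung-function-like mediator on a specified a/b/c′ path,
  case-control GWAS summary statistics with a chosen causal variant,
  and QC stressors (missingness, ≥6 SD outliers, related duplicates).

## Worked example

```bash
brainwas all --out run/ --seed 0
```

runs the demo configuration (2,000 subjects, 17 variants, 200 IDPs,
plus an independent 2,668-case / 8,951-control GWAS of the risk trait)
through every stage and writes TSV outputs plus `manifest.json`. With
seed 0 the manifest reports:

- `bwas`: 3,400 association records (17 × 200), Bonferroni threshold
  0.05/3400 = 1.47 × 10⁻⁵, and 4 significant associations — the three
  planted variant→IDP effects (β = 0.2–0.3 SD) plus the mediated
  phenotype, each found on its planted variant and nowhere else.
- `coloc`: for the top IDP at the risk-trait lead variant, PP4 ≈ 1.00
  (`shared_causal_variant: true`) — the IDP and the case-control trait
  were simulated with the same causal variant, and the posterior
  concentrates on the shared-variant hypothesis.
- `mediate`: a = 0.466, b = 0.291, c = 0.308, c′ = 0.172, Sobel
  p = 3.6 × 10⁻²⁰, proportion mediated 0.44 — recovering the generating
  path values (a = 0.5, b = 0.3, c′ = 0.2) within sampling error at
  n ≈ 2,000.

The same stages are importable directly; see the module docstrings.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the entire demo pipeline from scratch at the given seed —
generating the cohort, QC-ing it, building confounds, scanning all
variant × IDP pairs, colocalising and fitting the mediation model —
and writes the results JSON. The statistical acceptance checks
themselves (null calibration of the scan, enumeration-oracle agreement
of the colocalisation posteriors, mediation parameter recovery,
deconfounding orthogonality, the INT worked example) live in
`tests/test_acceptance.py`.
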