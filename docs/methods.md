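# Methods

This note documents the models and procedures the package implements,
the defaults and why they were chosen, what the synthetic-cohort
generator does and does not emulate, and the numerical choices that
affect reproducibility.

## Cohort QC

Technical outliers are cells further than `k_sd` (default 5) standard
deviations from the column mean, with mean and SD taken over the
non-missing cells of each IDP; flagged cells are set missing, and
subjects flagged in strictly more than `max_outliers` (default 10) IDPs
are excluded. Moment statistics (not median/MAD) are used here, and the
pass is single-shot — no re-flagging after removal. Constant columns
flag nothing.

Relatedness pruning builds a graph over subjects with an edge wherever
the KING kinship coefficient is at least 0.0884 (the conventional
boundary between 2nd- and 3rd-degree relatives) and keeps exactly one
representative per connected component — the lexicographically smallest
subject id, a deterministic tie-break — plus all isolated subjects.
Note this is "one per related group", not a maximum independent set: a
chain A–B–C yields one retained subject even though {A, C} would be a
larger unrelated set. The retained set never contains an edge at or
above the threshold, which is the property the association model needs.

The inverse normal transformation maps non-missing values to
Φ⁻¹((r − c)/(n − 2c + 1)) with Blom offset c = 3/8 and average ranks
for ties — the standard GWAS convention. Constant vectors have no rank
information and raise; at cohort level such columns are set entirely
missing instead so one degenerate phenotype cannot abort a run.

## Confound model

The confound matrix combines raw acquisition covariates (head motion,
head-size scaling, head/table position), site indicators (first level
dropped), and two derived versions of every continuous column: its INT
version and its centred square after MAD trimming (trimmed cells are
refilled with the column median before squaring so the design stays
complete). The centred square captures symmetric nonlinear confound
effects and is uncorrelated with the raw column for symmetric inputs.

Scan-date drift components are built by the chain
impute → trim → smooth → PCA:

1. **Low-rank imputation** — iterative truncated SVD (missing cells
   start at column means; truncate to `rank` singular values, restore
   observed cells, repeat until the imputed entries change by less than
   `tol` in relative norm). Defaults rank 10, tol 1e-6, max_iter 200.
   Observed cells are never modified.
2. **MAD trimming** — cells further than `mad_k` (default 5) *raw* MADs
   from the column median are set missing; the 1.4826 normal-consistency
   factor is deliberately not applied. Holes reopened here are refilled
   by the same imputer before smoothing.
3. **Spline smoothing over scan date** — each column is replaced by its
   regression-spline fit on the scan date: cubic B-splines with interior
   knots at date quantiles for `spline_df` ≥ 4, a polynomial basis of
   degree df−1 for df of 2 or 3 (too few degrees of freedom for a cubic
   basis). The basis reproduces polynomials up to its degree, so linear
   trends pass through unchanged. Default df 10: drift is slow, few
   degrees of freedom suffice.
4. **PCA** — the top `n_components` (default 10) principal-component
   scores of the column-centred smoothed matrix, ordered by explained
   variance, each component's sign fixed so its largest-magnitude
   loading is positive.

The whole chain is deterministic given its input. Drift components are
computed on the analysis cohort (post-QC); whether the original study
computed them before or after exclusions is not stated.

Deconfounding residualises each IDP on the complete confound design
(plus intercept) by least squares on that IDP's non-missing subjects,
using a pseudo-inverse so rank-deficient designs are tolerated; missing
cells stay missing. Per-column complete cases (rather than listwise
deletion across all IDPs) preserve each phenotype's sample size.
Residuals are exactly orthogonal to the confounds and the operation is
idempotent. Columns sharing a missingness pattern are solved in one
batched call.

## Association model

Each variant × IDP pair is fitted by OLS of the (INT-transformed,
deconfounded) IDP on [intercept, covariates, dosage], complete cases
per pair, with the dosage coded 0/1/2 in risk alleles. Two-sided
p-values come from the t distribution at the design's residual degrees
of freedom rather than a normal approximation. A dosage monomorphic in
the complete cases cannot be tested; the record is flagged with missing
statistics. The mass scan groups IDP columns by missingness pattern and
solves each group with one normal-equations factorisation per variant;
agreement with statsmodels OLS to 1e-8 is asserted in the tests.

Covariates: age, sex, age², age×sex, age²×sex, height, weight,
diastolic and systolic blood pressure, 10 genetic principal components,
an ever-smoker indicator and alcohol units/week, all de-meaned and
scaled to unit variance. Alcohol units are tallied from per-drink-type
counts (weekly counts directly, monthly counts divided by
365.25/12/7 ≈ 4.345). Missing body measures are median-imputed (the
original design imputed them from other assessment visits — a
multi-visit structure the generator does not simulate). INT is applied
before deconfounding by default, with a config switch for the reverse
order.

Family-wise control is Bonferroni α/(M·N) over all variant × IDP tests;
Benjamini–Hochberg FDR masks and adjusted values are reported alongside.

## Colocalisation

Evidence per variant and trait is the Wakefield approximate Bayes
factor: with V = SE², W the prior effect variance and z = β/SE,
log ABF = ½[log(V/(V+W)) + z²·W/(V+W)]. Prior effect SD defaults:
0.15 for quantitative traits (phenotype-SD units), 0.2 for case-control
(log-odds). When a trait lacks β/SE, they are reconstructed from
p, MAF and n via varbeta = 1/(2·maf·(1−maf)·n) (an extra s(1−s) factor
for case-control with case fraction s); when both are available, β/SE
wins (less approximation error).

Under the one-causal-variant-per-trait assumption, the posteriors over
H0 (no association) / H1, H2 (one trait) / H3 (distinct variants) /
H4 (shared variant) follow from configuration sums S1, S2, S12
accumulated in log space; the H3 term S1·S2 − S12 is computed as the
off-diagonal log-sum-exp, which is stable even when one variant
dominates. Per-variant priors default to p1 = p2 = 1e-4, p12 = 1e-5.
The analysis window is ±1 Mb around the lead variant, endpoints
inclusive, positions 1-based, both traits restricted to their common
variants. PP4 ≥ 0.8 is reported as a shared-variant verdict. The
implementation is checked against brute-force enumeration of all
(n+1)² causal configurations on small windows to 1e-10.

## Mediation

Three OLS fits on one shared complete-case sample give
a (X→M), b and c′ (Y ~ X + M), and c (Y ~ X), each adjusted for age,
sex and height (ethnicity, constant in the emulated cohort, is
dropped). On the shared sample c = c′ + ab holds to machine precision,
which the tests assert. The indirect effect ab is tested by the Sobel
normal approximation — conservative under the null, as the null-rate
test verifies. Proportion mediated is ab/(c′ + ab) (the standard
definition; undefined and flagged when direct and indirect effects
cancel exactly). The mediator is used raw (litres-like scale) by
default with an `int_mediator` switch. Mediation p-values are reported
both uncorrected and Bonferroni-scaled by the number of variants.

## Synthetic cohort

Genotypes: each subject is the sum of two independent haplotypes; a
haplotype carries the risk allele at variant j iff a latent AR(1)
Gaussian (lag-one correlation `ld_rho`) falls below Φ⁻¹(maf_j). This
gives exact per-variant Hardy–Weinberg proportions and pairwise LD that
decays geometrically with marker separation — the simplest mechanism
with both properties, sufficient for colocalisation tests without a
coalescent simulator. Demo-panel MAFs are an even 0.05–0.45 spread (a
documented package default, not values from any study).

IDPs are planted-effect + confound-loading + Gaussian-noise sums;
phenotypes without planted effects are exact nulls. The demo
configuration plants three effects of 0.2–0.3 SD per risk allele,
loads confounds at 0.1 SD and adds a two-basis scan-date drift at
0.15 SD — detectable but not overwhelming at n = 2,000. The mediator
is M = aX + ε and the mediated phenotype Y = c′X + bM + ε with
(a, b, c′) = (0.5, 0.3, 0.2) and unit noises, matching the scale of
weak-to-moderate standardised paths. Case-control summary statistics
draw case status from a logistic model on the causal dosage — the
intercept set so the expected case fraction matches
n_cases/(n_cases + n_controls) (realised counts fluctuate and are
recorded) — then fit marginal per-variant logistic regressions with a
vectorised Newton solver (statsmodels agreement asserted in tests);
separation is flagged and the SE set missing. The demo uses an
independent 2,668/8,951 case-control cohort for this trait.

Stressors (missingness, ≥6 SD displaced cells, duplicated-with-noise
related subjects at kinship 0.25) are injected after clean generation,
so QC round-trip tests can be exact.

What a green test does **not** establish: the generator draws
independent Gaussian IDP noise (real IDPs are heavily cross-correlated
within modality), uses hard-call genotypes (no imputation uncertainty),
one visit (no longitudinal structure), and linear confound effects
only. Power and calibration results transfer to real cohorts only up
to those simplifications.

## Numerical and reproducibility choices

All randomness flows from a single global seed, fanned out to stages by
SHA-256 hashing (`child_seed`), each child below 2³¹. Tabular outputs
are TSV with floats at 10 significant digits; manifests record stage
seeds, row counts and output hashes, and identical configs reproduce
identical hashes. Degenerate inputs are handled explicitly: zero-SD
columns flag no outliers, MAD-0 columns trim nothing, maf = 0 yields an
all-zero dosage column, constant dosages are flagged rather than
fitted, and ledger over-removal raises.

## Known limitations

- Relatedness is handled by pruning, not by mixed models; residual
  cryptic relatedness below 0.0884 is ignored.
- Colocalisation assumes at most one causal variant per trait in the
  window (no SuSiE-style multi-signal decomposition) and is expected to
  be inconclusive in regions of long-range LD.
- The Sobel test is conservative at small indirect effects; bootstrap
  CIs are not implemented.
- The 45-confound composition of the original design is study-specific;
  the package exposes the construction operators and takes the column
  list from configuration.
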