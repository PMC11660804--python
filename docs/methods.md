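# Methods

## Model and estimation

For one trait, `y = w_i b_i + C beta + W u + e` with
`u ~ N(0, O sigma_o^2)` and `e ~ N(0, I sigma_e^2)`. The ORM is
`O = Z'Z/m` over the standardized (population-variance) expression matrix
`Z`, which gives `mean(diag(O)) = 1` exactly and row sums of 0, so
`sigma_o^2` is interpretable as the phenotypic variance attributable to the
expression background.

REML works in the eigenbasis of `O`: with `O = U diag(d) U'` and
`gamma = sigma_o^2/sigma_e^2`, the rotated model has diagonal covariance
`sigma_e^2 (gamma d + 1)`. The restricted likelihood is profiled
analytically over `sigma_e^2` and maximized over `log gamma` by bounded
scalar search on [1e-6, 1e6] (tolerance 1e-8 in log-ratio). A boundary or
flat optimum (flatness tolerance 1e-8, e.g. `O ≈ I` where the components are
not separately identifiable) is reported as `sigma_o^2 = 0` with a warning,
never as a spurious interior estimate.

Target-gene exclusion is exact: `O_-i = (m O - z_i z_i')/(m - 1)` equals the
ORM recomputed without gene i. The production scan reuses the per-trait
eigendecomposition and applies a Sherman–Morrison rank-one correction, so
each gene costs O(n·p); an explicit dense path (`test_gene`) and a
per-gene-REML mode exist for verification, and the two routes agree to
1e-8 in the test suite. Variance components are estimated once per trait on
the full ORM and reused across genes: the rank-one perturbation of one gene
among thousands is negligible for the variance components, and re-estimating
them per gene costs O(m·n^3) for no measurable change (the per-gene mode is
oracle-checked against this claim at small m). Significance is a 1-df Wald
chi-square on `b_i`; a target collinear with the fixed design is flagged
(`ok = False`, NaN statistics) rather than raised.

Fixed effects (sex, season; intercept always) are selected per trait by OLS
backward elimination with whole-factor partial F-tests: the weakest factor
is dropped while its p ≥ 0.05. The selection is done on the phenotype alone
(ordinary least squares), before the mixed model.

## Preprocessing

- **TMM** follows the reference weighted-trimmed-mean dialect: pairwise zero
  removal, 30% two-sided trim on M-values, 5% on A-values, inverse
  delta-method variance weights, reference sample chosen by upper-quartile
  fraction closest to the mean, factors rescaled to geometric mean 1. The
  implementation reproduces Bioconductor edgeR's `calcNormFactors` to 1e-8
  (cross-checked in the test suite via Rscript where available).
- **CPM**: `counts / (libsize × factor) × 1e6`. Expression enters the ORM as
  CPM standardized per gene; a `log_cpm` flag (log2(CPM+1)) is available but
  off by default — the normalization target is plain CPM.
- **Expressed-gene filter**: retained iff count ≥ 2 in strictly more than
  30% of samples (the inequality is strict; at exactly 30% a gene is
  dropped). Applied once on the full count matrix.
- **Phenotype QC**: per trait, values outside median ± 3.5 × MAD are
  removed. The MAD is deliberately unscaled (no 1.4826 consistency factor),
  making the rule equivalent to roughly ±2.36 SD on normal data; both k and
  the rule are configurable. Masks are per trait, so each trait keeps its
  own N.
- **Per-trait rebuild**: after masking, TMM factors, CPM, standardization,
  and the ORM are recomputed on the retained samples, so the
  standardization convention holds exactly within each analysis.
- Standardization uses the population (1/n) variance so the ORM diagonal
  averages exactly 1; 1/(n−1) is available via `ddof`.

## Multiplicity and diagnostics

Raw p-values are mapped to 1-df chi-square statistics through the upper-tail
inverse; `lambda = median(chi2) / 0.45494` (the exact chi-square(1) median;
its 4-decimal rounding is the conventional 0.4549 denominator). The 95% CI
is the distribution-free binomial order-statistic interval for the median,
with a bootstrap alternative behind a flag. FDR control is
Benjamini–Hochberg (Benjamini–Yekutieli optional), with strict
`adjusted p < alpha` significance calls; candidate lists take the k = 20
lowest raw p with lexicographic gene-id tie-breaks. QQ data use plotting
positions (i − 0.5)/n. All diagnostics are exported as plot-ready TSV/JSON;
no figures are rendered.

## Synthetic data

`simulate_counts` draws gene means lognormally around a median of 50 counts
(sd of log 1.5), per-sample library-size factors lognormally (sd of log
0.5), and counts negative-binomially with variance `mu + phi mu^2`
(default `phi = 0.1`; `phi = 0` is the Poisson sentinel). Defaults emulate
a ~115-sample, ~10k-gene bulk study; with them ~99% of genes pass the
expression filter.

`simulate_phenotypes` generates each trait from the analysis model itself:
the filtered, TMM/CPM-normalized, standardized matrix of the simulated
counts supplies both the causal-gene columns and the polygenic term
`u_i ~ N(0, sigma_o^2/m)`, so the mixed-model assumption is exactly
satisfiable ("well-specified" default). `sigma_o^2` is parameterized as
`f/(1−f) × sigma_e^2` from the target fraction `f = polygenic_var_frac`
(default 0.4, a moderate expression-heritability; `residual_var` defaults
to 1). Sex is Bernoulli(1/2) with default effect 0.5 phenotype units;
season is uniform over 3 levels with effects (0, 0.25, −0.25). Outliers are
additive shifts of ±6 trait SD on a Bernoulli(0.02) subset — large enough
that the MAD rule must catch them. Causal effects default to
`N(0, causal_effect_sd^2)` draws; `causal_effects` can pin exact values for
power studies. Ground truth is written to separate files never read by
analysis stages.

What the generator does **not** emulate: batch effects beyond library size,
gene–gene correlation structure (co-expression modules), per-gene dispersion
heterogeneity, isoform structure, and missing phenotypes other than those QC
creates. Passing tests therefore demonstrate correctness of the estimation
machinery under the assumed model, not robustness to every real-data
pathology (a latent-Gaussian misspecification toggle is a natural extension).

## Simulation studies and their sizes

The studies behind `scripts/acceptance.py` and the acceptance tests use
20 replicates each at n = 200/m = 2000 (null calibration), n = 300/m = 1000
(variance-fraction recovery at true 0.5), and n = 200/m = 1000 (top-20
recovery of a planted causal gene of 1.5 baseline phenotype SD,
i.e. `b = 1.5 × sqrt(sigma_o^2 + sigma_e^2)`). These sizes give
Monte-Carlo error well inside the asserted bands while keeping a full run
under a minute on one core.

One deliberate choice: the recovery study estimates the variance fraction by
REML on the simulated samples directly, without the MAD phenotype filter.
On a clean normal phenotype the ±3.5-unscaled-MAD rule truncates ~1.8% of
legitimate tails (±2.36 SD), which empirically biases the estimated fraction
down by ~0.09 at true 0.5 — a property of outlier trimming under
model-faithful data, not of the estimator. The calibration and power
studies run the full pipeline including QC, where that truncation is
harmless (λ and type-I error stay nominal; ranking is unaffected).

## Numerical choices and degenerate inputs

- ORM symmetry is enforced by averaging; positive semi-definiteness is
  asserted at −1e-8 and violations raise rather than clip.
- Non-standardized input to `compute_orm` (row mean beyond 1e-6) is an
  error, not silently re-centered.
- Zero-variance genes are dropped with a warning at standardization, never
  propagated as NaN; a constant phenotype vector has MAD 0 and retains all
  values.
- A sample sharing no expressed gene with the TMM reference gets factor 1
  with a warning.
- `run_trait` refuses traits with fewer than 30 retained samples.
- Everything downstream of the generator is deterministic; reruns are
  byte-identical and manifests record SHA-256 hashes of all artifacts.

## Known limitations

- Single-component polygenic background: the target gene is excluded
  exactly, but genes are not binned into multiple variance components by a
  preliminary scan; with strong heterogeneous co-expression structure a
  multi-component extension could calibrate better.
- Wald (not likelihood-ratio) tests; at small n the chi-square reference is
  mildly anticonservative, visible as pooled type-I ≈ 0.055 at n = 200 in
  the calibration study.
- Variance components are held fixed across genes in the default mode;
  standard errors do not propagate their uncertainty.
- The λ confidence interval method is a choice (order-statistic default,
  bootstrap optional); other constructions exist.
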