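# Methods

## Dose coding and data model

Doses enter the model as ordinal indices `i = 1..m` with the control at
`i = 1`, not as physical concentrations. This keeps `log(i)` and negative
powers defined at every level and makes designs comparable across compounds
whose concentration grids differ. The response is the log2 fold change of a
sample versus the mean of its control-dose replicates, so control
observations are included in the fit and are mean-zero by construction
(`compute_fold_change` performs this centring; profiles built directly from
fold-change data skip it). Fitting on active doses only is possible by
passing profiles whose dose indices exclude the control, re-indexed from 1.

The reference design mirrors a large rat toxicogenomics repository:
`m = 4` dose levels, 2 replicates per dose in vitro (N = 8) and 3 in vivo
(N = 12). Nothing in the code assumes these sizes; they are defaults
(`TGP_VITRO_DESIGN`, `TGP_VIVO_DESIGN`).

## Fractional polynomial fitting and power selection

The FP2 mean is `β0 + β1·f(i; p1) + β2·g(i; p1, p2)` with powers from
`P = {−3, −2.5, …, 2}`. Pairs are enumerated unordered with repetition
(`p1 ≤ p2`, 66 candidates); the cases of `g` (extra `log i` factor for
repeated powers, `log i` for a zero second power) keep the basis
2-dimensional for every pair. Fits are ordinary least squares with the
Gaussian maximum-likelihood variance `σ̂² = RSS/N`, log-likelihood
`−N/2·(log(2π σ̂²) + 1)`, and `AIC = 2k − 2·logL` with `k` counting mean
parameters plus one variance parameter. Because every FP2 candidate shares
`k`, AIC selection is equivalent to RSS minimisation; ties break to the
lexicographically smallest pair so selection is deterministic. Degenerate
fits (RSS = 0) floor `σ̂²` at 1e−12 and are flagged. Rank-deficient designs
(possible at `m = 2`) are solved minimum-norm via `lstsq`/SVD, with the
condition number recorded on the fit.

## The disconnect test

Powers are selected by AIC on the source system only, then held fixed — the
projection direction matters, and both directions (`vitro_to_vivo`,
`vivo_to_vitro`) are first-class. The projected model shares `(β0, β1, β2)`
across the pooled systems; the interaction model adds target-system offsets
`(γ0, γ1, γ2)` on all three terms with a single shared residual variance (one
linear model, not two separate fits — although its mean estimates coincide
with per-system OLS). The disconnect statistic is the 3-df likelihood ratio.

**Calibration.** For nested Gaussian linear models the LR statistic is a
monotone transform of the F statistic, so referring
`F = ((RSS0−RSS1)/3)/(RSS1/(N−6))` to `F(3, N−6)` is the *exact*
finite-sample null distribution of the LRT with a fixed basis. This is the
default (`calibration="f"`). The large-sample chi-square reference
(`calibration="chisq"`) rejects ~23% of true nulls at the 10% level on the
reference design (N = 20) and is provided only for comparison. The same
choice applies to the 2-df single-system dose-response test.

AIC selection on the source data is ignored by the reference distribution,
as in the procedure this package implements. The residual effect is
measurable: under the global null the disconnect test rejects ~12.3%
instead of 10% at the reference design (specificity ~87.7%), and the
single-system dose-response test, whose selection and test share the same
8 observations, inflates further (~15% at nominal 10%). These numbers are
surfaced by the simulation study rather than corrected; a selection-aware
(e.g. resampling) calibration is future work.

## Multiplicity, filtering and grouping

BH adjustment is applied per compound per direction across genes
(`bh_family="per_compound"`, the default) or globally per direction
(`"global"`); the nominal FDR is `q = 0.10`. Disconnect calls additionally
require a maximal dose-specific fold change of at least `fc_min = 1` log2
unit, read as the max over doses of the absolute difference in per-dose
means *between systems* — the filter targets between-system effect size, and
this reading makes it exactly the estimated disconnect magnitude. The
alternative reading (largest within-system amplitude versus control) is
available via `max_dose_fold_change(..., mode="within_systems")`. The
boundary is kept: `max_fc = 1.0` passes. Genes are also grouped by their
per-system 2-df dose-response tests into `both` / `vitro_only` /
`vivo_only` / `neither` for reporting.

## Biclustering

Disconnect calls form a binary genes × compounds matrix restricted to genes
with at least one call. All inclusion-maximal all-ones submatrices are
enumerated by a divide-and-conquer recursion over compounds with a
first-parent canonicity test (a closed-concept enumeration); every maximal
submatrix is closed in both dimensions, so this produces exactly the
bicluster set the binary-inclusion-maximal (Bimax) formulation defines, each
exactly once and in deterministic order. Worst-case output is exponential;
a work cap (`max_biclusters`, default 1e5) aborts with a clear error.
Minimum sizes default to 2×2. Ranking is by area (genes × compounds)
descending, then more compounds, then lexicographic labels; `n_biclusters`
(default 10) are kept and summarised in a compound × bicluster membership
table.

## Synthetic data generator

`ScenarioSpec` defines seven kinds: a flat null and six disconnected
patterns — opposite profiles between systems, or an effect in only one
system, each with a linear or an FP2 shape. Mean profiles are anchored at 0
for the control dose and rescaled so the active system's maximal |mean| is
`delta` (log2 units); "opposite" kinds negate the profile in vivo, so their
maximal between-system fold change is `2·delta`. Noise is i.i.d. Gaussian.
Defaults, fixed once: `sigma = 0.25` log2 units (a realistic residual sd
for replicated microarray fold changes) and FP2 truth powers `(0.5, 2)` (a
smooth accelerating curve distinct from the linear scenarios). The generator
emulates the replication structure and noise scale of the real design but
not gene–gene correlation, heteroscedastic (intensity-dependent) variance,
or array-level batch effects — passing simulations therefore validate the
statistical machinery, not robustness to those real-data features.

Study 1 (`run_study1`) simulates independent gene-pairs per scenario and
calls at raw p ≤ α = 0.10: the quoted specificity is against the test level,
with no multiplicity family. Study 2 (`run_study2`) simulates datasets of
`n_genes` (half null, half opposite-FP2 at `delta = 1`, the minimal fold
change of interest), applies the full BH pipeline at `q = 0.10` per dataset,
and records per-dataset sensitivity, specificity, empirical FDR
(`FP/max(1, calls)`) and FNR, plus ROC curves vertically averaged on a
101-point FPR grid. Default sizes — 2,000 pairs per scenario and 100
datasets × 600 genes — give Monte-Carlo standard errors under one
percentage point for all reported rates while the vectorised fitting engine
(per-design orthonormal projectors shared across genes) keeps either study
under a second; flags scale both up.

## Numerical and design notes

- RSS ratios are floored at 1e−12 before logs; LR statistics are clipped at
  0 (and a perfect-fit full model yields p → 0 rather than NaN).
- The batch engine and the per-profile functions are independent code paths
  tested against each other and against external OLS/ANOVA oracles.
- Determinism: every stochastic entry point takes a seed or Generator;
  identical seeds give bit-identical results end to end.
- The estimator surface (`DisconnectAnalyzer`, `Bimax`) follows
  scikit-learn conventions (constructor params, `fit`, trailing-underscore
  attributes, `get_params`/`set_params`); module-level functions are thin
  wrappers suitable for scripting.

## Known limitations

- The chi-square option exists for comparison only; at these sample sizes
  it is badly anti-conservative.
- Selection-induced inflation (above) means the null specificity of the raw
  disconnect test is ~88%, not the nominal 90%, at the reference design.
- One shared residual variance across systems is assumed; strongly unequal
  in vitro / in vivo variances would miscalibrate the test.
- Unequal replicate counts are pooled without weighting.
- No covariates, time-course structure, or correlated-gene error models.
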