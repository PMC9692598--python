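# Methods

## Models

### IAM regression models

The registry models MLR1–MLR3 are linear predictors of log BCF (the EPI
Suite reference estimate used as the modelling response) evaluated with
their published coefficients on raw descriptor scales.  They are pure
functions: no refitting happens at prediction time.  Cross-validation of
these fixed models refits the *variable set* per training fold (the
coefficients are re-estimated on each k−1 fold subset), which is the
standard way a fixed published equation is subjected to k-fold CV.

### OLS and forward stepwise selection

`fit_ols` wraps ordinary least squares (via statsmodels) and reports
coefficients with standard errors, R², adjusted R², and the overall
F-test.  `stepwise_forward` adds, at each step, the candidate whose
partial-F p-value is smallest, provided it is below `alpha_enter`
(default 0.05); for a single added column the partial F-test is
identical to the t-test on its coefficient, which is how it is computed.
There is no removal step.  Ties are broken by larger |t|, then candidate
order.  The 0.05 default is a conventional entry threshold; the original
modelling software's exact threshold is not documented, so only the
selection *mode* and resulting variable sets are reproducible claims.
Predictors are deliberately not standardised so reported coefficients
stay on the scales the published equations use.

Degenerate inputs: a constant response is defined to have R² = 0 (no
variance to explain); rank-deficient designs raise an error naming the
collinear columns; candidates that add no rank are never selected.

### NIPALS-PLS and VIP

`fit_pls` autoscales X and y (mean 0, unit sample sd with the n−1
denominator — the conventional chemometric autoscale) and extracts
components by NIPALS.  For a single response the weight vector has the
closed form w ∝ X'y, so each component is extracted directly; the
iterative NIPALS loop (tolerance 1e−12, max 500 iterations) is retained
in the component routine for the multi-response generalisation and
converges in one pass here.  Predictions use the regression vector
b = W(P'W)⁻¹q, mapped back to the original y scale.

VIP_j = sqrt(p · Σ_a SSY_a·w_ja² / Σ_a SSY_a) with SSY_a = q_a²·t_a't_a
and unit-norm weight columns, so mean(VIP²) = 1 by construction.
`prune_by_vip` drops **all** variables with VIP < 1 each round (not one
at a time) and refits with a component count re-selected by CV each
round, until every survivor reaches the threshold or fewer than two
variables would remain; the trace records every round so any
intermediate model can be inspected rather than asserting a particular
number of rounds.

`select_components` picks the component count minimising the k-fold
CV-RMSE (ties to the smaller count).  A count whose extraction fails on
some training split — possible when the residual X block is numerically
rank-deficient — scores infinity rather than aborting the scan.

### Cross-validation

`make_folds` shuffles indices with a seeded generator and splits them
contiguously into k folds whose sizes differ by at most one; the default
seed 20221111 is arbitrary but always recorded in reports, because the
original study's fold assignment is unpublished and RMSECV depends on
it.  RMSECV aggregates per-fold RMSEs quadratically,
RMSECV = sqrt(Σ_j RMSE_j²/k); with equal fold sizes this equals the
pooled held-out RMSE and with unequal folds it differs (folds, not
observations, are weighted equally).  Both forms are available; the
aggregate is the one reported.  R² on training data is 1 − SSres/SStot;
R² against in-vivo measurements is the squared Pearson correlation of
predictions with measurements, appropriate because the models were never
fitted to those data.

### The log Kow compendium

The screening models are evaluated exactly as printed.  Boundary
conventions where printed ranges abut ("1 to 7", "7 to 10.5"): the lower
branch is closed at its upper endpoint, so log Kow = 7 uses the
mid-range formula.  The ionic step-function band edges differ between
the Meylan and US EPA schemes (1.75 band up to 7 vs 8).  Category
boundaries 1000 and 5000 (on BCF = 10^logBCF) both belong to the middle,
"bioaccumulative", category.  ΣF_i correction factors default to 0 and
are user-supplied; the factor values themselves are outside scope.  One
bilinear-type literature equation is printed ambiguously (a logarithm on
its Kow-correction term is almost certainly intended but not printed);
the logarithmic reading is the default and the literal product form is
available behind a flag, without asserting either as authoritative.  The
quantum-descriptor model's output is returned unlabeled because the
source prints it as "BCF" while the context suggests a log scale.

### Retention extrapolation

Only the linear Soczewiński–Wachmeister form log k = log kw + S·φ is
supported, fitted by unweighted OLS.  With exactly two points the fit is
exact (R² reported as 1) and the intercept SE is undefined (reported
missing).  All-identical φ values are an error.  Any n ≥ 2 is accepted
and n is reported, since source datasets differ in how many modifier
levels they used.

## Synthetic data generator

The generator emulates the *conditions* of the 120-compound training
set, not its compounds: it draws multivariate-Gaussian vectors for
log kw^IAM and the 16 calculated descriptors with the published 17×17
correlation matrix as target, then computes
log BCF = b₀ + Σ b_j·x_j + ε with the published four-variable model as
the default generative equation and ε ~ N(0, 0.35²).

Choices and what they imply:

- **PSD repair.** The published correlation matrix, printed to two
  decimals, is slightly indefinite (smallest eigenvalue ≈ −0.003).  It
  is repaired by eigenvalue clipping at 1e−8 followed by diagonal
  rescaling; the maximum entry change is ≈ 0.002 and the repair is an
  exact no-op on PSD input.  Sampling uses the Cholesky factor of the
  repaired matrix.
- **Marginals.** Only correlations are published, not marginal
  distributions, so marginals default to mean 0 and sd 1 and are
  user-overridable.  Count descriptors (HvAt, ArHvAt, FRB, HD, HA) are
  rounded to non-negative integers and F_Csp3 is clipped to [0, 1]
  *before* the response is computed, so refitting the generative
  variable set on a noiseless table returns the generative coefficients
  exactly, and coefficient recovery on noisy tables is unbiased.
- **Noise.** The default noise sd of 0.35 places single-predictor fits
  in the R² ≈ 0.8 regime of the original study; it is a package choice,
  not a published value.
- **What the emulation does not reproduce.**  Because marginals are
  standardised, raw-scale coefficients with small magnitudes (TPSA's
  −0.0043 per Å²) contribute almost nothing to the synthetic response,
  so the original stepwise entry order (TPSA second) and the original
  R² = 0.87 / RMSECV = 0.25 / VIP = 2.53 values — all properties of the
  real descriptor scales and variances — are not targets the emulation
  can hit.  Under the emulation, Monte-Carlo analysis of the generator's
  definition gives: single-predictor R² 0.78 ± 0.04, retention
  coefficient 0.710 ± 0.032, five-fold RMSECV 0.36 ± 0.03, the retention
  descriptor always entering first and always ranking first by VIP, and
  VIP pruning always terminating in a two-variable model containing it
  (its strongly correlated lipophilicity companion survives alongside —
  the same *structure* the original analysis reports, where a
  polarizability-related companion survived).  The end-to-end tests
  assert those emulation-derived expectations; passing them demonstrates
  the machinery is correct under the stated conditions, not that real
  IAM data would reproduce the original statistics.
- Also not emulated: real marginal shapes (skewed Mw, zero-inflated
  counts at realistic means), measurement error in log kw^IAM, and any
  in-vivo response column.

## Numerical conventions

Autoscaling uses the n−1 sample sd throughout.  Score orthogonality
holds to 1e−8 relative; VIP normalisation to 1e−10; full-component PLS
reproduces OLS predictions to 1e−8.  CSV round-trips are bit-exact for
finite values (floats are written with full repr precision); missing
values are empty cells (also accepted as "NA" on read), and unparseable
numeric cells become missing with a logged warning, never silent zeros.
Physical-range oddities (non-positive Mw, negative TPSA) warn once per
file at the CSV entry point rather than failing record construction, so
standardised simulated tables remain usable; structural violations
(F_Csp3 outside [0, 1], negative or fractional counts, unknown
descriptor names, duplicate ids) are hard errors everywhere.

Problem sizes in the shipped tests and the acceptance script — 120-row
tables for fitting workflows, 20 replicates or fold seeds for stability
checks, 200 replicates for bias checks, 100 000 rows for the correlation
target — were chosen so the whole suite runs in well under a minute
while keeping Monte-Carlo standard errors a factor of ≥ 3 below every
asserted tolerance.

## Known limitations

- The applicability domain of the IAM models ends near log Kow ≈ 7;
  beyond it IAM retention is not measurable and predictions carry a
  flag, not a refusal.
- The CAESAR rule is implemented only as the combination of its two
  sub-model outputs, which the caller must supply; the sub-models'
  descriptors and coefficients are not published in usable form.
- Correction-factor sums ΣF_i for the Meylan/US EPA models are inputs.
- Descriptor computation (SwissADME, MOPAC/OCHEM, KOWWIN) is out of
  scope; descriptor units are taken as delivered by those tools.
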