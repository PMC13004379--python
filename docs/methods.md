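# Methods

## Estimand and model

A cross-lagged panel network (CLPN) over p = 32 symptoms is the directed
graph whose edge i→j is the regularized partial regression coefficient of
symptom i at wave 1 on symptom j at wave 2, holding all other wave-1
symptoms and the covariates fixed. Estimation is node-wise: for each
outcome j we fit

    y_j = β0_j + X β_j + C γ_j + ε_j,

where X is the n×32 matrix of wave-1 total experience scores, C the
covariates (age in years, sex as a binary indicator), and β_j carries an
ℓ1 penalty while γ_j does not. Only completers (participants observed at
both waves) enter; no imputation is attempted.

Two response families are implemented, because symptom totals can be
analyzed either as continuous scores or as presence/absence:

- **gaussian** (default): totals are z-scored within wave, so β is a
  standardized coefficient and exp(β) is a dimensionless effect presented
  on an "OR scale". With the weak effects typical of symptom panels these
  exponentials fall in roughly 0.94–1.27, matching the magnitude of
  published CLPN edge weights.
- **binomial**: the wave-2 outcome is dichotomized to score > 0 and an
  ℓ1-penalized logistic regression is fitted; exp(β) is then a true odds
  ratio per standard deviation of the wave-1 predictor.

The two families answer slightly different questions and are both exposed;
the gaussian family is the default because the continuous-score analysis
is the one whose edge-weight range reproduces the published matrix.

### Solvers

The gaussian path is solved by coordinate descent
(`sklearn.linear_model.lasso_path`) after the covariates are projected
out of the outcome and every predictor column (Frisch–Waugh–Lovell), which
makes "unpenalized covariates" exact rather than approximate. The
binomial family uses an in-package FISTA proximal-gradient solver with a
penalty mask (intercept and covariates unpenalized), fixed step 1/L with
L = ‖X‖² / 4n.

Every fit can be audited with `kkt_violation`, which rebuilds the
standardized design and evaluates the stationarity conditions of the
penalized objective: |gradient| ≤ λ for zero coefficients,
gradient = −λ·sign(β) for active ones, zero gradient for unpenalized
terms. Solver tolerances are set so the maximal violation stays below the
configured `tolerance` (default 1e-7) for the gaussian family; the FISTA
stopping rule (coefficient change < tolerance) tracks the same scale but
is not a hard KKT bound, so binomial checks use a small multiple.

### Penalty selection

The λ grid has 100 points, log-spaced from the data-driven maximum
λ_max = max_j |x_jᵀy| / n (the smallest λ with an all-zero solution, after
residualization) down to 0.001·λ_max. Fold assignment is a seeded shuffled
K-fold (K = 10) shared across the 32 outcome fits; the selected λ
minimizes the mean validation loss (MSE, or mean logistic deviance), with
exact ties broken toward the larger λ. Validation predictions use the
training fold's covariate projection, so the CV loss is the loss of the
full model, not of the residualized one.

Consequences worth knowing:

- CV-min is deliberately permissive; at the null it admits roughly 5–15%
  spurious cross-lagged edges. This matches the density of published CLPN
  matrices (which report hundreds of retained edges), but it means an
  estimated edge is weak evidence on its own — hence the bootstrap layer.
- Fold assignment is positional: permuting participant rows changes fold
  membership and can perturb the selected λ. Fixed-λ fits
  (`fit_node_at_lambda`) are exactly row-order invariant; CV-based fits
  are invariant only in distribution.

## Centralities

Expected influence aggregates signed transformed weights, diagonal always
excluded: out-EI sums over a node's row, in-EI over its column, bridge-EI
over both directions restricted to edges whose endpoints lie in different
symptom domains (physical / cognitive / psychological — the instrument's
fixed partition; no community detection). The transform is ln(OR) by
default — identical to the regression coefficients — with OR − 1 as an
option. Both are monotone near 1 and order every clearly separated pair
identically; near-ties (differences below one 0.01 print unit) can order
differently between the scales, which is visible on the published
2-decimal matrix.

Z-scoring uses population scaling (ddof 0) over nodes; a constant metric
column yields all-zero z-scores with a warning. On the published
asymmetric matrix (PSYS7 has no outcome column as printed) PSYS7's in-EI
is reported as missing, not 0; its bridge-EI contains only the outgoing
half. The display filter drops the diagonal and removes off-diagonal
edges weaker than a threshold OR (optionally keeping the negative
mirror OR ≤ 1/t); the threshold is a plain parameter with no default
tied to any particular figure.

## Bootstrap machinery

All three procedures are pure functions of (panel, config, seed), using
`numpy.random.default_rng` throughout.

- **Edge CIs**: resample completers with replacement, re-estimate the full
  network, take percentile intervals (default 95%, 1000 resamples).
  Degenerate resamples (constant outcome) are dropped and counted.
- **Case-drop CS**: for each drop proportion p in the grid (default 0.05
  to 0.75 in steps of 0.05), draw subsamples retaining (1−p)·n
  participants without replacement, re-estimate, and correlate each
  centrality metric with its full-sample value; CS is the largest p at
  which ≥ 95% of correlations reach 0.7. These thresholds are the
  established convention for correlation-stability coefficients.
- **Difference tests**: for each node pair, the percentile interval of the
  bootstrap distribution of the centrality difference; significant at
  level α when the (1−α) interval excludes zero. No multiplicity
  correction, matching common practice in network psychometrics.

Re-estimation re-runs the full CV λ-selection per resample by default
(the honest variant). The labelled fast mode (`reselect_lambda=False`)
fixes each node's λ at its full-sample selection and refits only the
penalized solution — roughly 50× faster and adequate whenever λ
re-selection is not itself the quantity under study.

Calibration facts established by simulation (and encoded in the test
suite):

- Percentile CIs for a planted β = 0.3 edge at study scale exclude 1;
  under a pure-noise panel ≥ 90% of off-diagonal CIs contain 1.
- The CS coefficient reaches the top of the drop grid for an
  overwhelming-signal panel and is 0 for most pure-noise panels. It is
  not *always* 0 under noise: when the full-sample estimate happens to
  retain a spurious structure, subsamples at low drop proportions re-find
  it (they share most of the data), so an occasional noise panel yields
  CS = 0.25. For the same reason CS values below 0.25 are not
  interpretable, which is why the stability checks use a grid starting
  at 0.25.
- The difference test is conservative under the null only because
  shrinkage concentrates bootstrap distributions at zero. Conditional on
  a finite panel, accidental wave-1→wave-2 associations persist across
  resamples; such a pair is flagged "significant" even though the
  population difference is zero. The probability that an exchangeable
  panel shows at least one flagged pair grows with the number of
  candidate cells (~p²): measured rates of all-clear runs are ~90% for
  4-node networks but only ~65–75% for 8-node ones. Treat pairwise
  difference flags as descriptive, not as calibrated hypothesis tests.

## Synthetic panels

The generator emulates the study conditions rather than any particular
dataset: 791 enrolled, expected retention 706/791 ≈ 89.25%, wave-1 totals
zero-inflated on {0} ∪ [3, 13] (per-symptom endorsement probabilities
default to a 0.70→0.20 gradient; present totals are 3 + Binomial(10, 0.35)),
and a ground-truth coefficient matrix with diagonal N(0.15, 0.03) — so
exp(diagonal) centers on 1.16 — plus sparse off-diagonal effects (density
0.10, half-normal scale 0.06, 7% negative), calibrated to the published
matrix's diagonal mean, edge range and sign ratio. Wave-2 latents are
z1·B + covariate effects + N(0, 1) noise, mapped back to the discrete
scale by snapping to the nearest legal value (raw < 1.5 → 0, below 3 → 3,
else rounded and clamped at 13).

Attrition is drawn from a logistic model on three severity proxies whose
marginal distributions match the published baseline table (CD4 category,
ART-duration category, comorbidity count); retention rises with CD4 and
ART duration and falls with comorbidity (log-odds 0.35 / 0.20 / −0.40),
and the intercept is solved numerically so the expected completer
fraction equals the target. Dropouts therefore reproduce the published
attrition signature — lower CD4, more recent ART initiation, higher
comorbidity burden.

What the generator does *not* model: item-level frequency/severity/
distress response processes (totals are drawn directly), ordinal
measurement error, floor effects beyond zero-inflation, more than one
lag, and any real biology behind the severity proxies. Passing recovery
tests therefore demonstrate that the estimator recovers the model class
it assumes at study scale — not robustness to misspecification.

Recovery at study scale (n ≈ 706 completers, default truth): median
correlation between true coefficients and ln(estimated OR) across 20
seeds is ≈ 0.7 (the repo's regression bar is 0.6), with support
sensitivity ≈ 0.4 and specificity ≈ 0.84 — the expected profile for weak
true effects under CV-min: many sub-threshold edges are missed, few are
invented, and those invented are small.

## Problem sizes and numerical choices

The test suite and the acceptance script run the published-matrix and
contingency-table checks at full scale, parameter recovery at full study
scale (32 nodes, 20 seeds), and the bootstrap properties on reduced
instances (6–10 node networks, n = 500–2000, 100 resamples, fast mode)
— sizes chosen so the entire suite completes in a few minutes on one CPU
while keeping every property at the scale where it is informative.
Degenerate inputs are rejected loudly (constant outcomes, zero-margin
tables, n < folds); constant predictor columns are tolerated (their
z-score is all-zero and the coefficient is 0). Scores are validated
against {0} ∪ [3, 13] on every panel read.

## Known limitations

- The gaussian family's "OR scale" is a presentation convention
  (exponentiated standardized coefficients), not a true odds ratio; the
  binomial family provides the literal one. Which convention a published
  matrix used is usually not stated and cannot be inferred from the
  numbers alone.
- CV-min density, bootstrap CI coverage for shrunken estimates, and the
  difference test's null behavior are all entangled with regularization;
  none is a calibrated inferential procedure.
- Exact Fisher tests are limited to 2×2 tables; larger tables use a
  seeded Monte Carlo analogue with fixed-margin (Patefield) sampling.
- Two waves only; no ordinal family; no time-varying covariates.
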