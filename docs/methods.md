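# Methods

## The selection model

qPCR reports, per (gene, sample) reaction, a quantification cycle Cq
that is inversely proportional to log initial template; reactions that
never cross threshold yield no value (non-detects). We model the latent
complete data per gene *i*, sample *j* as

    X_ij = θ_ik(j) + δ_j + ε_ij,    ε_ij ~ N(0, σ²_i),

where k(j) indexes the sample-type (replicate group) of sample j, δ_j
is an optional global per-sample shift, and σ²_i is a common residual
variance across sample types per gene. Genes are treated as independent.
Detection is modelled jointly with the data ("selection model"): the
probability that a reaction drops out depends on its own latent value,

    Pr(Z_ij = 0 | X_ij = x) = h(β0 + β1 x)   for x <  S,
    Pr(Z_ij = 0 | X_ij = x) = 1              for x >= S,

with h the inverse link (logistic by default; probit and cloglog are
supported) and S the hard detection limit. One mechanism is shared by
the whole experiment and fit by pooling every reaction. β0 is the
non-detect log-odds at Cq 0 and β1 the log odds-ratio per cycle; with
β1 > 0, lowly expressed targets (high Cq) drop out more often, which is
the empirically observed orientation. Observed values at or above S are
coerced to non-detects on validation.

Identifiability and conventions:

- δ_j is constrained to sum to zero when estimated, and is fixed at zero
  by default (the shifts are rarely identifiable in small panels, and the
  synthetic benchmark generates data with δ = 0).
- Every (gene, sample-type) cell must contain at least one detected
  replicate; cells violating this are a hard validation error, because
  the group mean is then determined only through the missingness
  likelihood, which has no finite maximizer.
- Non-detects may be encoded either as a sentinel Cq at the detection
  limit (instrument convention) or as explicit missing values; the
  boolean detection matrix is carried internally either way.

## Estimation (ECM)

The observed-data likelihood multiplies, per cell,

- detected: `N(y; μ, σ²) · (1 − h(β0 + β1 y))`,
- non-detect: `∫_{-∞}^{S} N(x; μ, σ²) h(β0 + β1 x) dx + ∫_S^∞ N(x; μ, σ²) dx`,

and is maximized by expectation–conditional-maximization. Each
iteration: (A) E-step E(W) per non-detect, then θ (and δ) by least
squares on the completed data; (B) E-step refreshed at the new means,
then σ²_i by the maximum-likelihood variance formula (1/J form) using
E(W²); (C) E-step refreshed again, then (β0, β1) by maximizing the
*expected complete-data* log-likelihood of the mechanism — detected
cells contribute log detect-probability at their observed Cq,
non-detects the conditional expectation of the log non-detect
probability evaluated on the same quadrature grid as the moments (the
hard tail contributes zero). Step (C) re-estimates the mechanism from
all available information every pass while remaining a proper
conditional-maximization step, so the monitored objective is
non-decreasing by construction; a decrease beyond 1e-6 (relative) raises
an error as a bug signal, and the test suite asserts monotonicity at
1e-8.

Initialization: non-detects start at their (gene, sample-type) detected
means — the mean-imputation baseline. Convergence: relative change of
the monitored objective below `tol = 1e-8`, `max_iter = 200`;
non-convergence sets a flag rather than raising. After convergence σ² is
polished to a fixed point of its own update map (1e-13) so that the
stored variances satisfy the ML variance formula exactly at the stored
parameters — this makes the MLE-vs-SI variance-gap identity hold to
numerical precision rather than to the looser likelihood tolerance.

With zero non-detects the algorithm reduces to the complete-data sample
estimates in one iteration.

### Separation and the regularized mechanism fit

Completed data can exhibit (near-)perfect separation between detected
and non-detected values — hard truncation induces it exactly. The
default fit therefore maximizes a penalized likelihood with the
weakly-informative heavy-tailed priors of the standardized-coefficient
approach: Cauchy(0, 10) on the intercept and Cauchy(0, 2.5) on the
slope after centering the predictor and scaling to sd 0.5. These are
that approach's published defaults, not tuned values. The
standardization used by the prior is frozen at initialization inside the
ECM so the penalized objective stays a fixed function of the parameters.
The unregularized path (ordinary GLM) detects separation via exploding
standard errors and raises. The covariance of (β̂0, β̂1) — needed by the
MI "fit" source — is the inverse observed information of the penalized
pooled binary regression at the fixed point.

### Conditional moments

E(W | non-detect) and E(W² | non-detect) are computed as the moments of
`N(x; μ, σ²) · h(β0 + β1 x)` on (−∞, S) plus the closed-form normal tail
moments on [S, ∞). The public scalar routine uses adaptive quadrature
(relative tolerance 1e-8, splitting at mechanism breakpoints such as a
step cutoff); the ECM hot path uses a vectorized composite
Gauss–Legendre rule (28 panels × 12 nodes per cell on
[μ − 8σ, min(μ + 8σ, S)]) with the middle panels placed across the
sigmoid transition ±4/|β1|, which keeps even near-step mechanisms
(|β1| ≈ 30) accurate to better than 1e-8 relative; the two integrators
are cross-checked in the tests. Under a step mechanism the moments
reduce to the truncated-normal closed form, used as an exact oracle.

### Standard errors

se(θ̂_ik) comes from the observed information, diagonal approximation:
detected replicates contribute 1/σ², non-detects
(σ² − Var(W | non-detect))/σ⁴ — the exact second derivative of a
non-detect cell's marginal log-likelihood in its mean. Cross-terms with
σ² and β are neglected.

## DirEst, single imputation, and the variance gap

DirEst reports (θ̂, se(θ̂), σ̂²) and never materializes per-cell values —
sufficient for differential-expression analyses. SI completes the data
at E(W); the empirical variance of that completion equals σ̂²_MLE minus

    gap_i = (1/J) Σ_{non-detect cells j} [E(W_j²) − E(W_j)²],

strictly positive for any gene with a non-detect and non-decreasing as
more cells are masked. The package computes the gap independently from
the conditional moments and verifies the identity against the empirical
SI variance at 1e-10.

The reported σ̂² is the literal 1/J maximum-likelihood form. With K
estimated group means its finite-sample expectation is σ²(1 − K/J); no
degrees-of-freedom correction is applied, keeping the estimator exactly
the quantity the variance-gap identity is stated for.

## Multiple imputation

For each of M (default 10) completed datasets: optionally redraw
(β0, β1) from MVN(β̂, Σ̂_β) ("fit" source); optionally redraw θ from
N(θ̂, se(θ̂)) per cell ("θ" source — the standard error, not the residual
sd, since the source represents parameter uncertainty); recompute each
non-detect's conditional expectation under the drawn parameters; then
optionally add N(0, σ̂²_i) noise ("ε" source). Drawing parameters first
and conditioning afterwards makes the three sources independent by
construction. The mechanism is perturbed, not refit, per imputation.
The seed fully determines the output. Empirically the residual spread of
imputed cells orders fit < θ < ε, i.e. measurement error dominates,
mechanism uncertainty is minor. Estimates are combined across
imputations by the standard combining rules: pooled point = average,
total variance = within + (1 + 1/M) · between.

## Relative quantification

With matched controls (k = 0, Δ_i0 = 0) and batches n,

    X_ij = Δ_ik(j) + γ_in(j) + δ_j + ε_ij   (test samples)
    X_ij =           γ_in(j) + δ_j + ε_ij   (control samples),

fit as a two-step procedure: (1) controls alone under the absolute
model with batch as the replicate group, handling control non-detects
by the requested method (SI / MI / DirEst all complete controls at
conditional expectations; MI produces M control sets); (2) all samples,
with γ_in anchored on the completed controls within each batch and Δ_ik
estimated from the test samples, test non-detects handled by the same
ECM machinery. For MI, step 2 runs per control set and results are
pooled by averaging. Every batch must contain a control sample, and a
control (gene, batch) cell with no detection is an error.

## Synthetic data and the benchmark

The generator emulates a multi-gene qPCR panel near the detection
limit: per gene a grand mean μ_θ ~ TruncNormal(mean 31, sd 3.5, range
[20, 40.5] cycles); sample-type means θ ~ N(μ_θ, σ²_θ = 3) i.i.d.
across types; residual variances σ²_i ~ Unif(0.06, 1.3); δ = 0;
mechanism β0 = −35.7, β1 = 1 (non-detect odds crossing 1/2 at Cq 35.7);
hard limit S = 40, with non-detects written as the sentinel 40. Defaults
are 16 genes, 6 sample types, m ∈ {4, 6, 10} replicates. These settings
put roughly 13–14% of reactions below detection, concentrated in the
high-Cq genes; about 4% of (gene, sample-type) cells come out entirely
non-detect, which the model cannot estimate.

The benchmark therefore excludes the offending genes from the affected
replicate's fit and scoring (with a logged count) instead of failing the
replicate — the same policy the masking procedure applies. Each of the
(default 100) replicates calls the simulator afresh, redrawing the
generating parameters as well as the noise, so the reported medians
estimate performance over the generator's full parameter distribution;
a fixed parameter set can be supplied to emulate a single repeated
experiment instead. Scoring: per-cell bias (mean error across
replicates) and MSE (mean squared error) for θ and for
σ²_θ = σ²_i / m, summarized by 25/50/75% quantiles (linear
interpolation) across cells. Per-replicate seeds derive from the master
seed by counter; datasets are shared across methods and links, so
link-robustness comparisons use common random numbers. External
estimators can be scored through a subprocess contract (long-CSV in,
per-(gene, sample-type) table out).

What the synthetic benchmark does *not* emulate: reference-gene
normalization noise, amplification-efficiency differences, batch
structure in the absolute design, gene–gene correlation, and
instrument-specific artifacts. Passing benchmarks therefore demonstrate
correctness of the estimators under the stated generative model, not
performance guarantees on arbitrary real experiments.

The masked-data experiment generates a complete panel (80 genes by
default), imposes a new limit at Cq 30 (values strictly above are
masked; a value exactly at 30 is retained), drops genes left with an
all-masked sample type, and checks that (a) a regularized logistic fit
on the ECM-completed data recovers the induced near-step mechanism
(crossing within 0.5 cycles of 30, rising 0.05→0.95 within one cycle)
and (b) DirEst/MI estimates sit closer to the complete-data estimates
than limit substitution. The steep sigmoid is a property of the
plug-in completed-data fit; the exact ECM conditional step correctly
attributes masked mass to the hard limit and is not expected to produce
it.

## Numerical choices and limitations

- Quadrature: panels/nodes as above; domain ±8σ (the selection tilt
  shifts mass by at most β1σ², covered with margin at the benchmark's
  parameter ranges); normal tail handled in closed form.
- Ties/degenerate inputs: zero-width quadrature panels contribute zero;
  a σ² floor of 1e-10 guards degenerate genes; singular mechanism
  covariance degrades the MI "fit" draw to the point estimate with a
  warning.
- Problem sizes: the shipped benchmark uses 100 replicates of 16 x 36
  datasets (and the m = 4/10 and probit/cloglog variants), chosen to
  match the study design while keeping a full run in minutes on one
  CPU.
- Known limitations: no gene–gene dependence or variance shrinkage
  across genes; no gene- or sample-specific mechanisms; no
  amplification-efficiency correction; methods are inapplicable when a
  (gene, sample-type) cell has no detections, and results near the
  limit assume a non-detect reflects low (not zero) expression.
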