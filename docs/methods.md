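# Methods

## Target and estimators

The package targets the parameters of a working marginal structural model
for a time-varying binary treatment,

E(Y^ā | L01) = μ0 + μ1·L01 + μ2·cum(ā)  (optionally + μ3·L01·cum(ā)),

identified under consistency, sequential positivity and sequential
conditional exchangeability.  Two estimators are provided.

**Sequential G-computation.**  The nested counterfactual means are defined
backward from q_{T+1} = Y by q_t(ā, L̄_t) = E(q_{t+1} | Ā_t = ā_t, L̄_t).
Each step is a user-specified linear regression (main terms of the history
by default; interaction and power terms via a small term language such as
`"C0*A0"`, `"I0^2"`) fitted on the observed data and predicted with the
treatments forced to each pattern.  The stacked time-0 predictions over all
patterns are regressed on the MSM design.  No analytic standard error is
produced; the generic subject-level (m-out-of-n) bootstrap applies.

**Stabilized IPTW.**  Weights are ∏_t num_t/den_t with denominators from
the fitted pooled treatment model and numerators, per time, from a logistic
model of A_t on L01 alone (the MSM conditioning set).  The numerator choice
is swappable (`"marginal"` frequencies or a user matrix); stabilization
affects efficiency, not consistency, because the numerator conditions only
on MSM covariates.  The MSM is fitted by weighted least squares with the
HC0 sandwich covariance.  Weight truncation is available only by the user
pre-processing the weights; the default applies none.

## Working structural models and adaptive weights

The selection criterion retains covariates with nonzero coefficients β in
the working regressions of q_t^ā on the covariate history and past
treatments (one model per treatment time, stacked over patterns with unit
replicate weights).  β̂ is obtained by OLS on the stacked predictions.
Stacking is unweighted: the package does not weight patterns by their
empirical plausibility, a deliberate convention since the stacked risk
already defines β.  The adaptive penalty weight of coefficient j = (τ,t,k)
in the pooled treatment model is ω̂_j = |β̂_j|^(−γ).  γ defaults to 2.5:
selection consistency needs λ/n → 0 and λ·n^(γ/2−1) → ∞, which requires
γ > 2, and a value only slightly above 2 keeps the weights stable when β̂
is noisy.  β̂ exactly zero maps to a finite cap of 1e12 so the objective
stays finite while effectively excluding the covariate.

## Pooled design and the selection step

The pooled design has one row per (subject, treatment time) and blocks
V_{τ,−1} (per-time intercept indicators — there is no global intercept),
V_{τ,t,k} = 𝕀(time=τ)·L_{t,k} for t ≤ τ, and past-treatment slots
𝕀(time=τ)·A_{k<τ}.  Intercepts and treatment slots are never penalized.
For absorbing processes (monotone treatment, censoring) rows after the
first event are dropped; times are 0-based and histories are closed on the
left, open on the right of τ.  Future covariates are rejected at design
construction.

The weighted-L1 logistic path runs over a descending log-spaced grid of
30 λ values (configurable 20–50) from λ_max — computed from the KKT bound
max_j |gradient_j|/ω̂_j at the model with only unpenalized columns — down
to λ_max·1e-4, warm-started.  The solver is IRLS with cyclic coordinate
descent on the weighted quadratic approximation; convergence requires both
a coefficient change below tolerance and a KKT residual of the exact
sum-scale penalized objective below 1e-7 (at most 1e4 outer iterations; a
convergence failure raises an error carrying the λ index).  An equivalent
column-rescaling implementation would be admissible; the explicit weighted
solver was chosen because it extends directly to the zero-weight
(unpenalized) columns.

λ is selected by covariate balance, not predictive loss.  The balance
metric is a longitudinal weighted absolute mean difference: for each time
τ and each candidate covariate, the absolute difference of the
stabilized-IPT-weighted covariate means between the A_τ = 1 and A_τ = 0
rows, multiplied by the covariate's |β̂| and summed over covariates and
times, with equal weight across times.  Cumulative stabilized weights use
marginal per-time event frequencies as numerators (stabilization cancels
in the mean ratios but improves numerics).  This form of the metric is a
package reconstruction of the single-time-point construction it extends,
so it is isolated in
a single function (`loal.balance_score`) and can be swapped; its
`extra_weights` hook lets a companion censoring process contribute
multiplicative weight factors, which is how a joint treatment-plus-
censoring tuning criterion would be assembled.  Ties select the largest λ
(most parsimonious model).  λ grid points whose fitted probabilities hit
0/1 numerically are infeasible; if all are infeasible, the error advises
extending the grid.  A fixed-λ rule (for example λ = n^a, a < 0.5) can be
used by passing an explicit grid.  After selection, the model is refitted
unpenalized on the active set plus the protected columns (α̂refit).

## Fusion step

A fusion graph over the selected coefficients says which may share a
value: baseline covariates across model times (clique by default, chain
optional), time-varying covariates at equal lag τ−t (via a
`variable_family` map when repeated measurements carry distinct names).
The objective adds λ₁·Σ_edges |α*_u − α*_v| / |α̂ʳᵉᶠⁱᵗ_u − α̂ʳᵉᶠⁱᵗ_v|^γ₁ to
the pooled logistic negative log-likelihood, with no magnitude penalty —
selection and fusion have different statistical goals (balance versus
model simplification), so the zero pattern of the first step is preserved
exactly.

The solver is IRLS where each weighted-least-squares subproblem
½α'Qα − b'α + Σ|d_e'α| is minimized exactly through its smooth dual
(box-constrained quadratic, L-BFGS-B), giving a per-solution dual
certificate for the KKT conditions.  Coefficients equal within a relative
1e-6 tolerance are snapped to exact equality by refitting the logistic
model with the fused columns summed; "fused" is therefore a discrete
property.  The λ₁ grid is {0} plus 20 log-spaced points whose upper end is
doubled until every edge fuses, so the path always spans no-fusion to full
fusion.  (γ₁, λ₁) are selected by BIC = −2·loglik + df·log(N_rows) on the
snapped-refitted models, with df counting distinct values among penalized
coefficients plus the unpenalized parameters — the standard fused-lasso
convention, adopted here as the standard choice.  γ₁
defaults to the single value 2.5 (a grid such as {1, 2.5, 4} can be
passed); BIC ties prefer fewer degrees of freedom, then larger λ₁.  With
one fusible pair this selection rule is equivalent to a likelihood-ratio
test of coefficient equality at the log(N) threshold, which is why the
oracle-weighted fusion rate sits near 0.99.

## Synthetic data-generating process

`scenario1_spec` builds a two-time-point process: C0, I0 iid N(0,1);
A0 ~ Bern(expit(1.515·C0 + I0)); C1 ~ N(A0 + C0, 1); I1 ~ N(C0, 1);
A1 ~ Bern(expit(−0.5 + 0.5·C0 + 0.25·C1 + 0.5·A0 + I1)); and a Gaussian
outcome.  The treatment process is constructed so that the marginal
(instrument-free) logistic coefficient of C0 is about 1.28 in *both*
treatment models, making the time-shared (fused) C0 coefficient correct.
Covariates are standardized to zero sample mean and unit sample sd after
generation (mirroring applied practice); treatments and the outcome are
left raw; the constants are recorded.

The default outcome coefficients,

Y = −1.5 + 0.5·C0 + 0.25·A0 + 1.0·C1 + 1.25·A1 + ε,  ε ~ N(0,1),

with + 2.5·C0·C1 for the covariate-interaction variant and + 2.5·A0·C1²
for the effect-modification variant, were chosen so the three
variants have clean closed-form true MSM parameter values —
(−1.5, 1.5, 1.25), (1, 2.75, 1.25) and (−1.5, 4, 5) respectively; under the main-terms
variant the total effect of a0 (0.25 directly + 1.0 through C1) equals the
a1 effect, so the MSM is exactly linear in cum(ā) and every correctly
weighted estimator targets the same truth.  All Gaussian noise sds default
to 1 — a package convention — and every coefficient
is overridable.

True MSM parameters are computed by Monte-Carlo: counterfactual outcomes
under every pattern are simulated with common random numbers (patterns
only alter the forced treatments, so sharing exogenous draws is valid and
reduces variance; it also makes forcing the observed treatments reproduce
the factual outcome exactly), then least-squares-projected onto the MSM.

What the generator does *not* emulate: non-Gaussian or discrete
covariates, nonlinear treatment assignment, informative visit processes,
time-to-event outcomes, or realistic missingness.  Passing tests therefore
certify the estimation machinery under correctly structured parametric
data, not robustness to violations of those structures.

## Simulation harness

`run_experiment` replicates (generate → estimate → record) over derived
per-replication seeds (SeedSequence spawn keys, fully reproducible from
the base seed) and reports n×|mean bias| and n×mean|bias| (both, since
"n times absolute bias" is ambiguous between them), n×MSE, Monte-Carlo
SEs, selection proportions per covariate and model time, and fusion
proportions per covariate family.  Failed replications are excluded and
counted.  The default replication count is 200 with Monte-Carlo SEs always
reported; the test suite uses 200 replications and sample sizes
200–1000 (1000 for the efficiency comparisons), with truth evaluated on
4·10⁵–10⁶ Monte-Carlo draws — sizes chosen so the whole suite runs on a
desktop while keeping Monte-Carlo error visibly smaller than the effects
being asserted.  The q-model preset for the two-time-point scenario adds a
confounder-by-treatment interaction and a squared instrument to the time-0
regression: harmless under the main-terms outcome process, deliberately
misspecified under the interaction variants.

## Known limitations

* Post-selection inference is not addressed: sandwich standard errors
  ignore the selection and fusion steps, and the m-out-of-n bootstrap is
  provided as a hook without coverage guarantees.
* Treatment models are linear-logistic; covariate interactions or
  nonlinearities in the propensity are out of scope.
* The balance metric is a reconstruction (see above) and the BIC degrees
  of freedom a convention; both are isolated behind single functions.
* Exhaustive pattern sets grow as 2^(T+1); beyond T = 5 a restricted
  regimen space must be supplied.
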