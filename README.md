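# loalfuse

Adaptive variable selection and temporal smoothing of pooled treatment
models for marginal structural model (MSM) estimation with time-varying
binary treatments.

## The problem

Estimating the causal effect of a treatment sequence A₀,…,A_T on an
end-of-study outcome Y from longitudinal observational data typically uses
inverse-probability-of-treatment weighting (IPTW) for an MSM such as

    E(Y^ā | L01) = μ0 + μ1·L01 + μ2·cum(ā),

where cum(ā) counts treated time points and L01 is a baseline covariate.
The weights require a model of the propensity g_t(a_t | history) at every
time.  Two things go wrong in practice: adjusting for *instruments*
(covariates that affect treatment but not the outcome) inflates the
variance of the weighted estimator, and fully time-stratified ("saturated")
treatment models overfit when data are sparse.

`loalfuse` implements a two-step remedy for both:

1. **Longitudinal outcome-adaptive LASSO (LOAL).**  The time-specific
   logistic treatment models are pooled into one regression with per-time
   intercept indicators and indicator-masked covariate blocks
   V_{τ,t,k} = 𝕀(time=τ)·L_{t,k}.  Each covariate coefficient α_j is
   penalized with the adaptive weight ω̂_j = |β̂_j|^(−γ) (γ > 2, default
   2.5), where β̂ are coefficients of *working structural models*: the
   nested counterfactual regressions q_t^ā (estimated backward from Y) are
   stacked over treatment patterns and regressed on the covariate history.
   Covariates with no conditional outcome association get huge penalties
   and drop out of the treatment model.  The penalty level λ is tuned not
   for prediction but by a longitudinal covariate-balance criterion —
   |β̂|-weighted absolute differences of stabilized-IPT-weighted covariate
   means, summed over covariates and times.
2. **Adaptive fused LASSO.**  Coefficients of the same covariate in
   different time-specific models are shrunk toward equality along a
   user-chosen fusion graph (clique or chain for baseline covariates,
   equal-lag matching for time-varying ones), with edge weights
   |α̂ʳᵉᶠⁱᵗ_u − α̂ʳᵉᶠⁱᵗ_v|^(−γ₁) and no magnitude penalty, so the selection
   step's zero pattern is preserved.  (γ₁, λ₁) are chosen by BIC; fused
   groups are snapped to exact equality by a shared-column refit.

Both penalized problems are solved by solvers written for this package:
IRLS plus cyclic coordinate descent for the weighted-L1 logistic model and
IRLS plus an exact box-constrained dual solve for the graph fused-LASSO
logistic model, each with verifiable KKT certificates.  Downstream, the
package provides stabilized-weight IPTW with sandwich standard errors,
sequential G-computation, an m-out-of-n bootstrap, a synthetic
two-time-point data-generating process with known truth, and a replicated
simulation harness (n×|bias|, n×MSE, selection and fusion proportions).

The intended audience is biostatisticians and epidemiologists working on
causal inference for longitudinal exposures.

## Worked example

```python
import loalfuse as lf

spec = lf.scenario1_spec("main_terms")      # 2 time points, confounders C0, C1,
data = lf.generate(spec, n=1000, seed=7)    # instruments I0, I1

beta = lf.fit_working_coefficients(data, regressors=lf.scenario1_q_regressors(data))
fit = lf.fit_loal(data, beta)               # selection step
print("selected lambda:", round(fit.lambda_selected, 4))
print("active:", [fit.design.columns[j].label() for j in fit.active])

graph = lf.build_fusion_graph(fit.design, fit.active)
fused = lf.select_by_bic(fit.design, fit.active, graph, fit.alpha_refit)
print("fused groups:", [[fit.design.columns[j].label() for j in g] for g in fused.groups])

probs = lf.pooled_probabilities(fit.design, fused.alpha_star)
weights = lf.compute_weights(data, probs, l01="C0")
est = lf.fit_msm_iptw(data, weights, l01="C0")
print(est.mu.round(3).to_string())
```

prints

```
selected lambda: 0.0784
active: ['tau0:C0', 'tau1:C0', 'tau1:C1']
fused groups: [['tau0:C0', 'tau1:C0'], ['tau1:C1']]
const   -1.559
L01      1.559
cum      1.198
```

Both confounders are selected into the treatment models and both
instruments are excluded; the two C0 coefficients are fused into one
time-shared parameter; and the IPTW estimates sit near the generating
truth (μ0, μ1, μ2) = (−1.5, 1.5, 1.25) — each additional treated time
point raises the expected outcome by about 1.2 on this run.

A command-line interface mirrors the library:
`loalfuse simulate | fit-loal | fuse | estimate | run-sim` (see `--help`).

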