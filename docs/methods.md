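# Methods

## Model and estimation

The engine fits two latent-variable models over four regional 5-HT4R
binding potentials (neostriatum, hippocampus, amygdala, prefrontal
cortex). The *group_only* model has a single structural term — the
MDD−HC shift `γ` of the global latent factor. The *hormones* model adds
testosterone and estradiol main effects on the factor, their
group-interaction terms (`Δγ₁`, `Δγ₂`, coded MDD−HC), and a linear
testosterone→estradiol submodel with slope `γ₃` shared across groups.
Covariates (age, injected tracer mass per kg, scanner) enter the
measurement equations only; group and hormones enter the structural
equation only. Identification fixes the neostriatal loading at 1 with a
free latent disturbance SD; the alternative normalization (unit latent
SD, all loadings free) is available behind a flag and is an exact
reparameterization (verified in the tests by the analytic map between
the two).

Estimation is maximum likelihood. Within each group the model is
linear-Gaussian, so subjects sharing group and censoring status share
one implied covariance and the likelihood vectorizes over rows. The
optimizer is L-BFGS-B on an unconstrained internal parameterization
(SDs on the log scale, covariances and slopes raw), preconditioned by
the diagonal curvature at the starting point; without that
preconditioning the mixed parameter scales (intercepts near 3, hormone
slopes near 0.007) stall quasi-Newton convergence. The preconditioner
is recomputed and the search restarted up to twice if the optimizer
does not report convergence, which handles starts that sit in regions
of negative curvature. Starting values come from per-region least
squares plus moment-based loading ratios from the OLS residual
covariance. Standard errors are the inverse observed information
(central-difference Hessian, relative step 1e-4; SE step-size
stability was checked over 3e-5..1e-3). A singular Hessian leaves SEs
marked unavailable rather than failing the fit; a non-converged fit
withholds estimates entirely.

## Left-censored estradiol

Estradiol values at or below the assay LOQ (0.09 nM) are known only to
lie below the limit. Because `(Y, E) | T, G, x` is jointly Gaussian,
integrating the likelihood over `E ≤ LOQ` has the closed form
`φ(Y; μ_Y, Σ_YY) · Φ((LOQ − μ_{E|Y})/σ_{E|Y})`. Three treatments are
implemented:

- `integrate_full` — the exact per-group integral (the group-specific
  estradiol slope `γ₂ + Δγ₂G` carries the integration);
- `integrate_main_only` — integration only through the main estradiol
  pathway, with the interaction covariate plugged in at the LOQ. This
  reproduces the simplification used when jointly integrating main and
  interaction pathways makes estimation fragile at small n; it is the
  default for the hormones model;
- `plugin` — censored values treated as observed at the LOQ.

All three coincide on uncensored data (asserted to 1e-10), and the
closed form is checked against adaptive quadrature of the joint density
to better than 1e-8 across 100 random parameter draws.

## Mediation decomposition

`direct = γ₁(group)`, `indirect = γ₂(group)·γ₃`, `total` their sum; the
MDD−HC total contrast reduces to `Δγ₁ + Δγ₂·γ₃` because `γ₃` is shared.
Inference is the first-order delta method on the joint covariance of
(γ₁, Δγ₁, γ₂, Δγ₂, γ₃); no second-order correction is applied, matching
the symmetric confidence intervals standard latent-variable software
reports. Delta-method SEs agree with a 2000-draw parametric bootstrap
(parameters resampled from the fitted Gaussian) within 10% in the
tests. The decomposition is also exposed for plain coefficient dicts
(`decompose_from_coefs`) so published coefficient tables can be pushed
through the same code path. When the healthy-control coefficients
−0.0074, 1.74 and 0.003 are combined, the signed total is −0.0022; the
package reports signed values and summaries quote the magnitude 0.002.

## Score-test refinement of the residual covariance

For every region pair without a free residual covariance, a Rao score
test evaluates the extended model at the restricted MLE with the
candidate fixed at 0: `U_c² / (I_cc − I_cθ I_θθ⁻¹ I_θc)` against
chi-square(1). The information in this statistic is the *expected*
(Fisher) information, assembled stratum-wise from the implied Gaussian
moments (mean part `Σ ∂μ' Σ⁻¹ ∂μ`, covariance part
`n/2 · tr(Σ⁻¹ ∂Σ Σ⁻¹ ∂Σ)`, derivatives by central differences). The
observed information was tried first and rejected: at a restricted
estimate under exactly the misspecification the test must detect, the
observed information can turn indefinite in the candidate direction,
producing negative variance estimates for the score. The expected
information is positive semi-definite by construction, and its Schur
complement is therefore a valid variance. For censored strata the
information uses the marginal-Y Gaussian block; the score itself always
uses the exact likelihood. Score and likelihood-ratio statistics agree
within 10% for the top candidate on large-n data.

Refinement loops: fit, score-test all candidates, Holm-adjust within
the current round (the candidate family shrinks each round, and the
adjustment is per-round; whether one should adjust across rounds is
genuinely open, and per-round is the choice documented here), free the
smallest-p candidate if its adjusted p < α, warm-start the extended
refit at the previous estimates, repeat. Ties break lexicographically;
the loop is deterministic given data.

## Gehan's generalized Wilcoxon test

Left-censoring semantics: a censored value at c means "≤ c"; an
uncensored v separates from it only when v > c; two censored values
never separate; tied uncensored values score 0. The statistic is the
sum of +1/0/−1 scores over all between-group pairs, computed via pooled
per-observation scores (within-group terms cancel by antisymmetry,
which the tests verify against direct pairwise enumeration). Inference:
exact permutation by enumeration when the pooled n ≤ 10, Monte-Carlo
permutation (default 10,000 draws, seeded) otherwise, or the asymptotic
normal reference with the permutation variance
`n₁n₂ Σ s_k² / (N(N−1))`. With no censoring the statistic equals the
Mann–Whitney `U₁ − U₂`.

## Symptom–hormone–binding network

Nodes for the MDD subgroup: neostriatal BP_ND residualized on age and
dose, testosterone residualized on age, a binary below-LOQ estradiol
indicator residualized on age (linear-probability residuals keep the
correlation matrix well defined; flagged in output), the HAMD6 core
sum (items 1, 2, 7, 8, 10, 13), and five vegetative items (initial,
middle and delayed insomnia, gastrointestinal, weight loss) — nine
nodes. The graphical-lasso path over 100 log-spaced penalties (0.01–1
times the largest absolute off-diagonal correlation) proposes candidate
edge sets; each distinct support is refitted by the unpenalized
Gaussian MLE with that zero pattern (iterative proportional scaling
over edges), and the refit minimizing
`EBIC = −2ℓ + k·log n + 4·k·γ·log p` with γ = 0.5 is kept. Scoring
supports at their constrained MLE rather than at the shrunk path
solution is what makes the extended BIC consistent for support
recovery; scoring the shrunk solutions directly was tried first and
selected systematically too-dense graphs (spurious partial correlations
of 0.01–0.09), because small penalties are rewarded for unshrinking
strong true edges. Edges are partial correlations of the refitted
precision. Strength is the sum of absolute incident weights;
betweenness counts shortest paths with edge length 1/|weight|; both are
also z-scored across nodes since the standardization convention for
published centralities varies. Below 3 observations per node the
estimate is unstable and the module demands an explicit
acknowledgement flag.

## Synthetic cohorts

The generator draws, in order: covariates (group-specific truncated
normal age in 18–50; lognormal dose matching the printed group means
and SDs 0.012 (0.011) and 0.019 (0.015) μg/kg; GE-scanner assignment
for a configurable fraction of controls only, 6/52 by default),
testosterone (group-specific normal with the printed moments 16.7
(7.4) / 17.9 (5.7) nM, folded at zero), uncensored estradiol from the
hormone submodel, the latent factor from the structural equation, and
the four regional outcomes from the measurement equations with the
hippocampus–amygdala residual covariance. Censoring is applied last,
so the "true" estradiol exists for oracle tests and the structural
model is literally true in the simulated population. One master seed
spawns independent per-stage streams; identical seeds give bit-identical
tables.

Published values fix the group effect (−0.07), the hormone→latent
slopes (−0.0074 / 0.0001 for testosterone, 1.74 / 0.64 for estradiol),
`γ₃` (0.003), the LOQ (0.09 nM), sample sizes and testosterone moments.
No regional intercepts, loadings, residual scales, or estradiol
intercept/scale are published numerically; the defaults (ν = 3.00,
1.05, 1.00, 0.65; λ = 1, 0.45, 0.40, 0.30; σ = 0.22, 0.12, 0.12, 0.08;
σ_ζ = 0.12; hippocampus–amygdala covariance 0.004, i.e. residual
correlation ≈ 0.28; α_E = 0.05, σ_E = 0.03) are free choices that give
positive BP_ND with the high/intermediate/low regional ordering and
roughly 35–45% estradiol censoring. With a single shared estradiol
intercept the two groups' censoring fractions cannot simultaneously
match the extreme printed split (56% vs 8%); the generator reproduces
the mechanism and a realistic overall rate rather than that split.
HAMD items are ordinal scores from thresholded latent normals; the
five vegetative items load on standardized testosterone (default
loading 0.5), the rest are hormone-independent, and the marginal level
probabilities target a moderate-to-severe cohort (expected HAMD-17
total ≈ 22). Zero SDs are permitted so that noise-free cohorts exist
for exactness tests.

What the generator does *not* emulate: assay changes mid-study, scanner
resolution differences beyond a mean shift, non-Gaussian BP_ND tails,
item-level HAMD dependence beyond the single testosterone factor, and
any selection effects in recruitment. Passing tests therefore show the
machinery is correct under the stated model, not that the model is true
of any real cohort.

## Simulation scales and numerical choices

Parameter recovery runs 200 replicates at n = 2000 (1000 per group) for
both model specs, fitting with the exact (`integrate_full`) likelihood
and warm starts at the generating values — the MLE is the same optimum
regardless of start, and data-driven starts are exercised separately.
Mean estimates are required within 3 Monte-Carlo SEs of truth and 95%
CI coverage within [90%, 98%]. Score-test calibration uses 400
correctly specified replicates at n = 400 for the refinement trigger
and 150 misspecified replicates at n = 2000 (generator-default
hippocampus–amygdala covariance) for detection order. Graphical-lasso
support recovery uses a 5-node chain with partial correlations 0.35 at
n = 500, 100 replicates. The optimizer tolerance is gtol 1e-5 on the
preconditioned scale with ftol 1e-12, at most 500 iterations per
restart; likelihood evaluations returning non-finite values (degenerate
implied covariance) are mapped to a large penalty rather than clipped
silently. Internal log-SDs are capped at 150 to keep wild line-search
excursions from overflowing.

## Known limitations

- No robust/sandwich variances and no FIML for general missingness;
  subjects missing any model variable are dropped listwise with a
  logged count.
- The `integrate_main_only` mode is deliberately a simplification; for
  MDD-censored rows it mildly misstates the interaction pathway, which
  is why recovery studies use `integrate_full`.
- The network module's small-sample behaviour (n below 3 nodes'
  worth of observations per parameter) is acknowledged unstable; the
  study-scale pipeline runs it only behind the acknowledgement flag.
- Betweenness on near-equal edge weights is sensitive to tiny weight
  perturbations (shortest paths switch discretely).
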