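# Methods

## The model

Visits (level 1) are nested within subjects (level 2).  The outcome of
visit *t* in subject *i* is an ordered stage Y_ti ∈ {1, …, K} (default
K = 4: WHO immunological stages, 1 = normal, 2 = mild, 3 = advanced,
4 = severe, from CD4 bands [500, ∞), [350, 500), [200, 350), [0, 200)
cells/mm³).  The cumulative logits are

    logit P(Y_ti ≤ k) = δ^(k) + x*_ti′ β_c^(k) + x_ti′ β + u_0i + u_1i·t_ti

for k = 1, …, K−1, with strictly increasing thresholds δ^(1) < … < δ^(K−1),
shared (proportional-odds, PO) coefficients β, category-specific
(non-proportional-odds, NPO) coefficients β_c^(k) for the covariates in
x*, and a subject-level random intercept and time slope
(u_0i, u_1i) ~ N(0, D).  The sign convention follows the staging: a
positive coefficient raises P(Y ≤ k), i.e. favours better stages.

Under NPO a parameter vector can make the cumulative logits non-monotone
in k at an observed covariate pattern, implying a negative category
probability.  Such vectors receive log-likelihood −∞ (soft rejection).
This keeps the parameter space simple and is standard practice for
partial-proportional-odds fitting; its side effect is that the NPO
alternative is a constrained superset of the PO null, which makes the LR
test slightly conservative for continuous covariates with wide support
(see Calibration below).

The latent-scale intraclass correlation uses the standard-logistic level-1
variance π²/3: ICC = σ²_v0 / (σ²_v0 + π²/3).  At the reference intercept
variance 12.21 this gives 0.7877.  (The motivating study prints an ICC of
0.76 for the same variance, which is inconsistent with its own formula;
this package implements the formula.)

## Estimation

**Marginal likelihood.**  Random effects are integrated out by adaptive
Gauss–Hermite quadrature.  For each subject the conditional posterior of
u is maximized by Newton iteration in *prior-whitened* coordinates
v = L⁻¹u (L the Cholesky factor of D): the Hessian there is I plus a
positive-semidefinite likelihood curvature, so the system is well
conditioned for any admissible D, including a vanishing slope variance or
an intercept–slope correlation at ±1.  The tensor node grid
(`quad_order` nodes per dimension, default 9; experiments below use 5)
is centred at the mode and scaled by the Laplace curvature.  A zero D
degenerates to the conditional likelihood at u = 0; an intercept-only
model uses a 1-D grid.

The integrator was validated two ways: against plain Monte-Carlo
integration with 200,000 prior draws (agreement within 3 MC standard
errors per subject) and against direct adaptive numerical integration
(`scipy.integrate.quad`, agreement to ~1e-9 at order 61).  A caveat worth
stating: with an intercept variance as large as 12.21, subjects with only
1–3 visits whose outcomes all sit in one wide middle category have
posterior integrands shaped like soft-edged truncated Gaussians.  Tensor
Gauss–Hermite converges slowly on those (per-subject error ~2e-3 at
order 7, ~2e-4 at 15, ~2e-5 at 21); scale inflation and moment-matched
re-centering were tested and do not materially help.  Order-7 and
order-15 evaluations therefore do *not* agree to 1e-4 per subject on
default cohorts — an inherent property of the quadrature family on this
problem, not an implementation defect.

**Maximum likelihood.**  L-BFGS-B on an unconstrained parameterization:
δ^(1) plus log-increments for the thresholds, free coefficients, and D
through its Cholesky factor with log-diagonal (loose box bounds keep the
log-scale parameters from numerical runaway).  The gradient is computed
by forward differences from a per-subject mode snapshot so that every
perturbed evaluation shares the same warm start, making the gradient
smooth; the endpoint is re-validated from a cold mode state and the best
visited point is kept.  Standard errors come from the inverse numerical
Hessian (central differences, relative step 1e-3), mapped to the
reporting scale (thresholds, coefficients, variance components) by a
delta-method Jacobian; 95% intervals are Wald on the logit scale,
exponentiated for odds-ratio reports.  Deterministic start: thresholds at
the logits of the marginal cumulative frequencies, coefficients 0,
D = diag(1, 0.01).

**MCMC (for DIC).**  Adaptive random-walk Metropolis on the same
unconstrained parameterization, targeting marginal likelihood (random
effects integrated by the same quadrature) plus priors: diffuse normals
(SD 10) on coefficients and threshold parameters, half-normal (scale 5)
on the random-effect SDs, uniform on their correlation, with the exact
Jacobian of the Cholesky-log transform.  Per-coordinate proposal scales
come from the MLE covariance when available; the global scale adapts
toward ~30% acceptance during burn-in.  Deviance is −2× the marginal log
likelihood; dbar is its posterior mean, pD = dbar − deviance at the
posterior mean, DIC = dbar + pD.  This MLE+Metropolis pair is a
methodologically equivalent target to the MLwiN/SAS MCMC used in the
motivating study, not a software reproduction; its printed DIC/deviance
values depend on that software's deviance definition and are not
comparable level-for-level.

**Proportionality test.**  LR statistic = (−2logL of the PO fit) −
(−2logL of the NPO fit), χ² with (K−2) degrees of freedom per freed
covariate (the PO fit's single coefficient becomes K−1).  The NPO fit is
initialized from the PO solution with each freed coefficient replicated
across logits, which guarantees a non-negative statistic up to optimizer
tolerance (enforced at 1e-4).  The motivating study prints a LR χ² of
159.51 next to −2logL values that differ by 229.73; the two cannot both
arise from one nesting, so this package always computes the statistic
from its own pair of fits and prints the df beside it.

## The synthetic cohort generator

The generator emulates the study conditions the analysis assumes:

- **Cohort**: 219 subjects (configurable), all female in the motivating
  cohort; baseline covariate frequencies follow the published baseline
  table (age groups 29/178/12, education 16/50/153, marital 34/174/11,
  sex-under-alcohol 22/219 over 219).
- **Follow-up**: per-subject duration ~ lognormal with median 2.12 years
  and log-SD 1.61 — chosen to match the published median *and* IQR
  (0.67–5.86) — truncated at 13.13 years; visits are a homogeneous
  Poisson process (default 4/year) inside the window, plus a baseline
  visit at t = 0.  A single common follow-up window cannot reproduce a
  2.12-year median follow-up at any visit rate, which is why the duration
  is per-subject.
- **Outcomes**: drawn visit-by-visit from the cumulative-logit model with
  thresholds ln(0.02, 19.87, 24.51), D = [[12.21, −0.36], [−0.36, 0.02]]
  (the study body also prints 12.81 for the intercept variance; the
  tabulated 12.21 is used), and coefficients at the ln of published odds
  ratios: cART 0.25 (=ln 1.28), viral load −0.65 (=ln 0.52), physical QoL
  0.10 (=ln 1.11), plus a latent time trend of +0.15/year.  The study
  labels its time effect "per month" with ORs up to 1.76, which cannot be
  a per-year rate over 13 years; +0.15/year was fixed once as a clinically
  plausible recovery trend.  Continuous covariates enter the true model
  centered (viral load at 4.46 log10 copies/ml, physical QoL at 14) so the
  thresholds keep their published marginal meaning.
- **cART**: initiated from the first visit *after* a visit with stage ≥ 2
  (CD4 < 500 cells/mm³) and never reverts; initiation cannot precede the
  qualifying observation.  Because the published thresholds put most
  subjects at stage ≥ 2 early, cART behaves almost like a
  "post-baseline" indicator and is weakly identified against the
  thresholds — visible as the largest finite-sample biases in the
  recovery experiment.
- **CD4 counts**: drawn uniformly within the stage's band, with invented
  caps (1200 above, 50 below) for realism, so WHO staging round-trips
  exactly.
- **Phases**: II = [0, 0.25), III = [0.25, 1), IV = [1 year, cART),
  V = on cART; half-open on the left.
- **Clinical panels**: X = FΛ′ + E with standard-normal factors, the
  published white-cell loading block (0.925/0.936/0.635 granulocyte,
  0.838/0.616 mononuclear, 0.947 eosinophil) and noise SDs
  √(1 − communality).
- **Randomness**: a single seed feeds a splittable `SeedSequence`; visits
  and outcomes use one sub-stream per subject, so output is reproducible
  and per-subject draws are invariant to subject reordering.

What the generator does *not* emulate: viral dynamics or seroconversion
biology, informative dropout or death, within-subject autocorrelation of
the time-varying covariates (drawn i.i.d. across visits), or
measurement error in CD4.  Passing tests therefore demonstrate that the
estimation machinery recovers the data-generating process it assumes —
not that the model is correct for any real cohort.

## Factor reduction

Principal-component extraction from the correlation matrix; Kaiser
retention (eigenvalue > 1, strict — values within 1e-10 of 1 are
dropped); varimax by iterated pairwise planar rotations with Kaiser row
normalization (row scaling commutes with column rotation, so
communalities are preserved to machine precision and
`rotated = unrotated @ R` holds exactly); loading bands weak < 0.4 ≤
moderate ≤ 0.6 < strong; regression-method scores Z R⁻¹Λ.  The motivating
study names both "principal components" and "maximum likelihood
extraction"; PCA extraction is implemented because it is the one that
produces the described eigenvalue/Kaiser workflow.  Oblique rotations and
ML extraction are out of scope.

## Descriptives

Percentages are count/denominator×100 rounded half-up to one decimal;
the denominator is the per-variable non-missing count (the published BMI
row only reconciles at denominator 218, i.e. one missing value).  The
published TB row (18 of 219 printed as 9.2%) is a misprint; the correct
8.2% is produced.  Median/IQR use linear-interpolation (type-7)
quantiles.  Correlation screening is pairwise-complete Pearson with
two-sided p-values from the t approximation and star bands at
0.05/0.01/0.001 (a printed band of "P < 0.00" is read as P < 0.001).

## Validation experiments and problem sizes

Chosen so the whole suite runs comfortably on one CPU:

- **Quadrature vs MC**: 10 subjects under the default configuration,
  200,000 prior draws, quadrature order 21; agreement within 3 MC SEs per
  subject.
- **Parameter recovery**: 100 replicates of 300 subjects at visit rate
  1.2/year (~6 visits each), quadrature order 5.  Logit-scale parameters
  (thresholds and coefficients) are held to |bias| < 0.1 and 95%-interval
  coverage in [90%, 99%]; variance components are reported but not held
  to the logit-scale band.
- **LR calibration**: 200 replicates of 120 subjects at rate 1.2,
  quadrature order 3, cART freed (df = 2).  The replicate size was chosen
  in piloting as the smallest at which the χ² asymptotics are adequate:
  at 60 subjects the near-degenerate cART design inflates the type-I
  error to ~12%, while freeing a continuous covariate under-rejects
  (~0–2%) because of the monotonicity-constrained alternative.
- **Determinism**: the reduced pipeline (30 subjects, short chains) run
  twice; all numeric artifacts byte-identical (the manifest embeds
  wall-clock and is excluded).

## Known limitations

- Cumulative-logit link only (no probit/cauchit/cloglog); two levels
  only; no missing-data handling beyond per-variable denominators.
- DIC from integrated (marginal) deviance; software that defines deviance
  conditionally on random effects will print different dbar/pD levels.
- Tensor Gauss–Hermite accuracy degrades for very sparse subjects at
  large intercept variance (see Estimation); raise `quad_order` when
  absolute log-likelihood accuracy matters.
- The MLE of variance components is not restricted/bias-corrected;
  at 60–300 subjects modest finite-sample bias in D and in weakly
  identified coefficients (cART) is expected and observed.
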