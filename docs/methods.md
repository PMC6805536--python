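# Methods

## Model

`bayesnma` fits contrast-based Bayesian network meta-analysis models to
arm-level aggregate data. Arm `k` of study `i` carries a response
`R_ik` modeled by a family distribution with latent parameter `φ_ik`:
Normal(φ, se²) for continuous outcomes, Binomial(n, φ) for dichotomous
ones, Poisson(e·φ) for counts with person-time `e`. A link `g` maps
`φ_ik` to the linear predictor

    θ_ik = μ_i + δ_ik  (+ β_(t_i1,t_ik)·(x_ik − x̄) under meta-regression)

with two special cases: the binomial/cloglog model adds `log(f_i)`
(study follow-up time, in whatever time unit the data use — contrasts
are then log hazard ratios under a constant-rate assumption), and the
binomial/log model truncates `θ_ik` at `−10⁻¹⁶` to keep probabilities
inside (0, 1).

`μ_i` is the effect of the study's own control arm and is a nuisance
parameter; the estimands are the basic contrasts `d_(1,t)` versus the
network reference. Under **random effects** the study contrast vector
`δ_i = (δ_i2..δ_ia)` is MVN(`d_i`, Σ) with the compound-symmetry Σ
(variance σ², covariance σ²/2), which is what makes multi-arm trials
internally consistent. The joint MVN factors into univariate
conditionals with mean `d_(t1,tk) + Σ_{j<k}(δ_ij − d_(t1,tj))/(k−1)`
and variance `k σ²/(2(k−1))`; `conditional_re_moments` exposes this
decomposition and a test verifies its equivalence to direct MVN
sampling at 10⁶ draws. Under **consistency**, `d_(a,b) = d_(1,b) −
d_(1,a)` identically; the **inconsistency** (unrelated-mean-effects)
variant instead places an independent parameter on each directly
compared pair `(t_i1, t_ik)`, keyed by the study's control arm, and is
used purely as a comparison model for detecting direct/indirect
disagreement.

## Priors

All defaults are vague and scaled by `u`, the largest absolute
single-trial maximum-likelihood treatment difference on the link scale
(zero cells get a 0.5 continuity correction on all four cells of the
affected two-by-two; a fully degenerate network falls back to `u = 1`
with a warning). Baselines and contrasts: `N(0, (15u)²)`; exception:
binomial/log baselines are parameterized as `μ_i = log p_i` with
`p_i ~ U(0,1)`. Heterogeneity: `σ ~ U(0, u)`. Regression coefficients:
`t(location 0, scale u, df 1)` — a Cauchy, evaluated through its
log-density with no finite-variance assumptions — in three structures:
*unrelated* (iid per treatment), *exchangeable* (`N(b, γ²)` with
Cauchy `b` and `γ ~ U(0, u)`), or *equal* (a single shared `B`). Every
hyperparameter can be overridden per fit; overrides must be finite.

The covariate is centered at `x̄`, the mean of the covariate over all
arm rows (recorded in run metadata); users supply `x0` on the original
scale and the reporting layer undoes the centering.

## Sampler

A native adaptive random-walk Metropolis-within-Gibbs sampler:

- `μ_i` are updated as one vectorized block (conditionally independent
  across studies given everything else), each with its own proposal
  scale and accept/reject decision.
- Random-effects `δ_ik` are updated by arm-position slot, vectorized
  across studies, judged by the arm's likelihood plus the study's
  closed-form compound-symmetry MVN density (`Σ⁻¹` and `|Σ|` are
  analytic, so the quadratic form reduces to per-study sums).
- Each basic contrast `d` gets two scalar moves per sweep: a plain
  conditional move (efficient locally, since the δ-prior coupling is
  tight) and a *translation* move that shifts the affected study
  contrasts along with `d`. The translation leaves the δ-prior
  residuals invariant (unit Jacobian), so it is judged by likelihood
  and `d`-prior alone; without it, `d` would diffuse with step ~σ
  through the centered parameterization and mix very slowly —
  prior-only runs made this failure mode measurable.
- `σ`, regression coefficients, and exchangeable hyperparameters get
  scalar random-walk updates; bounded parameters reject proposals
  outside their support.

Proposal scales adapt toward a 0.44 scalar acceptance rate in windows
of 50 sweeps during the adaptation phase only, then freeze — frozen
scales preserve detailed balance for burn-in and sampling. Chains are
initialized at neutral values (`μ = d = 0`, `σ = u/2`) with
deterministic chain-indexed offsets of ±0.2 prior SD for
overdispersion; binomial/log baselines start inside their `μ < 0`
support. Each chain draws from a generator spawned from one
`SeedSequence`, so runs are bitwise reproducible by seed. Kept samples
are checked finite; a non-finite state aborts with the parameter
named. A `prior_only` mode drops the likelihood term and is used to
verify that the machinery reproduces the declared priors.

Default run sizes (1000 adapt / 2000 burn-in / 5000 kept × 2 chains)
are the package's test-problem defaults; real analyses should scale
iterations up and check the PSRF/ESS columns of `summary()`.

## Assessment

Fit is summarized by saturated-model residual deviance per arm:
binomial `2[r·ln(r/r̂) + (n−r)·ln((n−r)/(n−r̂))]` with `r̂ = nφ`
(zero-count terms contribute 0), Poisson `2[(r̂−r) + r·ln(r/r̂)]`,
normal `((R−φ)/se)²`. `Dbar` averages the total deviance over the
posterior; the plug-in deviance is evaluated at the **posterior-mean
fitted values** `φ̂` (not posterior-mean parameters — the convention is
recorded on the `FitStats` object); leverage is their per-arm
difference, `pD` the total leverage, and `DIC = Dbar + pD` exactly.
Leverage points are exported per arm (one per likelihood contribution)
as `(sign(r−r̂)·√dev̄, leverage)` with the usual `x² + y = c` parabolas.
For non-normal families leverage can go slightly negative through
Monte Carlo noise; tests tolerate −0.05.

Convergence: classic Gelman–Rubin PSRF with the √ correction (split
halves for a single chain; zero-variance chains are flagged, not
fatal) with a 1.05 advisory threshold, and ESS from the chain-averaged
autocorrelation function truncated at the first negative paired sum.
Both are cross-checked in the test suite against arviz as an
independent implementation.

Consistency is assessed globally by the DIC difference between the
consistency and inconsistency fits and locally by pairing each arm's
posterior mean deviance under the two models (points off the identity
line localize the disagreement).

## Pairwise screening

`pairwise_all` pools every directly compared pair by inverse-variance
fixed effects plus DerSimonian–Laird random effects (`τ² = max(0,
(Q−df)/(Σw − Σw²/Σw))`, `I² = max(0, (Q−df)/Q)`), with per-study log
odds ratios and Woolf variances for dichotomous data (0.5 added to all
four cells of any zero-cell study), mean differences for continuous
data, log rate ratios for counts. With one study, `I²` is reported as
undefined rather than zero. Multi-arm studies contribute each
within-study pair without a variance correction — this stage is a
screening device; the joint model handles multi-arm correlation
properly. For cloglog-family networks the screening scale is the log
odds ratio: the arm-level cloglog difference is not a conventional
screening statistic and would need the follow-up offset.

## Synthetic data

`generate_synthetic_network` draws study baselines
`μ_i ~ N(baseline_mean, baseline_sd²)` on the link scale, study
contrasts from the exact compound-symmetry MVN around the true `d`,
and arm responses from the matching family through the same linear
predictor code the sampler uses (including the cloglog offset and
log-link truncation). Defaults describe a realistic mid-sized evidence
base: two-arm trials, a few hundred patients per arm, event
probabilities around `logit⁻¹(−1) ≈ 0.27`, and moderate heterogeneity.
For the binomial log link the generator refuses configurations whose
truncation probability exceeds 1% (estimated from the normal tail of
`μ + δ`), since truncation would bias the planted truth. The generator
emulates clean aggregate data only — no selective reporting, missing
covariates correlated with design, or non-proportional hazards — so
parameter-recovery tests demonstrate correctness of the machinery, not
robustness to real-data pathologies.

The bundled `load_toy_diabetes()` fixture hard-codes only the seven
published arms (three studies) of the six-treatment antihypertensive /
new-onset-diabetes network, with mean age (and SD, where reported) as
an arm-level covariate; it exercises the descriptive and screening
layers on real numbers. The full 22-trial network is not bundled.

## Design choices and conventions

- Reference treatment when unspecified: alphabetically first label
  (deterministic). Re-declaring the reference permutes indices only.
- The control arm of a study is the arm carrying the network reference
  when present, else the first-listed arm — the model needs a
  designated `μ_i` arm and arm order is otherwise preserved.
- Follow-up is a study-level quantity; per-arm values must agree to
  1e-9 relative tolerance. "Mean follow-up" in the network summary is
  the unweighted mean over studies for the same reason.
- Covariate pooling in `covariate_table(group_by="treatment")` is
  sample-size-weighted when `n` is available, unweighted otherwise;
  unreported spreads stay missing rather than zero.
- League/forest point estimates are posterior medians (robust under
  exponentiation); means are also computed. Original-scale intervals
  are quantiles of exponentiated samples, which equal exponentials of
  the linear quantiles by monotonicity (asserted in tests).
- Rank ties break by treatment index (probability ~0 for continuous
  posteriors). The ranking direction is a required argument — whether
  small or large effects are "best" is outcome semantics the data do
  not encode.
- Zero-event arms are modellable in the Bayesian likelihood and are
  flagged as informational, not errors; continuity corrections are
  used only for the MLE-based quantities (`u`, pairwise screening) and
  are recorded in run metadata.

## Limitations

Contrast-level (study effect + SE) input, node-splitting, the Bucher
method, arm-based models, and multiple covariates per regression are
out of scope. The sampler is a random-walk scheme: adequate for the
moderate dimensionalities of typical NMA (tens of studies), but slow
mixing of `σ` on very sparse networks should be checked via ESS.
Plotting is intentionally data-only: every reporting function returns
the table behind the figure, not the figure.
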