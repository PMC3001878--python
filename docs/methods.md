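# Methods

## The two-level generative model

`metabayes` treats an experiment as two nested inference problems.

**Subject level.** The subject holds a perceptual model `m`: a prior over a
hidden state, `p(x | θ)`, and an input likelihood, `p(u | x, θ)`, with
perceptual parameters `θ` unknown to the experimenter.  Recognition — the
mapping from inputs to the subject's belief — is implemented as variational
inference under the Laplace approximation: the belief after trial `t` is a
Gaussian `q(x) = N(μ_t, Σ_t)` whose moments maximize a free-energy bound on
the log evidence of the inputs seen so far.  The recursion is *assumed-density
filtering*: the trial-`t` posterior becomes the trial-`t+1` prior.  This
propagation rule is exact within the Gaussian family (and exactly Bayes for
the conjugate toy model); it is the package's choice of closure for the
Markovian belief recursion, which fixes the evolution function
`λ_t = f(λ_{t-1}, u_t; θ)` completely.  The accumulated per-step free-energy
increments approximate the log marginal likelihood `log p(u_{1:t} | θ, m)`;
for conjugate-Gaussian models the approximation is exact, which the tests
exploit as an oracle.

**Experimenter level.** Decisions follow Bayesian decision theory: the
subject minimizes posterior risk `ρ(a) = E_q[ℓ(a, x; φ)]`, and measured
responses are the observation map of the belief plus zero-mean Gaussian
residuals, `y_t = g(λ_t; φ) + ε_t`, `ε_t ~ N(0, Σ_e)` (a softmax/logit
channel with temperature in `φ` is available for discrete choices; its
decision noise scales with posterior risk).  Embedding recognition inside
this response model makes the predicted response a deterministic function of
`(θ, φ)` given the inputs, so the experimenter's problem is an ordinary
nonlinear regression: maximize

    log p(y | θ, φ) + log p(θ, φ)

over the unconstrained parameter vector — penalized least squares for
Gaussian channels — and take the local curvature as the posterior precision.
The Laplace free energy of this fit,

    F = log p(y | η̂) − ½ (η̂ − η₀)ᵀ Π₀ (η̂ − η₀) + ½ log det(Σ_post Π₀),

is a lower bound on the log evidence of the observer model; the last two
terms penalize deviation from, and sharpening relative to, the prior
(`Π₀` the prior precision), which is what lets model comparison punish
redundant parameters.

## The toy observer (packaged worked example)

Task: report the mean of a unit-variance Gaussian signal using as few
samples as possible.

* Perceptual model: `x ~ N(m₀, 1/β)`, `u_i | x ~ N(x, 1)`; `θ = β` (prior
  precision).  Posterior precision after `n` samples is `β + n`; the
  posterior mean is the precision-weighted average.
* Loss: `ℓ(â, n, x) = (â − x)² + k·n`; `φ = k` (cost per sample).  Posterior
  risk at estimator offset `δ = â − μ_n` is `δ² + 1/(β+n) + k·n`; the
  optimal estimator is the posterior mean and the optimal sample size the
  integer minimizer of `1/(β+n) + k·n`.  Brute-force minimization is the
  binding definition; the stationary point `max(0, k^{-1/2} − β)` with
  floor/ceiling comparison is an accelerator verified against it.
* Response model: two Gaussian channels, the reported estimate and the
  chosen sample size, sharing residual variance `σ²` by default
  (per-channel overrides available).

### The smoothed sample-size channel

The integer-optimal sample size is piecewise constant in `(β, k)`; its
gradient is zero almost everywhere, so a curvature-based inversion would be
blind to `k` (and the `max(0, ·)` clamp kills the gradient entirely at the
wide prior's mean).  The inversion therefore predicts the sample-size
channel with the softplus relaxation `log(1 + exp(k^{-1/2} − β))`, which is
differentiable everywhere and deviates from the integer optimum by
`log(1 + e^{−z})` — under 1e-3 whenever `z = k^{-1/2} − β ≥ 7`, as at all
packaged study conditions, where `z` is an exact integer.  Simulated
subjects always choose the true integer optimum; only the experimenter's
prediction is smoothed.

## Estimation details

* **Parameterization.** All positive parameters (`β`, `k`, `σ²`,
  temperature) are estimated on the log scale with Gaussian priors.
  "Non-informative" priors are realized as proper wide Gaussians (default
  SD 10 on the log scale): the free-energy complexity term requires proper
  prior expectations, and improper flats would make it undefined.
* **Optimizer.** Damped Newton ascent (`vlaplace.laplace_fit`): exact
  derivatives when the model supplies them (the toy model does), central
  finite differences otherwise (gradient step 1e-5, Hessian step 3e-4,
  relative to `1 + |x|`); step-halving (up to 32) guarantees a
  non-decreasing objective; convergence at objective change < 1e-8 or
  gradient sup-norm < 1e-6.  The Hessian is symmetrized before inversion;
  if its condition number exceeds 1e12 a jitter of `1e-10·trace/d` is added
  with a logged warning.  Indefinite curvature away from the optimum is
  handled by a Levenberg shift for the step only; an indefinite Hessian *at*
  the terminal point raises an error naming the offending eigenvalue.
* **Multistart.** The inversion runs 5 starts by default (the prior mean
  plus 4 draws from the prior, sub-seeded from the options seed) and keeps
  the best free energy; starts that land in zero-density or numerically
  degenerate regions are skipped with a log entry.
* **Noise hyperparameter.** When the residual variance is estimated, the
  fit alternates Newton steps over parameters with a bounded 1-D
  maximization of the Laplace free energy over `log σ²` at the current mode
  (an inverse-gamma-kernel hyperprior is supported).  The point-optimized
  `σ²` is excluded from the parameter covariance; posterior metadata records
  this.
* **Missing responses.** NaN-coded channels contribute zero log-likelihood
  and are skipped in residual counts; with all responses missing the
  posterior equals the prior exactly.
* **Risk quadrature.** Posterior risk uses closed forms for quadratic
  losses, otherwise tensor-product Gauss–Hermite (order 21 per dimension,
  doubled while refinement changes the value by more than 1e-8; state
  dimension capped at 4).  Ties in `optimal_action` break deterministically
  to the lowest index/smallest value and are flagged.
* **Belief reconstruction.** The experimenter's estimate of the subject's
  belief propagates parameter uncertainty to first order: variance =
  subject posterior variance at the mode + `J Σ_{θφ} Jᵀ`, with `J` the
  central-finite-difference sensitivity of the belief mode to the
  unconstrained parameters (relative step 1e-4).  Credible intervals use
  two-sided normal quantiles, default level 0.90 (z = 1.6449).  The added
  term is positive semidefinite, so reconstructed intervals always contain
  the subject's own — response noise can only inflate the experimenter's
  estimate of the subject's uncertainty.

## What the simulator emulates — and what it does not

`simulate_observer` realizes the generative direction per trial: draw the
true signal mean from the subject's own prior (the subject is
well-calibrated by default; location/scale overrides exist), draw the
subject's `n*` unit-variance samples, compute the deterministic optimal
response, add independent Gaussian response noise.  A single integer seed
fixes every draw; identical configurations are bit-identical.

It does **not** emulate: within-trial sequential sampling dynamics (reaction
times), lapses or attention fluctuations, non-Gaussian response noise,
learning of `θ` across trials, subjects whose priors are miscalibrated to
the world (except via the generator overrides), or actions that feed back
into the hidden state.  Passing tests therefore certify the machinery —
recognition, decision, inversion, comparison — under the stated observer
assumptions, not the adequacy of those assumptions for any real dataset.

## Study conditions used by the validation suite

Chosen once as the package's reference conditions and shared by the tests
and `scripts/acceptance.py` (smaller replicate counts in the script to keep
a single run short):

* **Recovery/coverage study**: `β = 2`, `k = 0.01` (optimal sample size
  `1/√k − β = 8`, an exact integer, so the smoothed channel is exact to
  3e-4), response SD 0.05 on both channels, `T = 100` trials, 200
  replicates.  `β = 2` rather than 1 keeps `log β` away from zero so that
  relative-bias statements are meaningful.
* **Grid-oracle comparison**: `T = 40`, estimate-channel SD 0.1,
  sample-size-channel SD 2.0, prior SDs (1, 2) on `(log β, log k)`.  These
  are set by a resolvability requirement, not by the data: a 201-point-per-
  axis grid over ±4 prior SDs has steps (0.04, 0.08), and the posterior
  SDs under these conditions are ≈ (0.10–0.20, 0.08–0.13) — two to three
  grid steps per posterior SD — so the grid integral is an accurate Bayes
  oracle while the posterior stays close enough to Gaussian for the Laplace
  mean to be comparable.  With much tighter noise the posterior collapses to
  a sub-grid-step ridge and the "oracle" degenerates to nearest-node
  snapping; with much looser noise the posterior skews and neither
  approximation is meaningful.
* **Model recovery**: generating observer `β = 10`, `k = 0.0025` (optimal
  sample size 10), `T = 100`, response SD 0.05, against a candidate whose
  prior-precision is pinned at `β = 0.01` (a near-flat-prior observer);
  Occam check against a model with a redundant additive report-bias
  parameter.
* **Belief-inflation diagnostic**: noise-free simulated responses inverted
  under a grid of assumed noise variances `σ² ∈ [0.01, 1]`.  Holding the
  residuals at ≈ 0 makes the assumed `σ²` act only through the parameter
  covariance, isolating the predicted affine scaling of reconstructed
  subject variance in `σ²`; with fresh noise at every level an O(σ)
  mode-wobble term would dominate unless thousands of replicates were
  averaged.
* **Signal-power diagnostic**: paired datasets sharing signal and noise
  draws, with inputs doubled in one member; experimenter posterior
  variances must not increase, since stronger signals can only add
  information about the parameters.

## Known limitations

* The Laplace free energy is not a guaranteed lower bound on the log
  normalizer for arbitrary targets (e.g. flatter-than-Gaussian maxima); the
  bound property is verified on log-concave Gamma-kernel families, where the
  Laplace approximation is a strict underestimate.
* In the toy task the sample-size channel observes one quantity repeated
  across trials, so `(log β, log k)` are strongly correlated a posteriori
  (|r| ≈ 0.99 at the reference conditions); the identifiability report
  flags this by design.  Coverage statements hold marginally per parameter.
* Hyperparameter (residual-variance) uncertainty is not propagated into the
  parameter covariance.
* Hierarchical (group-level) priors, neurophysiological observation maps,
  closed-loop control (actions changing hidden states), and formal
  experimental-design optimization beyond the identifiability diagnostic are
  out of scope.
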