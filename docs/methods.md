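# Methods

## Observer model

The psychometric function (PF) maps a stimulus **x** ∈ ℝᵈ to a probability
vector over k discrete response options.  We model it as a multinomial
logistic (MNL) regression mixed with a stimulus-independent lapse
component.  With the affine feature embedding φ(x) = [1, xᵀ]ᵀ, each option
i carries a weight vector **w**ᵢ = [bᵢ, **a**ᵢᵀ]ᵀ (bias plus sensitivities)
and the lapse-free choice probabilities are the softmax

    qᵢ = exp(**w**ᵢ·φ) / Σⱼ exp(**w**ⱼ·φ).

The softmax is invariant to a common shift of all weight vectors, so the
last (reference) category's weights are fixed to zero; a flag selects a
different reference.  Omission/violation trials are simply one more
response category — the model makes no structural distinction, and dataset
loaders map the omission code to that index.

Lapses are a mixture: with probability λ the response is drawn from a
stimulus-independent distribution c on the k options, giving

    pᵢ = (1 − λ) qᵢ + λ cᵢ.

We parameterize the per-option lapse probabilities through unconstrained
auxiliary parameters uᵢ via λcᵢ = exp(uᵢ) / (1 + Σⱼ exp(uⱼ)).  Writing
eᵢ = exp(uᵢ) and S = 1 + Σⱼ eⱼ, the mixture collapses to

    pᵢ = (qᵢ + eᵢ) / S,

which is the form used for all derivative computations.  A uniform-lapse
mode ties every uᵢ to a single scalar (cᵢ = 1/k); lapse-disabled mode sets
λ = 0 exactly (rather than sending u → −∞), keeping derivatives finite.

Stimulus spaces are normalized so each dimension has zero mean and unit SD
over the candidate grid; biases are then average log-odds and a unit step
in any weight dimension is comparable to any other.

## Prior and posterior

Weights carry independent Gaussian priors N(0, σ²I) with σ = 3 by default:
on a normalized space that spans PF shapes from flat to very steep while
regularizing early-trial fits.  Each uᵢ has a flat prior on
[log 0.001, 0]; the upper bound caps per-option lapse at 1/(k+1) (and at
1/2 in the degenerate one-active-option limit), the lower bound reflects
that lapse rates below ~1/N are unresolvable at the trial counts used.
The flat box contributes 0 to the log posterior inside its support and −∞
outside, so samplers reject out-of-box proposals for free.

The log posterior is log prior plus the one-hot categorical log likelihood
Σₛ **y**ₛ·log **p**(xₛ, θ).  For the lapse-free model the log likelihood is
concave, so MAP optimization is global; with lapses it is not, and the
sampler-based route exists for exactly that reason.

### Gradient and Hessian

Per trial, with response index y, D_l ≡ q_y(δ_{yl} − q_l) and t_y ≡ q_y + e_y:

    ∂ℓ/∂v_l = D_l / t_y                     (v = free linear predictors)
    ∂ℓ/∂u_r = δ_{yr} e_r / t_y − e_r / S

    ∂²ℓ/∂v_j∂v_l = (D_j δ_{yl} − D_j q_l − q_y q_l(δ_{lj} − q_j)) / t_y
                   − D_l D_j / t_y²
    ∂²ℓ/∂u_r∂v_l = −D_l e_r δ_{yr} / t_y²
    ∂²ℓ/∂u_r∂u_s = δ_{yr}δ_{rs} e_r/t_y − δ_{yr}δ_{ys} e_r e_s/t_y²
                   − δ_{rs} e_r/S + e_r e_s/S²

Weight-space derivatives follow from the linear map v = Jw (J places φ on
the block of each free category); the uniform-lapse mode sums the full-u
derivatives (a linear reparameterization).  In the lapse-free limit
(e = 0) the predictor-space curvature reduces to the classical MNL
−(diag(q̃) − q̃q̃ᵀ).  All derivatives are validated against central finite
differences in the test suite; softmax/logistic computations use
log-sum-exp shifting throughout, so linear predictors up to ~±700 stay
finite.

## Inference

**Laplace.**  The MAP estimate maximizes the log posterior with a
trust-region Newton method (`scipy.optimize.minimize`, `trust-exact`) using
the analytic gradient and Hessian.  The u-box is handled by a scaled
logistic transform u = lo + (hi−lo)·σ(ξ) optimized unconstrained in ξ, so
u stays strictly interior; a short damped-Newton polish runs if the
trust-region stop leaves the gradient above 1e−6.  Closed-loop runs warm
start from the previous trial's mode (the posterior changes by one
likelihood term per trial).  The Gaussian approximation is N(θ̂, −H⁻¹);
information-gain computations use only the *partial* weight-block
covariance C_ww = −(∂² log P/∂w²)⁻¹.  Both matrices are repaired to the
Frobenius-nearest symmetric PSD matrix when needed — the simplest Higham
variant, eigenvalue clipping at zero with tolerance 1e−12.  (C_ww can be
indefinite in principle with lapses; it is asymptotically PSD as λ → 0.)

**MCMC.**  A Gaussian random-walk Metropolis–Hastings chain targets the
posterior over the full free parameter vector.  Default chain length
M = 1,000 with burn-in M/2 and no thinning; chains are deterministic given
their seed.  In the closed loop the proposal covariance is *semiadaptive*:
re-tuned between trials (never within a chain) as s_d·Cov(previous trial's
samples) + 1e−6·I with the canonical Haario–Saksman–Tamminen scaling
s_d = 2.38²/d.  The fall-back proposal, used on the first trial or when
the previous samples are degenerate, is (0.1)²·I.  Chains warm start at
the previous trial's sample mean (first trial: the prior mode).  A single
chain is run per trial; multi-chain R̂ diagnostics are a QC option, not
part of the per-trial loop.

## Stimulus selection

The next stimulus maximizes the conditional mutual information between the
upcoming response and the parameters, I(θ; y|x) — equivalently, it
minimizes the expected posterior entropy after the trial.  Selection is
greedy (one-trial horizon) over a finite candidate grid; exact utility
ties are broken uniformly at random with the experiment RNG, and candidate
evaluation is order-independent.

**Laplace engine (partial information).**  With a Gaussian posterior the
entropy is ½ log|C| + const, and a hypothetical trial at x updates the
weight covariance by a rank-(k−1) correction in predictor space:
C̃⁻¹ = C⁻¹ + Jᵀ Λ J, evaluated via the Woodbury identity as
log|C̃| = log|C| − log|I + Λ Σ_v| with Σ_v = J C_ww Jᵀ.  For the
lapse-free MNL the curvature Λ(v) = diag(q̃) − q̃q̃ᵀ does not depend on the
hypothetical response (canonical link), so the response expectation is
immediate and the utility is

    U(x) = ½ E_v [ log|I + Λ(v) Σ_v| ],

the expected entropy reduction of the weight posterior in nats.  The
expectation over v ~ N(Jŵ, Σ_v) is a tensorized Gauss–Hermite quadrature
over the (k−1)-dimensional predictor space (default order 7 per dimension;
the closed-loop harness uses order 5, which agrees with order 9 to <1e−4
on these models while costing order^(k−1) evaluations).  With lapse-aware
inference the engine still scores only the weight block (partial
information I(w; y|x)); Λ is then the expected Fisher information of the
mixture likelihood in predictor space with λ, c held at the posterior
mode — it reduces exactly to the lapse-free curvature at λ = 0.  This
generalization is this package's design choice for the lapse-aware
Laplace path.

**Sampler engine (full information).**  From posterior samples {θ_m} and
the potential matrix L_jm = p(y_j = 1|x, θ_m), the mutual information is
the marginal-minus-conditional response entropy,

    I = −(1/M) Σ_{j,m} L_jm log( L_jm / ((1/M) Σ_{m'} L_jm') ),

with 0·log 0 = 0.  No separation of weight and lapse parameters is made
here.

**Oracle.**  For ≤3 free parameters a brute-force routine integrates the
mutual information on a dense parameter grid and serves as ground truth
for both engines in the tests.

## Experiment harnesses

Closed-loop runs execute collect → infer → select.  For the adaptive
runner the first n_init = 10 trials are placed at regular intervals along
the row-major traversal of the candidate grid; the uniform baseline draws
uniformly at random from the grid on every trial, its initialization
block included.  Per trial the harness records the selected
stimulus, the response, the posterior entropy (Laplace: ½ log|C_ww|;
sampler: ½ log|Cov(samples)| — additive constants dropped, so traces are
comparable only within an engine) and the PF mean squared error: the mean
of (p_ij − p̂_ij)² over all grid points i and response categories j, with
p̂ the MAP plug-in (Laplace) or the posterior-predictive average (MCMC).
Inference failure truncates the trace with an error record.

The reordering harness replays a recorded trial table: trials are pooled
by distinct stimulus; each step scores the distinct stimuli remaining in
the pool, picks the best without access to any response, consumes one
recorded instance (FIFO among duplicates) and updates the posterior.
Errors are scored against a reference PF fitted to the full table.  The
uniform-subsampling baseline draws from the pool without replacement.

All randomness flows from a master seed: `numpy.random.SeedSequence`
spawns one sequence per run, which spawns separate streams for observer
responses, the inference chain, and tie-breaking.

## Synthetic observers

`make_fixture_observer` provides the standard study conditions:

* `fig3_binary` — 1-D stimulus (21 points on [−2, 2], then normalized),
  two alternatives, slope 2 and bias 0 on the normalized axis.
* `fig5_fourchoice` — 2-D 21×21 grid on [−2, 2]², four alternatives whose
  sensitivity vectors point along the four cardinal directions with zero
  biases.  The weight magnitude (3.0) is a package constant chosen so each
  quadrant has a clearly dominant choice while the decision boundaries
  remain graded within the grid.
* `rotated` — the same with sensitivity directions rotated 45°
  counterclockwise.

Optionally a uniform lapse mixture (cᵢ = 1/k) is added at a requested
total λ (0.2 in the lapse studies; per-option lapse 0.05 for k = 4).
These observers emulate stationary psychophysical behavior with
independent trials.  They do not emulate serial dependencies (history
effects), drifting attention, overdispersion, or asymmetric lapse
distributions, so passing tests demonstrate correctness of the algorithms
under the stated model, not robustness to those violations.

## Study sizes and numerical choices

The benchmark studies use: 100 runs of 100 trials per selection arm for
the speedup study and 20 runs per arm for the four-arm mismatch study,
Gauss–Hermite order 5, closed-loop chain
length M = 500 with burn-in 250 (shorter than the standalone default of
1,000; the per-trial posteriors of these 9–13-parameter models are
already well represented by a few hundred samples), 100 repetitions
for the slope-bias rate, 50 for the omission comparison, and dense
281-point-per-axis grids for the brute-force oracle.  Degenerate inputs:
constant stimulus dimensions are rejected at normalization; a response
with exactly zero probability yields −∞ log likelihood, not an exception;
empty datasets return the prior; proposal covariances are jittered by
1e−6·I before Cholesky.

## Known limitations

* The Laplace engine's utility ignores lapse-parameter information by
  construction; its entropy traces are offset from the sampler engine's.
* The closed-form covariance update is a one-step approximation — it is
  exact for the Gaussian-likelihood case and accurate near the mode, but
  it is never used for actual posterior updating, only for scoring
  candidates.
* Random-walk MH mixes slowly on strongly correlated posteriors in higher
  dimension; between-trial adaptation mitigates but does not remove this.
* Feature embeddings beyond user-supplied callables (e.g. Weibull or
  cumulative-Gaussian links), overdispersion, and history-dependent
  regressors are out of scope.
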