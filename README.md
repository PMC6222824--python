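# infomaxpf

Bayesian adaptive ("infomax") stimulus selection for multi-alternative
psychometric functions with lapses and omissions.

## The problem

A psychometric function (PF) maps a stimulus to a probability vector over
an observer's discrete response options.  Estimating it accurately usually
takes many hundreds of trials — expensive with animal subjects and
prohibitive for high-dimensional stimuli.  Closed-loop experiments shrink
that cost by choosing, on every trial, the stimulus expected to be most
informative about the PF given the data so far.  This package implements
such a closed loop for realistic multi-alternative behavior, for
experimentalists and methodologists in psychophysics and systems
neuroscience.

## The model and the selection rule

Responses follow a multinomial-logistic (MNL) mixture: with the feature
embedding φ(x) = [1, xᵀ]ᵀ,

    p_i = (1 − λ) q_i + λ c_i,    q_i = exp(w_i·φ) / Σ_j exp(w_j·φ),

where λ is the total lapse probability and c the stimulus-independent
lapse distribution, parameterized by auxiliary variables u_i through
λc_i = exp(u_i)/(1 + Σ_j exp(u_j)).  Omissions are just an extra response
category.  Weights carry a N(0, σ²I) prior (σ = 3); each u_i has a flat
prior on [log 0.001, 0].

The posterior p(θ | D_t) is tracked either by a **Laplace approximation**
(MAP via trust-region Newton with analytic gradient/Hessian, covariance
−H⁻¹) or by **semiadaptive Metropolis–Hastings** sampling whose proposal
covariance is re-tuned between trials with the Haario scaling 2.38²/d.
The next stimulus maximizes the conditional mutual information

    x_{t+1} = argmax_x I_t(θ; y | x),

computed from the Gaussian posterior via a closed-form covariance update
and Gauss–Hermite quadrature (Laplace engine, partial information over the
weights) or directly from posterior samples via response entropies
(sampler engine, full parameter vector).  See `docs/methods.md` for the
full derivations and design choices.

## Worked example

```python
import numpy as np
from infomaxpf import (make_fixture_observer, ExperimentConfig,
                       run_closed_loop, LaplacePsychometricModel,
                       sample_response)

# 1. a closed-loop experiment against a simulated binary observer
observer, space = make_fixture_observer("fig3_binary", seed=0)
cfg = ExperimentConfig(engine="laplace", selection="infomax",
                       n_trials=40, seed=42)
trace = run_closed_loop(observer, space, cfg)
print(round(trace.mse[-1], 4), round(trace.entropy[-1], 3))
# 0.0084 -1.612

# 2. a static fit with the sklearn-style estimator
rng = np.random.default_rng(1)
feats = space.features()
idx = rng.integers(0, 21, 200)
y = np.array([sample_response(observer, feats[i], rng) for i in idx]) + 1
model = LaplacePsychometricModel().fit(space.candidates[idx], y)
b, a = model.map_params_.weights[0]
sd = np.sqrt(np.diag(model.posterior_.cov_ww))
print(f"bias b = {b:.3f} ± {sd[0]:.3f}, slope a = {a:.3f} ± {sd[1]:.3f}")
# bias b = -0.033 ± 0.192, slope a = 1.996 ± 0.260
```

The trace numbers say: after 40 adaptively chosen trials the mean squared
error between the true and estimated choice probabilities over the grid
is 0.0084, and the posterior entropy of the weights has fallen to −1.61
nats (entropy constants dropped).  The infomax loop spends its early
trials on the easiest extreme stimuli and then homes in on the region
where the PF is steep.  The static fit recovers the true parameters
(slope 2, bias 0) well within one posterior standard deviation.

A command-line interface covers the same workflows:

```bash
infomaxpf simulate config.yaml --out runs/     # closed-loop simulations
infomaxpf fit trials.csv --config model.yaml   # static fit of a trial table
infomaxpf reorder trials.csv --config cfg.yaml # infomax replay of real data
infomaxpf benchmark-mi                         # MI engines vs. brute force
```

Trial tables are CSV (`trial,x_1..x_d,response` with 1-based response
codes); configs are YAML; posteriors are JSON.

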