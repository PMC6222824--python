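"""Benchmark studies: the package's headline simulated experiments.

Each function runs a complete, seeded study from scratch and returns plain
numbers; they are used both by the test suite and by the reproduction
script.  Problem sizes (number of runs, trials, chain lengths) are the
package defaults for these studies — see docs/methods.md for the choices.
"""

from __future__ import annotations

import numpy as np

from .experiment import (
    ExperimentConfig,
    make_fixture_observer,
    run_closed_loop,
    run_seeds,
    sample_response,
)
from .infomax import covariance_update, mi_laplace, mi_mcmc, mi_oracle
from .laplace import laplace_posterior, map_estimate
from .mcmc import HAARIO_FACTOR, sample_posterior
from .model import (
    Dataset,
    ModelParams,
    ParamLayout,
    PriorSpec,
    choice_probabilities,
)

__all__ = [
    "lapse_identities",
    "speedup_study",
    "mismatch_study",
    "oracle_agreement_study",
    "recovery_study",
    "slope_bias_study",
    "omission_bias_study",
]


def lapse_identities(k: int = 4) -> dict:
    """Closed-form identities of the lapse parameterization."""
    from .model import lapse_summary

    lam_max, c = lapse_summary(np.zeros(k))
    u_005 = np.full(k, np.log(0.05 / 0.8))
    lam_005, c_005 = lapse_summary(u_005)
    # supremum of per-option lapse over the prior box is at u_i = 0 with
    # all other options absent; probe the box densely as well
    rng = np.random.default_rng(0)
    prior = PriorSpec()
    u_grid = rng.uniform(prior.lapse_lower, prior.lapse_upper, (20000, k))
    u_grid[0, :] = prior.lapse_upper
    per_option = []
    for u in u_grid:
        lam, cc = lapse_summary(u)
        per_option.append((lam * cc).max())
    return {
        "per_option_lapse_at_u0": float(lam_max * c[0]),  # 1/(k+1)
        "total_lapse_at_per_option_005": float(lam_005),  # 0.2
        "max_per_option_lapse_in_box": float(np.max(per_option)),  # ≤ 1/2
    }


def _mean_mse_traces(kind, lapse, configs, master_seed, n_runs):
    """Run each configuration over the same seed fan-out; returns the mean
    MSE trace per configuration name."""
    observer, space = make_fixture_observer(kind, lapse=lapse)
    traces = {name: [] for name in configs}
    for streams in run_seeds(master_seed, n_runs):
        for name, cfg in configs.items():
            tr = run_closed_loop(observer, space, cfg, rng_streams=streams)
            if tr.error is not None:
                raise RuntimeError(f"{name}: {tr.error}")
            traces[name].append(tr.mse)
    return {
        name: np.stack(runs).mean(axis=0) for name, runs in traces.items()
    }


def speedup_study(master_seed: int = 0, n_runs: int = 100, n_trials: int = 100):
    """Infomax-vs-uniform speedup on the lapse-free 4-choice fixture.

    Returns the two mean-MSE traces, the uniform runner's final error and
    the first trial at which the infomax trace reaches it.
    """
    configs = {
        "infomax": ExperimentConfig(
            engine="laplace", selection="infomax", n_trials=n_trials
        ),
        "uniform": ExperimentConfig(
            engine="laplace", selection="uniform", n_trials=n_trials
        ),
    }
    means = _mean_mse_traces("fig5_fourchoice", 0.0, configs, master_seed, n_runs)
    uniform_final = float(means["uniform"][-1])
    reached = np.nonzero(means["infomax"] <= uniform_final)[0]
    crossing = int(reached[0]) + 1 if reached.size else n_trials + 1
    return {
        "infomax_mean_mse": means["infomax"],
        "uniform_mean_mse": means["uniform"],
        "uniform_final_mse": uniform_final,
        "infomax_final_mse": float(means["infomax"][-1]),
        "crossing_trial": crossing,
        "n_runs": n_runs,
    }


def mismatch_study(master_seed: int = 0, n_runs: int = 20, n_trials: int = 100):
    """Model-mismatch reversal with a lapsing (λ = 0.2) observer.

    Lapse-ignorant arms use the Laplace engine with the lapse-free model;
    lapse-aware arms use the sampler-based engine with the full lapse model.
    Returns mean trial-``n_trials`` MSE per arm.
    """
    ignorant = dict(engine="laplace", lapse_mode="none", n_trials=n_trials)
    aware = dict(
        engine="mcmc", lapse_mode="full", n_trials=n_trials, mcmc_samples=500
    )
    configs = {
        "ignorant_infomax": ExperimentConfig(selection="infomax", **ignorant),
        "ignorant_uniform": ExperimentConfig(selection="uniform", **ignorant),
        "aware_infomax": ExperimentConfig(selection="infomax", **aware),
        "aware_uniform": ExperimentConfig(selection="uniform", **aware),
    }
    means = _mean_mse_traces("fig5_fourchoice", 0.2, configs, master_seed, n_runs)
    return {name: float(trace[-1]) for name, trace in means.items()} | {
        "n_runs": n_runs
    }


def oracle_agreement_study(master_seed: int = 0, n_mcmc: int = 10000):
    """Both MI engines vs. dense numerical integration on a 2-parameter
    binary-logistic posterior, plus the matrix-determinant-lemma check for
    the one-step covariance update.

    The reference posterior is the (exactly Gaussian) Laplace approximation
    after 60 simulated trials, so the oracle integrates the same density
    both engines see.
    """
    rng = np.random.default_rng(master_seed)
    observer, space = make_fixture_observer("fig3_binary", seed=master_seed)
    layout = ParamLayout(2, 2, "none")
    prior = PriorSpec()
    feats = space.features()
    idx = rng.integers(0, space.n_candidates, 60)
    y = np.array([sample_response(observer, feats[i], rng) for i in idx])
    data = Dataset(phi=feats[idx], y=y)
    mode = map_estimate(data, prior, layout)
    post = laplace_posterior(data, prior, mode)

    mu = layout.pack(mode)
    cov = post.cov_ww
    ci = np.linalg.inv(cov)
    sd = np.sqrt(np.diag(cov))
    axes = [
        np.linspace(mu[i] - 6 * sd[i], mu[i] + 6 * sd[i], 281) for i in range(2)
    ]

    def log_density(pts):
        d = pts - mu
        return -0.5 * np.einsum("nd,de,ne->n", d, ci, d)

    from .mcmc import SampleSet

    draws = rng.multivariate_normal(mu, cov, n_mcmc)
    samples = SampleSet(
        samples=draws,
        log_post_values=np.zeros(n_mcmc),
        acceptance_rate=1.0,
        proposal_cov_used=cov,
        layout=layout,
    )

    lap_err, mc_err, mc_se, det_err = [], [], [], []
    for i in range(0, space.n_candidates, 2):
        phi = feats[i]

        def response_probs(pts):
            p1 = 1.0 / (1.0 + np.exp(-(pts @ phi)))
            return np.stack([p1, 1 - p1], axis=-1)

        oracle = mi_oracle(log_density, response_probs, axes)
        lap_err.append(abs(mi_laplace(post, phi, 9) - oracle))
        mc_err.append(abs(mi_mcmc(samples, phi) - oracle))
        reps = [
            mi_mcmc(
                SampleSet(draws[j::5], np.zeros(len(draws[j::5])), 1.0, cov,
                          layout=layout),
                phi,
            )
            for j in range(5)
        ]
        mc_se.append(np.std(reps, ddof=1) / np.sqrt(5))
        # covariance update vs the rank-one determinant lemma
        updated = covariance_update(post, phi)
        v = mode.weights[0] @ phi
        p = 1.0 / (1.0 + np.exp(-v))
        lemma = np.linalg.slogdet(cov)[1] - np.log(
            1 + p * (1 - p) * phi @ cov @ phi
        )
        det_err.append(abs(np.linalg.slogdet(updated)[1] - lemma))
    return {
        "max_laplace_oracle_diff": float(np.max(lap_err)),
        "max_mcmc_oracle_diff": float(np.max(mc_err)),
        "max_mcmc_se_ratio": float(np.max(np.array(mc_err) / np.array(mc_se))),
        "max_detlemma_diff": float(np.max(det_err)),
    }


def recovery_study(master_seed: int = 0, n_trials: int = 200):
    """Fig.-3-regime parameter recovery: 1-D binary data from slope 2 and
    bias 0, fitted with both inference engines."""
    rng = np.random.default_rng(master_seed)
    observer, space = make_fixture_observer("fig3_binary", seed=master_seed)
    layout = ParamLayout(2, 2, "none")
    prior = PriorSpec()
    feats = space.features()
    idx = rng.integers(0, space.n_candidates, n_trials)
    y = np.array([sample_response(observer, feats[i], rng) for i in idx])
    data = Dataset(phi=feats[idx], y=y)

    mode = map_estimate(data, prior, layout)
    post = laplace_posterior(data, prior, mode)
    truth = observer.params.weights[0]
    lap_sd = np.sqrt(np.diag(post.cov_ww))
    lap_z = np.abs(mode.weights[0] - truth) / lap_sd

    samples = sample_posterior(
        data, prior, layout, init=mode,
        proposal_cov=HAARIO_FACTOR / 2 * post.cov,
        n_samples=4000, seed=master_seed + 1,
    )
    mc_mean = samples.mean()
    mc_sd = np.sqrt(np.diag(samples.cov()))
    mc_z = np.abs(mc_mean - truth) / mc_sd

    p_lap = choice_probabilities(mode, feats).probs
    from .infomax import sample_choice_probs

    p_mc = sample_choice_probs(layout, samples.samples, feats).mean(axis=0)
    return {
        "laplace_bias_z": float(lap_z[0]),
        "laplace_slope_z": float(lap_z[1]),
        "mcmc_bias_z": float(mc_z[0]),
        "mcmc_slope_z": float(mc_z[1]),
        "pf_sup_norm_diff": float(np.abs(p_lap - p_mc).max()),
    }


def slope_bias_study(
    master_seed: int = 0, n_runs: int = 100, obs_per_point: int = 20
):
    """Lapse-ignorant fitting of lapsing (λ = 0.2) binary data: fraction of
    runs in which the fitted slope magnitude underestimates the truth."""
    observer, space = make_fixture_observer("fig3_binary", lapse=0.2)
    true_slope = abs(observer.params.weights[0, 1])
    layout = ParamLayout(2, 2, "none")
    prior = PriorSpec()
    feats = space.features()
    idx = np.tile(np.arange(space.n_candidates), obs_per_point)
    under = 0
    for run in range(n_runs):
        rng = np.random.default_rng(master_seed + 1000 + run)
        probs = choice_probabilities(observer.params, feats[idx]).probs
        y = (rng.random(len(idx)) >= probs[:, 0]).astype(int)
        mode = map_estimate(Dataset(phi=feats[idx], y=y), prior, layout)
        if abs(mode.weights[0, 1]) < true_slope:
            under += 1
    return {
        "underestimate_fraction": under / n_runs,
        "n_runs": n_runs,
        "n_trials": len(idx),
    }


def omission_bias_study(
    master_seed: int = 0, n_runs: int = 50, obs_per_point: int = 20
):
    """Discarding omission trials vs. modeling them as a third category.

    The true observer has two valid choices plus a stimulus-dependent
    omission category; both fits are scored by their maximum deviation from
    the true *conditional* (valid-choice) psychometric function.
    """
    from .space import normalize_space

    space = normalize_space(np.linspace(-2, 2, 21)[:, None])
    # choice 1 prefers +x, choice 2 prefers −x; the omission (reference)
    # category is likeliest where evidence for the valid choices is weak,
    # and asymmetrically so — omissions concentrate on one side, which is
    # what biases the exclusion-based fit
    weights = np.array([[0.5, 2.5], [-1.5, -2.5], [0.0, 0.0]])
    truth = ModelParams(weights=weights, lapse_mode="none")
    feats = space.features()
    p_true = choice_probabilities(truth, feats).probs
    cond_true = p_true[:, 0] / (p_true[:, 0] + p_true[:, 1])

    prior = PriorSpec()
    layout3 = ParamLayout(3, 2, "none")
    layout2 = ParamLayout(2, 2, "none")
    idx = np.tile(np.arange(space.n_candidates), obs_per_point)
    dev3, dev2 = [], []
    for run in range(n_runs):
        rng = np.random.default_rng(master_seed + 2000 + run)
        cum = p_true[idx].cumsum(axis=1)
        y = (rng.random((len(idx), 1)) > cum).sum(axis=1)
        # three-category fit on everything
        fit3 = map_estimate(Dataset(phi=feats[idx], y=y), prior, layout3)
        p3 = choice_probabilities(fit3, feats).probs
        cond3 = p3[:, 0] / (p3[:, 0] + p3[:, 1])
        dev3.append(np.abs(cond3 - cond_true).max())
        # two-category fit discarding omissions
        keep = y < 2
        fit2 = map_estimate(
            Dataset(phi=feats[idx][keep], y=y[keep]), prior, layout2
        )
        p2 = choice_probabilities(fit2, feats).probs
        dev2.append(np.abs(p2[:, 0] - cond_true).max())
    return {
        "mean_deviation_3cat": float(np.mean(dev3)),
        "mean_deviation_2cat_excluding": float(np.mean(dev2)),
        "n_runs": n_runs,
    }
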