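"""Simulated observers, closed-loop runners and evaluation metrics.

A simulated experiment alternates collect → infer → select: a response is
drawn from a fixed "true" observer, the posterior over the model parameters
is updated (Laplace or MCMC), and the next stimulus is chosen either by
maximizing expected information gain (infomax) or uniformly at random from
the candidate grid.  Performance is tracked by the posterior entropy of the
weights and by the mean squared error between true and estimated choice
probabilities over the full grid.

The reordering harness replays a recorded trial table: at each step the
highest-utility stimulus among the *remaining* recorded trials is selected
(without looking at its response), its recorded response is then attached,
and the posterior updated — an off-line test of how much faster the same
data could have narrowed the posterior in a different order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .infomax import (
    UtilityTable,
    laplace_utilities,
    mcmc_utilities,
    sample_choice_probs,
    select_stimulus,
)
from .laplace import GaussianPosterior, laplace_posterior, map_estimate
from .mcmc import SampleSet, adapt_proposal, default_proposal, sample_posterior
from .model import (
    Dataset,
    ModelParams,
    ParamLayout,
    PriorSpec,
    choice_probabilities,
    uniform_lapse_u,
)
from .space import StimulusSpace, grid_candidates, normalize_space

logger = logging.getLogger(__name__)

__all__ = [
    "TrueObserver",
    "ExperimentConfig",
    "ExperimentTrace",
    "sample_response",
    "run_closed_loop",
    "run_reordering",
    "pf_mse",
    "posterior_entropy",
    "make_fixture_observer",
    "init_indices",
    "run_seeds",
]

# Weight magnitude of the four-alternative fixture observer.  The magnitude
# is chosen so that each cardinal direction has a clearly dominant choice
# well inside its quadrant of the normalized grid while the decision
# boundaries remain graded (probabilities cross 0.5 within the grid).
FOURCHOICE_WEIGHT_SCALE = 3.0


@dataclass
class TrueObserver:
    """Ground-truth observer: fixed parameters plus a seeded response RNG."""

    params: ModelParams
    seed: int = 0
    rng: np.random.Generator = field(default=None, repr=False)

    def __post_init__(self):
        if self.rng is None:
            self.rng = np.random.default_rng(self.seed)


def sample_response(
    observer: TrueObserver,
    features_row: np.ndarray,
    rng: np.random.Generator | None = None,
) -> int:
    """Draw a categorical response (0-based index) from the true PF."""
    if rng is None:
        rng = observer.rng
    p = choice_probabilities(observer.params, np.asarray(features_row)).probs
    return int(rng.choice(p.shape[-1], p=p))


def init_indices(n_candidates: int, n_init: int) -> np.ndarray:
    """Initial-trial placement: evenly spaced indices along the row-major
    traversal of the candidate grid."""
    return np.unique(
        np.round(np.linspace(0, n_candidates - 1, n_init)).astype(int)
    )


def pf_mse(est, truth: ModelParams | np.ndarray, space: StimulusSpace) -> float:
    """Mean squared error between estimated and true choice probabilities,
    averaged over the candidate grid and all response categories.

    ``est`` may be a ModelParams (plug-in probabilities), a SampleSet
    (posterior-predictive average), or a precomputed (n, k) array.  ``truth``
    may likewise be a ModelParams or an (n, k) array.
    """
    feats = space.features()
    if isinstance(truth, ModelParams):
        p_true = choice_probabilities(truth, feats).probs
    else:
        p_true = np.asarray(truth, dtype=float)
    if isinstance(est, ModelParams):
        p_hat = choice_probabilities(est, feats).probs
    elif isinstance(est, SampleSet):
        p_hat = sample_choice_probs(est.layout, est.samples, feats).mean(axis=0)
    else:
        p_hat = np.asarray(est, dtype=float)
    if p_hat.shape != p_true.shape:
        raise ValueError(
            f"probability tables have mismatched shapes {p_hat.shape} vs "
            f"{p_true.shape} (grid or category-count mismatch)"
        )
    return float(np.mean((p_true - p_hat) ** 2))


def posterior_entropy(state: GaussianPosterior | SampleSet) -> float:
    """Posterior entropy in nats, additive constant dropped.

    Laplace: ½ log|C_ww| over the weight block.  MCMC: Gaussian-
    approximation entropy ½ log|Cov(samples)| over all free parameters.
    The per-engine constant conventions differ (partial vs full
    covariance), so traces are comparable only within an engine.
    """
    if isinstance(state, GaussianPosterior):
        return state.entropy_weights()
    cov = np.atleast_2d(state.cov())
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-PSD sample covariance")
    return 0.5 * logdet


# ---------------------------------------------------------------------------
# inference engines for the closed loop
# ---------------------------------------------------------------------------


class _LaplaceEngine:
    def __init__(self, prior, layout, gh_order):
        self.prior = prior
        self.layout = layout
        self.gh_order = gh_order
        self._mode = None
        self.posterior: GaussianPosterior | None = None

    def update(self, data: Dataset, rng) -> None:
        self._mode = map_estimate(data, self.prior, self.layout, init=self._mode)
        self.posterior = laplace_posterior(data, self.prior, self._mode)

    def utilities(self, features) -> UtilityTable:
        return laplace_utilities(self.posterior, features, self.gh_order)

    def entropy(self) -> float:
        return posterior_entropy(self.posterior)

    def predict_probs(self, features) -> np.ndarray:
        return choice_probabilities(self.posterior.mode, features).probs

    @property
    def state(self):
        return self.posterior


class _MCMCEngine:
    def __init__(self, prior, layout, n_samples, burn_in):
        self.prior = prior
        self.layout = layout
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.samples: SampleSet | None = None
        self._proposal = default_proposal(layout.n_free)

    def update(self, data: Dataset, rng) -> None:
        if self.samples is None:
            init = self.layout.default_params()
        else:
            init = self.layout.unpack(self.samples.mean())
            self._proposal = adapt_proposal(self.samples)
        self.samples = sample_posterior(
            data,
            self.prior,
            self.layout,
            init=init,
            proposal_cov=self._proposal,
            n_samples=self.n_samples,
            burn_in=self.burn_in,
            seed=rng,
        )

    def utilities(self, features) -> UtilityTable:
        return mcmc_utilities(self.samples, features)

    def entropy(self) -> float:
        return posterior_entropy(self.samples)

    def predict_probs(self, features) -> np.ndarray:
        return sample_choice_probs(
            self.layout, self.samples.samples, features
        ).mean(axis=0)

    @property
    def state(self):
        return self.samples


def _make_engine(config: "ExperimentConfig", layout: ParamLayout):
    if config.engine == "laplace":
        return _LaplaceEngine(config.prior, layout, config.gh_order)
    if config.engine == "mcmc":
        return _MCMCEngine(
            config.prior, layout, config.mcmc_samples, config.mcmc_burn_in
        )
    raise ValueError(f"unknown engine {config.engine!r}")


@dataclass
class ExperimentConfig:
    """Configuration of one closed-loop (or reordering) run."""

    engine: str = "laplace"  # laplace | mcmc
    selection: str = "infomax"  # infomax | uniform
    lapse_mode: str = "none"  # inference model: none | uniform | full
    n_trials: int = 100
    n_init: int = 10
    gh_order: int = 5
    mcmc_samples: int = 500
    mcmc_burn_in: int | None = None
    prior: PriorSpec = field(default_factory=PriorSpec)
    seed: int = 0

    @property
    def lapse_aware(self) -> bool:
        return self.lapse_mode != "none"


@dataclass
class ExperimentTrace:
    """Per-trial log of a closed-loop or reordering run."""

    stimulus_indices: np.ndarray  # candidate index per trial
    responses: np.ndarray  # 0-based category per trial
    entropy: np.ndarray  # nats; NaN during the initialization block
    mse: np.ndarray  # PF mean squared error; NaN during init
    config: ExperimentConfig
    error: str | None = None  # non-None if the run was truncated

    @property
    def n_trials(self) -> int:
        return len(self.stimulus_indices)


def run_seeds(master_seed: int, n_runs: int) -> list[tuple[int, int, int]]:
    """Deterministic seed fan-out: the master seed spawns one SeedSequence
    per run, which spawns (observer, inference-chain, tie-break) streams."""
    out = []
    for run_ss in np.random.SeedSequence(master_seed).spawn(n_runs):
        obs, chain, tie = run_ss.spawn(3)
        out.append(
            tuple(int(s.generate_state(1)[0] % (2 ** 31)) for s in (obs, chain, tie))
        )
    return out


def run_closed_loop(
    observer: TrueObserver,
    space: StimulusSpace,
    config: ExperimentConfig,
    rng_streams: tuple | None = None,
    eval_space: StimulusSpace | None = None,
) -> ExperimentTrace:
    """Execute the collect → infer → select loop against a true observer.

    The first ``n_init`` trials are placed at regular intervals over the
    grid; afterwards stimuli are chosen per ``config.selection``.  Posterior
    entropy and PF error are recorded after every post-initialization trial.
    Inference failure truncates the trace with an error record.

    ``eval_space`` optionally evaluates the PF error on a different grid
    than the selection grid (e.g. axes-only selection scored on the full
    plane); it defaults to ``space``.
    """
    if config.n_init < 1 or config.n_trials <= config.n_init:
        raise ValueError("need n_init >= 1 and n_trials > n_init")
    if rng_streams is None:
        rng_streams = run_seeds(config.seed, 1)[0]
    obs_rng = np.random.default_rng(rng_streams[0])
    chain_rng = np.random.default_rng(rng_streams[1])
    tie_rng = np.random.default_rng(rng_streams[2])

    k = observer.params.n_categories
    layout = ParamLayout(
        n_categories=k, n_features=space.n_features, lapse_mode=config.lapse_mode
    )
    engine = _make_engine(config, layout)
    feats = space.features()
    n_cand = space.n_candidates
    if eval_space is None:
        eval_space = space
    eval_feats = eval_space.features()

    chosen: list[int] = []
    responses: list[int] = []
    entropy = np.full(config.n_trials, np.nan)
    mse = np.full(config.n_trials, np.nan)
    data = Dataset.empty(space.n_features)
    error = None

    # The adaptive runner seeds inference with n_init trials at regular
    # grid intervals; the uniform baseline draws uniformly on *every*
    # trial, its init block included.
    if config.selection == "uniform":
        first = tie_rng.integers(n_cand, size=config.n_init)
    else:
        first = init_indices(n_cand, config.n_init)
    for idx in first:
        y = sample_response(observer, feats[idx], obs_rng)
        chosen.append(int(idx))
        responses.append(y)
        data = data.append(feats[idx], y)

    t = len(chosen)
    try:
        engine.update(data, chain_rng)
        entropy[t - 1] = engine.entropy()
        mse[t - 1] = pf_mse(
            engine.predict_probs(eval_feats), observer.params, eval_space
        )
        while t < config.n_trials:
            utility = np.nan
            if config.selection == "uniform":
                idx = int(tie_rng.integers(n_cand))
            elif config.selection == "infomax":
                table = engine.utilities(feats)
                idx = select_stimulus(table, tie_rng)
                utility = float(table.utilities[idx])
                if logger.isEnabledFor(logging.DEBUG):
                    logger.debug(
                        "trial %d grid utilities: %s", t + 1,
                        np.array2string(table.utilities, precision=4),
                    )
            else:
                raise ValueError(f"unknown selection {config.selection!r}")
            y = sample_response(observer, feats[idx], obs_rng)
            chosen.append(idx)
            responses.append(y)
            data = data.append(feats[idx], y)
            engine.update(data, chain_rng)
            entropy[t] = engine.entropy()
            mse[t] = pf_mse(
                engine.predict_probs(eval_feats), observer.params, eval_space
            )
            logger.info(
                "trial %d: stimulus %d, response %d, entropy %.3f nats, "
                "utility %.4f", t + 1, idx, y, entropy[t], utility,
            )
            t += 1
    except (np.linalg.LinAlgError, RuntimeError, ValueError) as exc:
        error = f"inference failed at trial {t}: {exc}"
        entropy = entropy[:t]
        mse = mse[:t]

    return ExperimentTrace(
        stimulus_indices=np.asarray(chosen, dtype=int),
        responses=np.asarray(responses, dtype=int),
        entropy=entropy,
        mse=mse,
        config=config,
        error=error,
    )


def run_reordering(
    stimuli: np.ndarray,
    responses: np.ndarray,
    space: StimulusSpace,
    config: ExperimentConfig,
    reference: ModelParams | None = None,
    rng_streams: tuple | None = None,
) -> ExperimentTrace:
    """Re-sequence recorded trials by expected informativeness.

    ``stimuli`` is an (n, d) array of *normalized* stimuli, ``responses``
    the matching 0-based categories.  Trials are pooled by distinct
    stimulus value; each step scores the distinct stimuli still in the
    pool, selects the best (never peeking at responses), consumes one
    recorded instance (FIFO among duplicates) and updates the posterior.
    The error trace is computed against ``reference`` — by default the MAP
    fit of the full recorded table, the stand-in for ground truth.
    """
    stimuli = np.atleast_2d(np.asarray(stimuli, dtype=float))
    responses = np.asarray(responses, dtype=int)
    if stimuli.shape[0] == 0:
        raise ValueError("recorded trial table is empty")
    if rng_streams is None:
        rng_streams = run_seeds(config.seed, 1)[0]
    chain_rng = np.random.default_rng(rng_streams[1])
    tie_rng = np.random.default_rng(rng_streams[2])

    k = int(responses.max()) + 1
    layout = ParamLayout(
        n_categories=k, n_features=space.n_features, lapse_mode=config.lapse_mode
    )
    feats_all = space.features(stimuli)

    distinct, inverse = np.unique(stimuli, axis=0, return_inverse=True)
    pool: dict[int, list[int]] = {g: [] for g in range(distinct.shape[0])}
    for trial, g in enumerate(inverse):
        pool[int(g)].append(trial)  # FIFO order of recording
    distinct_feats = space.features(distinct)

    if reference is None:
        full_data = Dataset(phi=feats_all, y=responses)
        reference = map_estimate(full_data, config.prior, layout)
    p_ref = choice_probabilities(reference, space.features()).probs

    n_trials = min(config.n_trials, stimuli.shape[0])
    n_init = min(config.n_init, n_trials)
    engine = _make_engine(config, layout)

    chosen: list[int] = []
    entropy = np.full(n_trials, np.nan)
    mse = np.full(n_trials, np.nan)
    data = Dataset.empty(space.n_features)
    error = None

    def pop_group(g: int) -> int:
        trial = pool[g].pop(0)
        if not pool[g]:
            del pool[g]
        return trial

    # initialization block: first trials in recording order
    for _ in range(n_init):
        g = min(pool, key=lambda gg: pool[gg][0])  # earliest recorded trial
        trial = pop_group(g)
        chosen.append(trial)
        data = data.append(feats_all[trial], responses[trial])

    t = len(chosen)
    try:
        engine.update(data, chain_rng)
        entropy[t - 1] = engine.entropy()
        mse[t - 1] = pf_mse(engine.predict_probs(space.features()), p_ref, space)
        while t < n_trials and pool:
            groups = sorted(pool.keys())
            if config.selection == "uniform":
                g = groups[int(tie_rng.integers(len(groups)))]
            else:
                util = engine.utilities(distinct_feats[groups])
                g = groups[select_stimulus(util, tie_rng)]
            trial = pop_group(g)
            chosen.append(trial)
            data = data.append(feats_all[trial], responses[trial])
            engine.update(data, chain_rng)
            entropy[t] = engine.entropy()
            mse[t] = pf_mse(
                engine.predict_probs(space.features()), p_ref, space
            )
            t += 1
    except (np.linalg.LinAlgError, RuntimeError, ValueError) as exc:
        error = f"inference failed at trial {t}: {exc}"
    entropy = entropy[:t]
    mse = mse[:t]

    return ExperimentTrace(
        stimulus_indices=np.asarray(chosen, dtype=int),
        responses=responses[np.asarray(chosen, dtype=int)],
        entropy=entropy,
        mse=mse,
        config=config,
        error=error,
    )


# ---------------------------------------------------------------------------
# fixture observers
# ---------------------------------------------------------------------------


def make_fixture_observer(
    kind: str, lapse: float = 0.0, seed: int = 0
) -> tuple[TrueObserver, StimulusSpace]:
    """Standard simulated observers used throughout the package.

    ``fig3_binary``
        1-D stimulus (21 points), two alternatives, slope 2 and bias 0 on
        the normalized axis: P(y=1|x) = σ(2x).
    ``fig5_fourchoice``
        2-D 21×21 grid, four alternatives whose sensitivity vectors point
        along the four cardinal directions (magnitude
        ``FOURCHOICE_WEIGHT_SCALE``), zero biases.
    ``rotated``
        Same, with the sensitivity directions rotated counterclockwise 45°.

    ``lapse`` > 0 adds a uniform lapse mixture (c_i = 1/k) with the given
    total lapse probability.
    """
    if not 0.0 <= lapse < 0.8:
        raise ValueError("lapse must lie in [0, 0.8)")
    if kind == "fig3_binary":
        space = normalize_space(np.linspace(-2.0, 2.0, 21)[:, None])
        k = 2
        raw_w = np.array([[0.0, 2.0], [0.0, 0.0]])
    elif kind in ("fig5_fourchoice", "rotated"):
        space = normalize_space(grid_candidates([-2.0, -2.0], [2.0, 2.0], 21))
        k = 4
        dirs = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        if kind == "rotated":
            c, s = math.cos(math.pi / 4), math.sin(math.pi / 4)
            rot = np.array([[c, -s], [s, c]])
            dirs = dirs @ rot.T
        raw_w = np.concatenate(
            [np.zeros((k, 1)), FOURCHOICE_WEIGHT_SCALE * dirs], axis=1
        )
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    # shift so the last category is the zero reference (softmax-invariant)
    weights = raw_w - raw_w[-1]
    if lapse > 0:
        params = ModelParams(
            weights=weights,
            u=np.array([uniform_lapse_u(lapse, k)]),
            lapse_mode="uniform",
        )
    else:
        params = ModelParams(weights=weights, lapse_mode="none")
    return TrueObserver(params=params, seed=seed), space
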