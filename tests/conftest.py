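import numpy as np
import pytest

from infomaxpf import (
    Dataset,
    ParamLayout,
    PriorSpec,
    laplace_posterior,
    map_estimate,
    make_fixture_observer,
    sample_response,
)
from infomaxpf.mcmc import sample_posterior


def simulate_dataset(observer, space, n_trials, seed, indices=None):
    """Draw a static dataset from a true observer at uniform (or given)
    stimulus indices."""
    rng = np.random.default_rng(seed)
    feats = space.features()
    if indices is None:
        indices = rng.integers(0, space.n_candidates, n_trials)
    y = np.array([sample_response(observer, feats[i], rng) for i in indices])
    return Dataset(phi=feats[indices], y=y), np.asarray(indices)


@pytest.fixture(scope="session")
def binary_toy():
    """Fig-3-style binary toy: observer (slope 2, bias 0), its stimulus
    space, and a 60-trial dataset."""
    observer, space = make_fixture_observer("fig3_binary", seed=7)
    data, _ = simulate_dataset(observer, space, 60, seed=11)
    return observer, space, data


@pytest.fixture(scope="session")
def binary_laplace(binary_toy):
    observer, space, data = binary_toy
    layout = ParamLayout(2, 2, "none")
    prior = PriorSpec()
    mode = map_estimate(data, prior, layout)
    return laplace_posterior(data, prior, mode)


@pytest.fixture(scope="session")
def binary_samples(binary_toy, binary_laplace):
    _, _, data = binary_toy
    layout = ParamLayout(2, 2, "none")
    return sample_posterior(
        data,
        PriorSpec(),
        layout,
        init=binary_laplace.mode,
        proposal_cov=2.0 * binary_laplace.cov,
        n_samples=4000,
        seed=3,
    )
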