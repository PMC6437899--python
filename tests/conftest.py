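import numpy as np
import pytest

from ehmm.emissions import EmissionModel
from ehmm.hmm_core import ConstrictedHMM
from ehmm.signal_io import GenomePartition, SignalMatrix


def make_hmm(init, trans, mask, mu, sigma, roles=None, features=None):
    """Assemble a ConstrictedHMM from raw arrays (single- or multi-feature)."""
    mu = np.atleast_2d(np.asarray(mu, float))
    sigma = np.atleast_2d(np.asarray(sigma, float))
    if mu.shape[0] == 1 and len(init) > 1:
        mu, sigma = mu.T, sigma.T
    n = len(init)
    features = features or tuple(f"f{j}" for j in range(mu.shape[1]))
    emissions = EmissionModel(list(range(n)), features, mu, sigma)
    roles = roles or ["BG"] * n
    return ConstrictedHMM(list(roles), np.asarray(init, float),
                          np.asarray(trans, float), np.asarray(mask, bool), emissions)


def sample_observations(rng, model, length):
    """Draw a state path and pseudo-counted observations from a model."""
    states = np.empty(length, dtype=int)
    states[0] = rng.choice(model.n_states, p=model.startprob)
    for t in range(1, length):
        states[t] = rng.choice(model.n_states, p=model.transmat[states[t - 1]])
    mu = model.emissions.mu[states]
    sigma = model.emissions.sigma[states]
    obs = np.exp(rng.normal(mu, sigma))
    return states, np.maximum(obs, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_partition():
    return GenomePartition({"chr1": 2000, "chr2": 1450}, bin_width=100)


@pytest.fixture
def small_signals(small_partition, rng):
    counts = {c: rng.integers(0, 30, size=(small_partition.n_bins(c), 4)).astype(np.int64)
              for c in small_partition.chroms}
    return SignalMatrix(small_partition,
                        ("accessibility", "H3K27ac", "H3K4me1", "H3K4me3"), counts)


@pytest.fixture(scope="session")
def easy_truth():
    """A modest synthetic genome from the easy ground-truth model, shared
    across tests that only read from it."""
    from ehmm.synthetic import default_truth_model, simulate

    model = default_truth_model("easy")
    return simulate(model, n_bins=60_000, seed=7)
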