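"""Generic HMM engine with a boolean transition mask.

Supports forward-backward posteriors, Viterbi decoding, Baum-Welch, and
Viterbi training with frozen emissions and start/end role constraints — the
training mode used for the directed N1 -> A -> N2 foreground modules, where
hard path assignment makes it possible to force every training region to
begin at the first flanking nucleosome and end at the second.

Observations are pseudo-counted count matrices (n_bins, n_features) with all
values >= 1; emissions are evaluated on their logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .emissions import EmissionModel, fit_lognormal

ROW_TOL = 1e-9
TRANSITION_SMOOTHING = 1e-6  # expected-count floor for allowed transitions


@dataclass
class ConstrictedHMM:
    """An HMM whose transition matrix is constrained by a boolean mask.

    Attributes
    ----------
    roles : per-state labels (BG, E_N1, E_A, E_N2, P_N1, P_A, P_N2, or FG5
        for an unselected 5-state foreground fit)
    startprob : initial distribution; zero for states disallowed as starts
    transmat : row-stochastic matrix, zero wherever ``mask`` is False
    mask : True where a transition is allowed
    emissions : per-state log-normal emission parameters
    """

    roles: list[str]
    startprob: np.ndarray
    transmat: np.ndarray
    mask: np.ndarray
    emissions: EmissionModel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.startprob = np.asarray(self.startprob, dtype=np.float64)
        self.transmat = np.asarray(self.transmat, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.roles)

    @property
    def features(self) -> tuple[str, ...]:
        return self.emissions.features

    def validate(self) -> None:
        n = self.n_states
        if self.startprob.shape != (n,) or self.transmat.shape != (n, n) \
                or self.mask.shape != (n, n):
            raise ValueError("inconsistent model dimensions")
        if self.emissions.n_states != n:
            raise ValueError("emission model does not match state count")
        if abs(self.startprob.sum() - 1.0) > ROW_TOL or (self.startprob < 0).any():
            raise ValueError("startprob must be a probability vector")
        rowsums = self.transmat.sum(axis=1)
        if (np.abs(rowsums - 1.0) > ROW_TOL).any() or (self.transmat < 0).any():
            raise ValueError("transition rows must be stochastic")
        if (self.transmat[~self.mask] != 0).any():
            raise ValueError("masked transitions must be exactly zero")
        if (~self.mask.any(axis=1)).any():
            raise ValueError("a state has no allowed outgoing transition")

    def role_indices(self, roles) -> np.ndarray:
        """Indices of all states whose role is in ``roles``."""
        roles = {roles} if isinstance(roles, str) else set(roles)
        return np.flatnonzero([r in roles for r in self.roles])

    def copy(self) -> "ConstrictedHMM":
        return ConstrictedHMM(list(self.roles), self.startprob.copy(),
                              self.transmat.copy(), self.mask.copy(),
                              self.emissions.copy(), dict(self.metadata))


@dataclass
class PosteriorMatrix:
    """Forward-backward posteriors for one or more observation sequences."""

    gamma: list[np.ndarray]          # per sequence, (T, S), rows sum to 1
    log_likelihoods: np.ndarray      # per sequence

    @property
    def total_log_likelihood(self) -> float:
        return float(self.log_likelihoods.sum())


@dataclass
class StatePath:
    """A Viterbi path: per-bin state indices and the path log-probability."""

    states: np.ndarray
    log_probability: float


def _as_sequences(observations):
    if isinstance(observations, np.ndarray) and observations.ndim == 2:
        return [observations]
    seqs = list(observations)
    if not seqs:
        raise ValueError("observations must be non-empty")
    return seqs


def _log_transmat(model: ConstrictedHMM) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lt = np.log(model.transmat)
    lt[~model.mask] = -np.inf
    return lt


def _frame_loglik(model: ConstrictedHMM, obs: np.ndarray) -> np.ndarray:
    obs = np.asarray(obs, dtype=np.float64)
    if (obs < 1).any():
        raise ValueError("observations must be pseudo-counted (>= 1)")
    return model.emissions.frame_log_likelihood(obs)


def forward_backward(model: ConstrictedHMM, observations) -> PosteriorMatrix:
    """Posterior state probabilities and log-likelihood per sequence.

    Numerically stable via per-frame rescaling of emission likelihoods plus
    scaled recursions, so megabase-scale sequences pose no problem.
    """
    seqs = _as_sequences(observations)
    gammas, lls = [], []
    for obs in seqs:
        logb = _frame_loglik(model, obs)
        shift = logb.max(axis=1)
        bstar = np.exp(logb - shift[:, None])
        gamma, _, log_norm = _kernels.forward_backward_scaled(
            model.startprob, model.transmat, bstar)
        gammas.append(gamma)
        lls.append(log_norm + shift.sum())
    return PosteriorMatrix(gammas, np.asarray(lls))


def viterbi(model: ConstrictedHMM, observations, start_states=None, end_states=None):
    """Globally most likely state path(s); respects the transition mask.

    ``start_states`` / ``end_states`` optionally restrict the first / last
    bin to a subset of states (used by constrained Viterbi training); the
    restriction is applied in the lattice, the model is not modified.

    Returns a StatePath for a single (T, F) array, else a list of them.
    """
    single = isinstance(observations, np.ndarray) and observations.ndim == 2
    seqs = _as_sequences(observations)
    with np.errstate(divide="ignore"):
        log_init = np.log(model.startprob)
    log_trans = _log_transmat(model)
    out = []
    for k, obs in enumerate(seqs):
        logb = _frame_loglik(model, obs)
        if start_states is not None:
            banned = np.setdiff1d(np.arange(model.n_states), start_states)
            logb = logb.copy()
            logb[0, banned] = -np.inf
        if end_states is not None:
            banned = np.setdiff1d(np.arange(model.n_states), end_states)
            if start_states is None:
                logb = logb.copy()
            logb[-1, banned] = -np.inf
        path, logp = _kernels.viterbi_log(log_init, log_trans, logb)
        if not np.isfinite(logp):
            raise ValueError(f"no admissible state path for sequence {k}")
        out.append(StatePath(path, float(logp)))
    return out[0] if single else out


def baum_welch(model: ConstrictedHMM, observations, max_iter: int = 100,
               tol: float = 1e-4) -> ConstrictedHMM:
    """Baum-Welch EM restricted to the transition mask.

    Transitions are re-estimated from expected counts (masked entries stay
    exactly zero); emissions are refit per state and feature by the weighted
    log-normal estimator with posterior weights.  Stops when the
    log-likelihood improves by less than ``tol`` or after ``max_iter``
    iterations; the likelihood is non-decreasing up to numerical slack.
    """
    seqs = [np.asarray(o, dtype=np.float64) for o in _as_sequences(observations)]
    model = model.copy()
    prev_ll = -np.inf
    for _ in range(max_iter):
        xi_total = np.zeros((model.n_states, model.n_states))
        start_total = np.zeros(model.n_states)
        gammas = []
        ll = 0.0
        for obs in seqs:
            logb = _frame_loglik(model, obs)
            shift = logb.max(axis=1)
            bstar = np.exp(logb - shift[:, None])
            gamma, xi, log_norm = _kernels.forward_backward_scaled(
                model.startprob, model.transmat, bstar)
            ll += log_norm + shift.sum()
            xi_total += xi
            start_total += gamma[0]
            gammas.append(gamma)
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite likelihood (last good ll={prev_ll})")

        # M-step: transitions from expected counts, restricted to the mask
        xi_total[~model.mask] = 0.0
        rowsums = xi_total.sum(axis=1)
        new_trans = model.transmat.copy()
        nz = rowsums > 0
        new_trans[nz] = xi_total[nz] / rowsums[nz, None]
        model.transmat = new_trans
        model.startprob = start_total / start_total.sum()

        # emissions from posterior-weighted fits
        all_obs = np.concatenate(seqs, axis=0)
        all_gamma = np.concatenate(gammas, axis=0)
        for i in range(model.n_states):
            w = all_gamma[:, i]
            if w.sum() <= 0:
                continue
            for j in range(len(model.features)):
                p = fit_lognormal(all_obs[:, j], w)
                model.emissions.mu[i, j] = p.mu
                model.emissions.sigma[i, j] = p.sigma

        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll
    return model


def viterbi_train(model: ConstrictedHMM, training_sequences, start_roles,
                  end_roles, max_iter: int = 50, tol: float = 0.0) -> ConstrictedHMM:
    """Hard-EM transition re-estimation with frozen emissions.

    Per iteration: (1) constrained Viterbi per sequence with the first bin
    restricted to ``start_roles`` states and the last bin to ``end_roles``
    states; (2) transitions re-estimated from hard path transition counts
    with a small smoothing count added to every allowed transition so none
    collapses to exactly zero from finite data.  Emission parameters are
    never modified.  Stops when the decoded paths reach a fixed point or
    after ``max_iter`` iterations.
    """
    del tol  # convergence is a path fixed-point, not a likelihood threshold
    seqs = [np.asarray(o, dtype=np.float64) for o in _as_sequences(training_sequences)]
    model = model.copy()
    frozen = model.emissions  # never rebuilt; shared by reference on purpose
    start_states = model.role_indices(start_roles)
    end_states = model.role_indices(end_roles)
    if start_states.size == 0 or end_states.size == 0:
        raise ValueError("start/end roles match no state")
    prev_paths = None
    for _ in range(max_iter):
        paths = [viterbi(model, obs, start_states, end_states).states for obs in seqs]
        counts = np.zeros((model.n_states, model.n_states))
        for p in paths:
            np.add.at(counts, (p[:-1], p[1:]), 1.0)
        counts[model.mask] += TRANSITION_SMOOTHING
        counts[~model.mask] = 0.0
        model.transmat = counts / counts.sum(axis=1, keepdims=True)
        if prev_paths is not None and all(
                np.array_equal(a, b) for a, b in zip(paths, prev_paths)):
            break
        prev_paths = paths
    model.emissions = frozen
    return model


def stationary_distribution(transmat: np.ndarray) -> np.ndarray:
    """Left stationary distribution of a row-stochastic matrix (principal
    eigenvector, normalized; real part taken)."""
    vals, vecs = np.linalg.eig(transmat.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    v = np.abs(v)
    return v / v.sum()
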