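"""Numba dynamic-programming kernels for the HMM engine.

All kernels work on dense per-frame emission scores.  Forward-backward uses
per-step scaling; Viterbi runs fully in log space.  Genome-scale sequences
(1e6 bins, 22 states) decode in seconds.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def forward_backward_scaled(init, trans, bstar):
    """Scaled forward-backward.

    Parameters
    ----------
    init : (S,) initial distribution
    trans : (S, S) row-stochastic transition matrix
    bstar : (T, S) emission likelihoods rescaled per frame (any positive
        per-frame rescaling leaves gamma and xi unchanged)

    Returns
    -------
    gamma : (T, S) posterior state probabilities
    xi_sum : (S, S) expected transition counts summed over t
    log_norm : sum of log scaling constants; the caller adds back the
        per-frame log rescaling to obtain the true log-likelihood
    """
    T, S = bstar.shape
    alpha = np.empty((T, S))
    c = np.empty(T)

    a = init * bstar[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = np.zeros(S)
        for i in range(S):
            ai = alpha[t - 1, i]
            if ai > 0.0:
                for j in range(S):
                    a[j] += ai * trans[i, j]
        a *= bstar[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]

    beta = np.ones(S)
    gamma = np.empty((T, S))
    xi_sum = np.zeros((S, S))
    gamma[T - 1] = alpha[T - 1] * beta
    for t in range(T - 2, -1, -1):
        bb = bstar[t + 1] * beta / c[t + 1]
        newbeta = np.zeros(S)
        for i in range(S):
            ai = alpha[t, i]
            acc = 0.0
            for j in range(S):
                w = trans[i, j] * bb[j]
                acc += w
                xi_sum[i, j] += ai * w
            newbeta[i] = acc
        beta = newbeta
        gamma[t] = alpha[t] * beta
    log_norm = 0.0
    for t in range(T):
        log_norm += np.log(c[t])
    return gamma, xi_sum, log_norm


@njit(cache=True)
def viterbi_log(log_init, log_trans, log_b):
    """Log-space Viterbi; ties broken toward the lowest state index.

    Returns (path, best log joint probability).  If no admissible path
    exists the returned log probability is -inf.
    """
    T, S = log_b.shape
    delta = log_init + log_b[0]
    back = np.zeros((T, S), dtype=np.int64)
    for t in range(1, T):
        newdelta = np.empty(S)
        for j in range(S):
            best = -np.inf
            arg = 0
            for i in range(S):
                v = delta[i] + log_trans[i, j]
                if v > best:
                    best = v
                    arg = i
            newdelta[j] = best + log_b[t, j]
            back[t, j] = arg
        delta = newdelta
    best = -np.inf
    arg = 0
    for j in range(S):
        if delta[j] > best:
            best = delta[j]
            arg = j
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = arg
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, best


@njit(cache=True)
def sample_path(init_cum, trans_cum, uniforms):
    """Sample a state path from cumulative initial/transition distributions."""
    T = uniforms.shape[0]
    S = init_cum.shape[0]
    path = np.empty(T, dtype=np.int64)
    u = uniforms[0]
    s = 0
    while s < S - 1 and u > init_cum[s]:
        s += 1
    path[0] = s
    for t in range(1, T):
        u = uniforms[t]
        row = trans_cum[path[t - 1]]
        s = 0
        while s < S - 1 and u > row[s]:
            s += 1
        path[t] = s
    return path
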