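"""Independent brute-force oracles used to check the dynamic-programming
and metric implementations.  Everything here enumerates exhaustively and is
only feasible at toy sizes."""

import itertools

import numpy as np


def enumerate_paths(n_states: int, length: int):
    return itertools.product(range(n_states), repeat=length)


def path_log_prob(path, log_init, log_trans, log_b) -> float:
    lp = log_init[path[0]] + log_b[0, path[0]]
    for t in range(1, len(path)):
        lp += log_trans[path[t - 1], path[t]] + log_b[t, path[t]]
    return lp


def brute_force_posteriors(init, trans, log_b):
    """Posterior state probabilities and log-likelihood by summing over all
    state sequences."""
    T, S = log_b.shape
    with np.errstate(divide="ignore"):
        log_init, log_trans = np.log(init), np.log(trans)
    joint = np.full((S,) * T, -np.inf)
    for path in enumerate_paths(S, T):
        joint[path] = path_log_prob(path, log_init, log_trans, log_b)
    flat = joint.reshape(-1)
    m = flat.max()
    total = m + np.log(np.exp(flat - m).sum())
    gamma = np.zeros((T, S))
    for path in enumerate_paths(S, T):
        w = np.exp(joint[path] - total)
        for t, s in enumerate(path):
            gamma[t, s] += w
    return gamma, float(total)


def brute_force_viterbi(init, trans, log_b):
    """Best path and its log joint probability by exhaustive enumeration;
    ties resolved toward the lexicographically smallest path (matching the
    lowest-index tie-break of the lattice recursion)."""
    T, S = log_b.shape
    with np.errstate(divide="ignore"):
        log_init, log_trans = np.log(init), np.log(trans)
    best_lp, best_path = -np.inf, None
    for path in enumerate_paths(S, T):
        lp = path_log_prob(path, log_init, log_trans, log_b)
        if lp > best_lp:
            best_lp, best_path = lp, path
    return np.array(best_path), float(best_lp)


def brute_force_pr(scores, labels):
    """Precision/recall at every distinct threshold plus the step-wise area
    (average precision), by direct enumeration."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    thresholds = np.unique(scores)[::-1]
    n_pos = labels.sum()
    points = []
    for th in thresholds:
        called = scores >= th
        tp = int((called & (labels == 1)).sum())
        points.append((th, tp / called.sum(), tp / n_pos))
    ap = 0.0
    prev_recall = 0.0
    for _, prec, rec in points:
        ap += (rec - prev_recall) * prec
        prev_recall = rec
    return points, ap


def brute_force_nearest(points_a, points_b):
    """O(n*m) nearest-neighbour distances from each a to the closest b."""
    return np.array([min(abs(a - b) for b in points_b) for a in points_a])


def random_masked_model(rng, n_states, mask_density=1.0):
    """A random valid (init, trans, mask) triple; every row keeps >= 1
    allowed transition, the diagonal always allowed."""
    mask = rng.random((n_states, n_states)) < mask_density
    np.fill_diagonal(mask, True)
    trans = rng.random((n_states, n_states)) * mask
    trans /= trans.sum(axis=1, keepdims=True)
    init = rng.random(n_states)
    init /= init.sum()
    return init, trans, mask
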