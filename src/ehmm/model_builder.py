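"""Supervised construction of the combined enhancer/promoter/background model.

The foreground (enhancer and promoter) sub-models are built in two steps:
an unsupervised 5-state HMM is fitted to the training regions, then states
are selected by their emission patterns — the two states with the highest
accessibility/H3K27ac mean ratio become accessible-chromatin (A) states, and
among the remaining three the two with the highest (enhancer) or lowest
(promoter) H3K4me1/H3K4me3 ratio become nucleosome (N) states.  The N states
are duplicated into N1 and N2 and arranged in the directed order
N1 -> A -> N2; transitions against that direction are forbidden.  The module
is then refined by Viterbi training with frozen emissions, forcing training
regions to start in N1 and end in N2.

A conventional 10-state background HMM is fitted to an unbalanced background
set, and the three sub-models are composed into one 22-state model.  The
background-to-N1 entry rates derive from genome-scale element counts
(399,124 enhancers and 70,292 promoters in ~3e9 bp at 100 bp bins give
1.33% and 0.23%); N2-to-background exit mass is set to the learned N1-to-A
mass since the two flanking nucleosomes are expected to be equally sized.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .emissions import SIGMA_FLOOR, EmissionModel
from .hmm_core import ConstrictedHMM, baum_welch, stationary_distribution, viterbi_train
from .signal_io import CANONICAL_FEATURES

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class StateSelection:
    """Assignment of the 5 foreground states to A/N roles (one discarded)."""

    a_states: tuple[int, int]
    n_states: tuple[int, int]
    discarded: int

    def __post_init__(self):
        ids = set(self.a_states) | set(self.n_states) | {self.discarded}
        if ids != set(range(5)) or set(self.a_states) & set(self.n_states):
            raise ValueError("selection must partition states 0..4")


@dataclass(frozen=True)
class CompositionConfig:
    """Genome-scale statistics that set the background-to-foreground entry rates."""

    n_enhancers_genome: int = 399_124
    n_promoters_genome: int = 70_292
    genome_bp: int = 3_000_000_000
    bin_width: int = 100

    def __post_init__(self):
        if min(self.n_enhancers_genome, self.n_promoters_genome) < 0 \
                or self.genome_bp <= 0 or self.bin_width <= 0:
            raise ValueError("config entries must be positive")


def entry_rates(config: CompositionConfig = CompositionConfig()) -> tuple[float, float]:
    """Per-bin background-to-N1 entry rates (enhancer, promoter).

    rate = n_elements / (genome_bp / bin_width); with the default human
    genome statistics this yields 1.33% and 0.23%.
    """
    n_bins = config.genome_bp / config.bin_width
    e = config.n_enhancers_genome / n_bins
    p = config.n_promoters_genome / n_bins
    if e + p >= 1:
        raise ValueError("entry rates must be < 1")
    return e, p


def _init_model(n_states: int, features, sequences, seed: int) -> ConstrictedHMM:
    """Unconstrained model seeded by k-means on log-counts."""
    all_obs = np.concatenate([np.asarray(s, dtype=np.float64) for s in sequences])
    logs = np.log(all_obs)
    km = KMeans(n_clusters=n_states, n_init=5, random_state=seed).fit(logs)
    mu = np.empty((n_states, len(features)))
    sigma = np.empty_like(mu)
    for i in range(n_states):
        member = logs[km.labels_ == i]
        if member.size == 0:
            member = logs
        mu[i] = member.mean(axis=0)
        sigma[i] = np.maximum(member.std(axis=0), 10 * SIGMA_FLOOR)
    for j in range(logs.shape[1]):
        if np.unique(logs[:, j]).size == 1:
            warnings.warn(f"feature {features[j]!r} is constant in the training data")
    order = np.argsort(mu.sum(axis=1))  # deterministic state order
    emissions = EmissionModel(list(range(n_states)), features, mu[order], sigma[order])
    transmat = np.full((n_states, n_states), 1.0 / n_states)
    mask = np.ones((n_states, n_states), dtype=bool)
    start = np.full(n_states, 1.0 / n_states)
    return ConstrictedHMM(["FG5"] * n_states, start, transmat, mask, emissions)


def _fit_unconstrained(sequences, n_states, features, roles, seed, max_iter, tol):
    seqs = [np.asarray(s, dtype=np.float64) for s in sequences]
    if not seqs:
        raise ValueError("need at least one training region")
    if any(len(s) < n_states for s in seqs):
        raise ValueError(f"every training region must have >= {n_states} bins")
    model = _init_model(n_states, features, seqs, seed)
    model = baum_welch(model, seqs, max_iter=max_iter, tol=tol)
    model.roles = list(roles)
    return model


def fit_foreground_5state(training_regions, features=CANONICAL_FEATURES, seed: int = 0,
                          max_iter: int = 100, tol: float = 1e-4) -> ConstrictedHMM:
    """Fit the unsupervised 5-state HMM to foreground training-region slices.

    ``training_regions`` is a list of pseudo-counted (n_bins, n_features)
    observation matrices, one per region.
    """
    return _fit_unconstrained(training_regions, 5, features, ["FG5"] * 5,
                              seed, max_iter, tol)


def fit_background(background_regions, features=CANONICAL_FEATURES, seed: int = 0,
                   n_states: int = 10, max_iter: int = 100, tol: float = 1e-4) -> ConstrictedHMM:
    """Fit the conventional 10-state background HMM to background slices."""
    return _fit_unconstrained(background_regions, n_states, features,
                              ["BG"] * n_states, seed, max_iter, tol)


def select_states(model5: ConstrictedHMM, kind: str) -> StateSelection:
    """Assign A/N roles to the 5 foreground states from emission patterns.

    Ranks use count-scale log-normal means exp(mu + sigma^2/2): the two
    states with the highest accessibility/H3K27ac ratio become A; among the
    remaining three, the two with the highest (enhancer) or lowest
    (promoter) H3K4me1/H3K4me3 ratio become N; the last state is discarded.
    """
    if kind not in ("enhancer", "promoter"):
        raise ValueError("kind must be 'enhancer' or 'promoter'")
    if model5.n_states != 5:
        raise ValueError("state selection expects a 5-state model")
    feats = model5.features
    means = model5.emissions.means()
    acc = means[:, feats.index("accessibility")]
    k27 = means[:, feats.index("H3K27ac")]
    me1 = means[:, feats.index("H3K4me1")]
    me3 = means[:, feats.index("H3K4me3")]

    a_ratio = acc / k27
    # stable sort descending with ties broken toward the lowest index
    order = np.lexsort((np.arange(5), -a_ratio))
    if a_ratio[order[1]] == a_ratio[order[2]]:
        warnings.warn("accessibility/H3K27ac ratio tie at the A-state boundary")
    a_states = tuple(int(i) for i in sorted(order[:2]))
    rest = np.array(sorted(order[2:]))

    n_ratio = me1[rest] / me3[rest]
    sign = -1.0 if kind == "enhancer" else 1.0  # highest for enhancers, lowest for promoters
    sub = np.lexsort((np.arange(3), sign * n_ratio))
    if n_ratio[sub[1]] == n_ratio[sub[2]]:
        warnings.warn("H3K4me1/H3K4me3 ratio tie at the N-state boundary")
    n_sel = tuple(int(rest[i]) for i in sub[:2])
    discarded = int(rest[sub[2]])
    return StateSelection(a_states, n_sel, discarded)


def _module_roles(kind: str) -> list[str]:
    p = "E" if kind == "enhancer" else "P"
    return [f"{p}_N1", f"{p}_N1", f"{p}_A", f"{p}_A", f"{p}_N2", f"{p}_N2"]


def module_mask(n_groups: int = 3, group_size: int = 2) -> np.ndarray:
    """Directed-module mask: within-group (incl. self) plus one step forward."""
    n = n_groups * group_size
    mask = np.zeros((n, n), dtype=bool)
    for g in range(n_groups):
        lo, hi = g * group_size, (g + 1) * group_size
        mask[lo:hi, lo:hi] = True
        if g + 1 < n_groups:
            mask[lo:hi, hi:hi + group_size] = True
    return mask


def build_foreground_module(model5: ConstrictedHMM, selection: StateSelection,
                            kind: str) -> ConstrictedHMM:
    """Duplicate the N states into N1/N2 and arrange N1 -> A -> N2.

    State order: [N1, N1, A, A, N2, N2].  N2 emissions are exact copies of
    N1 emissions.  Transition rows are initialized from the 5-state fit
    restricted to the directed mask and renormalized; the N2 intra-group
    rows are copied from N1's.
    """
    roles = _module_roles(kind)
    src = list(selection.n_states) + list(selection.a_states) + list(selection.n_states)
    emissions = model5.emissions.subset(src, states=list(range(6)))

    mask = module_mask()
    trans = np.zeros((6, 6))
    t5 = model5.transmat
    for i in range(6):
        for j in range(6):
            if mask[i, j]:
                trans[i, j] = t5[src[i], src[j]]
    # N2 rows: intra-group structure copied from N1's intra-group rows
    trans[4:6, 4:6] = trans[0:2, 0:2]
    rowsum = trans.sum(axis=1, keepdims=True)
    if (rowsum == 0).any():
        raise ValueError("foreground module is mask-disconnected")
    trans /= rowsum

    start = np.zeros(6)
    start[:2] = 0.5  # uniform over N1: training paths begin at the first nucleosome
    return ConstrictedHMM(roles, start, trans, mask, emissions)


def refine_foreground(module: ConstrictedHMM, training_regions,
                      max_iter: int = 50) -> ConstrictedHMM:
    """Viterbi-train the module with frozen emissions: every training region
    is forced to start in an N1 state and end in an N2 state."""
    roles = set(module.roles)
    n1 = {r for r in roles if r.endswith("N1")}
    n2 = {r for r in roles if r.endswith("N2")}
    return viterbi_train(module, training_regions, start_roles=n1,
                         end_roles=n2, max_iter=max_iter)


def _n1_entry_split(module: ConstrictedHMM) -> np.ndarray:
    """Split of the module entry mass over its two N1 states.

    Proportional to the module chain's stationary occupancy of the N1
    states; that chain is absorbing in N2, so when the N1 stationary mass is
    (numerically) zero the split falls back to 50/50.
    """
    pi = stationary_distribution(module.transmat)
    n1 = module.role_indices({r for r in module.roles if r.endswith("N1")})
    w = pi[n1]
    if w.sum() < 1e-12:
        return np.full(n1.size, 1.0 / n1.size)
    return w / w.sum()


def compose(background: ConstrictedHMM, enhancer_module: ConstrictedHMM,
            promoter_module: ConstrictedHMM,
            config: CompositionConfig = CompositionConfig()) -> ConstrictedHMM:
    """Combine background + enhancer + promoter modules into one model.

    State order: 10 BG, 6 enhancer (N1,N1,A,A,N2,N2), 6 promoter.  From
    every BG state a total mass equal to the enhancer (promoter) entry rate
    flows to the module's N1 states; remaining BG mass is rescaled
    uniformly.  Each N2 state's exit mass to BG equals its module's learned
    N1 -> A mass (flanking nucleosomes are expected to be equally sized),
    distributed over BG states by the background stationary distribution;
    N2 intra-group mass is rescaled to keep rows stochastic.  Emission
    parameters of the sub-models are never altered.
    """
    if not (background.features == enhancer_module.features == promoter_module.features):
        raise ValueError("sub-models must share the same feature set")
    rate_e, rate_p = entry_rates(config)
    n_bg = background.n_states
    n = n_bg + 12
    roles = list(background.roles) + list(enhancer_module.roles) + list(promoter_module.roles)

    mu = np.concatenate([background.emissions.mu, enhancer_module.emissions.mu,
                         promoter_module.emissions.mu])
    sigma = np.concatenate([background.emissions.sigma, enhancer_module.emissions.sigma,
                            promoter_module.emissions.sigma])
    emissions = EmissionModel(list(range(n)), background.features, mu, sigma)

    trans = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    e0, p0 = n_bg, n_bg + 6

    # background rows: intra-BG rescaled, entry mass to each module's N1 pair
    trans[:n_bg, :n_bg] = background.transmat * (1.0 - rate_e - rate_p)
    mask[:n_bg, :n_bg] = background.mask
    split_e = _n1_entry_split(enhancer_module)
    split_p = _n1_entry_split(promoter_module)
    trans[:n_bg, e0:e0 + 2] = rate_e * split_e[None, :]
    trans[:n_bg, p0:p0 + 2] = rate_p * split_p[None, :]
    mask[:n_bg, e0:e0 + 2] = True
    mask[:n_bg, p0:p0 + 2] = True

    bg_pi = stationary_distribution(background.transmat)
    for off, module in ((e0, enhancer_module), (p0, promoter_module)):
        trans[off:off + 6, off:off + 6] = module.transmat
        mask[off:off + 6, off:off + 6] = module.mask
        n1_idx = module.role_indices({r for r in module.roles if r.endswith("N1")})
        a_idx = module.role_indices({r for r in module.roles if r.endswith("A")})
        n2_idx = module.role_indices({r for r in module.roles if r.endswith("N2")})
        for k, n2 in enumerate(n2_idx):
            exit_mass = float(module.transmat[n1_idx[k], a_idx].sum())
            exit_mass = min(exit_mass, 1.0 - 1e-9)
            row = off + n2
            intra = trans[row, off + n2_idx[0]:off + n2_idx[-1] + 1]
            intra_sum = intra.sum()
            if intra_sum > 0:
                trans[row, off + n2_idx[0]:off + n2_idx[-1] + 1] = \
                    intra * (1.0 - exit_mass) / intra_sum
            trans[row, :n_bg] = exit_mass * bg_pi
            mask[row, :n_bg] = True

    start = np.zeros(n)
    start[:n_bg] = 1.0 / n_bg
    trans /= trans.sum(axis=1, keepdims=True)
    trans[~mask] = 0.0
    meta = {"bin_width": config.bin_width,
            "entry_rate_enhancer": rate_e, "entry_rate_promoter": rate_p}
    return ConstrictedHMM(roles, start, trans, mask, emissions, meta)


def save_model(model: ConstrictedHMM, path) -> None:
    """Serialize a model to a self-describing JSON file.

    The round trip is bit-exact: floats are written with full repr
    precision and keys are sorted, so save -> load -> save reproduces the
    file byte for byte.
    """
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "roles": list(model.roles),
        "features": list(model.features),
        "startprob": model.startprob.tolist(),
        "transmat": model.transmat.tolist(),
        "mask": model.mask.astype(int).tolist(),
        "emission_mu": model.emissions.mu.tolist(),
        "emission_sigma": model.emissions.sigma.tolist(),
        "metadata": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in model.metadata.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_model(path) -> ConstrictedHMM:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version: "
                         f"{payload.get('format_version')!r}")
    for key in ("roles", "features", "startprob", "transmat", "mask",
                "emission_mu", "emission_sigma"):
        if key not in payload:
            raise ValueError(f"model file missing field {key!r}")
    if not payload["features"]:
        raise ValueError("model file has no feature names")
    roles = payload["roles"]
    emissions = EmissionModel(list(range(len(roles))), tuple(payload["features"]),
                              np.array(payload["emission_mu"]),
                              np.array(payload["emission_sigma"]))
    meta = {k: (np.array(v) if isinstance(v, list) else v)
            for k, v in payload.get("metadata", {}).items()}
    return ConstrictedHMM(roles, np.array(payload["startprob"]),
                          np.array(payload["transmat"]),
                          np.array(payload["mask"], dtype=bool), emissions, meta)
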