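"""Self-contained synthetic data: a known 22-state constricted model, count
tracks sampled from it, and the ground-truth element intervals.

The default truth model encodes the expected chromatin logic of regulatory
elements: enhancer nucleosome states carry high H3K4me1/H3K27ac, promoter
nucleosome states high H3K4me3, accessible-core states high accessibility,
and the ten background states carry low, slightly varied signal.  Counts
are rounded log-normal draws — exactly the emission family the model fits —
so parameter- and element-recovery tests are well specified.  The generator
does not emulate mappability artefacts, copy-number variation, replication
timing or peak-caller noise present in real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .emissions import EmissionModel
from .hmm_core import ConstrictedHMM, StatePath
from .model_builder import CompositionConfig, compose, module_mask
from .predict import PredictionTrack, extract_elements
from .region_sets import BED_COLUMNS, RegionSet, remove_neighbors, write_bed
from .signal_io import (CANONICAL_FEATURES, GenomePartition, SignalMatrix,
                        write_bedgraph)

DEFAULT_BIN_WIDTH = 100
DEFAULT_N_BINS = 1_000_000  # 2 chromosomes x 5e5 bins
DEFAULT_N_CHROMS = 2


@dataclass
class GroundTruth:
    """A simulated genome with its generating model and true elements."""

    model: ConstrictedHMM
    paths: dict[str, StatePath]
    elements: RegionSet
    tracks: SignalMatrix

    @property
    def partition(self) -> GenomePartition:
        return self.tracks.partition


def _background_model(sigma: float) -> ConstrictedHMM:
    """10 background states with low, slightly varied log-mean signal."""
    n = 10
    rngless = np.linspace(0.3, 1.2, n)
    mu = np.empty((n, 4))
    for j in range(4):
        mu[:, j] = np.roll(rngless, 2 * j)
    sig = np.full((n, 4), sigma)
    em = EmissionModel(list(range(n)), CANONICAL_FEATURES, mu, sig)
    trans = np.full((n, n), 0.1 / (n - 1))
    np.fill_diagonal(trans, 0.9)
    start = np.full(n, 1.0 / n)
    return ConstrictedHMM(["BG"] * n, start, trans, np.ones((n, n), bool), em)


def _foreground_module(kind: str, amplitude: float, sigma: float) -> ConstrictedHMM:
    """Directed 6-state module [N1,N1,A,A,N2,N2] with the expected marks.

    ``amplitude`` scales the log-mean contrast of the informative features
    above the ~0.75 background level; the easy setting uses >= 2 log-units,
    the hard setting 0.5.
    """
    base = 0.75
    if kind == "enhancer":
        n_mu = base + amplitude * np.array([0.1, 1.4, 1.4, 0.1])
        a_mu = base + amplitude * np.array([1.6, 1.1, 1.0, 0.1])
    else:
        n_mu = base + amplitude * np.array([0.1, 1.4, 0.1, 1.4])
        a_mu = base + amplitude * np.array([1.6, 1.1, 0.1, 1.2])
    jitter = np.array([0.0, 0.1])  # the two states of a group differ slightly
    mu = np.vstack([n_mu + jitter[0], n_mu + jitter[1],
                    a_mu + jitter[0], a_mu + jitter[1],
                    n_mu + jitter[0], n_mu + jitter[1]])
    sig = np.full((6, 4), sigma)
    roles = [f"{'E' if kind == 'enhancer' else 'P'}_{p}"
             for p in ("N1", "N1", "A", "A", "N2", "N2")]
    em = EmissionModel(list(range(6)), CANONICAL_FEATURES, mu, sig)
    # dwell ~3 bins per group: leave probability 1/3 split over the next pair
    trans = np.zeros((6, 6))
    for g in range(3):
        lo = 2 * g
        trans[lo:lo + 2, lo:lo + 2] = np.array([[0.42, 0.25], [0.25, 0.42]])
        if g < 2:
            trans[lo:lo + 2, lo + 2:lo + 4] = np.array([[0.18, 0.15], [0.18, 0.15]])
    trans[4:6] /= trans[4:6].sum(axis=1, keepdims=True)  # N2 absorbs in-module
    start = np.array([0.5, 0.5, 0, 0, 0, 0.0])
    return ConstrictedHMM(roles, start, trans, module_mask(), em)


def default_truth_model(separation: str = "easy",
                        config: CompositionConfig = CompositionConfig()) -> ConstrictedHMM:
    """The documented 22-state ground-truth model.

    'easy' uses well-separated emission means (>= 2 log-units of contrast on
    the informative features), 'hard' overlapping means (<= 0.5 log-units).
    Entry rates follow the genome-scale element counts in ``config``.
    """
    if separation == "easy":
        amplitude, sigma = 1.45, 0.5
    elif separation == "hard":
        amplitude, sigma = 0.33, 0.8
    else:
        raise ValueError("separation must be 'easy' or 'hard'")
    bg = _background_model(sigma=0.6)
    enh = _foreground_module("enhancer", amplitude, sigma)
    pro = _foreground_module("promoter", amplitude, sigma)
    return compose(bg, enh, pro, config)


def _truth_track(model: ConstrictedHMM, partition: GenomePartition,
                 paths: dict[str, StatePath]) -> PredictionTrack:
    roles = list(model.roles)
    e_a = set(model.role_indices("E_A"))
    p_a = set(model.role_indices("P_A"))
    e_sc = {c: np.isin(p.states, list(e_a)).astype(float) for c, p in paths.items()}
    p_sc = {c: np.isin(p.states, list(p_a)).astype(float) for c, p in paths.items()}
    return PredictionTrack(partition, roles, {c: p.states for c, p in paths.items()},
                           e_sc, p_sc)


def elements_from_paths(model: ConstrictedHMM, partition: GenomePartition,
                        paths: dict[str, StatePath]) -> RegionSet:
    """True element intervals, extracted from the state path exactly as
    prediction extracts them from a decoded path."""
    els = extract_elements(_truth_track(model, partition, paths))
    rows = [(e.chrom, e.start, e.end, e.kind, 0.0) for e in els]
    return RegionSet(pd.DataFrame(rows, columns=BED_COLUMNS))


def simulate(model: ConstrictedHMM, n_bins: int = DEFAULT_N_BINS, seed: int = 0,
             n_chroms: int = DEFAULT_N_CHROMS,
             bin_width: int = DEFAULT_BIN_WIDTH) -> GroundTruth:
    """Sample a state path and integer count tracks from ``model``.

    ``n_bins`` total bins are split evenly over ``n_chroms`` chromosomes
    (chrS1, chrS2, ...).  Per bin and feature,
    count = round(exp(Normal(mu, sigma))) clamped at 0.  Deterministic for a
    given seed.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    per = [n_bins // n_chroms] * n_chroms
    per[-1] += n_bins - sum(per)
    sizes = {f"chrS{i + 1}": per[i] * bin_width for i in range(n_chroms)}
    partition = GenomePartition(sizes, bin_width)

    init_cum = np.cumsum(model.startprob)
    trans_cum = np.cumsum(model.transmat, axis=1)
    mu, sigma = model.emissions.mu, model.emissions.sigma

    paths, tracks = {}, {}
    for chrom, t in zip(partition.chroms, per):
        states = _kernels.sample_path(init_cum, trans_cum, rng.random(t))
        z = rng.standard_normal((t, mu.shape[1]))
        counts = np.rint(np.exp(mu[states] + sigma[states] * z))
        tracks[chrom] = np.maximum(counts, 0).astype(np.int64)
        with np.errstate(divide="ignore"):
            logp = (np.log(model.startprob[states[0]])
                    + np.log(model.transmat[states[:-1], states[1:]]).sum())
        paths[chrom] = StatePath(states, float(logp))

    matrix = SignalMatrix(partition, CANONICAL_FEATURES, tracks)
    elements = elements_from_paths(model, partition, paths)
    return GroundTruth(model, paths, elements, matrix)


def sample_training_regions(truth: GroundTruth, kind: str, n: int = 300,
                            seed: int = 0, min_distance: int = 2000,
                            chroms=None, min_width_bp: int = 500) -> RegionSet:
    """Sample isolated truth elements of one kind as training regions,
    mirroring the 2 kb neighbor-isolation rule of the real training-set
    protocol.  Elements narrower than ``min_width_bp`` are skipped (the
    foreground fit needs several bins per region; real anchored training
    regions are ~2 kb)."""
    df = truth.elements.df
    df = df[(df["label"] == kind) & (df["end"] - df["start"] >= min_width_bp)]
    if chroms is not None:
        df = df[df["chrom"].isin(list(chroms))]
    isolated = remove_neighbors(RegionSet(df), min_distance)
    rng = np.random.default_rng(seed)
    k = min(n, len(isolated))
    idx = np.sort(rng.choice(len(isolated), size=k, replace=False))
    return RegionSet(isolated.df.iloc[idx])


def sample_background_regions(truth: GroundTruth, n: int = 300, seed: int = 0,
                              region_bp: int = 2000, chroms=None,
                              enhancer_frac: float = 0.0,
                              promoter_frac: float = 0.0) -> RegionSet:
    """Sample 2 kb background training windows.

    Mirrors the background-set protocol: windows overlapping annotated
    enhancers or active promoters are excluded and their quota slots
    refilled from ordinary territory, so by default every window is
    element-free.  Nonzero ``enhancer_frac`` / ``promoter_frac`` instead
    plant that share of windows on true elements (used for building mixed
    evaluation sets, not for training)."""
    rng = np.random.default_rng(seed)
    partition = truth.partition
    chroms = list(chroms) if chroms is not None else list(partition.chroms)
    n_enh = round(n * enhancer_frac)
    n_pro = round(n * promoter_frac)
    n_free = n - n_enh - n_pro

    df = truth.elements.df[truth.elements.df["chrom"].isin(chroms)]
    rows = []
    for label, count in (("enhancer", n_enh), ("promoter", n_pro)):
        sub = df[df["label"] == label]
        if len(sub) == 0:
            n_free += count
            continue
        pick = rng.choice(len(sub), size=min(count, len(sub)), replace=False)
        for r in sub.iloc[np.sort(pick)].itertuples(index=False):
            center = (r.start + r.end) // 2
            start = max(center - region_bp // 2, 0)
            rows.append((r.chrom, start, start + region_bp, "background", 0.0))

    element_idx = {c: df[df["chrom"] == c][["start", "end"]].to_numpy()
                   for c in chroms}
    tries = 0
    while n_free > 0 and tries < 100000:
        tries += 1
        chrom = chroms[rng.integers(len(chroms))]
        size = partition.chrom_sizes[chrom]
        start = int(rng.integers(0, max(size - region_bp, 1)))
        iv = element_idx[chrom]
        if len(iv) and ((iv[:, 0] < start + region_bp) & (iv[:, 1] > start)).any():
            continue
        rows.append((chrom, start, start + region_bp, "background", 0.0))
        n_free -= 1
    return RegionSet(pd.DataFrame(rows, columns=BED_COLUMNS)).sort()


def region_observations(signals: SignalMatrix, regions: RegionSet) -> list[np.ndarray]:
    """Pseudo-counted observation slices, one (n_bins, n_features) matrix
    per region."""
    out = []
    pc = float(signals.pseudocount)
    for r in regions:
        out.append(signals.slice(r.chrom, r.start, r.end).astype(np.float64) + pc)
    return out


def export_fixture(truth: GroundTruth, directory, n_training: int = 300,
                   seed: int = 0) -> dict[str, str]:
    """Write a complete text fixture: per-feature bedGraphs, chrom sizes,
    truth BED and training-region BEDs consumable by the train CLI."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for j, feat in enumerate(truth.tracks.features):
        track = {c: truth.tracks.counts[c][:, j] for c in truth.partition.chroms}
        p = directory / f"{feat}.bedgraph"
        write_bedgraph(track, truth.partition, p)
        paths[feat] = str(p)
    p = directory / "chrom.sizes"
    with open(p, "w") as fh:
        for chrom, size in truth.partition.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    paths["chrom_sizes"] = str(p)
    p = directory / "truth_elements.bed"
    write_bed(truth.elements, p)
    paths["truth"] = str(p)
    for kind in ("enhancer", "promoter"):
        regions = sample_training_regions(truth, kind, n_training, seed)
        p = directory / f"training_{kind}s.bed"
        write_bed(regions, p)
        paths[kind] = str(p)
    bg = sample_background_regions(truth, n_training, seed)
    p = directory / "training_background.bed"
    write_bed(bg, p)
    paths["background"] = str(p)
    return paths
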