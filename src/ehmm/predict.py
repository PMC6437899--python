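"""Genome-wide application of a trained model: Viterbi segmentation and
posterior accessibility scoring.

Viterbi decoding returns the globally most likely path, which yields a
definite set of predicted elements without any score threshold and — unlike
posterior decoding — cannot violate the model grammar.  The per-bin sum of
posteriors over accessible-chromatin states serves as a local certainty
score, peaking at element centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hmm_core import ConstrictedHMM, forward_backward, viterbi
from .signal_io import GenomePartition, SignalMatrix, write_bedgraph


@dataclass
class PredictionTrack:
    """Per-bin decoded roles and posterior accessibility scores."""

    partition: GenomePartition
    roles: list[str]                      # model role per state index
    state_path: dict[str, np.ndarray]     # chrom -> per-bin state indices
    enhancer_score: dict[str, np.ndarray]  # chrom -> per-bin sum of E_A posteriors
    promoter_score: dict[str, np.ndarray]  # chrom -> per-bin sum of P_A posteriors

    def role_path(self, chrom: str) -> np.ndarray:
        lookup = np.array(self.roles)
        return lookup[self.state_path[chrom]]


@dataclass
class PredictedElement:
    """One predicted enhancer or promoter with its N1/A/N2 substructure."""

    chrom: str
    start: int
    end: int
    kind: str                      # 'enhancer' | 'promoter'
    score: float                   # max per-bin accessibility posterior inside
    substructure: list[tuple[str, int, int]]  # (part, start, end) tiling N1,A,N2


def segment_genome(model: ConstrictedHMM, signals: SignalMatrix) -> PredictionTrack:
    """Viterbi-decode and posterior-score every chromosome independently."""
    if tuple(signals.features) != tuple(model.features):
        raise ValueError(
            f"signal features {signals.features} do not match model "
            f"features {model.features}")
    e_a = model.role_indices("E_A")
    p_a = model.role_indices("P_A")
    paths, e_scores, p_scores = {}, {}, {}
    for chrom in signals.partition.chroms:
        obs = signals.pseudo_counts(chrom)
        paths[chrom] = viterbi(model, obs).states
        post = forward_backward(model, obs)
        gamma = post.gamma[0]
        e_scores[chrom] = np.clip(gamma[:, e_a].sum(axis=1), 0.0, 1.0)
        p_scores[chrom] = np.clip(gamma[:, p_a].sum(axis=1), 0.0, 1.0)
    return PredictionTrack(signals.partition, list(model.roles), paths,
                           e_scores, p_scores)


def _runs(values: np.ndarray):
    """Yield (value, start_index, end_index) for maximal constant runs."""
    if len(values) == 0:
        return
    change = np.flatnonzero(values[1:] != values[:-1]) + 1
    bounds = np.concatenate([[0], change, [len(values)]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        yield values[a], int(a), int(b)


def extract_elements(track: PredictionTrack,
                     partition: GenomePartition | None = None) -> list[PredictedElement]:
    """Turn maximal runs of enhancer (promoter) roles into elements.

    Element score is the maximum per-bin accessibility posterior of its own
    module inside the element; the substructure records the N1/A/N2
    sub-runs in order.
    """
    partition = partition or track.partition
    bw = partition.bin_width
    elements = []
    for chrom in partition.chroms:
        roles = track.role_path(chrom)
        module = np.array([r[0] if r[0] in "EP" else "B" for r in roles])
        for mod, a, b in _runs(module):
            if mod == "B":
                continue
            kind = "enhancer" if mod == "E" else "promoter"
            scores = (track.enhancer_score if kind == "enhancer"
                      else track.promoter_score)[chrom][a:b]
            subs = []
            part_codes = np.array([r.split("_", 1)[1] for r in roles[a:b]])
            for part, i, j in _runs(part_codes):
                subs.append((str(part), (a + i) * bw,
                             min((a + j) * bw, partition.chrom_sizes[chrom])))
            elements.append(PredictedElement(
                chrom, a * bw, min(b * bw, partition.chrom_sizes[chrom]),
                kind, float(scores.max()), subs))
    return elements


def write_predictions(elements: list[PredictedElement], path) -> None:
    """Write elements as BED6 (score column = round(1000 * posterior))."""
    with open(path, "w") as fh:
        for el in elements:
            fh.write(f"{el.chrom}\t{el.start}\t{el.end}\t{el.kind}\t"
                     f"{round(1000 * el.score)}\t.\n")


def write_scores(track: PredictionTrack, path, kind: str = "enhancer") -> None:
    """Write the per-bin accessibility posterior as a bedGraph."""
    scores = track.enhancer_score if kind == "enhancer" else track.promoter_score
    write_bedgraph(scores, track.partition, path)
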