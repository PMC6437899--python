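"""Validation metrics: precision-recall over scored test regions, the
Viterbi operating point, distance-to-feature distributions and TSS overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve

from .predict import PredictedElement, PredictionTrack
from .region_sets import RegionSet


@dataclass
class PRCurve:
    """A precision-recall curve with its step-wise area (average precision)."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auprc: float


def score_test_regions(track: PredictionTrack, test: RegionSet,
                       kind: str = "enhancer") -> np.ndarray:
    """Per-region score: max per-bin accessibility posterior over the
    region's bins."""
    scores = track.enhancer_score if kind == "enhancer" else track.promoter_score
    bw = track.partition.bin_width
    out = np.empty(len(test))
    for i, r in enumerate(test):
        if r.chrom not in scores:
            raise ValueError(f"region on chromosome {r.chrom!r} is off the partition")
        b0, b1 = r.start // bw, -(-r.end // bw)
        vals = scores[r.chrom][b0:b1]
        if vals.size == 0:
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} overlaps no bins")
        out[i] = vals.max()
    return out


def pr_curve(scores, labels) -> PRCurve:
    """Precision/recall at every distinct score threshold; area by the
    step-wise (average-precision) estimator, so results are reproducible
    bit-exactly across runs."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    auprc = float(average_precision_score(labels, scores))
    return PRCurve(thresholds, precision, recall, auprc)


class _OverlapIndex:
    """Sorted-interval index answering 'overlaps by >= min_overlap bp?'."""

    def __init__(self, intervals_by_chrom: dict[str, np.ndarray]):
        self.index = {}
        for chrom, iv in intervals_by_chrom.items():
            if len(iv) == 0:
                continue
            order = np.argsort(iv[:, 0], kind="mergesort")
            starts = iv[order, 0].astype(np.int64)
            ends = iv[order, 1].astype(np.int64)
            # prefix max of ends lets a single searchsorted decide overlap
            self.index[chrom] = (starts, np.maximum.accumulate(ends))

    @classmethod
    def from_regions(cls, regions: RegionSet) -> "_OverlapIndex":
        return cls({c: regions.intervals(c) for c in regions.df["chrom"].unique()})

    @classmethod
    def from_elements(cls, elements) -> "_OverlapIndex":
        by_chrom: dict[str, list] = {}
        for el in elements:
            by_chrom.setdefault(el.chrom, []).append((el.start, el.end))
        return cls({c: np.array(v) for c, v in by_chrom.items()})

    def overlaps(self, chrom: str, start: int, end: int, min_overlap: int = 1) -> bool:
        if chrom not in self.index:
            return False
        starts, maxends = self.index[chrom]
        i = int(np.searchsorted(starts, end - min_overlap, side="right"))
        return i > 0 and maxends[i - 1] >= start + min_overlap


def viterbi_point(elements: list[PredictedElement], test: RegionSet,
                  kind: str = "enhancer", min_overlap: int = 1) -> tuple[float, float]:
    """Precision and recall of the hard Viterbi calls against test regions.

    A test positive is recalled if overlapped (>= min_overlap bp) by a
    predicted element of the right kind; precision is the fraction of such
    predictions overlapping a test positive among those overlapping any
    test region.  With no qualifying predictions, precision is reported as
    0 with a warning.
    """
    preds = [e for e in elements if e.kind == kind]
    pos = RegionSet(test.df[test.df["label"] == "test_pos"])
    pred_idx = _OverlapIndex.from_elements(preds)
    recalled = sum(pred_idx.overlaps(r.chrom, r.start, r.end, min_overlap) for r in pos)
    recall = recalled / len(pos) if len(pos) else 0.0

    any_idx = _OverlapIndex.from_regions(test)
    pos_idx = _OverlapIndex.from_regions(pos)
    n_hit = n_scored = 0
    for p in preds:
        if not any_idx.overlaps(p.chrom, p.start, p.end, min_overlap):
            continue
        n_scored += 1
        if pos_idx.overlaps(p.chrom, p.start, p.end, min_overlap):
            n_hit += 1
    if n_scored == 0:
        warnings.warn("no predictions overlap any test region; precision undefined, "
                      "reported as 0")
        return 0.0, recall
    return n_hit / n_scored, recall


def distance_to_features(elements: list[PredictedElement],
                         features: RegionSet) -> np.ndarray:
    """Center-to-center distance (bp) from each element to its nearest feature."""
    if len(features) == 0:
        raise ValueError("features must be non-empty")
    centers = {}
    for chrom in features.df["chrom"].unique():
        iv = features.intervals(chrom)
        centers[chrom] = np.sort((iv[:, 0] + iv[:, 1]) / 2.0)
    out = np.empty(len(elements))
    for i, el in enumerate(elements):
        c = (el.start + el.end) / 2.0
        pos = centers.get(el.chrom)
        if pos is None or len(pos) == 0:
            out[i] = np.inf
            continue
        j = np.searchsorted(pos, c)
        cand = pos[max(j - 1, 0):j + 1]
        out[i] = np.abs(cand - c).min()
    return out


def distance_summary(distances: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(distances[np.isfinite(distances)], [25, 50, 75])
    return {"median": float(med), "iqr": float(q3 - q1)}


def tss_overlap_fraction(elements: list[PredictedElement], tss: RegionSet) -> float:
    """Fraction of elements whose interval contains a TSS position (TSS
    taken as the 1-bp midpoint of each annotation record)."""
    if not elements:
        warnings.warn("no predicted elements; TSS overlap fraction is 0")
        return 0.0
    pos = {}
    for chrom in tss.df["chrom"].unique():
        iv = tss.intervals(chrom)
        pos[chrom] = (iv[:, 0] + iv[:, 1]) // 2
    hit = sum(
        1 for el in elements
        if el.chrom in pos and (((pos[el.chrom] >= el.start)
                                 & (pos[el.chrom] < el.end)).any())
    )
    return hit / len(elements)
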