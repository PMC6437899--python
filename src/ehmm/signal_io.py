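"""Binned multi-feature coverage: read binning, pseudo-counting, quantile normalization.

The model consumes integer read counts in fixed-width genomic bins (default
100 bp) for four features in canonical order: chromatin accessibility
(ATAC-seq or DNase-seq), H3K27ac, H3K4me1 and H3K4me3.  ChIP-seq reads are
shifted by 75 bp toward the fragment center before binning (expected fragment
length 150 bp); accessibility reads are binned at the cut site (shift 0).
A pseudocount of 1 keeps all logarithms finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CANONICAL_FEATURES = ("accessibility", "H3K27ac", "H3K4me1", "H3K4me3")
DEFAULT_SHIFTS = {"accessibility": 0, "H3K27ac": 75, "H3K4me1": 75, "H3K4me3": 75}


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column (name, length) chromosome sizes file."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


@dataclass(frozen=True)
class GenomePartition:
    """Tiling of a genome into fixed-width, 0-based half-open bins.

    Each chromosome of length L yields ceil(L / bin_width) bins laid left to
    right; the last bin may be truncated by the chromosome end.
    """

    chrom_sizes: dict[str, int]
    bin_width: int = 100

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self.chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.bin_width)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_sizes)

    def bin_index(self, chrom: str, pos: int) -> int:
        """Bin containing position `pos`, clipped to the chromosome's bins."""
        idx = pos // self.bin_width
        return min(max(idx, 0), self.n_bins(chrom) - 1)

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_width

    def bin_ends(self, chrom: str) -> np.ndarray:
        ends = self.bin_starts(chrom) + self.bin_width
        return np.minimum(ends, self.chrom_sizes[chrom])


@dataclass
class SignalMatrix:
    """Per-bin, per-feature non-negative integer counts over a partition.

    ``counts`` maps chromosome -> (n_bins, n_features) integer array with
    features in the order given by ``features``.
    """

    partition: GenomePartition
    features: tuple[str, ...]
    counts: dict[str, np.ndarray]
    pseudocount: int = 1
    shift_bp: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SHIFTS))

    def __post_init__(self):
        self.features = tuple(self.features)
        for chrom, arr in self.counts.items():
            expect = (self.partition.n_bins(chrom), len(self.features))
            if arr.shape != expect:
                raise ValueError(
                    f"counts for {chrom!r} have shape {arr.shape}, expected {expect}"
                )
            if (arr < 0).any():
                raise ValueError("counts must be non-negative")
        if self.pseudocount < 1:
            raise ValueError("pseudocount must be >= 1")

    @classmethod
    def from_tracks(cls, partition, tracks: dict[str, dict[str, np.ndarray]],
                    pseudocount: int = 1, shift_bp=None) -> "SignalMatrix":
        """Build from per-feature per-chromosome 1-D count tracks."""
        features = tuple(tracks)
        counts = {}
        for chrom in partition.chroms:
            cols = [np.asarray(tracks[f][chrom], dtype=np.int64) for f in features]
            counts[chrom] = np.stack(cols, axis=1)
        kw = {} if shift_bp is None else {"shift_bp": dict(shift_bp)}
        return cls(partition, features, counts, pseudocount, **kw)

    def pseudo_counts(self, chrom: str) -> np.ndarray:
        """Counts plus pseudocount (all values >= 1); dtype float64."""
        return self.counts[chrom].astype(np.float64) + self.pseudocount

    def log_counts(self, chrom: str) -> np.ndarray:
        return np.log(self.pseudo_counts(chrom))

    def feature_column(self, feature: str) -> np.ndarray:
        """Genome-wide 1-D concatenated counts for one feature."""
        j = self.features.index(feature)
        return np.concatenate([self.counts[c][:, j] for c in self.partition.chroms])

    def slice(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Raw counts for bins overlapping [start, end)."""
        b0 = start // self.partition.bin_width
        b1 = -(-end // self.partition.bin_width)
        return self.counts[chrom][b0:b1]

    def subset_chroms(self, chroms) -> "SignalMatrix":
        chroms = list(chroms)
        part = GenomePartition({c: self.partition.chrom_sizes[c] for c in chroms},
                               self.partition.bin_width)
        return SignalMatrix(part, self.features,
                            {c: self.counts[c].copy() for c in chroms},
                            self.pseudocount, dict(self.shift_bp))

    def normalize_to_reference(self, reference_quantiles: dict[str, np.ndarray]) -> "SignalMatrix":
        """Quantile-normalize each feature to stored reference quantiles.

        Values are mapped rank-wise onto the reference distribution and
        rounded back to non-negative integers so downstream code sees the
        same integer count type.
        """
        new_counts = {c: arr.copy() for c, arr in self.counts.items()}
        for j, feat in enumerate(self.features):
            query = np.concatenate([self.counts[c][:, j] for c in self.partition.chroms])
            mapped = quantile_normalize(query, reference_quantiles[feat])
            mapped = np.maximum(np.rint(mapped), 0).astype(np.int64)
            off = 0
            for c in self.partition.chroms:
                n = self.partition.n_bins(c)
                new_counts[c][:, j] = mapped[off:off + n]
                off += n
        return SignalMatrix(self.partition, self.features, new_counts,
                            self.pseudocount, dict(self.shift_bp))

    def reference_quantiles(self) -> dict[str, np.ndarray]:
        """Sorted genome-wide count values per feature (the reference side
        of cross-sample quantile normalization)."""
        return {f: np.sort(self.feature_column(f)) for f in self.features}


@dataclass(frozen=True)
class QuantileMap:
    """The order-preserving rank mapping behind quantile normalization:
    sorted query values and the reference quantiles they map to."""

    query_quantiles: np.ndarray
    reference_quantiles: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.query_quantiles, dtype=np.float64)
        r = np.asarray(self.reference_quantiles, dtype=np.float64)
        if q.shape != r.shape or q.ndim != 1:
            raise ValueError("quantile sequences must be 1-D and equal length")
        if (np.diff(q) < 0).any() or (np.diff(r) < 0).any():
            raise ValueError("quantile sequences must be sorted (monotone mapping)")
        object.__setattr__(self, "query_quantiles", q)
        object.__setattr__(self, "reference_quantiles", r)

    @classmethod
    def from_data(cls, query, reference) -> "QuantileMap":
        query = np.asarray(query, dtype=np.float64)
        mapped = quantile_normalize(query, reference)
        order = np.argsort(query, kind="mergesort")
        return cls(query[order], mapped[order])

    def apply(self, values) -> np.ndarray:
        return np.interp(np.asarray(values, dtype=np.float64),
                         self.query_quantiles, self.reference_quantiles)


def bin_reads(alignments, partition: GenomePartition, shift_bp: int = 75) -> dict[str, np.ndarray]:
    """Count shifted read 5' positions into the partition's bins.

    Each read contributes 1 to the bin containing its strand-aware shifted
    5' position (+shift on the forward strand, -shift on the reverse strand,
    estimating the fragment center).  Positions shifted off the chromosome
    are clipped to the terminal bin.  Reads on chromosomes absent from the
    partition are skipped with a warning.

    Parameters
    ----------
    alignments : pysam.AlignmentFile or path to a SAM/BAM file.
    """
    import pysam

    own = False
    if not hasattr(alignments, "fetch"):
        alignments = pysam.AlignmentFile(str(alignments))
        own = True
    counts = {c: np.zeros(partition.n_bins(c), dtype=np.int64) for c in partition.chroms}
    skipped = set()
    try:
        for read in alignments:
            if read.is_unmapped:
                continue
            chrom = read.reference_name
            if chrom not in counts:
                skipped.add(chrom)
                continue
            if read.is_reverse:
                pos = read.reference_end - 1 - shift_bp
            else:
                pos = read.reference_start + shift_bp
            counts[chrom][partition.bin_index(chrom, pos)] += 1
    finally:
        if own:
            alignments.close()
    if skipped:
        warnings.warn(f"skipped reads on unknown chromosomes: {sorted(skipped)}")
    return counts


def load_binned(path, partition: GenomePartition) -> dict[str, np.ndarray]:
    """Load a bedGraph / tabular bins file (chrom start end value) onto the
    partition.  Interval values are distributed over overlapping bins
    proportionally to overlap length, then rounded to nearest integer."""
    acc = {c: np.zeros(partition.n_bins(c), dtype=np.float64) for c in partition.chroms}
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    skipped = set()
    bw = partition.bin_width
    for chrom, start, end, value in df.itertuples(index=False):
        chrom = str(chrom)
        if chrom not in acc:
            skipped.add(chrom)
            continue
        start, end = int(start), int(end)
        length = end - start
        if length <= 0:
            continue
        track = acc[chrom]
        b0, b1 = start // bw, -(-end // bw)
        for b in range(b0, min(b1, len(track))):
            ov = min(end, (b + 1) * bw) - max(start, b * bw)
            track[b] += float(value) * ov / length
    if skipped:
        warnings.warn(f"skipped intervals on unknown chromosomes: {sorted(skipped)}")
    return {c: np.rint(v).astype(np.int64) for c, v in acc.items()}


def write_bedgraph(track: dict[str, np.ndarray], partition: GenomePartition, path) -> None:
    """Write one per-bin track as a 4-column bedGraph (one record per bin)."""
    with open(path, "w") as fh:
        for chrom in partition.chroms:
            starts = partition.bin_starts(chrom)
            ends = partition.bin_ends(chrom)
            for s, e, v in zip(starts, ends, track[chrom]):
                fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def apply_pseudocount_log(counts: np.ndarray, pseudocount: int = 1) -> np.ndarray:
    """Natural log of (count + pseudocount); finite for all counts >= 0."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return np.log(counts + float(pseudocount))


def quantile_normalize(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Map query values rank-wise onto the reference distribution.

    The i-th smallest query value becomes the reference quantile at plotting
    position i/(n_query - 1), linearly interpolated when the lengths differ.
    Tied query values all receive the mean of the reference quantiles their
    rank range spans, so the mapping is monotone non-decreasing.
    """
    query = np.asarray(query, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if reference.size == 0:
        raise ValueError("reference must be non-empty")
    if query.size == 0:
        raise ValueError("query must be non-empty")
    ref_sorted = np.sort(reference)
    n = query.size
    if n == 1:
        pos = np.array([0.5])
    else:
        pos = np.arange(n) / (n - 1)
    ref_pos = (np.arange(ref_sorted.size) / max(ref_sorted.size - 1, 1)
               if ref_sorted.size > 1 else np.array([0.0]))
    mapped_sorted = np.interp(pos, ref_pos, ref_sorted)

    order = np.argsort(query, kind="mergesort")
    out = np.empty(n, dtype=np.float64)
    out[order] = mapped_sorted
    # average over tie groups so equal inputs map to equal outputs
    qs = query[order]
    boundaries = np.flatnonzero(np.diff(qs) != 0) + 1
    groups = np.split(order, boundaries)
    for g in groups:
        if g.size > 1:
            out[g] = out[g].mean()
    return out
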