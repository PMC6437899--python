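"""Training- and test-region construction from CAGE regions, peak calls and
gene annotation.

Enhancer training sets start from bidirectionally transcribed CAGE regions
(tag-count thresholded), are narrowed by k-means to the cluster with the
strongest active-enhancer chromatin signature, anchored to
H3K27ac - ATAC - H3K27ac peak triplets under 2 kb so regions start and end
at nucleosome positions, and stripped of neighbors closer than 2 kb.  The
background set samples 2 kb regions at rough mammalian genome proportions
(10% enhancers, 5% active promoters, 5% inactive promoters, 10% genic,
70% intergenic), excluding known enhancers and active promoters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

BED_COLUMNS = ["chrom", "start", "end", "label", "score"]
VALID_LABELS = {"enhancer", "promoter", "background", "test_pos", "test_neg"}


@dataclass
class RegionSet:
    """Labelled genomic intervals, 0-based half-open, BED-conventioned."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=BED_COLUMNS))

    def __post_init__(self):
        df = self.df.copy()
        for col in BED_COLUMNS:
            if col not in df.columns:
                df[col] = "." if col == "label" else 0.0
        df = df[BED_COLUMNS].reset_index(drop=True)
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["score"] = df["score"].astype(np.float64)
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("regions must satisfy start < end")
        if len(df) and df["score"].isna().any():
            raise ValueError("scores must not be NaN")
        self.df = df

    def __len__(self):
        return len(self.df)

    def __iter__(self):
        return self.df.itertuples(index=False)

    def sort(self) -> "RegionSet":
        return RegionSet(self.df.sort_values(["chrom", "start", "end"], kind="mergesort"))

    def relabel(self, label: str) -> "RegionSet":
        df = self.df.copy()
        df["label"] = label
        return RegionSet(df)

    def intervals(self, chrom: str) -> np.ndarray:
        sub = self.df[self.df["chrom"] == chrom]
        return sub[["start", "end"]].to_numpy(dtype=np.int64)

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        iv = self.intervals(chrom)
        return bool(len(iv)) and bool(((iv[:, 0] < end) & (iv[:, 1] > start)).any())


def read_bed(path, label: str | None = None) -> RegionSet:
    """Read a 3-6 column BED; column 4 as label (unless overridden), column 5
    as score (tag counts / peak scores)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return RegionSet()
    df = df.iloc[:, :5]
    df.columns = BED_COLUMNS[: df.shape[1]]
    if label is not None:
        df["label"] = label
    return RegionSet(df)


def write_bed(regions: RegionSet, path) -> None:
    df = regions.df.copy()
    df["score"] = df["score"].map(lambda s: int(s) if float(s).is_integer() else s)
    df.to_csv(path, sep="\t", header=False, index=False)


def filter_cage(cage_regions: RegionSet, min_tags: int) -> RegionSet:
    """Keep CAGE regions with at least ``min_tags`` tags (score column)."""
    return RegionSet(cage_regions.df[cage_regions.df["score"] >= min_tags])


def region_feature_summary(regions: RegionSet, signals) -> np.ndarray:
    """Per-region mean log signal per feature over the region's bins."""
    out = np.empty((len(regions), len(signals.features)))
    pc = float(signals.pseudocount)
    for i, r in enumerate(regions):
        sl = signals.slice(r.chrom, r.start, r.end)
        if sl.size == 0:
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} overlaps no bins")
        out[i] = np.log(sl + pc).mean(axis=0)
    return out


def select_active_cluster(regions: RegionSet, signals, k: int = 5,
                          seed: int = 0) -> RegionSet:
    """k-means the regions' chromatin signals and return the cluster with the
    strongest active-enhancer signature.

    Activity score per cluster: mean z(accessibility) + mean z(H3K27ac)
    + mean z(H3K4me1) - mean z(H3K4me3), z-scored across regions; the
    discarded clusters correspond to promoter-like, poised, or
    signal-depleted patterns.
    """
    if len(regions) < k:
        raise ValueError(f"need at least k={k} regions")
    X = region_feature_summary(regions, signals)
    sd = X.std(axis=0)
    if (sd == 0).all():
        warnings.warn("all regions have identical signal; returning all of them")
        return regions
    z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    labels = KMeans(n_clusters=k, n_init=5, random_state=seed).fit_predict(X)
    feats = list(signals.features)
    sign = np.array([{"accessibility": 1, "H3K27ac": 1, "H3K4me1": 1,
                      "H3K4me3": -1}[f] for f in feats])
    activity = z @ sign
    scores = [activity[labels == c].mean() if (labels == c).any() else -np.inf
              for c in range(k)]
    best = int(np.argmax(scores))
    return RegionSet(regions.df[labels == best])


def match_peak_triplets(candidates: RegionSet, h3k27ac_peaks: RegionSet,
                        atac_peaks: RegionSet, max_width: int = 2000) -> RegionSet:
    """Anchor candidates to H3K27ac - ATAC - H3K27ac peak triplets < max_width.

    For each candidate, an overlapping ATAC peak is sought with the nearest
    H3K27ac peak center on each side of the ATAC peak center; the triplet
    span (leftmost start to rightmost end) must be under ``max_width`` and
    becomes the output interval.  Candidates without a qualifying triplet
    are dropped.  Among several qualifying triplets the narrowest span wins.
    """
    rows = []
    for cand in candidates:
        k27 = h3k27ac_peaks.intervals(cand.chrom)
        atac = atac_peaks.intervals(cand.chrom)
        best = None
        for a_start, a_end in atac:
            if a_start >= cand.end or a_end <= cand.start:
                continue
            a_center = (a_start + a_end) / 2
            centers = (k27[:, 0] + k27[:, 1]) / 2 if len(k27) else np.empty(0)
            left = np.flatnonzero(centers < a_center)
            right = np.flatnonzero(centers > a_center)
            if left.size == 0 or right.size == 0:
                continue
            li = left[np.argmax(centers[left])]
            ri = right[np.argmin(centers[right])]
            span_start = min(k27[li, 0], a_start)
            span_end = max(k27[ri, 1], a_end)
            width = span_end - span_start
            if width < max_width and (best is None or width < best[2]):
                best = (span_start, span_end, width)
        if best is not None:
            rows.append((cand.chrom, best[0], best[1], cand.label, cand.score))
    return RegionSet(pd.DataFrame(rows, columns=BED_COLUMNS))


def remove_neighbors(regions: RegionSet, min_distance: int = 2000) -> RegionSet:
    """Drop *both* members of every pair of regions with an edge-to-edge gap
    below ``min_distance``, keeping only isolated elements (the model
    assumes flanking background on both sides)."""
    df = regions.sort().df
    keep = np.ones(len(df), dtype=bool)
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    for i in range(len(df) - 1):
        if chroms[i] == chroms[i + 1] and starts[i + 1] - ends[i] < min_distance:
            keep[i] = keep[i + 1] = False
    return RegionSet(df[keep])


@dataclass(frozen=True)
class BackgroundProportions:
    """Rough proportions of functional elements in mammalian genomes."""

    enhancer: float = 0.10
    active_promoter: float = 0.05
    inactive_promoter: float = 0.05
    genic: float = 0.10
    intergenic: float = 0.70

    def __post_init__(self):
        total = (self.enhancer + self.active_promoter + self.inactive_promoter
                 + self.genic + self.intergenic)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


def _sample_in_intervals(rng, intervals, n, region_bp, exclusions, max_tries=10000):
    """Uniformly sample n regions of region_bp within the given territory,
    rejecting overlaps with any exclusion RegionSet."""
    usable = [(c, s, e) for c, s, e in intervals if e - s >= region_bp]
    if not usable:
        raise ValueError("category has no territory wide enough to sample from")
    lengths = np.array([e - s - region_bp + 1 for _, s, e in usable], dtype=float)
    probs = lengths / lengths.sum()
    out = []
    tries = 0
    while len(out) < n:
        if tries > max_tries:
            raise ValueError("could not sample enough regions outside exclusions")
        tries += 1
        k = rng.choice(len(usable), p=probs)
        chrom, s, e = usable[k]
        start = int(rng.integers(s, e - region_bp + 1))
        end = start + region_bp
        if any(x.overlaps_any(chrom, start, end) for x in exclusions):
            continue
        out.append((chrom, start, end))
    return out


def sample_background(annotation: RegionSet, enhancers: RegionSet,
                      active_promoters: RegionSet,
                      proportions: BackgroundProportions = BackgroundProportions(),
                      n: int = 100, region_bp: int = 2000, seed: int = 0,
                      chrom_sizes: dict[str, int] | None = None) -> RegionSet:
    """Sample ``n`` background regions of ``region_bp`` at genome proportions.

    ``annotation`` holds gene bodies (label 'gene') and promoters/TSS
    windows (label 'promoter').  Genic territory is the gene bodies,
    intergenic the complement (requires ``chrom_sizes``), inactive promoters
    the annotated promoters not in the active set.  Regions overlapping the
    supplied enhancer or active-promoter sets are rejected and resampled;
    their quota slots are re-allocated to genic/intergenic draws in
    proportion.
    """
    if chrom_sizes is None:
        raise ValueError("chrom_sizes is required to derive intergenic territory")
    rng = np.random.default_rng(seed)
    genes = annotation.df[annotation.df["label"] == "gene"]
    promoters = annotation.df[annotation.df["label"] == "promoter"]

    genic_iv = [(r.chrom, r.start, r.end) for r in RegionSet(genes).sort()]
    inter_iv = []
    gene_set = RegionSet(genes)
    for chrom, size in chrom_sizes.items():
        iv = gene_set.intervals(chrom)
        iv = iv[np.argsort(iv[:, 0])] if len(iv) else iv
        pos = 0
        for s, e in iv:
            if s > pos:
                inter_iv.append((chrom, pos, int(s)))
            pos = max(pos, int(e))
        if pos < size:
            inter_iv.append((chrom, pos, size))
    inactive = [
        (r.chrom, r.start, r.end)
        for r in RegionSet(promoters)
        if not active_promoters.overlaps_any(r.chrom, r.start, r.end)
    ]

    n_inact = round(n * proportions.inactive_promoter)
    n_genic = round(n * proportions.genic)
    n_inter = round(n * proportions.intergenic)
    # enhancer / active-promoter slots re-allocated to genic+intergenic
    spare = n - n_inact - n_genic - n_inter
    frac_genic = proportions.genic / (proportions.genic + proportions.intergenic)
    extra_genic = round(spare * frac_genic)
    n_genic += extra_genic
    n_inter += spare - extra_genic

    excl = [enhancers, active_promoters]
    rows = []
    for iv, count in ((inactive, n_inact), (genic_iv, n_genic), (inter_iv, n_inter)):
        if count == 0:
            continue
        for chrom, start, end in _sample_in_intervals(rng, iv, count, region_bp, excl):
            rows.append((chrom, start, end, "background", 0.0))
    return RegionSet(pd.DataFrame(rows, columns=BED_COLUMNS)).sort()


def process_test_regions(raw: RegionSet, tss: RegionSet, atac_peaks: RegionSet,
                         merge_within: int = 500, tss_exclude: int = 2000) -> RegionSet:
    """Merge, promoter-filter and peak-center raw test regions.

    Regions with gaps <= ``merge_within`` are combined; merged regions
    within ``tss_exclude`` bp of an annotated TSS are dropped; survivors are
    re-centered on the summit (midpoint) of the highest-scoring overlapping
    ATAC peak, keeping the merged width.  Survivors without an overlapping
    ATAC peak are dropped.
    """
    df = raw.sort().df
    merged = []
    for r in df.itertuples(index=False):
        if merged and r.chrom == merged[-1][0] and r.start - merged[-1][2] <= merge_within:
            merged[-1][2] = max(merged[-1][2], r.end)
        else:
            merged.append([r.chrom, r.start, r.end])

    tss_pos = {c: np.sort((tss.intervals(c)[:, 0] + tss.intervals(c)[:, 1]) // 2)
               if len(tss.intervals(c)) else np.empty(0)
               for c in {m[0] for m in merged}}
    rows = []
    for chrom, start, end in merged:
        pos = tss_pos[chrom]
        if len(pos):
            dist = np.minimum(np.abs(pos - start), np.abs(pos - end))
            dist[(pos >= start) & (pos < end)] = 0
            if dist.min() < tss_exclude:
                continue
        peaks = atac_peaks.df[(atac_peaks.df["chrom"] == chrom)
                              & (atac_peaks.df["start"] < end)
                              & (atac_peaks.df["end"] > start)]
        if peaks.empty:
            continue
        top = peaks.loc[peaks["score"].idxmax()]
        summit = int((top["start"] + top["end"]) // 2)
        width = end - start
        new_start = max(summit - width // 2, 0)
        rows.append((chrom, new_start, new_start + width, "test_pos", float(top["score"])))
    return RegionSet(pd.DataFrame(rows, columns=BED_COLUMNS))


def make_cv_folds(enhancers: RegionSet, background_pool: RegionSet,
                  k_folds: int = 5, seed: int = 0,
                  positive_fraction: float = 0.10):
    """k-fold splits: enhancers partitioned into near-equal disjoint folds;
    each test set is one enhancer fold plus negatives drawn from the
    background pool so positives make up ``positive_fraction`` of the test
    set (reflecting rough genomic proportions); train sets exclude the test
    fold."""
    if len(enhancers) < k_folds:
        raise ValueError("need at least k_folds enhancers")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(enhancers))
    folds = np.array_split(order, k_folds)
    neg_df = background_pool.df
    splits = []
    for f in folds:
        test_pos = RegionSet(enhancers.df.iloc[np.sort(f)]).relabel("test_pos")
        train_idx = np.sort(np.setdiff1d(order, f))
        train = RegionSet(enhancers.df.iloc[train_idx])
        n_neg = min(int(round(len(f) * (1 - positive_fraction) / positive_fraction)),
                    len(neg_df))
        neg_idx = rng.choice(len(neg_df), size=n_neg, replace=False) if n_neg else []
        test_neg = RegionSet(neg_df.iloc[np.sort(neg_idx)]).relabel("test_neg")
        test = RegionSet(pd.concat([test_pos.df, test_neg.df], ignore_index=True))
        splits.append((train, test))
    return splits
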