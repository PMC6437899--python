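"""High-level training and evaluation pipelines tying the modules together."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import pr_curve, score_test_regions, viterbi_point
from .hmm_core import ConstrictedHMM
from .model_builder import (CompositionConfig, build_foreground_module, compose,
                            fit_background, fit_foreground_5state,
                            refine_foreground, select_states)
from .predict import extract_elements, segment_genome
from .region_sets import RegionSet
from .signal_io import SignalMatrix
from .synthetic import (default_truth_model, region_observations,
                        sample_background_regions, sample_training_regions,
                        simulate)

N_REFERENCE_QUANTILES = 1001


def train_model(signals: SignalMatrix, enhancers: RegionSet, promoters: RegionSet,
                background: RegionSet, config: CompositionConfig = CompositionConfig(),
                seed: int = 0, max_iter: int = 100) -> ConstrictedHMM:
    """Full supervised construction from training regions and signal tracks.

    Fits the two 5-state foreground models, selects and duplicates states
    into the directed modules, Viterbi-refines them with frozen emissions,
    fits the 10-state background model and composes the combined model.
    The model stores downsampled reference quantiles of the training
    signal, enabling cross-sample quantile normalization at prediction
    time.
    """
    modules = {}
    for kind, regions in (("enhancer", enhancers), ("promoter", promoters)):
        obs = region_observations(signals, regions)
        model5 = fit_foreground_5state(obs, signals.features, seed=seed,
                                       max_iter=max_iter)
        selection = select_states(model5, kind)
        module = build_foreground_module(model5, selection, kind)
        modules[kind] = refine_foreground(module, obs)
    bg = fit_background(region_observations(signals, background),
                        signals.features, seed=seed, max_iter=max_iter)
    model = compose(bg, modules["enhancer"], modules["promoter"], config)

    q = np.linspace(0, 1, N_REFERENCE_QUANTILES)
    for feat in signals.features:
        col = np.sort(signals.feature_column(feat))
        model.metadata[f"reference_quantiles_{feat}"] = np.quantile(col, q)
    return model


def model_reference_quantiles(model: ConstrictedHMM) -> dict[str, np.ndarray] | None:
    refs = {}
    for feat in model.features:
        key = f"reference_quantiles_{feat}"
        if key not in model.metadata:
            return None
        refs[feat] = np.asarray(model.metadata[key], dtype=np.float64)
    return refs


def make_test_set(truth, chroms, n_positives: int = 500, negatives_per_positive: int = 9,
                  seed: int = 0, region_bp: int = 2000) -> RegionSet:
    """Evaluation set from a synthetic genome: a sample of truth enhancers
    as positives plus element-free windows as negatives (roughly genomic
    class imbalance)."""
    rng = np.random.default_rng(seed)
    df = truth.elements.df
    pos_df = df[(df["label"] == "enhancer") & df["chrom"].isin(list(chroms))]
    k = min(n_positives, len(pos_df))
    pick = np.sort(rng.choice(len(pos_df), size=k, replace=False))
    pos = RegionSet(pos_df.iloc[pick]).relabel("test_pos")
    neg = sample_background_regions(
        truth, n=k * negatives_per_positive, seed=seed + 1,
        region_bp=region_bp, chroms=chroms, enhancer_frac=0.0,
        promoter_frac=0.05).relabel("test_neg")
    return RegionSet(pd.concat([pos.df, neg.df], ignore_index=True))


def run_end_to_end(seed: int = 0, n_bins: int = 1_000_000, separation: str = "easy",
                   n_training: int = 300, n_test_positives: int = 500) -> dict:
    """Simulate, build training sets, train, predict on a held-out
    chromosome, and evaluate against the ground truth.

    Training regions come from the first synthetic chromosome; prediction
    and evaluation use the second, so the evaluated sequence is never seen
    during training.
    """
    truth_model = default_truth_model(separation)
    truth = simulate(truth_model, n_bins=n_bins, seed=seed)
    train_chrom, test_chrom = truth.partition.chroms[0], truth.partition.chroms[-1]

    enh = sample_training_regions(truth, "enhancer", n_training, seed, chroms=[train_chrom])
    pro = sample_training_regions(truth, "promoter", n_training, seed, chroms=[train_chrom])
    bg = sample_background_regions(truth, n_training, seed, chroms=[train_chrom])
    model = train_model(truth.tracks, enh, pro, bg, seed=seed)

    test_signals = truth.tracks.subset_chroms([test_chrom])
    track = segment_genome(model, test_signals)
    elements = extract_elements(track)

    test = make_test_set(truth, [test_chrom], n_test_positives, seed=seed)
    scores = score_test_regions(track, test)
    labels = (test.df["label"] == "test_pos").to_numpy().astype(int)
    curve = pr_curve(scores, labels)
    precision, recall = viterbi_point(elements, test)

    truth_bins = {c: np.isin(np.array(truth.model.roles)[truth.paths[c].states],
                             ["E_N1", "E_A", "E_N2"])
                  for c in [test_chrom]}
    pred_roles = track.role_path(test_chrom)
    pred_bins = np.isin(pred_roles, ["E_N1", "E_A", "E_N2"])
    tb = truth_bins[test_chrom]
    bin_recall = float((pred_bins & tb).sum() / tb.sum()) if tb.any() else 0.0

    return {
        "model": model,
        "truth": truth,
        "elements": elements,
        "track": track,
        "test": test,
        "auprc": curve.auprc,
        "viterbi_precision": precision,
        "viterbi_recall": recall,
        "enhancer_bin_recall": bin_recall,
        "n_predicted_enhancers": sum(e.kind == "enhancer" for e in elements),
        "n_true_enhancers_test_chrom": int(
            (truth.elements.df["label"].eq("enhancer")
             & truth.elements.df["chrom"].eq(test_chrom)).sum()),
    }
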