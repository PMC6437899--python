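import numpy as np
import pandas as pd
import pytest

from ehmm.region_sets import (BED_COLUMNS, BackgroundProportions, RegionSet,
                              filter_cage, make_cv_folds, match_peak_triplets,
                              process_test_regions, read_bed, remove_neighbors,
                              sample_background, select_active_cluster,
                              write_bed)
from ehmm.signal_io import SignalMatrix


def regions(rows):
    return RegionSet(pd.DataFrame(rows, columns=BED_COLUMNS))


class TestRegionSet:
    def test_coordinate_invariant(self):
        with pytest.raises(ValueError):
            regions([("chr1", 100, 100, "enhancer", 0.0)])

    def test_bed_roundtrip(self, tmp_path, rng):
        rows = [("chr1", int(s), int(s) + 100, "enhancer", float(v))
                for s, v in zip(sorted(rng.choice(10000, 20, replace=False)),
                                rng.integers(0, 50, 20))]
        rs = regions(rows)
        path = tmp_path / "r.bed"
        write_bed(rs, path)
        back = read_bed(path)
        pd.testing.assert_frame_equal(back.df, rs.df)


class TestFilterCage:
    def test_threshold_is_inclusive(self):
        rs = regions([("chr1", 0, 100, "enhancer", 11.0),
                      ("chr1", 200, 300, "enhancer", 10.0),
                      ("chr1", 400, 500, "enhancer", 12.0)])
        assert len(filter_cage(rs, 11)) == 2

    def test_zero_threshold_keeps_all(self):
        rs = regions([("chr1", 0, 100, "enhancer", 0.0)])
        assert len(filter_cage(rs, 0)) == 1

    def test_empty_input(self):
        assert len(filter_cage(RegionSet(), 5)) == 0


class TestSelectActiveCluster:
    def planted(self, rng, n_per=20):
        """5 planted clusters over a 4-feature signal; cluster 0 has the
        active-enhancer signature (high acc/K27/me1, low me3)."""
        patterns = np.array([
            [30, 30, 30, 1],   # active enhancer
            [30, 30, 1, 30],   # promoter-like
            [1, 1, 30, 1],     # poised
            [1, 1, 1, 1],      # depleted
            [10, 1, 1, 10],    # mixed
        ])
        sizes = {"chr1": 100 * 20 * 5 * n_per}
        rows, tracks = [], []
        for c, pat in enumerate(patterns):
            for i in range(n_per):
                start = (c * n_per + i) * 2000
                rows.append(("chr1", start, start + 500, "enhancer", 0.0))
        n_bins = sizes["chr1"] // 100
        counts = rng.poisson(2, size=(n_bins, 4))
        for c, pat in enumerate(patterns):
            for i in range(n_per):
                b0 = ((c * n_per + i) * 2000) // 100
                counts[b0:b0 + 5] = rng.poisson(pat, size=(5, 4))
        from ehmm.signal_io import GenomePartition
        matrix = SignalMatrix(GenomePartition(sizes),
                              ("accessibility", "H3K27ac", "H3K4me1", "H3K4me3"),
                              {"chr1": counts.astype(np.int64)})
        return regions(rows), matrix

    def test_planted_cluster_recovered(self, rng):
        rs, matrix = self.planted(rng)
        out = select_active_cluster(rs, matrix, k=5, seed=0)
        # the first 20 regions are the planted active cluster
        assert set(out.df["start"]) == set(rs.df["start"][:20])

    def test_identical_regions_degenerate(self, rng):
        rs, matrix = self.planted(rng)
        same = regions([("chr1", 0, 500, "enhancer", 0.0)] * 6)
        with pytest.warns(UserWarning):
            out = select_active_cluster(same, matrix, k=5, seed=0)
        assert len(out) == len(same)

    def test_fewer_regions_than_k(self, rng):
        rs, matrix = self.planted(rng)
        with pytest.raises(ValueError):
            select_active_cluster(regions([("chr1", 0, 500, "enhancer", 0.0)]),
                                  matrix, k=5)


class TestMatchPeakTriplets:
    k27 = regions([("chr1", 0, 300, "peak", 5.0), ("chr1", 900, 1200, "peak", 5.0)])

    def test_qualifying_triplet_span(self):
        atac = regions([("chr1", 450, 750, "peak", 9.0)])
        cand = regions([("chr1", 400, 800, "enhancer", 0.0)])
        out = match_peak_triplets(cand, self.k27, atac, max_width=2000)
        assert len(out) == 1
        r = next(iter(out))
        assert (r.start, r.end) == (0, 1200)

    def test_wide_triplet_dropped(self):
        k27 = regions([("chr1", 0, 300, "peak", 5.0), ("chr1", 2100, 2400, "peak", 5.0)])
        atac = regions([("chr1", 450, 750, "peak", 9.0)])
        cand = regions([("chr1", 400, 800, "enhancer", 0.0)])
        assert len(match_peak_triplets(cand, k27, atac, max_width=2000)) == 0

    def test_missing_flank_dropped(self):
        k27 = regions([("chr1", 0, 300, "peak", 5.0)])  # no right flank
        atac = regions([("chr1", 450, 750, "peak", 9.0)])
        cand = regions([("chr1", 400, 800, "enhancer", 0.0)])
        assert len(match_peak_triplets(cand, k27, atac, max_width=2000)) == 0


class TestRemoveNeighbors:
    def test_both_members_of_close_pair_removed(self):
        rs = regions([("chr1", 0, 100, "enhancer", 0.0),
                      ("chr1", 1500, 1600, "enhancer", 0.0)])
        assert len(remove_neighbors(rs, 2000)) == 0

    def test_distant_pair_kept(self):
        rs = regions([("chr1", 0, 100, "enhancer", 0.0),
                      ("chr1", 3000, 3100, "enhancer", 0.0)])
        assert len(remove_neighbors(rs, 2000)) == 2

    def test_single_region_kept(self):
        rs = regions([("chr1", 0, 100, "enhancer", 0.0)])
        assert len(remove_neighbors(rs, 2000)) == 1

    def test_gap_exact(self):
        out = remove_neighbors(regions([("chr1", 0, 100, "enhancer", 0.0),
                                        ("chr1", 2100, 2200, "enhancer", 0.0)]), 2000)
        assert len(out) == 2  # gap exactly 2000 is allowed

    def test_minimum_pairwise_gap_invariant(self, rng):
        starts = np.sort(rng.choice(100_000, 60, replace=False))
        rs = regions([("chr1", int(s), int(s) + 50, "enhancer", 0.0) for s in starts])
        out = remove_neighbors(rs, 2000).df
        gaps = out["start"].to_numpy()[1:] - out["end"].to_numpy()[:-1]
        assert (gaps >= 2000).all()

    def test_different_chromosomes_never_neighbors(self):
        rs = regions([("chr1", 0, 100, "enhancer", 0.0),
                      ("chr2", 50, 150, "enhancer", 0.0)])
        assert len(remove_neighbors(rs, 2000)) == 2


class TestSampleBackground:
    def setup_inputs(self):
        annotation = regions(
            [("chr1", 100_000, 200_000, "gene", 0.0),
             ("chr1", 95_000, 100_000, "promoter", 0.0),
             ("chr1", 300_000, 400_000, "gene", 0.0),
             ("chr1", 295_000, 300_000, "promoter", 0.0)])
        enhancers = regions([("chr1", 50_000, 52_000, "enhancer", 0.0)])
        active = regions([("chr1", 95_000, 100_000, "promoter", 0.0)])
        sizes = {"chr1": 1_000_000}
        return annotation, enhancers, active, sizes

    def test_category_quota_and_exclusions(self):
        annotation, enhancers, active, sizes = self.setup_inputs()
        out = sample_background(annotation, enhancers, active, n=100, seed=0,
                                chrom_sizes=sizes)
        assert len(out) == 100
        for r in out:
            assert not enhancers.overlaps_any(r.chrom, r.start, r.end)
            assert not active.overlaps_any(r.chrom, r.start, r.end)
            assert r.end - r.start == 2000

    def test_deterministic_given_seed(self):
        annotation, enhancers, active, sizes = self.setup_inputs()
        a = sample_background(annotation, enhancers, active, n=50, seed=3,
                              chrom_sizes=sizes)
        b = sample_background(annotation, enhancers, active, n=50, seed=3,
                              chrom_sizes=sizes)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_proportions_sum_validation(self):
        with pytest.raises(ValueError):
            BackgroundProportions(enhancer=0.5)


class TestProcessTestRegions:
    tss = regions([("chr1", 50_000, 50_001, "promoter", 0.0)])
    atac = regions([("chr1", 10_200, 10_400, "peak", 9.0),
                    ("chr1", 10_450, 10_500, "peak", 3.0),
                    ("chr1", 60_000, 60_200, "peak", 5.0)])

    def test_merge_within_gap(self):
        raw = regions([("chr1", 10_000, 10_300, "test_pos", 0.0),
                       ("chr1", 10_700, 11_000, "test_pos", 0.0)])  # gap 400
        out = process_test_regions(raw, self.tss, self.atac)
        assert len(out) == 1
        r = next(iter(out))
        assert r.end - r.start == 1000  # merged width preserved

    def test_tss_proximity_threshold(self):
        near = regions([("chr1", 47_000, 48_100, "test_pos", 0.0)])   # 1900 bp away
        far = regions([("chr1", 46_000, 47_900, "test_pos", 0.0)])    # 2100 bp away
        atac = regions([("chr1", 47_200, 47_400, "peak", 5.0)])
        assert len(process_test_regions(near, self.tss, atac)) == 0
        assert len(process_test_regions(far, self.tss, atac)) == 1

    def test_centering_on_best_peak_summit(self):
        raw = regions([("chr1", 10_000, 11_000, "test_pos", 0.0)])
        out = process_test_regions(raw, self.tss, self.atac)
        r = next(iter(out))
        assert (r.start + r.end) // 2 == 10_300  # summit of the score-9 peak

    def test_no_overlapping_peak_dropped(self):
        raw = regions([("chr1", 20_000, 21_000, "test_pos", 0.0)])
        assert len(process_test_regions(raw, self.tss, self.atac)) == 0

    def test_engineered_count(self):
        raw = regions([
            ("chr1", 10_000, 10_300, "test_pos", 0.0),   # merges with next, has peak
            ("chr1", 10_500, 11_000, "test_pos", 0.0),
            ("chr1", 49_000, 49_500, "test_pos", 0.0),   # near TSS -> dropped
            ("chr1", 60_000, 60_300, "test_pos", 0.0),   # kept, peak overlaps
            ("chr1", 80_000, 80_500, "test_pos", 0.0),   # no peak -> dropped
        ])
        assert len(process_test_regions(raw, self.tss, self.atac)) == 2


class TestCVFolds:
    def make_pool(self, n, label, width=500):
        return regions([("chr1", 10_000 * i, 10_000 * i + width, label, 0.0)
                        for i in range(n)])

    def test_fold_sizes(self):
        splits = make_cv_folds(self.make_pool(300, "enhancer"),
                               self.make_pool(400, "background"), k_folds=5, seed=0)
        assert len(splits) == 5
        for train, test in splits:
            assert (test.df["label"] == "test_pos").sum() == 60
            assert len(train) == 240

    def test_folds_disjoint_and_cover_input(self):
        enh = self.make_pool(101, "enhancer")
        splits = make_cv_folds(enh, self.make_pool(50, "background"), seed=1)
        seen = []
        for _, test in splits:
            seen += list(test.df[test.df["label"] == "test_pos"]["start"])
        assert sorted(seen) == sorted(enh.df["start"])

    def test_deterministic(self):
        enh = self.make_pool(40, "enhancer")
        bg = self.make_pool(60, "background")
        a = make_cv_folds(enh, bg, seed=9)
        b = make_cv_folds(enh, bg, seed=9)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            pd.testing.assert_frame_equal(te1.df, te2.df)
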