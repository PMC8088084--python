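"""Sliding-window scanner: binning, strata, stratified permutation null."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import toy_annotation
from sexarch import regions as reg


def _cfg(**kw):
    base = dict(bin_size=100_000, window_bins=20, n_perm=200, seed=0)
    base.update(kw)
    return reg.RegionScanConfig(**base)


class TestAssignBins:
    def test_midpoint_conventions(self):
        ann = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "scaffold": "s1",
                "start": [149_500, 99_500],
                "end": [150_500, 100_500],  # midpoints 150000 and 100000
                "strand": "+",
            }
        )
        out = reg.assign_bins(ann, _cfg())
        assert list(out["bin"]) == [1, 1]  # 150k in bin 1; exactly 100k -> bin 1

    def test_toy_hand_enumeration(self):
        starts = [0, 40_000, 99_000, 140_000, 260_000, 300_000, 955_000]
        ann = toy_annotation(starts, gene_len=2000)
        out = reg.assign_bins(ann, _cfg())
        mids = [s + 1000 for s in starts]
        assert list(out["bin"]) == [m // 100_000 for m in mids]

    def test_gene_beyond_scaffold_errors(self):
        ann = toy_annotation([500_000], gene_len=1000)
        with pytest.raises(ValueError, match="beyond"):
            reg.assign_bins(ann, _cfg(), scaffold_lengths=pd.Series({"s1": 400_000}))


class TestWindowMeans:
    @staticmethod
    def _toy(values, starts, scaffold_len=3_000_000, **cfg_kw):
        ann = toy_annotation(starts, gene_len=1000)
        cfg = _cfg(**cfg_kw)
        bin_map = reg.assign_bins(ann, cfg)
        vals = pd.Series(values, index=ann["gene_id"])
        lengths = pd.Series({"s1": scaffold_len})
        return reg.compute_window_means(vals, bin_map, lengths, cfg), cfg

    def test_all_zero_values(self):
        out, _ = self._toy([0.0] * 5, [i * 300_000 for i in range(5)])
        assert (out.loc[out["n_genes"] > 0, "mean_log2fc"] == 0).all()

    def test_simple_arithmetic(self):
        out, _ = self._toy([1.0, -1.0, 0.0], [10_000, 20_000, 30_000])
        first = out.iloc[0]
        assert first["n_genes"] == 3
        assert first["mean_log2fc"] == pytest.approx(0.0)

    def test_matches_naive_rescan(self):
        rng = np.random.default_rng(9)
        starts = np.sort(rng.choice(np.arange(0, 4_000_000, 2000), 80, replace=False))
        values = rng.normal(size=80)
        out, cfg = self._toy(values, starts.tolist(), scaffold_len=4_000_000)
        mids = starts + 1000
        for _, row in out.iterrows():
            # naive: gene in window iff its bin is within [start, end) bins
            bins = mids // cfg.bin_size
            w0 = row["start"] // cfg.bin_size
            w1 = row["end"] // cfg.bin_size
            member = (bins >= w0) & (bins < w1)
            assert row["n_genes"] == member.sum()
            if member.sum():
                assert row["mean_log2fc"] == pytest.approx(values[member].mean())

    def test_truncated_windows_dropped(self):
        out, cfg = self._toy([1.0], [10_000], scaffold_len=2_500_000)
        # 25 bins, 20-bin windows -> 6 windows, last ends at bin 25
        assert len(out) == 6
        assert out["end"].max() == 2_500_000

    def test_short_scaffold_no_windows(self):
        out, _ = self._toy([1.0], [10_000], scaffold_len=1_000_000)
        assert out.empty

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(10)
        starts = np.sort(rng.choice(np.arange(0, 4_000_000, 2000), 50, replace=False))
        ann = toy_annotation(starts.tolist(), gene_len=1000)
        cfg = _cfg()
        vals = pd.Series(rng.normal(size=50), index=ann["gene_id"])
        lengths = pd.Series({"s1": 4_000_000})
        a = reg.compute_window_means(vals, reg.assign_bins(ann, cfg), lengths, cfg)
        shuffled = ann.sample(frac=1.0, random_state=1).reset_index(drop=True)
        b = reg.compute_window_means(
            vals.sample(frac=1.0, random_state=2), reg.assign_bins(shuffled, cfg), lengths, cfg
        )
        pd.testing.assert_frame_equal(a, b)


class TestStrata:
    def test_ten_values_five_strata_pairs(self):
        base = pd.Series(np.arange(1.0, 11.0), index=[f"g{i}" for i in range(10)])
        strata = reg.build_strata(base, 5)
        expected = np.repeat(np.arange(5), 2)
        assert list(strata) == list(expected)

    def test_all_equal_single_stratum(self):
        base = pd.Series(np.full(8, 3.0))
        assert reg.build_strata(base, 5).nunique() == 1

    def test_balanced_sizes_for_distinct_values(self):
        rng = np.random.default_rng(11)
        base = pd.Series(rng.permutation(np.arange(100, dtype=float)))
        sizes = reg.build_strata(base, 5).value_counts()
        assert sizes.max() - sizes.min() <= 1


class TestPermutation:
    def test_shuffle_conserves_stratum_multisets(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(size=30)
        idx = [np.arange(0, 15), np.arange(15, 30)]
        out = reg.stratified_shuffle(vals, idx, rng)
        for i in idx:
            assert sorted(out[i]) == pytest.approx(sorted(vals[i]))
        assert np.sum(out) == pytest.approx(np.sum(vals))  # genome-wide mean conserved

    def test_tiny_case_matches_exhaustive_enumeration(self):
        """4 genes, 2 strata of 2: one window's permuted mean must take the 4
        enumerable values with equal frequency."""
        ann = toy_annotation([10_000, 30_000, 110_000, 130_000], gene_len=2000)
        cfg = _cfg(bin_size=100_000, window_bins=1, min_genes_per_window=1, n_perm=2000)
        bin_map = reg.assign_bins(ann, cfg)
        vals = pd.Series([1.0, 2.0, 4.0, 8.0], index=ann["gene_id"])
        strata = pd.Series([0, 1, 0, 1], index=ann["gene_id"])  # {g1,g3}, {g2,g4}
        lengths = pd.Series({"s1": 200_000})
        null = reg.permute_profiles(vals, strata, bin_map, lengths, cfg, tail_fraction=1.0)
        # window 0 holds slots of g1 (stratum 0) and g2 (stratum 1):
        # mean in {(1+2)/2, (1+8)/2, (4+2)/2, (4+8)/2}
        means = null.upper_tail[:, 0]
        expected = {1.5, 4.5, 3.0, 6.0}
        assert set(np.round(np.unique(means), 9)) == expected
        freqs = pd.Series(means).value_counts(normalize=True)
        assert np.allclose(freqs, 0.25, atol=0.06)

    def test_refuses_too_few_permutations(self):
        with pytest.raises(ValueError):
            _cfg(n_perm=50)


class TestCalling:
    @staticmethod
    def _planted_profile(rng, ann, region=(1_000_000, 3_000_000), n_planted=30):
        n = len(ann)
        vals = np.zeros(n)
        biased = rng.random(n) < 0.08
        vals[biased] = rng.choice([-1, 1], size=biased.sum()) * (
            0.6 + rng.exponential(0.5, size=biased.sum())
        )
        mid = ((ann["start"] + ann["end"]) // 2).to_numpy()
        if region is not None:
            inside = np.flatnonzero((mid >= region[0]) & (mid < region[1]))
            chosen = rng.choice(inside, size=n_planted, replace=False)
            vals[chosen] = 2.0
        base = pd.Series(rng.lognormal(4, 1.5, size=n), index=ann["gene_id"])
        return pd.Series(vals, index=ann["gene_id"]), base

    def test_null_median_observation_never_called(self):
        ann = toy_annotation([i * 20_000 for i in range(150)], gene_len=2000)
        cfg = _cfg(n_perm=200, min_genes_per_window=1)
        bin_map = reg.assign_bins(ann, cfg)
        vals = pd.Series(0.0, index=ann["gene_id"])
        lengths = pd.Series({"s1": 3_000_000})
        strata = reg.build_strata(pd.Series(1.0, index=ann["gene_id"]), 5)
        windows = reg.compute_window_means(vals, bin_map, lengths, cfg)
        null = reg.permute_profiles(vals, strata, bin_map, lengths, cfg)
        called = reg.call_enriched_windows(windows, null, cfg)
        assert (called["call"] == "none").all()

    def test_planted_region_recovered(self):
        rng = np.random.default_rng(13)
        ann = toy_annotation(sorted(rng.choice(np.arange(0, 5_000_000, 2500), 250, replace=False)), gene_len=2000)
        cfg = _cfg(n_perm=2000)
        bin_map = reg.assign_bins(ann, cfg)
        lengths = pd.Series({"s1": 5_000_000})
        vals, base = self._planted_profile(rng, ann)
        strata = reg.build_strata(base, 5)
        windows = reg.compute_window_means(vals, bin_map, lengths, cfg)
        null = reg.permute_profiles(vals, strata, bin_map, lengths, cfg)
        called = reg.call_enriched_windows(windows, null, cfg)
        hits = called[(called["call"] == "male") & (called["end"] > 1_000_000) & (called["start"] < 3_000_000)]
        assert len(hits) >= 1

    def test_multi_scale_calls_overlap_planted_region(self):
        rng = np.random.default_rng(14)
        ann = toy_annotation(sorted(rng.choice(np.arange(0, 5_000_000, 2500), 250, replace=False)), gene_len=2000)
        lengths = pd.Series({"s1": 5_000_000})
        vals, base = self._planted_profile(rng, ann)
        for window_bins in (20, 10, 5):  # 2 Mb, 1 Mb, 500 kb
            cfg = _cfg(window_bins=window_bins, n_perm=1000)
            bin_map = reg.assign_bins(ann, cfg)
            strata = reg.build_strata(base, 5)
            windows = reg.compute_window_means(vals, bin_map, lengths, cfg)
            null = reg.permute_profiles(vals, strata, bin_map, lengths, cfg)
            called = reg.call_enriched_windows(windows, null, cfg)
            hits = called[
                (called["call"] == "male")
                & (called["end"] > 1_000_000)
                & (called["start"] < 3_000_000)
            ]
            assert len(hits) >= 1, f"no overlap at window span {window_bins * 100} kb"

    def test_doubling_permutations_is_stable(self):
        rng = np.random.default_rng(15)
        ann = toy_annotation(sorted(rng.choice(np.arange(0, 3_000_000, 3000), 120, replace=False)), gene_len=2000)
        lengths = pd.Series({"s1": 3_000_000})
        vals, base = self._planted_profile(rng, ann, region=None)
        strata = reg.build_strata(base, 5)
        ps = []
        for n_perm in (400, 800):
            cfg = _cfg(n_perm=n_perm, seed=3)
            bin_map = reg.assign_bins(ann, cfg)
            windows = reg.compute_window_means(vals, bin_map, lengths, cfg)
            null = reg.permute_profiles(vals, strata, bin_map, lengths, cfg)
            called = reg.call_enriched_windows(windows, null, cfg)
            ps.append(called["p_upper"].to_numpy())
        p1, p2 = ps
        # binomial MC noise bound at ~3 sigma
        se = np.sqrt(np.maximum(p1 * (1 - p1), 0.25 / 400) / 400)
        assert (np.abs(p1 - p2) <= 4 * se + 0.01).all()


class TestMerge:
    @staticmethod
    def _called(rows):
        df = pd.DataFrame(rows, columns=["scaffold", "start", "end", "call"])
        df["n_genes"] = 10
        df["mean_log2fc"] = np.where(df["call"] == "male", 1.0, -1.0)
        df["usable"] = True
        return df

    def test_overlapping_same_direction_merged(self):
        out = reg.merge_regions(
            self._called([("s1", 0, 2_000_000, "male"), ("s1", 100_000, 2_100_000, "male")])
        )
        assert len(out) == 1
        assert out.iloc[0]["start"] == 0 and out.iloc[0]["end"] == 2_100_000

    def test_opposite_directions_stay_separate(self):
        out = reg.merge_regions(
            self._called([("s1", 0, 2_000_000, "male"), ("s1", 2_000_000, 4_000_000, "female")])
        )
        assert len(out) == 2

    def test_five_window_hand_merge(self):
        out = reg.merge_regions(
            self._called(
                [
                    ("s1", 0, 2_000_000, "male"),
                    ("s1", 1_000_000, 3_000_000, "male"),
                    ("s1", 5_000_000, 7_000_000, "male"),
                    ("s2", 0, 2_000_000, "female"),
                    ("s2", 100_000, 2_100_000, "female"),
                ]
            )
        )
        spans = set(zip(out["scaffold"], out["start"], out["end"]))
        assert spans == {("s1", 0, 3_000_000), ("s1", 5_000_000, 7_000_000), ("s2", 0, 2_100_000)}
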