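"""CO context: feature distances, metaplots, peak tests, scaled regions."""

import numpy as np
import pandas as pd
import pytest

from xomap import SignalTrack, SimConfig, TrackSpec
from xomap.context import (
    anchored_density_profile,
    anchored_signal_profile,
    distance_to_nearest,
    distribution_ks_test,
    fraction_within,
    profile_peak_test,
    random_placement_test,
    scaled_region_profile,
)
from xomap.synthio import simulate_gametes, simulate_marker_set, simulate_tracks

from oracles import brute_nearest_distance, ks_statistic


def nonoverlapping_features(rng, n=30, chrom="chr1", span=1_000_000):
    starts = np.sort(rng.choice(span // 2000, n, replace=False)) * 2000
    lengths = rng.integers(200, 1500, n)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + lengths,
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
            "gene_id": [f"g{i}" for i in range(n)],
        }
    )


class TestDistances:
    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(0)
        feats = nonoverlapping_features(rng)
        pts = pd.DataFrame(
            {"chrom": "chr1", "pos": rng.integers(0, 1_000_000, 200)}
        )
        d = distance_to_nearest(pts, feats)["distance"].to_numpy()
        for p, got in zip(pts["pos"], d):
            want = brute_nearest_distance(p, feats["start"], feats["end"])
            assert got == want

    def test_point_inside_feature_is_zero(self):
        feats = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200], "strand": ["+"]}
        )
        pts = pd.DataFrame({"chrom": ["chr1"], "pos": [150]})
        assert distance_to_nearest(pts, feats)["distance"][0] == 0.0

    def test_upstream_sign_convention(self):
        """500 bp 5' of a + strand TSS is -500; mirrored for - strand."""
        feats = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [10_000, 50_000],
                "end": [12_000, 52_000],
                "strand": ["+", "-"],
            }
        )
        pts = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [9_500, 52_499]})
        res = distance_to_nearest(pts, feats, signed=True)
        assert res["signed_distance"][0] == -500.0
        assert res["signed_distance"][1] == -500.0

    def test_unknown_chromosome_gives_nan(self):
        feats = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [10], "strand": ["+"]}
        )
        pts = pd.DataFrame({"chrom": ["chrX"], "pos": [5]})
        assert np.isnan(distance_to_nearest(pts, feats)["distance"][0])

    def test_fraction_within_threshold(self):
        assert fraction_within(np.array([0, 5_000, 50_000]), 10_000) == pytest.approx(2 / 3)


class TestRandomPlacement:
    def test_planted_enrichment_is_significant(self):
        rng = np.random.default_rng(1)
        feats = nonoverlapping_features(rng, n=40)
        inside = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": (feats["start"] + (feats["end"] - feats["start"]) // 2),
            }
        )
        _, p = random_placement_test(
            inside, feats, {"chr1": 1_000_000}, n_random=500, seed=2
        )
        assert p < 1e-3

    def test_null_pvalues_roughly_uniform(self):
        """Observed points drawn from the same uniform null: p ~ U(0,1)."""
        rng = np.random.default_rng(3)
        feats = nonoverlapping_features(rng, n=25)
        ps = []
        for s in range(200):
            obs = pd.DataFrame(
                {"chrom": "chr1", "pos": rng.integers(0, 1_000_000, 40)}
            )
            _, p = random_placement_test(
                obs, feats, {"chr1": 1_000_000}, n_random=100, seed=1000 + s
            )
            ps.append(p)
        from scipy import stats as ss

        assert ss.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_random_points_error(self):
        with pytest.raises(ValueError):
            random_placement_test(
                pd.DataFrame({"chrom": ["chr1"], "pos": [1]}),
                pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10]}),
                {"chr1": 100},
                n_random=0,
            )


class TestAnchoredProfiles:
    def test_planted_cos_at_tss_minus_400(self):
        anchors = pd.DataFrame(
            {"chrom": "chr1", "pos": np.arange(50) * 10_000 + 5_000, "strand": "+"}
        )
        points = pd.DataFrame({"chrom": "chr1", "pos": anchors["pos"] - 400})
        prof = anchored_density_profile(points, anchors)
        assert abs(prof.peak - (-400)) <= 50
        assert prof.values.sum() == prof.n == 50

    def test_strand_flip_mirrors_relative_positions(self):
        anchors_plus = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000], "strand": ["+"]})
        anchors_minus = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000], "strand": ["-"]})
        points = pd.DataFrame({"chrom": ["chr1"], "pos": [10_300]})
        p_plus = anchored_density_profile(points, anchors_plus)
        p_minus = anchored_density_profile(points, anchors_minus)
        assert p_plus.contributions[0] == 300
        assert p_minus.contributions[0] == -300

    def test_reversing_genome_leaves_profile_invariant(self):
        """Mirroring all coordinates and strands preserves the metaplot."""
        rng = np.random.default_rng(4)
        L = 1_000_000
        apos = rng.integers(10_000, L - 10_000, 30)
        strands = np.where(rng.random(30) < 0.5, "+", "-")
        ppos = rng.integers(0, L, 500)
        fwd = anchored_density_profile(
            pd.DataFrame({"chrom": "chr1", "pos": ppos}),
            pd.DataFrame({"chrom": "chr1", "pos": apos, "strand": strands}),
        )
        flipped = np.where(strands == "+", "-", "+")
        rev = anchored_density_profile(
            pd.DataFrame({"chrom": "chr1", "pos": L - 1 - ppos}),
            pd.DataFrame({"chrom": "chr1", "pos": L - 1 - apos, "strand": flipped}),
        )
        assert np.array_equal(fwd.values, rev.values)

    def test_constant_track_gives_flat_profile(self):
        track = SignalTrack(step=50, values={"chr1": np.full(2000, 3.5)})
        anchors = pd.DataFrame({"chrom": "chr1", "pos": [30_000, 50_000, 70_000]})
        prof = anchored_signal_profile(track, anchors, {"chr1": 100_000})
        assert np.allclose(prof.values, 3.5)

    def test_truncated_anchor_counted(self):
        track = SignalTrack(step=50, values={"chr1": np.full(200, 1.0)})
        anchors = pd.DataFrame({"chrom": "chr1", "pos": [500, 5_000]})
        prof = anchored_signal_profile(track, anchors, {"chr1": 10_000})
        assert prof.n_truncated == 1

    def test_planted_gaussian_bump_recovered(self):
        cfg = SimConfig(
            chrom_lengths={"chr1": 5_000_000},
            co_per_meiosis_lambda=5.0,
            track_spec=[TrackSpec("t", 250.0)],
            seed=51,
        )
        mk = simulate_marker_set(cfg)
        _, truth = simulate_gametes(cfg, mk, 80)
        track = simulate_tracks(cfg, truth)["t"]
        anchors = truth.co[["chrom", "pos"]]
        prof = anchored_signal_profile(track, anchors, cfg.chrom_lengths)
        assert abs(prof.peak - 250.0) <= 50


class TestPeakTest:
    def _profiles(self, offset_b, seed, n_anchors=150):
        cfg = SimConfig(
            chrom_lengths={"chr1": 8_000_000},
            co_per_meiosis_lambda=8.0,
            track_spec=[TrackSpec("a", 0.0), TrackSpec("b", offset_b)],
            seed=seed,
        )
        mk = simulate_marker_set(cfg)
        _, truth = simulate_gametes(cfg, mk, n_anchors)
        tracks = simulate_tracks(cfg, truth)
        anchors = truth.co[["chrom", "pos"]]
        pa = anchored_signal_profile(tracks["a"], anchors, cfg.chrom_lengths)
        pb = anchored_signal_profile(tracks["b"], anchors, cfg.chrom_lengths)
        return pa, pb

    def test_separated_peaks_detected(self):
        pa, pb = self._profiles(-400.0, seed=61)
        res = profile_peak_test(pa, pb, n_boot=300, seed=1)
        assert res.p_z < 0.01
        assert len(res.replicates_a) == len(res.replicates_b) == 300

    def test_identical_tracks_not_significant(self):
        pa, pb = self._profiles(0.0, seed=62)
        res = profile_peak_test(pa, pb, n_boot=300, seed=2)
        assert res.p_z > 0.05

    def test_mismatched_binning_error(self):
        pa, _ = self._profiles(0.0, seed=63, n_anchors=30)
        anchors = pd.DataFrame({"chrom": ["chr1"], "pos": [1_000_000]})
        track = SignalTrack(step=50, values={"chr1": np.full(200_000, 1.0)})
        pb = anchored_signal_profile(
            track, anchors, {"chr1": 10_000_000}, flank=1_000
        )
        with pytest.raises(ValueError):
            profile_peak_test(pa, pb)


class TestKsTest:
    def test_identical_samples_d_zero(self):
        x = np.arange(20.0)
        d, p = distribution_ks_test(x, x)
        assert d == 0.0 and p == 1.0

    def test_shifted_samples_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 200)
        b = rng.normal(2, 1, 200)
        _, p = distribution_ks_test(a, b)
        assert p < 1e-6

    def test_d_matches_brute_force_sup(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 57)
        b = rng.normal(0.5, 1.3, 43)
        d, _ = distribution_ks_test(a, b)
        assert abs(d - ks_statistic(a, b)) < 1e-12

    def test_too_few_positions_error(self):
        with pytest.raises(ValueError):
            distribution_ks_test(np.arange(5.0), np.arange(20.0))


class TestScaledRegions:
    def test_linear_ramp_reproduced(self):
        track = SignalTrack(step=10, values={"chr1": np.arange(100, dtype=float)})
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000]})
        prof = scaled_region_profile(regions, track=track, nbins=10)
        assert np.allclose(prof.values, np.arange(10) * 10 + 4.5)

    def test_uniform_signal_different_lengths_flat(self):
        track = SignalTrack(step=10, values={"chr1": np.full(10_000, 2.0)})
        regions = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [0, 30_000, 50_000], "end": [7_000, 43_000, 90_000]}
        )
        prof = scaled_region_profile(regions, track=track, nbins=100)
        assert np.allclose(prof.values, 2.0)

    def test_two_region_fractional_overlap_oracle(self):
        """Hand-computed fractional-bin averages for two short regions."""
        track = SignalTrack(step=10, values={"chr1": np.array([1.0, 3.0, 5.0, 7.0])})
        regions = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 20], "end": [20, 40]}
        )
        prof = scaled_region_profile(regions, track=track, nbins=2)
        # region 1 bins: [0,10)=1, [10,20)=3; region 2: [20,30)=5, [30,40)=7
        assert np.allclose(prof.values, [(1 + 5) / 2, (3 + 7) / 2])
        # odd split exercises partial track-bin overlap
        prof4 = scaled_region_profile(regions.iloc[[0]], track=track, nbins=4)
        assert np.allclose(prof4.values, [1.0, 1.0, 3.0, 3.0])

    def test_region_shorter_than_nbins_flagged(self):
        track = SignalTrack(step=10, values={"chr1": np.full(100, 1.0)})
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [50]})
        prof = scaled_region_profile(regions, track=track, nbins=100)
        assert prof.n_truncated == 1

    def test_points_mode_histogram(self):
        regions = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 1000], "end": [100, 2000]}
        )
        points = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [10, 90, 1500]})
        prof = scaled_region_profile(regions, points=points, nbins=10)
        assert prof.values.sum() == 3
        assert prof.values[1] == 1  # pos 10 -> fraction 0.1
        assert prof.values[5] == 1  # pos 1500 -> fraction 0.5
        assert prof.values[9] == 1  # pos 90 -> fraction 0.9

    def test_empty_regions_error(self):
        with pytest.raises(ValueError):
            scaled_region_profile(pd.DataFrame(columns=["chrom", "start", "end"]))
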