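"""Crossover calling: binning, changepoint segmentation, HMM, refinement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import xomap
from xomap import HmmConfig, SimConfig
from xomap.cocall import (
    bin_allele_frequency,
    call_crossovers,
    cos_per_meiosis,
    detect_breakpoints,
    hmm_posterior,
    refine_and_call,
    resolution_summary,
)
from xomap.containers import events_frame
from xomap.markerqc import apply_filters
from xomap.synthio import simulate_gametes, simulate_marker_set, simulate_reads

from conftest import make_depth_matrix
from oracles import best_double_split, best_single_split, enumerate_posterior


class TestBinFrequency:
    def test_bin_values_and_missing(self):
        # three 1-kbp bins: (ref 8, alt 0) -> 0.0; (3, 3) -> 0.5; empty -> NaN
        adm = make_depth_matrix(
            [[5, 3, 2, 1, 0]], [[0, 0, 1, 2, 0]],
            positions=[100, 800, 1200, 1800, 2500],
        )
        adm.ref[0, 4] = 0  # leave third bin uncovered
        track = bin_allele_frequency(adm, {"chr1": 3_000}, bin_size=1000)
        f = track.freq["chr1"][0]
        assert f[0] == 0.0
        assert f[1] == 0.5
        assert np.isnan(f[2])


class TestChangepoints:
    def test_constant_series_has_no_breakpoints(self):
        assert detect_breakpoints(np.full(50, 0.25), 1000) == []

    def test_noise_free_step_found_exactly(self):
        y = np.concatenate([np.zeros(20), np.full(30, 0.5)])
        assert detect_breakpoints(y, 1000) == [20_000]

    def test_single_split_agrees_with_exhaustive_search(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            k = rng.integers(5, 45)
            y = np.concatenate([np.zeros(k), np.full(50 - k, 0.5)])
            y += rng.normal(0, 0.03, 50)
            found = detect_breakpoints(y, 1000)
            assert found == [best_single_split(y) * 1000]

    def test_two_steps_agree_with_exhaustive_double_split(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            y = np.concatenate([np.zeros(15), np.full(15, 0.5), np.zeros(20)])
            y += rng.normal(0, 0.03, 50)
            found = detect_breakpoints(y, 1000)
            s1, s2 = best_double_split(y)
            assert found == [s1 * 1000, s2 * 1000]

    def test_all_missing_series_is_empty(self):
        assert detect_breakpoints(np.full(30, np.nan), 1000) == []

    def test_missing_bins_skipped_breakpoint_in_gap(self):
        y = np.concatenate([np.zeros(10), np.full(4, np.nan), np.full(10, 0.5)])
        (bp,) = detect_breakpoints(y, 1000)
        assert 10_000 <= bp <= 14_000


class TestHmm:
    def test_all_zero_depth_posterior_equals_prior(self):
        post = hmm_posterior(
            np.zeros(20, int), np.zeros(20, int), np.arange(20) * 1000, HmmConfig()
        )
        assert np.allclose(post, 0.5)

    def test_three_marker_posterior_matches_enumeration(self):
        cfg = HmmConfig(error_eps=0.05, switch_tau=1e-6)
        alt = np.array([0, 1, 2])
        ref = np.array([3, 1, 0])
        pos = np.array([0, 40_000, 90_000])
        post = hmm_posterior(alt, ref, pos, cfg)
        brute = enumerate_posterior(alt, ref, pos, cfg)
        assert np.abs(post - brute).max() < 1e-12

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_posterior_matches_enumeration_randomised(self, seed):
        """Forward-backward equals exhaustive path enumeration (<=10 markers)."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 11))
        depth = rng.poisson(2.0, m)
        alt = rng.binomial(depth, rng.random())
        pos = np.sort(rng.choice(2_000_000, m, replace=False))
        cfg = HmmConfig(
            error_eps=float(rng.uniform(0.001, 0.2)),
            switch_tau=float(10 ** rng.uniform(-9, -4)),
        )
        post = hmm_posterior(alt, depth - alt, pos, cfg)
        brute = enumerate_posterior(alt, depth - alt, pos, cfg)
        assert np.abs(post - brute).max() < 1e-10
        assert np.all((post >= 0) & (post <= 1))

    def test_error_free_switch_decoded_between_true_flanks(self):
        """Depth-10 error-free data: the 0.5 crossing always lands between
        the markers flanking the true switch."""
        rng = np.random.default_rng(4)
        cfg = HmmConfig(error_eps=1e-4, switch_tau=1e-6)
        for _ in range(50):
            m = 40
            pos = np.sort(rng.choice(1_000_000, m, replace=False))
            k = int(rng.integers(5, m - 5))
            states = np.zeros(m, int)
            states[k:] = 1
            depth = np.full(m, 10)
            alt = np.where(states == 1, rng.binomial(10, 0.5, m), 0)
            alt[states == 1] = np.maximum(alt[states == 1], 1)  # informative HET
            post = hmm_posterior(alt, depth - alt, pos, cfg)
            decoded = post > 0.5
            (flips,) = np.where(np.diff(decoded.astype(int)) != 0)
            assert list(flips) == [k - 1]


class TestRefineAndCall:
    def test_uniform_region_candidate_yields_no_event(self):
        rng = np.random.default_rng(5)
        m = 2000
        depth = rng.poisson(1.5, (1, m))
        alt = rng.binomial(depth, 0.01)
        adm = make_depth_matrix(depth - alt, alt, positions=np.arange(m) * 1000 + 50)
        _, events = refine_and_call(
            adm, {"chr1": 2_000_000}, {("i0", "chr1"): [1_000_000]}
        )
        assert len(events) == 0

    def test_co_in_desert_spans_the_desert(self):
        """A CO inside a polymorphism desert is called with the desert width
        as its (correct, wide) resolution."""
        rng = np.random.default_rng(6)
        pos = np.concatenate(
            [np.arange(0, 900_000, 500), np.arange(1_100_000, 2_000_000, 500)]
        )  # 200-kbp desert around the CO at 1 Mbp
        states = (pos > 1_000_000).astype(int)
        depth = rng.poisson(3.0, (1, pos.size)) + 1
        alt = rng.binomial(depth, np.where(states == 1, 0.5, 0.01))
        adm = make_depth_matrix(depth - alt, alt, positions=pos)
        _, events = refine_and_call(
            adm, {"chr1": 2_000_000}, {("i0", "chr1"): [1_000_000]}
        )
        assert len(events) == 1
        ev = events.iloc[0]
        assert ev["left_bp"] < 900_000
        assert ev["right_bp"] >= 1_100_000
        assert ev["resolution"] >= 200_000

    def test_recovery_and_interval_containment_on_small_population(self):
        cfg = SimConfig(
            chrom_lengths={"chr1": 20_000_000}, co_per_meiosis_lambda=2.0, seed=21
        )
        mk = simulate_marker_set(cfg)
        g, truth = simulate_gametes(cfg, mk, 30)
        adm = simulate_reads(g, cfg, mk)
        _, events, _ = call_crossovers(adm, cfg.chrom_lengths)
        res = xomap.match_events(truth.co, events, min_truth_spacing=1_000_000)
        assert res["sensitivity"] >= 0.9
        assert res["precision"] >= 0.9
        assert res["containment"] >= 0.95

    def test_wider_coverage_never_worsens_median_resolution(self):
        """Median called-interval width is non-increasing in coverage."""
        medians = []
        for lam in (1.0, 3.0):
            cfg = SimConfig(
                chrom_lengths={"chr1": 10_000_000},
                co_per_meiosis_lambda=1.0,
                coverage_lambda=lam,
                seed=23,
            )
            mk = simulate_marker_set(cfg)
            g, _ = simulate_gametes(cfg, mk, 40)
            adm = simulate_reads(g, cfg, mk)
            _, events, _ = call_crossovers(adm, cfg.chrom_lengths)
            medians.append(events["resolution"].median())
        assert medians[1] <= medians[0]

    def test_structural_noise_region_produces_no_calls(self):
        """Clustered spurious-het noise is removed by QC and never becomes a
        crossover call, even with candidates planted on it."""
        cfg = SimConfig(
            chrom_lengths={"chr1": 10_000_000},
            co_per_meiosis_lambda=0.0,
            noise_spec=[xomap.NoiseSpec("chr1", 4_000_000, 4_200_000, alt_bias=0.5)],
            seed=25,
        )
        mk = simulate_marker_set(cfg)
        g, _ = simulate_gametes(cfg, mk, 100)
        adm = simulate_reads(g, cfg, mk)
        flagged, _ = apply_filters(adm)
        pos = mk.positions("chr1")
        in_noise = (pos >= 4_000_000) & (pos < 4_200_000)
        assert flagged.pass_mask[in_noise].mean() < 0.1  # AF filter catches it
        _, events, _ = call_crossovers(
            adm, cfg.chrom_lengths, pass_mask=flagged.pass_mask
        )
        assert len(events) == 0


class TestBookkeeping:
    @pytest.mark.parametrize(
        "total,n,expected",
        [(1164, 135, 17.2), (1139, 122, 18.7), (0, 50, 0.0)],
    )
    def test_cos_per_meiosis(self, total, n, expected):
        assert cos_per_meiosis(total, n, ndigits=1) == expected

    def test_cos_per_meiosis_rejects_empty_population(self):
        with pytest.raises(ValueError):
            cos_per_meiosis(10, 0)

    def test_resolution_summary_matches_direct_recount(self):
        rng = np.random.default_rng(8)
        res = rng.integers(100, 10_000, 200)
        events = events_frame(
            [
                {
                    "individual": f"i{k}",
                    "chrom": "chr1",
                    "left_bp": 0,
                    "right_bp": int(r),
                    "midpoint": 0,
                    "resolution": 0,
                    "sex": "male" if k % 2 else "female",
                }
                for k, r in enumerate(res)
            ]
        )
        summ = resolution_summary(events, thresholds=(2000, 5000))
        assert summ["thresholds"][2000]["n_le"] == int((res <= 2000).sum())
        assert summ["thresholds"][5000]["n_le"] == int((res <= 5000).sum())

    def test_resolution_summary_empty_events_error(self):
        with pytest.raises(ValueError):
            resolution_summary(events_frame())

    def test_all_resolutions_above_threshold_count_zero(self):
        events = events_frame(
            [
                {
                    "individual": "i0",
                    "chrom": "chr1",
                    "left_bp": 0,
                    "right_bp": 10_000,
                    "midpoint": 0,
                    "resolution": 0,
                    "sex": None,
                }
            ]
        )
        assert resolution_summary(events)["thresholds"][2000]["n_le"] == 0
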