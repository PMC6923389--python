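"""The position-local background-noise test: difference track, windowed
null, tail test, thresholds and region-level calling."""

import numpy as np
import pytest
from scipy.stats import norm

from adenoclone.caller import (
    BackgroundModel,
    CallerConfig,
    DegenerateBackgroundError,
    DifferenceTrack,
    RegionMismatchError,
    TdsNoiseModel,
    _upper_tail_p,
    call_region,
    difference_track,
    fit_background,
)
from adenoclone.caller import test_position as evaluate_position
from adenoclone.pileup import ALLELE_INDEX, TargetRegion, compute_vaf
from adenoclone.simulate import _alt_for, reference_for_region, simulate_amplicon

from conftest import make_counts


def profiles_from(region, lesion_spec, control_spec, depth=10_000):
    lesion = compute_vaf(make_counts("L", region, lesion_spec, depth=depth))
    control = compute_vaf(make_counts("N", region, control_spec, depth=depth))
    return lesion, control


def make_track(d_values, region_id="R", start=0, defined=None):
    d = np.asarray(d_values, dtype=float)
    if defined is None:
        defined = ~np.isnan(d)
    return DifferenceTrack(
        region_id=region_id,
        positions=np.arange(start, start + d.shape[0]),
        d=d,
        alt_index=np.ones(d.shape[0], dtype=np.int64),
        defined=np.asarray(defined),
    )


class TestDifferenceTrack:
    def test_identical_profiles_give_zero(self, small_region):
        lesion, control = profiles_from(
            small_region, {3: {"C": 0.05}}, {3: {"C": 0.05}}
        )
        track = difference_track(lesion, control)
        np.testing.assert_allclose(track.d, 0.0, atol=1e-15)

    def test_forced_arithmetic(self, small_region):
        lesion, control = profiles_from(
            small_region, {5: {"C": 0.10}}, {5: {"C": 0.01}}
        )
        track = difference_track(lesion, control)
        assert track.d[5] == pytest.approx(0.09, abs=1e-12)
        assert track.alt_index[5] == ALLELE_INDEX["C"]

    def test_matches_per_allele_brute_force(self, small_region, rng):
        for _ in range(10):
            spec_l = {
                i: {a: f for a, f in zip("CGT", rng.dirichlet([1, 1, 1, 5])[:3] * 0.2)}
                for i in range(len(small_region))
            }
            spec_n = {
                i: {a: f for a, f in zip("CGT", rng.dirichlet([1, 1, 1, 5])[:3] * 0.2)}
                for i in range(len(small_region))
            }
            lesion, control = profiles_from(small_region, spec_l, spec_n)
            track = difference_track(lesion, control)
            brute = np.max(np.abs(lesion.vaf - control.vaf), axis=1)
            np.testing.assert_allclose(track.d, brute, atol=1e-15)

    def test_symmetric_under_sample_swap(self, small_region):
        lesion, control = profiles_from(
            small_region, {2: {"G": 0.07}}, {9: {"T": 0.002}}
        )
        forward = difference_track(lesion, control)
        backward = difference_track(control, lesion)
        np.testing.assert_allclose(forward.d, backward.d, atol=1e-15)

    def test_region_mismatch_rejected(self, small_region):
        other = TargetRegion("AMP2", "chr3", 1000, 1020)
        lesion, _ = profiles_from(small_region, {}, {})
        _, control = profiles_from(other, {}, {})
        with pytest.raises(RegionMismatchError):
            difference_track(lesion, control)


class TestFitBackground:
    def test_constant_window_gives_zero_sd(self):
        track = make_track([0.004] * 11)
        bg = fit_background(track, 5)
        assert bg.mu == pytest.approx(0.004)
        assert bg.sigma == pytest.approx(0.0, abs=1e-15)
        assert bg.n_window == 10

    def test_three_value_window_oracle(self):
        # window {0.001, 0.002, 0.003}: mu = 0.002, population SD =
        # sqrt(2/3) * 0.001
        track = make_track([0.001, 0.002, 0.05, 0.003])
        bg = fit_background(track, 2)
        assert bg.mu == pytest.approx(0.002, abs=1e-15)
        assert bg.sigma == pytest.approx(np.sqrt(2 / 3) * 0.001, abs=1e-12)

    def test_sample_sd_option(self):
        track = make_track([0.001, 0.002, 0.05, 0.003])
        bg = fit_background(track, 2, CallerConfig(sd_ddof=1))
        assert bg.sigma == pytest.approx(0.001, abs=1e-12)

    def test_edge_window_truncated_not_padded(self):
        track = make_track(np.linspace(0.001, 0.002, 30))
        bg = fit_background(track, 0, CallerConfig(K=10))
        assert bg.n_window == 10  # only right-hand neighbours exist

    def test_excludes_tested_position(self):
        # a huge d at j must not contaminate its own background
        d = np.full(21, 0.001)
        d[10] = 0.9
        bg = fit_background(make_track(d), 10)
        assert bg.mu == pytest.approx(0.001)
        assert bg.sigma == pytest.approx(0.0, abs=1e-15)

    def test_degenerate_background_carries_position(self):
        track = make_track(
            [0.001, 0.005, np.nan, 0.002], defined=[True, True, False, True]
        )
        with pytest.raises(DegenerateBackgroundError) as err:
            fit_background(track, 1, CallerConfig(K=1))  # window: {d_0, d_2}
        assert err.value.position == 1

    def test_matches_naive_recomputation_on_random_tracks(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 60))
            d = rng.gamma(2.0, 5e-4, size=n)
            drop = rng.random(n) < 0.1
            d[drop] = np.nan
            track = make_track(d, defined=~drop)
            K = int(rng.integers(2, n + 5))
            cfg = CallerConfig(K=K)
            for j in np.flatnonzero(~drop):
                window = np.r_[d[max(0, j - K) : j], d[j + 1 : j + K + 1]]
                window = window[~np.isnan(window)]
                if window.size < 2:
                    continue
                bg = fit_background(track, j, cfg)
                assert bg.mu == pytest.approx(window.mean(), abs=1e-14)
                assert bg.sigma == pytest.approx(window.std(ddof=0), abs=1e-14)
                assert bg.n_window == window.size


class TestTestPosition:
    def _setup(self, lesion_spec, control_spec, region=None):
        region = region or TargetRegion("AMP1", "chr12", 1000, 1020)
        lesion, control = profiles_from(region, lesion_spec, control_spec)
        track = difference_track(lesion, control)
        return track, lesion, control

    def test_two_sigma_exceedance(self):
        track, lesion, control = self._setup({5: {"C": 0.002}}, {})
        bg = BackgroundModel(position=1005, K=20, mu=0.001, sigma=0.0005, n_window=19)
        call = evaluate_position(track, bg, lesion, control, 1005)
        # z = (0.002 - 0.001) / 0.0005 = 2
        assert call.p_value == pytest.approx(norm.sf(2.0), abs=1e-9)
        assert call.p_value == pytest.approx(0.02275, abs=1e-5)
        assert call.p_pass and call.d_pass and call.control_pass and call.verdict

    def test_small_difference_fails_d_min(self):
        track, lesion, control = self._setup({5: {"C": 0.0005}}, {})
        bg = BackgroundModel(position=1005, K=20, mu=0.0, sigma=1e-5, n_window=19)
        call = evaluate_position(track, bg, lesion, control, 1005)
        assert call.p_pass
        assert not call.d_pass
        assert not call.verdict

    def test_noisy_control_fails_control_gate(self):
        track, lesion, control = self._setup(
            {5: {"C": 0.10}}, {5: {"C": 0.02}}
        )
        bg = BackgroundModel(position=1005, K=20, mu=0.001, sigma=0.0005, n_window=19)
        call = evaluate_position(track, bg, lesion, control, 1005)
        assert call.p_pass and call.d_pass
        assert not call.control_pass
        assert not call.verdict

    def test_zero_sigma_point_mass_rule(self):
        assert _upper_tail_p(0.002, 0.001, 0.0) == 0.0
        assert _upper_tail_p(0.0005, 0.001, 0.0) == 1.0
        assert _upper_tail_p(0.001, 0.001, 0.0) == 1.0

    def test_p_monotone_nonincreasing_in_d(self):
        ds = np.linspace(0, 0.01, 50)
        ps = [_upper_tail_p(d, 0.002, 0.0007) for d in ds]
        assert all(p2 <= p1 + 1e-15 for p1, p2 in zip(ps, ps[1:]))

    def test_verdict_not_symmetric_under_swap(self):
        # lesion carries the variant; swapping samples must flip the
        # control gate even though d is symmetric.
        region = TargetRegion("AMP1", "chr12", 1000, 1020)
        lesion, control = profiles_from(region, {5: {"C": 0.10}}, {})
        bg = BackgroundModel(position=1005, K=20, mu=0.001, sigma=0.0005, n_window=19)
        fwd = evaluate_position(
            difference_track(lesion, control), bg, lesion, control, 1005
        )
        rev = evaluate_position(
            difference_track(control, lesion), bg, control, lesion, 1005
        )
        assert fwd.d == pytest.approx(rev.d)
        assert fwd.verdict
        assert not rev.control_pass
        assert not rev.verdict


class TestCallRegion:
    def test_deterministic_for_fixed_input(self, small_region):
        lesion = make_counts("L", small_region, {4: {"T": 0.03}})
        control = make_counts("N", small_region, {})
        one = call_region(lesion, control, small_region)
        two = call_region(lesion, control, small_region)
        assert one == two

    def test_candidate_restriction(self, small_region):
        lesion = make_counts("L", small_region, {4: {"T": 0.03}})
        control = make_counts("N", small_region, {})
        calls = call_region(lesion, control, small_region, positions=[1004, 1007])
        assert [c.pos for c in calls] == [1004, 1007]

    def test_verdict_set_shrinks_with_tighter_thresholds(self):
        region = TargetRegion("AMP1", "chr12", 1000, 1250)
        ref = reference_for_region(region)
        alt1, alt2 = _alt_for(ref[100]), _alt_for(ref[200])
        lesion = simulate_amplicon(
            region, 10_000, spikes=[(1100, alt1, 0.03), (1200, alt2, 0.005)], seed=5,
            sample_id="L",
        )
        control = simulate_amplicon(region, 10_000, seed=6, sample_id="N")
        base = {
            c.pos
            for c in call_region(lesion, control, region)
            if c.verdict
        }
        for cfg in (
            CallerConfig(alpha=0.005),
            CallerConfig(d_min=0.01),
            CallerConfig(control_vaf_max=0.001),
        ):
            tighter = {
                c.pos
                for c in call_region(lesion, control, region, cfg)
                if c.verdict
            }
            assert tighter <= base

    def test_bonferroni_never_adds_calls(self):
        region = TargetRegion("AMP1", "chr12", 1000, 1250)
        alt = _alt_for(reference_for_region(region)[100])
        lesion = simulate_amplicon(region, 10_000, spikes=[(1100, alt, 0.03)], seed=7)
        control = simulate_amplicon(region, 10_000, seed=8)
        plain = {c.pos for c in call_region(lesion, control, region) if c.verdict}
        bonf = {
            c.pos
            for c in call_region(
                lesion, control, region, CallerConfig(bonferroni=True)
            )
            if c.verdict
        }
        assert bonf <= plain
        assert 1100 in bonf  # a 3% spike at depth 10,000 survives correction

    def test_spike_detected_across_seeds(self):
        region = TargetRegion("AMP1", "chr12", 1000, 1250)
        hits = 0
        for seed in range(20):
            alt = _alt_for(reference_for_region(region)[125])
            lesion = simulate_amplicon(
                region, 10_000, spikes=[(1125, alt, 0.03)], seed=seed, sample_id="L"
            )
            control = simulate_amplicon(region, 10_000, seed=1000 + seed, sample_id="N")
            [call] = call_region(lesion, control, region, positions=[1125])
            hits += call.verdict
        assert hits >= 19

    def test_no_overlap_rejected(self, small_region):
        lesion = make_counts("L", small_region, {})
        control = make_counts("N", small_region, {})
        other = TargetRegion("ELSEWHERE", "chr9", 5000, 5100)
        with pytest.raises(RegionMismatchError):
            TdsNoiseModel(lesion, control, other)


class TestCalibration:
    def test_type_one_error_on_gaussian_noise(self):
        """Under a Gaussian-like difference track, the p_pass flag fires
        at close to the nominal 5% rate (10,000 tested positions)."""
        rng = np.random.default_rng(0)
        cfg = CallerConfig()
        fired = total = 0
        for _ in range(40):
            d = rng.normal(0.005, 0.0005, size=250)  # strictly positive
            track = make_track(d)
            for j in range(250):
                bg = fit_background(track, j, cfg)
                p = _upper_tail_p(track.d[j], bg.mu, bg.sigma)
                fired += p < cfg.alpha
                total += 1
        assert total == 10_000
        assert 0.03 <= fired / total <= 0.07


class TestModelResults:
    def test_summary_reports_somatic_calls(self, small_region):
        lesion = make_counts("L", small_region, {4: {"T": 0.05}})
        control = make_counts("N", small_region, {})
        results = TdsNoiseModel(lesion, control, small_region).fit()
        text = results.summary()
        assert "somatic calls" in text
        assert "1004" in text
        frame = results.to_frame()
        assert len(frame) == len(results.calls)
        assert frame["verdict"].sum() == len(results.somatic)
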