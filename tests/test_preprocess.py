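"""Denoising chain: Butterworth, Kalman machinery, spike repair, MAD."""

import numpy as np
import pytest

from handkin import (
    SmoothingConfig,
    butterworth_lowpass,
    detect_misestimated_frames,
    ensemble_kalman_smooth,
    mad,
    optimize_smoother_hyperparams,
    preprocess_chain,
    repair_frames,
)
from handkin.preprocess import DegenerateSeriesWarning, PreprocessError


def sinusoid(n=300, fps=30.0, amp=40.0, freq=1.0, base=50.0):
    t = np.arange(n) / fps
    return base + amp * np.sin(2 * np.pi * freq * t)


class TestButterworth:
    def test_constant_unchanged(self, series_factory):
        s = series_factory(np.full(100, 33.0))
        out = butterworth_lowpass(s)
        np.testing.assert_allclose(out.angles, 33.0, atol=1e-9)

    def test_sinusoid_gain_matches_analytic_response(self, series_factory):
        # zero-phase filtering applies |H(f)|^2 of the single-pass 2nd-order
        # Butterworth: |H|^2 = 1 / (1 + (f / fc)^4)
        fps, f, fc = 30.0, 1.0, 12.0
        s = series_factory(sinusoid(n=3000, fps=fps, amp=40.0, freq=f, base=0.0), fps=fps)
        out = butterworth_lowpass(s)
        measured = out.angles[1000:2000].max() / s.angles[1000:2000].max()
        analytic = 1.0 / (1.0 + (f / fc) ** 4)
        assert measured == pytest.approx(analytic, rel=0.05)

    def test_cutoff_above_nyquist_rejected(self, series_factory):
        s = series_factory(np.zeros(100), fps=20.0)  # Nyquist 10 < 12
        with pytest.raises(PreprocessError):
            butterworth_lowpass(s)

    def test_too_short_rejected(self, series_factory):
        with pytest.raises(PreprocessError):
            butterworth_lowpass(series_factory(np.zeros(5)))


class TestHyperparameterSearch:
    def test_noiseless_ramp_selects_smallest_r(self, series_factory):
        s = series_factory(np.linspace(0, 40, 200))
        r, _ = optimize_smoother_hyperparams(s)
        assert r == min(SmoothingConfig().meas_noise_grid)

    def test_white_noise_recovers_sigma_within_one_grid_step(self, series_factory):
        grid = SmoothingConfig().meas_noise_grid  # log10-spaced: 0.01 .. 100
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            s = series_factory(20 + rng.normal(0, 1.0, 150))
            r, _ = optimize_smoother_hyperparams(s)
            # true sigma^2 = 1; one grid step on either side
            hits += r in (0.1, 1.0, 10.0)
        assert hits >= 40
        assert set(grid) >= {0.1, 1.0, 10.0}

    def test_single_candidate_grid_forced(self, series_factory):
        cfg = SmoothingConfig(meas_noise_grid=(2.5,), proc_noise_grid=(0.3,))
        s = series_factory(np.sin(np.arange(100)) * 5 + 50)
        assert optimize_smoother_hyperparams(s, cfg) == (2.5, 0.3)

    def test_degenerate_series_warns_and_returns_minimum(self, series_factory):
        s = series_factory(np.full(100, 7.0))
        with pytest.warns(DegenerateSeriesWarning):
            r, q = optimize_smoother_hyperparams(s)
        cfg = SmoothingConfig()
        assert (r, q) == (min(cfg.meas_noise_grid), min(cfg.proc_noise_grid))

    def test_too_short_for_cv_rejected(self, series_factory):
        with pytest.raises(PreprocessError):
            optimize_smoother_hyperparams(series_factory(np.arange(30.0)))


class TestEnsembleKalman:
    def test_constant_series_reproduced(self, series_factory):
        s = series_factory(np.full(200, 30.0))
        out = ensemble_kalman_smooth(s, R=1.0, Q=0.0)
        np.testing.assert_allclose(out.angles, 30.0, atol=1e-6)

    def test_white_noise_variance_contracts(self, rng, series_factory):
        s = series_factory(rng.normal(0, 1, 500))
        out = ensemble_kalman_smooth(s, R=1.0, Q=0.01)
        assert np.var(out.angles) < np.var(s.angles)

    def test_two_way_pass_beats_forward_only(self, series_factory):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            clean = sinusoid(n=300, freq=0.5)
            s = series_factory(clean + rng.normal(0, 2, 300))
            cfg = SmoothingConfig(seed=seed)
            sm = ensemble_kalman_smooth(s, R=4.0, Q=0.05, config=cfg)
            fl = ensemble_kalman_smooth(s, R=4.0, Q=0.05, config=cfg, return_filtered=True)
            wins += np.mean((sm.angles - clean) ** 2) <= np.mean((fl.angles - clean) ** 2)
        assert wins >= 18

    def test_deterministic_given_seed(self, rng, series_factory):
        s = series_factory(rng.normal(50, 2, 100))
        a = ensemble_kalman_smooth(s, R=1.0, Q=0.01)
        b = ensemble_kalman_smooth(s, R=1.0, Q=0.01)
        np.testing.assert_array_equal(a.angles, b.angles)

    def test_invalid_noise_rejected(self, series_factory):
        s = series_factory(np.zeros(50))
        with pytest.raises(PreprocessError):
            ensemble_kalman_smooth(s, R=0.0, Q=0.1)


class TestMisestimationDetection:
    def test_single_spike_on_constant_attributed_to_spiked_frame(self, series_factory):
        x = np.full(60, 5.0)
        x[20] += 100.0
        flags = detect_misestimated_frames(series_factory(x))
        assert flags.flagged == {20}

    def test_constant_series_no_flags(self, series_factory):
        flags = detect_misestimated_frames(series_factory(np.full(50, 3.0)))
        assert flags.flagged == frozenset()

    def test_gaussian_null_flag_rate_below_one_percent(self, series_factory):
        rng = np.random.default_rng(42)
        flags = detect_misestimated_frames(series_factory(rng.normal(0, 1, 10000)))
        assert 0 <= len(flags.flagged) / 10000 < 0.01

    def test_offset_invariance(self, rng, series_factory):
        x = rng.normal(0, 1, 500)
        x[100] += 30
        f1 = detect_misestimated_frames(series_factory(x))
        f2 = detect_misestimated_frames(series_factory(x + 1000.0))
        assert f1.flagged == f2.flagged

    def test_monotone_detection_power(self, rng, series_factory):
        x = rng.normal(0, 1, 300)
        for amp in (1e3, 1e6, 1e9):
            y = x.copy()
            y[150] += amp
            assert 150 in detect_misestimated_frames(series_factory(y)).flagged

    def test_flagged_indices_exceed_threshold(self, rng, series_factory):
        x = rng.normal(0, 1, 400)
        x[[50, 200, 344]] += 25
        flags = detect_misestimated_frames(series_factory(x))
        for i in flags.flagged:
            assert np.abs(x[i] - x[i - 1]) > flags.threshold


class TestRepair:
    def test_linear_midpoint_before_spline(self, series_factory):
        from handkin.preprocess import FrameFlagResult

        s = series_factory([0.0, 50.0, 2.0])
        flags = FrameFlagResult(
            dx=np.abs(np.diff(s.angles)), mean_dx=0.0, sd_dx=0.0, flagged=frozenset({1})
        )
        out = repair_frames(s, flags, spline=False)
        np.testing.assert_allclose(out.angles, [0.0, 1.0, 2.0])

    def test_no_flags_near_identity_on_smooth_input(self, series_factory):
        s = series_factory(sinusoid(n=300))
        flags = detect_misestimated_frames(s)
        out = repair_frames(s, flags)
        assert np.max(np.abs(out.angles - s.angles)) < 0.5

    def test_spike_injection_recovery(self, series_factory):
        clean = sinusoid(n=600, freq=1.0, amp=45.0)
        x = clean.copy()
        sd = np.abs(np.diff(clean)).std()
        spikes = [77, 150, 301, 442, 555]
        for i in spikes:
            x[i] += 10 * sd * (1 if i % 2 else -1)
        s = series_factory(x)
        flags = detect_misestimated_frames(s)
        assert set(spikes) <= flags.flagged
        out = repair_frames(s, flags)
        assert np.max(np.abs(out.angles - clean)) < 3.0

    def test_all_frames_flagged_rejected(self, series_factory):
        from handkin.preprocess import FrameFlagResult

        s = series_factory([1.0, 2.0, 3.0])
        flags = FrameFlagResult(dx=np.ones(2), mean_dx=0, sd_dx=0, flagged=frozenset({0, 1, 2}))
        with pytest.raises(PreprocessError):
            repair_frames(s, flags)


class TestMad:
    @pytest.mark.parametrize("values,expected", [([1, 1, 1], 0.0), ([0, 2], 1.0)])
    def test_worked_examples(self, series_factory, values, expected):
        assert mad(series_factory(values)) == expected

    def test_gaussian_identity(self):
        # E|X - mu| = sigma * sqrt(2/pi); sigma chosen so the MAD is 2.46
        sigma = 2.46 * np.sqrt(np.pi / 2)
        rng = np.random.default_rng(7)
        x = rng.normal(0, sigma, 10000)
        assert mad(x) == pytest.approx(2.46, rel=0.05)


class TestChain:
    def test_constant_series_passes_through(self, series_factory):
        s = series_factory(np.full(300, 42.0))
        res = preprocess_chain(s)
        assert len(res.series) == 300
        np.testing.assert_allclose(res.series.angles, 42.0, atol=1e-6)

    def test_chain_is_length_preserving(self, rng, series_factory):
        s = series_factory(sinusoid(n=450) + rng.normal(0, 2, 450))
        res = preprocess_chain(s)
        assert len(res.series) == 450

    def test_noise_mad_halved_on_no_motion_series(self, series_factory):
        sigma = 2.46 * np.sqrt(np.pi / 2)
        rng = np.random.default_rng(0)
        s = series_factory(50 + rng.normal(0, sigma, 600))
        res = preprocess_chain(s)
        assert res.mad_processed <= 0.5 * res.mad_raw
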