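"""Filtering, baselining, thresholding, and movement-epoch detection."""

import numpy as np
import pytest

from dgspace import (
    lowpass_filter,
    movement_epochs,
    rolling_baseline,
    threshold_events,
    threshold_traces,
)

from conftest import make_track


class TestLowpassFilter:
    def test_dc_gain_is_one(self):
        out = lowpass_filter(np.full(500, 3.7), frame_rate=15.253, cutoff=2.0)
        assert np.abs(out - 3.7).max() < 1e-9

    def test_attenuation_matches_squared_butterworth_response(self):
        # forward-backward pass squares the single-pass magnitude response
        # (sample fast relative to the cutoff so bilinear warping is negligible
        # and the analog closed form is the right oracle)
        fr, cutoff, order, f = 1000.0, 2.0, 3, 6.0
        t = np.arange(60000) / fr
        out = lowpass_filter(np.sin(2 * np.pi * f * t), fr, cutoff, order)
        expected = 1.0 / (1.0 + (f / cutoff) ** (2 * order))
        peak = np.abs(out[20000:40000]).max()  # interior, away from edges
        assert peak == pytest.approx(expected, rel=0.05)

    def test_zero_phase_time_reversal_symmetry(self, rng):
        x = rng.normal(size=1000)
        a = lowpass_filter(x, 15.253, 2.0)
        b = lowpass_filter(x[::-1], 15.253, 2.0)[::-1]
        assert np.abs(a - b).max() < 1e-9

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(100), frame_rate=10.0, cutoff=6.0)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(10), frame_rate=10.0, cutoff=2.0, order=3)


class TestRollingBaseline:
    def test_constant_trace(self):
        out = rolling_baseline(np.full(100, 2.5), frame_rate=1.0, window=7.0)
        assert np.abs(out - 2.5).max() < 1e-12

    def test_linear_ramp_interior_is_exact(self):
        x = np.arange(100.0)
        out = rolling_baseline(x, frame_rate=1.0, window=7.0)
        assert np.abs(out[3:-3] - x[3:-3]).max() < 1e-9

    def test_matches_brute_force_truncated_windows(self, rng):
        # centred window [i-(w-1)//2, i+w//2], truncated at the edges
        for _ in range(20):
            n = int(rng.integers(5, 60))
            w = int(rng.integers(1, 12))
            x = rng.normal(size=n)
            out = rolling_baseline(x, frame_rate=1.0, window=float(w))
            for i in range(n):
                lo = max(0, i - (w - 1) // 2)
                hi = min(n - 1, i + w // 2)
                assert out[i] == pytest.approx(np.mean(x[lo : hi + 1]), rel=1e-10)


class TestThresholdTraces:
    def test_constant_trace_is_degenerate(self):
        res = threshold_traces(np.full((1, 200), 5.0), 10.0, window=3.0)
        assert np.all(res.supra == 0) and res.degenerate[0]

    def test_white_noise_suprathreshold_fraction_matches_gaussian_tail(self, rng):
        # with a very long baseline window the baseline is ~0 and sigma ~1,
        # so P(supra > 0) ~ P(Z > 2) = 0.0228
        from scipy.stats import norm

        n = 10_000
        x = rng.normal(size=(1, n))
        res = threshold_traces(x, frame_rate=1.0, window=float(n * 2), k=2.0)
        frac = (res.supra > 0).mean()
        p = norm.sf(2.0)
        assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_rectangular_transient_matches_hand_computation(self):
        # flat zero trace with one rectangular transient; brute-force the
        # definition (truncated rolling mean, residual SD, subtract k*sigma)
        n, w = 400, 101
        x = np.zeros(n)
        x[200:210] = 1.0
        res = threshold_traces(x[None, :], frame_rate=1.0, window=float(w), k=2.0)
        base = np.array(
            [
                np.mean(x[max(0, i - (w - 1) // 2) : min(n - 1, i + w // 2) + 1])
                for i in range(n)
            ]
        )
        sigma = (x - base).std()
        expected = np.maximum(0.0, x - base - 2 * sigma)
        assert np.abs(res.supra[0] - expected).max() < 1e-12
        # transient stands h - k*sigma - baseline above threshold inside
        assert np.all(res.supra[0, 202:208] > 0)

    def test_scale_equivariance(self, rng):
        x = rng.normal(size=(3, 300))
        a = threshold_traces(x, 10.0, window=5.0)
        b = threshold_traces(2.5 * x, 10.0, window=5.0)
        assert np.allclose(b.supra, 2.5 * a.supra)
        assert np.allclose(b.sigma, 2.5 * a.sigma)

    def test_supra_mass_nonincreasing_in_k(self, rng):
        x = rng.normal(size=(2, 500))
        masses = [
            threshold_traces(x, 10.0, window=5.0, k=k).supra.sum()
            for k in (1.0, 2.0, 3.0)
        ]
        assert masses[0] >= masses[1] >= masses[2]


class TestThresholdEvents:
    def test_all_zero_rows_stay_zero(self):
        res = threshold_events(np.zeros((2, 50)))
        assert np.all(res.supra == 0) and np.all(res.degenerate)

    def test_sparse_large_events_pass_unchanged(self):
        ev = np.zeros((1, 1000))
        ev[0, ::100] = 5.0  # sparse: RMS sigma well below amplitude/2
        res = threshold_events(ev, k=2.0)
        assert np.array_equal(res.supra, ev)

    def test_mixed_amplitudes_match_elementwise_rule(self, rng):
        ev = np.where(rng.uniform(size=(3, 400)) < 0.1, rng.gamma(2, 1, (3, 400)), 0.0)
        res = threshold_events(ev, k=2.0)
        for c in range(3):
            sigma = np.sqrt(np.mean(ev[c] ** 2))
            expected = np.array([v if v > 2 * sigma else 0.0 for v in ev[c]])
            assert np.array_equal(res.supra[c], expected)
        # gated, not subtracted: surviving values keep full amplitude
        kept = res.supra[res.supra > 0]
        assert np.all(np.isin(kept, ev))


class TestMovementEpochs:
    def test_stationary_has_no_epochs(self):
        mask = movement_epochs(make_track(np.full(100, 10.0)), 1.0, 1.0)
        assert mask.epochs == () and not mask.moving.any()

    def test_continuous_running_is_one_epoch(self):
        n = 9152  # ~10 min at 15.253 fps
        time = np.arange(n) / 15.253
        pos = np.mod(20.0 * time, 180.0)
        track = make_track(pos, time)
        mask = movement_epochs(track, 1.0, 1.0)
        assert mask.epochs == ((0, n),) and mask.moving.all()

    def test_short_alternating_runs_are_discarded(self):
        # 0.5 s moving / 0.5 s still at 10 fps; all runs <= 1 s
        fr = 10.0
        block = np.concatenate([np.full(5, 2.0), np.zeros(5)])
        speed = np.tile(block, 20)
        pos = np.mod(np.concatenate([[0.0], np.cumsum(speed[:-1] / fr)]), 180.0)
        track = make_track(pos, np.arange(speed.size) / fr)
        mask = movement_epochs(track, speed_threshold=1.0, min_duration=1.0)
        # brute-force run-length check on the candidate mask
        cand = track.speed > 1.0
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, cand, 0])))[::2]
        assert (runs / fr <= 1.0).all()
        assert mask.epochs == ()

    def test_no_cross_boundary_runs_when_concatenating_masks(self, rng):
        # epochs found separately on two halves agree with restricting each
        # half's own computation (no run can span the boundary)
        fr = 10.0
        speed = np.where(rng.uniform(size=300) < 0.6, 5.0, 0.0)
        pos = np.mod(np.concatenate([[0.0], np.cumsum(speed[:-1] / fr)]), 180.0)
        t = np.arange(300) / fr
        full_a = movement_epochs(make_track(pos[:150], t[:150]), 1.0, 1.0)
        pos2 = np.mod(
            np.concatenate([[0.0], np.cumsum(speed[150:-1] / fr)]), 180.0
        )
        full_b = movement_epochs(make_track(pos2, t[:150]), 1.0, 1.0)
        # each epoch lies fully within its own half
        for s, e in full_a.epochs:
            assert 0 <= s < e <= 150
        for s, e in full_b.epochs:
            assert 0 <= s < e <= 150
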