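"""Occupancy maps, tuning vectors, circular tuning index, lap rasters."""

import numpy as np
import pytest
from scipy.special import i0, i1

from dgspace import (
    lap_raster,
    occupancy_map,
    select_top_fi_cells,
    tuning_index,
    tuning_vector,
)
from dgspace.preprocess import MovementMask, ThresholdedTraces
from dgspace.tuning import RasterError, position_bins

from conftest import constant_speed_track, make_track

BELT = 180.0


def all_moving(n):
    return MovementMask(np.ones(n, dtype=bool), ((0, n),))


def _thr(supra):
    supra = np.atleast_2d(np.asarray(supra, dtype=float))
    return ThresholdedTraces(
        supra, np.zeros_like(supra), np.ones(supra.shape[0]), "events",
        np.zeros(supra.shape[0], dtype=bool),
    )


class TestOccupancy:
    def test_parked_mouse_has_zero_occupancy(self):
        track = make_track(np.full(100, 20.0))
        mask = MovementMask(np.zeros(100, dtype=bool), ())
        assert occupancy_map(track, mask, 100, BELT).sum() == 0

    def test_single_moving_frame_at_origin(self):
        track = constant_speed_track(20.0, n_frames=10)
        moving = np.zeros(10, dtype=bool)
        moving[0] = True
        occ = occupancy_map(track, MovementMask(moving, ((0, 1),)), 100, BELT)
        assert occ[0] > 0 and occ[1:].sum() == 0

    def test_uniform_motion_gives_near_equal_occupancy(self):
        # speed incommensurate with the bin width so laps drift in phase
        track = constant_speed_track(18.049, n_frames=20000, frame_rate=10.0)
        occ = occupancy_map(track, all_moving(20000), 100, BELT)
        assert occ.max() / occ.min() < 1.05

    def test_total_occupancy_equals_moving_time(self):
        track = constant_speed_track(20.0, n_frames=500, frame_rate=10.0)
        mask = all_moving(500)
        occ = occupancy_map(track, mask, 100, BELT)
        assert occ.sum() == pytest.approx(track.frame_dt()[mask.moving].sum(), abs=1e-9)


class TestTuningVector:
    def test_activity_in_one_bin_gives_indicator_weights(self):
        track = constant_speed_track(20.0, n_frames=900, frame_rate=10.0)
        bins = position_bins(track.position, BELT, 100)
        supra = np.where(bins == 40, 1.0, 0.0)[None, :]
        res = tuning_vector(_thr(supra), track, all_moving(900), 100, BELT)
        assert res.defined[0]
        assert res.weights[0, 40] == pytest.approx(1.0)
        assert res.tuning_index[0] == pytest.approx(1.0)
        assert res.preferred_bin[0] == 40

    def test_activity_proportional_to_occupancy_is_uniform(self):
        track = constant_speed_track(20.0, n_frames=5000, frame_rate=10.0)
        res = tuning_vector(_thr(np.ones((1, 5000))), track, all_moving(5000), 100, BELT)
        occupied = res.occupancy > 0
        assert np.allclose(res.weights[0, occupied], 1.0 / occupied.sum())

    def test_silent_cell_is_flagged_not_raised(self):
        track = constant_speed_track(20.0, n_frames=100, frame_rate=10.0)
        res = tuning_vector(_thr(np.zeros((1, 100))), track, all_moving(100), 100, BELT)
        assert not res.defined[0] and np.isnan(res.tuning_index[0])

    def test_matches_brute_force_accumulation(self, rng):
        track = constant_speed_track(17.0, n_frames=800, frame_rate=10.0)
        supra = np.where(rng.uniform(size=(2, 800)) < 0.05, rng.gamma(2, 1, (2, 800)), 0)
        moving = rng.uniform(size=800) < 0.7
        mask = MovementMask(moving, ())
        res = tuning_vector(_thr(supra), track, mask, 100, BELT)
        bins = position_bins(track.position, BELT, 100)
        dt = track.frame_dt()
        for c in range(2):
            num = np.zeros(100)
            occ = np.zeros(100)
            for t in range(800):
                if moving[t]:
                    num[bins[t]] += supra[c, t] * dt[t]
                    occ[bins[t]] += dt[t]
            rate = np.where(occ > 0, num / np.where(occ > 0, occ, 1), 0.0)
            assert np.allclose(res.rate_map[c], rate)


class TestTuningIndex:
    def test_indicator_weights_give_one(self):
        w = np.zeros(100)
        w[13] = 1.0
        assert tuning_index(w) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_weights_give_zero(self):
        assert tuning_index(np.full(100, 0.01)) < 1e-12

    def test_opposite_bins_cancel(self):
        w = np.zeros(100)
        w[10] = w[60] = 0.5
        assert tuning_index(w) < 1e-12

    def test_adjacent_bins_closed_form(self):
        # two equal weights one bin apart: resultant = cos(half the bin angle)
        w = np.zeros(100)
        w[30] = w[31] = 0.5
        assert tuning_index(w) == pytest.approx(np.cos(np.pi / 100), abs=1e-12)

    def test_rotation_invariance(self, rng):
        w = rng.dirichlet(np.ones(100))
        base = tuning_index(w)
        for shift in (1, 17, 50, 99):
            assert tuning_index(np.roll(w, shift)) == pytest.approx(base, abs=1e-12)

    @pytest.mark.parametrize("kappa", [0.5, 2.0, 8.0])
    def test_noiseless_von_mises_cell_matches_bessel_ratio(self, kappa):
        # 30 laps of noiseless activity following a von Mises tuning curve:
        # the index converges to I1(kappa)/I0(kappa)
        track = constant_speed_track(20.0, n_frames=30 * 90, frame_rate=10.0)
        theta = 2 * np.pi * track.position / BELT
        supra = np.exp(kappa * (np.cos(theta - 1.3) - 1.0))[None, :]
        res = tuning_vector(_thr(supra), track, all_moving(track.n_frames), 100, BELT)
        assert res.tuning_index[0] == pytest.approx(i1(kappa) / i0(kappa), abs=0.02)

    def test_untuned_cells_match_null_resultant_length(self, rng):
        # kappa = 0: m effective events at uniform positions; the mean
        # resultant length of m uniform unit vectors is ~ sqrt(pi/(4m))
        m = 40
        n_rep = 400
        vals = []
        track = constant_speed_track(20.0, n_frames=2000, frame_rate=10.0)
        for _ in range(n_rep):
            frames = rng.choice(2000, size=m, replace=False)
            supra = np.zeros((1, 2000))
            supra[0, frames] = 1.0
            res = tuning_vector(_thr(supra), track, all_moving(2000), 100, BELT)
            vals.append(res.tuning_index[0])
        expected = np.sqrt(np.pi / (4 * m))
        se = np.std(vals) / np.sqrt(n_rep)
        assert abs(np.mean(vals) - expected) < 3 * se + 0.01


class TestLapRaster:
    def test_place_cell_column(self):
        track = constant_speed_track(20.0, n_frames=1800, frame_rate=10.0)
        bins = position_bins(track.position, BELT, 100)
        supra = np.where(bins == 40, 1.0, 0.0)[None, :]
        r = lap_raster(_thr(supra), track, all_moving(1800), 100, BELT)
        visited = r.raster[0].sum(axis=1) > 0
        assert np.all(r.raster[0][visited, 40] > 0)
        other = np.delete(r.raster[0], 40, axis=1)
        assert other.sum() == 0

    def test_parity_split_partitions_laps(self):
        track = constant_speed_track(20.0, n_frames=1800, frame_rate=10.0)
        supra = np.abs(np.sin(np.arange(1800)))[None, :]
        r = lap_raster(_thr(supra), track, all_moving(1800), 100, BELT)
        assert r.even.shape[1] + r.odd.shape[1] == r.raster.shape[1]
        merged = r.raster.sum(axis=1)
        assert np.allclose(r.even.sum(axis=1) + r.odd.sum(axis=1), merged)

    def test_zero_completed_laps_raises(self):
        track = constant_speed_track(1.0, n_frames=100, frame_rate=10.0)  # < 1 lap
        with pytest.raises(RasterError):
            lap_raster(_thr(np.ones((1, 100))), track, all_moving(100), 100, BELT)

    def test_matches_brute_force_accumulation(self, rng):
        track = constant_speed_track(25.0, n_frames=600, frame_rate=10.0)
        supra = rng.gamma(1, 1, (2, 600)) * (rng.uniform(size=(2, 600)) < 0.1)
        moving = rng.uniform(size=600) < 0.8
        r = lap_raster(_thr(supra), track, MovementMask(moving, ()), 100, BELT)
        bins = position_bins(track.position, BELT, 100)
        dt = track.frame_dt()
        expected = np.zeros_like(r.raster)
        for t in range(600):
            if moving[t]:
                expected[:, track.lap_index[t], bins[t]] += supra[:, t] * dt[t]
        assert np.allclose(r.raster, expected)


class TestSelectTopFiCells:
    def test_top_decile_of_ten(self):
        ids = [f"c{i}" for i in range(10)]
        fi = np.arange(1.0, 11.0)
        assert select_top_fi_cells(fi, ids, 0.1) == ["c9"]

    def test_ceiling_takes_everything_near_one(self):
        ids = [f"c{i}" for i in range(10)]
        assert len(select_top_fi_cells(np.arange(10.0), ids, 0.999)) == 10

    def test_ties_broken_by_cell_id(self):
        ids = ["b", "a", "c", "d"]
        out = select_top_fi_cells(np.ones(4), ids, 0.5)
        assert out == ["a", "b"]

    def test_bottom_mode_and_nan_exclusion(self):
        ids = ["a", "b", "c", "d"]
        fi = np.array([3.0, np.nan, 1.0, 2.0])
        # NaN excluded: n = 3, ceil(0.3 * 3) = 1
        assert select_top_fi_cells(fi, ids, 0.3, mode="bottom") == ["c"]
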