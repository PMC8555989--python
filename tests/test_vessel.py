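"""Vessel videometry: registration, profiles, wall detection, response."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_shift_search
from optopace.exceptions import (
    PipelineError,
    TwoWallsNotFoundError,
    ValidationError,
)
from optopace.synth import VesselSimSpec, sinusoid_width, synth_vessel_video
from optopace.vessel import (
    FrameStack,
    MeasureLine,
    ResponseMetrics,
    band_sample_count,
    detect_walls,
    diameter_series,
    extract_profile,
    register_translation,
    response_metrics,
    smooth_running_average,
    stabilize_stack,
)


class TestRegistration:
    def test_identical_frames_zero_shift(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(48, 64))
        assert register_translation(f, f.copy(), search_radius=8) == (0, 0)

    def test_known_shift_recovered(self):
        rng = np.random.default_rng(1)
        scene = rng.normal(size=(48, 64))
        frame = np.roll(scene, (3, -2), axis=(0, 1))
        assert register_translation(scene, frame, search_radius=8) == (-3, 2)

    def test_matches_exhaustive_oracle_on_random_frames(self):
        rng = np.random.default_rng(2)
        scene = rng.normal(size=(48, 64))
        for k in range(20):
            sh = rng.integers(-10, 11, 2)
            frame = np.roll(scene, tuple(sh), axis=(0, 1)) + rng.normal(0, 0.3, scene.shape)
            got = register_translation(scene, frame, search_radius=10)
            assert tuple(got) == brute_force_shift_search(scene, frame, radius=10)

    def test_blob_in_exclusion_region_ignored(self):
        """A bright moving blob confined to the excluded area must not drag
        the registration; compare against the masked oracle too."""
        rng = np.random.default_rng(3)
        scene = rng.normal(size=(60, 60))
        mask = np.ones((60, 60), bool)
        mask[5:25, 5:25] = False
        for pos in ((8, 8), (12, 15), (18, 10)):
            frame = scene.copy()
            frame[pos[0] : pos[0] + 4, pos[1] : pos[1] + 4] += 50.0
            got = register_translation(scene, frame, mask=mask, search_radius=6)
            assert tuple(got) == (0, 0)
            assert tuple(got) == brute_force_shift_search(scene, frame, mask, radius=6)

    def test_stabilization_idempotent(self):
        spec = VesselSimSpec(n_frames=8, jitter_max=4, noise_sd=0.0, seed=5)
        frames, _ = synth_vessel_video(spec)
        stack = FrameStack(frames, 10.0, 0.55)
        stab1, shifts1 = stabilize_stack(stack, search_radius=6)
        stab2, shifts2 = stabilize_stack(stab1, search_radius=6)
        assert np.any(shifts1 != 0)
        assert np.all(shifts2 == 0)
        assert np.array_equal(stab1.frames, stab2.frames)

    def test_static_scene_ground_truth_recovery(self):
        spec = VesselSimSpec(n_frames=15, jitter_max=10, noise_sd=10.0, seed=6)
        frames, gt = synth_vessel_video(spec)
        _, shifts = stabilize_stack(FrameStack(frames, 10.0, 0.55), search_radius=10)
        assert np.array_equal(shifts, -gt.shift_per_frame)

    def test_full_exclusion_rejected(self):
        frames = np.zeros((3, 10, 10))
        stack = FrameStack(frames, 10.0, 0.55, exclusion=(0, 10, 0, 10))
        with pytest.raises(ValidationError):
            stabilize_stack(stack)


class TestProfiles:
    def test_constant_image_constant_profile(self):
        frame = np.full((60, 80), 7.5)
        line = MeasureLine((10, 30), (70, 30), band_width=5.0)
        _, prof = extract_profile(frame, line, 0.55)
        assert prof == pytest.approx(7.5)

    @pytest.mark.parametrize("p0,p1", [((10, 20), (70, 20)), ((15, 10), (60, 45)),
                                       ((20, 45), (65, 12))])
    def test_linear_ramp_exact(self, p0, p1):
        """Bilinear interpolation is exact on a plane, so any oriented profile
        through a linear intensity field is exactly linear."""
        yy, xx = np.mgrid[0:60, 0:80]
        frame = 2.0 * xx + 0.5 * yy + 3.0
        line = MeasureLine(p0, p1, band_width=3.0)
        pos, prof = extract_profile(frame, line, 1.0)
        # fit a line; residuals at machine precision
        coef = np.polyfit(pos, prof, 1)
        assert prof == pytest.approx(np.polyval(coef, pos), abs=1e-9)

    def test_band_sample_count_28um(self):
        assert band_sample_count(28.05, 0.55) == 51

    def test_band_average_matches_direct_summation(self):
        rng = np.random.default_rng(4)
        frame = rng.normal(size=(60, 80))
        line = MeasureLine((10, 30), (70, 30), band_width=5.0)
        pos, prof = extract_profile(frame, line, 1.0)
        # oracle: direct per-offset interpolation and summation
        from scipy.ndimage import map_coordinates

        nb = band_sample_count(5.0, 1.0)
        offs = np.arange(nb) - (nb - 1) / 2
        acc = np.zeros_like(prof)
        xs = 10 + np.arange(len(pos)) * 0.5
        for o in offs:
            acc += map_coordinates(frame, [np.full_like(xs, 30 + o), xs], order=1)
        assert prof == pytest.approx(acc / nb, abs=1e-9)

    def test_band_exiting_frame_names_endpoint(self):
        frame = np.zeros((40, 80))
        line = MeasureLine((5, 2), (70, 2), band_width=20.0)
        with pytest.raises(ValidationError, match="p0"):
            extract_profile(frame, line, 1.0)


class TestDetectWalls:
    def test_exact_parabola_vertex(self):
        pos = np.arange(0, 50, 0.5)
        y = np.full_like(pos, 1.0)
        for c, a in ((12.3, 5.0), (37.8, 4.0)):
            m = np.abs(pos - c) <= 3
            y[m] += a - 0.5 * (pos[m] - c) ** 2
        lp, rp, li, ri = detect_walls(pos, y)
        assert lp == pytest.approx(12.3, abs=1e-9)
        assert rp == pytest.approx(37.8, abs=1e-9)

    def test_gaussian_ridges_vs_dense_grid_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            c1 = rng.uniform(8, 20)
            c2 = c1 + rng.uniform(20, 45)
            s1, s2 = rng.uniform(1.5, 3.0, 2)
            a1, a2 = rng.uniform(0.5, 1.5, 2)
            def f(x):
                return (a1 * np.exp(-((x - c1) ** 2) / (2 * s1**2))
                        + a2 * np.exp(-((x - c2) ** 2) / (2 * s2**2)))
            pos = np.arange(0, c2 + 15, 0.5)
            lp, rp, *_ = detect_walls(pos, f(pos))
            dense = np.arange(0, c2 + 15, 0.001)
            yd = f(dense)
            mid = (c1 + c2) / 2
            true_l = dense[np.argmax(np.where(dense < mid, yd, -np.inf))]
            true_r = dense[np.argmax(np.where(dense >= mid, yd, -np.inf))]
            assert (rp - lp) == pytest.approx(true_r - true_l, abs=0.1)

    def test_monotonic_profile_error(self):
        pos = np.arange(20.0)
        with pytest.raises(TwoWallsNotFoundError):
            detect_walls(pos, pos * 2.0)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(6)
        pos = np.arange(0, 60, 0.5)
        y = (np.exp(-((pos - 15) ** 2) / 8) + np.exp(-((pos - 45) ** 2) / 8)
             + rng.normal(0, 0.01, pos.size))
        lp0, rp0, *_ = detect_walls(pos, y)
        lp1, rp1, *_ = detect_walls(pos, 3.7 * y + 11.0)
        assert lp1 == pytest.approx(lp0, abs=1e-9)
        assert rp1 == pytest.approx(rp0, abs=1e-9)


class TestDiameterSeries:
    def line_for(self, spec):
        rows, cols = spec.image_shape
        return MeasureLine((6, rows / 2), (cols - 6, rows / 2))

    def test_constant_width_recovered(self, quiet_vessel):
        spec, frames, gt = quiet_vessel
        stack = FrameStack(frames, spec.frame_rate, spec.pixel_size)
        tr = diameter_series(stack, self.line_for(spec))
        assert np.all(np.isfinite(tr.width_um))
        assert tr.width_um.to_numpy() == pytest.approx(50.0, abs=0.1)
        assert np.all(tr.left_um < tr.right_um)

    def test_all_dark_stack_pipeline_error(self):
        stack = FrameStack(np.zeros((6, 40, 60)), 10.0, 0.55)
        with pytest.raises(PipelineError):
            diameter_series(stack, MeasureLine((5, 20), (55, 20)))

    def test_sinusoid_rmse_within_bounds(self):
        spec = VesselSimSpec(
            n_frames=80, noise_sd=50.0, width_timecourse=sinusoid_width(50, 5, 4.0),
            seed=8,
        )
        frames, gt = synth_vessel_video(spec)
        stack = FrameStack(frames, spec.frame_rate, spec.pixel_size)
        tr = diameter_series(stack, self.line_for(spec))
        err = tr.width_um.to_numpy() - gt.width_per_frame
        assert np.sqrt(np.nanmean(err**2)) <= 0.3


class TestSmoothingAndResponse:
    def trace(self, widths, frame_rate=10.0):
        n = len(widths)
        return pd.DataFrame({
            "time_s": np.arange(n) / frame_rate,
            "width_um": np.asarray(widths, float),
        })

    def test_window_one_identity(self):
        tr = self.trace([50, 51, 52, 51, 50])
        out = smooth_running_average(tr, 1)
        assert out.width_um.tolist() == tr.width_um.tolist()

    def test_constant_unchanged(self):
        tr = self.trace([50.0] * 9)
        assert smooth_running_average(tr, 5).width_um.tolist() == [50.0] * 9

    def test_impulse_spread(self):
        w = np.full(15, 50.0)
        w[7] += 10.0
        out = smooth_running_average(self.trace(w), 5)
        assert out.width_um[5:10].to_numpy() == pytest.approx(52.0)
        assert out.width_um[4] == pytest.approx(50.0)

    def test_even_or_long_window_rejected(self):
        tr = self.trace([50.0] * 9)
        with pytest.raises(ValidationError):
            smooth_running_average(tr, 4)
        with pytest.raises(ValidationError):
            smooth_running_average(tr, 11)

    def test_pct_change_formula(self):
        w = np.concatenate([np.full(20, 50.0), np.full(60, 60.0), np.full(40, 55.0)])
        tr = self.trace(w)  # laser_on at t=1.5 s, frame 15
        m = response_metrics(tr, laser_on=1.5, laser_off=9.5)
        assert m.min_width == 50.0
        assert m.max_width == 60.0
        assert m.net_change == 10.0
        assert m.pct_change == pytest.approx(20.0)

    def test_constant_width_zero_change(self):
        m = response_metrics(self.trace([50.0] * 120), 1.0, 9.0)
        assert m.net_change == 0.0 and m.pct_change == 0.0

    def test_constriction_direction_swaps_roles(self):
        w = np.concatenate([np.full(20, 60.0), np.full(100, 48.0)])
        m = response_metrics(self.trace(w), 1.5, 11.0, direction="constrict")
        assert m.max_width == 60.0 and m.min_width == 48.0
        assert m.pct_change == pytest.approx((60 - 48) / 48 * 100)

    def test_empty_window_error(self):
        tr = self.trace([np.nan] * 30)
        with pytest.raises(ValidationError):
            response_metrics(tr, 0.5, 2.0)
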