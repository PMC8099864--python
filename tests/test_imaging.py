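"""Anisotropy maps, display smoothing, IMD rendering, ROI traces and SNR."""

import numpy as np
import pytest

from faded.anisotropy import CorrectionFactors, PolarizedSignal, steady_state_anisotropy
from faded.calibration import GEUSAPVC260_CALIBRATION
from faded.imaging import (
    AnisotropyMovie,
    PolarizedImageStack,
    anisotropy_maps,
    channel_snr,
    imd_render,
    roi_trace,
    smooth_for_display,
)
from faded.simulate import CellMovieConfig, make_cell_movie


def uniform_stack(r=0.10, total=1000.0, shape=(20, 32, 32), noise_rng=None, G=1.0):
    par = np.full(shape, total * (1 + 2 * r) / 3)
    perp = np.full(shape, total * (1 - r) / 3 / G)
    if noise_rng is not None:
        par = noise_rng.poisson(par).astype(float)
        perp = noise_rng.poisson(perp).astype(float)
    return PolarizedImageStack(
        parallel=par, perpendicular=perp, corrections=CorrectionFactors(G=G)
    )


class TestAnisotropyMaps:
    def test_uniform_noisy_stack_matches_shot_noise_prediction(self, rng):
        stack = uniform_stack(r=0.10, total=1000.0, noise_rng=rng)
        movie = anisotropy_maps(stack)
        vals = movie.r[movie.mask]
        assert vals.mean() == pytest.approx(0.10, abs=0.002)
        # first-order error propagation for Poisson channels at r, N counts:
        # var(r) = (3/N^2)^2 (Q^2 P + P^2 Q) with P,Q the channel means
        P = 1000 * (1 + 2 * 0.10) / 3
        Q = 1000 * (1 - 0.10) / 3
        sigma_pred = np.sqrt((3 / 1000.0**2) ** 2 * (Q**2 * P + P**2 * Q))
        assert vals.std() == pytest.approx(sigma_pred, rel=0.2)

    def test_equal_channels_give_zero_map(self):
        stack = uniform_stack(r=0.0)
        movie = anisotropy_maps(stack)
        np.testing.assert_allclose(movie.r[movie.mask], 0.0)

    def test_zero_frame_fully_masked(self):
        par = np.ones((3, 8, 8)) * 500
        par[1] = 0.0
        stack = PolarizedImageStack(parallel=par, perpendicular=par.copy())
        movie = anisotropy_maps(stack)
        assert not movie.mask[1].any()
        assert movie.mask[0].all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PolarizedImageStack(parallel=np.ones((2, 4, 4)), perpendicular=np.ones((2, 4, 5)))


class TestSmoothForDisplay:
    def test_constant_movie_unchanged_and_upsampled(self):
        movie = anisotropy_maps(uniform_stack(r=0.08, shape=(6, 200, 200)))
        sm = smooth_for_display(movie)
        assert sm.r.shape == (6, 400, 400)
        np.testing.assert_allclose(sm.r[sm.mask], 0.08, atol=1e-9)

    def test_impulse_spreads_with_requested_sigmas(self):
        # moment oracle on an impulse, no upsampling so the filter acts alone
        shape = (21, 31, 31)
        r = np.zeros(shape)
        r[10, 15, 15] = 1.0
        movie = AnisotropyMovie(r=r, mask=np.ones(shape, bool), mean_intensity=np.ones(shape[1:]))
        sm = smooth_for_display(movie, upsample=1)
        blob = sm.r
        idx = [np.arange(s) for s in shape]
        total = blob.sum()
        for axis, expected in zip(range(3), (2.0, 0.75, 0.75)):
            marg = blob.sum(axis=tuple(a for a in range(3) if a != axis))
            mu = (idx[axis] * marg).sum() / total
            var = (((idx[axis] - mu) ** 2) * marg).sum() / total
            assert np.sqrt(var) == pytest.approx(expected, rel=0.05)

    def test_mask_propagated(self):
        movie = anisotropy_maps(uniform_stack(shape=(4, 16, 16)))
        movie.mask[:, :4, :] = False
        movie.r[:, :4, :] = np.nan
        sm = smooth_for_display(movie)
        assert not sm.mask[:, :4, :].any()
        assert np.isfinite(sm.r[sm.mask]).all()


class TestImdRender:
    def _movie(self, r_value, intensity=1.0, shape=(2, 8, 8)):
        r = np.full(shape, r_value)
        return AnisotropyMovie(
            r=r, mask=np.ones(shape, bool),
            mean_intensity=np.full(shape[1:], intensity),
        )

    def test_below_range_clips_to_lower_bound(self):
        low = imd_render(self._movie(-0.5))
        floor = imd_render(self._movie(0.0))
        np.testing.assert_array_equal(low, floor)

    def test_midrange_hue(self):
        # r = 0.06 sits exactly mid-way in [0, 0.12]; its hue must equal the
        # analytic HSV->RGB of hue 0.5 * span
        from skimage.color import hsv2rgb

        frames = imd_render(self._movie(0.06))
        expected = np.round(hsv2rgb(np.array([[[2 / 3 * 0.5, 1.0, 1.0]]])) * 255).astype(np.uint8)
        np.testing.assert_array_equal(frames[0, 0, 0], expected[0, 0])

    def test_zero_intensity_pixel_is_black(self):
        movie = self._movie(0.10)
        movie.mean_intensity[0, 0] = 0.0
        frames = imd_render(movie)
        np.testing.assert_array_equal(frames[:, 0, 0], 0)

    def test_hue_monotone_in_anisotropy(self):
        # hue angle (before colour conversion) increases with r inside the clip range
        rs = np.linspace(0.0, 0.12, 13)
        hues = (np.clip(rs, 0, 0.12) - 0) / 0.12 * (2 / 3)
        assert np.all(np.diff(hues) > 0)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            imd_render(self._movie(0.05), hue_range=(0.1, 0.1))


class TestRoiTrace:
    def test_uniform_stack_equals_summed_steady_state(self, rng):
        stack = uniform_stack(r=0.10, noise_rng=rng, G=1.1)
        roi = np.zeros(stack.parallel.shape[1:], bool)
        roi[4:10, 4:10] = True
        trace = roi_trace(stack, roi)
        # exactness: each frame equals the corrected ratio of ROI-summed counts
        for k in (0, 7):
            expected = steady_state_anisotropy(
                PolarizedSignal(
                    stack.parallel[k][roi].sum(), stack.perpendicular[k][roi].sum()
                ),
                stack.corrections,
            )
            assert trace.r[k] == pytest.approx(expected, abs=1e-12)

    def test_single_pixel_roi(self, rng):
        stack = uniform_stack(noise_rng=rng)
        trace = roi_trace(stack, np.array([[3, 5]]))
        with np.errstate(invalid="ignore"):
            manual = (stack.parallel[:, 3, 5] - stack.perpendicular[:, 3, 5]) / (
                stack.parallel[:, 3, 5] + 2 * stack.perpendicular[:, 3, 5]
            )
        np.testing.assert_allclose(trace.r, manual)

    def test_step_scenario_reproduced(self):
        cfg = CellMovieConfig(
            seed=11, shape=(64, 64), n_frames=60, frame_interval=2.0, stimulus_time=60.0
        )
        stack, truth = make_cell_movie(cfg)
        trace = roi_trace(stack, truth.roi_masks[0], cal=cfg.calibration)
        pre = trace.r[truth.times < 60.0]
        post = trace.r[truth.times >= 70.0]
        assert pre.mean() == pytest.approx(0.10, abs=3 * pre.std(ddof=1) / np.sqrt(pre.size) + 1e-3)
        assert post.mean() == pytest.approx(0.02, abs=3 * post.std(ddof=1) / np.sqrt(post.size) + 1e-3)
        # calibrated concentrations: resting pinned at the r_free bound, stimulated finite
        assert np.isfinite(trace.concentration[truth.times >= 70.0]).all()

    def test_compensated_trace(self, rng):
        stack = uniform_stack(r=0.10, noise_rng=rng)
        trace = roi_trace(stack, np.ones(stack.parallel.shape[1:], bool), r_d=0.35, f_d=0.20)
        assert trace.r_compensated.mean() == pytest.approx(0.0375, abs=0.002)

    def test_empty_roi_rejected(self):
        stack = uniform_stack()
        with pytest.raises(ValueError):
            roi_trace(stack, np.zeros(stack.parallel.shape[1:], bool))


class TestChannelSnr:
    def test_noiseless_signal_is_flagged_infinite(self):
        stack = uniform_stack(shape=(12, 8, 8))
        snr_par, snr_perp = channel_snr(stack, np.ones((8, 8), bool))
        assert np.isinf(snr_par) and np.isinf(snr_perp)

    def test_poisson_snr_follows_sqrt_n(self, rng):
        # ROI-summed Poisson signal at mean 400/frame: SNR ~= sqrt(400) = 20
        par = rng.poisson(400.0, size=(300, 1, 1)).astype(float)
        perp = rng.poisson(400.0, size=(300, 1, 1)).astype(float)
        stack = PolarizedImageStack(parallel=par, perpendicular=perp)
        snr_par, snr_perp = channel_snr(stack, np.ones((1, 1), bool))
        assert snr_par == pytest.approx(20.0, rel=0.15)
        assert snr_perp == pytest.approx(20.0, rel=0.15)

    def test_doubling_intensity_raises_snr_by_sqrt2(self, rng):
        par1 = rng.poisson(400.0, size=(400, 1, 1)).astype(float)
        par2 = rng.poisson(800.0, size=(400, 1, 1)).astype(float)
        s1 = PolarizedImageStack(parallel=par1, perpendicular=par1.copy())
        s2 = PolarizedImageStack(parallel=par2, perpendicular=par2.copy())
        roi = np.ones((1, 1), bool)
        ratio = channel_snr(s2, roi)[0] / channel_snr(s1, roi)[0]
        assert ratio == pytest.approx(np.sqrt(2), rel=0.10)

    def test_too_few_frames_rejected(self):
        stack = uniform_stack(shape=(5, 4, 4))
        with pytest.raises(ValueError):
            channel_snr(stack, np.ones((4, 4), bool))
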