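"""Synthetic-data generators: reproducibility, stationarity and consistency
with the spectral model that the analysis chain fits."""

import math

import numpy as np
import pytest

from memfluct import (
    CalibrationCurve,
    MechanicalParams,
    PunctaSpec,
    SceneSpec,
    SceneSpecError,
    build_height_movie,
    model_psd,
    render_irm,
    simulate_cohort,
    simulate_height_movie,
    simulate_puncta_image,
)
from memfluct.mechanics import default_q_band
from memfluct.simulate import RenderError, predicted_pixel_sd
from memfluct.spectra import estimate_psd_fft_stack, exposure_correct


class TestSceneSpec:
    def test_regions_must_tile_grid(self):
        p = MechanicalParams(sigma=1e-5, gamma=1e5, eta_eff=4.0, a_active=1.0)
        with pytest.raises(SceneSpecError):
            SceneSpec(grid=(16, 16), param_regions=[((0, 0, 8, 16), p)])
        with pytest.raises(SceneSpecError):
            SceneSpec(
                grid=(16, 16),
                param_regions=[((0, 0, 16, 16), p), ((0, 0, 4, 4), p)],
            )

    def test_mean_height_outside_branch_rejected(self):
        spec = SceneSpec(grid=(8, 8), n_frames=64, mean_height=150.0)
        with pytest.raises(SceneSpecError):
            simulate_height_movie(spec)

    def test_likely_branch_escape_warns(self):
        wild = MechanicalParams(sigma=2e-7, gamma=1e6, eta_eff=0.1, a_active=1.0)
        spec = SceneSpec(
            grid=(16, 16), n_frames=64,
            param_regions=[((0, 0, 16, 16), wild)],
        )
        with pytest.warns(UserWarning, match="branch"):
            simulate_height_movie(spec)


class TestSimulateHeightMovie:
    def test_zero_activity_is_perfectly_flat(self):
        p = MechanicalParams(sigma=1e-5, gamma=1e5, eta_eff=4.0, a_active=0.0)
        spec = SceneSpec(
            grid=(8, 8), n_frames=16, param_regions=[((0, 0, 8, 8), p)]
        )
        hm, _ = simulate_height_movie(spec)
        assert np.allclose(np.asarray(hm.heights), spec.mean_height)

    def test_bit_reproducible_from_seed(self):
        a, _ = simulate_height_movie(SceneSpec(grid=(8, 8), n_frames=32, seed=9))
        b, _ = simulate_height_movie(SceneSpec(grid=(8, 8), n_frames=32, seed=9))
        c, _ = simulate_height_movie(SceneSpec(grid=(8, 8), n_frames=32, seed=10))
        assert np.array_equal(np.asarray(a.heights), np.asarray(b.heights))
        assert not np.array_equal(np.asarray(a.heights), np.asarray(c.heights))

    def test_pixel_variance_matches_mode_sum_prediction(self):
        spec = SceneSpec(grid=(32, 32), n_frames=2048, seed=2, exposure_fraction=0.0)
        hm, truth = simulate_height_movie(spec)
        emp = np.asarray(hm.heights).std(axis=0, ddof=1).mean()
        assert emp == pytest.approx(truth["predicted_sd_map"][0, 0], rel=0.10)

    def test_band_averaged_psd_matches_model_within_three_se(self):
        # the generator's defining property: the per-pixel temporal spectrum
        # reproduces the Helfrich model of its parameters
        spec = SceneSpec(grid=(32, 32), n_frames=2048, seed=3)
        hm, truth = simulate_height_movie(spec)
        p = spec.param_regions[0][1]
        data = np.asarray(hm.heights)
        psd = exposure_correct(
            estimate_psd_fft_stack(data.reshape(2048, -1), spec.dt), spec.dt
        )
        from memfluct.mechanics import model_psd_modes

        model = model_psd_modes(
            psd.freqs, p, (32, 32), spec.pixel_size, dt=spec.dt
        )
        edges = np.logspace(math.log10(0.1), math.log10(8.0), 9)
        for lo, hi in zip(edges[:-1], edges[1:]):
            k = (psd.freqs > lo) & (psd.freqs <= hi)
            est, mod = psd.power[k].mean(), model[k].mean()
            se = psd.power[k].std(ddof=1) / math.sqrt(k.sum())
            assert abs(est - mod) < 3 * max(se, 0.02 * mod), (lo, hi)

    def test_total_variance_matches_integral_of_model_spectrum(self):
        spec = SceneSpec(grid=(32, 32), n_frames=2048, seed=4, exposure_fraction=0.0)
        hm, _ = simulate_height_movie(spec)
        p = spec.param_regions[0][1]
        var_emp = np.asarray(hm.heights).var(axis=0, ddof=1).mean()
        # integrate the finite-patch model spectrum over all frequencies;
        # aliasing folds the >Nyquist tail into the sampled band, so the
        # full integral is the prediction for the sampled variance
        from memfluct.mechanics import model_psd_modes

        f = np.logspace(-3, 3, 6000)
        var_model = np.trapezoid(
            model_psd_modes(f, p, (32, 32), spec.pixel_size), f
        )
        assert var_emp == pytest.approx(var_model, rel=0.10)

    def test_sd_space_matches_equipartition_prediction(self):
        spec = SceneSpec(grid=(32, 32), n_frames=64, seed=8, exposure_fraction=0.0)
        hm, truth = simulate_height_movie(spec)
        data = np.asarray(hm.heights)
        per_frame_sd = data.reshape(64, -1).std(axis=1, ddof=1)
        assert per_frame_sd.mean() == pytest.approx(
            truth["predicted_sd_map"][0, 0], rel=0.10
        )

    def test_raising_tension_lowers_sd_time_and_sd_space(self):
        sds_t, sds_s = [], []
        for sigma in (6e-6, 1.2e-5, 2.4e-5):
            p = MechanicalParams(sigma=sigma, gamma=1e5, eta_eff=4.0, a_active=1.0)
            spec = SceneSpec(
                grid=(16, 16), n_frames=512, seed=12,
                param_regions=[((0, 0, 16, 16), p)],
            )
            hm, _ = simulate_height_movie(spec)
            data = np.asarray(hm.heights)
            sds_t.append(data.std(axis=0, ddof=1).mean())
            sds_s.append(data.reshape(512, -1).std(axis=1, ddof=1)[:20].mean())
        assert sds_t[0] > sds_t[1] > sds_t[2]
        assert sds_s[0] > sds_s[1] > sds_s[2]


class TestRenderIrm:
    def test_zero_height_renders_to_i_min(self, curve):
        from memfluct import HeightMovie

        hm = HeightMovie(
            np.ma.MaskedArray(np.zeros((4, 4, 4)), mask=False),
            dt=0.05, pixel_size=180.0,
        )
        stack = render_irm(hm, curve, noise_sd=0.0)
        assert np.allclose(stack, curve.i_min)

    def test_noiseless_round_trip(self, curve):
        spec = SceneSpec(grid=(16, 16), n_frames=64, seed=5)
        hm, _ = simulate_height_movie(spec)
        stack = render_irm(hm, curve, noise_sd=0.0)
        back = build_height_movie(stack, curve, dt=spec.dt, pixel_size=spec.pixel_size)
        assert np.abs(
            np.asarray(back.heights) - np.asarray(hm.heights)
        ).max() < 1e-6

    def test_camera_noise_level(self, curve):
        from memfluct import HeightMovie

        hm = HeightMovie(
            np.ma.MaskedArray(np.full((2048, 4, 4), 50.0), mask=False),
            dt=0.05, pixel_size=180.0,
        )
        stack = render_irm(hm, curve, noise_sd=2.0, seed=7)
        assert stack.std(axis=0).mean() == pytest.approx(2.0, rel=0.05)

    def test_out_of_branch_errors_when_strict(self, curve):
        from memfluct import HeightMovie

        heights = np.full((4, 4, 4), 50.0)
        heights[2, 1, 1] = 110.0
        hm = HeightMovie(
            np.ma.MaskedArray(heights, mask=False), dt=0.05, pixel_size=180.0
        )
        with pytest.raises(RenderError):
            render_irm(hm, curve)
        # non-strict folds the overshoot through the physical cosine
        stack = render_irm(hm, curve, strict=False)
        assert curve.i_min <= stack[2, 1, 1] <= curve.i_max

    def test_reproducible_from_seed(self, curve):
        spec = SceneSpec(grid=(8, 8), n_frames=16, seed=2)
        hm, _ = simulate_height_movie(spec)
        a = render_irm(hm, curve, noise_sd=1.0, seed=3)
        b = render_irm(hm, curve, noise_sd=1.0, seed=3)
        assert np.array_equal(a, b)


class TestSimulatePunctaImage:
    def test_no_puncta_gives_uniform_background(self):
        img, truth = simulate_puncta_image(
            PunctaSpec(shape=(64, 64), n_puncta=0, background=80.0)
        )
        assert np.allclose(img, 80.0)
        assert len(truth) == 0

    def test_true_mask_ratio_is_exact_without_blur_or_noise(self):
        spec = PunctaSpec(
            shape=(128, 128), n_puncta=10, radius_px=3,
            amplitude=100.0, background=100.0, seed=1,
        )
        img, truth = simulate_puncta_image(spec)
        assert set(np.unique(img)) == {100.0, 200.0}
        mask = img > 150
        ratio = img[mask].mean() / img[~mask].mean()
        assert ratio == pytest.approx(2.0, abs=1e-12)

    def test_blur_preserves_total_added_intensity(self):
        sharp, _ = simulate_puncta_image(PunctaSpec(seed=2, blur_sd=0.0))
        blurred, _ = simulate_puncta_image(PunctaSpec(seed=2, blur_sd=3.0))
        assert sharp.sum() == pytest.approx(blurred.sum(), rel=1e-6)

    def test_impossible_packing_raises(self):
        with pytest.raises(SceneSpecError):
            simulate_puncta_image(
                PunctaSpec(shape=(32, 32), n_puncta=60, radius_px=3)
            )

    def test_reproducible_from_seed(self):
        a, _ = simulate_puncta_image(PunctaSpec(seed=5, noise_sd=3.0))
        b, _ = simulate_puncta_image(PunctaSpec(seed=5, noise_sd=3.0))
        assert np.array_equal(a, b)


class TestSimulateCohort:
    def test_reproducible_and_sized(self):
        a, ta = simulate_cohort(20, seed=3)
        b, tb = simulate_cohort(20, seed=3)
        assert len(a) == 20 and ta.equals(tb)
        assert a[0].tension == b[0].tension

    def test_noise_free_perfect_coupling(self):
        cohort, truth = simulate_cohort(
            30, dip_prevalence=0.5, dip_fate_coupling=1.0, noise_cv=0.0, seed=8
        )
        for tr, (_, row) in zip(cohort, truth.iterrows()):
            assert (tr.fate == "FD") == bool(row["planted_dip"])

    def test_sd_time_anticorrelates_with_tension(self):
        cohort, _ = simulate_cohort(50, seed=4)
        rel_t, rel_s = [], []
        for tr in cohort:
            rel_t.append(tr.tension[1] / tr.tension[0])
            rel_s.append(tr.sd_time[1] / tr.sd_time[0])
        assert np.corrcoef(np.log(rel_t), np.log(rel_s))[0, 1] < -0.8


def test_predicted_sd_decreases_with_tension():
    sds = [
        predicted_pixel_sd(
            (32, 32), 180.0,
            MechanicalParams(sigma=s, gamma=1e5, eta_eff=4.0, a_active=1.0),
        )
        for s in (6e-6, 1.2e-5, 2.4e-5)
    ]
    assert sds[0] > sds[1] > sds[2]
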