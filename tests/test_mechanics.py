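"""Helfrich PSD model, parameter fitting, exponent and tension maps."""

import numpy as np
import pytest

from memfluct import (
    FitConfig,
    MechanicalParams,
    PSDEstimate,
    SceneSpec,
    default_q_band,
    fit_psd,
    kbt,
    model_psd,
    psd_exponent,
    simulate_height_movie,
    tension_map,
)
from memfluct.mechanics import fit_sigma_only, model_psd_modes

FREQS = np.fft.rfftfreq(2048, 0.05)[1:]


class TestModelPsd:
    def test_closed_form_tension_only_limit(self):
        # kappa=0, gamma=0 over a wide q range: PSD = A kB T / (4 pi sigma f)
        p = MechanicalParams(sigma=2e-7, gamma=0.0, eta_eff=0.1, a_active=1.0, kappa=0.0)
        f = np.logspace(-1, 1, 40)
        closed = p.a_active * kbt() / (4 * np.pi * p.sigma * f) * 1e18
        num = model_psd(f, p, 1e-2, 1e12, n_nodes=400)
        assert np.max(np.abs(num / closed - 1)) < 0.01

    def test_matches_fine_trapezoid_oracle(self, rng):
        q_min, q_max = default_q_band(12, 180.0)
        for _ in range(5):
            p = MechanicalParams(
                sigma=10 ** rng.uniform(-7.5, -5),
                gamma=10 ** rng.uniform(4, 7),
                eta_eff=10 ** rng.uniform(-1, 1),
                a_active=10 ** rng.uniform(-0.5, 0.5),
            )
            q = np.linspace(q_min, q_max, 1_000_000)
            e = p.kappa * q**3 + p.sigma * q + p.gamma / q
            for f in (0.13, 1.7, 9.3):
                oracle = (
                    4 * p.eta_eff * p.a_active * kbt() / np.pi
                    * np.trapezoid(
                        1.0 / ((4 * p.eta_eff * 2 * np.pi * f) ** 2 + e**2), q
                    )
                    * 1e18
                )
                assert model_psd(f, p, q_min, q_max) == pytest.approx(
                    oracle, rel=1e-3
                )

    def test_linear_in_active_temperature(self, default_params):
        q_min, q_max = default_q_band(64, 180.0)
        f = np.logspace(-1, 1, 20)
        base = model_psd(f, default_params, q_min, q_max)
        from dataclasses import replace

        doubled = model_psd(
            f, replace(default_params, a_active=2.0), q_min, q_max
        )
        assert np.allclose(doubled, 2 * base, rtol=1e-12)

    def test_strictly_decreasing_in_frequency(self, default_params):
        q_min, q_max = default_q_band(64, 180.0)
        f = np.logspace(-1, 1, 200)
        psd = model_psd(f, default_params, q_min, q_max)
        assert (np.diff(psd) < 0).all()

    def test_tension_suppresses_fluctuations(self):
        # at fixed f in the tension-dominated band, higher sigma, lower PSD
        q_min, q_max = default_q_band(64, 180.0)
        psds = [
            model_psd(
                1.0,
                MechanicalParams(sigma=s, gamma=1e5, eta_eff=4.0, a_active=1.0),
                q_min,
                q_max,
            )
            for s in (5e-6, 1e-5, 2e-5)
        ]
        assert psds[0] > psds[1] > psds[2]

    def test_invalid_inputs(self, default_params):
        with pytest.raises(ValueError):
            model_psd(-1.0, default_params, 1e5, 1e7)
        with pytest.raises(ValueError):
            model_psd(1.0, default_params, 1e7, 1e5)

    def test_discrete_mode_sum_converges_to_continuum(self, default_params):
        # for a large patch the lattice sum approaches the q integral
        f = np.logspace(-1, 0.5, 15)
        discrete = model_psd_modes(f, default_params, (256, 256), 180.0)
        continuum = model_psd(f, default_params, *default_q_band(256, 180.0))
        assert np.max(np.abs(discrete / continuum - 1)) < 0.05


class TestExponent:
    def test_tension_dominated_slope_is_minus_one(self):
        p = MechanicalParams(sigma=2e-7, gamma=0.0, eta_eff=0.1, a_active=1.0, kappa=0.0)
        power = model_psd(FREQS, p, 1e-2, 1e12, n_nodes=400)
        psd = PSDEstimate(FREQS, power, "fft", 2048, 0.05)
        assert psd_exponent(psd, 0.0, 10.0) == pytest.approx(-1.0, abs=0.05)

    def test_bending_dominated_slope_is_minus_five_thirds(self):
        p = MechanicalParams(sigma=0.0, gamma=0.0, eta_eff=0.1, a_active=1.0)
        power = model_psd(FREQS, p, 1e0, 1e12, n_nodes=600)
        psd = PSDEstimate(FREQS, power, "fft", 2048, 0.05)
        assert psd_exponent(psd, 0.0, 10.0) == pytest.approx(-5 / 3, abs=0.05)

    def test_flat_spectrum_has_zero_slope(self):
        psd = PSDEstimate(FREQS, np.full_like(FREQS, 2.5), "fft", 2048, 0.05)
        assert psd_exponent(psd, 0.0, 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_confinement_makes_exponent_less_negative_at_low_f(self):
        # gamma flattens the low-frequency spectrum (plateau), so the 0-10 Hz
        # slope of a confined membrane is shallower at low f and the knee
        # moves; checked as monotone trend of the low-band slope
        q_min, q_max = default_q_band(64, 180.0)
        slopes = []
        for g in (1e4, 1e6, 1e8):
            p = MechanicalParams(sigma=1e-6, gamma=g, eta_eff=0.5, a_active=1.0)
            power = model_psd(FREQS, p, q_min, q_max)
            psd = PSDEstimate(FREQS, power, "fft", 2048, 0.05)
            slopes.append(psd_exponent(psd, 0.0, 1.0))
        assert slopes[0] < slopes[1] < slopes[2]

    def test_too_few_bins_rejected(self):
        psd = PSDEstimate(FREQS[:3], np.ones(3), "fft", 2048, 0.05)
        with pytest.raises(ValueError):
            psd_exponent(psd, 0.0, 10.0)


class TestFitPsd:
    def test_noiseless_self_consistency(self):
        # the printed example parameter set: recovered exactly from its own curve
        truth = MechanicalParams(sigma=2e-7, gamma=1e6, eta_eff=0.1, a_active=1.0)
        q_band = default_q_band(12, 180.0)
        power = model_psd(FREQS, truth, *q_band)
        fit = fit_psd(
            PSDEstimate(FREQS, power, "fft", 2048, 0.05),
            q_band=q_band,
            bins_per_decade=None,
        )
        assert fit.fit_ok and fit.r2 > 0.9999
        assert fit.sigma == pytest.approx(truth.sigma, rel=0.01)
        assert fit.gamma == pytest.approx(truth.gamma, rel=0.01)
        assert fit.eta_eff == pytest.approx(truth.eta_eff, rel=0.01)
        assert fit.a_active == pytest.approx(truth.a_active, rel=0.01)

    def test_noisy_recovery_at_identifiable_conditions(self, default_params, rng):
        q_band = default_q_band(64, 180.0)
        power = model_psd(FREQS, default_params, *q_band)
        errs = []
        for _ in range(8):
            noisy = power * np.exp(rng.normal(0, 0.05, FREQS.size))
            fit = fit_psd(
                PSDEstimate(FREQS, noisy, "fft", 2048, 0.05),
                q_band=q_band,
                bins_per_decade=None,
            )
            errs.append(abs(fit.sigma / default_params.sigma - 1))
        assert np.median(errs) < 0.10

    def test_recovery_across_sigma_gamma_grid(self, rng):
        # median relative sigma error over a 3x3 grid of (sigma, gamma)
        # spanning the tensed-membrane regime, at 5% multiplicative noise
        q_band = default_q_band(64, 180.0)
        errs = []
        for s in (2e-6, 5e-6, 1e-5):
            for g in (3e6, 1e7, 3e7):
                truth = MechanicalParams(
                    sigma=s, gamma=g, eta_eff=2.0, a_active=1.0
                )
                power = model_psd(FREQS, truth, *q_band)
                cell = []
                for _ in range(3):
                    noisy = power * np.exp(rng.normal(0, 0.05, FREQS.size))
                    fit = fit_psd(
                        PSDEstimate(FREQS, noisy, "fft", 2048, 0.05),
                        q_band=q_band,
                        bins_per_decade=None,
                    )
                    cell.append(abs(fit.sigma / s - 1))
                errs.append(np.median(cell))
        assert np.median(errs) < 0.15

    def test_kappa_stays_fixed(self, default_params):
        q_band = default_q_band(64, 180.0)
        power = model_psd(FREQS, default_params, *q_band)
        fit = fit_psd(PSDEstimate(FREQS, power, "fft", 2048, 0.05), q_band=q_band)
        assert fit.kappa == default_params.kappa

    def test_flat_spectrum_is_flagged_unusable(self):
        psd = PSDEstimate(FREQS, np.full_like(FREQS, 1.0), "fft", 2048, 0.05)
        fit = fit_psd(psd, q_band=default_q_band(12, 180.0))
        # a flat spectrum carries no Helfrich structure: r2 must fail the
        # acceptance threshold used for maps
        assert fit.r2 < 0.8

    def test_all_zero_power_rejected(self):
        psd = PSDEstimate(FREQS, np.zeros_like(FREQS), "fft", 2048, 0.05)
        with pytest.raises(ValueError):
            fit_psd(psd, q_band=default_q_band(12, 180.0))

    def test_sigma_only_refit_pins_medium_parameters(self, default_params):
        from dataclasses import replace

        q_band = default_q_band(64, 180.0)
        truth = replace(default_params, sigma=2 * default_params.sigma)
        power = model_psd(FREQS, truth, *q_band)
        fit = fit_sigma_only(
            PSDEstimate(FREQS, power, "fft", 2048, 0.05),
            default_params,
            q_band=q_band,
        )
        assert fit.sigma == pytest.approx(truth.sigma, rel=0.02)
        assert fit.gamma == default_params.gamma
        assert fit.eta_eff == default_params.eta_eff


@pytest.fixture(scope="module")
def uniform_map():
    spec = SceneSpec(grid=(16, 16), n_frames=1024, seed=5)
    hm, truth = simulate_height_movie(spec)
    cfg = FitConfig(block=4, mode_shape=(16, 16), sampled=True, exposure_time=0.05)
    return tension_map(hm, cfg), truth


class TestTensionMap:
    def test_uniform_movie_gives_spatially_uniform_map(self, uniform_map):
        tm, truth = uniform_map
        vals = tm.sigma_map[~np.isnan(tm.sigma_map)]
        assert vals.size > 0
        assert vals.std() / vals.mean() < 0.25

    def test_uniform_movie_map_tracks_truth(self, uniform_map):
        tm, truth = uniform_map
        med = np.nanmedian(tm.sigma_map)
        assert med == pytest.approx(truth["sigma_map"][0, 0], rel=0.5)

    def test_masked_pixels_are_missing_exactly(self):
        spec = SceneSpec(grid=(16, 16), n_frames=1024, seed=7)
        hm, _ = simulate_height_movie(spec)
        mask = np.zeros(hm.heights.shape, bool)
        mask[:, 0:4, 0:4] = True
        hm.heights.mask = mask
        cfg = FitConfig(block=4, mode_shape=(16, 16), sampled=True, exposure_time=0.05)
        tm = tension_map(hm, cfg)
        assert np.isnan(tm.sigma_map[0:4, 0:4]).all()
        assert not np.isnan(tm.sigma_map[8:12, 8:12]).any()

    def test_two_region_map_recovers_tension_contrast(self):
        pL = MechanicalParams(sigma=1.2e-5, gamma=1e5, eta_eff=4.0, a_active=1.0)
        pR = MechanicalParams(sigma=2.4e-5, gamma=1e5, eta_eff=4.0, a_active=1.0)
        spec = SceneSpec(
            grid=(16, 32),
            n_frames=2048,
            param_regions=[((0, 0, 16, 16), pL), ((0, 16, 16, 16), pR)],
            seed=6,
        )
        hm, _ = simulate_height_movie(spec)
        cfg = FitConfig(block=4, mode_shape=(16, 16), sampled=True, exposure_time=0.05)
        tm = tension_map(hm, cfg)
        ratio = np.nanmedian(tm.sigma_map[:, 16:]) / np.nanmedian(tm.sigma_map[:, :16])
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_short_movie_rejected(self):
        spec = SceneSpec(grid=(8, 8), n_frames=128, seed=1)
        hm, _ = simulate_height_movie(spec)
        with pytest.raises(ValueError):
            tension_map(hm, FitConfig())
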