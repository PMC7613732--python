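"""Self-validation experiments exercising the full pipeline on ground truth.

Each function builds its own inputs (analytic limits, synthetic movies,
planted scenes or cohorts), runs the package's analysis chain, and returns a
dict of the measured quantities.  These are the experiments the test suite
asserts on and the reproduction script reports.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import replace
from typing import Dict

import numpy as np

from .calibration import CalibrationCurve, height_of_intensity, intensity_of_height
from .cohort import detect_dip, dip_fate_table, normalize_trajectory
from .heights import build_height_movie
from .mechanics import (
    MechanicalParams,
    default_q_band,
    fit_psd,
    fit_sigma_only,
    kbt,
    model_psd,
    psd_exponent,
)
from .puncta import cluster_ratio, detect_clusters
from .simulate import (
    PunctaSpec,
    SceneSpec,
    render_irm,
    simulate_cohort,
    simulate_height_movie,
    simulate_puncta_image,
)
from .spectra import PSDEstimate, estimate_psd_fft, estimate_psd_fft_stack, exposure_correct

#: study-condition mechanical parameters: a tensed adherent membrane whose
#: tension-to-bending crossover lies inside the 0.1-10 Hz acquisition band
DEFAULT_PARAMS = MechanicalParams(sigma=1.2e-5, gamma=1e5, eta_eff=4.0, a_active=1.0)
DEFAULT_CURVE = CalibrationCurve(i_min=100.0, i_max=200.0)
FRAME_DT = 0.05
N_FRAMES = 2048
PIXEL_NM = 180.0


def closed_form_limit() -> Dict[str, float]:
    """Tension-only model against the analytic A kB T / (4 pi sigma f) law."""
    p = MechanicalParams(sigma=2e-7, gamma=0.0, eta_eff=0.1, a_active=1.0, kappa=0.0)
    f = np.logspace(math.log10(0.1), 1.0, 50)
    closed = p.a_active * kbt() / (4.0 * math.pi * p.sigma * f) * 1e18
    num = model_psd(f, p, 1e-2, 1e12, n_nodes=400)
    return {"max_rel_dev_pct": float(np.max(np.abs(num / closed - 1)) * 100)}


def quadrature_oracle(seed: int = 0, n_sets: int = 20) -> Dict[str, float]:
    """Gauss-Legendre quadrature against a 10^6-node trapezoid evaluation."""
    rng = np.random.default_rng(seed)
    q_min, q_max = default_q_band(12, PIXEL_NM)
    worst = 0.0
    for _ in range(n_sets):
        p = MechanicalParams(
            sigma=10 ** rng.uniform(-7.5, -4.5),
            gamma=10 ** rng.uniform(3.5, 7.5),
            eta_eff=10 ** rng.uniform(-1.5, 1.0),
            a_active=10 ** rng.uniform(-0.5, 0.5),
        )
        q = np.linspace(q_min, q_max, 1_000_000)
        e = p.kappa * q**3 + p.sigma * q + p.gamma / q
        for f in (0.1 + 9.9 * rng.random(3)):
            oracle = (
                4 * p.eta_eff * p.a_active * kbt() / math.pi
                * np.trapezoid(
                    1.0 / ((4 * p.eta_eff * 2 * math.pi * f) ** 2 + e**2), q
                )
                * 1e18
            )
            worst = max(worst, abs(model_psd(float(f), p, q_min, q_max) / oracle - 1))
    return {"max_rel_dev_pct": worst * 100}


def spectral_estimator_oracle(seed: int = 0) -> Dict[str, float]:
    """Periodogram against a direct O(n^2) DFT; Parseval on a long series."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(20):
        x = rng.normal(0, 3.0, 64)
        psd = estimate_psd_fft(x, FRAME_DT)
        xc = x - x.mean()
        t = np.arange(64)
        for k in range(1, 33):
            coeff = np.sum(xc * np.exp(-2j * math.pi * k * t / 64))
            p_oracle = (abs(coeff) ** 2) * FRAME_DT / 64 * (2.0 if k < 32 else 1.0)
            if p_oracle > 0:
                worst = max(worst, abs(psd.power[k - 1] / p_oracle - 1))
    x = rng.normal(0, 5.0, N_FRAMES)
    psd = estimate_psd_fft(x, FRAME_DT)
    df = psd.freqs[1] - psd.freqs[0]
    parseval_dev = abs(psd.power.sum() * df / np.var(x) - 1)
    return {
        "max_rel_dev_dft": worst,
        "parseval_dev_pct": parseval_dev * 100,
    }


def parameter_recovery(seed: int = 0, n_replicates: int = 50) -> Dict[str, float]:
    """Fit model-generated spectra carrying 5% multiplicative noise."""
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(N_FRAMES, FRAME_DT)[1:]
    q_band = default_q_band(64, PIXEL_NM)
    power = model_psd(freqs, DEFAULT_PARAMS, *q_band)
    sig_errs, eta_errs = [], []
    for _ in range(n_replicates):
        noisy = power * np.exp(rng.normal(0.0, 0.05, freqs.size))
        fit = fit_psd(
            PSDEstimate(freqs, noisy, "fft", N_FRAMES, FRAME_DT),
            q_band=q_band,
            bins_per_decade=None,
        )
        sig_errs.append(abs(fit.sigma / DEFAULT_PARAMS.sigma - 1))
        eta_errs.append(abs(fit.eta_eff / DEFAULT_PARAMS.eta_eff - 1))
    return {
        "median_sigma_err_pct": float(np.median(sig_errs) * 100),
        "median_eta_err_pct": float(np.median(eta_errs) * 100),
    }


def two_region_tension_contrast(seed: int = 0) -> Dict[str, float]:
    """The primary end-to-end experiment.

    A 64 x 64 x 2048-frame membrane movie with tension sigma on the left
    half and 2 sigma on the right is rendered to IRM intensities with camera
    noise, inverted back to heights through the calibration curve, and
    analysed: pooled per-region Helfrich fits provide the shared medium
    parameters, then tension is refit per 4 x 4-pixel FBR and summarised by
    region medians.
    """
    sigma = DEFAULT_PARAMS.sigma
    p_left = DEFAULT_PARAMS
    p_right = replace(DEFAULT_PARAMS, sigma=2 * sigma)
    spec = SceneSpec(
        grid=(64, 64),
        n_frames=N_FRAMES,
        dt=FRAME_DT,
        pixel_size=PIXEL_NM,
        param_regions=[((0, 0, 64, 32), p_left), ((0, 32, 64, 32), p_right)],
        seed=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hm, _ = simulate_height_movie(spec)
    noise_sd = 0.5
    stack = render_irm(hm, DEFAULT_CURVE, noise_sd=noise_sd, seed=seed + 1, strict=False)
    hm2 = build_height_movie(stack, DEFAULT_CURVE, dt=FRAME_DT, pixel_size=PIXEL_NM)
    data = np.asarray(hm2.heights.filled(0.0))
    mask = hm2.pixel_mask
    # white height-noise floor implied by the camera noise and the mid-branch
    # calibration slope (measurable from dark frames in a real experiment)
    didh = (
        DEFAULT_CURVE.amplitude
        * 4 * math.pi * DEFAULT_CURVE.refractive_index / DEFAULT_CURVE.wavelength
    )
    floor = 2 * FRAME_DT * (noise_sd / didh) ** 2
    fit_kwargs = dict(
        mode_shape=(64, 32), pixel_size=PIXEL_NM, sampled=True, noise_floor=floor
    )
    shared = {}
    for reg, (c0, c1) in enumerate([(0, 32), (32, 64)]):
        sel = ~mask[:, c0:c1]
        pooled = data[:, :, c0:c1][:, sel].reshape(N_FRAMES, -1)
        psd = exposure_correct(estimate_psd_fft_stack(pooled, FRAME_DT), FRAME_DT)
        shared[reg] = fit_psd(psd, **fit_kwargs)
    base = replace(
        shared[0],
        gamma=math.sqrt(shared[0].gamma * shared[1].gamma),
        eta_eff=math.sqrt(shared[0].eta_eff * shared[1].eta_eff),
        a_active=math.sqrt(shared[0].a_active * shared[1].a_active),
    )
    sig_est: dict[int, list[float]] = {0: [], 1: []}
    for r0 in range(0, 64, 4):
        for c0 in range(0, 64, 4):
            if mask[r0 : r0 + 4, c0 : c0 + 4].any():
                continue
            px = data[:, r0 : r0 + 4, c0 : c0 + 4].reshape(N_FRAMES, -1)
            psd = exposure_correct(estimate_psd_fft_stack(px, FRAME_DT), FRAME_DT)
            fit = fit_sigma_only(psd, base, **fit_kwargs)
            if fit.fit_ok and fit.r2 > 0.8:
                sig_est[0 if c0 < 32 else 1].append(fit.sigma)
    med_low = float(np.median(sig_est[0]))
    med_high = float(np.median(sig_est[1]))
    return {
        "sigma_true_low": sigma,
        "sigma_true_high": 2 * sigma,
        "sigma_median_low": med_low,
        "sigma_median_high": med_high,
        "ratio": med_high / med_low,
        "ratio_dev_pct": abs(med_high / med_low / 2.0 - 1) * 100,
        "n_fbrs_low": len(sig_est[0]),
        "n_fbrs_high": len(sig_est[1]),
        "n_masked_pixels": int(mask.sum()),
    }


def exponent_limits() -> Dict[str, float]:
    """Log-log slope of the two analytic regimes over the 0-10 Hz band."""
    freqs = np.fft.rfftfreq(N_FRAMES, FRAME_DT)[1:]
    tension = MechanicalParams(
        sigma=2e-7, gamma=0.0, eta_eff=0.1, a_active=1.0, kappa=0.0
    )
    p_t = model_psd(freqs, tension, 1e-2, 1e12, n_nodes=400)
    bending = MechanicalParams(sigma=0.0, gamma=0.0, eta_eff=0.1, a_active=1.0)
    p_b = model_psd(freqs, bending, 1e0, 1e12, n_nodes=600)
    return {
        "tension_dominated": psd_exponent(
            PSDEstimate(freqs, p_t, "fft", N_FRAMES, FRAME_DT), 0.0, 10.0
        ),
        "bending_dominated": psd_exponent(
            PSDEstimate(freqs, p_b, "fft", N_FRAMES, FRAME_DT), 0.0, 10.0
        ),
    }


def calibration_round_trip(seed: int = 0) -> Dict[str, float]:
    """Height -> intensity -> height identity on the first branch."""
    rng = np.random.default_rng(seed)
    curve = CalibrationCurve(i_min=100.0, i_max=200.0)
    h = rng.uniform(0.0, curve.h_branch, 100)
    back = height_of_intensity(intensity_of_height(h, curve), curve)
    return {
        "max_roundtrip_err_nm": float(np.abs(back - h).max()),
        "h_branch_nm": curve.h_branch,
    }


def puncta_recovery(seed: int = 0) -> Dict[str, float]:
    """Planted-disk detection, exact noiseless ratio, blur monotonicity."""
    base = dict(
        shape=(128, 128), n_puncta=12, radius_px=3,
        amplitude=100.0, background=100.0,
    )
    img, truth = simulate_puncta_image(PunctaSpec(**base, noise_sd=5.0, seed=seed))
    seg = detect_clusters(img, window=15, offset=10.0, min_area=4)
    hits = 0
    for _, row in truth.iterrows():
        d = np.hypot(
            seg.objects["centroid_row"] - row["centroid_row"],
            seg.objects["centroid_col"] - row["centroid_col"],
        )
        if len(d) and d.min() <= 3:
            hits += 1
    false_pos = int(
        sum(
            np.hypot(
                truth["centroid_row"] - obj["centroid_row"],
                truth["centroid_col"] - obj["centroid_col"],
            ).min()
            > 5
            for _, obj in seg.objects.iterrows()
        )
    )
    clean, _ = simulate_puncta_image(PunctaSpec(**base, seed=seed))
    seg_clean = detect_clusters(clean, window=15, offset=10.0, min_area=4)
    ratio_clean = cluster_ratio(clean, seg_clean)
    ratios = []
    for blur in (0.0, 2.0, 4.0):
        img_b, _ = simulate_puncta_image(PunctaSpec(**base, blur_sd=blur, seed=seed))
        seg_b = detect_clusters(img_b, window=15, offset=5.0, min_area=4)
        ratios.append(cluster_ratio(img_b, seg_b))
    return {
        "detected_of_12": hits,
        "false_positives": false_pos,
        "noiseless_cluster_ratio": ratio_clean,
        "blur_strictly_decreases_ratio": bool(ratios[0] > ratios[1] > ratios[2]),
    }


def cohort_recovery(seed: int = 0) -> Dict[str, float]:
    """Dip prevalence and dip-fate coupling from a 200-cell cohort."""
    prevalence, coupling = 0.6, 0.8
    cohort, truth = simulate_cohort(
        200, dip_prevalence=prevalence, dip_fate_coupling=coupling, seed=seed
    )
    detected = np.array(
        [detect_dip(normalize_trajectory(tr))[0] for tr in cohort]
    )
    planted = truth["planted_dip"].to_numpy()
    table = dip_fate_table(cohort)
    p_fd_given_dip = float(table.loc["dip", "frac_FD"])
    planted_coupling = float(truth.loc[truth["planted_dip"], "fate"].eq("FD").mean())
    return {
        "planted_prevalence": float(planted.mean()),
        "detected_prevalence": float(detected.mean()),
        "prevalence_ci_halfwidth": 1.96 * math.sqrt(prevalence * (1 - prevalence) / 200),
        "planted_coupling": planted_coupling,
        "recovered_coupling": p_fd_given_dip,
        "coupling_ci_halfwidth": 1.96
        * math.sqrt(coupling * (1 - coupling) / max(int(planted.sum()), 1)),
    }
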