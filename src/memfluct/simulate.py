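"""Ground-truth synthetic data for every pipeline stage.

Height movies are synthesised mode by mode: on a periodic patch each spatial
Fourier mode q of the membrane evolves as an independent complex
Ornstein–Uhlenbeck process with relaxation rate

    lambda(q) = E(q) / (4 eta_eff),   E(q) = kappa q^3 + sigma q + gamma / q,

and stationary variance chosen so that the one-sided per-pixel temporal PSD
of the summed field equals :func:`memfluct.mechanics.model_psd` of the
patch's parameters exactly:

    var(q) = A kB T / (2 L^2 q E(q)).

Exact stationary sampling and the exact discrete-time OU update give correct
joint space–time statistics, so SD_time, SD_space and the PSD are all
simultaneously meaningful.  Hermitian symmetry of the mode field (hence a
real height field) is maintained by driving the update with the FFT of
white real-space noise.

IRM rendering applies the calibration-curve interference relation pixelwise
and adds Gaussian camera noise; puncta scenes plant non-overlapping disks on
a diffuse background with optional blur (sharp = early clusters, blurred =
diffused late/cholesterol-depleted state); cohorts plant 24-h tension dips
with configurable prevalence and dip–fate coupling.

All generators are reproducible from their integer seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from .calibration import (
    DEFAULT_REFRACTIVE_INDEX,
    DEFAULT_WAVELENGTH_NM,
    CalibrationCurve,
    intensity_of_height,
)
from .cohort import NOMINAL_TIMEPOINTS_H, CellTrajectory
from .heights import HeightMovie
from .mechanics import MechanicalParams, mode_statistics

__all__ = [
    "SceneSpec",
    "PunctaSpec",
    "SceneSpecError",
    "simulate_height_movie",
    "render_irm",
    "simulate_puncta_image",
    "simulate_cohort",
    "predicted_pixel_sd",
]

Rect = Tuple[int, int, int, int]  # (row0, col0, n_rows, n_cols)

#: escape probability bound for the branch check: P(|z| > 3.29) ~ 1e-3
_Z_BRANCH = 3.29


class SceneSpecError(ValueError):
    """Scene specification is inconsistent or physically unrealisable."""


@dataclass
class SceneSpec:
    """Specification of a synthetic fluctuating-membrane movie.

    Defaults mirror a standard fast IRM acquisition: 2048 frames at 20
    frames/s, 180-nm pixels (12 pixels spanning 2.16 um), membrane resting
    mid-branch at 50 nm.  ``param_regions`` assigns mechanical parameters to
    rectangles that must tile the grid exactly; each region fluctuates as an
    independent periodic patch.
    """

    grid: Tuple[int, int] = (64, 64)
    pixel_size: float = 180.0  # nm
    n_frames: int = 2048
    dt: float = 0.05  # s
    param_regions: Optional[list[Tuple[Rect, MechanicalParams]]] = None
    mean_height: float = 50.0  # nm, mid first branch
    camera_noise_sd: float = 0.0
    seed: int = 0
    confinement_form: str = "gamma_over_q"
    exposure_fraction: float = 1.0  # camera duty cycle; 0 = instantaneous sampling

    def __post_init__(self) -> None:
        if self.param_regions is None:
            self.param_regions = [
                (
                    (0, 0, self.grid[0], self.grid[1]),
                    MechanicalParams(
                        sigma=1.2e-5, gamma=1e5, eta_eff=4.0, a_active=1.0
                    ),
                )
            ]
        self._check_coverage()

    def _check_coverage(self) -> None:
        cover = np.zeros(self.grid, dtype=int)
        for (r0, c0, nr, nc), _ in self.param_regions:
            if r0 < 0 or c0 < 0 or r0 + nr > self.grid[0] or c0 + nc > self.grid[1]:
                raise SceneSpecError(f"region {(r0, c0, nr, nc)} exceeds grid")
            cover[r0 : r0 + nr, c0 : c0 + nc] += 1
        if not (cover == 1).all():
            raise SceneSpecError("param_regions must cover every pixel exactly once")


@dataclass
class PunctaSpec:
    """Specification of a synthetic puncta (cluster) fluorescence image."""

    shape: Tuple[int, int] = (256, 256)
    n_puncta: int = 12
    radius_px: int = 3
    amplitude: float = 100.0  # intensity above background
    background: float = 100.0
    blur_sd: float = 0.0  # px; 0 = sharp early clusters, large = diffused
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.background <= 0:
            raise SceneSpecError("amplitude must be >=0 and background > 0")
        if self.n_puncta < 0 or self.radius_px < 1:
            raise SceneSpecError("need n_puncta >= 0 and radius_px >= 1")


def _mode_arrays(
    shape: Tuple[int, int],
    pixel_size_nm: float,
    p: MechanicalParams,
    confinement_form: str,
) -> Tuple[np.ndarray, np.ndarray]:
    """Stationary variance (m^2) and relaxation rate (1/s) per FFT mode."""
    rows, cols = shape
    a_m = pixel_size_nm * 1e-9
    qy = 2.0 * math.pi * np.fft.fftfreq(rows, d=a_m)
    qx = 2.0 * math.pi * np.fft.fftfreq(cols, d=a_m)
    qmag = np.sqrt(qy[:, None] ** 2 + qx[None, :] ** 2)
    area = rows * cols * a_m * a_m
    var = np.zeros(shape)
    lam = np.ones(shape)
    nz = qmag > 0
    var[nz], lam[nz] = mode_statistics(qmag[nz], p, area, confinement_form)
    return var, lam


def predicted_pixel_sd(
    shape: Tuple[int, int],
    pixel_size_nm: float,
    p: MechanicalParams,
    confinement_form: str = "gamma_over_q",
) -> float:
    """Stationary per-pixel height SD (nm) of a periodic patch: sqrt(sum var(q))."""
    var, _ = _mode_arrays(shape, pixel_size_nm, p, confinement_form)
    return float(math.sqrt(var.sum()) * 1e9)


def _simulate_patch(
    shape: Tuple[int, int],
    pixel_size_nm: float,
    p: MechanicalParams,
    n_frames: int,
    dt: float,
    rng: np.random.Generator,
    confinement_form: str,
    exposure_fraction: float = 1.0,
) -> np.ndarray:
    """Stationary OU evolution of one periodic patch; returns (frames, r, c) in m.

    With ``exposure_fraction > 0`` each recorded frame is the exact time
    average of the field over the exposure window (camera integration),
    sampled jointly with the endpoint states through the OU bridge: for a
    mode with rate ``lam`` and variance ``v``, the frame average ``Y`` given
    the window endpoints ``(X0, X1)`` is Gaussian with mean
    ``c (X0 + X1)`` and variance ``v (g - 2 b^2/(1+rho))`` where
    ``a = lam T``, ``b = (1-e^-a)/a``, ``g = 2(a-1+e^-a)/a^2``,
    ``c = b/(1+rho)``.  This reproduces the suppression of fast-mode power a
    real integrating detector provides; instantaneous sampling
    (``exposure_fraction = 0``) would alias that power back into the band.
    """
    rows, cols = shape
    var, lam = _mode_arrays(shape, pixel_size_nm, p, confinement_form)
    n_tot = rows * cols
    rho_dt = np.exp(-lam * dt)
    kick_dt = np.sqrt(var * (1.0 - rho_dt**2))

    def hermitian_noise() -> np.ndarray:
        # FFT of real white noise is Hermitian with E|W|^2 = n_tot
        return np.fft.fft2(rng.standard_normal(shape)) / math.sqrt(n_tot)

    h_modes = np.sqrt(var) * hermitian_noise()
    out = np.empty((n_frames, rows, cols))

    if exposure_fraction <= 0.0:
        for t in range(n_frames):
            out[t] = (np.fft.ifft2(h_modes) * n_tot).real
            if t + 1 < n_frames:
                h_modes = rho_dt * h_modes + kick_dt * hermitian_noise()
        return out

    t_exp = exposure_fraction * dt
    a = lam * t_exp
    rho_e = np.exp(-a)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = -np.expm1(-a) / a
        g = 2.0 * (a + np.expm1(-a)) / a**2
    b = np.where(a > 0, b, 1.0)
    g = np.where(a > 0, g, 1.0)
    c = b / (1.0 + rho_e)
    s_bridge = np.sqrt(np.clip(var * (g - 2.0 * b**2 / (1.0 + rho_e)), 0.0, None))
    # dead time between exposure end and the next exposure start
    t_gap = dt - t_exp
    rho_g = np.exp(-lam * t_gap)
    kick_e = np.sqrt(var * (1.0 - rho_e**2))
    kick_g = np.sqrt(var * (1.0 - rho_g**2))
    for t in range(n_frames):
        x_end = rho_e * h_modes + kick_e * hermitian_noise()
        y = c * (h_modes + x_end) + s_bridge * hermitian_noise()
        out[t] = (np.fft.ifft2(y) * n_tot).real
        h_modes = x_end
        if t_gap > 0 and t + 1 < n_frames:
            h_modes = rho_g * h_modes + kick_g * hermitian_noise()
    return out


def simulate_height_movie(
    spec: SceneSpec,
    h_branch: Optional[float] = None,
) -> Tuple[HeightMovie, dict]:
    """Generate a fluctuating height movie with per-pixel ground truth.

    Returns the movie (nm, unmasked) and a truth dict with the per-pixel
    ``sigma_map`` (N/m), ``predicted_sd_map`` (nm) and the region list.
    When the fluctuations are likely to escape the first interference branch
    (``mean_height`` +/- 3.29 predicted SD outside ``(0, h_branch)``, i.e.
    escape probability above ~1e-3 per pixel-frame) a warning is issued —
    such a movie analyses fine as heights but cannot be rendered to IRM
    without masking.  A ``mean_height`` outside the branch altogether raises
    :class:`SceneSpecError`.
    """
    if h_branch is None:
        h_branch = DEFAULT_WAVELENGTH_NM / (4.0 * DEFAULT_REFRACTIVE_INDEX)
    if not 0.0 < spec.mean_height < h_branch:
        raise SceneSpecError(
            f"mean_height {spec.mean_height} nm outside the first branch "
            f"(0, {h_branch:.1f}) nm"
        )
    rows, cols = spec.grid
    heights = np.empty((spec.n_frames, rows, cols))
    sigma_map = np.empty((rows, cols))
    sd_map = np.empty((rows, cols))
    seeds = np.random.SeedSequence(spec.seed).spawn(len(spec.param_regions))
    for ((r0, c0, nr, nc), p), ss in zip(spec.param_regions, seeds):
        sd_nm = predicted_pixel_sd((nr, nc), spec.pixel_size, p, spec.confinement_form)
        lo = spec.mean_height - _Z_BRANCH * sd_nm
        hi = spec.mean_height + _Z_BRANCH * sd_nm
        if lo <= 0.0 or hi >= h_branch:
            warnings.warn(
                f"region {(r0, c0, nr, nc)}: mean_height {spec.mean_height} nm "
                f"+/- {_Z_BRANCH:.2f} x {sd_nm:.2f} nm leaves the first branch "
                f"(0, {h_branch:.1f}) nm; IRM rendering would require masking",
                stacklevel=2,
            )
        rng = np.random.default_rng(ss)
        patch_m = _simulate_patch(
            (nr, nc), spec.pixel_size, p, spec.n_frames, spec.dt, rng,
            spec.confinement_form, spec.exposure_fraction,
        )
        heights[:, r0 : r0 + nr, c0 : c0 + nc] = patch_m * 1e9 + spec.mean_height
        sigma_map[r0 : r0 + nr, c0 : c0 + nc] = p.sigma
        sd_map[r0 : r0 + nr, c0 : c0 + nc] = sd_nm
    hm = HeightMovie(
        heights=np.ma.MaskedArray(heights, mask=False),
        dt=spec.dt,
        pixel_size=spec.pixel_size,
    )
    truth = {
        "sigma_map": sigma_map,
        "predicted_sd_map": sd_map,
        "regions": list(spec.param_regions),
        "spec": spec,
    }
    return hm, truth


class RenderError(ValueError):
    """Height field cannot be rendered through the calibration curve."""


def render_irm(
    hm: HeightMovie,
    curve: CalibrationCurve,
    noise_sd: float = 0.0,
    seed: int = 0,
    strict: bool = True,
) -> np.ndarray:
    """Render a height movie to an IRM intensity stack with camera noise.

    With ``strict`` (default) heights outside the first branch raise
    :class:`RenderError`.  ``strict=False`` instead applies the physical
    two-beam interference cosine at any height — the relation does not stop
    at the branch edge, only its inversion does — so rare excursions past
    the branch render to intensities that the first-branch inversion folds
    back by the (small) overshoot, as happens with real cells.
    """
    heights = np.asarray(hm.heights.filled(np.nan))
    if np.isnan(heights).any():
        raise RenderError("height movie contains masked pixels; cannot render")
    if heights.min() < 0 or heights.max() > curve.h_branch:
        if strict:
            raise RenderError("heights leave the first branch; cannot render")
        phase = (
            4.0 * math.pi * curve.refractive_index * heights / curve.wavelength
        )
        stack = curve.i_mid - curve.amplitude * np.cos(phase)
    else:
        stack = intensity_of_height(heights, curve)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
    return stack


def simulate_puncta_image(spec: PunctaSpec) -> Tuple[np.ndarray, pd.DataFrame]:
    """Plant non-overlapping bright disks on a diffuse background.

    Placement is rejection-sampled (centres at least one diameter plus two
    pixels apart, disks clear of the border); the puncta layer is blurred by
    ``blur_sd`` before noise, so total added intensity is blur-invariant.
    Returns the image and the planted-truth table (centroids, radius, area).
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    r = spec.radius_px
    margin = r + int(math.ceil(3 * spec.blur_sd)) + 1
    if 2 * margin >= min(rows, cols) and spec.n_puncta > 0:
        raise SceneSpecError("image too small for requested puncta and blur")
    centers: list[Tuple[int, int]] = []
    min_sep2 = (2 * r + 2) ** 2
    attempts = 0
    max_attempts = 1000 * max(spec.n_puncta, 1)
    while len(centers) < spec.n_puncta:
        if attempts >= max_attempts:
            raise SceneSpecError(
                f"could not place {spec.n_puncta} non-overlapping puncta "
                f"in {spec.shape} after {max_attempts} attempts"
            )
        attempts += 1
        cr = int(rng.integers(margin, rows - margin))
        cc = int(rng.integers(margin, cols - margin))
        if all((cr - a) ** 2 + (cc - b) ** 2 >= min_sep2 for a, b in centers):
            centers.append((cr, cc))
    layer = np.zeros(spec.shape)
    records = []
    for i, (cr, cc) in enumerate(centers, start=1):
        rr, cc_idx = skdraw.disk((cr, cc), r + 0.5, shape=spec.shape)
        layer[rr, cc_idx] = spec.amplitude
        records.append(
            {
                "id": i,
                "centroid_row": cr,
                "centroid_col": cc,
                "radius_px": r,
                "area_px": rr.size,
            }
        )
    if spec.blur_sd > 0:
        layer = ndimage.gaussian_filter(layer, spec.blur_sd)
    img = spec.background + layer
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    truth = pd.DataFrame(
        records,
        columns=["id", "centroid_row", "centroid_col", "radius_px", "area_px"],
    )
    return img, truth


def simulate_cohort(
    n_cells: int,
    dip_prevalence: float = 0.6,
    dip_fate_coupling: float = 0.8,
    noise_cv: float = 0.05,
    seed: int = 0,
    recovery_fraction: float = 0.8,
    baseline_tension: float = 2e-7,
    baseline_cv: float = 0.3,
) -> Tuple[list[CellTrajectory], pd.DataFrame]:
    """Longitudinal tension trajectories with planted dips and fates.

    Each cell carries a lognormal baseline tension around
    ``baseline_tension`` N/m.  A planted dip drops the 24-h fold change to
    0.55–0.75 (well past the default 10% detection depth);
    ``recovery_fraction`` of dipped cells recover above baseline by 48 h,
    matching the usual transient phenotype.  Cells without a dip drift
    mildly upward.  Fate FD is drawn with probability
    ``dip_fate_coupling`` for dipped cells and its complement otherwise.
    Measurement noise is multiplicative with coefficient of variation
    ``noise_cv`` (per-cell medians over thousands of FBRs are tight, hence
    the small default).  SD_time is generated as the inverse-square-root
    companion of tension (higher tension, lower fluctuation amplitude).
    """
    for name, v in (
        ("dip_prevalence", dip_prevalence),
        ("dip_fate_coupling", dip_fate_coupling),
        ("recovery_fraction", recovery_fraction),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cohort: list[CellTrajectory] = []
    truth_rows = []
    for i in range(n_cells):
        baseline = baseline_tension * rng.lognormal(0.0, baseline_cv)
        planted_dip = bool(rng.random() < dip_prevalence)
        if planted_dip:
            shape24 = rng.uniform(0.55, 0.75)
            planted_recovery = bool(rng.random() < recovery_fraction)
            shape48 = rng.uniform(1.0, 1.2) if planted_recovery else shape24 + 0.05
        else:
            shape24 = rng.uniform(1.0, 1.15)
            shape48 = rng.uniform(1.05, 1.3)
            planted_recovery = False
        shape = np.array(
            [1.0, shape24, shape48, rng.uniform(1.0, 1.4), rng.uniform(1.1, 1.6)]
        )
        fate_p = dip_fate_coupling if planted_dip else 1.0 - dip_fate_coupling
        fate = "FD" if rng.random() < fate_p else "FU"
        noise = 1.0 + noise_cv * rng.standard_normal(len(shape)) if noise_cv > 0 else 1.0
        tension = baseline * shape * noise
        tension = np.clip(tension, 1e-12, None)
        sd_noise = (
            1.0 + noise_cv * rng.standard_normal(len(shape)) if noise_cv > 0 else 1.0
        )
        sd_time = 100.0 * (tension / baseline) ** -0.5 * sd_noise
        cell_id = f"cell{i:04d}"
        cohort.append(
            CellTrajectory(
                cell_id=cell_id,
                timepoints_h=NOMINAL_TIMEPOINTS_H,
                tension=tuple(float(v) for v in tension),
                sd_time=tuple(float(v) for v in sd_time),
                fate=fate,
            )
        )
        truth_rows.append(
            {
                "cell_id": cell_id,
                "planted_dip": planted_dip,
                "planted_recovery": planted_recovery,
                "fate": fate,
                "baseline_tension": baseline,
            }
        )
    return cohort, pd.DataFrame(truth_rows)
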