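"""Helfrich-based mechanics: PSD model, parameter fitting, tension maps.

The temporal power spectral density of membrane height fluctuations at a
point, for a membrane with bending rigidity ``kappa``, tension ``sigma``,
harmonic confinement ``gamma`` and effective medium viscosity ``eta_eff``,
driven at an effective active temperature ``A`` times thermal, is

    PSD(f) = (4 eta_eff A kB T / pi)
             * Integral_{q_min}^{q_max} dq /
               [ (4 eta_eff * 2 pi f)^2 + E(q)^2 ],
    E(q) = kappa q^3 + sigma q + gamma / q,

a superposition of Lorentzians, one per spatial mode q, each with relaxation
rate E(q) / (4 eta_eff).  Fitting the measured PSD with this model (kappa
held fixed) yields the *fluctuation tension* sigma along with gamma,
eta_eff and A.  The confinement term flattens the low-frequency spectrum;
the log–log slope ("exponent") over the low-frequency band summarises the
confinement state without a full fit: -1 in the tension-dominated limit,
-5/3 when bending dominates.

Units are SI internally (sigma N/m, gamma N/m^3, eta_eff Pa s, kappa J);
spectra are expressed in nm^2/Hz to match the height series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .spectra import PSDEstimate, estimate_psd_fft_stack, exposure_correct

__all__ = [
    "K_B",
    "T_DEFAULT",
    "kbt",
    "MechanicalParams",
    "FitConfig",
    "TensionMap",
    "model_psd",
    "fit_psd",
    "psd_exponent",
    "tension_map",
    "default_q_band",
]

K_B = 1.380649e-23  # J/K
T_DEFAULT = 310.15  # K (37 C incubation)


def kbt(temperature: float = T_DEFAULT) -> float:
    """Thermal energy k_B*T in joules (4.28e-21 J at 310.15 K)."""
    return K_B * temperature


KAPPA_DEFAULT = 15.0 * kbt()  # bending rigidity held fixed during fits


@dataclass
class MechanicalParams:
    """Membrane mechanical parameters extracted from (or driving) the PSD.

    sigma : fluctuation tension, N/m
    gamma : confinement strength, N/m^3
    eta_eff : effective viscosity, Pa s
    a_active : effective active temperature (dimensionless multiplier of kT)
    kappa : bending rigidity, J — fixed, never fitted
    temperature : K
    r2 : goodness of the log-space fit (NaN before fitting)
    exponent : low-frequency log–log PSD slope (NaN before fitting)
    fit_ok : False when the solver failed to converge or the fit is unusable
    """

    sigma: float
    gamma: float
    eta_eff: float
    a_active: float
    kappa: float = KAPPA_DEFAULT
    temperature: float = T_DEFAULT
    r2: float = math.nan
    exponent: float = math.nan
    fit_ok: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.gamma < 0:
            raise ValueError("sigma and gamma must be non-negative")
        if self.eta_eff <= 0:
            raise ValueError("eta_eff must be positive")
        if self.a_active < 0:
            raise ValueError("a_active must be non-negative")

    def to_dict(self) -> dict:
        """JSON-ready parameter record with units in the key names."""
        return {
            "sigma_N_per_m": self.sigma,
            "gamma_N_per_m3": self.gamma,
            "eta_eff_Pa_s": self.eta_eff,
            "a_active": self.a_active,
            "kappa_J": self.kappa,
            "temperature_K": self.temperature,
            "r2": self.r2,
            "exponent": self.exponent,
            "fit_ok": self.fit_ok,
        }


@lru_cache(maxsize=8)
def _leggauss(n: int) -> Tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def _restoring(q: np.ndarray, p: MechanicalParams, confinement_form: str) -> np.ndarray:
    if confinement_form == "gamma_over_q":
        return p.kappa * q**3 + p.sigma * q + p.gamma / q
    if confinement_form == "gamma_times_q":
        return p.kappa * q**3 + p.sigma * q + p.gamma * q
    raise ValueError(f"unknown confinement_form: {confinement_form!r}")


def model_psd(
    f,
    p: MechanicalParams,
    q_min: float,
    q_max: float,
    n_nodes: int = 200,
    confinement_form: str = "gamma_over_q",
):
    """Evaluate the Helfrich PSD model (nm^2/Hz) at frequencies ``f`` (Hz).

    The mode integral is evaluated by Gauss–Legendre quadrature in log q
    (the integrand is smooth and slowly varying on that scale), vectorised
    jointly over frequencies and nodes.  ``q_min``/``q_max`` are the wave
    number cutoffs in 1/m set by the analysed region and the pixel size.
    """
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))
    if np.any(f_arr <= 0):
        raise ValueError("frequencies must be positive")
    if not 0 < q_min < q_max:
        raise ValueError("require 0 < q_min < q_max")
    x, w = _leggauss(n_nodes)
    lo, hi = math.log(q_min), math.log(q_max)
    u = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    q = np.exp(u)
    jac = 0.5 * (hi - lo) * q  # dq = q du
    e = _restoring(q, p, confinement_form)
    drag = (4.0 * p.eta_eff * 2.0 * math.pi * f_arr)[:, None] ** 2
    integral = ((w * jac)[None, :] / (drag + e[None, :] ** 2)).sum(axis=1)
    prefac = 4.0 * p.eta_eff * p.a_active * kbt(p.temperature) / math.pi
    psd_si = prefac * integral  # m^2/Hz
    out = psd_si * 1e18  # nm^2/Hz
    if not np.isfinite(out).all():
        raise ArithmeticError(
            "model PSD quadrature produced non-finite values "
            f"(q_band=({q_min:.3g},{q_max:.3g}), params={p})"
        )
    return out if np.ndim(f) else float(out[0])


def default_q_band(tile_size: int, pixel_size_nm: float) -> Tuple[float, float]:
    """Wave-number band (1/m) resolved by a tile: 2*pi/L to the Nyquist 2*pi/(2*px)."""
    px_m = pixel_size_nm * 1e-9
    return 2.0 * math.pi / (tile_size * px_m), 2.0 * math.pi / (2.0 * px_m)


def mode_table(
    shape: Tuple[int, int], pixel_size_nm: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Distinct wave numbers (1/m) and multiplicities of a periodic pixel patch.

    The zero mode is excluded.  Grouping degenerate modes keeps mode-sum
    spectra cheap on large patches.
    """
    rows, cols = shape
    a_m = pixel_size_nm * 1e-9
    qy = 2.0 * math.pi * np.fft.fftfreq(rows, d=a_m)
    qx = 2.0 * math.pi * np.fft.fftfreq(cols, d=a_m)
    qmag = np.sqrt(qy[:, None] ** 2 + qx[None, :] ** 2).ravel()
    qmag = qmag[qmag > 0]
    q, counts = np.unique(np.round(qmag, 3), return_counts=True)
    return q, counts.astype(float)


def mode_statistics(
    q: np.ndarray,
    p: MechanicalParams,
    area_m2: float,
    confinement_form: str = "gamma_over_q",
) -> Tuple[np.ndarray, np.ndarray]:
    """Stationary variance (m^2) and relaxation rate (1/s) of Helfrich modes.

    For a periodic patch of area ``area_m2`` each mode q carries variance
    ``A kB T / (2 area q E(q))`` — normalised so that the one-sided
    per-pixel temporal PSD of the mode sum reproduces :func:`model_psd` in
    the continuum limit — and relaxes at ``E(q) / (4 eta_eff)``.
    """
    e = _restoring(q, p, confinement_form)
    var = p.a_active * kbt(p.temperature) / (2.0 * area_m2 * q * e)
    lam = e / (4.0 * p.eta_eff)
    return var, lam


def model_psd_modes(
    f,
    p: MechanicalParams,
    shape: Tuple[int, int],
    pixel_size_nm: float,
    dt: Optional[float] = None,
    exposure_fraction: float = 1.0,
    confinement_form: str = "gamma_over_q",
):
    """Finite-patch counterpart of :func:`model_psd` (nm^2/Hz).

    Sums the per-mode Lorentzians of a periodic ``shape`` patch instead of
    integrating a continuum of wave numbers.  With ``dt`` given, the exact
    spectrum seen by a camera sampling every ``dt`` seconds and integrating
    over ``exposure_fraction * dt`` is returned, post-divided by the sinc^2
    exposure transfer so it pairs directly with
    :func:`memfluct.spectra.exposure_correct`-treated estimates.  This is
    the right model when the analysed membrane region is comparable to the
    longest undulation wavelengths, where the continuum integral
    misrepresents the handful of discrete low-q modes.
    """
    f_arr = np.atleast_1d(np.asarray(f, dtype=float))
    if np.any(f_arr <= 0):
        raise ValueError("frequencies must be positive")
    rows, cols = shape
    area = rows * cols * (pixel_size_nm * 1e-9) ** 2
    q, mult = mode_table(shape, pixel_size_nm)
    var, lam = mode_statistics(q, p, area, confinement_form)
    w = 2.0 * math.pi * f_arr
    if dt is None:
        s = (mult * 4.0 * var * lam / (lam[None, :] ** 2 + w[:, None] ** 2)).sum(
            axis=1
        )
        out = s * 1e18
        return out if np.ndim(f) else float(out[0])
    # exact sampled (and optionally exposure-integrated) spectrum
    z = np.exp(-1j * w * dt)[:, None]
    rho_dt = np.exp(-lam * dt)
    s_x = 2.0 * dt * var * (1.0 - rho_dt**2) / np.abs(1.0 - rho_dt[None, :] * z) ** 2
    if exposure_fraction > 0:
        t_exp = exposure_fraction * dt
        a = lam * t_exp
        rho_e = np.exp(-a)
        b = -np.expm1(-a) / a
        g = 2.0 * (a + np.expm1(-a)) / a**2
        c = b / (1.0 + rho_e)
        s_res = np.clip(var * (g - 2.0 * b**2 / (1.0 + rho_e)), 0.0, None)
        # exact for full-frame exposure; for shorter duty cycles the gap
        # decorrelation is neglected in the cross term
        s_y = c[None, :] ** 2 * np.abs(1.0 + z) ** 2 * s_x + 2.0 * dt * s_res
        s_meas = (mult * s_y).sum(axis=1) / np.sinc(f_arr * t_exp) ** 2
    else:
        s_meas = (mult * s_x).sum(axis=1)
    out = s_meas * 1e18
    return out if np.ndim(f) else float(out[0])


def psd_exponent(psd: PSDEstimate, f_lo: float = 0.0, f_hi: float = 10.0) -> float:
    """Slope of log10(power) vs log10(frequency) over ``(f_lo, f_hi]``.

    Captures the confinement state of the membrane; requires at least five
    positive-power bins in the band.
    """
    band = psd.band(f_lo, f_hi)
    keep = band.power > 0
    if keep.sum() < 5:
        raise ValueError("need at least 5 positive-power bins in the fit band")
    slope = np.polyfit(np.log10(band.freqs[keep]), np.log10(band.power[keep]), 1)[0]
    return float(slope)


class _FitGrid:
    """Log-binned fitting grid.

    Data power is arithmetically averaged within each log-spaced band; the
    model is averaged over (a subsample of) the same member frequencies, so
    the binning operation is applied identically to both sides and
    introduces no systematic offset that the fit could chase.
    """

    def __init__(
        self, freqs: np.ndarray, power: np.ndarray,
        bins_per_decade: Optional[int], max_rep: int = 5,
    ) -> None:
        if bins_per_decade is None:
            self.eval_freqs = freqs
            self.log_power = np.log10(power)
            self._segments = None
            return
        lo, hi = math.log10(freqs[0]), math.log10(freqs[-1])
        n_edges = max(int(math.ceil((hi - lo) * bins_per_decade)), 2) + 1
        edges = np.logspace(lo, hi, n_edges)
        edges[0] *= 1 - 1e-12
        edges[-1] *= 1 + 1e-12
        idx = np.digitize(freqs, edges) - 1
        rep_freqs: list[np.ndarray] = []
        segments: list[tuple[int, int]] = []
        p_out = []
        pos = 0
        for i in range(n_edges - 1):
            (members,) = np.nonzero(idx == i)
            if members.size == 0:
                continue
            if members.size > max_rep:
                members = members[
                    np.linspace(0, members.size - 1, max_rep).round().astype(int)
                ]
            rep_freqs.append(freqs[members])
            segments.append((pos, pos + members.size))
            pos += members.size
            p_out.append(power[idx == i].mean())
        self.eval_freqs = np.concatenate(rep_freqs)
        self.log_power = np.log10(np.asarray(p_out))
        self._segments = segments

    def bin_model(self, model_power: np.ndarray) -> np.ndarray:
        if self._segments is None:
            return model_power
        return np.array([model_power[a:b].mean() for a, b in self._segments])


# starting points for the multi-start fit: (sigma N/m, gamma N/m^3, eta Pa s)
_STARTS: tuple[tuple[float, float, float], ...] = (
    (5e-8, 1e5, 0.05),
    (3e-7, 1e6, 0.2),
    (2e-6, 1e7, 1.0),
)

# log10 bounds for (sigma, gamma, eta_eff, a_active)
_LOG_LO = np.array([-10.0, -2.0, -4.0, -5.0])
_LOG_HI = np.array([-3.0, 10.0, 3.0, 5.0])


def fit_psd(
    psd: PSDEstimate,
    init: Optional[MechanicalParams] = None,
    fit_band: Tuple[float, float] = (0.1, 10.0),
    q_band: Optional[Tuple[float, float]] = None,
    kappa: float = KAPPA_DEFAULT,
    temperature: float = T_DEFAULT,
    n_nodes: int = 128,
    confinement_form: str = "gamma_over_q",
    bins_per_decade: Optional[int] = 16,
    mode_shape: Optional[Tuple[int, int]] = None,
    pixel_size: Optional[float] = None,
    sampled: bool = False,
    exposure_fraction: float = 1.0,
    camera_floor: bool = False,
    noise_floor: Optional[float] = None,
) -> MechanicalParams:
    """Fit the Helfrich model to a measured PSD; kappa stays fixed.

    By default the continuum :func:`model_psd` over ``q_band`` is fitted.
    When the analysed region is small enough that individual undulation
    modes matter, pass ``mode_shape`` (patch extent in pixels) and
    ``pixel_size`` (nm) to fit the discrete :func:`model_psd_modes` instead;
    ``sampled=True`` additionally folds the camera sampling/exposure
    transfer (frame interval taken from the PSD) into the fitted model —
    the appropriate choice near the Nyquist frequency.  ``camera_floor``
    adds a fitted white detection-noise floor (constant in the raw
    spectrum, hence rising as 1/sinc^2 in exposure-corrected estimates),
    which otherwise biases the high-frequency tail and with it sigma;
    ``noise_floor`` instead fixes that floor at a known level (nm^2/Hz, as
    measured from dark frames or computed from the camera noise and the
    calibration slope), which is far more stable than fitting it.

    Least squares is performed on log10(power) over ``fit_band`` — the
    spectrum spans decades, and the log residual weighs them evenly.  With
    ``bins_per_decade`` set (default), bins are averaged into log-spaced
    frequency bands first, so every decade contributes comparable weight
    regardless of the linear bin density (and bin noise is averaged down);
    pass None to fit raw bins.  Parameters are optimised in log space
    (enforcing positivity); with no ``init``, three canned starts spanning
    the physiological range are tried and the best-r2 solution kept.
    ``a_active`` enters linearly, so its start is set by matching the
    geometric-mean power.  A solver failure or non-finite result is returned
    flagged (``fit_ok=False``), never silently.
    """
    if mode_shape is None and q_band is None:
        raise ValueError("q_band must be provided (see default_q_band)")
    if mode_shape is not None and pixel_size is None:
        raise ValueError("pixel_size (nm) is required with mode_shape")
    band = psd.band(*fit_band)
    good = band.power > 0
    if good.sum() < 10:
        raise ValueError("need at least 10 positive-power bins in fit_band")
    if np.all(band.power <= 0):
        raise ValueError("all-zero power in fit band")
    grid = _FitGrid(band.freqs[good], band.power[good], bins_per_decade)
    freqs = grid.eval_freqs
    logp = grid.log_power

    def eval_model(p: MechanicalParams) -> np.ndarray:
        if mode_shape is not None:
            return model_psd_modes(
                freqs, p, mode_shape, pixel_size,
                dt=psd.dt if sampled else None,
                exposure_fraction=exposure_fraction,
                confinement_form=confinement_form,
            )
        return model_psd(
            freqs, p, q_band[0], q_band[1], n_nodes=n_nodes,
            confinement_form=confinement_form,
        )

    if camera_floor and noise_floor is not None:
        raise ValueError("camera_floor and noise_floor are mutually exclusive")
    if (camera_floor or noise_floor is not None) and sampled and exposure_fraction > 0:
        # white detector noise enters after exposure integration, so the
        # correction applied to the data lifts it toward Nyquist
        floor_shape = 1.0 / np.sinc(freqs * exposure_fraction * psd.dt) ** 2
    else:
        floor_shape = np.ones_like(freqs)

    def log_model(theta: np.ndarray) -> np.ndarray:
        p = MechanicalParams(
            sigma=10.0 ** theta[0],
            gamma=10.0 ** theta[1],
            eta_eff=10.0 ** theta[2],
            a_active=10.0 ** theta[3],
            kappa=kappa,
            temperature=temperature,
        )
        m = eval_model(p)
        if camera_floor:
            m = m + 10.0 ** theta[4] * floor_shape
        elif noise_floor is not None:
            m = m + noise_floor * floor_shape
        return np.log10(grid.bin_model(m))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return log_model(theta) - logp

    if init is not None:
        starts = [(init.sigma, init.gamma, init.eta_eff)]
        a_inits = [init.a_active]
    else:
        starts = list(_STARTS)
        a_inits = [None] * len(starts)

    ss_tot = float(((logp - logp.mean()) ** 2).sum())
    best: Optional[Tuple[float, np.ndarray, bool]] = None
    for (s0, g0, e0), a0 in zip(starts, a_inits):
        if a0 is None:
            # amplitude start: A is a pure prefactor, match geometric means
            probe = MechanicalParams(
                sigma=s0, gamma=g0, eta_eff=e0, a_active=1.0,
                kappa=kappa, temperature=temperature,
            )
            lm = np.log10(grid.bin_model(eval_model(probe)))
            a0 = 10.0 ** float(np.mean(logp - lm))
        lo, hi = _LOG_LO, _LOG_HI
        theta0 = np.log10([s0, g0, e0, max(a0, 1e-5)])
        if camera_floor:
            lo = np.append(lo, -10.0)
            hi = np.append(hi, 4.0)
            theta0 = np.append(
                theta0, math.log10(max(10.0 ** logp.min() * 0.2, 1e-9))
            )
        theta0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(
                residuals, theta0, bounds=(lo, hi),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400,
            )
        except (ArithmeticError, ValueError):
            continue
        ss_res = float((sol.fun**2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -math.inf
        if best is None or r2 > best[0]:
            best = (r2, sol.x, bool(sol.success))

    try:
        exponent = psd_exponent(psd, f_lo=0.0, f_hi=fit_band[1])
    except ValueError:
        exponent = math.nan

    if best is None:
        fallback = init or MechanicalParams(
            sigma=_STARTS[1][0], gamma=_STARTS[1][1], eta_eff=_STARTS[1][2],
            a_active=1.0, kappa=kappa, temperature=temperature,
        )
        return replace(fallback, r2=-math.inf, exponent=exponent, fit_ok=False)

    r2, theta, ok = best
    return MechanicalParams(
        sigma=10.0 ** theta[0],
        gamma=10.0 ** theta[1],
        eta_eff=10.0 ** theta[2],
        a_active=10.0 ** theta[3],
        kappa=kappa,
        temperature=temperature,
        r2=r2,
        exponent=exponent,
        fit_ok=ok and math.isfinite(r2),
    )


def fit_sigma_only(
    psd: PSDEstimate,
    base: MechanicalParams,
    fit_band: Tuple[float, float] = (0.1, 10.0),
    q_band: Optional[Tuple[float, float]] = None,
    n_nodes: int = 128,
    confinement_form: str = "gamma_over_q",
    bins_per_decade: Optional[int] = 16,
    mode_shape: Optional[Tuple[int, int]] = None,
    pixel_size: Optional[float] = None,
    sampled: bool = False,
    exposure_fraction: float = 1.0,
    noise_floor: Optional[float] = None,
) -> MechanicalParams:
    """Refit the tension alone, holding gamma, eta_eff and a_active fixed.

    Local tension mapping benefits from a global-then-local strategy: the
    full four-parameter Helfrich fit has a soft direction (a common rescaling
    of sigma, gamma, eta_eff and a_active is constrained only through the
    fixed kappa), so per-region estimates scatter along it.  Estimating the
    medium parameters once on pooled data (``base``) and then sliding only
    sigma per tile pins that direction; relative tension between regions is
    then insensitive to the global scale uncertainty.
    """
    if mode_shape is None and q_band is None:
        raise ValueError("q_band must be provided (see default_q_band)")
    band = psd.band(*fit_band)
    good = band.power > 0
    if good.sum() < 10:
        raise ValueError("need at least 10 positive-power bins in fit_band")
    grid = _FitGrid(band.freqs[good], band.power[good], bins_per_decade)
    freqs = grid.eval_freqs
    logp = grid.log_power
    if noise_floor is not None and sampled and exposure_fraction > 0:
        floor_shape = 1.0 / np.sinc(freqs * exposure_fraction * psd.dt) ** 2
    else:
        floor_shape = np.ones_like(freqs)

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = replace(base, sigma=10.0 ** theta[0], r2=math.nan, exponent=math.nan)
        if mode_shape is not None:
            m = model_psd_modes(
                freqs, p, mode_shape, pixel_size,
                dt=psd.dt if sampled else None,
                exposure_fraction=exposure_fraction,
                confinement_form=confinement_form,
            )
        else:
            m = model_psd(
                freqs, p, q_band[0], q_band[1], n_nodes=n_nodes,
                confinement_form=confinement_form,
            )
        if noise_floor is not None:
            m = m + noise_floor * floor_shape
        return np.log10(grid.bin_model(m)) - logp

    theta0 = np.array([math.log10(max(base.sigma, 1e-9))])
    sol = least_squares(
        residuals, theta0, bounds=([_LOG_LO[0]], [_LOG_HI[0]]),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=200,
    )
    ss_tot = float(((logp - logp.mean()) ** 2).sum())
    r2 = 1.0 - float((sol.fun**2).sum()) / ss_tot if ss_tot > 0 else -math.inf
    return replace(
        base,
        sigma=10.0 ** float(sol.x[0]),
        r2=r2,
        exponent=math.nan,
        fit_ok=bool(sol.success) and math.isfinite(r2),
    )


@dataclass
class FitConfig:
    """Configuration for PSD fitting over a movie.

    ``block`` controls spatial granularity: 1 fits every pixel's own PSD;
    ``block > 1`` averages per-pixel PSDs over non-overlapping block x block
    tiles before fitting (the per-FBR statistic) and broadcasts the fitted
    values to the tile's pixels.
    """

    fit_band: Tuple[float, float] = (0.1, 10.0)
    q_band: Optional[Tuple[float, float]] = None  # derived from geometry if None
    q_tile_size: int = 12  # tile extent used for the default q_min
    r2_threshold: float = 0.8
    block: int = 1
    kappa: float = KAPPA_DEFAULT
    temperature: float = T_DEFAULT
    n_nodes: int = 128
    confinement_form: str = "gamma_over_q"
    exposure_time: Optional[float] = None  # s; enables sinc^2 exposure correction
    bins_per_decade: Optional[int] = 16
    # finite-patch fitting (see fit_psd): patch extent in pixels, and whether
    # to fold the camera sampling transfer into the fitted model
    mode_shape: Optional[Tuple[int, int]] = None
    sampled: bool = False
    noise_floor: Optional[float] = None
    # fit the medium parameters (gamma, eta_eff, a_active) once on the pooled
    # movie PSD and refit only sigma per pixel/block: pins the soft scaling
    # direction of the model so the map shows relative tension cleanly
    global_medium: bool = True


@dataclass
class TensionMap:
    """Per-pixel fitted mechanical parameter maps (NaN where no usable fit)."""

    sigma_map: np.ndarray
    r2_map: np.ndarray
    gamma_map: np.ndarray
    eta_map: np.ndarray
    a_map: np.ndarray
    config: FitConfig = field(default_factory=FitConfig)


def tension_map(hm, cfg: FitConfig | None = None) -> TensionMap:
    """Fit the Helfrich model across a height movie and assemble maps.

    The PSD is computed per pixel (or averaged per ``cfg.block`` tile), the
    model fitted, and pixels whose fit misses ``cfg.r2_threshold`` — or that
    are masked — are left missing.
    """
    cfg = cfg or FitConfig()
    if hm.n_frames < 512:
        raise ValueError("need >=512 frames for per-pixel spectral fitting")
    rows, cols = hm.shape
    q_band = cfg.q_band or default_q_band(cfg.q_tile_size, hm.pixel_size)
    maps = {
        k: np.full((rows, cols), np.nan)
        for k in ("sigma", "r2", "gamma", "eta", "a")
    }
    pixel_mask = hm.pixel_mask
    data = np.asarray(hm.heights.filled(0.0))
    b = cfg.block
    common = dict(
        fit_band=cfg.fit_band,
        confinement_form=cfg.confinement_form,
        bins_per_decade=cfg.bins_per_decade,
        mode_shape=cfg.mode_shape,
        pixel_size=hm.pixel_size if cfg.mode_shape else None,
        sampled=cfg.sampled,
        noise_floor=cfg.noise_floor,
    )
    base: Optional[MechanicalParams] = None
    if cfg.global_medium:
        pooled = data[:, ~pixel_mask].reshape(hm.n_frames, -1)
        if pooled.shape[1] == 0:
            return TensionMap(
                sigma_map=maps["sigma"], r2_map=maps["r2"],
                gamma_map=maps["gamma"], eta_map=maps["eta"], a_map=maps["a"],
                config=cfg,
            )
        psd = estimate_psd_fft_stack(pooled, hm.dt)
        if cfg.exposure_time:
            psd = exposure_correct(psd, cfg.exposure_time)
        base = fit_psd(
            psd, q_band=q_band, kappa=cfg.kappa, temperature=cfg.temperature,
            n_nodes=cfg.n_nodes, **common,
        )
    for r0 in range(0, rows - b + 1, b):
        for c0 in range(0, cols - b + 1, b):
            sl = (slice(r0, r0 + b), slice(c0, c0 + b))
            if pixel_mask[sl].any():
                continue
            block_px = data[:, sl[0], sl[1]].reshape(hm.n_frames, -1)
            psd = estimate_psd_fft_stack(block_px, hm.dt)
            if cfg.exposure_time:
                psd = exposure_correct(psd, cfg.exposure_time)
            if base is not None and base.fit_ok:
                fitted = fit_sigma_only(
                    psd, base, q_band=q_band, n_nodes=cfg.n_nodes, **common
                )
            else:
                fitted = fit_psd(
                    psd, q_band=q_band, kappa=cfg.kappa,
                    temperature=cfg.temperature, n_nodes=cfg.n_nodes, **common,
                )
            if not fitted.fit_ok or fitted.r2 < cfg.r2_threshold:
                continue
            maps["sigma"][sl] = fitted.sigma
            maps["r2"][sl] = fitted.r2
            maps["gamma"][sl] = fitted.gamma
            maps["eta"][sl] = fitted.eta_eff
            maps["a"][sl] = fitted.a_active
    return TensionMap(
        sigma_map=maps["sigma"],
        r2_map=maps["r2"],
        gamma_map=maps["gamma"],
        eta_map=maps["eta"],
        a_map=maps["a"],
        config=cfg,
    )
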