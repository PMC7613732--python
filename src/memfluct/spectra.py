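"""Power spectral density estimation for height time series.

Two estimators are provided, mirroring common practice in flicker
spectroscopy: a direct FFT periodogram (optionally segment-averaged) and an
autoregressive estimate fitted by the covariance (conditional least squares)
method.  Both return one-sided densities in nm²/Hz on a frequency axis that
excludes 0 Hz, normalised so that ``sum(power) * df`` equals the variance of
the mean-removed series (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "PSDEstimate",
    "DegenerateModelError",
    "estimate_psd_fft",
    "estimate_psd_ar",
    "exposure_correct",
]


class DegenerateModelError(RuntimeError):
    """The fitted autoregressive model is unstable or degenerate."""


def exposure_correct(psd: "PSDEstimate", exposure_time: float) -> "PSDEstimate":
    """Undo the sinc^2 attenuation of camera exposure integration.

    A detector integrating over ``exposure_time`` seconds low-passes the
    signal with transfer ``sinc^2(f * exposure_time)``; dividing the measured
    density by it restores the underlying spectrum (accurate away from the
    Nyquist frequency).
    """
    if exposure_time < 0:
        raise ValueError("exposure_time must be non-negative")
    if exposure_time == 0:
        return psd
    corr = np.sinc(psd.freqs * exposure_time) ** 2
    return PSDEstimate(
        psd.freqs, psd.power / corr, psd.method, psd.n_frames, psd.dt
    )


@dataclass
class PSDEstimate:
    """One-sided PSD of a height series.

    Attributes
    ----------
    freqs : ndarray
        Frequencies in Hz, strictly increasing, 0 Hz excluded.
    power : ndarray
        Power density in nm²/Hz; non-negative.
    method : str
        ``"fft"`` or ``"autoregressive"``.
    n_frames : int
        Number of samples in the analysed series.
    dt : float
        Sampling interval in seconds.
    """

    freqs: np.ndarray
    power: np.ndarray
    method: str
    n_frames: int
    dt: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have matching shapes")

    def band(self, f_lo: float, f_hi: float) -> "PSDEstimate":
        """Restrict to frequencies in ``(f_lo, f_hi]``."""
        keep = (self.freqs > f_lo) & (self.freqs <= f_hi)
        return PSDEstimate(
            self.freqs[keep], self.power[keep], self.method, self.n_frames, self.dt
        )

    def to_frame(self):
        """Tidy export: one row per bin (freq_hz, power_nm2_per_hz)."""
        import pandas as pd

        return pd.DataFrame(
            {"freq_hz": self.freqs, "power_nm2_per_hz": self.power}
        )


def _validate_series(series: np.ndarray) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite samples")
    return x


def estimate_psd_fft(
    series: np.ndarray, dt: float, nperseg: int | None = None
) -> PSDEstimate:
    """One-sided periodogram of a height series.

    The mean is removed, and with ``nperseg`` set the estimate is
    segment-averaged (boxcar Welch); otherwise a plain periodogram is used so
    that ``sum(power) * df`` reproduces the series variance exactly.
    """
    x = _validate_series(series)
    if x.size < 64:
        raise ValueError("need at least 64 frames for a PSD estimate")
    if dt <= 0:
        raise ValueError("dt must be positive")
    fs = 1.0 / dt
    if nperseg is None:
        f, p = signal.periodogram(x, fs=fs, window="boxcar", detrend="constant")
    else:
        f, p = signal.welch(
            x, fs=fs, window="boxcar", nperseg=nperseg, noverlap=0, detrend="constant"
        )
    return PSDEstimate(f[1:], p[1:], "fft", x.size, dt)


def estimate_psd_fft_stack(pixels: np.ndarray, dt: float) -> PSDEstimate:
    """Periodogram averaged over many pixels of one region.

    ``pixels`` is ``(n_frames, n_pixels)``; per-pixel periodograms of the
    mean-removed series are averaged, sharpening the estimate while keeping
    the Parseval normalisation (against the pixel-averaged variance).
    """
    x = np.asarray(pixels, dtype=float)
    if x.ndim != 2:
        raise ValueError("pixels must be (n_frames, n_pixels)")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite samples")
    fs = 1.0 / dt
    f, p = signal.periodogram(
        x, fs=fs, window="boxcar", detrend="constant", axis=0
    )
    return PSDEstimate(f[1:], p[1:].mean(axis=1), "fft", x.shape[0], dt)


def estimate_psd_ar(series: np.ndarray, dt: float, order: int = 24) -> PSDEstimate:
    """Autoregressive (covariance-method) PSD estimate.

    An AR(``order``) model is fitted to the mean-removed series by
    conditional least squares and its one-sided rational spectrum

        S(f) = 2 * sigma2 * dt / |1 - sum_k a_k exp(-2 pi i f k dt)|^2

    is evaluated on the same frequency grid the FFT estimator uses.  An
    unstable fitted model (roots on or inside the unit circle of the AR
    polynomial) raises :class:`DegenerateModelError`.
    """
    x = _validate_series(series)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0 < order < x.size / 2:
        raise ValueError("order must satisfy 0 < order < n_frames/2")
    n = x.size
    fs = 1.0 / dt
    freqs = np.fft.rfftfreq(n, d=dt)[1:]
    xc = x - x.mean()
    if np.allclose(xc, 0.0):
        return PSDEstimate(freqs, np.zeros_like(freqs), "autoregressive", n, dt)

    from statsmodels.tsa.ar_model import AutoReg

    res = AutoReg(xc, lags=order, trend="n").fit()
    a = np.asarray(res.params, dtype=float)
    sigma2 = float(res.sigma2)
    # stability: roots of 1 - a_1 z^-1 - ... - a_p z^-p must lie inside |z|<1
    roots = np.roots(np.concatenate(([1.0], -a)))
    if np.any(np.abs(roots) >= 1.0 - 1e-10):
        raise DegenerateModelError("fitted AR model is unstable")
    k = np.arange(1, order + 1)
    # transfer denominator on the shared frequency grid
    z = np.exp(-2j * np.pi * freqs[:, None] * k[None, :] * dt)
    denom = np.abs(1.0 - z @ a) ** 2
    power = 2.0 * sigma2 * dt / denom
    return PSDEstimate(freqs, power, "autoregressive", n, dt)
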