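"""IRM intensity–height calibration on the first interference branch.

In interference reflection microscopy the reflected intensity at a pixel
encodes the distance ``h`` between the basal membrane and the coverslip
through thin-film interference.  For a two-beam interferometer the intensity
follows

    I(h) = i_mid - amp * cos(4 pi n h / lambda)

with ``i_mid = (i_max + i_min) / 2`` and ``amp = (i_max - i_min) / 2``, where
``n`` is the refractive index of the medium and ``lambda`` the illumination
wavelength.  The relation increases monotonically from ``i_min`` at ``h = 0``
up to ``i_max`` at ``h = lambda / (4 n)`` (~100 nm for green light in aqueous
medium) — the *first branch* — and reverses beyond it, so heights are only
recoverable unambiguously on this branch.

Because net reflectivity varies from cell to cell, a bank of calibration
curves (built from large-bead reference images) is kept and the curve whose
intensity extremes best match those observed in a given cell is selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationCurve",
    "OutOfBranchError",
    "ConfigurationError",
    "intensity_of_height",
    "height_of_intensity",
    "select_curve",
    "load_bank",
    "save_bank",
]

#: default illumination wavelength, nm (green interference filter)
DEFAULT_WAVELENGTH_NM = 546.0
#: default refractive index of the imaging medium (aqueous)
DEFAULT_REFRACTIVE_INDEX = 1.337


class OutOfBranchError(ValueError):
    """Height or intensity falls outside the first interference branch."""


class ConfigurationError(ValueError):
    """Invalid calibration configuration (e.g. empty curve bank)."""


@dataclass(frozen=True)
class CalibrationCurve:
    """One intensity–height calibration curve for the first branch.

    Parameters
    ----------
    i_min : float
        Intensity at zero membrane height (camera units).
    i_max : float
        Intensity at the first-branch maximum, ``h = wavelength / (4 n)``.
    wavelength : float
        Illumination wavelength in nm.
    refractive_index : float
        Refractive index of the medium between membrane and coverslip.
    """

    i_min: float
    i_max: float
    wavelength: float = DEFAULT_WAVELENGTH_NM
    refractive_index: float = DEFAULT_REFRACTIVE_INDEX

    def __post_init__(self) -> None:
        if not self.i_max > self.i_min:
            raise ConfigurationError(
                f"i_max ({self.i_max}) must exceed i_min ({self.i_min})"
            )
        if self.wavelength <= 0 or self.refractive_index <= 0:
            raise ConfigurationError("wavelength and refractive_index must be positive")

    @property
    def h_branch(self) -> float:
        """First-branch height extent, ``wavelength / (4 n)`` in nm."""
        return self.wavelength / (4.0 * self.refractive_index)

    @property
    def i_mid(self) -> float:
        return 0.5 * (self.i_max + self.i_min)

    @property
    def amplitude(self) -> float:
        return 0.5 * (self.i_max - self.i_min)


def intensity_of_height(h, curve: CalibrationCurve):
    """Map membrane height (nm) to IRM intensity on the first branch.

    Accepts scalars or arrays.  Heights outside ``[0, h_branch]`` raise
    :class:`OutOfBranchError`.
    """
    h_arr = np.asarray(h, dtype=float)
    hb = curve.h_branch
    if np.any(h_arr < -1e-12) or np.any(h_arr > hb * (1 + 1e-12)):
        raise OutOfBranchError(
            f"height outside first branch [0, {hb:.3f}] nm"
        )
    phase = 4.0 * math.pi * curve.refractive_index * h_arr / curve.wavelength
    out = curve.i_mid - curve.amplitude * np.cos(phase)
    return float(out) if np.isscalar(h) else out


def height_of_intensity(i, curve: CalibrationCurve):
    """Invert the first-branch intensity–height relation (returns nm).

    Exact inverse of :func:`intensity_of_height` on ``[i_min, i_max]``;
    intensities outside that range raise :class:`OutOfBranchError` so that
    the caller can decide how to mask (clamping would bias fluctuation
    amplitudes).
    """
    i_arr = np.asarray(i, dtype=float)
    span = curve.amplitude
    tol = 1e-9 * max(span, 1.0)
    if np.any(i_arr < curve.i_min - tol) or np.any(i_arr > curve.i_max + tol):
        raise OutOfBranchError(
            f"intensity outside first branch [{curve.i_min}, {curve.i_max}]"
        )
    cosarg = np.clip((curve.i_mid - i_arr) / span, -1.0, 1.0)
    h = np.arccos(cosarg) * curve.wavelength / (4.0 * math.pi * curve.refractive_index)
    return float(h) if np.isscalar(i) else h


def in_branch(i, curve: CalibrationCurve) -> np.ndarray:
    """Boolean mask of intensities that lie on the first branch."""
    i_arr = np.asarray(i, dtype=float)
    return (i_arr >= curve.i_min) & (i_arr <= curve.i_max)


def select_curve(
    observed_min: float,
    observed_max: float,
    bank: Sequence[CalibrationCurve],
) -> CalibrationCurve:
    """Pick the bank curve nearest the observed single-cell intensity extremes.

    Distance is Euclidean on the ``(i_min, i_max)`` pair; ties break to the
    lowest bank index, so the choice is deterministic.
    """
    if len(bank) == 0:
        raise ConfigurationError("calibration bank is empty")
    if not observed_max > observed_min:
        raise ValueError("observed_max must exceed observed_min")
    d2 = [
        (c.i_min - observed_min) ** 2 + (c.i_max - observed_max) ** 2 for c in bank
    ]
    return bank[int(np.argmin(d2))]


def load_bank(path: Union[str, Path]) -> list[CalibrationCurve]:
    """Read a calibration bank from delimited text.

    One curve per row with columns ``i_min, i_max, wavelength_nm,
    refractive_index`` (header optional; comma or whitespace separated).
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    # headerless files come back with numeric-looking column names
    try:
        [float(c) for c in df.columns]
    except (TypeError, ValueError):
        pass
    else:
        df = pd.read_csv(
            path,
            sep=None,
            engine="python",
            comment="#",
            header=None,
            names=["i_min", "i_max", "wavelength_nm", "refractive_index"],
        )
    df.columns = [str(c).strip().lower() for c in df.columns]
    return [
        CalibrationCurve(
            i_min=float(r["i_min"]),
            i_max=float(r["i_max"]),
            wavelength=float(r.get("wavelength_nm", DEFAULT_WAVELENGTH_NM)),
            refractive_index=float(
                r.get("refractive_index", DEFAULT_REFRACTIVE_INDEX)
            ),
        )
        for _, r in df.iterrows()
    ]


def save_bank(bank: Sequence[CalibrationCurve], path: Union[str, Path]) -> None:
    """Write a calibration bank as CSV (inverse of :func:`load_bank`)."""
    pd.DataFrame(
        {
            "i_min": [c.i_min for c in bank],
            "i_max": [c.i_max for c in bank],
            "wavelength_nm": [c.wavelength for c in bank],
            "refractive_index": [c.refractive_index for c in bank],
        }
    ).to_csv(path, index=False)
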