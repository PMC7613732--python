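"""Height movies, first-branch regions (FBRs) and fluctuation amplitudes.

A :class:`HeightMovie` holds per-pixel membrane height time series (nm)
reconstructed from an IRM intensity stack.  Pixels whose intensity leaves the
first interference branch in *any* frame are masked for the whole series, so
every temporal statistic is defined on complete series.

Analysis proceeds on square tiles — first branch regions (FBRs) — that are
fully in-branch for the whole movie and whose pixels are neither abnormally
quiet (e.g. focal adhesions) nor abnormally noisy (cell interior).  Two
amplitude statistics are computed per FBR:

* ``SD_time`` — per-pixel temporal standard deviation, averaged over the tile;
* ``SD_space`` — per-frame spatial standard deviation over the tile's pixels,
  averaged over the first ``n_frames`` frames (20 by default).

Sample standard deviations (``ddof=1``) are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, height_of_intensity, in_branch

__all__ = [
    "HeightMovie",
    "FBRSet",
    "build_height_movie",
    "select_fbrs",
    "sd_time",
    "sd_space",
    "intracellular_variation",
    "fbr_table",
]

Tile = Tuple[int, int]


@dataclass
class HeightMovie:
    """Per-pixel membrane height time series on a fixed grid.

    Attributes
    ----------
    heights : numpy.ma.MaskedArray
        Heights in nm, indexed ``(frame, row, col)``.  Masked entries mark
        pixels excluded because they left the first branch at some frame.
    dt : float
        Frame interval in seconds.
    pixel_size : float
        Pixel edge length in nm.
    """

    heights: np.ma.MaskedArray
    dt: float
    pixel_size: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        h = np.ma.asarray(self.heights)
        if h.ndim != 3:
            raise ValueError("heights must be (frame, row, col)")
        self.heights = h

    @property
    def n_frames(self) -> int:
        return self.heights.shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.heights.shape[1:]

    @property
    def pixel_mask(self) -> np.ndarray:
        """Boolean (row, col) array; True where the pixel is excluded."""
        m = np.ma.getmaskarray(self.heights)
        return m.any(axis=0)


@dataclass
class FBRSet:
    """Selected first-branch-region tiles and the per-tile selection log."""

    tile_size: int
    tiles: list[Tile]
    selection_log: dict[Tile, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)


def build_height_movie(
    stack: np.ndarray,
    curve: CalibrationCurve,
    dt: float = 0.05,
    pixel_size: float = 180.0,
) -> HeightMovie:
    """Convert an IRM intensity stack to a masked height movie.

    Pixels are scrutinized frame by frame: any pixel whose intensity falls
    outside ``[i_min, i_max]`` (off the first branch) in at least one frame is
    masked for the whole series; the remaining pixels are inverted through the
    calibration curve.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be a (frames, rows, cols) array with >=2 frames")
    good = in_branch(stack, curve).all(axis=0)
    heights = np.zeros_like(stack)
    if good.any():
        heights[:, good] = height_of_intensity(stack[:, good], curve)
    mask = np.broadcast_to(~good, stack.shape).copy()
    return HeightMovie(
        heights=np.ma.MaskedArray(heights, mask=mask),
        dt=dt,
        pixel_size=pixel_size,
    )


def _tile_corners(shape: Tuple[int, int], tile_size: int) -> list[Tile]:
    """Non-overlapping raster-order tiling that stays inside image bounds."""
    rows, cols = shape
    return [
        (r0, c0)
        for r0 in range(0, rows - tile_size + 1, tile_size)
        for c0 in range(0, cols - tile_size + 1, tile_size)
    ]


def _pixel_sd_time(hm: HeightMovie) -> np.ma.MaskedArray:
    return hm.heights.std(axis=0, ddof=1)


def select_fbrs(
    hm: HeightMovie,
    tile_size: int = 12,
    low_q: float = 0.05,
    high_q: float = 0.95,
) -> FBRSet:
    """Select analyzable FBR tiles.

    A tile qualifies when every pixel is in-branch for the whole series and
    every pixel's temporal SD lies within the ``[low_q, high_q]`` quantiles of
    the in-branch per-pixel SD distribution — excluding abnormally quiet
    pixels (focal adhesions) and abnormally noisy ones (cell interior).
    An empty result is not an error; consult ``selection_log`` for reasons.
    """
    if tile_size < 2:
        raise ValueError("tile_size must be >= 2")
    if not (0 <= low_q < high_q <= 1):
        raise ValueError("require 0 <= low_q < high_q <= 1")
    pixel_mask = hm.pixel_mask
    sd_map = _pixel_sd_time(hm)
    in_sd = sd_map.compressed()
    tiles: list[Tile] = []
    log: dict[Tile, str] = {}
    if in_sd.size == 0:
        for t in _tile_corners(hm.shape, tile_size):
            log[t] = "masked"
        return FBRSet(tile_size=tile_size, tiles=[], selection_log=log)
    lo, hi = np.quantile(in_sd, [low_q, high_q])
    for r0, c0 in _tile_corners(hm.shape, tile_size):
        sl = (slice(r0, r0 + tile_size), slice(c0, c0 + tile_size))
        if pixel_mask[sl].any():
            log[(r0, c0)] = "masked"
            continue
        tile_sd = np.asarray(sd_map[sl])
        if (tile_sd < lo).any():
            log[(r0, c0)] = "sd_low"
        elif (tile_sd > hi).any():
            log[(r0, c0)] = "sd_high"
        else:
            log[(r0, c0)] = "ok"
            tiles.append((r0, c0))
    return FBRSet(tile_size=tile_size, tiles=tiles, selection_log=log)


def _check_tile(hm: HeightMovie, tile: Tile, tile_size: int) -> tuple[slice, slice]:
    r0, c0 = tile
    rows, cols = hm.shape
    if r0 < 0 or c0 < 0 or r0 + tile_size > rows or c0 + tile_size > cols:
        raise ValueError(f"tile {tile} with size {tile_size} exceeds image bounds")
    sl = (slice(r0, r0 + tile_size), slice(c0, c0 + tile_size))
    if hm.pixel_mask[sl].any():
        raise ValueError(f"tile {tile} contains masked (out-of-branch) pixels")
    return sl


def sd_time(hm: HeightMovie, tile: Tile, tile_size: int = 12) -> float:
    """Temporal fluctuation amplitude of one FBR (nm).

    Per-pixel sample SD of the height time series, averaged over the tile.
    """
    sl = _check_tile(hm, tile, tile_size)
    data = np.asarray(hm.heights[:, sl[0], sl[1]])
    return float(data.std(axis=0, ddof=1).mean())


def sd_space(hm: HeightMovie, tile: Tile, tile_size: int = 12, n_frames: int = 20) -> float:
    """Spatial undulation amplitude of one FBR (nm).

    Per-frame sample SD across the tile's pixels, averaged over the first
    ``n_frames`` frames.
    """
    if n_frames > hm.n_frames:
        raise ValueError("n_frames exceeds movie length")
    sl = _check_tile(hm, tile, tile_size)
    data = np.asarray(hm.heights[:n_frames, sl[0], sl[1]])
    per_frame = data.reshape(n_frames, -1).std(axis=1, ddof=1)
    return float(per_frame.mean())


def intracellular_variation(values: Sequence[float]) -> Tuple[float, float]:
    """Cell-internal heterogeneity of a per-FBR statistic.

    Returns ``(sd, sd / mean)`` over the supplied per-FBR values; the
    mean-normalized SD removes the effect of a changing mean when comparing
    heterogeneity across conditions.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    sd = float(v.std(ddof=1))
    mean = float(v.mean())
    if mean == 0.0:
        if sd == 0.0:
            return 0.0, 0.0
        raise ZeroDivisionError("mean is zero with nonzero SD: normalization undefined")
    return sd, sd / mean


def fbr_table(
    hm: HeightMovie,
    fbrs: FBRSet,
    cell_id: str = "cell",
    n_frames_space: int = 20,
) -> pd.DataFrame:
    """Tidy per-FBR statistics: one row per tile with SD_time and SD_space."""
    rows = []
    for (r0, c0) in fbrs:
        rows.append(
            {
                "cell_id": cell_id,
                "row0": r0,
                "col0": c0,
                "tile_size": fbrs.tile_size,
                "sd_time_nm": sd_time(hm, (r0, c0), fbrs.tile_size),
                "sd_space_nm": sd_space(
                    hm, (r0, c0), fbrs.tile_size, min(n_frames_space, hm.n_frames)
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "row0", "col0", "tile_size", "sd_time_nm", "sd_space_nm"],
    )
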