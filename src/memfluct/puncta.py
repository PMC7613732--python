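"""Fluorescence puncta detection and cluster/background quantification.

Surface fusogen (myomerger) immunofluorescence appears as bright puncta on a
diffuse background.  Clusters are segmented by local-mean thresholding with
an additive offset followed by connected-component labelling; the readouts
are the ratio of mean cluster intensity to mean diffuse-background intensity
within an ROI, the puncta density, and region-wise rank correlations between
local tension and local fluorescence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure

__all__ = [
    "ClusterSegmentation",
    "CorrelationRecord",
    "UndefinedRatioError",
    "detect_clusters",
    "cluster_ratio",
    "puncta_density",
    "local_correlation",
    "correlation_class_fractions",
]

Rect = Tuple[int, int, int, int]  # (row0, col0, height, width)


class UndefinedRatioError(ValueError):
    """Cluster/background ratio requested with no detected clusters."""


@dataclass
class ClusterSegmentation:
    """Labelled puncta mask over an ROI.

    ``mask`` is the binary cluster indicator, ``labels`` the per-object ids
    (contiguous from 1), both with the full image shape; ``roi`` is the
    rectangle analysed.  ``objects`` is a tidy per-object table
    (id, area_px, centroid, mean_intensity).
    """

    mask: np.ndarray
    labels: np.ndarray
    n_objects: int
    roi: Rect
    objects: pd.DataFrame

    def roi_slices(self) -> Tuple[slice, slice]:
        r0, c0, h, w = self.roi
        return slice(r0, r0 + h), slice(c0, c0 + w)


def detect_clusters(
    img: np.ndarray,
    window: int = 15,
    offset: float = 10.0,
    min_area: int = 4,
    roi: Optional[Rect] = None,
) -> ClusterSegmentation:
    """Segment bright puncta by local thresholding and object detection.

    A pixel is a cluster candidate when its intensity exceeds the local mean
    over a ``window``-pixel square by at least ``offset``; candidates are
    grouped with 8-connectivity and components smaller than ``min_area``
    pixels are discarded.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("img must be 2-D")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > min(img.shape):
        raise ValueError("window larger than image")
    if roi is None:
        roi = (0, 0, img.shape[0], img.shape[1])
    r0, c0, h, w = roi
    if h <= 0 or w <= 0 or r0 < 0 or c0 < 0 or r0 + h > img.shape[0] or c0 + w > img.shape[1]:
        raise ValueError("roi outside image")

    local_mean = ndimage.uniform_filter(img, size=window, mode="reflect")
    candidate = img > local_mean + offset
    inside = np.zeros_like(candidate)
    inside[r0 : r0 + h, c0 : c0 + w] = candidate[r0 : r0 + h, c0 : c0 + w]

    labels = measure.label(inside, connectivity=2)
    props = measure.regionprops(labels, intensity_image=img)
    keep = [p for p in props if p.area >= min_area]
    relabel = np.zeros_like(labels)
    records = []
    for new_id, p in enumerate(sorted(keep, key=lambda p: p.label), start=1):
        relabel[labels == p.label] = new_id
        records.append(
            {
                "id": new_id,
                "area_px": int(p.area),
                "centroid_row": float(p.centroid[0]),
                "centroid_col": float(p.centroid[1]),
                "mean_intensity": float(p.intensity_mean),
            }
        )
    objects = pd.DataFrame(
        records,
        columns=["id", "area_px", "centroid_row", "centroid_col", "mean_intensity"],
    )
    return ClusterSegmentation(
        mask=relabel > 0,
        labels=relabel,
        n_objects=len(records),
        roi=roi,
        objects=objects,
    )


def cluster_ratio(img: np.ndarray, seg: ClusterSegmentation) -> float:
    """Mean intensity inside clusters / mean diffuse background in the ROI.

    Raises :class:`UndefinedRatioError` when no cluster exists — the ratio
    must never silently read 0.
    """
    img = np.asarray(img, dtype=float)
    if seg.n_objects == 0:
        raise UndefinedRatioError("no clusters detected in ROI")
    rs, cs = seg.roi_slices()
    roi_img = img[rs, cs]
    roi_mask = seg.mask[rs, cs]
    if roi_mask.all():
        raise UndefinedRatioError("no background pixels left in ROI")
    fg = float(roi_img[roi_mask].mean())
    bg = float(roi_img[~roi_mask].mean())
    return fg / bg


def puncta_density(seg: ClusterSegmentation, pixel_size: float) -> float:
    """Puncta count per square micrometre of ROI (``pixel_size`` in nm)."""
    _, _, h, w = seg.roi
    area_um2 = h * w * (pixel_size / 1000.0) ** 2
    if area_um2 <= 0:
        raise ValueError("roi area must be positive")
    return seg.n_objects / area_um2


@dataclass
class CorrelationRecord:
    """Region-wise tension–intensity rank correlation for one cell section."""

    rho: float
    p_value: float
    n_regions: int
    klass: str  # "negative" | "positive" | "ns"


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (no ties)."""
    n = x.size
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    denom = n * (n**2 - 1)
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(ry):
        d2 = ((rx - np.asarray(perm)) ** 2).sum()
        rho = 1.0 - 6.0 * d2 / denom
        if abs(rho) >= target:
            count += 1
        total += 1
    return count / total


def local_correlation(
    tension_values: Sequence[float],
    intensity_values: Sequence[float],
    alpha: float = 0.05,
) -> CorrelationRecord:
    """Spearman correlation between region-wise tension and fluorescence.

    Both lists hold one value per matched FBR-sized region of the same cell
    section.  The p-value is an exact permutation enumeration for n <= 9
    samples without ties, and the large-sample approximation otherwise.
    Classification: ``negative``/``positive`` when significant at ``alpha``,
    ``ns`` otherwise.
    """
    x = np.asarray(tension_values, dtype=float)
    y = np.asarray(intensity_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("tension and intensity lists must be 1-D and paired")
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 paired regions")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input list: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    no_ties = np.unique(x).size == n and np.unique(y).size == n
    if n <= 9 and no_ties:
        p = _exact_spearman_p(x, y, rho)
    p = float(p)
    if p < alpha:
        klass = "negative" if rho < 0 else "positive"
    else:
        klass = "ns"
    return CorrelationRecord(rho=rho, p_value=p, n_regions=n, klass=klass)


def correlation_class_fractions(
    records: Sequence[CorrelationRecord],
) -> dict[str, float]:
    """Fraction of cell sections in each correlation class (sums to 1)."""
    if len(records) == 0:
        raise ValueError("no correlation records")
    out = {"negative": 0.0, "positive": 0.0, "ns": 0.0}
    for r in records:
        out[r.klass] += 1.0
    return {k: v / len(records) for k, v in out.items()}
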