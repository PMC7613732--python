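"""Cohort-level metrics for longitudinal single-cell mechanics.

Cells followed through differentiation (nominal timepoints 2, 24, 48, 72,
96 h) are summarised per timepoint by tension and fluctuation amplitude and
labelled by final fate: FD (finally differentiated / fused) or FU (finally
undifferentiated).  Metrics:

* fusion index — percent of nuclei residing in myotubes within a frame;
* trajectory normalisation — fold change relative to the same cell's 2-h
  value, making cells with different baselines comparable;
* dip detection — a transient tension decrease at 24 h (relative drop of at
  least ``depth``), optionally recovered by 48 h;
* FD/FU ratio — ratio of group mean tensions at a timepoint;
* dip x fate contingency table.

Exports are tidy one-row-per-(cell, timepoint) tables ready for external
mixed-model or rank testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "CellTrajectory",
    "FusionCount",
    "fusion_index",
    "normalize_trajectory",
    "detect_dip",
    "fate_ratio",
    "dip_fate_table",
    "cohort_to_table",
    "cohort_from_table",
]

NOMINAL_TIMEPOINTS_H = (2.0, 24.0, 48.0, 72.0, 96.0)


@dataclass
class CellTrajectory:
    """Per-cell longitudinal record.

    ``tension`` (N/m) and optional ``sd_time`` (nm) are aligned with
    ``timepoints_h``; missing measurements are NaN and are never
    interpolated.  ``fate`` is an input label ("FD", "FU" or "unknown").
    """

    cell_id: str
    timepoints_h: Tuple[float, ...]
    tension: Tuple[float, ...]
    sd_time: Optional[Tuple[float, ...]] = None
    fate: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.timepoints_h) != len(self.tension):
            raise ValueError("timepoints and tension must align")
        if any(b <= a for a, b in zip(self.timepoints_h, self.timepoints_h[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.sd_time is not None and len(self.sd_time) != len(self.timepoints_h):
            raise ValueError("sd_time must align with timepoints")
        if self.fate not in ("FD", "FU", "unknown"):
            raise ValueError("fate must be FD, FU or unknown")

    def value_at(self, timepoint_h: float, field: str = "tension") -> float:
        series = self.tension if field == "tension" else self.sd_time
        if series is None:
            raise ValueError(f"trajectory has no {field} values")
        for t, v in zip(self.timepoints_h, series):
            if math.isclose(t, timepoint_h):
                return v
        return math.nan


@dataclass(frozen=True)
class FusionCount:
    """Nuclei counted in one frame: inside myotubes vs total."""

    nuclei_in_myotubes: int
    nuclei_total: int

    def __post_init__(self) -> None:
        if self.nuclei_total <= 0:
            raise ValueError("nuclei_total must be positive")
        if not 0 <= self.nuclei_in_myotubes <= self.nuclei_total:
            raise ValueError("0 <= nuclei_in_myotubes <= nuclei_total required")


def fusion_index(fc: FusionCount) -> float:
    """Percent of nuclei residing in multinucleated myotubes."""
    return 100.0 * fc.nuclei_in_myotubes / fc.nuclei_total


def normalize_trajectory(tr: CellTrajectory, field: str = "tension") -> CellTrajectory:
    """Express a trajectory as fold change over the cell's own 2-h value.

    The first (reference) timepoint maps to 1; a missing or zero reference is
    an error since no fold change is defined.
    """
    series = tr.tension if field == "tension" else tr.sd_time
    if series is None:
        raise ValueError(f"trajectory has no {field} values")
    ref = series[0]
    if not math.isfinite(ref) or ref == 0:
        raise ValueError(f"missing or zero reference value for cell {tr.cell_id}")
    normed = tuple(v / ref for v in series)
    if field == "tension":
        return replace(tr, tension=normed)
    return replace(tr, sd_time=normed)


def detect_dip(
    tr: CellTrajectory,
    depth: float = 0.1,
    recovery: float = 0.9,
    field: str = "tension",
) -> Tuple[bool, bool]:
    """Flag a transient 24-h dip in a *normalised* trajectory.

    ``has_dip`` — the 24-h fold change is at most ``1 - depth``;
    ``recovered`` — additionally the 48-h fold change is back to at least
    ``recovery``.  Thresholds are reported with any exported table since the
    dip definition is a tunable convention.
    """
    if not (0 < depth <= 1 and 0 < recovery <= 1):
        raise ValueError("depth and recovery must lie in (0, 1]")
    v24 = tr.value_at(24.0, field)
    if not math.isfinite(v24):
        raise ValueError(f"cell {tr.cell_id}: missing 24 h value")
    has_dip = v24 <= 1.0 - depth
    v48 = tr.value_at(48.0, field)
    recovered = bool(has_dip and math.isfinite(v48) and v48 >= recovery)
    return has_dip, recovered


def fate_ratio(
    cohort: Sequence[CellTrajectory],
    timepoint_h: float,
    field: str = "tension",
) -> float:
    """Ratio of FD to FU group mean values at one timepoint."""
    groups: dict[str, list[float]] = {"FD": [], "FU": []}
    for tr in cohort:
        if tr.fate in groups:
            v = tr.value_at(timepoint_h, field)
            if math.isfinite(v):
                groups[tr.fate].append(v)
    if not groups["FD"] or not groups["FU"]:
        raise ValueError(f"both fate groups must be non-empty at {timepoint_h} h")
    return float(np.mean(groups["FD"]) / np.mean(groups["FU"]))


def dip_fate_table(
    cohort: Sequence[CellTrajectory],
    depth: float = 0.1,
    recovery: float = 0.9,
    field: str = "tension",
    normalized: bool = False,
) -> pd.DataFrame:
    """2x2 contingency of 24-h dips against final fate.

    Rows "dip"/"no_dip", columns "FD"/"FU", plus a ``row_fraction`` column
    pair giving P(fate | dip status).  Cells with unknown fate are skipped.
    Trajectories are normalised internally unless already ``normalized``.
    """
    counts = pd.DataFrame(
        0, index=pd.Index(["dip", "no_dip"], name="dip_status"), columns=["FD", "FU"]
    )
    for tr in cohort:
        if tr.fate == "unknown":
            continue
        ntr = tr if normalized else normalize_trajectory(tr, field)
        has_dip, _ = detect_dip(ntr, depth, recovery, field)
        counts.loc["dip" if has_dip else "no_dip", tr.fate] += 1
    totals = counts.sum(axis=1)
    out = counts.copy()
    for fate in ("FD", "FU"):
        out[f"frac_{fate}"] = np.where(totals > 0, counts[fate] / totals, np.nan)
    return out


def cohort_to_table(cohort: Sequence[CellTrajectory]) -> pd.DataFrame:
    """Tidy one-row-per-(cell, timepoint) export."""
    rows = []
    for tr in cohort:
        for i, t in enumerate(tr.timepoints_h):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "timepoint_h": t,
                    "tension_N_per_m": tr.tension[i],
                    "sd_time_nm": tr.sd_time[i] if tr.sd_time is not None else np.nan,
                    "fate": tr.fate,
                }
            )
    return pd.DataFrame(
        rows, columns=["cell_id", "timepoint_h", "tension_N_per_m", "sd_time_nm", "fate"]
    )


def cohort_from_table(table: Union[pd.DataFrame, str, Path]) -> list[CellTrajectory]:
    """Inverse of :func:`cohort_to_table`; accepts a DataFrame or CSV path."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep=None, engine="python")
    cohort = []
    for cell_id, grp in table.groupby("cell_id", sort=False):
        grp = grp.sort_values("timepoint_h")
        sd = None
        if "sd_time_nm" in grp and grp["sd_time_nm"].notna().any():
            sd = tuple(float(v) for v in grp["sd_time_nm"])
        fate = str(grp["fate"].iloc[0]) if "fate" in grp else "unknown"
        cohort.append(
            CellTrajectory(
                cell_id=str(cell_id),
                timepoints_h=tuple(float(t) for t in grp["timepoint_h"]),
                tension=tuple(float(v) for v in grp["tension_N_per_m"]),
                sd_time=sd,
                fate=fate if fate in ("FD", "FU") else "unknown",
            )
        )
    return cohort
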