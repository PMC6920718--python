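"""Morphometric distributions on the percent-bone-length axis, and
Trabecular Extent (Tb.E).

Each per-slice parameter becomes a *distribution* over percent bone
length (native resolution: one sample per slice).  Because specimens
differ in geometry and slice count, cross-specimen comparison happens on
a common 1%-step grid obtained by cubic interpolation of each native
distribution (trabecular default 60–100%, cortical 40–80%).

Tb.E quantifies how far the distal trabecular structure extends
proximally into the medullary cavity from the growth-plate reference
level: the distance (mm) from the reference level to the first position,
scanning proximally, where the BA/TA distribution falls to a threshold
(defaults 30%, 20%, 10% and 0).  Tb.E_Abs is the distance to the most
proximal native sample with any trabecular bone at all.  Crossings are
located on the native-resolution profile with linear interpolation
between bracketing slices — "first occurrence" is resolution-sensitive,
so the 1% grid is never used for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .axis_align import SpecimenFrame
from .errors import ValidationError

DEFAULT_TBE_THRESHOLDS = (0.30, 0.20, 0.10, 0.0)
TRABECULAR_RANGE = (60.0, 100.0)
CORTICAL_RANGE = (40.0, 80.0)


def percent_grid(lo: float, hi: float, step: float = 1.0) -> np.ndarray:
    """The shared percent-bone-length grid, inclusive of both ends."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


@dataclass
class MorphProfile:
    """One parameter sampled on a uniform percent-length grid."""

    parameter_name: str
    grid_percent: np.ndarray
    values: np.ndarray
    specimen_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.grid_percent = np.asarray(self.grid_percent, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid_percent.ndim != 1 or len(self.grid_percent) < 2:
            raise ValidationError("profile grid must be 1D with >= 2 points")
        steps = np.diff(self.grid_percent)
        if not (steps > 0).all():
            raise ValidationError("profile grid must be strictly increasing")
        if not np.allclose(steps, steps[0]):
            raise ValidationError("profile grid step must be uniform")
        if self.values.shape != self.grid_percent.shape:
            raise ValidationError("values and grid must have the same length")
        if not np.isfinite(self.values).all():
            raise ValidationError("profile values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "specimen_id": self.specimen_id,
            "group": self.group,
            "parameter": self.parameter_name,
            "percent": self.grid_percent,
            "value": self.values,
        })


@dataclass
class TrabecularExtent:
    """Tb.E at a set of BA/TA thresholds plus the absolute extent.

    ``censored[t]`` marks thresholds never reached inside the analysed
    range (the distribution stayed above the threshold throughout); the
    reported distance is then the full-range distance, not a true
    crossing.
    """

    thresholds: tuple
    tbe_mm: dict = field(default_factory=dict)
    censored: dict = field(default_factory=dict)
    tbe_abs_mm: float = 0.0
    reference_percent: float = 100.0
    specimen_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"specimen_id": self.specimen_id, "threshold": t,
             "tbe_mm": self.tbe_mm[t], "censored": self.censored[t]}
            for t in self.thresholds
        ]
        rows.append({"specimen_id": self.specimen_id, "threshold": "abs",
                     "tbe_mm": self.tbe_abs_mm, "censored": False})
        return pd.DataFrame(rows)


def build_profile(
    metrics_table: pd.DataFrame,
    frame: SpecimenFrame,
    parameter_name: str,
    grid: np.ndarray,
    range_percent: tuple[float, float] | None = None,
    specimen_id: str = "",
    group: str = "",
) -> MorphProfile:
    """Cubic-interpolate one per-slice parameter onto a percent grid.

    ``metrics_table`` is the per-slice table from
    :func:`osteoslice.slice_morph.compute_slice_metrics`; native sample
    positions are the percent-length values of its slices.  Grid points
    outside the covered native range raise (no extrapolation).
    """
    grid = np.asarray(grid, dtype=float)
    if parameter_name not in metrics_table.columns:
        raise ValidationError(f"parameter {parameter_name!r} not in metrics table")
    if "percent_length" in metrics_table.columns:
        native_pct = metrics_table["percent_length"].to_numpy(dtype=float)
    else:
        native_pct = frame.percent_of_slice(metrics_table["slice"].to_numpy())
    values = metrics_table[parameter_name].to_numpy(dtype=float)
    order = np.argsort(native_pct)
    native_pct, values = native_pct[order], values[order]
    if range_percent is not None:
        lo, hi = range_percent
        keep = (native_pct >= lo - frame.percent_per_slice) & (
            native_pct <= hi + frame.percent_per_slice)
        native_pct, values = native_pct[keep], values[keep]
    if len(native_pct) < 4:
        raise ValidationError("need at least 4 native samples for cubic interpolation")
    # grid points within half a native step of the covered ends are fine
    # (sub-step edge effects), anything farther is true extrapolation
    tol = 0.5 * float(np.median(np.diff(native_pct)))
    if grid.min() < native_pct[0] - tol or grid.max() > native_pct[-1] + tol:
        raise ValidationError(
            f"grid [{grid.min():g}, {grid.max():g}] outside covered native range "
            f"[{native_pct[0]:g}, {native_pct[-1]:g}]; extrapolation is not performed"
        )
    spline = CubicSpline(native_pct, values)
    return MorphProfile(parameter_name, grid, spline(grid), specimen_id, group)


def _first_crossing(pct: np.ndarray, val: np.ndarray, threshold: float):
    """First position, scanning down from pct[0], where val crosses threshold.

    ``pct`` is sorted descending from the reference.  Returns the percent
    of the crossing (linear interpolation between bracketing samples) or
    None when the profile stays above the threshold throughout.
    """
    above = val > threshold
    if not above[0]:
        return pct[0]
    for i in range(1, len(val)):
        if not above[i]:
            v0, v1 = val[i - 1], val[i]
            if v0 == v1:
                return pct[i]
            f = (v0 - threshold) / (v0 - v1)
            return pct[i - 1] + f * (pct[i] - pct[i - 1])
    return None


def trabecular_extent(
    native_percent: np.ndarray,
    ba_ta: np.ndarray,
    frame: SpecimenFrame,
    reference_percent: float,
    thresholds: tuple = DEFAULT_TBE_THRESHOLDS,
    range_percent: tuple[float, float] = TRABECULAR_RANGE,
    specimen_id: str = "",
) -> TrabecularExtent:
    """Tb.E of one specimen from its native-resolution BA/TA distribution.

    Scanning proximally (decreasing percent) from the growth-plate
    reference level, the first crossing of each threshold is located by
    linear interpolation between bracketing native samples and converted
    to mm with ``L/100``.  Conventions:

    * threshold above BA/TA at the reference level → extent 0, flagged
      censored (nothing to measure);
    * threshold never reached inside the range → full-range distance,
      flagged censored.
    """
    pct = np.asarray(native_percent, dtype=float)
    val = np.asarray(ba_ta, dtype=float)
    if pct.shape != val.shape or pct.ndim != 1:
        raise ValidationError("percent and BA/TA arrays must be 1D and equal length")
    lo = range_percent[0]
    keep = (pct >= lo) & (pct <= reference_percent + 1e-9)
    pct, val = pct[keep], val[keep]
    if len(pct) < 2:
        raise ValidationError(
            f"BA/TA distribution does not cover [{lo}, {reference_percent}]"
        )
    order = np.argsort(pct)[::-1]  # descending: reference first
    pct, val = pct[order], val[order]
    mm_per_pct = frame.mm_per_percent()

    result = TrabecularExtent(
        thresholds=tuple(thresholds),
        reference_percent=reference_percent,
        specimen_id=specimen_id,
    )
    for t in thresholds:
        if val[0] <= t and t > 0:
            result.tbe_mm[t] = 0.0
            result.censored[t] = True
            continue
        crossing = _first_crossing(pct, val, t)
        if crossing is None:
            result.tbe_mm[t] = (reference_percent - pct[-1]) * mm_per_pct
            result.censored[t] = True
        else:
            result.tbe_mm[t] = (reference_percent - crossing) * mm_per_pct
            result.censored[t] = False

    positive = np.flatnonzero(val > 0)
    if positive.size:
        most_proximal = pct[positive[-1]]
        result.tbe_abs_mm = (reference_percent - most_proximal) * mm_per_pct
    return result


def difference_profile(
    group_a: list[MorphProfile], group_b: list[MorphProfile]
) -> pd.DataFrame:
    """Per-grid-point mean difference mean(a) − mean(b), with |diff| and sign."""
    if not group_a or not group_b:
        raise ValidationError("both groups must contain at least one profile")
    grid = group_a[0].grid_percent
    for p in list(group_a) + list(group_b):
        if p.grid_percent.shape != grid.shape or not np.allclose(p.grid_percent, grid):
            raise ValidationError("all profiles must share one grid")
    mean_a = np.mean([p.values for p in group_a], axis=0)
    mean_b = np.mean([p.values for p in group_b], axis=0)
    diff = mean_a - mean_b
    return pd.DataFrame({
        "percent": grid,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "diff": diff,
        "abs_diff": np.abs(diff),
        "sign": np.where(diff > 0, "positive", np.where(diff < 0, "negative", "zero")),
    })
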