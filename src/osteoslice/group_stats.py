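"""Group statistics: normality screening, per-grid-point t-tests,
p-value banding and normalized summary tables.

The comparison of two cohorts of morphometric distributions is a classic
equal-variance Student t-test for independent samples at every 1%
bone-length grid point, reported as mean ± SE per group, the signed
difference, the p-value and a p-band for heat-map rendering
(NS / .05 > p ≥ .01 / .01 > p ≥ .001 / .001 > p ≥ .0001 / p < .0001).
No multiple-testing correction is applied across grid points by default
(a typical 41–61-point grid implies as many tests — a Holm option is
provided for users who want family-wise control).

Normality is screened per group with Anderson-Darling and Lilliefors
(Kolmogorov-Smirnov with estimated parameters) tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import kstest_normal, normal_ad
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .profiles import MorphProfile

BANDS = ("NS", "p05", "p01", "p001", "p0001")
_CUTPOINTS = (0.05, 0.01, 0.001, 0.0001)
_STARS = {"NS": "", "p05": "*", "p01": "**", "p001": "***", "p0001": "****"}


def band_classify(p: float) -> str:
    """Map a p-value to its significance band (half-open intervals).

    ``p = 0.05`` is NS and ``p = 0.01`` falls in the p05 band: each band
    is ``cut_low > p >= cut_high``; ``p < 0.0001`` is the strongest band.
    """
    if not (0.0 < p <= 1.0):
        raise ValidationError(f"p-value must be in (0, 1], got {p}")
    if p >= 0.05:
        return "NS"
    if p >= 0.01:
        return "p05"
    if p >= 0.001:
        return "p01"
    if p >= 0.0001:
        return "p001"
    return "p0001"


def stars(p: float) -> str:
    return _STARS[band_classify(p)]


def normality_screen(samples, min_n: int = 4) -> pd.DataFrame:
    """Anderson-Darling + Lilliefors normality screen per group.

    ``samples`` maps group label → 1D array.  A group is flagged when
    either test rejects at p < .05, or when it is degenerate (zero
    variance); groups below ``min_n`` are skipped with a flag.
    """
    rows = []
    for label, x in dict(samples).items():
        x = np.asarray(x, dtype=float)
        row = {"group": label, "n": len(x), "ad_p": np.nan, "ks_p": np.nan}
        if len(x) < min_n:
            row.update(flagged=True, reason="n_too_small")
        elif np.ptp(x) == 0:
            row.update(ad_p=0.0, ks_p=0.0, flagged=True, reason="degenerate")
        else:
            _, ad_p = normal_ad(x)
            _, ks_p = kstest_normal(x, dist="norm")
            row.update(
                ad_p=float(ad_p), ks_p=float(ks_p),
                flagged=bool(ad_p < 0.05 or ks_p < 0.05),
                reason="non_normal" if (ad_p < 0.05 or ks_p < 0.05) else "",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def ttest_arrays(a: np.ndarray, b: np.ndarray, *, equal_var: bool = True):
    """Vectorized two-sample t-test along axis 0; returns (t, p, diff, se_a, se_b).

    Zero pooled variance at a point degenerates to p = 1 when the means
    agree and p → 0 (reported as the smallest positive float) when they
    differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValidationError("need >= 2 specimens per group")
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate points handled below
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    diff = mean_a - mean_b
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        same = degenerate & np.isclose(diff, 0.0)
        p = np.where(same, 1.0, p)
        t = np.where(same, 0.0, t)
        blowup = degenerate & ~same
        p = np.where(blowup, np.finfo(float).tiny, p)
        with np.errstate(invalid="ignore"):
            t = np.where(blowup, np.sign(diff) * np.inf, t)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    se_a = a.std(axis=0, ddof=1) / np.sqrt(na)
    se_b = b.std(axis=0, ddof=1) / np.sqrt(nb)
    return t, p, diff, se_a, se_b


@dataclass
class GroupResult:
    """Per-grid-point two-group comparison of one parameter."""

    parameter_name: str
    grid_percent: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    se_a: np.ndarray
    se_b: np.ndarray
    diff: np.ndarray
    t: np.ndarray
    p: np.ndarray
    band: np.ndarray
    n_a: int
    n_b: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.parameter_name,
            "percent": self.grid_percent,
            "mean_a": self.mean_a, "se_a": self.se_a,
            "mean_b": self.mean_b, "se_b": self.se_b,
            "diff": self.diff, "abs_diff": np.abs(self.diff),
            "t": self.t, "p": self.p, "band": self.band,
            "n_a": self.n_a, "n_b": self.n_b,
        })

    def significant_runs(self, alpha: float = 0.05) -> list[tuple[float, float]]:
        """Contiguous percent intervals where p < alpha."""
        sig = self.p < alpha
        runs, start = [], None
        for i, s in enumerate(sig):
            if s and start is None:
                start = i
            elif not s and start is not None:
                runs.append((float(self.grid_percent[start]), float(self.grid_percent[i - 1])))
                start = None
        if start is not None:
            runs.append((float(self.grid_percent[start]), float(self.grid_percent[-1])))
        return runs


def ttest_profile(
    profiles_a: list[MorphProfile],
    profiles_b: list[MorphProfile],
    *,
    equal_var: bool = True,
    holm: bool = False,
) -> GroupResult:
    """Student t-test at every grid point between two cohorts of profiles."""
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValidationError("need >= 2 specimens per group")
    grid = profiles_a[0].grid_percent
    name = profiles_a[0].parameter_name
    for prof in list(profiles_a) + list(profiles_b):
        if prof.grid_percent.shape != grid.shape or not np.allclose(prof.grid_percent, grid):
            raise ValidationError("profiles must share one grid")
    a = np.stack([prof.values for prof in profiles_a])
    b = np.stack([prof.values for prof in profiles_b])
    t, p, diff, se_a, se_b = ttest_arrays(a, b, equal_var=equal_var)
    if holm:
        p = multipletests(p, method="holm")[1]
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    band = np.array([band_classify(pi) for pi in p])
    return GroupResult(
        parameter_name=name, grid_percent=grid,
        mean_a=a.mean(axis=0), mean_b=b.mean(axis=0),
        se_a=se_a, se_b=se_b, diff=diff, t=t, p=p, band=band,
        n_a=a.shape[0], n_b=b.shape[0],
    )


def normalized_group_table(
    voi_metrics_control: pd.DataFrame,
    voi_metrics_test: pd.DataFrame,
    parameters: list[str] | None = None,
) -> pd.DataFrame:
    """Control-normalized means ± SE and significance stars per parameter.

    Inputs are per-specimen tables (rows = specimens, columns =
    parameters).  Each group's mean is divided by the control-group
    mean; parameters with a zero control mean are skipped with a flag.
    """
    if parameters is None:
        parameters = [c for c in voi_metrics_control.columns
                      if c in voi_metrics_test.columns
                      and pd.api.types.is_numeric_dtype(voi_metrics_control[c])]
    rows = []
    for param in parameters:
        a = voi_metrics_control[param].to_numpy(dtype=float)
        b = voi_metrics_test[param].to_numpy(dtype=float)
        ctrl_mean = a.mean()
        if ctrl_mean == 0:
            rows.append({"parameter": param, "skipped": True})
            continue
        _, p, _, se_a, se_b = ttest_arrays(a[:, None], b[:, None])
        p = float(p[0])
        rows.append({
            "parameter": param,
            "control_norm_mean": 1.0,
            "control_norm_se": float(se_a[0]) / abs(ctrl_mean),
            "test_norm_mean": b.mean() / ctrl_mean,
            "test_norm_se": float(se_b[0]) / abs(ctrl_mean),
            "p": p,
            "stars": stars(p),
            "skipped": False,
        })
    return pd.DataFrame(rows)
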