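"""ICH-style validation statistics for a quantitative HPLC assay.

Covers calibration linearity, LOD/LOQ from calibration noise, recovery
and precision, two-sample method-comparison t/F tests against a
reference method, and the bookkeeping of forced-degradation experiments
(percent degradation and degradant-peak identification from tabulated
peak lists).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "MethodComparison",
    "PeakTable",
    "fit_calibration",
    "lod_loq",
    "recovery_and_precision",
    "compare_methods",
    "critical_values",
    "percent_degradation",
]


@dataclass
class CalibrationCurve:
    """Least-squares calibration line and its sensitivity limits."""

    analyte: str
    concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    r2: float
    sigma: float | None = None    # response SD used for LOD/LOQ
    lod: float | None = None      # ug/mL
    loq: float | None = None      # ug/mL


@dataclass
class MethodComparison:
    """Two-sample t and variance-ratio F comparison of two methods."""

    analyte: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    f: float
    t_crit: float
    f_crit: float
    alpha: float
    t_df: int
    f_df: tuple[int, int]
    equivalent_means: bool = True
    equivalent_variances: bool = True


@dataclass
class PeakTable:
    """Tabulated chromatogram: (retention time, area) pairs per condition.

    ``parent`` flags mark the assay's target analyte peaks (the three
    curcuminoids in the reference run).
    """

    condition: str
    rt: np.ndarray
    area: np.ndarray
    parent: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.parent is None:
            self.parent = np.zeros(len(self.rt), dtype=bool)
        self.parent = np.asarray(self.parent, dtype=bool)
        if np.any(self.rt <= 0):
            raise ValueError("retention times must be positive")
        if np.any(np.diff(self.rt) <= 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(self.area < 0):
            raise ValueError("areas must be non-negative")


def fit_calibration(concentrations, responses, analyte: str = "") -> CalibrationCurve:
    """Ordinary least-squares calibration line with R^2."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct concentration levels")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        analyte=analyte,
        concentrations=x,
        responses=y,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
    )


def lod_loq(sigma: float, slope: float) -> tuple[float, float]:
    """Detection and quantitation limits: LOD = 3.3 sigma/s, LOQ = 10 sigma/s."""
    if slope == 0:
        raise ZeroDivisionError("slope must be nonzero")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    return 3.3 * sigma / abs(slope), 10.0 * sigma / abs(slope)


def recovery_and_precision(found, nominal: float) -> tuple[float, float]:
    """Percent recovery (vs the nominal level) and percent RSD.

    %recovery = 100 mean(found)/nominal; %RSD = 100 SD(found)/mean(found)
    with the sample (ddof=1) standard deviation.
    """
    found = np.asarray(found, dtype=float)
    if len(found) < 2:
        raise ValueError("need at least 2 replicates")
    if nominal <= 0:
        raise ValueError("nominal level must be positive")
    m = found.mean()
    if m == 0:
        raise ZeroDivisionError("mean of found values is zero")
    return 100.0 * m / nominal, 100.0 * found.std(ddof=1) / m


def critical_values(
    alpha: float = 0.05,
    t_df: int = 4,
    f_df: tuple[int, int] = (4, 4),
) -> tuple[float, float]:
    """Two-sided t and upper-tail F critical values at level ``alpha``."""
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, t_df))
    f_crit = float(stats.f.ppf(1.0 - alpha, *f_df))
    return t_crit, f_crit


def compare_methods(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    alpha: float = 0.05,
    analyte: str = "",
    welch: bool = False,
    f_df: tuple[int, int] | None = None,
) -> MethodComparison:
    """Two-sample t (pooled by default) and variance-ratio F from summaries.

    F puts the larger variance in the numerator, so F >= 1.  ``f_df``
    overrides the degrees of freedom used for the F critical value
    (report conventions vary); the default is (n-1, n-1) ordered to match
    the numerator/denominator choice.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 in each group")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("SDs must be positive")

    va, vb = sd_a**2, sd_b**2
    if welch:
        se = np.sqrt(va / n_a + vb / n_b)
        t_df = int(
            np.floor(
                (va / n_a + vb / n_b) ** 2
                / ((va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1))
            )
        )
    else:
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        t_df = n_a + n_b - 2
    t = abs(mean_a - mean_b) / se

    if va >= vb:
        f, fd = va / vb, (n_a - 1, n_b - 1)
    else:
        f, fd = vb / va, (n_b - 1, n_a - 1)
    if f_df is not None:
        fd = tuple(f_df)

    t_crit, f_crit = critical_values(alpha, t_df, fd)
    return MethodComparison(
        analyte=analyte,
        mean_a=mean_a, sd_a=sd_a, n_a=n_a,
        mean_b=mean_b, sd_b=sd_b, n_b=n_b,
        t=float(t), f=float(f),
        t_crit=t_crit, f_crit=f_crit,
        alpha=alpha, t_df=t_df, f_df=fd,
        equivalent_means=bool(t <= t_crit),
        equivalent_variances=bool(f <= f_crit),
    )


def percent_degradation(
    reference: PeakTable,
    stressed: PeakTable,
    rt_tolerance: float = 0.2,
) -> tuple[float, PeakTable]:
    """Percent loss of parent-peak area and the list of degradant peaks.

    Parent peaks in the stressed table are matched to the reference
    parents by retention time within ``rt_tolerance`` minutes; unmatched
    stressed peaks are reported as degradants.
    """
    ref_parent_rt = reference.rt[reference.parent]
    if len(ref_parent_rt) == 0:
        raise ValueError("reference table has no parent peaks flagged")
    ref_area = float(reference.area[reference.parent].sum())
    if ref_area == 0:
        raise ZeroDivisionError("reference parent area sum is zero")

    matched = np.zeros(len(stressed.rt), dtype=bool)
    stressed_parent_area = 0.0
    for rt0 in ref_parent_rt:
        dist = np.abs(stressed.rt - rt0)
        dist[matched] = np.inf
        i = int(np.argmin(dist))
        if dist[i] <= rt_tolerance:
            matched[i] = True
            stressed_parent_area += float(stressed.area[i])

    pct = 100.0 * (ref_area - stressed_parent_area) / ref_area
    degradants = PeakTable(
        condition=stressed.condition,
        rt=stressed.rt[~matched],
        area=stressed.area[~matched],
        parent=np.zeros(int((~matched).sum()), dtype=bool),
    )
    return pct, degradants
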