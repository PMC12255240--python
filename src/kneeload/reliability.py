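"""Intraclass correlation ICC(2,k), confidence intervals and SEM.

Convention: two-way random-effects, absolute-agreement ICC for the average
of k measurements (Shrout–Fleiss ICC(2,k) / McGraw–Wong ICC(A,k)), computed
from the ANOVA mean squares of the complete subjects × measurements grid::

    ICC(2,k) = (MS_subjects − MS_error) / (MS_subjects + (MS_raters − MS_error) / n)

The 95% confidence interval uses the standard F-distribution bounds for the
single-measure ICC(2,1) with the Satterthwaite degrees of freedom, stepped
up to the average-of-k form by the Spearman–Brown relation.  Measurement
precision is the standard error of measurement::

    SEM = SD × sqrt(1 − ICC)

with SD the standard deviation of all measurements in the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ICCResult:
    """ICC estimate with confidence interval and SEM (input units)."""

    icc: float
    ci95: tuple
    sem: float
    icc_single: float
    n_subjects: int
    k: int

    def __post_init__(self) -> None:
        if self.icc <= 1.0 and self.sem < 0:
            raise ValueError("SEM must be non-negative")


def _anova_mean_squares(grid: np.ndarray) -> tuple:
    """Two-way (subjects × raters) ANOVA mean squares, one value per cell."""
    n, k = grid.shape
    grand = grid.mean()
    row_means = grid.mean(axis=1)
    col_means = grid.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((grid - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1) if k > 1 else 0.0
    mse = ss_err / ((n - 1) * (k - 1)) if k > 1 else 0.0
    return msr, msc, mse


def sem_from_icc(sd: float, icc: float) -> float:
    """Standard error of measurement from an ICC and the observed SD."""
    if not icc <= 1.0:
        raise ValueError("ICC cannot exceed 1")
    return float(sd * np.sqrt(1.0 - icc))


def icc_2k(grid, alpha: float = 0.05) -> ICCResult:
    """Absolute-agreement average-measures ICC(2,k) on a complete grid.

    Parameters
    ----------
    grid : array-like or DataFrame, shape (n_subjects, k)
        One measurement per subject × rater/repeat cell; must be complete.
    alpha : float
        1 − confidence level for the interval (default 95% CI).

    Notes
    -----
    Degenerate tables are reported as computed (the estimate may be ≤ 0 when
    between-subject variance vanishes).  A perfect-agreement grid gives
    ICC = 1 and SEM = 0.
    """
    if isinstance(grid, pd.DataFrame):
        grid = grid.to_numpy(dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2 or grid.shape[0] < 2 or grid.shape[1] < 2:
        raise ValueError("need a 2-D grid with >= 2 subjects and >= 2 measurements")
    if np.isnan(grid).any():
        raise ValueError("incomplete grid: ICC(2,k) requires a complete two-way table")
    n, k = grid.shape
    msr, msc, mse = _anova_mean_squares(grid)
    # floating-point dust from a perfect-agreement table must read as exact
    # agreement, so that ICC = 1 and SEM = 0 hold exactly
    tol = 1e-12 * max(msr, 1e-300)
    if msc <= tol and mse <= tol:
        msc = mse = 0.0

    denom_single = msr + (k - 1) * mse + k * (msc - mse) / n
    icc1 = (msr - mse) / denom_single if denom_single != 0 else 1.0
    denom_avg = msr + (msc - mse) / n
    icck = (msr - mse) / denom_avg if denom_avg != 0 else 1.0

    sd = float(grid.std(ddof=1))
    sem = sem_from_icc(sd, min(icck, 1.0))

    if mse == 0 and msc == 0:
        return ICCResult(icck, (icck, icck), sem, icc1, n, k)

    # Satterthwaite df for the single-measure bounds (McGraw & Wong)
    r = icc1
    fj = msc / mse if mse > 0 else np.inf
    vn = (k - 1) * (n - 1) * (k * r * fj + n * (1 + (k - 1) * r) - k * r) ** 2
    vd = (n - 1) * k**2 * r**2 * fj**2 + (n * (1 + (k - 1) * r) - k * r) ** 2
    v = vn / vd
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower1 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    # Spearman-Brown step-up to average measures
    lower = k * lower1 / (1 + (k - 1) * lower1)
    upper = k * upper1 / (1 + (k - 1) * upper1)
    return ICCResult(float(icck), (float(lower), float(upper)), sem, float(icc1), n, k)
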