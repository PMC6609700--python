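"""Biomarker correlation analyses around a selected metabolite ratio.

Pearson correlation of the ratio with serum cartilage-degradation markers
(COMP, MMP-1), covariate-adjusted (partial) correlation via double
residualization, and comparison of a marker (LCAT) between the extreme
top/bottom deciles of the ratio distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ratio_screen import encode_covariates

__all__ = [
    "CorrelationResult",
    "DecileComparison",
    "pearson_correlation",
    "adjusted_correlation",
    "extreme_decile_compare",
]


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    adjusted: bool = False
    covariates: tuple[str, ...] = ()


@dataclass
class DecileComparison:
    """Equal-variance t comparison of a marker between ratio extremes."""

    t: float
    p: float
    n_bottom: int
    n_top: int
    mean_bottom: float
    mean_top: float
    median_bottom: float
    median_top: float


def _clean_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = ~np.isnan(x) & ~np.isnan(y)
    return x[ok], y[ok]


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson r with two-sided p from the t distribution (n−2 df)."""
    x, y = _clean_xy(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def adjusted_correlation(
    x, y, covariates: pd.DataFrame, covariate_names=None
) -> CorrelationResult:
    """Partial correlation controlling for covariates.

    Both variables are residualized on the covariates (with intercept) by
    OLS and the residuals correlated; with an empty covariate set this is
    exactly the unadjusted Pearson correlation.  The p-value uses n−p−2
    degrees of freedom, the standard partial-correlation inference.
    """
    if covariate_names is not None:
        covariates = encode_covariates(covariates, covariate_names)
    if covariates is None or covariates.shape[1] == 0:
        return pearson_correlation(x, y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = covariates.to_numpy(dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y) & ~np.isnan(c).any(axis=1)
    x, y, c = x[ok], y[ok], c[ok]
    n, p = len(x), c.shape[1]
    if n < p + 3:
        raise ValueError(f"too few complete cases: n={n} for {p} covariates")
    X = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate design")
    q, _ = np.linalg.qr(X)
    rx = x - q @ (q.T @ x)
    ry = y - q @ (q.T @ y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("residual vector constant after adjustment")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - p - 2
    t = r * np.sqrt(df / max(1e-300, 1.0 - r * r))
    p_val = float(2.0 * stats.t.sf(abs(t), df))
    return CorrelationResult(
        r=r,
        p=max(p_val, np.nextafter(0, 1)),
        n=n,
        adjusted=True,
        covariates=tuple(covariates.columns),
    )


def extreme_decile_compare(
    ratio_values: pd.Series,
    marker_values: pd.Series,
    frac: float = 0.10,
    equal_var: bool = True,
) -> DecileComparison:
    """Compare a marker between the bottom and top ``frac`` of the ratio.

    Subjects are ranked by the ratio (ties broken by subject id after a
    stable sort); the extreme groups are then intersected with marker
    availability, so group sizes may be unequal.  Student's equal-variance
    t test by default (Welch behind the flag).  The comparison is invariant
    to any strictly monotone transform of the ranking variable.
    """
    if not 0.0 < frac < 0.5:
        raise ValueError("frac must lie in (0, 0.5)")
    ratio = ratio_values.dropna()
    k = int(round(frac * len(ratio)))
    if k < 2:
        raise ValueError("extreme groups would have fewer than 2 subjects")
    order = ratio.reset_index()
    order.columns = ["subject_id", "ratio"]
    order = order.sort_values(["ratio", "subject_id"], kind="mergesort")
    bottom_ids = order["subject_id"].head(k)
    top_ids = order["subject_id"].tail(k)
    marker = marker_values.dropna()
    bottom = marker.loc[marker.index.intersection(bottom_ids)]
    top = marker.loc[marker.index.intersection(top_ids)]
    if len(bottom) < 2 or len(top) < 2:
        raise ValueError("too few subjects with marker data in an extreme group")
    res = stats.ttest_ind(bottom, top, equal_var=equal_var)
    t_stat = float(res.statistic)
    if np.isnan(t_stat) and bottom.mean() == top.mean():
        t_stat = 0.0  # zero variance, zero difference
    return DecileComparison(
        t=t_stat,
        p=float(res.pvalue) if not np.isnan(res.pvalue) else 1.0,
        n_bottom=int(len(bottom)),
        n_top=int(len(top)),
        mean_bottom=float(bottom.mean()),
        mean_top=float(top.mean()),
        median_bottom=float(bottom.median()),
        median_top=float(top.median()),
    )
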