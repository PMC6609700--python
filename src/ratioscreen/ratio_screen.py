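"""Metabolome-wide pairwise ratio screen.

Metabolite concentrations are standardized to Z-scores, every ordered (or
unordered) pair of distinct metabolites is turned into a ratio of Z-scores
— a proxy for the enzymatic reaction converting denominator to numerator —
and each ratio is regressed (OLS) against percent cartilage-volume change,
unadjusted and adjusted for the seven clinical covariates, under
metabolome-wide Bonferroni control.

The ratio-of-Z-scores is implemented literally.  It is heavy-tailed when
the denominator Z-score is near zero; an optional guard epsilon flags such
cells as degenerate and excludes them from that pair's regression (default
off, reproducing the literal definition).  The m = 152 ordered-pair count
is m·(m−1) = 22,952; the Bonferroni divisor defaults to the number of
pairs actually fitted and can be overridden to reproduce a published
divisor.

The hot path is a vectorized Frisch–Waugh–Lovell solve: the outcome and
all ratio columns are residualized against the base design (intercept, or
intercept + covariates) with one QR decomposition, after which every
pair's slope, t statistic and confidence interval follow from column sums.
This is algebraically identical to fitting each full OLS model separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import ConcentrationMatrix, RunConfig

__all__ = [
    "ScreenThreshold",
    "AssociationFit",
    "RatioMatrix",
    "zscore_standardize",
    "build_pairwise_ratios",
    "bonferroni_threshold",
    "encode_covariates",
    "fit_linear_association",
    "run_screen",
    "posthoc_power",
    "analytic_power",
]


# ---------------------------------------------------------------------------
# Standardization and ratios
# ---------------------------------------------------------------------------


def zscore_standardize(matrix) -> pd.DataFrame:
    """Column-wise Z-scores: (x − mean) / sample SD (n−1 denominator).

    Accepts a fully imputed :class:`ConcentrationMatrix` or a plain
    subjects × metabolites DataFrame.  Every column of the result has mean
    0 and SD 1 to within 1e−10.
    """
    values = matrix.values if isinstance(matrix, ConcentrationMatrix) else matrix
    if values.isna().any().any():
        raise ValueError("matrix must be fully imputed before Z-scoring")
    sd = values.std(ddof=1)
    constant = sd[sd == 0]
    if not constant.empty:
        raise ValueError(
            f"constant metabolite column {constant.index[0]!r}: Z-score undefined"
        )
    return (values - values.mean()) / sd


@dataclass
class RatioMatrix:
    """All pairwise ratio columns plus bookkeeping.

    ``ratios``: subjects × pairs frame (columns are ``pair_id`` strings
    "numerator/denominator"); ``degenerate``: same-shape boolean frame
    flagging cells whose denominator was within the guard epsilon of zero;
    ``pairs``: one row per pair with numerator and denominator ids.
    """

    ratios: pd.DataFrame
    degenerate: pd.DataFrame
    pairs: pd.DataFrame
    mode: str
    guard_epsilon: float


def build_pairwise_ratios(
    z: pd.DataFrame,
    mode: str = "ordered",
    guard_epsilon: float = 0.0,
    scheme: str = "zscore_then_ratio",
) -> RatioMatrix:
    """Construct every pairwise ratio column.

    ``mode="ordered"`` yields m·(m−1) directed pairs (a/b and b/a are
    distinct reaction directions); ``"unordered"`` yields m·(m−1)/2 with
    the earlier column as numerator.  Under the default scheme the input
    must already be Z-scored and each ratio is z_num / z_den; under
    ``scheme="ratio_then_zscore"`` the input is raw concentrations, the raw
    ratio is built first and then Z-scored per pair (a secondary reading of
    "standardized ratios", provided for sensitivity analysis).

    Cells with |denominator| < ``guard_epsilon`` — or exactly 0 when the
    guard is off — are flagged degenerate; flagged cells carry NaN in the
    ratio frame and are excluded from that pair's regression.
    """
    if z.shape[1] < 2:
        raise ValueError("need at least 2 metabolites to build ratios")
    if mode not in ("ordered", "unordered"):
        raise ValueError(f"unknown pair mode {mode!r}")
    if scheme not in ("zscore_then_ratio", "ratio_then_zscore"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if scheme == "zscore_then_ratio":
        mu = z.mean().abs().max()
        sd_err = (z.std(ddof=1) - 1).abs().max()
        if mu > 1e-8 or sd_err > 1e-8:
            raise ValueError("input is not column-standardized; Z-score first")

    cols = list(z.columns)
    m = len(cols)
    num_idx, den_idx = [], []
    for i in range(m):
        start = i + 1 if mode == "unordered" else 0
        for j in range(start, m):
            if i == j:
                continue
            num_idx.append(i)
            den_idx.append(j)
    num_idx = np.asarray(num_idx)
    den_idx = np.asarray(den_idx)

    x = z.to_numpy(dtype=float)
    num = x[:, num_idx]
    den = x[:, den_idx]
    eps = float(guard_epsilon)
    degenerate = np.abs(den) < eps if eps > 0 else den == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    ratio[degenerate] = np.nan
    if scheme == "ratio_then_zscore":
        mu = np.nanmean(ratio, axis=0)
        sd = np.nanstd(ratio, axis=0, ddof=1)
        sd[sd == 0] = np.nan
        ratio = (ratio - mu) / sd

    pair_ids = [f"{cols[i]}/{cols[j]}" for i, j in zip(num_idx, den_idx)]
    pairs = pd.DataFrame(
        {
            "pair_id": pair_ids,
            "numerator": [cols[i] for i in num_idx],
            "denominator": [cols[j] for j in den_idx],
        }
    )
    return RatioMatrix(
        ratios=pd.DataFrame(ratio, index=z.index, columns=pair_ids),
        degenerate=pd.DataFrame(degenerate, index=z.index, columns=pair_ids),
        pairs=pairs,
        mode=mode,
        guard_epsilon=eps,
    )


# ---------------------------------------------------------------------------
# Bonferroni threshold
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenThreshold:
    """Metabolome-wide significance threshold alpha / n_tests."""

    alpha: float
    n_tests: int
    threshold: float


def bonferroni_threshold(alpha: float, n_tests: int) -> ScreenThreshold:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return ScreenThreshold(alpha=alpha, n_tests=int(n_tests), threshold=alpha / n_tests)


# ---------------------------------------------------------------------------
# OLS with t inference
# ---------------------------------------------------------------------------


@dataclass
class AssociationFit:
    """One ratio-vs-outcome regression row."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    df_resid: int


def encode_covariates(
    cohort: pd.DataFrame, covariates=("age", "sex", "bmi", "diabetes",
                                     "hypertension", "dyslipidemia", "treatment")
) -> pd.DataFrame:
    """Numeric design columns for the adjustment covariates.

    Binary codings: female = 1, licofelone = 1, comorbidity flags 0/1.
    The frame is indexed by subject_id.
    """
    df = cohort.set_index("subject_id") if "subject_id" in cohort.columns else cohort
    out = {}
    for cov in covariates:
        if cov not in df.columns:
            raise ValueError(f"covariate column {cov!r} missing from cohort")
        if cov == "sex":
            out[cov] = (df[cov] == "female").astype(float)
        elif cov == "treatment":
            out[cov] = (df[cov] == "licofelone").astype(float)
        else:
            out[cov] = df[cov].astype(float)
    return pd.DataFrame(out, index=df.index)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Names of columns involved in exact linear dependence (QR pivot check)."""
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    return [names[i] for i in np.where(diag < tol)[0]]


def fit_linear_association(
    ratio,
    outcome,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> AssociationFit:
    """OLS of outcome on one ratio (plus optional covariates), t inference.

    The slope on the ratio is reported with its two-sided t-test p-value
    and a (1−alpha) confidence interval at t quantiles with n−p−1 residual
    degrees of freedom.  Rows with NaN in any variable are dropped as
    incomplete cases.
    """
    r = np.asarray(ratio, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if covariates is not None and len(covariates.columns) > 0:
        c = covariates.to_numpy(dtype=float)
        names = ["const"] + list(covariates.columns) + ["ratio"]
        X = np.column_stack([np.ones_like(y), c, r])
    else:
        names = ["const", "ratio"]
        X = np.column_stack([np.ones_like(y), r])
    complete = ~np.isnan(X).any(axis=1) & ~np.isnan(y)
    X, y = X[complete], y[complete]
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"too few complete cases: n={n} for {p} parameters")
    if np.linalg.matrix_rank(X) < p:
        cols = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient design; collinear columns: {cols}")

    q, rr = np.linalg.qr(X)
    coef = np.linalg.solve(rr, q.T @ y)
    resid = y - X @ coef
    df_resid = n - p
    if df_resid == 0:
        sigma2 = 0.0
    else:
        sigma2 = float(resid @ resid) / df_resid
    xtx_inv = np.linalg.inv(rr.T @ rr)
    se_all = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    beta = float(coef[-1])
    se = float(se_all[-1])
    if se > 0 and df_resid > 0:
        t = beta / se
        p_val = float(2.0 * stats.t.sf(abs(t), df_resid))
        tq = float(stats.t.ppf(1.0 - alpha / 2.0, df_resid))
    else:
        p_val = 0.0 if beta != 0 else 1.0
        tq = 0.0
    p_val = max(p_val, np.nextafter(0, 1))  # p in (0, 1]
    return AssociationFit(
        beta=beta,
        se=se,
        ci_low=beta - tq * se,
        ci_high=beta + tq * se,
        p=p_val,
        n_used=int(n),
        df_resid=int(df_resid),
    )


def _screen_fit(R: np.ndarray, y: np.ndarray, X0: np.ndarray, alpha: float):
    """Vectorized OLS slopes for every column of R given base design X0.

    Residualizes y and R against X0 (Frisch–Waugh–Lovell) and returns
    (beta, se, p, ci_low, ci_high) arrays; identical to fitting
    [X0, R[:, k]] by OLS for each k.
    """
    n, k = X0.shape
    q, _ = np.linalg.qr(X0)
    ry = y - q @ (q.T @ y)
    rr = R - q @ (q.T @ R)
    sxx = np.einsum("ij,ij->j", rr, rr)
    sxy = rr.T @ ry
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        sse = ry @ ry - beta * sxy
        df = n - k - 1
        sigma2 = np.maximum(sse, 0.0) / df
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.maximum(p, np.nextafter(0, 1))
    tq = stats.t.ppf(1.0 - alpha / 2.0, df)
    return beta, se, p, beta - tq * se, beta + tq * se


def run_screen(
    ratios: RatioMatrix,
    progression: pd.DataFrame,
    compartment: str,
    cohort: pd.DataFrame,
    config: RunConfig = RunConfig(),
    adjusted: bool = True,
) -> tuple[pd.DataFrame, ScreenThreshold]:
    """Screen every pairwise ratio against one compartment's volume change.

    Returns the association table — one row per pair, ranked by unadjusted
    p ascending (ties: \\|β\\| descending, then pair id) — and the
    metabolome-wide threshold.  ``significant`` flags rows with unadjusted
    p ≤ alpha / n_tests, where n_tests is the number of pairs actually
    fitted unless overridden in the config.
    """
    prog = progression[progression["compartment"] == compartment]
    if prog.empty:
        raise ValueError(f"compartment {compartment!r} missing from progression table")
    outcome = prog.set_index("subject_id")["pct_change"]
    # subjects without an outcome row (e.g. lost follow-up) drop out as
    # incomplete cases; the fits use the intersection
    subjects = ratios.ratios.index.intersection(outcome.index)
    if len(subjects) == 0:
        raise ValueError("no subjects shared between ratios and outcomes")
    y = outcome.loc[subjects].to_numpy(dtype=float)

    cov_df = None
    if adjusted:
        cov_df = encode_covariates(cohort, config.covariates).loc[subjects]

    R = ratios.ratios.loc[subjects].to_numpy(dtype=float)
    n = len(subjects)
    good_cells = ~np.isnan(R)
    clean = good_cells.all(axis=0)

    out = pd.DataFrame(index=ratios.ratios.columns)
    out["numerator"] = ratios.pairs.set_index("pair_id")["numerator"]
    out["denominator"] = ratios.pairs.set_index("pair_id")["denominator"]
    for label in ("unadj",) + (("adj",) if adjusted else ()):
        for col in ("beta", "ci_low", "ci_high", "p"):
            out[f"{col}_{label}"] = np.nan
    out["n_used"] = good_cells.sum(axis=0)

    # constant (zero-variance) ratios cannot be fitted
    sd = np.nanstd(R, axis=0, ddof=1)
    fittable = sd > 0
    clean &= fittable

    X0 = np.ones((n, 1))
    if clean.any():
        b, _, p, lo, hi = _screen_fit(R[:, clean], y, X0, config.alpha)
        out.loc[clean, ["beta_unadj", "ci_low_unadj", "ci_high_unadj", "p_unadj"]] = (
            np.column_stack([b, lo, hi, p])
        )
        if adjusted:
            Xc = np.column_stack([np.ones(n), cov_df.to_numpy(dtype=float)])
            b, _, p, lo, hi = _screen_fit(R[:, clean], y, Xc, config.alpha)
            out.loc[clean, ["beta_adj", "ci_low_adj", "ci_high_adj", "p_adj"]] = (
                np.column_stack([b, lo, hi, p])
            )

    # pairs with degenerate cells: per-pair complete-case fits
    for j in np.where(fittable & ~clean)[0]:
        r_col = R[:, j]
        fit_u = fit_linear_association(r_col, y, None, config.alpha)
        row = out.index[j]
        out.loc[row, ["beta_unadj", "ci_low_unadj", "ci_high_unadj", "p_unadj"]] = [
            fit_u.beta, fit_u.ci_low, fit_u.ci_high, fit_u.p,
        ]
        out.loc[row, "n_used"] = fit_u.n_used
        if adjusted:
            fit_a = fit_linear_association(r_col, y, cov_df, config.alpha)
            out.loc[row, ["beta_adj", "ci_low_adj", "ci_high_adj", "p_adj"]] = [
                fit_a.beta, fit_a.ci_low, fit_a.ci_high, fit_a.p,
            ]

    fitted = out["p_unadj"].notna()
    out = out[fitted]
    n_tests = (
        int(config.n_tests_override)
        if config.n_tests_override
        else int(fitted.sum())
    )
    threshold = bonferroni_threshold(config.alpha, n_tests)
    out["significant"] = out["p_unadj"] <= threshold.threshold
    if not adjusted:
        for col in ("beta_adj", "ci_low_adj", "ci_high_adj", "p_adj"):
            out[col] = np.nan

    out = out.reset_index(names="pair_id")
    out["_absb"] = -out["beta_unadj"].abs()
    out = out.sort_values(
        ["p_unadj", "_absb", "pair_id"], kind="mergesort"
    ).drop(columns="_absb")
    out = out.reset_index(drop=True)
    cols = [
        "pair_id", "numerator", "denominator",
        "beta_unadj", "ci_low_unadj", "ci_high_unadj", "p_unadj",
        "beta_adj", "ci_low_adj", "ci_high_adj", "p_adj",
        "n_used", "significant",
    ]
    return out[cols], threshold


# ---------------------------------------------------------------------------
# Post-hoc power
# ---------------------------------------------------------------------------


def posthoc_power(
    beta: float,
    n: int,
    alpha: float,
    sim_reps: int = 1000,
    seed: int = 1,
    residual_sd: float = 3.6,
    ratio_dist: str = "z_ratio",
    rho: float = 0.3,
) -> float:
    """Monte-Carlo power of the single-ratio test at significance ``alpha``.

    Each replicate draws a ratio regressor — ``"z_ratio"``: the ratio of
    two sample-standardized correlated normals (the screen's own regressor
    family); ``"normal"``: a plain standard-normal regressor — simulates
    the outcome as beta·ratio + Normal(0, residual_sd²) noise, fits the
    unadjusted model, and counts p ≤ alpha.
    """
    if sim_reps < 100:
        raise ValueError("sim_reps must be >= 100")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(sim_reps):
        if ratio_dist == "z_ratio":
            u = rng.standard_normal(n)
            a = np.sqrt(rho) * u + np.sqrt(1 - rho) * rng.standard_normal(n)
            b = np.sqrt(rho) * u + np.sqrt(1 - rho) * rng.standard_normal(n)
            za = (a - a.mean()) / a.std(ddof=1)
            zb = (b - b.mean()) / b.std(ddof=1)
            r = za / zb
        elif ratio_dist == "normal":
            r = rng.standard_normal(n)
        else:
            raise ValueError(f"unknown ratio_dist {ratio_dist!r}")
        y = beta * r + rng.normal(0.0, residual_sd, n)
        fit = fit_linear_association(r, y)
        hits += fit.p <= alpha
    return hits / sim_reps


def analytic_power(beta: float, se: float, alpha: float) -> float:
    """Normal-approximation power Φ(|β|/SE − z_{1−α/2}) for a fixed design."""
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(abs(beta) / se - z_crit))
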