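"""Relative gene-expression quantification from qPCR Ct values.

Implements the 2^−ΔΔCt (Livak) method against a reference gene and a
calibrator sample, group comparison of log relative quantification (RQ),
pairwise cytokine correlations, the multivariable cytokine model, and
primer-efficiency calculation from a dilution series.

Triplicate Ct values are averaged before ΔCt; replicates whose range
exceeds 0.5 cycles are flagged (a common lab QC rule) but not dropped.
Group differences are analysed on the natural-log RQ scale and percent
increase is reported on the geometric-mean scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import validate_qpcr_plate
from .biomarkers import CorrelationResult

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "EfficiencyResult",
    "livak_rq",
    "rq_wide",
    "compare_expression_groups",
    "cytokine_correlation_matrix",
    "multivariable_cytokine_model",
    "efficiency_from_dilution_series",
]

REPLICATE_RANGE_FLAG = 0.5  # cycles


@dataclass
class GroupComparison:
    """Student's t comparison of log RQ between OA and control."""

    t: float
    p: float
    n_oa: int
    n_control: int
    fold_change: float
    percent_increase: float


@dataclass
class EfficiencyResult:
    """Primer efficiency from a dilution-series standard curve."""

    gene: str
    slope: float
    r2: float
    efficiency_percent: float


def livak_rq(
    plate: pd.DataFrame, target_gene: str, reference_gene: str = "GAPDH"
) -> pd.DataFrame:
    """Relative quantification of ``target_gene`` by the 2^−ΔΔCt method.

    Per sample: ΔCt = mean Ct(target) − mean Ct(reference);
    ΔΔCt = ΔCt(sample) − ΔCt(calibrator); RQ = 2^−ΔΔCt (calibrator RQ is
    exactly 1).  Returns one row per sample with ``delta_ct``,
    ``delta_delta_ct``, ``rq``, ``log_rq`` (natural log) plus ``group`` and
    ``replicate_flag`` (triplicate range > 0.5 cycles for either gene).
    """
    validate_qpcr_plate(plate)
    ct_cols = ["ct1", "ct2", "ct3"]
    sub = plate[plate["gene"].isin([target_gene, reference_gene])].copy()
    if not (sub["gene"] == target_gene).any():
        raise ValueError(f"target gene {target_gene!r} not on plate")
    sub["mean_ct"] = sub[ct_cols].mean(axis=1)
    sub["ct_range"] = sub[ct_cols].max(axis=1) - sub[ct_cols].min(axis=1)

    wide = sub.pivot_table(index="sample_id", columns="gene", values="mean_ct")
    missing_ref = wide.index[wide.get(reference_gene, pd.Series(dtype=float)).isna()] \
        if reference_gene in wide.columns else wide.index
    if reference_gene not in wide.columns or len(missing_ref):
        which = missing_ref[0] if reference_gene in wide.columns else "all samples"
        raise ValueError(
            f"reference gene {reference_gene!r} missing for sample {which!r}"
        )
    missing_tgt = wide.index[wide[target_gene].isna()]
    if len(missing_tgt):
        raise ValueError(
            f"target gene {target_gene!r} missing for sample {missing_tgt[0]!r}"
        )

    meta = plate.drop_duplicates("sample_id").set_index("sample_id")
    calibrators = meta.index[meta["is_calibrator"].astype(bool)]
    delta_ct = wide[target_gene] - wide[reference_gene]
    delta_delta = delta_ct - delta_ct.loc[calibrators[0]]
    rq = np.exp2(-delta_delta)

    flag = (
        sub.groupby("sample_id")["ct_range"].max() > REPLICATE_RANGE_FLAG
    ).reindex(wide.index)
    n_flagged = int(flag.sum())
    if n_flagged:
        logger.warning(
            "%d sample(s) with triplicate Ct range > %.1f cycles for %s",
            n_flagged, REPLICATE_RANGE_FLAG, target_gene,
        )
    out = pd.DataFrame(
        {
            "sample_id": wide.index,
            "gene": target_gene,
            "delta_ct": delta_ct.to_numpy(),
            "delta_delta_ct": delta_delta.to_numpy(),
            "rq": rq.to_numpy(),
            "log_rq": np.log(rq.to_numpy()),
            "group": meta.loc[wide.index, "group"].to_numpy(),
            "replicate_flag": flag.to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def rq_wide(plate: pd.DataFrame, genes, reference_gene: str = "GAPDH") -> pd.DataFrame:
    """Samples × genes frame of natural-log RQ values."""
    cols = {}
    for gene in genes:
        tab = livak_rq(plate, gene, reference_gene).set_index("sample_id")
        cols[gene] = tab["log_rq"]
    return pd.DataFrame(cols)


def compare_expression_groups(
    rq_table: pd.DataFrame, equal_var: bool = True, scale: str = "log"
) -> GroupComparison:
    """OA vs control comparison of one gene's expression.

    Student's t test on natural-log RQ (default); percent increase is the
    geometric-mean ratio minus one.  ``scale="arithmetic"`` tests raw RQ
    and reports the arithmetic-mean ratio instead.
    """
    if scale not in ("log", "arithmetic"):
        raise ValueError(f"unknown scale {scale!r}")
    col = "log_rq" if scale == "log" else "rq"
    oa = rq_table.loc[rq_table["group"] == "OA", col].to_numpy()
    ctl = rq_table.loc[rq_table["group"] == "control", col].to_numpy()
    if len(oa) < 2 or len(ctl) < 2:
        raise ValueError("need at least 2 samples per group")
    res = stats.ttest_ind(oa, ctl, equal_var=equal_var)
    if scale == "log":
        fold = float(np.exp(oa.mean() - ctl.mean()))
    else:
        fold = float(oa.mean() / ctl.mean())
    p = float(res.pvalue)
    return GroupComparison(
        t=float(res.statistic),
        p=1.0 if np.isnan(p) else p,
        n_oa=len(oa),
        n_control=len(ctl),
        fold_change=fold,
        percent_increase=(fold - 1.0) * 100.0,
    )


def cytokine_correlation_matrix(
    log_rq: pd.DataFrame,
    method: str = "t",
    n_permutations: int = 10_000,
    seed: int = 1,
) -> dict[tuple[str, str], CorrelationResult]:
    """All pairwise Pearson correlations between gene log-RQ columns.

    Rows with any missing gene are dropped (shared sample set).  P-values
    come from the two-sided t approximation by default; ``method="permutation"``
    uses a seeded permutation null of ``n_permutations`` shuffles instead.
    """
    data = log_rq.dropna()
    n = len(data)
    if n < 3:
        raise ValueError("shared sample set must have >= 3 samples")
    genes = list(data.columns)
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], CorrelationResult] = {}
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            x = data[a].to_numpy()
            y = data[b].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                raise ValueError(f"constant gene vector {a if np.std(x)==0 else b!r}")
            res = stats.pearsonr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
            if method == "permutation":
                perm_r = np.empty(n_permutations)
                for k in range(n_permutations):
                    perm_r[k] = np.corrcoef(x, rng.permutation(y))[0, 1]
                p = float((np.sum(np.abs(perm_r) >= abs(r)) + 1) / (n_permutations + 1))
            elif method != "t":
                raise ValueError(f"unknown method {method!r}")
            out[(a, b)] = CorrelationResult(r=r, p=p, n=n)
    return out


def multivariable_cytokine_model(
    log_rq: pd.DataFrame,
    response: str = "PLA2G5",
    predictors: tuple[str, ...] = ("IL6", "TNFa", "IL1b"),
) -> pd.DataFrame:
    """OLS of the target gene's log RQ on the cytokines' log RQ.

    Returns a frame indexed by term (const + predictors) with columns
    ``beta``, ``se``, ``t``, ``p``.
    """
    data = log_rq[[response, *predictors]].dropna()
    n = len(data)
    if n < len(predictors) + 3:
        raise ValueError("too few complete cases for the multivariable model")
    X = np.column_stack([np.ones(n), data[list(predictors)].to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear cytokine predictors")
    y = data[response].to_numpy()
    q, r = np.linalg.qr(X)
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - X @ coef
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(r.T @ r)))
    t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame(
        {"beta": coef, "se": se, "t": t, "p": p},
        index=["const", *predictors],
    )


def efficiency_from_dilution_series(log10_input, ct) -> EfficiencyResult:
    """Primer efficiency from a standard curve of Ct versus log10 input.

    Fits Ct = a + slope·log10(input) and converts the slope to percent
    efficiency, (10^(−1/slope) − 1) × 100; a slope of −3.3219 (−1/log10 2)
    is perfect doubling, i.e. 100%.
    """
    x = np.asarray(log10_input, dtype=float)
    y = np.asarray(ct, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct dilution levels")
    res = stats.linregress(x, y)
    slope = float(res.slope)
    if slope >= 0:
        raise ValueError("amplification curve inverted (slope >= 0)")
    eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    return EfficiencyResult(
        gene="", slope=slope, r2=float(res.rvalue**2), efficiency_percent=eff
    )
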