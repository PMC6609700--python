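"""Quality control for the concentration matrix.

The QC chain mirrors standard targeted-metabolomics practice: (1) remove
metabolites with too many below-LOD/missing values, (2) mean-impute the
remaining gaps, (3) check for batch effects with PCA.  Replicate-based
coefficient-of-variation assessment of assay precision is also provided.

Below-LOD and missing cells are pooled for the removal rule and both
imputed afterwards (the conservative reading when the two are not
distinguished upstream); the pooling is driven by the mask, never by the
stored value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io_tables import ConcentrationMatrix

__all__ = [
    "QcReport",
    "CvReport",
    "filter_by_lod",
    "impute_missing_mean",
    "pca_batch_check",
    "replicate_cv",
]


@dataclass
class QcReport:
    """Outcome of the LOD filter (and optionally the batch check)."""

    removed_metabolites: list[tuple[str, float]]
    retained_count: int
    input_count: int
    imputed_cell_count: int = 0
    batch_pc_scores: pd.DataFrame | None = None
    batch_separation_p: float | None = None
    batch_flag: bool | None = None


@dataclass
class CvReport:
    """Replicate coefficient-of-variation summary."""

    per_metabolite_cv: pd.Series
    mean_cv: float
    sd_cv: float
    frac_below_0p10: float


def filter_by_lod(
    matrix: ConcentrationMatrix, threshold: float = 0.10
) -> tuple[ConcentrationMatrix, QcReport]:
    """Remove metabolites whose below-LOD-or-missing fraction exceeds ``threshold``.

    The rule is strict ("more than"): a metabolite with fraction exactly
    equal to the threshold is retained.  Column and subject order are
    preserved; the operation is idempotent.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if matrix.values.empty:
        raise ValueError("concentration matrix is empty")
    frac = matrix.masked_or_missing().mean(axis=0)
    removed = frac[frac > threshold]
    keep = [m for m in matrix.metabolites if m not in removed.index]
    if not keep:
        raise ValueError("no metabolites survive QC")
    filtered = ConcentrationMatrix(
        values=matrix.values[keep].copy(),
        below_lod=matrix.below_lod[keep].copy(),
        batch=matrix.batch.copy(),
    )
    report = QcReport(
        removed_metabolites=[(m, float(removed[m])) for m in removed.index],
        retained_count=len(keep),
        input_count=len(matrix.metabolites),
    )
    return filtered, report


def impute_missing_mean(
    matrix: ConcentrationMatrix,
) -> tuple[ConcentrationMatrix, int]:
    """Replace every masked-or-missing cell by its metabolite's observed mean.

    Observed cells are never changed, so each column's observed mean is
    preserved exactly.  Imputed cells have their below-LOD flag cleared
    (the matrix is analysis-ready afterwards).
    """
    bad = matrix.masked_or_missing()
    values = matrix.values.copy()
    n_imputed = 0
    for met in matrix.metabolites:
        col_bad = bad[met]
        if not col_bad.any():
            continue
        obs = values.loc[~col_bad, met]
        if obs.empty:
            raise ValueError(f"metabolite {met!r} has no observed values")
        values.loc[col_bad, met] = obs.mean()
        n_imputed += int(col_bad.sum())
    out = ConcentrationMatrix(
        values=values,
        below_lod=pd.DataFrame(
            False, index=matrix.subjects, columns=matrix.metabolites
        ),
        batch=matrix.batch.copy(),
    )
    return out, n_imputed


def pca_batch_check(
    matrix: ConcentrationMatrix, n_components: int = 2
) -> QcReport:
    """PCA-based batch-effect screen.

    Columns are standardized, PCA fitted, and batch separation quantified
    as the one-way ANOVA p-value of batch label on the first principal
    component's scores; ``batch_flag`` is raised when p < 0.05.  This
    operationalizes a visual "no batch clustering" check as a test.
    """
    batches = matrix.batch.unique()
    if len(batches) < 2:
        raise ValueError("batch check requires >=2 batches")
    counts = matrix.batch.value_counts()
    if (counts < 3).any():
        raise ValueError("each batch needs at least 3 subjects")
    if matrix.values.isna().any().any():
        raise ValueError("matrix must be fully imputed before the batch check")
    x = matrix.values.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    xs = (x[:, keep] - mean[keep]) / sd[keep]
    k = min(n_components, xs.shape[1], xs.shape[0])
    scores = PCA(n_components=k, svd_solver="full").fit_transform(xs)
    score_df = pd.DataFrame(
        scores,
        index=matrix.subjects,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    groups = [scores[matrix.batch.to_numpy() == b, 0] for b in batches]
    if all(np.ptp(np.concatenate(groups)) == 0 for _ in (0,)):
        p = 1.0  # identical scores in every batch: no separation
    else:
        p = float(stats.f_oneway(*groups).pvalue)
        if np.isnan(p):
            p = 1.0
    return QcReport(
        removed_metabolites=[],
        retained_count=len(matrix.metabolites),
        input_count=len(matrix.metabolites),
        batch_pc_scores=score_df,
        batch_separation_p=p,
        batch_flag=p < 0.05,
    )


def replicate_cv(replicates: pd.DataFrame) -> CvReport:
    """Assay precision from repeated measurements.

    ``replicates`` is a long table with columns ``metabolite_id``,
    ``sample_id`` and ``value`` holding >= 2 replicate measurements per
    (metabolite, sample).  The CV of each (metabolite, sample) set is the
    sample SD (n−1 denominator) over the mean; per-metabolite CVs average
    across samples.  The report also gives the grand mean CV and the
    fraction of metabolites with CV < 0.10.
    """
    for col in ("metabolite_id", "sample_id", "value"):
        if col not in replicates.columns:
            raise ValueError(f"replicate table missing column {col!r}")
    grouped = replicates.groupby(["metabolite_id", "sample_id"])["value"]
    if (grouped.count() < 2).any():
        raise ValueError("need >=2 replicates per (metabolite, sample)")
    means = grouped.mean()
    if (means == 0).any():
        raise ValueError("zero-mean replicate set: CV undefined")
    cv = grouped.std(ddof=1) / means.abs()
    per_met = cv.groupby("metabolite_id").mean()
    return CvReport(
        per_metabolite_cv=per_met,
        mean_cv=float(per_met.mean()),
        sd_cv=float(per_met.std(ddof=1)) if len(per_met) > 1 else 0.0,
        frac_below_0p10=float((per_met < 0.10).mean()),
    )
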