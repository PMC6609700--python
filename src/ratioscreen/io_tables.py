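"""Tabular contracts and CSV I/O for the ratio-screening pipeline.

Every artifact the pipeline consumes or emits is a plain CSV (UTF-8,
comma-separated, mandatory header, empty string = missing).  The quantified
concentration table is the entry point: upstream assay processing (vendor
quantification software) is assumed to have already produced per-subject
metabolite concentrations in μM.

In-memory containers are pandas objects with documented column contracts,
validated on read and on construction:

* metabolite panel  -- DataFrame indexed by ``metabolite_id`` with columns
  ``class_label`` (one of the five assay classes) and ``lod`` (μM).
* :class:`ConcentrationMatrix` -- subjects × metabolites values plus a
  below-LOD mask and per-subject batch labels.
* cohort table      -- one row per subject with the seven adjustment
  covariates (age, sex, BMI, diabetes, hypertension, dyslipidemia,
  treatment arm).
* volume table      -- baseline and 24-month cartilage volume (mm³) per
  knee compartment.
* biomarker table   -- long table of serum marker measurements.
* qPCR plate        -- per-sample triplicate Ct values per gene.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CLASS_LABELS",
    "DEFAULT_CLASS_COUNTS",
    "COVARIATE_COLUMNS",
    "ASSOCIATION_COLUMNS",
    "TableContractError",
    "RunConfig",
    "ConcentrationMatrix",
    "validate_panel",
    "validate_cohort",
    "validate_volumes",
    "validate_biomarkers",
    "validate_qpcr_plate",
    "read_panel",
    "write_panel",
    "read_concentrations",
    "write_concentrations",
    "read_cohort",
    "write_cohort",
    "read_volumes",
    "write_volumes",
    "read_biomarkers",
    "write_biomarkers",
    "read_qpcr_plate",
    "write_qpcr_plate",
    "read_association_table",
    "write_association_table",
]

#: The five metabolite classes of a 186-analyte targeted assay panel.
CLASS_LABELS = (
    "acylcarnitine",
    "amino_acid",
    "biogenic_amine",
    "hexose",
    "glycerophospholipid_sphingolipid",
)

#: Class sizes of the default panel (40 acylcarnitines, 22 amino acids,
#: 18 biogenic amines, 1 hexose sum, 105 phospho- and sphingolipids).
DEFAULT_CLASS_COUNTS: Mapping[str, int] = {
    "acylcarnitine": 40,
    "amino_acid": 22,
    "biogenic_amine": 18,
    "hexose": 1,
    "glycerophospholipid_sphingolipid": 105,
}

#: The seven adjustment covariates, in design-matrix order.
COVARIATE_COLUMNS = (
    "age",
    "sex",
    "bmi",
    "diabetes",
    "hypertension",
    "dyslipidemia",
    "treatment",
)

#: Column schema of the association result table.
ASSOCIATION_COLUMNS = (
    "pair_id",
    "numerator",
    "denominator",
    "beta_unadj",
    "ci_low_unadj",
    "ci_high_unadj",
    "p_unadj",
    "beta_adj",
    "ci_low_adj",
    "ci_high_adj",
    "p_adj",
    "n_used",
    "significant",
)

_FLOAT_FMT = "%.12g"  # 12 significant digits: lossless for reported effects


class TableContractError(ValueError):
    """A tabular artifact violates its declared column contract."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Run-level knobs shared across pipeline stages.

    Parameters
    ----------
    lod_missing_threshold
        Metabolites whose below-LOD-or-missing fraction is *strictly greater*
        than this are removed during QC.  Default 0.10 ("more than 10%").
    alpha
        Family-wise significance level before Bonferroni division.
    pair_mode
        ``"ordered"`` (m·(m−1) directed ratios, default) or ``"unordered"``
        (m·(m−1)/2).
    covariates
        Cohort columns entering the adjusted model.
    seed
        Master seed; component seeds are fanned out from it.
    denominator_guard_epsilon
        Cells with \\|denominator Z\\| below this are flagged degenerate and
        dropped from that pair's regression.  0 = off (only exact zeros are
        flagged), which reproduces the literal ratio-of-Z definition.
    n_tests_override
        If set, the Bonferroni divisor uses this instead of the number of
        pairs actually fitted (e.g. 21952 to reproduce a published divisor).
    """

    lod_missing_threshold: float = 0.10
    alpha: float = 0.05
    pair_mode: str = "ordered"
    covariates: tuple[str, ...] = COVARIATE_COLUMNS
    seed: int = 1
    denominator_guard_epsilon: float = 0.0
    n_tests_override: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.lod_missing_threshold < 1.0:
            raise ValueError("lod_missing_threshold must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.pair_mode not in ("ordered", "unordered"):
            raise ValueError(f"unknown pair_mode {self.pair_mode!r}")
        unknown = set(self.covariates) - set(COVARIATE_COLUMNS)
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")
        self.covariates = tuple(self.covariates)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise TableContractError(f"config file {path} is not a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise TableContractError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["covariates"] = list(self.covariates)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check the metabolite-panel contract and return the frame unchanged."""
    for col in ("class_label", "lod"):
        if col not in panel.columns:
            raise TableContractError(f"panel missing column {col!r}")
    if panel.index.name != "metabolite_id":
        raise TableContractError("panel must be indexed by metabolite_id")
    if panel.index.duplicated().any():
        dup = panel.index[panel.index.duplicated()][0]
        raise TableContractError(f"duplicate metabolite_id {dup!r}")
    bad = set(panel["class_label"]) - set(CLASS_LABELS)
    if bad:
        raise TableContractError(f"unknown class labels: {sorted(bad)}")
    if not (panel["lod"] > 0).all():
        raise TableContractError("every LOD must be > 0")
    return panel


def read_panel(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "panel")
    _require_columns(df, ("metabolite_id", "class_label", "lod"), "panel")
    return validate_panel(df.set_index("metabolite_id"))


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    validate_panel(panel)
    panel.reset_index().to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Concentration matrix
# ---------------------------------------------------------------------------


@dataclass
class ConcentrationMatrix:
    """Subjects × metabolites concentrations with below-LOD mask and batches.

    ``values`` holds concentrations in μM with ``NaN`` for missing cells;
    ``below_lod`` is a boolean frame of identical shape; ``batch`` maps each
    subject to its measurement batch.  A cell may be masked below-LOD while
    still carrying a numeric value (the mask, not the value, drives QC).
    """

    values: pd.DataFrame
    below_lod: pd.DataFrame
    batch: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise TableContractError(f"duplicate subject id {dup!r}")
        if not self.values.index.equals(self.below_lod.index) or not list(
            self.values.columns
        ) == list(self.below_lod.columns):
            raise TableContractError("values and below_lod must be aligned")
        if not self.values.index.equals(self.batch.index):
            raise TableContractError("batch labels must cover every subject")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise TableContractError("concentrations must be >= 0")

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def metabolites(self) -> pd.Index:
        return self.values.columns

    def masked_or_missing(self) -> pd.DataFrame:
        """Boolean frame: cell is below LOD or missing (pooled QC mask)."""
        return self.below_lod | self.values.isna()

    def copy(self) -> "ConcentrationMatrix":
        return ConcentrationMatrix(
            self.values.copy(), self.below_lod.copy(), self.batch.copy()
        )


def read_concentrations(
    path: str | Path,
    panel: pd.DataFrame,
    mask_path: str | Path | None = None,
) -> ConcentrationMatrix:
    """Read a subjects × metabolites concentration CSV.

    The file has columns ``subject_id``, ``batch`` and one column per
    metabolite.  When ``mask_path`` is given, the below-LOD mask is read from
    that companion CSV (same shape, 0/1); otherwise the mask is computed from
    the panel LODs (``value < lod``) with missing cells masked as well.
    """
    validate_panel(panel)
    df = _read_csv(path, "concentrations")
    _require_columns(df, ("subject_id", "batch"), "concentrations")
    met_cols = [c for c in df.columns if c not in ("subject_id", "batch")]
    unknown = [c for c in met_cols if c not in panel.index]
    if unknown:
        raise TableContractError(
            f"concentration column {unknown[0]!r} is not in the panel"
        )
    values = df.set_index("subject_id")[met_cols].astype(float)
    values.columns.name = "metabolite_id"
    if values.index.duplicated().any():
        dup = values.index[values.index.duplicated()][0]
        raise TableContractError(f"duplicate subject id {dup!r}")
    batch = df.set_index("subject_id")["batch"].astype(str)
    if mask_path is not None:
        mdf = _read_csv(mask_path, "below-LOD mask").set_index("subject_id")
        mask = mdf[met_cols].astype(float).fillna(0).astype(bool)
        mask = mask.reindex(index=values.index)
        mask.columns.name = "metabolite_id"
    else:
        lod = panel["lod"].reindex(met_cols)
        with np.errstate(invalid="ignore"):
            mask = values.lt(lod, axis=1)
        mask |= values.isna()
    return ConcentrationMatrix(values=values, below_lod=mask, batch=batch)


def write_concentrations(
    matrix: ConcentrationMatrix,
    path: str | Path,
    mask_path: str | Path | None = None,
) -> None:
    out = matrix.values.copy()
    out.insert(0, "batch", matrix.batch)
    out.index.name = "subject_id"
    out.reset_index().to_csv(path, index=False, float_format=_FLOAT_FMT)
    if mask_path is not None:
        m = matrix.below_lod.astype(int)
        m.index.name = "subject_id"
        m.reset_index().to_csv(mask_path, index=False)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

_BOOL_COVARIATES = ("diabetes", "hypertension", "dyslipidemia")


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    _require_columns(cohort, ("subject_id",) + COVARIATE_COLUMNS, "cohort")
    if cohort["subject_id"].duplicated().any():
        dup = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise TableContractError(f"duplicate subject id {dup!r}")
    if not (cohort["age"] > 0).all():
        raise TableContractError("age must be > 0")
    if not (cohort["bmi"] > 0).all():
        raise TableContractError("bmi must be > 0")
    if not cohort["sex"].isin(["female", "male"]).all():
        raise TableContractError("sex must be 'female' or 'male'")
    if not cohort["treatment"].isin(["licofelone", "naproxen"]).all():
        raise TableContractError("treatment must be 'licofelone' or 'naproxen'")
    return cohort


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "cohort")
    validate_cohort(df)
    for col in _BOOL_COVARIATES:
        df[col] = df[col].astype(int).astype(bool)
    return df


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(cohort)
    out = cohort.copy()
    for col in _BOOL_COVARIATES:
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

COMPARTMENTS = ("lateral", "medial")


def validate_volumes(volumes: pd.DataFrame) -> pd.DataFrame:
    _require_columns(
        volumes,
        ("subject_id", "compartment", "volume_baseline", "volume_24m"),
        "volumes",
    )
    if not volumes["compartment"].isin(COMPARTMENTS).all():
        raise TableContractError("compartment must be 'lateral' or 'medial'")
    if volumes.duplicated(["subject_id", "compartment"]).any():
        raise TableContractError("duplicate (subject, compartment) row")
    if not (volumes["volume_baseline"] > 0).all() or not (
        volumes["volume_24m"] > 0
    ).all():
        raise TableContractError("volumes must be strictly positive")
    return volumes


def read_volumes(path: str | Path) -> pd.DataFrame:
    return validate_volumes(_read_csv(path, "volumes"))


def write_volumes(volumes: pd.DataFrame, path: str | Path) -> None:
    validate_volumes(volumes)
    volumes.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Biomarkers
# ---------------------------------------------------------------------------


def validate_biomarkers(markers: pd.DataFrame) -> pd.DataFrame:
    _require_columns(
        markers, ("subject_id", "marker", "timepoint", "value"), "biomarkers"
    )
    if not markers["timepoint"].isin(["baseline", "followup"]).all():
        raise TableContractError("timepoint must be 'baseline' or 'followup'")
    if markers.duplicated(["subject_id", "marker", "timepoint"]).any():
        raise TableContractError("duplicate (subject, marker, timepoint) row")
    if (markers["value"].dropna() < 0).any():
        raise TableContractError("biomarker values must be >= 0")
    return markers


def read_biomarkers(path: str | Path) -> pd.DataFrame:
    return validate_biomarkers(_read_csv(path, "biomarkers"))


def write_biomarkers(markers: pd.DataFrame, path: str | Path) -> None:
    validate_biomarkers(markers)
    markers.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

QPCR_COLUMNS = (
    "sample_id",
    "gene",
    "ct1",
    "ct2",
    "ct3",
    "group",
    "tissue",
    "is_calibrator",
)


def validate_qpcr_plate(plate: pd.DataFrame) -> pd.DataFrame:
    _require_columns(plate, QPCR_COLUMNS, "qPCR plate")
    cts = plate[["ct1", "ct2", "ct3"]].to_numpy(dtype=float)
    if not ((cts > 0) & (cts < 45)).all():
        raise TableContractError("Ct values must lie in (0, 45)")
    if not plate["group"].isin(["OA", "control"]).all():
        raise TableContractError("group must be 'OA' or 'control'")
    n_cal = plate.loc[plate["is_calibrator"].astype(bool), "sample_id"].nunique()
    if n_cal != 1:
        raise TableContractError(
            f"exactly one calibrator sample required, found {n_cal}"
        )
    return plate


def read_qpcr_plate(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "qPCR plate")
    df["is_calibrator"] = df["is_calibrator"].astype(int).astype(bool)
    return validate_qpcr_plate(df)


def write_qpcr_plate(plate: pd.DataFrame, path: str | Path) -> None:
    validate_qpcr_plate(plate)
    out = plate.copy()
    out["is_calibrator"] = out["is_calibrator"].astype(int)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Association results
# ---------------------------------------------------------------------------


def write_association_table(results: pd.DataFrame, path: str | Path) -> None:
    """Serialize the per-pair association table (screen output schema)."""
    if results.empty:
        raise TableContractError("association table is empty")
    _require_columns(results, ASSOCIATION_COLUMNS, "association table")
    out = results[list(ASSOCIATION_COLUMNS)].copy()
    out["significant"] = out["significant"].astype(int)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_association_table(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, "association table")
    _require_columns(df, ASSOCIATION_COLUMNS, "association table")
    df["significant"] = df["significant"].astype(int).astype(bool)
    df["n_used"] = df["n_used"].astype(int)
    return df


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _read_csv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise TableContractError(f"{what} file {path} has no data rows")
    return df


def _require_columns(
    df: pd.DataFrame, columns: Sequence[str], what: str
) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableContractError(f"{what} missing column {missing[0]!r}")
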