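"""Synthetic study-input generator.

Emulates the full input bundle of a 24-month knee-osteoarthritis progression
study: a 186-analyte targeted metabolomics panel (five classes: 40
acylcarnitines, 22 amino acids, 18 biogenic amines, 1 hexose sum, 105
phospho- and sphingolipids), log-normal serum concentrations with
within-class correlation and limit-of-detection censoring, a two-arm cohort
(licofelone vs naproxen, n = 69 + 70), MRI cartilage volumes whose
percentage change carries a planted metabolite-ratio effect, serum
biomarkers (COMP, MMP-1, LCAT), and qPCR plates with a planted group fold
change and cytokine correlation structure.

All generators are pure functions of (parameters, seed): identical inputs
yield byte-identical outputs.  A master seed fans out to per-component
streams through :func:`component_rng`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest

from .io_tables import (
    CLASS_LABELS,
    DEFAULT_CLASS_COUNTS,
    ConcentrationMatrix,
    validate_panel,
)

__all__ = [
    "EffectSpec",
    "QpcrEffectSpec",
    "ConcentrationModel",
    "CohortModel",
    "OutcomeModel",
    "component_rng",
    "make_default_panel",
    "make_panel",
    "default_censor_plan",
    "simulate_concentrations",
    "simulate_cohort",
    "simulate_outcomes",
    "simulate_biomarkers",
    "simulate_qpcr",
    "simulate_bundle",
    "planted_ratio",
    "metabolite_log_means",
]


def component_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-component random stream fanned out from a master seed.

    The component name is hashed (CRC-32) into the seed sequence entropy, so
    streams for different components are statistically independent and adding
    a component never perturbs the others.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


# ---------------------------------------------------------------------------
# Panel: metabolite identities, classes, LODs
# ---------------------------------------------------------------------------

_ACYLCARNITINES = [
    "C0", "C2", "C3", "C3:1", "C3-OH", "C3-DC", "C4", "C4:1", "C5", "C5:1",
    "C5:1-DC", "C5-OH", "C5-DC", "C5-M-DC", "C6", "C6:1", "C7-DC", "C8",
    "C9", "C10", "C10:1", "C10:2", "C12", "C12:1", "C12-DC", "C14", "C14:1",
    "C14:1-OH", "C14:2", "C14:2-OH", "C16", "C16:1", "C16:2", "C16-OH",
    "C16:1-OH", "C16:2-OH", "C18", "C18:1", "C18:2", "C18:1-OH",
]

_AMINO_ACIDS = [
    "Ala", "Arg", "Asn", "Asp", "Cit", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Orn", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr",
    "Val", "xLeu",
]

_BIOGENIC_AMINES = [
    "Ac-Orn", "ADMA", "alpha-AAA", "Carnosine", "Creatinine", "DOPA",
    "Dopamine", "Histamine", "Kynurenine", "Met-SO", "Nitro-Tyr", "PEA",
    "Putrescine", "Sarcosine", "Serotonin", "Spermidine", "Spermine",
    "Taurine",
]

_HEXOSES = ["H1"]

_LYSOPC = [
    "lysoPC a C14:0", "lysoPC a C16:0", "lysoPC a C16:1", "lysoPC a C17:0",
    "lysoPC a C18:0", "lysoPC a C18:1", "lysoPC a C18:2", "lysoPC a C20:3",
    "lysoPC a C20:4", "lysoPC a C24:0", "lysoPC a C26:0", "lysoPC a C26:1",
    "lysoPC a C28:0", "lysoPC a C28:1",
]

_PC_AA = [
    "PC aa C24:0", "PC aa C26:0", "PC aa C28:1", "PC aa C30:0",
    "PC aa C32:0", "PC aa C32:1", "PC aa C32:2", "PC aa C32:3",
    "PC aa C34:1", "PC aa C34:2", "PC aa C34:3", "PC aa C34:4",
    "PC aa C36:0", "PC aa C36:1", "PC aa C36:2", "PC aa C36:3",
    "PC aa C36:4", "PC aa C36:5", "PC aa C36:6", "PC aa C38:0",
    "PC aa C38:1", "PC aa C38:2", "PC aa C38:3", "PC aa C38:4",
    "PC aa C38:5", "PC aa C38:6", "PC aa C40:1", "PC aa C40:2",
    "PC aa C40:3", "PC aa C40:4", "PC aa C40:5", "PC aa C40:6",
    "PC aa C42:0", "PC aa C42:1", "PC aa C42:2", "PC aa C42:4",
    "PC aa C42:5", "PC aa C42:6",
]

_PC_AE = [
    "PC ae C30:0", "PC ae C30:1", "PC ae C30:2", "PC ae C32:1",
    "PC ae C32:2", "PC ae C34:0", "PC ae C34:1", "PC ae C34:2",
    "PC ae C34:3", "PC ae C36:0", "PC ae C36:1", "PC ae C36:2",
    "PC ae C36:3", "PC ae C36:4", "PC ae C36:5", "PC ae C38:0",
    "PC ae C38:1", "PC ae C38:2", "PC ae C38:3", "PC ae C38:4",
    "PC ae C38:5", "PC ae C38:6", "PC ae C40:1", "PC ae C40:2",
    "PC ae C40:3", "PC ae C40:4", "PC ae C40:5", "PC ae C40:6",
    "PC ae C42:0", "PC ae C42:1", "PC ae C42:2", "PC ae C42:3",
    "PC ae C42:4", "PC ae C42:5", "PC ae C44:3", "PC ae C44:4",
    "PC ae C44:5", "PC ae C44:6",
]

_SM = [
    "SM C16:0", "SM C16:1", "SM C18:0", "SM C18:1", "SM C20:2", "SM C22:3",
    "SM C24:0", "SM C24:1", "SM C26:0", "SM C26:1", "SM (OH) C14:1",
    "SM (OH) C16:1", "SM (OH) C22:1", "SM (OH) C22:2", "SM (OH) C24:1",
]

_CLASS_MEMBERS: Mapping[str, list[str]] = {
    "acylcarnitine": _ACYLCARNITINES,
    "amino_acid": _AMINO_ACIDS,
    "biogenic_amine": _BIOGENIC_AMINES,
    "hexose": _HEXOSES,
    "glycerophospholipid_sphingolipid": _LYSOPC + _PC_AA + _PC_AE + _SM,
}

#: LOD draw ranges (μM, log-uniform) per class — typical assay sensitivities.
_LOD_RANGES: Mapping[str, tuple[float, float]] = {
    "acylcarnitine": (0.005, 0.1),
    "amino_acid": (1.0, 10.0),
    "biogenic_amine": (0.01, 0.5),
    "hexose": (10.0, 100.0),
    "glycerophospholipid_sphingolipid": (0.01, 1.0),
}

#: Metabolites the default censor plan never censors: the planted pair and
#: the other named top-ranked analytes, so they always survive QC.
PROTECTED_METABOLITES = (
    "lysoPC a C18:2", "lysoPC a C18:1", "PC ae C44:3", "Gln", "Met", "Pro",
    "Arg", "PC aa C32:1", "PC aa C32:2", "PC aa C42:0", "PC aa C34:1",
    "PC ae C40:5",
)


def make_default_panel(seed: int = 1) -> pd.DataFrame:
    """Default 186-metabolite panel with per-class log-uniform LODs."""
    rng = component_rng(seed, "panel")
    rows = []
    for label in CLASS_LABELS:
        members = _CLASS_MEMBERS[label]
        lo, hi = _LOD_RANGES[label]
        lods = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(members)))
        for met, lod in zip(members, lods):
            rows.append((met, label, lod))
    panel = pd.DataFrame(rows, columns=["metabolite_id", "class_label", "lod"])
    panel = panel.set_index("metabolite_id")
    counts = panel["class_label"].value_counts().to_dict()
    assert counts == dict(DEFAULT_CLASS_COUNTS), counts
    return validate_panel(panel)


def make_panel(class_counts: Mapping[str, int], seed: int = 1) -> pd.DataFrame:
    """Reduced or custom panel: first ``k`` members of each class."""
    rng = component_rng(seed, "panel")
    rows = []
    for label, k in class_counts.items():
        members = _CLASS_MEMBERS[label][:k]
        if len(members) < k:
            raise ValueError(f"class {label!r} has only {len(members)} members")
        lo, hi = _LOD_RANGES[label]
        lods = np.exp(rng.uniform(np.log(lo), np.log(hi), size=k))
        rows.extend(zip(members, [label] * k, lods))
    panel = pd.DataFrame(rows, columns=["metabolite_id", "class_label", "lod"])
    return validate_panel(panel.set_index("metabolite_id"))


# ---------------------------------------------------------------------------
# Concentrations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConcentrationModel:
    """Log-normal concentration model with class-block correlation.

    Per metabolite j in class c:  log X_ij = μ_j + σ·(√ρ·U_ic + √(1−ρ)·E_ij)
    with μ_j ~ Normal(class log-mean, class spread).  The exchangeable
    class factor U gives every within-class pair correlation ρ on the log
    scale.  Class log-means reflect typical serum levels (amino acids
    ~100 μM, hexoses ~mM, lipids ~tens of μM, acylcarnitines/amines sub-μM).
    """

    class_log_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "acylcarnitine": np.log(0.3),
            "amino_acid": np.log(100.0),
            "biogenic_amine": np.log(0.5),
            "hexose": np.log(4500.0),
            "glycerophospholipid_sphingolipid": np.log(20.0),
        }
    )
    class_log_spread: Mapping[str, float] = field(
        default_factory=lambda: {
            "acylcarnitine": 1.0,
            "amino_acid": 0.8,
            "biogenic_amine": 1.0,
            "hexose": 0.1,
            "glycerophospholipid_sphingolipid": 1.2,
        }
    )
    subject_log_sd: float = 0.4
    within_class_rho: float = 0.3
    n_batches: int = 2


def metabolite_log_means(
    panel: pd.DataFrame, seed: int, model: ConcentrationModel = ConcentrationModel()
) -> pd.Series:
    """Per-metabolite log-scale location parameters (deterministic in seed)."""
    rng = component_rng(seed, "metabolite-log-means")
    mus = np.empty(len(panel))
    for label in CLASS_LABELS:
        sel = (panel["class_label"] == label).to_numpy()
        mus[sel] = rng.normal(
            model.class_log_mean[label], model.class_log_spread[label], sel.sum()
        )
    return pd.Series(mus, index=panel.index, name="log_mean")


def default_censor_plan(
    panel: pd.DataFrame,
    seed: int = 1,
    n_removed: int = 34,
    n_light: int = 30,
) -> dict[str, float]:
    """Per-metabolite below-LOD fractions emulating the study's QC outcome.

    ``n_removed`` metabolites receive censoring fractions in [0.12, 0.35]
    (above the 10% removal rule at n = 139), ``n_light`` receive fractions
    in [0.005, 0.09] (retained), and the rest — including the protected,
    analysis-critical metabolites — are uncensored.  With the default
    n = 139 cohort this yields exactly ``186 − n_removed = 152`` metabolites
    surviving QC.
    """
    rng = component_rng(seed, "censor-plan")
    eligible = [m for m in panel.index if m not in PROTECTED_METABOLITES]
    if n_removed + n_light > len(eligible):
        raise ValueError("censor plan larger than eligible metabolite set")
    chosen = rng.choice(len(eligible), size=n_removed + n_light, replace=False)
    plan = {m: 0.0 for m in panel.index}
    for i, idx in enumerate(chosen):
        met = eligible[idx]
        if i < n_removed:
            plan[met] = float(rng.uniform(0.12, 0.35))
        else:
            plan[met] = float(rng.uniform(0.005, 0.09))
    return plan


def simulate_concentrations(
    panel: pd.DataFrame,
    n_subjects: int,
    seed: int,
    censor_plan: Mapping[str, float] | None = None,
    model: ConcentrationModel = ConcentrationModel(),
) -> ConcentrationMatrix:
    """Draw a subjects × metabolites concentration matrix with LOD censoring.

    Censoring removes the ``round(fraction · n)`` *lowest* values of each
    metabolite (the LOD mechanism): those cells become missing and are
    flagged below-LOD.  ``censor_plan=None`` applies the default plan.
    """
    validate_panel(panel)
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if censor_plan is None:
        censor_plan = default_censor_plan(panel, seed=seed)
    bad = {m: f for m, f in censor_plan.items() if not 0.0 <= f <= 1.0}
    if bad:
        raise ValueError(f"censor fractions outside [0, 1]: {bad}")

    rng = component_rng(seed, "concentrations")
    mus = metabolite_log_means(panel, seed, model).to_numpy()
    m = len(panel)
    rho = model.within_class_rho
    if not 0.0 <= rho < 1.0:
        raise ValueError("within_class_rho must lie in [0, 1)")

    # exchangeable class factor + idiosyncratic noise, both N(0,1)
    class_codes = pd.Categorical(
        panel["class_label"], categories=CLASS_LABELS
    ).codes
    u = rng.standard_normal((n_subjects, len(CLASS_LABELS)))
    e = rng.standard_normal((n_subjects, m))
    z = np.sqrt(rho) * u[:, class_codes] + np.sqrt(1.0 - rho) * e
    values = np.exp(mus[None, :] + model.subject_log_sd * z)

    subjects = pd.Index(
        [f"S{i + 1:03d}" for i in range(n_subjects)], name="subject_id"
    )
    vals = pd.DataFrame(values, index=subjects, columns=panel.index)
    mask = pd.DataFrame(False, index=subjects, columns=panel.index)
    for met in panel.index:
        frac = float(censor_plan.get(met, 0.0))
        k = int(round(frac * n_subjects))
        if k <= 0:
            continue
        order = np.argsort(vals[met].to_numpy(), kind="stable")[:k]
        mask.iloc[order, mask.columns.get_loc(met)] = True
        vals.iloc[order, vals.columns.get_loc(met)] = np.nan

    half = n_subjects // 2
    batch = pd.Series(
        ["B1"] * half + ["B2"] * (n_subjects - half),
        index=subjects,
        name="batch",
    )
    return ConcentrationMatrix(values=vals, below_lod=mask, batch=batch)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortModel:
    """Arm-level covariate moments (licofelone arm first, naproxen second)."""

    age_mean: tuple[float, float] = (61.0, 61.0)
    age_sd: tuple[float, float] = (9.0, 8.0)
    bmi_mean: tuple[float, float] = (32.3, 31.2)
    bmi_sd: tuple[float, float] = (5.8, 5.7)
    female_frac: tuple[float, float] = (0.74, 0.61)
    comorbidity_p: float = 0.2


def simulate_cohort(
    n_per_arm: tuple[int, int] = (69, 70),
    seed: int = 1,
    model: CohortModel = CohortModel(),
) -> pd.DataFrame:
    """Two-arm cohort table with the seven adjustment covariates."""
    if min(n_per_arm) < 1:
        raise ValueError("both arm sizes must be >= 1")
    rng = component_rng(seed, "cohort")
    arms = ("licofelone", "naproxen")
    rows = []
    idx = 0
    for a, (arm, n) in enumerate(zip(arms, n_per_arm)):
        ages = np.clip(rng.normal(model.age_mean[a], model.age_sd[a], n), 18, None)
        bmis = np.clip(rng.normal(model.bmi_mean[a], model.bmi_sd[a], n), 15, None)
        female = rng.random(n) < model.female_frac[a]
        flags = rng.random((n, 3)) < model.comorbidity_p
        for i in range(n):
            idx += 1
            rows.append(
                {
                    "subject_id": f"S{idx:03d}",
                    "age": float(ages[i]),
                    "sex": "female" if female[i] else "male",
                    "bmi": float(bmis[i]),
                    "diabetes": bool(flags[i, 0]),
                    "hypertension": bool(flags[i, 1]),
                    "dyslipidemia": bool(flags[i, 2]),
                    "treatment": arm,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Outcomes (cartilage volumes with planted ratio effect)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectSpec:
    """Planted association between one metabolite ratio and volume change.

    ``beta`` is the percent cartilage-volume change at 24 months per unit of
    the Z-score ratio; ``residual_sd`` the percent-scale noise SD around the
    linear predictor.  The default residual SD (3.6%) is calibrated so the
    generated total lateral-change SD reproduces the cohort's ≈4.16%
    (residual plus ratio-term plus small covariate contributions).
    """

    numerator_id: str = "lysoPC a C18:2"
    denominator_id: str = "PC ae C44:3"
    beta: float = -0.21
    compartment: str = "lateral"
    residual_sd: float = 3.6

    def __post_init__(self) -> None:
        if self.numerator_id == self.denominator_id:
            raise ValueError("numerator and denominator must differ")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.compartment not in ("lateral", "medial"):
            raise ValueError("compartment must be 'lateral' or 'medial'")


@dataclass(frozen=True)
class OutcomeModel:
    """Compartment/arm baseline-volume moments and percent-change predictor.

    Intercepts are the naproxen-arm means; ``treatment_effect`` is the
    licofelone minus naproxen difference, so the arm means of the generated
    percent changes match the cohort's printed values.  Covariate effects
    default to small nonzero values so adjusted and unadjusted fits differ.
    """

    baseline_mean: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("lateral", "licofelone"): 6095.5,
            ("lateral", "naproxen"): 6364.1,
            ("medial", "licofelone"): 5523.0,
            ("medial", "naproxen"): 5690.0,
        }
    )
    baseline_sd: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("lateral", "licofelone"): 1594.7,
            ("lateral", "naproxen"): 1822.0,
            ("medial", "licofelone"): 1503.3,
            ("medial", "naproxen"): 1640.0,
        }
    )
    intercept: Mapping[str, float] = field(
        default_factory=lambda: {"lateral": -6.40, "medial": -8.25}
    )
    treatment_effect: Mapping[str, float] = field(
        default_factory=lambda: {"lateral": 1.70, "medial": 0.67}
    )
    age_effect: float = -0.03  # % change per year, centered at 61
    female_effect: float = 0.30
    bmi_effect: float = -0.05  # % change per kg/m², centered at 31.7
    diabetes_effect: float = -0.20
    hypertension_effect: float = -0.10
    dyslipidemia_effect: float = -0.10


def planted_ratio(
    matrix: ConcentrationMatrix, numerator_id: str, denominator_id: str
) -> pd.Series:
    """Ratio of Z-scores for one metabolite pair, as the screen computes it.

    Masked/missing cells are mean-imputed per metabolite and the columns
    Z-scored (sample SD) before division, mirroring the analysis chain so
    that planted-effect recovery is well posed.
    """
    out = {}
    for met in (numerator_id, denominator_id):
        if met not in matrix.values.columns:
            raise ValueError(f"effect metabolite {met!r} absent from matrix")
        col = matrix.values[met].copy()
        bad = matrix.masked_or_missing()[met]
        obs = col[~bad]
        if obs.empty:
            raise ValueError(f"effect metabolite {met!r} has no observed values")
        col[bad] = obs.mean()
        out[met] = (col - col.mean()) / col.std(ddof=1)
    return out[numerator_id] / out[denominator_id]


def simulate_outcomes(
    concentrations: ConcentrationMatrix,
    cohort: pd.DataFrame,
    effect: EffectSpec = EffectSpec(),
    seed: int = 1,
    model: OutcomeModel = OutcomeModel(),
) -> pd.DataFrame:
    """Volume table whose percent change embeds the planted ratio effect.

    The follow-up volume is derived from the simulated percent change, so
    the percentage-change formula recovers the linear predictor exactly.
    Because the ratio of Z-scores is heavy-tailed, the linear predictor can
    rarely fall at or below −100%, which no positive follow-up volume can
    represent; such (subject, compartment) rows are omitted from the table
    (a lost follow-up measurement) rather than truncated, so every emitted
    row satisfies the linear model exactly.
    """
    rng = component_rng(seed, "outcomes")
    cohort = cohort.set_index("subject_id").loc[concentrations.subjects]
    ratio = planted_ratio(
        concentrations, effect.numerator_id, effect.denominator_id
    )

    lin_cov = (
        model.age_effect * (cohort["age"] - 61.0)
        + model.female_effect * (cohort["sex"] == "female")
        + model.bmi_effect * (cohort["bmi"] - 31.7)
        + model.diabetes_effect * cohort["diabetes"].astype(float)
        + model.hypertension_effect * cohort["hypertension"].astype(float)
        + model.dyslipidemia_effect * cohort["dyslipidemia"].astype(float)
    )
    is_lico = (cohort["treatment"] == "licofelone").astype(float)

    rows = []
    for comp in ("lateral", "medial"):
        mean = np.array(
            [model.baseline_mean[(comp, t)] for t in cohort["treatment"]]
        )
        sd = np.array(
            [model.baseline_sd[(comp, t)] for t in cohort["treatment"]]
        )
        v0 = np.clip(rng.normal(mean, sd), 500.0, None)
        pct = (
            model.intercept[comp]
            + model.treatment_effect[comp] * is_lico.to_numpy()
            + lin_cov.to_numpy()
            + rng.normal(0.0, effect.residual_sd, len(cohort))
        )
        if comp == effect.compartment:
            pct = pct + effect.beta * ratio.to_numpy()
        representable = pct > -99.9  # follow-up volume must stay positive
        v24 = v0 * (1.0 + pct / 100.0)
        for sid, b, f, ok in zip(cohort.index, v0, v24, representable):
            if not ok:
                continue
            rows.append(
                {
                    "subject_id": sid,
                    "compartment": comp,
                    "volume_baseline": float(b),
                    "volume_24m": float(f),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Biomarkers
# ---------------------------------------------------------------------------

#: (mean, sd, target Pearson r with the planted ratio) per marker/timepoint.
_BIOMARKER_TARGETS: Mapping[tuple[str, str], tuple[float, float, float]] = {
    ("COMP", "baseline"): (10.0, 2.0, 0.32),
    ("COMP", "followup"): (10.0, 2.0, 0.32),
    ("MMP1", "baseline"): (5.0, 1.5, 0.10),
    ("MMP1", "followup"): (5.0, 1.5, 0.26),
    ("LCAT", "baseline"): (8.0, 2.0, -0.10),
}


def simulate_biomarkers(
    concentrations: ConcentrationMatrix,
    effect: EffectSpec = EffectSpec(),
    seed: int = 1,
    targets: Mapping[tuple[str, str], tuple[float, float, float]] = _BIOMARKER_TARGETS,
) -> pd.DataFrame:
    """Serum biomarker table correlated with the planted ratio.

    Each marker value is ``mean + sd·(r·ratioZ + √(1−r²)·noise)`` with the
    ratio standardized in sample, so the sample Pearson correlation with the
    ratio concentrates near the target ``r``.
    """
    rng = component_rng(seed, "biomarkers")
    ratio = planted_ratio(
        concentrations, effect.numerator_id, effect.denominator_id
    )
    rz = (ratio - ratio.mean()) / ratio.std(ddof=1)
    rows = []
    for (marker, timepoint), (mean, sd, r) in targets.items():
        noise = rng.standard_normal(len(rz))
        noise = (noise - noise.mean()) / noise.std(ddof=1)
        vals = mean + sd * (r * rz.to_numpy() + np.sqrt(1 - r**2) * noise)
        vals = np.clip(vals, 0.05, None)
        for sid, v in zip(rz.index, vals):
            rows.append(
                {
                    "subject_id": sid,
                    "marker": marker,
                    "timepoint": timepoint,
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrEffectSpec:
    """Planted qPCR group effect and cytokine correlation targets.

    ``group_fold_change`` is the OA/control fold on the relative
    quantification of the target gene (1.85 ≙ +85% expression).
    ``cytokine_correlations`` maps each cytokine to its target Pearson r
    with the target gene on the log-RQ scale.
    """

    gene: str = "PLA2G5"
    group_fold_change: float = 1.85
    cytokine_correlations: Mapping[str, float] = field(
        default_factory=lambda: {"IL6": 0.63, "TNFa": 0.57, "IL1b": 0.27}
    )

    def __post_init__(self) -> None:
        if self.group_fold_change <= 0:
            raise ValueError("group_fold_change must be > 0")
        for g, r in self.cytokine_correlations.items():
            if not -1.0 < r < 1.0:
                raise ValueError(f"|r| must be < 1 for {g}")


#: Default cytokine–cytokine log-RQ correlations.
DEFAULT_CYTOKINE_CORR: Mapping[frozenset, float] = {
    frozenset(("IL6", "TNFa")): 0.78,
    frozenset(("IL6", "IL1b")): 0.45,
    frozenset(("TNFa", "IL1b")): 0.45,
}

REFERENCE_GENE = "GAPDH"
_CT_REPLICATE_SD = 0.15  # cycles, per-replicate technical noise
_LOG2RQ_SD = 0.9  # cycles, between-sample biological spread
_CYTOKINE_OA_SHIFT = np.log2(1.3)  # mild cytokine elevation in OA
_BASE_DELTA_CT = {"PLA2G5": 8.0, "IL6": 7.0, "TNFa": 6.5, "IL1b": 7.5}


def simulate_qpcr(
    effect: QpcrEffectSpec = QpcrEffectSpec(),
    n_oa: int = 32,
    n_control: int = 16,
    seed: int = 1,
    tissue: str = "cartilage",
) -> pd.DataFrame:
    """Triplicate Ct plate for the target gene, three cytokines and GAPDH.

    Per sample, a latent log2-RQ vector for (target, IL-6, TNF-α, IL-1β) is
    drawn from a multivariate normal whose correlation matrix hits the
    specified targets (nearest-positive-definite corrected if necessary);
    the target gene's latent mean is shifted by log2(fold) in the OA group.
    Ct values are reference Ct + ΔCt + replicate noise.  The first control
    sample is the calibrator.
    """
    if n_oa < 2 or n_control < 2:
        raise ValueError("need at least 2 samples per group")
    rng = component_rng(seed, f"qpcr-{tissue}")

    genes = [effect.gene] + sorted(effect.cytokine_correlations)
    g = len(genes)
    corr = np.eye(g)
    for i in range(g):
        for j in range(i + 1, g):
            a, b = genes[i], genes[j]
            if a == effect.gene:
                r = effect.cytokine_correlations[b]
            else:
                r = DEFAULT_CYTOKINE_CORR.get(frozenset((a, b)), 0.0)
            corr[i, j] = corr[j, i] = r
    if np.linalg.eigvalsh(corr).min() <= 1e-10:
        corr = corr_nearest(corr, threshold=1e-8)
    chol = np.linalg.cholesky(corr)

    n = n_oa + n_control
    latent = rng.standard_normal((n, g)) @ chol.T  # unit-variance, corr target
    log2rq = _LOG2RQ_SD * latent
    is_oa = np.array([True] * n_oa + [False] * n_control)
    log2rq[is_oa, 0] += np.log2(effect.group_fold_change)
    log2rq[is_oa, 1:] += _CYTOKINE_OA_SHIFT

    sample_ids = [f"OA{i + 1:02d}" for i in range(n_oa)] + [
        f"CT{i + 1:02d}" for i in range(n_control)
    ]
    calibrator = f"CT01"
    ref_ct = rng.normal(18.0, 0.7, n)
    rows = []
    for s in range(n):
        group = "OA" if is_oa[s] else "control"
        reps = ref_ct[s] + rng.normal(0.0, _CT_REPLICATE_SD, 3)
        rows.append(
            {
                "sample_id": sample_ids[s],
                "gene": REFERENCE_GENE,
                "ct1": reps[0],
                "ct2": reps[1],
                "ct3": reps[2],
                "group": group,
                "tissue": tissue,
                "is_calibrator": sample_ids[s] == calibrator,
            }
        )
        for gi, gene in enumerate(genes):
            delta = _BASE_DELTA_CT.get(gene, 7.0) - log2rq[s, gi]
            reps = ref_ct[s] + delta + rng.normal(0.0, _CT_REPLICATE_SD, 3)
            rows.append(
                {
                    "sample_id": sample_ids[s],
                    "gene": gene,
                    "ct1": reps[0],
                    "ct2": reps[1],
                    "ct3": reps[2],
                    "group": group,
                    "tissue": tissue,
                    "is_calibrator": sample_ids[s] == calibrator,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------


def simulate_bundle(
    seed: int = 1,
    n_per_arm: tuple[int, int] = (69, 70),
    effect: EffectSpec = EffectSpec(),
    qpcr_effect: QpcrEffectSpec = QpcrEffectSpec(),
) -> dict:
    """Generate the complete synthetic study-input bundle.

    Returns a dict with keys ``panel``, ``concentrations``, ``cohort``,
    ``volumes``, ``biomarkers`` and ``qpcr``.
    """
    panel = make_default_panel(seed)
    n = int(sum(n_per_arm))
    conc = simulate_concentrations(panel, n, seed)
    cohort = simulate_cohort(n_per_arm, seed)
    volumes = simulate_outcomes(conc, cohort, effect, seed)
    markers = simulate_biomarkers(conc, effect, seed)
    qpcr = simulate_qpcr(qpcr_effect, seed=seed)
    return {
        "panel": panel,
        "concentrations": conc,
        "cohort": cohort,
        "volumes": volumes,
        "biomarkers": markers,
        "qpcr": qpcr,
    }
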