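"""End-to-end pipeline orchestration.

Runs simulate/load → QC → progression → ratio screen → biomarker
correlations → qPCR quantification, writing every stage output plus a run
manifest into an output directory.  All randomness flows from the single
master seed in the run configuration, so a run is reproducible from its
manifest alone (bit-identical CSV text).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io_tables import (
    ConcentrationMatrix,
    RunConfig,
    read_biomarkers,
    read_cohort,
    read_concentrations,
    read_panel,
    read_qpcr_plate,
    read_volumes,
    write_association_table,
    write_biomarkers,
    write_cohort,
    write_concentrations,
    write_panel,
    write_qpcr_plate,
    write_volumes,
)
from .biomarkers import adjusted_correlation, extreme_decile_compare, pearson_correlation
from .expression import (
    compare_expression_groups,
    cytokine_correlation_matrix,
    livak_rq,
    multivariable_cytokine_model,
    rq_wide,
)
from .outcomes import build_progression_table
from .preprocessing import filter_by_lod, impute_missing_mean, pca_batch_check
from .ratio_screen import build_pairwise_ratios, run_screen, zscore_standardize
from .synthetic_data import simulate_bundle

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "summarize_cohort", "write_bundle", "load_bundle"]

_CYTOKINES = ("IL6", "TNFa", "IL1b")


def write_bundle(bundle: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated input bundle as the CSV contract files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel": out_dir / "panel.csv",
        "concentrations": out_dir / "concentrations.csv",
        "concentrations_mask": out_dir / "concentrations_mask.csv",
        "cohort": out_dir / "cohort.csv",
        "volumes": out_dir / "volumes.csv",
        "biomarkers": out_dir / "biomarkers.csv",
        "qpcr": out_dir / "qpcr.csv",
    }
    write_panel(bundle["panel"], paths["panel"])
    write_concentrations(
        bundle["concentrations"],
        paths["concentrations"],
        paths["concentrations_mask"],
    )
    write_cohort(bundle["cohort"], paths["cohort"])
    write_volumes(bundle["volumes"], paths["volumes"])
    write_biomarkers(bundle["biomarkers"], paths["biomarkers"])
    write_qpcr_plate(bundle["qpcr"], paths["qpcr"])
    return paths


def load_bundle(input_dir: str | Path) -> dict:
    """Read an input bundle from a directory of contract CSVs."""
    input_dir = Path(input_dir)
    panel = read_panel(input_dir / "panel.csv")
    mask_path = input_dir / "concentrations_mask.csv"
    conc = read_concentrations(
        input_dir / "concentrations.csv",
        panel,
        mask_path if mask_path.exists() else None,
    )
    bundle = {
        "panel": panel,
        "concentrations": conc,
        "cohort": read_cohort(input_dir / "cohort.csv"),
        "volumes": read_volumes(input_dir / "volumes.csv"),
    }
    for key, reader in (("biomarkers", read_biomarkers), ("qpcr", read_qpcr_plate)):
        path = input_dir / f"{key}.csv"
        if path.exists():
            bundle[key] = reader(path)
    return bundle


def summarize_cohort(cohort: pd.DataFrame, volumes: pd.DataFrame) -> pd.DataFrame:
    """Per-arm descriptive summary: mean ± SD rows, percent female, arm sizes."""
    if cohort.empty or volumes.empty:
        raise ValueError("cohort and volume tables must be non-empty")
    arms = sorted(cohort["treatment"].unique())
    known = {"licofelone", "naproxen"}
    unknown = set(arms) - known
    if unknown:
        raise ValueError(f"unknown treatment arm {sorted(unknown)[0]!r}")
    prog = build_progression_table(volumes)
    rows: dict[str, dict] = {}

    def put(var, arm, mean, sd):
        rows.setdefault(var, {})[arm] = f"{mean:.2f} +/- {sd:.2f}"

    for arm in arms:
        ids = cohort.loc[cohort["treatment"] == arm, "subject_id"]
        sub = cohort[cohort["treatment"] == arm]
        rows.setdefault("n", {})[arm] = str(len(sub))
        rows.setdefault("female_pct", {})[arm] = (
            f"{(sub['sex'] == 'female').mean() * 100:.0f}%"
        )
        put("age", arm, sub["age"].mean(), sub["age"].std(ddof=1) if len(sub) > 1 else 0.0)
        put("bmi", arm, sub["bmi"].mean(), sub["bmi"].std(ddof=1) if len(sub) > 1 else 0.0)
        for comp in ("lateral", "medial"):
            v = volumes[
                volumes["subject_id"].isin(ids) & (volumes["compartment"] == comp)
            ]
            c = prog[
                prog["subject_id"].isin(ids) & (prog["compartment"] == comp)
            ]
            if not v.empty:
                put(
                    f"{comp}_baseline_volume", arm,
                    v["volume_baseline"].mean(),
                    v["volume_baseline"].std(ddof=1) if len(v) > 1 else 0.0,
                )
                put(
                    f"{comp}_pct_change", arm,
                    c["pct_change"].mean(),
                    c["pct_change"].std(ddof=1) if len(c) > 1 else 0.0,
                )
    out = pd.DataFrame(rows).T
    out.index.name = "variable"
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    input_dir: str | Path | None = None,
    simulate: bool = False,
    compartments: tuple[str, ...] = ("lateral", "medial"),
    top_k: int = 10,
) -> dict:
    """Execute the full analysis and write all outputs.

    Either ``simulate=True`` (generate the synthetic bundle from the config
    seed) or ``input_dir`` pointing at contract CSVs.  Returns a summary
    dict (also serialized as ``manifest.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        report_lines.append(msg)

    if simulate:
        bundle = simulate_bundle(config.seed)
        input_paths = write_bundle(bundle, out_dir / "inputs")
        log(f"stage=simulate seed={config.seed} subjects={len(bundle['cohort'])}")
    elif input_dir is not None:
        bundle = load_bundle(input_dir)
        input_paths = {
            k: Path(input_dir) / f"{k}.csv"
            for k in ("panel", "concentrations", "cohort", "volumes")
        }
        log(f"stage=load input_dir={input_dir}")
    else:
        raise ValueError("either simulate=True or input_dir is required")

    conc: ConcentrationMatrix = bundle["concentrations"]
    cohort = bundle["cohort"]
    missing_cov = [c for c in config.covariates if c not in cohort.columns]
    if missing_cov:
        raise ValueError(f"covariate column {missing_cov[0]!r} missing from cohort")

    # --- QC ------------------------------------------------------------
    filtered, qc = filter_by_lod(conc, config.lod_missing_threshold)
    imputed, n_imputed = impute_missing_mean(filtered)
    qc.imputed_cell_count = n_imputed
    log(
        f"stage=qc metabolites_in={qc.input_count} removed={len(qc.removed_metabolites)} "
        f"retained={qc.retained_count} imputed_cells={n_imputed}"
    )
    batch_p = None
    counts = imputed.batch.value_counts()
    if len(counts) >= 2 and (counts >= 3).all():
        batch_report = pca_batch_check(imputed)
        batch_p = batch_report.batch_separation_p
        log(
            f"stage=batch_check p={batch_p:.4g} "
            f"flag={'yes' if batch_report.batch_flag else 'no'}"
        )
    pd.DataFrame(
        qc.removed_metabolites, columns=["metabolite_id", "masked_fraction"]
    ).to_csv(out_dir / "qc_removed.csv", index=False)

    # --- outcomes and cohort summary ------------------------------------
    progression = build_progression_table(bundle["volumes"])
    summary = summarize_cohort(cohort, bundle["volumes"])
    summary.to_csv(out_dir / "cohort_summary.csv")
    log("stage=progression rows=%d" % len(progression))

    # --- ratio screen ----------------------------------------------------
    z = zscore_standardize(imputed)
    ratios = build_pairwise_ratios(
        z, mode=config.pair_mode, guard_epsilon=config.denominator_guard_epsilon
    )
    screens: dict[str, pd.DataFrame] = {}
    thresholds: dict[str, float] = {}
    n_tests: dict[str, int] = {}
    for comp in compartments:
        table, thr = run_screen(ratios, progression, comp, cohort, config)
        screens[comp] = table
        thresholds[comp] = thr.threshold
        n_tests[comp] = thr.n_tests
        write_association_table(table, out_dir / f"screen_{comp}.csv")
        n_sig = int(table["significant"].sum())
        log(
            f"stage=screen compartment={comp} pairs_fitted={thr.n_tests} "
            f"threshold={thr.threshold:.3g} significant={n_sig} "
            f"top_pair={table['pair_id'].iloc[0]} top_p={table['p_unadj'].iloc[0]:.3g}"
        )

    # --- biomarker correlations -----------------------------------------
    biomarker_rows = []
    lead_pair = screens[compartments[0]].iloc[0]
    if "biomarkers" in bundle:
        pair_ratio = (
            z[lead_pair["numerator"]] / z[lead_pair["denominator"]]
        )
        markers = bundle["biomarkers"]
        cov_cols = [c for c in config.covariates]
        for (marker, timepoint), grp in markers.groupby(["marker", "timepoint"]):
            vals = grp.set_index("subject_id")["value"].reindex(pair_ratio.index)
            if marker == "LCAT":
                cmp_res = extreme_decile_compare(pair_ratio, vals.dropna())
                log(
                    f"stage=biomarker marker=LCAT bottom_n={cmp_res.n_bottom} "
                    f"top_n={cmp_res.n_top} p={cmp_res.p:.3g}"
                )
                biomarker_rows.append(
                    {
                        "marker": marker, "timepoint": timepoint,
                        "analysis": "extreme_decile_t", "estimate": cmp_res.t,
                        "p": cmp_res.p, "n": cmp_res.n_bottom + cmp_res.n_top,
                    }
                )
                continue
            ok = vals.notna()
            unadj = pearson_correlation(pair_ratio[ok], vals[ok])
            adj = adjusted_correlation(
                pair_ratio[ok],
                vals[ok],
                cohort.set_index("subject_id").loc[pair_ratio.index[ok]],
                covariate_names=cov_cols,
            )
            log(
                f"stage=biomarker marker={marker} timepoint={timepoint} "
                f"r={unadj.r:.2f} p={unadj.p:.3g} r_adj={adj.r:.2f}"
            )
            for res, kind in ((unadj, "pearson"), (adj, "pearson_adjusted")):
                biomarker_rows.append(
                    {
                        "marker": marker, "timepoint": timepoint,
                        "analysis": kind, "estimate": res.r, "p": res.p, "n": res.n,
                    }
                )
        pd.DataFrame(biomarker_rows).to_csv(out_dir / "biomarker_results.csv", index=False)

    # --- qPCR ------------------------------------------------------------
    qpcr_summary = {}
    if "qpcr" in bundle:
        plate = bundle["qpcr"]
        target = "PLA2G5"
        rq = livak_rq(plate, target)
        rq.to_csv(out_dir / "qpcr_rq.csv", index=False)
        grp = compare_expression_groups(rq)
        log(
            f"stage=qpcr gene={target} percent_increase={grp.percent_increase:.1f} "
            f"p={grp.p:.3g}"
        )
        wide = rq_wide(plate, (target, *_CYTOKINES))
        corr = cytokine_correlation_matrix(wide)
        model = multivariable_cytokine_model(wide)
        model.to_csv(out_dir / "qpcr_cytokine_model.csv")
        pd.DataFrame(
            [
                {"gene_a": a, "gene_b": b, "r": res.r, "p": res.p, "n": res.n}
                for (a, b), res in corr.items()
            ]
        ).to_csv(out_dir / "qpcr_correlations.csv", index=False)
        qpcr_summary = {
            "percent_increase": grp.percent_increase,
            "p": grp.p,
            "n_oa": grp.n_oa,
            "n_control": grp.n_control,
        }

    manifest = {
        "version": __version__,
        "config": {
            "lod_missing_threshold": config.lod_missing_threshold,
            "alpha": config.alpha,
            "pair_mode": config.pair_mode,
            "covariates": list(config.covariates),
            "seed": config.seed,
            "denominator_guard_epsilon": config.denominator_guard_epsilon,
            "n_tests_override": config.n_tests_override,
        },
        "input_digests": {k: _sha256(p) for k, p in input_paths.items() if p.exists()},
        "qc": {
            "metabolites_in": qc.input_count,
            "removed": len(qc.removed_metabolites),
            "retained": qc.retained_count,
            "imputed_cells": n_imputed,
            "batch_separation_p": batch_p,
        },
        "screen": {
            comp: {
                "n_tests": n_tests[comp],
                "threshold": thresholds[comp],
                "n_significant": int(screens[comp]["significant"].sum()),
                "top_pair": screens[comp]["pair_id"].iloc[0],
            }
            for comp in compartments
        },
        "qpcr": qpcr_summary,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )

    # --- report ----------------------------------------------------------
    lines = ["ratio screen run report", "=" * 40, ""]
    lines.append("Cohort summary (mean +/- SD):")
    lines.append(summary.to_string())
    lines.append("")
    for comp in compartments:
        thr = thresholds[comp]
        lines.append(
            f"Top {top_k} ratios, {comp} compartment "
            f"(threshold {thr:.3g}, {n_tests[comp]} tests):"
        )
        head = screens[comp].head(top_k)[
            ["pair_id", "beta_unadj", "ci_low_unadj", "ci_high_unadj",
             "p_unadj", "beta_adj", "p_adj", "significant"]
        ]
        lines.append(head.to_string(index=False))
        lines.append("")
    lines.append("Stage log:")
    lines.extend(report_lines)
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return manifest
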