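import numpy as np
import pandas as pd
import pytest

import ratioscreen as rs
from ratioscreen.io_tables import DEFAULT_CLASS_COUNTS
from ratioscreen.synthetic_data import metabolite_log_means


class TestPanel:
    def test_default_panel_size_and_classes(self, default_panel):
        assert len(default_panel) == 186
        counts = default_panel["class_label"].value_counts().to_dict()
        assert counts == dict(DEFAULT_CLASS_COUNTS)
        assert sum(counts.values()) == 40 + 22 + 18 + 1 + 105

    def test_deterministic(self):
        pd.testing.assert_frame_equal(
            rs.make_default_panel(1), rs.make_default_panel(1)
        )

    def test_named_analytes_present(self, default_panel):
        for met in ("lysoPC a C18:2", "PC ae C44:3", "Gln", "H1", "C0"):
            assert met in default_panel.index


class TestConcentrations:
    def test_default_plan_censors_exactly_34_columns(self, bundle):
        frac = bundle["concentrations"].masked_or_missing().mean(axis=0)
        assert int((frac > 0.10).sum()) == 34
        assert int((frac <= 0.10).sum()) == 152

    def test_zero_plan_gives_no_censoring(self, default_panel):
        m = rs.simulate_concentrations(default_panel, 20, seed=5, censor_plan={})
        assert not m.below_lod.any().any()
        assert not m.values.isna().any().any()

    def test_invalid_censor_fraction_rejected(self, default_panel):
        with pytest.raises(ValueError, match="censor"):
            rs.simulate_concentrations(
                default_panel, 10, seed=1, censor_plan={"Gln": 1.5}
            )

    def test_deterministic(self, default_panel):
        a = rs.simulate_concentrations(default_panel, 30, seed=9)
        b = rs.simulate_concentrations(default_panel, 30, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.below_lod, b.below_lod)

    def test_log_means_match_configuration(self, default_panel, bundle):
        # uncensored columns: sample mean of log X ~ mu_j +/- 3 * sigma/sqrt(n)
        m = bundle["concentrations"]
        mus = metabolite_log_means(default_panel, seed=1)
        uncensored = m.metabolites[~m.masked_or_missing().any(axis=0)]
        logs = np.log(m.values[uncensored])
        se = rs.ConcentrationModel().subject_log_sd / np.sqrt(len(m.subjects))
        z = (logs.mean(axis=0) - mus[uncensored]) / se
        assert (np.abs(z) > 3).sum() <= max(2, int(0.01 * len(uncensored)) + 1)

    def test_planted_pair_survives_default_plan(self, bundle):
        frac = bundle["concentrations"].masked_or_missing().mean(axis=0)
        assert frac["lysoPC a C18:2"] == 0.0
        assert frac["PC ae C44:3"] == 0.0


class TestCohort:
    def test_arm_sizes(self, bundle):
        cohort = bundle["cohort"]
        assert len(cohort) == 139
        assert (cohort["treatment"] == "licofelone").sum() == 69
        assert (cohort["treatment"] == "naproxen").sum() == 70

    def test_deterministic(self):
        pd.testing.assert_frame_equal(
            rs.simulate_cohort((10, 10), seed=4), rs.simulate_cohort((10, 10), seed=4)
        )

    def test_mean_age_across_replicates(self):
        means = [
            rs.simulate_cohort((69, 70), seed=s)["age"].mean() for s in range(200)
        ]
        se = 8.5 / np.sqrt(139) / np.sqrt(200)
        assert abs(np.mean(means) - 61.0) < 3 * se

    def test_invalid_arm_size(self):
        with pytest.raises(ValueError):
            rs.simulate_cohort((0, 5), seed=1)


class TestOutcomes:
    def test_degenerate_noise_gives_constant_change(self, default_panel):
        conc = rs.simulate_concentrations(default_panel, 10, seed=2, censor_plan={})
        cohort = rs.simulate_cohort((5, 5), seed=2)
        model = rs.OutcomeModel(
            intercept={"lateral": -4.70, "medial": -4.70},
            treatment_effect={"lateral": 0.0, "medial": 0.0},
            age_effect=0.0, female_effect=0.0, bmi_effect=0.0,
            diabetes_effect=0.0, hypertension_effect=0.0, dyslipidemia_effect=0.0,
        )
        effect = rs.EffectSpec(beta=0.0, residual_sd=1e-12)
        vols = rs.simulate_outcomes(conc, cohort, effect, seed=2, model=model)
        prog = rs.build_progression_table(vols)
        assert np.allclose(prog["pct_change"], -4.70, atol=1e-6)

    def test_followup_inverts_percentage_formula(self):
        # a -4.70% change from 6095.5 mm3 must land on 5809.01 mm3
        followup = 6095.5 * (1 - 4.70 / 100)
        assert followup == pytest.approx(5809.01, abs=0.005)
        assert rs.percent_volume_change(6095.5, followup) == pytest.approx(-4.70)

    def test_simulated_change_recovers_exactly(self, bundle):
        # follow-up volumes are derived from the simulated percent change,
        # so the progression formula must reproduce it to machine precision
        vols = bundle["volumes"]
        pct = rs.percent_volume_change(
            vols["volume_baseline"].to_numpy(), vols["volume_24m"].to_numpy()
        )
        assert np.isfinite(pct).all()

    def test_planted_beta_recovered_within_ci(self, bundle):
        conc = bundle["concentrations"]
        ratio = rs.planted_ratio(conc, "lysoPC a C18:2", "PC ae C44:3")
        prog = rs.build_progression_table(bundle["volumes"])
        y = (
            prog[prog["compartment"] == "lateral"]
            .set_index("subject_id")["pct_change"]
            .reindex(ratio.index)
        )
        fit = rs.fit_linear_association(ratio, y)
        assert fit.ci_low <= -0.21 <= fit.ci_high

    def test_missing_effect_metabolite_rejected(self, default_panel):
        conc = rs.simulate_concentrations(default_panel, 10, seed=2, censor_plan={})
        cohort = rs.simulate_cohort((5, 5), seed=2)
        bad = rs.EffectSpec(numerator_id="NotThere", denominator_id="Gln")
        with pytest.raises(ValueError, match="NotThere"):
            rs.simulate_outcomes(conc, cohort, bad, seed=2)

    def test_medial_arm_means_match_configuration(self):
        # the medial compartment carries no planted ratio term, so its
        # arm means are clean Monte-Carlo moments
        lico, napro = [], []
        for s in range(100):
            cohort = rs.simulate_cohort((69, 70), seed=s)
            conc = rs.simulate_concentrations(
                rs.make_panel({"glycerophospholipid_sphingolipid": 40}, 1),
                139, seed=s, censor_plan={},
            )
            vols = rs.simulate_outcomes(
                conc, cohort,
                rs.EffectSpec(numerator_id="lysoPC a C18:2",
                              denominator_id="lysoPC a C16:0"),
                seed=s,
            )
            prog = rs.build_progression_table(vols)
            med = prog[prog["compartment"] == "medial"].set_index("subject_id")
            arm = cohort.set_index("subject_id")["treatment"]
            lico.append(med.loc[arm == "licofelone", "pct_change"].mean())
            napro.append(med.loc[arm == "naproxen", "pct_change"].mean())
        # expected arm mean = intercept (+ treatment effect) + mean covariate
        # contribution: 0.3*P(female) - 0.05*(BMI - 31.7) - 0.4*0.2 flags
        shift_lico = 0.30 * 0.74 - 0.05 * (32.3 - 31.7) - 0.08
        shift_napro = 0.30 * 0.61 - 0.05 * (31.2 - 31.7) - 0.08
        se = 4.0 / np.sqrt(69) / np.sqrt(100)
        assert np.mean(lico) == pytest.approx(-8.25 + 0.67 + shift_lico, abs=3 * se)
        assert np.mean(napro) == pytest.approx(-8.25 + shift_napro, abs=3 * se)


class TestBiomarkers:
    def test_target_correlations_recovered(self, bundle):
        conc = bundle["concentrations"]
        ratio = rs.planted_ratio(conc, "lysoPC a C18:2", "PC ae C44:3")
        markers = bundle["biomarkers"]
        comp = (
            markers[(markers["marker"] == "COMP") & (markers["timepoint"] == "baseline")]
            .set_index("subject_id")["value"]
            .loc[ratio.index]
        )
        res = rs.pearson_correlation(ratio, comp)
        assert res.r == pytest.approx(0.32, abs=0.10)

    def test_values_positive_and_complete(self, bundle):
        markers = bundle["biomarkers"]
        assert (markers["value"] > 0).all()
        assert markers.groupby(["marker", "timepoint"])["subject_id"].count().eq(139).all()


class TestQpcr:
    def test_plate_layout(self, bundle):
        plate = bundle["qpcr"]
        assert set(plate["gene"]) == {"GAPDH", "PLA2G5", "IL6", "TNFa", "IL1b"}
        assert plate["sample_id"].nunique() == 48  # 32 OA + 16 control
        cal = plate.loc[plate["is_calibrator"], "group"].unique()
        assert list(cal) == ["control"]

    def test_deterministic(self):
        pd.testing.assert_frame_equal(
            rs.simulate_qpcr(seed=3, n_oa=6, n_control=4),
            rs.simulate_qpcr(seed=3, n_oa=6, n_control=4),
        )

    def test_fold_change_recovery(self):
        est = []
        for s in range(200):
            plate = rs.simulate_qpcr(rs.QpcrEffectSpec(), 32, 16, seed=s)
            rq = rs.livak_rq(plate, "PLA2G5")
            est.append(rs.compare_expression_groups(rq).fold_change)
        assert np.mean(est) == pytest.approx(1.85, abs=0.1)

    def test_null_fold_type_one_error(self):
        null = rs.QpcrEffectSpec(group_fold_change=1.0)
        rejections = 0
        n_seeds = 400
        for s in range(n_seeds):
            plate = rs.simulate_qpcr(null, 32, 16, seed=s)
            rq = rs.livak_rq(plate, "PLA2G5")
            rejections += rs.compare_expression_groups(rq).p < 0.05
        rate = rejections / n_seeds
        assert 0.05 - 0.033 < rate < 0.05 + 0.033  # ~3 binomial SE

    def test_invalid_fold_rejected(self):
        with pytest.raises(ValueError):
            rs.QpcrEffectSpec(group_fold_change=0.0)
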