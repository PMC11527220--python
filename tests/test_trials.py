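"""Eligibility, index dates, cohorts, covariates, matching, and Cox estimation."""

import numpy as np
import pandas as pd
import pytest

from netgen.trials import (
    PatientTables,
    TrialSpec,
    apply_eligibility,
    assign_dates,
    build_trial_cohorts,
    estimate_propensity_and_match,
    estimate_treatment_effect,
    extract_covariates,
    standardized_mean_differences,
    MatchedTrial,
)

SPEC = TrialSpec(
    drug="DRUGX",
    outcome_codes=("F03",),
    disease_codes=("G20",),
    exclusion_codes=("G30",),
    comorbidity_codes={"htn": ("I10",)},
    medication_ingredients=("OTHERMED",),
    min_users=1,
)


def _tables(patients, diagnoses, prescriptions):
    return PatientTables(
        patients=pd.DataFrame(patients),
        diagnoses=pd.DataFrame(diagnoses, columns=["id", "icd", "date"]),
        prescriptions=pd.DataFrame(prescriptions, columns=["id", "ingredient", "atc", "date"]),
    )


def _patient(pid, birth="1950-06-15", sex="F", race="white"):
    return {"id": pid, "birth_date": birth, "sex": sex, "race": race}


class TestEligibility:
    def test_age_49_excluded_50_included(self):
        tables = _tables(
            [_patient("P1", birth="1971-01-01"), _patient("P2", birth="1970-01-01")],
            [("P1", "G20", "2020-06-01"), ("P2", "G20", "2020-06-01")],
            [],
        )
        # P1 is 49.4 years old at diagnosis, P2 is 50.4
        eligible = apply_eligibility(tables, SPEC)
        assert list(eligible["id"]) == ["P2"]

    def test_prior_exclusion_diagnosis_excluded(self):
        tables = _tables(
            [_patient("P1")],
            [("P1", "G30", "2018-01-01"), ("P1", "G20", "2020-01-01")],
            [],
        )
        assert apply_eligibility(tables, SPEC).empty

    def test_exclusion_after_disease_is_fine(self):
        tables = _tables(
            [_patient("P1")],
            [("P1", "G20", "2020-01-01"), ("P1", "G30", "2021-01-01")],
            [],
        )
        assert list(apply_eligibility(tables, SPEC)["id"]) == ["P1"]

    def test_missing_birth_date_excluded(self):
        tables = _tables(
            [{"id": "P1", "birth_date": None, "sex": "F", "race": "white"}],
            [("P1", "G20", "2020-01-01")],
            [],
        )
        assert apply_eligibility(tables, SPEC).empty

    def test_ten_patient_hand_walkthrough(self):
        patients, diagnoses = [], []
        for i in range(7):  # seven clean patients
            patients.append(_patient(f"OK{i}"))
            diagnoses.append((f"OK{i}", "G20", "2020-01-01"))
        patients.append(_patient("BAD_AGE", birth="1990-01-01"))
        diagnoses.append(("BAD_AGE", "G20", "2020-01-01"))
        patients.append(_patient("BAD_PRIOR"))
        diagnoses += [("BAD_PRIOR", "G30", "2015-01-01"), ("BAD_PRIOR", "G20", "2020-01-01")]
        patients.append(_patient("NO_DX"))  # never diagnosed
        eligible = apply_eligibility(_tables(patients, diagnoses, []), SPEC)
        assert sorted(eligible["id"]) == [f"OK{i}" for i in range(7)]


class TestAssignDates:
    def _eligible(self, dx_date="2015-07-02"):
        tables = _tables(
            [_patient("P1")],
            [("P1", "G20", dx_date)],
            [("P1", "DRUGX", "C10A", "2015-08-01")],
        )
        return apply_eligibility(tables, SPEC), tables

    def test_initiation_is_182_days_before_diagnosis(self):
        eligible, tables = self._eligible(dx_date="2015-07-02")
        out = assign_dates(eligible, tables, "DRUGX", SPEC)
        assert out.loc[0, "initiation_date"] == pd.Timestamp("2015-01-01")

    def test_index_before_initiation_ineligible(self):
        tables = _tables(
            [_patient("P1")],
            [("P1", "G20", "2020-06-01")],
            [("P1", "DRUGX", "C10A", "2019-01-01")],
        )
        eligible = apply_eligibility(tables, SPEC)
        assert assign_dates(eligible, tables, "DRUGX", SPEC).empty

    def test_outcome_on_index_date_ineligible(self):
        tables = _tables(
            [_patient("P1")],
            [("P1", "G20", "2020-01-01"), ("P1", "F03", "2020-03-01")],
            [("P1", "DRUGX", "C10A", "2020-03-01")],
        )
        eligible = apply_eligibility(tables, SPEC)
        assert assign_dates(eligible, tables, "DRUGX", SPEC).empty

    def test_outcome_after_index_kept(self):
        tables = _tables(
            [_patient("P1")],
            [("P1", "G20", "2020-01-01"), ("P1", "F03", "2020-06-01")],
            [("P1", "DRUGX", "C10A", "2020-03-01")],
        )
        eligible = apply_eligibility(tables, SPEC)
        assert len(assign_dates(eligible, tables, "DRUGX", SPEC)) == 1


class TestCohorts:
    def _catalog_tables(self):
        patients = [_patient(p) for p in ("T1", "T2", "C1", "C2", "B1")]
        diagnoses = [(p, "G20", "2020-01-01") for p in ("T1", "T2", "C1", "C2", "B1")]
        prescriptions = [
            ("T1", "DRUGX", "C10AA01", "2020-03-01"),
            ("T2", "DRUGX", "C10AA01", "2020-04-01"),
            ("C1", "COMP", "C10AA02", "2020-03-01"),   # same ATC-L3 (C10A)
            ("C2", "COMP", "C10AA02", "2020-05-01"),
            ("B1", "DRUGX", "C10AA01", "2020-03-01"),  # exposed to both
            ("B1", "COMP", "C10AA02", "2020-06-01"),
            ("X1", "OTHER", "N02BE01", "2020-03-01"),  # different class entirely
        ]
        return _tables(patients, diagnoses, prescriptions)

    def test_same_atc_l3_defines_controls(self):
        tables = self._catalog_tables()
        eligible = apply_eligibility(tables, SPEC)
        cohorts = build_trial_cohorts(eligible, tables, "DRUGX", SPEC)
        assert sorted(cohorts.controls["id"]) == ["C1", "C2"]

    def test_dual_exposure_counts_as_treated(self):
        tables = self._catalog_tables()
        eligible = apply_eligibility(tables, SPEC)
        cohorts = build_trial_cohorts(eligible, tables, "DRUGX", SPEC)
        assert "B1" in set(cohorts.treated["id"])
        assert "B1" not in set(cohorts.controls["id"])

    def test_rare_drug_skipped(self):
        tables = self._catalog_tables()
        eligible = apply_eligibility(tables, SPEC)
        spec = TrialSpec(**{**SPEC.__dict__, "min_users": 100})
        cohorts = build_trial_cohorts(eligible, tables, "DRUGX", spec)
        assert cohorts.skipped

    def test_absent_drug_raises(self):
        tables = self._catalog_tables()
        eligible = apply_eligibility(tables, SPEC)
        with pytest.raises(ValueError, match="absent"):
            build_trial_cohorts(eligible, tables, "NOSUCH", SPEC)


class TestCovariates:
    def _cohort(self, extra_dx=(), extra_rx=()):
        tables = _tables(
            [_patient("P1", sex="M")],
            [("P1", "G20", "2020-01-01")] + list(extra_dx),
            [("P1", "DRUGX", "C10A", "2020-06-01")] + list(extra_rx),
        )
        eligible = apply_eligibility(tables, SPEC)
        cohort = assign_dates(eligible, tables, "DRUGX", SPEC)
        return extract_covariates(cohort, tables, SPEC)

    def test_no_baseline_events_all_binary_zero(self):
        x = self._cohort()
        assert x.loc["P1", "cm_htn"] == 0 and x.loc["P1", "med_OTHERMED"] == 0

    def test_baseline_comorbidity_flagged(self):
        x = self._cohort(extra_dx=[("P1", "I10", "2020-02-01")])
        assert x.loc["P1", "cm_htn"] == 1

    def test_post_index_comorbidity_ignored(self):
        x = self._cohort(extra_dx=[("P1", "I10", "2020-08-01")])
        assert x.loc["P1", "cm_htn"] == 0

    def test_hand_built_vector(self):
        x = self._cohort(
            extra_dx=[("P1", "I10", "2020-02-01")],
            extra_rx=[("P1", "OTHERMED", "N02B", "2020-03-01")],
        )
        row = x.loc["P1"]
        assert row["cm_htn"] == 1 and row["med_OTHERMED"] == 1 and row["male"] == 1
        assert row["days_to_index"] == pytest.approx(
            (pd.Timestamp("2020-06-01") - (pd.Timestamp("2020-01-01")
                                           - pd.Timedelta(days=182))).days
        )


class TestMatching:
    def test_identical_distributions_balanced(self, rng):
        x = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"),
                         index=[f"P{i}" for i in range(60)])
        trial = estimate_propensity_and_match(x.iloc[:30], x.iloc[30:], seed=0)
        assert trial.balanced and (trial.smd < 0.2).all()

    def test_equal_prevalence_binary_smd_zero(self):
        x1 = pd.DataFrame({"flag": [1, 1, 0, 0]})
        x0 = pd.DataFrame({"flag": [0, 1, 0, 1]})
        smd = standardized_mean_differences(x1, x0)
        assert smd["flag"] == 0

    def test_no_control_reused(self, rng):
        treated = pd.DataFrame(rng.normal(size=(25, 3)), index=[f"T{i}" for i in range(25)])
        controls = pd.DataFrame(rng.normal(size=(60, 3)), index=[f"C{i}" for i in range(60)])
        trial = estimate_propensity_and_match(treated, controls, seed=1)
        assert len(trial.control_ids) == len(set(trial.control_ids))

    def test_shortfall_flagged_when_controls_scarce(self, rng):
        treated = pd.DataFrame(rng.normal(size=(20, 2)), index=[f"T{i}" for i in range(20)])
        controls = pd.DataFrame(rng.normal(size=(5, 2)), index=[f"C{i}" for i in range(5)])
        trial = estimate_propensity_and_match(treated, controls, seed=1, caliper=None)
        assert trial.shortfall == 15 and len(trial.control_ids) == 5

    def test_matching_reduces_confounder_imbalance(self):
        """On a strongly confounded cohort, matching shrinks the confounder SMD."""
        improved = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n_t, n_c = 150, 500
            conf_t = (rng.random(n_t) < 0.7).astype(float)   # prevalent in treated
            conf_c = (rng.random(n_c) < 0.3).astype(float)
            noise_t, noise_c = rng.normal(size=n_t), rng.normal(size=n_c)
            xt = pd.DataFrame({"conf": conf_t, "noise": noise_t},
                              index=[f"T{i}" for i in range(n_t)])
            xc = pd.DataFrame({"conf": conf_c, "noise": noise_c},
                              index=[f"C{i}" for i in range(n_c)])
            pre = standardized_mean_differences(xt, xc)["conf"]
            trial = estimate_propensity_and_match(xt, xc, seed=seed)
            if trial.smd["conf"] < pre:
                improved += 1
        assert improved >= 9  # at least 95%-ish of seeded runs


def _matched_survival_tables(hr_flip=False, n=120, seed=0):
    """Tiny cohort with identical survival in both arms (null effect)."""
    rng = np.random.default_rng(seed)
    patients, diagnoses, prescriptions = [], [], []
    for i in range(n):
        pid = f"P{i:03d}"
        treated = i < n // 2
        patients.append(_patient(pid))
        diagnoses.append((pid, "G20", "2019-01-01"))
        drug = "DRUGX" if treated else "COMP"
        atc = "C10AA01" if treated else "C10AA02"
        prescriptions.append((pid, drug, atc, "2019-06-01"))
        t_event = rng.exponential(700.0)
        t_cens = rng.uniform(100, 1500)
        end = pd.Timestamp("2019-06-01") + pd.Timedelta(days=int(min(t_event, t_cens)) + 1)
        code = "F03" if t_event <= t_cens else "Z00"
        diagnoses.append((pid, code, end))
    return _tables(patients, diagnoses, prescriptions)


class TestTreatmentEffect:
    def test_null_survival_hr_near_one(self):
        tables = _matched_survival_tables()
        eligible = apply_eligibility(tables, SPEC)
        cohorts = build_trial_cohorts(eligible, tables, "DRUGX", SPEC)
        tx = extract_covariates(cohorts.treated, tables, SPEC)
        cx = extract_covariates(cohorts.controls, tables, SPEC)
        trial = estimate_propensity_and_match(tx, cx, seed=0)
        dates = pd.concat([cohorts.treated, cohorts.controls], ignore_index=True)
        est = estimate_treatment_effect(trial, dates, tables, SPEC, n_boot=40, seed=0)
        assert est.ci_lower < 1.0 < est.ci_upper

    def test_zero_events_in_arm_inestimable(self):
        tables = _tables(
            [_patient(f"P{i}") for i in range(8)],
            [(f"P{i}", "G20", "2019-01-01") for i in range(8)]
            + [(f"P{i}", "Z00", "2021-01-01") for i in range(8)],  # nobody has the outcome
            [(f"P{i}", "DRUGX" if i < 4 else "COMP",
              "C10AA01" if i < 4 else "C10AA02", "2019-06-01") for i in range(8)],
        )
        eligible = apply_eligibility(tables, SPEC)
        cohorts = build_trial_cohorts(eligible, tables, "DRUGX", SPEC)
        tx = extract_covariates(cohorts.treated, tables, SPEC)
        cx = extract_covariates(cohorts.controls, tables, SPEC)
        trial = estimate_propensity_and_match(tx, cx, seed=0, caliper=None)
        dates = pd.concat([cohorts.treated, cohorts.controls], ignore_index=True)
        est = estimate_treatment_effect(trial, dates, tables, SPEC, n_boot=10, seed=0)
        assert est.inestimable

    def test_permuted_labels_center_at_null(self):
        """Shuffling who counts as treated yields log-HRs centered near zero."""
        tables = _matched_survival_tables(n=160, seed=3)
        eligible = apply_eligibility(tables, SPEC)
        cohorts = build_trial_cohorts(eligible, tables, "DRUGX", SPEC)
        dates = pd.concat([cohorts.treated, cohorts.controls], ignore_index=True)
        all_ids = list(dates["id"])
        rng = np.random.default_rng(7)
        log_hrs = []
        for _ in range(40):
            perm = rng.permutation(all_ids)
            half = len(perm) // 2
            trial = MatchedTrial(
                treated_ids=list(perm[:half]), control_ids=list(perm[half: 2 * half]),
                propensity=pd.Series(dtype=float), iptw=pd.Series(dtype=float),
                smd=pd.Series(dtype=float), balanced=True, shortfall=0,
            )
            est = estimate_treatment_effect(trial, dates, tables, SPEC, n_boot=0, seed=0)
            if not est.inestimable:
                log_hrs.append(np.log(est.hr))
        assert abs(np.mean(log_hrs)) < 0.15
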