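import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from pgxlos.cohort_synth import (
    Admission,
    BASELINE_COVARIATES,
    GeneratorConfig,
    PatientRecord,
    TrueModel,
    apply_cohort_filters,
    build_design_matrix,
    cohort_table,
    expected_retention,
    filter_patients,
    generate_raw_cohort,
)
from pgxlos.cohort_synth import DesignError
from pgxlos.risk_scoring import MedicationRecord
from pgxlos.ztnb_model import ztnb_truncated_mean


def _patient(pid="P0", enrollment=24, admissions=None, income=60_000.0,
             meds=None):
    start = dt.date(2020, 3, 1)
    if admissions is None:
        admissions = [Admission(start, start + dt.timedelta(days=8),
                                True, False)]
    return PatientRecord(
        patient_id=pid, age=78.0, gender="female", race_ethnicity="white",
        residence="urban", median_income=income, c_snp=False, d_snp=False,
        i_snp=False, hcc_count_category="2-3", raf_score=1.2, copd=False,
        diabetes=True, hyperlipidemia=False, hypertension=True,
        medications=meds or [MedicationRecord(
            "metoprolol", start - dt.timedelta(days=30), None)],
        admissions=admissions, enrollment_months=enrollment,
    )


class TestGenerator:
    def test_same_seed_reproduces_identical_cohort(self, kb):
        cfg = GeneratorConfig(n_patients=200, seed=5)
        a = generate_raw_cohort(cfg, kb)
        b = generate_raw_cohort(cfg, kb)
        assert repr([p.__dict__ for p in a]) == repr([p.__dict__ for p in b])
        c = generate_raw_cohort(GeneratorConfig(n_patients=200, seed=6), kb)
        assert [p.patient_id for p in a] == [p.patient_id for p in c]
        assert [p.age for p in a] != [p.age for p in c]

    def test_invalid_config_reported_field_by_field(self, kb):
        cfg = GeneratorConfig(n_patients=0, death_rate=1.5)
        cfg.pip_dist = {"low": 0.5, "moderate": 0.3, "high": 0.3}
        with pytest.raises(ValueError) as err:
            generate_raw_cohort(cfg, kb)
        msg = str(err.value)
        assert "n_patients" in msg and "death_rate" in msg \
            and "pip_dist" in msg

    def test_marginals_recovered_within_3se(self, kb):
        n = 6025
        cfg = GeneratorConfig(n_patients=n, seed=11)
        raw = generate_raw_cohort(cfg, kb)
        df = pd.DataFrame({
            "gender": [p.gender for p in raw],
            "i_snp": [p.i_snp for p in raw],
            "hcc": [p.hcc_count_category for p in raw],
            "race": [p.race_ethnicity for p in raw],
        })
        def within(share, p):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(share - p) < 3 * se, (share, p)

        within((df.gender == "female").mean(), cfg.female_share)
        within(df.i_snp.mean(), cfg.snp_dist["i_snp"])
        for cat, p in cfg.hcc_dist.items():
            within((df.hcc == cat).mean(), p)
        for cat, p in cfg.race_dist.items():
            within((df.race == cat).mean(), p)

    def test_female_share_within_2se_at_study_scale(self, kb):
        n = 6025
        raw = generate_raw_cohort(GeneratorConfig(n_patients=n, seed=2), kb)
        share = np.mean([p.gender == "female" for p in raw])
        se = math.sqrt(0.61 * 0.39 / n)
        assert abs(share - 0.61) < 2 * se

    def test_scored_exposure_mix_matches_targets(self, kb, small_cohort):
        cfg = GeneratorConfig()
        n = len(small_cohort)
        for cat, p in cfg.pip_dist.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs((small_cohort.pip_category == cat).mean() - p) < 3 * se
        p_flag = 1.0 - cfg.ddi_dist["none"]
        se = math.sqrt(p_flag * (1 - p_flag) / n)
        assert abs(small_cohort.ddi_moderate_plus.mean() - p_flag) < 3 * se

    def test_at_most_one_snp_type(self, kb):
        raw = generate_raw_cohort(GeneratorConfig(n_patients=500, seed=3), kb)
        assert all(p.c_snp + p.d_snp + p.i_snp <= 1 for p in raw)

    def test_los_at_least_one_day(self, kb):
        raw = generate_raw_cohort(GeneratorConfig(n_patients=500, seed=4), kb)
        assert all(a.los_days >= 1 for p in raw for a in p.admissions)

    def test_generative_round_trip_of_truncated_mean(self, kb):
        """With a flat generating model, the retained-LOS mean approaches
        the closed-form zero-truncated NB mean (1% at n=50,000)."""
        tm = TrueModel(intercept=math.log(9.0), theta=1.5,
                       coefficients={})
        cfg = GeneratorConfig(
            n_patients=50_000, seed=8, true_model=tm,
            death_rate=0.0, sub12_enrollment_rate=0.0,
            multiple_admission_rate=0.0, missing_income_rate=0.0,
        )
        raw = generate_raw_cohort(cfg, kb)
        los = np.array([p.admissions[0].los_days for p in raw])
        expected = ztnb_truncated_mean(9.0, 1.5)
        assert los.mean() == pytest.approx(expected, rel=0.01)


class TestFilters:
    def test_hand_enumerated_toy_cohort(self, kb):
        start = dt.date(2020, 2, 1)
        died = _patient("P1", admissions=[Admission(
            start, start + dt.timedelta(days=5), True, True)])
        short = _patient("P2", enrollment=11)
        clean = [_patient(f"C{i}") for i in range(3)]
        kept, tally = filter_patients([died, short] + clean)
        assert [p.patient_id for p in kept] == ["C0", "C1", "C2"]
        assert tally["death"] == 1
        assert tally["enrollment"] == 1
        assert tally["missingness"] == 0

    def test_first_covid_admission_retained(self):
        s1, s2 = dt.date(2020, 2, 1), dt.date(2020, 4, 1)
        p = _patient(admissions=[
            Admission(s2, s2 + dt.timedelta(days=3), True, False),
            Admission(s1, s1 + dt.timedelta(days=7), True, False),
        ])
        kept, tally = filter_patients([p])
        assert kept[0].admissions[0].start_date == s1
        assert tally["later_admissions_dropped"] == 1

    def test_death_judged_on_index_admission_only(self):
        # death during a LATER admission does not exclude the patient
        s1, s2 = dt.date(2020, 2, 1), dt.date(2020, 4, 1)
        p = _patient(admissions=[
            Admission(s1, s1 + dt.timedelta(days=7), True, False),
            Admission(s2, s2 + dt.timedelta(days=3), True, True),
        ])
        kept, _ = filter_patients([p])
        assert len(kept) == 1

    def test_missing_income_excluded_missing_race_kept(self, kb):
        missing_income = _patient("P1", income=float("nan"))
        unknown_race = _patient("P2")
        unknown_race.race_ethnicity = "unknown"
        kept, tally = filter_patients([missing_income, unknown_race])
        assert [p.patient_id for p in kept] == ["P2"]
        assert tally["missingness"] == 1

    def test_empty_input(self):
        kept, tally = filter_patients([])
        assert kept == []
        assert all(v == 0 for v in tally.values())

    def test_idempotence(self, kb):
        raw = generate_raw_cohort(GeneratorConfig(n_patients=400, seed=9), kb)
        once, _ = filter_patients(raw)
        twice, tally = filter_patients(once)
        assert len(twice) == len(once)
        assert tally["death"] == tally["enrollment"] \
            == tally["missingness"] == 0

    def test_expected_retention_matches_observed(self, kb):
        cfg = GeneratorConfig(n_patients=8000, seed=13)
        raw = generate_raw_cohort(cfg, kb)
        kept, _ = filter_patients(raw)
        frac = len(kept) / len(raw)
        assert frac == pytest.approx(expected_retention(cfg), abs=0.02)

    def test_scoring_reproduces_from_medications(self, kb):
        """The cohort table's PIP/DDI columns derive from the medication
        claims, not from stored labels."""
        p = _patient()
        table = cohort_table([p], kb)
        assert table.loc[0, "pip"] == pytest.approx(0.46)
        assert table.loc[0, "pip_category"] == "moderate"
        assert not table.loc[0, "ddi_moderate_plus"]


class TestDesignMatrix:
    def test_reference_coding_of_pip(self, small_cohort):
        d = build_design_matrix(small_cohort, ["pip_category"])
        assert list(d.columns) == ["pip_moderate", "pip_high"]
        low = small_cohort.pip_category == "low"
        assert (d.loc[low.to_numpy(), :].sum(axis=1) == 0).all()

    def test_age_centered(self, small_cohort):
        d = build_design_matrix(small_cohort, ["age"])
        assert d["age"].mean() == pytest.approx(0.0, abs=1e-9)

    def test_baseline_columns_ordered(self, small_cohort):
        d = build_design_matrix(small_cohort, BASELINE_COVARIATES)
        assert list(d.columns) == ["age", "gender_male", "pip_moderate",
                                   "pip_high", "ddi_moderate_plus"]

    def test_degenerate_column_names_covariate(self, small_cohort):
        allf = small_cohort.copy()
        allf["gender"] = "female"
        with pytest.raises(DesignError, match="gender"):
            build_design_matrix(allf, ["gender"])

    def test_absent_reference_level_reported(self, small_cohort):
        males = small_cohort[small_cohort.gender == "male"]
        with pytest.raises(DesignError, match="reference"):
            build_design_matrix(males, ["gender"])

    def test_unknown_covariate(self, small_cohort):
        with pytest.raises(DesignError, match="unknown"):
            build_design_matrix(small_cohort, ["bmi"])
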