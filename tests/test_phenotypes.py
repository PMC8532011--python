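import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carefrag.errors import PhenotypeError
from carefrag.phenotypes import (
    classify_diabetes_type,
    detect_asthma,
    detect_ckd,
    detect_copd,
    detect_diabetes,
    egfr_mdrd,
    enumerate_diabetes_events,
    label_all,
)
from conftest import make_record


class TestEgfr:
    # frozen values computed independently by direct evaluation of
    # 175 * age^-0.203 * scr^-1.154 * 0.742[f] * 1.212[b]
    def test_female_nonblack(self):
        assert egfr_mdrd(1.0, 50, "female", False) == pytest.approx(58.6882, abs=1e-3)

    def test_male_black(self):
        assert egfr_mdrd(1.0, 50, "male", True) == pytest.approx(95.8627, abs=1e-3)

    def test_female_factor_exact_ratio(self):
        f = egfr_mdrd(1.3, 64, "female", False)
        m = egfr_mdrd(1.3, 64, "male", False)
        assert f / m == pytest.approx(0.742, rel=1e-12)

    def test_race_factor_exact_ratio(self):
        b = egfr_mdrd(0.9, 40, "male", True)
        w = egfr_mdrd(0.9, 40, "male", False)
        assert b / w == pytest.approx(1.212, rel=1e-12)

    def test_nonpositive_creatinine_rejected(self):
        with pytest.raises(PhenotypeError):
            egfr_mdrd(0.0, 50, "male", False)

    @given(scr=st.floats(0.3, 8.0), age=st.floats(18, 95))
    @settings(max_examples=100, deadline=None)
    def test_monotone_decreasing_in_creatinine_and_age(self, scr, age):
        base = egfr_mdrd(scr, age, "male", False)
        assert egfr_mdrd(scr * 1.1, age, "male", False) < base
        assert egfr_mdrd(scr, age + 1, "male", False) < base


class TestAsthma:
    def test_single_code_in_year(self):
        rec = make_record(diagnoses=[{"code": "J45.909", "date": "2018-03-02"}])
        assert detect_asthma(rec, 2018)

    def test_code_outside_year(self):
        rec = make_record(diagnoses=[{"code": "J45.909", "date": "2017-12-31"}])
        assert not detect_asthma(rec, 2018)

    def test_copd_range_code_does_not_count(self):
        rec = make_record(diagnoses=[{"code": "493.20", "code_system": "icd9",
                                      "date": "2018-03-02"}])
        assert not detect_asthma(rec, 2018)

    def test_evidence_nonempty_when_true(self):
        rec = make_record(diagnoses=[{"code": "J45", "date": "2018-06-01"}])
        det = detect_asthma(rec, 2018)
        assert det.value and det.evidence


def _scr_for(egfr_target, age, sex="male", race_black=False):
    from carefrag.synthetic_ehr import creatinine_for_egfr

    return creatinine_for_egfr(egfr_target, age, sex, race_black)


class TestCkd:
    BIRTH = "1960-01-01"  # age 58 in 2018

    def _scr_labs(self, dates, egfr=55.0):
        scr = _scr_for(egfr, 58)
        return [{"date": d, "analyte": "serum_creatinine", "value": scr} for d in dates]

    def test_two_low_egfr_three_months_apart(self):
        rec = make_record(birth=self.BIRTH,
                          labs=self._scr_labs(["2018-01-10", "2018-04-11"]))
        assert detect_ckd(rec)

    def test_gap_under_three_months_fails(self):
        rec = make_record(birth=self.BIRTH,
                          labs=self._scr_labs(["2018-01-10", "2018-03-01"]))
        assert not detect_ckd(rec)

    def test_exact_three_month_boundary_inclusive(self):
        rec = make_record(birth=self.BIRTH,
                          labs=self._scr_labs(["2018-01-10", "2018-04-10"]))
        assert detect_ckd(rec)

    def test_mixed_pair_both_orders(self):
        dip_first = make_record(birth=self.BIRTH, labs=[
            {"date": "2018-02-01", "analyte": "urine_protein_dipstick", "value": 1.0},
        ] + self._scr_labs(["2018-06-01"], egfr=58))
        egfr_first = make_record(birth=self.BIRTH, labs=self._scr_labs(
            ["2018-02-01"], egfr=58) + [
            {"date": "2018-06-01", "analyte": "urine_protein_dipstick", "value": 1.0},
        ])
        assert detect_ckd(dip_first)
        assert detect_ckd(egfr_first)

    def test_strict_mode_rejects_mixed_pair(self):
        rec = make_record(birth=self.BIRTH, labs=[
            {"date": "2018-02-01", "analyte": "urine_protein_dipstick", "value": 1.0},
        ] + self._scr_labs(["2018-06-01"]))
        assert detect_ckd(rec, mixed_pairs=True)
        assert not detect_ckd(rec, mixed_pairs=False)

    def test_egfr_60_exactly_not_qualifying(self):
        rec = make_record(birth=self.BIRTH,
                          labs=self._scr_labs(["2018-01-10", "2018-06-10"], egfr=60.0))
        assert not detect_ckd(rec)

    def test_dipstick_trace_grade_zero_not_qualifying(self):
        rec = make_record(birth=self.BIRTH, labs=[
            {"date": "2018-01-10", "analyte": "urine_protein_dipstick", "value": 0.0},
            {"date": "2018-06-10", "analyte": "urine_protein_dipstick", "value": 0.0},
        ])
        assert not detect_ckd(rec)

    def test_window_restriction(self):
        rec = make_record(birth=self.BIRTH,
                          labs=self._scr_labs(["2015-01-10", "2018-04-11"]))
        assert detect_ckd(rec)  # full span
        assert not detect_ckd(rec, window=("2018-01-01", "2018-12-31"))


class TestCopd:
    def _dx(self, code="J44.9", system="icd10", vt="outpatient", date="2018-02-01",
            rank="unranked", visit_id="V1"):
        return {"code": code, "code_system": system, "visit_type": vt,
                "date": date, "rank": rank, "visit_id": visit_id}

    def test_condition_1_dx_then_lama_within_6_months(self):
        rec = make_record(
            diagnoses=[self._dx()],
            medications=[{"date": "2018-05-01", "drug_class": "lama",
                          "drug_name": "tiotropium"}],
        )
        det = detect_copd(rec, 45)
        assert det.value and det.evidence[0][0] == "copd_condition_1"

    def test_age_39_fails(self):
        rec = make_record(
            diagnoses=[self._dx()],
            medications=[{"date": "2018-05-01", "drug_class": "lama"}],
        )
        assert not detect_copd(rec, 39)

    def test_lama_before_dx_does_not_count(self):
        rec = make_record(
            diagnoses=[self._dx(date="2018-06-01")],
            medications=[{"date": "2018-01-01", "drug_class": "lama"}],
        )
        assert not detect_copd(rec, 60)

    def test_lama_at_7_months_fails(self):
        rec = make_record(
            diagnoses=[self._dx(date="2018-01-01")],
            medications=[{"date": "2018-08-02", "drug_class": "lama"}],
        )
        assert not detect_copd(rec, 60)

    def test_condition_2_single_ed_dx(self):
        rec = make_record(diagnoses=[self._dx(vt="emergency")])
        det = detect_copd(rec, 60)
        assert det.value and det.evidence[0][0] == "copd_condition_2"

    def test_condition_2_needs_two_outpatient(self):
        one = make_record(diagnoses=[self._dx(code="J43.9")])
        two = make_record(diagnoses=[
            self._dx(code="J43.9", visit_id="V1"),
            self._dx(code="J44.9", date="2018-05-01", visit_id="V2"),
        ])
        assert not detect_copd(one, 60)
        assert detect_copd(two, 60)

    def test_condition_3_inpatient_principal(self):
        rec = make_record(diagnoses=[self._dx(vt="inpatient", rank="principal")])
        det = detect_copd(rec, 60)
        assert det.value and det.evidence[0][0] == "copd_condition_3"

    def test_inpatient_secondary_alone_fails(self):
        rec = make_record(diagnoses=[self._dx(vt="inpatient", rank="secondary")])
        assert not detect_copd(rec, 60)

    def test_condition_4_respiratory_failure_plus_exacerbation(self):
        rec = make_record(diagnoses=[
            self._dx(code="518.81", system="icd9", vt="inpatient",
                     rank="principal", visit_id="V9"),
            self._dx(code="491.21", system="icd9", vt="inpatient",
                     rank="secondary", visit_id="V9"),
        ])
        det = detect_copd(rec, 60)
        assert det.value and det.evidence[0][0] == "copd_condition_4"

    def test_condition_4_requires_same_stay(self):
        rec = make_record(diagnoses=[
            self._dx(code="518.81", system="icd9", vt="inpatient",
                     rank="principal", visit_id="V1"),
            self._dx(code="491.21", system="icd9", vt="inpatient",
                     rank="secondary", visit_id="V2"),
        ])
        assert not detect_copd(rec, 60)


class TestDiabetesEvents:
    def test_two_days_two_events(self):
        rec = make_record(labs=[
            {"date": "2015-01-10", "analyte": "hba1c", "value": 7.0},
            {"date": "2015-01-11", "analyte": "hba1c", "value": 7.0},
        ])
        assert len(enumerate_diabetes_events(rec)) == 2

    def test_same_day_deduplicates(self):
        rec = make_record(labs=[
            {"date": "2015-01-10", "analyte": "hba1c", "value": 7.0},
            {"date": "2015-01-10", "analyte": "hba1c", "value": 7.2},
        ])
        assert len(enumerate_diabetes_events(rec)) == 1

    def test_pregnancy_excludes_events(self):
        rec = make_record(
            sex="female",
            medications=[{"date": "2018-05-01", "drug_class": "insulin"}],
            pregnancies=[{"start": "2018-02-01", "end": "2018-11-01"}],
        )
        assert len(enumerate_diabetes_events(rec)) == 0

    def test_threshold_boundaries(self):
        rec = make_record(labs=[
            {"date": "2018-01-01", "analyte": "hba1c", "value": 6.5},
            {"date": "2018-01-02", "analyte": "hba1c", "value": 6.4},
            {"date": "2018-01-03", "analyte": "random_glucose", "value": 200.0},
            {"date": "2018-01-04", "analyte": "random_glucose", "value": 199.9},
            {"date": "2018-01-05", "analyte": "fasting_glucose", "value": 126.0},
            {"date": "2018-01-06", "analyte": "fasting_glucose", "value": 125.9},
        ])
        ev = enumerate_diabetes_events(rec)
        assert len(ev) == 3  # the three >= threshold rows
        assert sorted(ev["event_type"]) == [
            "fasting_glucose_ge_126", "hba1c_ge_6_5", "random_glucose_ge_200"]

    def test_sorted_chronologically(self):
        rec = make_record(labs=[
            {"date": "2016-05-01", "analyte": "hba1c", "value": 7.0},
            {"date": "2015-01-10", "analyte": "hba1c", "value": 7.0},
        ])
        ev = enumerate_diabetes_events(rec)
        assert list(ev["date"]) == sorted(ev["date"])


class TestDetectDiabetes:
    def test_single_inpatient_dx(self):
        rec = make_record(diagnoses=[{"code": "E11.9", "date": "2018-05-01",
                                      "visit_type": "inpatient"}])
        det = detect_diabetes(rec)
        assert det.value and det.evidence[0][0] == "diabetes_inpatient_dx"

    def test_metformin_pair_alone_fails(self):
        rec = make_record(medications=[
            {"date": "2015-03-01", "drug_class": "metformin"},
            {"date": "2015-09-01", "drug_class": "metformin"},
        ])
        assert not detect_diabetes(rec)

    def test_metformin_thiazolidinedione_pair_fails(self):
        rec = make_record(medications=[
            {"date": "2015-03-01", "drug_class": "metformin"},
            {"date": "2015-09-01", "drug_class": "thiazolidinedione"},
        ])
        assert not detect_diabetes(rec)

    def test_metformin_pair_with_other_manifestation_qualifies(self):
        rec = make_record(
            labs=[{"date": "2011-02-01", "analyte": "hba1c", "value": 7.0}],
            medications=[
                {"date": "2015-03-01", "drug_class": "metformin"},
                {"date": "2015-09-01", "drug_class": "metformin"},
            ],
        )
        assert detect_diabetes(rec)

    def test_lab_plus_outpatient_dx_within_two_years(self):
        rec = make_record(
            diagnoses=[{"code": "250.00", "code_system": "icd9",
                        "date": "2016-06-01", "visit_type": "outpatient"}],
            labs=[{"date": "2015-01-10", "analyte": "hba1c", "value": 6.8}],
        )
        assert detect_diabetes(rec)

    def test_events_beyond_two_years_fail(self):
        rec = make_record(labs=[
            {"date": "2015-01-10", "analyte": "hba1c", "value": 7.0},
            {"date": "2017-06-01", "analyte": "hba1c", "value": 7.0},
        ])
        assert not detect_diabetes(rec)

    def test_two_year_boundary_inclusive(self):
        rec = make_record(labs=[
            {"date": "2015-01-10", "analyte": "hba1c", "value": 7.0},
            {"date": "2017-01-10", "analyte": "hba1c", "value": 7.0},
        ])
        assert detect_diabetes(rec)

    def test_outpatient_dx_alone_is_one_event(self):
        rec = make_record(diagnoses=[{"code": "E11.9", "date": "2018-05-01",
                                      "visit_type": "outpatient"}])
        assert not detect_diabetes(rec)


def _diabetic_base_labs():
    return [
        {"date": "2017-03-01", "analyte": "hba1c", "value": 7.1},
        {"date": "2017-09-01", "analyte": "hba1c", "value": 6.8},
    ]


class TestClassifyDiabetesType:
    def _codes(self, n_t1, n_t2):
        out = []
        for i in range(n_t1):
            out.append({"code": "E10.9", "date": f"2018-0{i + 1}-05",
                        "visit_type": "outpatient"})
        for i in range(n_t2):
            out.append({"code": "E11.9", "date": f"2018-0{i + 1}-20",
                        "visit_type": "outpatient"})
        return out

    def test_condition_1_majority_plus_glucagon(self):
        rec = make_record(
            diagnoses=self._codes(3, 1),
            medications=[{"date": "2018-02-01", "drug_class": "glucagon"}],
        )
        det = classify_diabetes_type(rec)
        assert det.value and det.evidence[0][0] == "t1d_condition_1"

    def test_tie_with_negative_c_peptide_is_condition_3(self):
        rec = make_record(
            diagnoses=self._codes(1, 1),
            labs=[{"date": "2018-03-01", "analyte": "c_peptide",
                   "qualitative_flag": "negative"}] + _diabetic_base_labs(),
        )
        det = classify_diabetes_type(rec)
        assert det.value and det.evidence[0][0] == "t1d_condition_3"

    def test_t2_codes_only(self):
        rec = make_record(diagnoses=self._codes(0, 4))
        # inpatient dx needed for detect_diabetes: 4 outpatient dx are events
        assert not classify_diabetes_type(rec).value  # type 2

    def test_condition_2_blocked_by_oral_agent(self):
        rec = make_record(
            diagnoses=self._codes(2, 1),
            medications=[{"date": "2018-02-01", "drug_class": "sulfonylurea"}],
        )
        assert not classify_diabetes_type(rec).value  # type 2

    def test_condition_2_majority_no_oral(self):
        rec = make_record(diagnoses=self._codes(2, 1))
        det = classify_diabetes_type(rec)
        assert det.value and det.evidence[0][0] == "t1d_condition_2"

    def test_metformin_does_not_block_condition_2(self):
        rec = make_record(
            diagnoses=self._codes(2, 1),
            medications=[{"date": "2018-02-01", "drug_class": "metformin"}],
        )
        assert classify_diabetes_type(rec).value

    def test_positive_autoantibody_is_condition_4(self):
        rec = make_record(
            diagnoses=self._codes(0, 1),
            labs=[{"date": "2018-03-01", "analyte": "diabetes_autoantibody",
                   "qualitative_flag": "positive"}] + _diabetic_base_labs(),
        )
        det = classify_diabetes_type(rec)
        assert det.value and det.evidence[0][0] == "t1d_condition_4"

    def test_icd9_positional_codes_counted(self):
        rec = make_record(diagnoses=[
            {"code": "250.01", "code_system": "icd9", "date": "2018-01-05",
             "visit_type": "outpatient"},
            {"code": "250.03", "code_system": "icd9", "date": "2018-02-05",
             "visit_type": "outpatient"},
            {"code": "250.00", "code_system": "icd9", "date": "2018-03-05",
             "visit_type": "outpatient"},
        ])
        det = classify_diabetes_type(rec)  # 2 type-1 rows vs 1 type-2 row
        assert det.value and det.evidence[0][0] == "t1d_condition_2"

    def test_error_on_non_diabetic(self):
        rec = make_record()
        with pytest.raises(PhenotypeError):
            classify_diabetes_type(rec)


class TestLabelAll:
    def test_fixture_positives_match_manifest(self, fixture_data):
        ds, manifest = fixture_data
        labels = label_all(ds).set_index("patient_id")
        for row in manifest.itertuples():
            for flag in ("asthma", "ckd", "copd", "diabetes", "t1d", "t2d"):
                assert bool(labels.loc[row.patient_id, flag]) == bool(
                    getattr(row, flag)), (row.patient_id, row.branch, row.polarity, flag)

    def test_empty_dataset(self):
        from carefrag.ehr_model import EHRDataset

        assert label_all(EHRDataset()).empty

    def test_t1d_t2d_mutually_exclusive_and_imply_diabetes(self, small_gen):
        labels = label_all(small_gen.dataset)
        assert not (labels["t1d"] & labels["t2d"]).any()
        assert (labels.loc[labels["t1d"] | labels["t2d"], "diabetes"]).all()
        assert (labels.loc[labels["diabetes"], ["t1d", "t2d"]].any(axis=1)).all()

    def test_overlapping_subgroups_possible(self):
        rec_rows = dict(
            diagnoses=[
                {"code": "J45.909", "date": "2018-03-02", "visit_type": "outpatient"},
                {"code": "E11.9", "date": "2018-05-01", "visit_type": "inpatient"},
            ],
        )
        rec = make_record(**rec_rows)
        assert detect_asthma(rec, 2018).value
        assert detect_diabetes(rec).value

    def test_evidence_nonempty_for_every_true_flag(self, fixture_data):
        ds, _ = fixture_data
        labels = label_all(ds)
        for row in labels.itertuples():
            if any([row.asthma, row.ckd, row.copd, row.diabetes]):
                assert row.evidence


class TestPermutationInvariance:
    def test_detectors_invariant_to_row_order(self, fixture_data):
        from carefrag.ehr_model import EHRDataset

        ds, manifest = fixture_data
        tables = ds.tables()
        for name in ("diagnoses", "labs", "medications"):
            tables[name] = tables[name].sample(
                frac=1.0, random_state=7).reset_index(drop=True)
        shuffled = EHRDataset(**tables)
        labels = label_all(shuffled).set_index("patient_id")
        for row in manifest.itertuples():
            for flag in ("asthma", "ckd", "copd", "diabetes", "t1d", "t2d"):
                assert bool(labels.loc[row.patient_id, flag]) == bool(
                    getattr(row, flag))

    def test_monotone_adding_qualifying_dx(self):
        base = [{"code": "J44.9", "date": "2018-02-01", "visit_type": "emergency"}]
        rec1 = make_record(diagnoses=base)
        rec2 = make_record(diagnoses=base + [
            {"code": "496", "code_system": "icd9", "date": "2018-03-01",
             "visit_type": "outpatient"}])
        assert detect_copd(rec1, 60).value
        assert detect_copd(rec2, 60).value
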