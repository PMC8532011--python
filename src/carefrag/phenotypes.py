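"""Rule-based chronic-disease phenotypes over one patient's records.

Five computable phenotypes are implemented: asthma, chronic kidney disease
(CKD), chronic obstructive pulmonary disease (COPD), and diabetes split
into type 1 and type 2. Each detector returns a boolean plus an evidence
trace naming the satisfied rule branch and the supporting rows.

Conventions (all configurable where noted):

* month/year windows use inclusive calendar arithmetic (:mod:`carefrag.dates`);
* CKD accepts mixed qualifying pairs (one low eGFR + one proteinuria) by
  default; a strict same-type mode is available;
* the type-1 vs type-2 split counts diagnosis rows (not distinct days) by
  default; distinct-day counting is available;
* the pregnancy exclusion applies to the five diabetes event types only,
  not to inpatient diabetes diagnoses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .dates import add_months, age_at, months_apart_at_least, within_years
from .ehr_model import (
    ANTIHYPERGLYCEMIC_CLASSES,
    EHRDataset,
    ORAL_HYPOGLYCEMIC_NON_METFORMIN,
    filter_cohort,
)
from .errors import PhenotypeError
from .icd_codes import Vocabulary, any_match, default_vocabulary

EGFR_CKD_THRESHOLD = 60.0
DIPSTICK_PROTEINURIA_GRADE = 1.0
HBA1C_THRESHOLD = 6.5
RANDOM_GLUCOSE_THRESHOLD = 200.0
FASTING_GLUCOSE_THRESHOLD = 126.0
METFORMIN_LIKE = ("metformin", "thiazolidinedione")

DIABETES_EVENT_TYPES = (
    "hba1c_ge_6_5",
    "random_glucose_ge_200",
    "fasting_glucose_ge_126",
    "outpatient_dx",
    "antihyperglycemic_rx",
)


@dataclass
class PatientRecord:
    """One patient's rows from every table, with visit context merged into
    the diagnosis rows (``visit_type`` column)."""

    patient_id: str
    birth_date: pd.Timestamp
    sex: str
    race_black: bool
    diagnoses: pd.DataFrame
    labs: pd.DataFrame
    medications: pd.DataFrame
    pregnancies: pd.DataFrame


@dataclass
class Detection:
    value: bool
    evidence: list = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.value


@dataclass
class PhenotypeLabel:
    patient_id: str
    asthma: bool = False
    ckd: bool = False
    copd: bool = False
    diabetes: bool = False
    t1d: bool = False
    t2d: bool = False
    evidence: list = field(default_factory=list)


def build_patient_records(ds: EHRDataset, patient_ids: Iterable[str] | None = None):
    """Yield a :class:`PatientRecord` per patient (optionally restricted)."""
    dx = ds.diagnoses.merge(
        ds.visits[["visit_id", "visit_type"]], on="visit_id", how="left"
    )
    dx["visit_type"] = dx["visit_type"].fillna("")
    groups = {name: dict(list(df.groupby("patient_id")))
              for name, df in [("dx", dx), ("labs", ds.labs),
                               ("meds", ds.medications), ("preg", ds.pregnancies)]}
    patients = ds.patients
    if patient_ids is not None:
        wanted = set(patient_ids)
        patients = patients[patients["patient_id"].isin(wanted)]
    for row in patients.itertuples():
        pid = row.patient_id
        yield PatientRecord(
            patient_id=pid,
            birth_date=row.birth_date,
            sex=row.sex,
            race_black=bool(row.race_black),
            diagnoses=groups["dx"].get(pid, dx.iloc[0:0]),
            labs=groups["labs"].get(pid, ds.labs.iloc[0:0]),
            medications=groups["meds"].get(pid, ds.medications.iloc[0:0]),
            pregnancies=groups["preg"].get(pid, ds.pregnancies.iloc[0:0]),
        )


def egfr_mdrd(serum_creatinine: float, age: float, sex: str, race_black: bool) -> float:
    """Estimated GFR (mL/min/1.73 m^2), MDRD study equation:

    175 * age^-0.203 * creatinine^-1.154 * 0.742 (if female) * 1.212 (if Black).
    """
    if serum_creatinine <= 0:
        raise PhenotypeError(f"serum creatinine must be positive, got {serum_creatinine}")
    if age <= 0:
        raise PhenotypeError(f"age must be positive, got {age}")
    value = 175.0 * age ** -0.203 * serum_creatinine ** -1.154
    if sex == "female":
        value *= 0.742
    if race_black:
        value *= 1.212
    return value


def detect_asthma(record: PatientRecord, year: int,
                  vocab: Vocabulary | None = None) -> Detection:
    """>=1 asthma diagnosis code (any visit type) dated in ``year``."""
    vocab = vocab or default_vocabulary()
    hits = any_match(
        record.diagnoses, vocab["asthma_dx"],
        date_from=pd.Timestamp(year=year, month=1, day=1),
        date_to=pd.Timestamp(year=year, month=12, day=31),
    )
    if hits.empty:
        return Detection(False)
    return Detection(True, [("asthma_dx", _dx_refs(hits))])


def _dx_refs(df: pd.DataFrame) -> list[dict]:
    return [
        {"code": r.code, "code_system": r.code_system, "date": str(r.date.date())}
        for r in df.itertuples()
    ]


def _ckd_measurements(record: PatientRecord, window) -> list[tuple[pd.Timestamp, str, float]]:
    out = []
    labs = record.labs
    if window is not None:
        lo, hi = (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
        labs = labs[(labs["date"] >= lo) & (labs["date"] <= hi)]
    scr = labs[labs["analyte"] == "serum_creatinine"]
    for row in scr.itertuples():
        if pd.isna(row.value):
            continue
        age = age_at(record.birth_date, row.date)
        if age <= 0:
            continue
        egfr = egfr_mdrd(row.value, age, record.sex, record.race_black)
        if egfr < EGFR_CKD_THRESHOLD:
            out.append((row.date, "egfr", egfr))
    dip = labs[labs["analyte"] == "urine_protein_dipstick"]
    for row in dip.itertuples():
        if pd.notna(row.value) and row.value >= DIPSTICK_PROTEINURIA_GRADE:
            out.append((row.date, "proteinuria", row.value))
    out.sort(key=lambda t: t[0])
    return out


def detect_ckd(record: PatientRecord, window=None, mixed_pairs: bool = True) -> Detection:
    """Two qualifying measurements (eGFR < 60 or dipstick protein >= 1+)
    at least 3 calendar months apart. ``window`` optionally restricts the
    measurement dates (inclusive); default is the full record.

    ``mixed_pairs=False`` requires both measurements of the pair to be of
    the same type (strict mode).
    """
    ms = _ckd_measurements(record, window)
    for i in range(len(ms)):
        for j in range(i + 1, len(ms)):
            if not months_apart_at_least(ms[i][0], ms[j][0], 3):
                continue
            if not mixed_pairs and ms[i][1] != ms[j][1]:
                continue
            ev = [
                {"date": str(m[0].date()), "kind": m[1], "value": round(float(m[2]), 4)}
                for m in (ms[i], ms[j])
            ]
            return Detection(True, [("ckd_pair", ev)])
    return Detection(False)


def detect_copd(record: PatientRecord, age_at_index: int,
                vocab: Vocabulary | None = None) -> Detection:
    """Age >= 40 and any of the four COPD conditions.

    1. outpatient COPD dx followed by a LAMA prescription within 6 months;
    2. >=1 emergency-department COPD dx, or >=2 outpatient COPD dx rows;
    3. >=1 inpatient stay with a principal COPD dx;
    4. >=1 inpatient stay with a principal respiratory-failure dx and a
       secondary acute-exacerbation dx on the same stay.

    Evidence names the first satisfied condition.
    """
    if age_at_index < 40:
        return Detection(False)
    vocab = vocab or default_vocabulary()
    dx = record.diagnoses
    copd_all = any_match(dx, vocab["copd_dx"])

    outpatient = copd_all[copd_all["visit_type"] == "outpatient"]
    lama = record.medications[record.medications["drug_class"] == "lama"]
    for d in outpatient.itertuples():
        hi = add_months(d.date, 6)
        ok = lama[(lama["date"] >= d.date) & (lama["date"] <= hi)]
        if not ok.empty:
            return Detection(True, [(
                "copd_condition_1",
                {"dx": _dx_refs(outpatient.loc[[d.Index]]),
                 "lama_date": str(ok.iloc[0]["date"].date())},
            )])

    ed = copd_all[copd_all["visit_type"] == "emergency"]
    if len(ed) >= 1:
        return Detection(True, [("copd_condition_2", _dx_refs(ed.head(1)))])
    if len(outpatient) >= 2:
        return Detection(True, [("copd_condition_2", _dx_refs(outpatient.head(2)))])

    inpatient_principal = copd_all[
        (copd_all["visit_type"] == "inpatient") & (copd_all["rank"] == "principal")
    ]
    if not inpatient_principal.empty:
        return Detection(True, [("copd_condition_3", _dx_refs(inpatient_principal.head(1)))])

    inp = dx[dx["visit_type"] == "inpatient"]
    rf = any_match(inp, vocab["respiratory_failure_dx"], rank="principal")
    exac = any_match(inp, vocab["copd_exacerbation_dx"], rank="secondary")
    stays = set(rf["visit_id"]) & set(exac["visit_id"]) - {""}
    if stays:
        stay = sorted(stays)[0]
        return Detection(True, [(
            "copd_condition_4",
            {"visit_id": stay,
             "principal": _dx_refs(rf[rf["visit_id"] == stay].head(1)),
             "secondary": _dx_refs(exac[exac["visit_id"] == stay].head(1))},
        )])
    return Detection(False)


def _in_pregnancy(dates: pd.Series, pregnancies: pd.DataFrame) -> pd.Series:
    mask = pd.Series(False, index=dates.index)
    for ep in pregnancies.itertuples():
        mask |= (dates >= ep.start_date) & (dates <= ep.end_date)
    return mask


def enumerate_diabetes_events(record: PatientRecord,
                              vocab: Vocabulary | None = None) -> pd.DataFrame:
    """The five diabetes event types, one event per (type, day), events
    during a pregnancy episode excluded, chronologically sorted.

    Columns: event_type, date, detail (drug class for prescription events).
    """
    vocab = vocab or default_vocabulary()
    rows: list[tuple[str, pd.Timestamp, str]] = []
    labs = record.labs
    for analyte, threshold, etype in [
        ("hba1c", HBA1C_THRESHOLD, "hba1c_ge_6_5"),
        ("random_glucose", RANDOM_GLUCOSE_THRESHOLD, "random_glucose_ge_200"),
        ("fasting_glucose", FASTING_GLUCOSE_THRESHOLD, "fasting_glucose_ge_126"),
    ]:
        hit = labs[(labs["analyte"] == analyte) & (labs["value"] >= threshold)]
        rows.extend((etype, r.date, "") for r in hit.itertuples())
    dx = any_match(record.diagnoses, vocab["diabetes_dx"], visit_type="outpatient")
    rows.extend(("outpatient_dx", r.date, r.code) for r in dx.itertuples())
    rx = record.medications[
        record.medications["drug_class"].isin(ANTIHYPERGLYCEMIC_CLASSES)
    ]
    rows.extend(("antihyperglycemic_rx", r.date, r.drug_class) for r in rx.itertuples())

    events = pd.DataFrame(rows, columns=["event_type", "date", "detail"])
    if events.empty:
        return events
    # one event per (type, day); for prescriptions keep one row per
    # (class, day) so the metformin/thiazolidinedione rule can see classes
    events = events.drop_duplicates(subset=["event_type", "date", "detail"])
    non_rx = events["event_type"] != "antihyperglycemic_rx"
    events = pd.concat([
        events[non_rx].drop_duplicates(subset=["event_type", "date"]),
        events[~non_rx].drop_duplicates(subset=["event_type", "date", "detail"]),
    ])
    events = events[~_in_pregnancy(events["date"], record.pregnancies)]
    return events.sort_values(["date", "event_type", "detail"]).reset_index(drop=True)


def _is_metformin_like_rx(ev) -> bool:
    return ev.event_type == "antihyperglycemic_rx" and ev.detail in METFORMIN_LIKE


def detect_diabetes(record: PatientRecord, vocab: Vocabulary | None = None) -> Detection:
    """Diabetes: >=1 inpatient diabetes diagnosis code, or any 2 events
    within 2 years of each other. A pair of metformin/thiazolidinedione
    prescriptions does not qualify when no other manifestation exists."""
    vocab = vocab or default_vocabulary()
    inpatient = any_match(record.diagnoses, vocab["diabetes_dx"], visit_type="inpatient")
    if not inpatient.empty:
        return Detection(True, [("diabetes_inpatient_dx", _dx_refs(inpatient.head(1)))])
    events = enumerate_diabetes_events(record, vocab)
    if len(events) < 2:
        return Detection(False)
    evs = list(events.itertuples())
    has_other = any(not _is_metformin_like_rx(e) for e in evs)
    for i in range(len(evs)):
        for j in range(i + 1, len(evs)):
            a, b = evs[i], evs[j]
            if (a.event_type, a.date) == (b.event_type, b.date):
                continue  # same deduplicated event
            if not within_years(a.date, b.date, 2):
                continue
            if not has_other and _is_metformin_like_rx(a) and _is_metformin_like_rx(b):
                continue
            ev = [
                {"event_type": e.event_type, "date": str(e.date.date()), "detail": e.detail}
                for e in (a, b)
            ]
            return Detection(True, [("diabetes_event_pair", ev)])
    return Detection(False)


def classify_diabetes_type(record: PatientRecord,
                           vocab: Vocabulary | None = None,
                           span=None,
                           count_distinct_days: bool = False,
                           oral_non_metformin=ORAL_HYPOGLYCEMIC_NON_METFORMIN) -> Detection:
    """Type-1 vs type-2 split for a patient already detected as diabetic.

    Type 1 iff any of:
      1. #type-1 codes > #type-2 codes and a glucagon prescription exists;
      2. #type-1 codes > #type-2 codes and no oral hypoglycemic other than
         metformin was prescribed;
      3. a negative C-peptide result;
      4. a positive diabetes-autoantibody result.
    Otherwise type 2. Returns ``Detection(True)`` for type 1 with the
    satisfied condition in the evidence, ``Detection(False)`` for type 2.

    Codes are counted as raw rows by default (``count_distinct_days=True``
    counts distinct dates); ``span`` optionally restricts the dates used.
    """
    if not detect_diabetes(record, vocab):
        raise PhenotypeError(
            f"classify_diabetes_type called on non-diabetic patient {record.patient_id}"
        )
    vocab = vocab or default_vocabulary()
    dx = record.diagnoses
    kwargs = {}
    if span is not None:
        kwargs = {"date_from": span[0], "date_to": span[1]}
    t1_rows = any_match(dx, vocab["t1d_dx"], **kwargs)
    t2_rows = any_match(dx, vocab["t2d_dx"], **kwargs)
    if count_distinct_days:
        n1 = t1_rows["date"].nunique()
        n2 = t2_rows["date"].nunique()
    else:
        n1, n2 = len(t1_rows), len(t2_rows)

    meds = record.medications
    if span is not None:
        meds = meds[(meds["date"] >= pd.Timestamp(span[0]))
                    & (meds["date"] <= pd.Timestamp(span[1]))]
    labs = record.labs
    if span is not None:
        labs = labs[(labs["date"] >= pd.Timestamp(span[0]))
                    & (labs["date"] <= pd.Timestamp(span[1]))]

    counts = {"t1d_codes": int(n1), "t2d_codes": int(n2)}
    if n1 > n2 and (meds["drug_class"] == "glucagon").any():
        return Detection(True, [("t1d_condition_1", counts)])
    if n1 > n2 and not meds["drug_class"].isin(oral_non_metformin).any():
        return Detection(True, [("t1d_condition_2", counts)])
    cpep = labs[(labs["analyte"] == "c_peptide") & (labs["qualitative_flag"] == "negative")]
    if not cpep.empty:
        return Detection(True, [("t1d_condition_3", {"date": str(cpep.iloc[0]["date"].date())})])
    auto = labs[(labs["analyte"] == "diabetes_autoantibody")
                & (labs["qualitative_flag"] == "positive")]
    if not auto.empty:
        return Detection(True, [("t1d_condition_4", {"date": str(auto.iloc[0]["date"].date())})])
    return Detection(False, [("t2d_default", counts)])


def label_patient(record: PatientRecord, *, cohort_year: int, index_date,
                  vocab: Vocabulary, ckd_window=None, ckd_mixed_pairs: bool = True,
                  klompas_span=None, klompas_distinct_days: bool = False) -> PhenotypeLabel:
    label = PhenotypeLabel(patient_id=record.patient_id)
    asthma = detect_asthma(record, cohort_year, vocab)
    label.asthma = asthma.value
    ckd = detect_ckd(record, ckd_window, ckd_mixed_pairs)
    label.ckd = ckd.value
    copd = detect_copd(record, age_at(record.birth_date, index_date), vocab)
    label.copd = copd.value
    diabetes = detect_diabetes(record, vocab)
    label.diabetes = diabetes.value
    evidence = asthma.evidence + ckd.evidence + copd.evidence + diabetes.evidence
    if diabetes.value:
        t1 = classify_diabetes_type(
            record, vocab, span=klompas_span, count_distinct_days=klompas_distinct_days
        )
        label.t1d = t1.value
        label.t2d = not t1.value
        evidence += t1.evidence
    label.evidence = evidence
    return label


def label_all(ds: EHRDataset, *, cohort_year: int = 2018, index_date=None,
              vocab: Vocabulary | None = None, ckd_window=None,
              ckd_mixed_pairs: bool = True, klompas_span=None,
              klompas_distinct_days: bool = False,
              patient_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """One label row per cohort patient (or per given patient id).

    Returns a DataFrame with patient_id, the six boolean flags, and an
    ``evidence`` object column (list of (branch, detail) pairs).
    """
    vocab = vocab or default_vocabulary()
    if index_date is None:
        index_date = pd.Timestamp(year=cohort_year + 1, month=1, day=1)
    if patient_ids is None:
        patient_ids = filter_cohort(ds, cohort_year, index_date)
    records = build_patient_records(ds, patient_ids)
    labels = [
        label_patient(
            rec, cohort_year=cohort_year, index_date=index_date, vocab=vocab,
            ckd_window=ckd_window, ckd_mixed_pairs=ckd_mixed_pairs,
            klompas_span=klompas_span, klompas_distinct_days=klompas_distinct_days,
        )
        for rec in records
    ]
    df = pd.DataFrame(
        [
            {
                "patient_id": l.patient_id, "asthma": l.asthma, "ckd": l.ckd,
                "copd": l.copd, "diabetes": l.diabetes, "t1d": l.t1d, "t2d": l.t2d,
                "evidence": l.evidence,
            }
            for l in labels
        ],
        columns=["patient_id", "asthma", "ckd", "copd", "diabetes", "t1d", "t2d", "evidence"],
    )
    return df.sort_values("patient_id").reset_index(drop=True)
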