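import numpy as np
import pandas as pd
import pytest

from carefrag.icd_codes import default_vocabulary
from carefrag.synthetic_ehr import GeneratorConfig, fixture_suite, generate


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def fixture_data():
    return fixture_suite()


@pytest.fixture(scope="session")
def small_gen():
    return generate(GeneratorConfig(n_patients=400, seed=11))


def make_record(pid="P1", birth="1970-01-01", sex="male", race_black=False,
                diagnoses=(), labs=(), medications=(), pregnancies=()):
    """Build a PatientRecord from terse row dicts (test helper)."""
    from carefrag.phenotypes import PatientRecord

    dx_rows = []
    for d in diagnoses:
        dx_rows.append({
            "patient_id": pid, "visit_id": d.get("visit_id", ""),
            "code": d["code"], "code_system": d.get("code_system", "icd10"),
            "rank": d.get("rank", "unranked"), "date": pd.Timestamp(d["date"]),
            "visit_type": d.get("visit_type", ""),
        })
    lab_rows = []
    for l in labs:
        lab_rows.append({
            "patient_id": pid, "date": pd.Timestamp(l["date"]),
            "analyte": l["analyte"], "value": float(l.get("value", np.nan)),
            "qualitative_flag": l.get("qualitative_flag", "none"),
        })
    med_rows = []
    for m in medications:
        med_rows.append({
            "patient_id": pid, "date": pd.Timestamp(m["date"]),
            "drug_class": m["drug_class"], "drug_name": m.get("drug_name", ""),
        })
    preg_rows = []
    for p in pregnancies:
        preg_rows.append({
            "patient_id": pid, "start_date": pd.Timestamp(p["start"]),
            "end_date": pd.Timestamp(p["end"]),
        })
    dx_cols = ["patient_id", "visit_id", "code", "code_system", "rank", "date", "visit_type"]
    lab_cols = ["patient_id", "date", "analyte", "value", "qualitative_flag"]
    med_cols = ["patient_id", "date", "drug_class", "drug_name"]
    preg_cols = ["patient_id", "start_date", "end_date"]
    return PatientRecord(
        patient_id=pid, birth_date=pd.Timestamp(birth), sex=sex, race_black=race_black,
        diagnoses=pd.DataFrame(dx_rows, columns=dx_cols),
        labs=pd.DataFrame(lab_rows, columns=lab_cols),
        medications=pd.DataFrame(med_rows, columns=med_cols),
        pregnancies=pd.DataFrame(preg_rows, columns=preg_cols),
    )
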