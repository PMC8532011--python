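"""Relational EHR data model: table schemas, CSV I/O, validation, cohort filter.

The dataset is a bundle of nine delimited-text tables (eight EHR tables
plus the all-payer hospital-visit registry). The dialect is fixed:
comma-separated, UTF-8, ISO-8601 dates, header row required. Loading
validates every schema and cross-table invariant and reports violations
with table, row number and column; writing then loading reproduces the
dataset field for field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DatasetValidationError, IntegrityError

SEXES = ("female", "male", "unknown")
VISIT_TYPES = ("outpatient", "emergency", "inpatient")
REGISTRY_VISIT_TYPES = ("emergency", "inpatient")
DIAGNOSIS_RANKS = ("principal", "secondary", "unranked")
CODE_SYSTEMS = ("icd9", "icd10")
ANALYTES = (
    "serum_creatinine",
    "hba1c",
    "random_glucose",
    "fasting_glucose",
    "urine_protein_dipstick",
    "c_peptide",
    "diabetes_autoantibody",
)
QUALITATIVE_FLAGS = ("positive", "negative", "none")
QUALITATIVE_ANALYTES = ("c_peptide", "diabetes_autoantibody")
DRUG_CLASSES = (
    "lama",
    "glucagon",
    "metformin",
    "thiazolidinedione",
    "insulin",
    "sulfonylurea",
    "meglitinide",
    "dpp4_inhibitor",
    "alpha_glucosidase_inhibitor",
    "amylin_analogue",
    "incretin_mimetic",
    "other",
)

# Oral hypoglycemic agents other than metformin (used by the type-1/type-2
# split); configurable at call sites, this is the default.
ORAL_HYPOGLYCEMIC_NON_METFORMIN = (
    "sulfonylurea",
    "meglitinide",
    "dpp4_inhibitor",
    "alpha_glucosidase_inhibitor",
    "thiazolidinedione",
)

ANTIHYPERGLYCEMIC_CLASSES = (
    "alpha_glucosidase_inhibitor",
    "amylin_analogue",
    "metformin",  # biguanide class
    "dpp4_inhibitor",
    "incretin_mimetic",
    "insulin",
    "meglitinide",
    "sulfonylurea",
    "thiazolidinedione",
)

# column kinds: str, opt_str, date, opt_date, float, opt_float, bool, enum, grade_or_float
TABLE_SCHEMAS: dict[str, list[tuple[str, str, tuple | None]]] = {
    "patients": [
        ("patient_id", "str", None),
        ("birth_date", "date", None),
        ("sex", "enum", SEXES),
        ("race_black", "bool", None),
        ("death_date", "opt_date", None),
        ("home_lat", "opt_float", None),
        ("home_lon", "opt_float", None),
    ],
    "visits": [
        ("visit_id", "str", None),
        ("patient_id", "str", None),
        ("visit_type", "enum", VISIT_TYPES),
        ("start_date", "date", None),
        ("end_date", "date", None),
        ("facility_id", "opt_str", None),
    ],
    "diagnoses": [
        ("patient_id", "str", None),
        ("visit_id", "opt_str", None),
        ("code", "str", None),
        ("code_system", "enum", CODE_SYSTEMS),
        ("rank", "enum", DIAGNOSIS_RANKS),
        ("date", "date", None),
    ],
    "labs": [
        ("patient_id", "str", None),
        ("date", "date", None),
        ("analyte", "enum", ANALYTES),
        ("value", "grade_or_float", None),
        ("qualitative_flag", "enum", QUALITATIVE_FLAGS),
    ],
    "medications": [
        ("patient_id", "str", None),
        ("date", "date", None),
        ("drug_class", "enum", DRUG_CLASSES),
        ("drug_name", "opt_str", None),
    ],
    "pcp": [
        ("patient_id", "str", None),
        ("has_in_system_pcp", "bool", None),
        ("as_of_date", "date", None),
    ],
    "pregnancies": [
        ("patient_id", "str", None),
        ("start_date", "date", None),
        ("end_date", "date", None),
    ],
    "facilities": [
        ("facility_id", "str", None),
        ("name", "opt_str", None),
        ("in_system", "bool", None),
        ("lat", "float", None),
        ("lon", "float", None),
        ("is_hospital", "bool", None),
    ],
    "registry": [
        ("patient_id", "str", None),
        ("date", "date", None),
        ("visit_type", "enum", REGISTRY_VISIT_TYPES),
        ("facility_id", "str", None),
    ],
}

TABLE_FILES = {name: f"{name}.csv" for name in TABLE_SCHEMAS}

_DATE_KINDS = {"date", "opt_date"}


def empty_table(name: str) -> pd.DataFrame:
    cols = {}
    for col, kind, _ in TABLE_SCHEMAS[name]:
        if kind in _DATE_KINDS:
            cols[col] = pd.Series(dtype="datetime64[ns]")
        elif kind in ("float", "opt_float", "grade_or_float"):
            cols[col] = pd.Series(dtype=float)
        elif kind == "bool":
            cols[col] = pd.Series(dtype=bool)
        else:
            cols[col] = pd.Series(dtype=object)
    return pd.DataFrame(cols)


@dataclass
class EHRDataset:
    """The eight EHR tables plus the hospital-visit registry, as DataFrames."""

    patients: pd.DataFrame = field(default_factory=lambda: empty_table("patients"))
    visits: pd.DataFrame = field(default_factory=lambda: empty_table("visits"))
    diagnoses: pd.DataFrame = field(default_factory=lambda: empty_table("diagnoses"))
    labs: pd.DataFrame = field(default_factory=lambda: empty_table("labs"))
    medications: pd.DataFrame = field(default_factory=lambda: empty_table("medications"))
    pcp: pd.DataFrame = field(default_factory=lambda: empty_table("pcp"))
    pregnancies: pd.DataFrame = field(default_factory=lambda: empty_table("pregnancies"))
    facilities: pd.DataFrame = field(default_factory=lambda: empty_table("facilities"))
    registry: pd.DataFrame = field(default_factory=lambda: empty_table("registry"))

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_SCHEMAS}

    def __eq__(self, other) -> bool:
        if not isinstance(other, EHRDataset):
            return NotImplemented
        for name, df in self.tables().items():
            if not df.reset_index(drop=True).equals(getattr(other, name).reset_index(drop=True)):
                return False
        return True

    def validate(self) -> None:
        validate_dataset(self)


def _coerce_column(table: str, col: str, kind: str, choices, raw: pd.Series, violations):
    """Coerce one string column to its typed form, recording violations."""
    stripped = raw.fillna("").astype(str).str.strip()

    def bad(mask, why):
        for idx in stripped.index[mask]:
            violations.append(f"{table}.csv row {idx + 2}, column {col}: {why(stripped[idx])}")

    if kind in ("str",):
        bad(stripped == "", lambda v: "value required")
        return stripped
    if kind == "opt_str":
        return stripped
    if kind == "enum":
        bad(~stripped.isin(choices), lambda v: f"{v!r} not in {sorted(choices)}")
        return stripped
    if kind == "bool":
        lower = stripped.str.lower()
        ok = lower.isin(["true", "false"])
        bad(~ok, lambda v: f"{v!r} is not a boolean (true/false)")
        return lower == "true"
    if kind in ("date", "opt_date"):
        empty = stripped == ""
        if kind == "date":
            bad(empty, lambda v: "date required")
        parsed = pd.to_datetime(stripped.where(~empty, None), format="%Y-%m-%d", errors="coerce")
        bad(parsed.isna() & ~empty, lambda v: f"{v!r} is not an ISO date (YYYY-MM-DD)")
        return parsed
    if kind in ("float", "opt_float", "grade_or_float"):
        empty = stripped == ""
        if kind == "float":
            bad(empty, lambda v: "value required")
        # dipstick grades may be written "1+" .. "4+"
        cleaned = stripped.str.rstrip("+") if kind == "grade_or_float" else stripped

        def to_float(v: str) -> float:  # exact inverse of repr()
            try:
                return float(v)
            except ValueError:
                return np.nan

        parsed = cleaned.where(~empty, "").map(lambda v: np.nan if v == "" else to_float(v))
        bad(parsed.isna() & ~empty, lambda v: f"{v!r} is not numeric")
        return parsed.astype(float)
    raise AssertionError(f"unknown column kind {kind}")


def _parse_table(name: str, path: Path, violations: list[str]) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    expected = [c for c, _, _ in TABLE_SCHEMAS[name]]
    missing = [c for c in expected if c not in raw.columns]
    if missing:
        violations.append(f"{name}.csv: missing columns {missing}")
        return empty_table(name)
    out = {}
    for col, kind, choices in TABLE_SCHEMAS[name]:
        out[col] = _coerce_column(name, col, kind, choices, raw[col], violations)
    return pd.DataFrame(out)


def _row_invariants(ds: EHRDataset, violations: list[str]) -> None:
    p = ds.patients
    dup = p["patient_id"][p["patient_id"].duplicated()]
    for pid in dup:
        violations.append(f"patients.csv: duplicate patient_id {pid!r}")
    for col, lo, hi in [("home_lat", -90, 90), ("home_lon", -180, 180)]:
        bad = p[(p[col].notna()) & ((p[col] < lo) | (p[col] > hi))]
        for row in bad.itertuples():
            violations.append(
                f"patients.csv: patient {row.patient_id}: {col} outside [{lo}, {hi}]"
            )
    v = ds.visits
    for vid in v["visit_id"][v["visit_id"].duplicated()]:
        violations.append(f"visits.csv: duplicate visit_id {vid!r}")
    bad = v[v["end_date"] < v["start_date"]]
    for row in bad.itertuples():
        violations.append(f"visits.csv: visit {row.visit_id}: end_date before start_date")
    bad = v[v["visit_type"].isin(["emergency", "inpatient"]) & (v["facility_id"] == "")]
    for row in bad.itertuples():
        violations.append(
            f"visits.csv: visit {row.visit_id}: facility_id required for {row.visit_type} visits"
        )
    labs = ds.labs
    dip = labs[labs["analyte"] == "urine_protein_dipstick"]
    bad_grade = dip[
        dip["value"].isna()
        | (dip["value"] % 1 != 0)
        | (dip["value"] < 0)
        | (dip["value"] > 4)
    ]
    for row in bad_grade.itertuples():
        violations.append(
            f"labs.csv: patient {row.patient_id}: dipstick grade must be 0..4+, got {row.value}"
        )
    qual = labs[labs["analyte"].isin(QUALITATIVE_ANALYTES)]
    for row in qual[qual["qualitative_flag"] == "none"].itertuples():
        violations.append(
            f"labs.csv: patient {row.patient_id}: {row.analyte} requires a "
            "positive/negative qualitative_flag"
        )
    for row in ds.diagnoses[ds.diagnoses["code"] == ""].itertuples():
        violations.append(f"diagnoses.csv: patient {row.patient_id}: empty code")
    pcp_dup = ds.pcp[ds.pcp.duplicated(subset=["patient_id", "as_of_date"], keep=False)]
    for key in pcp_dup[["patient_id", "as_of_date"]].drop_duplicates().itertuples():
        violations.append(
            f"pcp.csv: patient {key.patient_id}: multiple rows for as_of_date "
            f"{key.as_of_date.date()}"
        )
    preg = ds.pregnancies
    bad = preg[preg["end_date"] < preg["start_date"]]
    for row in bad.itertuples():
        violations.append(f"pregnancies.csv: patient {row.patient_id}: end before start")
    for pid, grp in preg.groupby("patient_id"):
        g = grp.sort_values("start_date")
        prev_end = None
        for row in g.itertuples():
            if prev_end is not None and row.start_date <= prev_end:
                violations.append(
                    f"pregnancies.csv: patient {pid}: overlapping episodes"
                )
                break
            prev_end = row.end_date
    f = ds.facilities
    for fid in f["facility_id"][f["facility_id"].duplicated()]:
        violations.append(f"facilities.csv: duplicate facility_id {fid!r}")
    for col, lo, hi in [("lat", -90, 90), ("lon", -180, 180)]:
        bad = f[(f[col] < lo) | (f[col] > hi)]
        for row in bad.itertuples():
            violations.append(
                f"facilities.csv: facility {row.facility_id}: {col} outside [{lo}, {hi}]"
            )


def _integrity(ds: EHRDataset, violations: list[str]) -> None:
    known_patients = set(ds.patients["patient_id"])
    for name in ("visits", "diagnoses", "labs", "medications", "pcp", "pregnancies", "registry"):
        df = getattr(ds, name)
        unknown = sorted(set(df["patient_id"]) - known_patients)
        for pid in unknown:
            violations.append(f"{name}.csv: unknown patient_id {pid!r}")
    known_visits = set(ds.visits["visit_id"])
    dx_vids = set(ds.diagnoses["visit_id"]) - {""}
    for vid in sorted(dx_vids - known_visits):
        violations.append(f"diagnoses.csv: unknown visit_id {vid!r}")
    known_fac = set(ds.facilities["facility_id"])
    vis_fids = set(ds.visits["facility_id"]) - {""}
    for fid in sorted(vis_fids - known_fac):
        violations.append(f"visits.csv: unknown facility_id {fid!r}")
    for fid in sorted(set(ds.registry["facility_id"]) - known_fac):
        violations.append(f"registry.csv: unknown facility_id {fid!r}")
    # birth precedes every event
    births = ds.patients.set_index("patient_id")["birth_date"]
    for name, col in [
        ("visits", "start_date"),
        ("diagnoses", "date"),
        ("labs", "date"),
        ("medications", "date"),
        ("registry", "date"),
    ]:
        df = getattr(ds, name)
        if df.empty:
            continue
        joined = df[["patient_id", col]].join(births, on="patient_id")
        bad = joined[joined[col] < joined["birth_date"]]
        for row in bad.itertuples():
            violations.append(
                f"{name}.csv: patient {row.patient_id}: {col} precedes birth_date"
            )


def validate_dataset(ds: EHRDataset) -> None:
    """Run all row-level and cross-table invariants; raise on any breach."""
    row_violations: list[str] = []
    _row_invariants(ds, row_violations)
    integrity_violations: list[str] = []
    _integrity(ds, integrity_violations)
    if integrity_violations:
        raise IntegrityError(row_violations + integrity_violations)
    if row_violations:
        raise DatasetValidationError(row_violations)


def load_dataset(directory_path, require_registry: bool = False) -> EHRDataset:
    """Load and validate a dataset from a directory of CSV tables.

    A missing table file is fatal (named in the error), except registry.csv
    which defaults to empty unless ``require_registry`` is set.
    """
    directory = Path(directory_path)
    violations: list[str] = []
    frames = {}
    for name, fname in TABLE_FILES.items():
        path = directory / fname
        if not path.exists():
            if name == "registry" and not require_registry:
                frames[name] = empty_table(name)
                continue
            raise FileNotFoundError(f"missing table file: {path}")
        frames[name] = _parse_table(name, path, violations)
    if violations:
        raise DatasetValidationError(violations)
    ds = EHRDataset(**frames)
    validate_dataset(ds)
    return ds


def _format_for_csv(name: str, df: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for col, kind, _ in TABLE_SCHEMAS[name]:
        s = df[col]
        if kind in _DATE_KINDS:
            out[col] = s.dt.strftime("%Y-%m-%d").fillna("")
        elif kind == "bool":
            out[col] = s.map({True: "true", False: "false"})
        elif kind in ("float", "opt_float", "grade_or_float"):
            out[col] = s.map(lambda x: "" if pd.isna(x) else repr(float(x)))
        else:
            out[col] = s.fillna("")
    return pd.DataFrame(out)


def write_dataset(ds: EHRDataset, directory_path) -> list[Path]:
    """Write all tables as CSV; the write -> load round trip is the identity."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, fname in TABLE_FILES.items():
        path = directory / fname
        _format_for_csv(name, getattr(ds, name)).to_csv(path, index=False, encoding="utf-8")
        written.append(path)
    return written


def filter_cohort(ds: EHRDataset, cohort_year: int, age_reference_date=None) -> set[str]:
    """Patients with >=1 visit of any type at an in-system facility in the
    cohort year, aged >=18 at the age-reference date (default: January 1 of
    the following year), and with no death date in the cohort year."""
    if age_reference_date is None:
        age_reference_date = pd.Timestamp(year=cohort_year + 1, month=1, day=1)
    else:
        age_reference_date = pd.Timestamp(age_reference_date)
    in_system = set(ds.facilities.loc[ds.facilities["in_system"], "facility_id"])
    v = ds.visits
    visited = set(
        v.loc[
            (v["start_date"].dt.year == cohort_year) & v["facility_id"].isin(in_system),
            "patient_id",
        ]
    )
    p = ds.patients
    adult = p["birth_date"] <= (age_reference_date - pd.DateOffset(years=18))
    died = p["death_date"].notna() & (p["death_date"].dt.year == cohort_year)
    eligible = set(p.loc[adult & ~died, "patient_id"])
    return visited & eligible
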