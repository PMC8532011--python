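"""Synthetic EHR + registry generator.

Produces datasets with the statistical structure the analysis assumes:

* configurable disease prevalences (defaults mimic a large urban cohort:
  asthma 4.3%, CKD 7.4%, COPD 2.2%, type-2 diabetes 16.5%, type-1 0.8%);
* a share of patients holding an in-system primary care physician;
* home locations at controlled distances from three in-system hospitals
  (distance sampled from a near-urban/far-tail log-normal mixture, bearing
  uniform, coordinates laid out by a direct geodesic step);
* registry hospital visits whose probability of being in-system follows
  logistic(b0 + b_pcp * has_pcp + b_dist * distance_km).

Every phenotype rule branch has an implant function able to produce a
minimal positive and a near-miss negative, used both to seed disease
prevalence and to build the deterministic fixture suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .dates import add_months
from .ehr_model import EHRDataset, empty_table, validate_dataset
from .errors import ConfigError
from .geodesy import GeoPoint, min_hospital_distance_km, vincenty_direct

INDEX_DATE = pd.Timestamp("2019-01-01")
COHORT_YEAR = 2018

# Three in-system hospitals in an urban cluster (ordering matters for
# reproducibility; values are plausible city coordinates, not a map).
DEFAULT_HOSPITALS = (
    (47.6496, -122.3080),
    (47.6040, -122.3233),
    (47.7022, -122.3250),
)


class GeneratorConfig(BaseModel):
    n_patients: int = Field(2000, ge=0)
    seed: int = 0
    disease_prevalences: dict[str, float] = Field(
        default_factory=lambda: {
            "asthma": 0.043, "ckd": 0.074, "copd": 0.022, "t2d": 0.165, "t1d": 0.008,
        }
    )
    pcp_probability: float = Field(0.35, ge=0.0, le=1.0)
    # home-distance mixture (km): near-urban log-normal plus a far tail
    near_weight: float = Field(0.8, ge=0.0, le=1.0)
    near_log_mu: float = 1.4
    near_log_sigma: float = Field(0.9, gt=0)
    far_log_mu: float = 3.3
    far_log_sigma: float = Field(0.6, gt=0)
    hospitals: list[tuple[float, float]] = Field(
        default_factory=lambda: [tuple(h) for h in DEFAULT_HOSPITALS]
    )
    n_outside_facilities: int = Field(6, ge=1)
    outpatient_rate: float = Field(1.5, ge=0)
    registry_rate_base: float = Field(0.4, ge=0)
    registry_rate_disease: float = Field(1.6, ge=0)
    ed_share: float = Field(0.65, ge=0.0, le=1.0)
    # in-system assignment model
    b0: float = -1.0
    b_pcp: float = 2.0
    b_dist: float = -0.06
    death_probability: float = Field(0.008, ge=0.0, le=1.0)
    minor_fraction: float = Field(0.03, ge=0.0, le=1.0)
    pregnancy_probability: float = Field(0.08, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self):
        for k, v in self.disease_prevalences.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"prevalence {k}={v} outside [0, 1]")
        if not self.hospitals:
            raise ConfigError("at least one in-system hospital is required")
        return self


@dataclass
class PatientAttrs:
    patient_id: str
    birth_date: pd.Timestamp
    sex: str
    race_black: bool


class _Sink:
    """Accumulates rows for all tables with dataset-wide unique visit ids."""

    def __init__(self, vid_counter=None):
        self.visits: list[dict] = []
        self.diagnoses: list[dict] = []
        self.labs: list[dict] = []
        self.medications: list[dict] = []
        self.pregnancies: list[dict] = []
        self._vid = vid_counter if vid_counter is not None else itertools.count(1)

    def visit(self, pid, visit_type, date, facility_id, end_date=None) -> str:
        vid = f"V{next(self._vid):06d}"
        date = pd.Timestamp(date)
        self.visits.append({
            "visit_id": vid, "patient_id": pid, "visit_type": visit_type,
            "start_date": date,
            "end_date": pd.Timestamp(end_date) if end_date is not None else date,
            "facility_id": facility_id,
        })
        return vid

    def dx(self, pid, code, code_system, rank, date, visit_id=""):
        self.diagnoses.append({
            "patient_id": pid, "visit_id": visit_id, "code": code,
            "code_system": code_system, "rank": rank, "date": pd.Timestamp(date),
        })

    def lab(self, pid, date, analyte, value=np.nan, qualitative_flag="none"):
        self.labs.append({
            "patient_id": pid, "date": pd.Timestamp(date), "analyte": analyte,
            "value": float(value) if not pd.isna(value) else np.nan,
            "qualitative_flag": qualitative_flag,
        })

    def med(self, pid, date, drug_class, drug_name=""):
        self.medications.append({
            "patient_id": pid, "date": pd.Timestamp(date),
            "drug_class": drug_class, "drug_name": drug_name or drug_class,
        })

    def pregnancy(self, pid, start, end):
        self.pregnancies.append({
            "patient_id": pid, "start_date": pd.Timestamp(start),
            "end_date": pd.Timestamp(end),
        })


def creatinine_for_egfr(target_egfr: float, age: float, sex: str, race_black: bool) -> float:
    """Serum creatinine (mg/dL) that yields the target MDRD eGFR for the
    given demographics (inverse of the estimating equation)."""
    base = 175.0 * age ** -0.203
    if sex == "female":
        base *= 0.742
    if race_black:
        base *= 1.212
    return (base / target_egfr) ** (1.0 / 1.154)


def _age_at_index(attrs: PatientAttrs) -> int:
    from .dates import age_at

    return age_at(attrs.birth_date, INDEX_DATE)


def _dx_visit(sink, attrs, visit_type, date, code, code_system, rank="unranked",
              facility_id="C1"):
    vid = sink.visit(attrs.patient_id, visit_type, date, facility_id)
    sink.dx(attrs.patient_id, code, code_system, rank, date, visit_id=vid)
    return vid


# --- implant branches ------------------------------------------------------
# Each function writes rows such that the relevant detector fires via exactly
# the requested branch (positive) or misses by one minimal edit (near_miss).

def _asthma_dx(attrs, sink, rng, positive):
    if positive:
        date = pd.Timestamp("2018-01-01") + pd.Timedelta(days=int(rng.integers(0, 365)))
    else:
        date = pd.Timestamp("2017-12-31")  # one day outside the cohort year
    _dx_visit(sink, attrs, "outpatient", date, "J45.909", "icd10")


def _ckd_egfr_pair(attrs, sink, rng, positive):
    age = _age_at_index(attrs)
    creat = creatinine_for_egfr(45.0, age, attrs.sex, attrs.race_black)
    d1 = pd.Timestamp("2018-01-10")
    d2 = add_months(d1, 4 if positive else 2)
    sink.lab(attrs.patient_id, d1, "serum_creatinine", creat)
    sink.lab(attrs.patient_id, d2, "serum_creatinine", creat)


def _ckd_dipstick_pair(attrs, sink, rng, positive):
    d1 = pd.Timestamp("2018-02-01")
    sink.lab(attrs.patient_id, d1, "urine_protein_dipstick", 2.0)
    if positive:
        sink.lab(attrs.patient_id, add_months(d1, 5), "urine_protein_dipstick", 1.0)


def _ckd_mixed_pair(attrs, sink, rng, positive):
    age = _age_at_index(attrs)
    creat = creatinine_for_egfr(55.0, age, attrs.sex, attrs.race_black)
    d1 = pd.Timestamp("2018-02-01")
    sink.lab(attrs.patient_id, d1, "urine_protein_dipstick", 1.0)
    sink.lab(attrs.patient_id, add_months(d1, 4 if positive else 2),
             "serum_creatinine", creat)


def _copd_condition_1(attrs, sink, rng, positive):
    date = pd.Timestamp("2018-02-01")
    _dx_visit(sink, attrs, "outpatient", date, "J44.9", "icd10")
    gap = 3 if positive else 7  # months; rule window is 6
    sink.med(attrs.patient_id, add_months(date, gap), "lama", "tiotropium")


def _copd_condition_2_ed(attrs, sink, rng, positive):
    date = pd.Timestamp("2018-03-05")
    vtype = "emergency" if positive else "outpatient"
    fac = "H1" if positive else "C1"
    _dx_visit(sink, attrs, vtype, date, "496", "icd9", facility_id=fac)


def _copd_condition_2_outpatient(attrs, sink, rng, positive):
    _dx_visit(sink, attrs, "outpatient", "2018-03-01", "J43.9", "icd10")
    if positive:
        _dx_visit(sink, attrs, "outpatient", "2018-05-01", "J44.9", "icd10")


def _copd_condition_3(attrs, sink, rng, positive):
    rank = "principal" if positive else "secondary"
    _dx_visit(sink, attrs, "inpatient", "2018-04-10", "491.21", "icd9",
              rank=rank, facility_id="H1")


def _copd_condition_4(attrs, sink, rng, positive):
    date = pd.Timestamp("2018-06-15")
    vid = sink.visit(attrs.patient_id, "inpatient", date, "H1", end_date=date)
    sink.dx(attrs.patient_id, "518.81", "icd9", "principal", date, visit_id=vid)
    if positive:
        sink.dx(attrs.patient_id, "491.21", "icd9", "secondary", date, visit_id=vid)


def _dm_inpatient_dx(attrs, sink, rng, positive):
    vtype = "inpatient" if positive else "outpatient"
    fac = "H1" if positive else "C1"
    _dx_visit(sink, attrs, vtype, "2018-05-20", "E11.9", "icd10",
              rank="principal", facility_id=fac)
    # near miss: a single outpatient dx is one event, not a qualifying pair


def _dm_hba1c_pair(attrs, sink, rng, positive):
    d1 = pd.Timestamp("2017-03-01")
    gap = 6 if positive else 25  # months; rule window is 24
    sink.lab(attrs.patient_id, d1, "hba1c", 7.1)
    sink.lab(attrs.patient_id, add_months(d1, gap), "hba1c", 6.8)


def _dm_glucose_pair(attrs, sink, rng, positive):
    d1 = pd.Timestamp("2018-04-01")
    if positive:
        sink.lab(attrs.patient_id, d1, "random_glucose", 220.0)
        sink.lab(attrs.patient_id, add_months(d1, 1), "fasting_glucose", 140.0)
    else:
        sink.lab(attrs.patient_id, d1, "random_glucose", 199.0)
        sink.lab(attrs.patient_id, add_months(d1, 1), "fasting_glucose", 125.0)


def _dm_dx_rx_pair(attrs, sink, rng, positive):
    _dx_visit(sink, attrs, "outpatient", "2018-02-10", "250.00", "icd9")
    if positive:
        sink.med(attrs.patient_id, pd.Timestamp("2018-05-10"), "insulin")


def _dm_rx_pair(attrs, sink, rng, positive):
    d1 = pd.Timestamp("2018-03-01")
    d2 = pd.Timestamp("2018-09-01")
    if positive:
        sink.med(attrs.patient_id, d1, "insulin")
        sink.med(attrs.patient_id, d2, "sulfonylurea")
    else:
        # metformin/thiazolidinedione only, no other manifestation
        sink.med(attrs.patient_id, d1, "metformin")
        sink.med(attrs.patient_id, d2, "thiazolidinedione")


def _dm_pregnancy_exclusion(attrs, sink, rng, positive):
    sink.pregnancy(attrs.patient_id, "2018-02-01", "2018-10-20")
    if positive:
        d1, d2 = pd.Timestamp("2017-05-01"), pd.Timestamp("2017-11-01")
    else:
        d1, d2 = pd.Timestamp("2018-03-01"), pd.Timestamp("2018-09-01")
    sink.lab(attrs.patient_id, d1, "hba1c", 7.0)
    sink.lab(attrs.patient_id, d2, "hba1c", 7.2)


def _t1d_condition_1(attrs, sink, rng, positive):
    _dx_visit(sink, attrs, "inpatient", "2018-01-15", "E10.9", "icd10",
              rank="principal", facility_id="H1")
    sink.med(attrs.patient_id, pd.Timestamp("2018-02-01"), "glucagon")
    if not positive:
        # two type-2 codes tip the count the other way; conditions 1-2 need
        # a strict majority of type-1 codes
        _dx_visit(sink, attrs, "outpatient", "2018-03-01", "E11.9", "icd10")
        _dx_visit(sink, attrs, "outpatient", "2018-06-01", "E11.9", "icd10")
        sink.med(attrs.patient_id, pd.Timestamp("2018-03-01"), "sulfonylurea")


def _t1d_condition_2(attrs, sink, rng, positive):
    _dx_visit(sink, attrs, "inpatient", "2018-01-15", "E10.9", "icd10",
              rank="principal", facility_id="H1")
    _dx_visit(sink, attrs, "inpatient", "2018-07-15", "E10.9", "icd10",
              rank="principal", facility_id="H1")
    _dx_visit(sink, attrs, "outpatient", "2018-03-01", "E11.9", "icd10")
    if not positive:
        sink.med(attrs.patient_id, pd.Timestamp("2018-04-01"), "sulfonylurea")


def _t1d_condition_3(attrs, sink, rng, positive):
    _dm_hba1c_pair(attrs, sink, rng, True)
    sink.lab(attrs.patient_id, pd.Timestamp("2018-05-01"), "c_peptide",
             qualitative_flag="negative" if positive else "positive")


def _t1d_condition_4(attrs, sink, rng, positive):
    _dm_hba1c_pair(attrs, sink, rng, True)
    sink.lab(attrs.patient_id, pd.Timestamp("2018-05-01"), "diabetes_autoantibody",
             qualitative_flag="positive" if positive else "negative")


def _t2d_codes(attrs, sink, rng, positive):
    if positive:
        _dx_visit(sink, attrs, "inpatient", "2018-02-01", "E11.9", "icd10",
                  rank="principal", facility_id="H1")
        for d in ("2018-03-01", "2018-06-01", "2018-09-01"):
            _dx_visit(sink, attrs, "outpatient", d, "E11.9", "icd10")
        sink.med(attrs.patient_id, pd.Timestamp("2018-03-15"), "sulfonylurea")
    else:
        _dx_visit(sink, attrs, "outpatient", "2018-03-01", "E11.9", "icd10")


def _flags(**kw) -> dict:
    out = {k: False for k in ("asthma", "ckd", "copd", "diabetes", "t1d", "t2d")}
    out.update(kw)
    return out


@dataclass(frozen=True)
class Branch:
    disease: str
    fn: Callable
    expected_positive: dict
    expected_near_miss: dict
    min_age: int = 18
    sex: str | None = None


BRANCHES: dict[str, Branch] = {
    "asthma_dx": Branch("asthma", _asthma_dx, _flags(asthma=True), _flags()),
    "ckd_egfr_pair": Branch("ckd", _ckd_egfr_pair, _flags(ckd=True), _flags()),
    "ckd_dipstick_pair": Branch("ckd", _ckd_dipstick_pair, _flags(ckd=True), _flags()),
    "ckd_mixed_pair": Branch("ckd", _ckd_mixed_pair, _flags(ckd=True), _flags()),
    "copd_condition_1": Branch("copd", _copd_condition_1, _flags(copd=True), _flags(),
                               min_age=40),
    "copd_condition_2_ed": Branch("copd", _copd_condition_2_ed, _flags(copd=True),
                                  _flags(), min_age=40),
    "copd_condition_2_outpatient": Branch("copd", _copd_condition_2_outpatient,
                                          _flags(copd=True), _flags(), min_age=40),
    "copd_condition_3": Branch("copd", _copd_condition_3, _flags(copd=True), _flags(),
                               min_age=40),
    "copd_condition_4": Branch("copd", _copd_condition_4, _flags(copd=True), _flags(),
                               min_age=40),
    "dm_inpatient_dx": Branch("t2d", _dm_inpatient_dx,
                              _flags(diabetes=True, t2d=True), _flags()),
    "dm_hba1c_pair": Branch("t2d", _dm_hba1c_pair,
                            _flags(diabetes=True, t2d=True), _flags()),
    "dm_glucose_pair": Branch("t2d", _dm_glucose_pair,
                              _flags(diabetes=True, t2d=True), _flags()),
    "dm_dx_rx_pair": Branch("t2d", _dm_dx_rx_pair,
                            _flags(diabetes=True, t2d=True), _flags()),
    "dm_rx_pair": Branch("t2d", _dm_rx_pair,
                         _flags(diabetes=True, t2d=True), _flags()),
    "dm_pregnancy_exclusion": Branch("t2d", _dm_pregnancy_exclusion,
                                     _flags(diabetes=True, t2d=True), _flags(),
                                     sex="female"),
    "t1d_condition_1": Branch("t1d", _t1d_condition_1,
                              _flags(diabetes=True, t1d=True),
                              _flags(diabetes=True, t2d=True)),
    "t1d_condition_2": Branch("t1d", _t1d_condition_2,
                              _flags(diabetes=True, t1d=True),
                              _flags(diabetes=True, t2d=True)),
    "t1d_condition_3": Branch("t1d", _t1d_condition_3,
                              _flags(diabetes=True, t1d=True),
                              _flags(diabetes=True, t2d=True)),
    "t1d_condition_4": Branch("t1d", _t1d_condition_4,
                              _flags(diabetes=True, t1d=True),
                              _flags(diabetes=True, t2d=True)),
    "t2d_codes": Branch("t2d", _t2d_codes, _flags(diabetes=True, t2d=True), _flags()),
}

POSITIVE_BRANCHES_BY_DISEASE: dict[str, list[str]] = {}
for _name, _b in BRANCHES.items():
    POSITIVE_BRANCHES_BY_DISEASE.setdefault(_b.disease, []).append(_name)


@dataclass(frozen=True)
class ImplantSpec:
    disease: str
    polarity: str  # "positive" | "near_miss"
    branch: str

    def __post_init__(self):
        if self.branch not in BRANCHES:
            raise ConfigError(f"unknown implant branch {self.branch!r}")
        if BRANCHES[self.branch].disease != self.disease:
            raise ConfigError(
                f"branch {self.branch!r} does not belong to disease {self.disease!r}"
            )
        if self.polarity not in ("positive", "near_miss"):
            raise ConfigError(f"unknown polarity {self.polarity!r}")


def implant(patient: PatientAttrs, spec: ImplantSpec, rng) -> dict[str, list[dict]]:
    """Produce the record rows realizing ``spec`` for one patient."""
    sink = _Sink()
    BRANCHES[spec.branch].fn(patient, sink, rng, spec.polarity == "positive")
    return {
        "visits": sink.visits, "diagnoses": sink.diagnoses, "labs": sink.labs,
        "medications": sink.medications, "pregnancies": sink.pregnancies,
    }


# --- population generator --------------------------------------------------

@dataclass
class GeneratedData:
    dataset: EHRDataset
    # one row per registry visit, aligned by position: the generator's
    # in-system probability for that visit (ground truth for recovery tests)
    visit_truth: pd.DataFrame = dc_field(default_factory=pd.DataFrame)


def _facilities_frame(cfg: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for i, (lat, lon) in enumerate(cfg.hospitals, start=1):
        rows.append({"facility_id": f"H{i}", "name": f"In-System Hospital {i}",
                     "in_system": True, "lat": float(lat), "lon": float(lon),
                     "is_hospital": True})
    h1 = GeoPoint(float(cfg.hospitals[0][0]), float(cfg.hospitals[0][1]))
    rows.append({"facility_id": "C1", "name": "In-System Clinic",
                 "in_system": True, "lat": h1.lat, "lon": h1.lon,
                 "is_hospital": False})
    for i in range(1, cfg.n_outside_facilities + 1):
        # ring of outside hospitals at 3..45 km
        p = vincenty_direct(h1, 360.0 * i / cfg.n_outside_facilities,
                            (3.0 + 42.0 * (i - 1) / max(cfg.n_outside_facilities - 1, 1))
                            * 1000.0)
        rows.append({"facility_id": f"X{i}", "name": f"Outside Hospital {i}",
                     "in_system": False, "lat": p.lat, "lon": p.lon,
                     "is_hospital": True})
    return pd.DataFrame(rows)


def _sample_distance_km(cfg: GeneratorConfig, rng) -> float:
    if rng.random() < cfg.near_weight:
        return float(rng.lognormal(cfg.near_log_mu, cfg.near_log_sigma))
    return float(rng.lognormal(cfg.far_log_mu, cfg.far_log_sigma))


def p_in_system(cfg: GeneratorConfig, has_pcp: bool, distance_km: float) -> float:
    z = cfg.b0 + cfg.b_pcp * float(has_pcp) + cfg.b_dist * distance_km
    return 1.0 / (1.0 + math.exp(-z))


def generate(config: GeneratorConfig) -> GeneratedData:
    """Generate a full dataset + registry. Deterministic under a fixed config."""
    cfg = config if isinstance(config, GeneratorConfig) else GeneratorConfig(**config)
    rng = np.random.default_rng(cfg.seed)
    sink = _Sink()
    facilities = _facilities_frame(cfg)
    hospital_points = [GeoPoint(float(lat), float(lon)) for lat, lon in cfg.hospitals]

    patients_rows, pcp_rows, registry_rows, truth_rows = [], [], [], []
    diseases = list(cfg.disease_prevalences)
    for i in range(1, cfg.n_patients + 1):
        pid = f"P{i:06d}"
        sick = {d: rng.random() < cfg.disease_prevalences[d] for d in diseases}
        if sick.get("t1d") and sick.get("t2d"):
            sick["t2d"] = False  # the two types are mutually exclusive
        if rng.random() < cfg.minor_fraction:
            age = int(rng.integers(12, 18))
        else:
            age = int(rng.integers(18, 91))
        if sick.get("copd") and age < 40:
            age = int(rng.integers(40, 91))
        sex = "female" if rng.random() < 0.53 else "male"
        race_black = bool(rng.random() < 0.074)
        birth = (INDEX_DATE - pd.DateOffset(years=age)
                 - pd.Timedelta(days=int(rng.integers(0, 364))))
        death = pd.NaT
        if rng.random() < cfg.death_probability:
            death = pd.Timestamp("2018-10-01") + pd.Timedelta(days=int(rng.integers(0, 90)))

        # home location: sampled distance + bearing from a random hospital
        anchor = hospital_points[int(rng.integers(0, len(hospital_points)))]
        dist_km = _sample_distance_km(cfg, rng)
        home = vincenty_direct(anchor, float(rng.uniform(0.0, 360.0)), dist_km * 1000.0)
        patients_rows.append({
            "patient_id": pid, "birth_date": birth, "sex": sex,
            "race_black": race_black, "death_date": death,
            "home_lat": home.lat, "home_lon": home.lon,
        })
        has_pcp = bool(rng.random() < cfg.pcp_probability)
        pcp_rows.append({"patient_id": pid, "has_in_system_pcp": has_pcp,
                         "as_of_date": INDEX_DATE})

        attrs = PatientAttrs(pid, birth, sex, race_black)
        # background outpatient contact keeps every living adult in the cohort
        n_outpt = 1 + int(rng.poisson(cfg.outpatient_rate))
        last_day = 180 if not pd.isna(death) else 365
        for _ in range(n_outpt):
            day = int(rng.integers(0, last_day))
            sink.visit(pid, "outpatient", pd.Timestamp("2018-01-01") + pd.Timedelta(days=day), "C1")
        if sex == "female" and 18 <= age <= 45 and rng.random() < cfg.pregnancy_probability:
            # kept clear of 2018 so it cannot overlap an implanted episode
            start = pd.Timestamp("2013-01-01") + pd.Timedelta(days=int(rng.integers(0, 700)))
            sink.pregnancy(pid, start, start + pd.Timedelta(days=270))

        for d in diseases:
            if not sick[d]:
                continue
            branches = [
                b for b in POSITIVE_BRANCHES_BY_DISEASE[d]
                if BRANCHES[b].sex in (None, sex)
                and (BRANCHES[b].min_age <= 18 or age >= BRANCHES[b].min_age)
            ]
            branch = branches[int(rng.integers(0, len(branches)))]
            BRANCHES[branch].fn(attrs, sink, rng, True)

        # registry hospital visits in 2019
        min_dist = min_hospital_distance_km(home, hospital_points)
        rate = cfg.registry_rate_base
        if any(sick.values()):
            rate += cfg.registry_rate_disease
        p_in = p_in_system(cfg, has_pcp, min_dist)
        seen_visits: set[tuple] = set()
        for _ in range(int(rng.poisson(rate))):
            vtype = "emergency" if rng.random() < cfg.ed_share else "inpatient"
            if rng.random() < p_in:
                fac = f"H{int(rng.integers(1, len(cfg.hospitals) + 1))}"
            else:
                fac = f"X{int(rng.integers(1, cfg.n_outside_facilities + 1))}"
            # avoid exact duplicate rows, which downstream deduplication
            # would collapse and desynchronize from the truth frame
            for _attempt in range(50):
                day = int(rng.integers(0, 365))
                if (day, vtype, fac) not in seen_visits:
                    break
            seen_visits.add((day, vtype, fac))
            date = pd.Timestamp("2019-01-01") + pd.Timedelta(days=day)
            registry_rows.append({"patient_id": pid, "date": date,
                                  "visit_type": vtype, "facility_id": fac})
            truth_rows.append({"patient_id": pid, "p_in_system": p_in,
                               "has_pcp": has_pcp, "distance_km": min_dist})

    def frame(rows, name):
        return pd.DataFrame(rows) if rows else empty_table(name)

    ds = EHRDataset(
        patients=frame(patients_rows, "patients"),
        visits=frame(sink.visits, "visits"),
        diagnoses=frame(sink.diagnoses, "diagnoses"),
        labs=frame(sink.labs, "labs"),
        medications=frame(sink.medications, "medications"),
        pcp=frame(pcp_rows, "pcp"),
        pregnancies=frame(sink.pregnancies, "pregnancies"),
        facilities=facilities,
        registry=frame(registry_rows, "registry"),
    )
    validate_dataset(ds)
    return GeneratedData(dataset=ds, visit_truth=pd.DataFrame(truth_rows))


# --- deterministic fixture suite -------------------------------------------

def fixture_suite() -> tuple[EHRDataset, pd.DataFrame]:
    """Miniature dataset covering every rule branch x polarity, plus a
    manifest of hand-derived expected labels (one patient per combination)."""
    rng = np.random.default_rng(7)
    sink = _Sink()
    facilities = _facilities_frame(GeneratorConfig(n_patients=0))
    patients_rows, pcp_rows, manifest = [], [], []
    i = 0
    for branch_name, branch in BRANCHES.items():
        for polarity in ("positive", "near_miss"):
            i += 1
            pid = f"F{i:03d}"
            age = max(branch.min_age, 30) + 10  # comfortably above the floor
            sex = branch.sex or ("female" if i % 2 else "male")
            birth = INDEX_DATE - pd.DateOffset(years=age) - pd.Timedelta(days=100)
            patients_rows.append({
                "patient_id": pid, "birth_date": birth, "sex": sex,
                "race_black": i % 7 == 0, "death_date": pd.NaT,
                "home_lat": facilities.iloc[0]["lat"],
                "home_lon": facilities.iloc[0]["lon"],
            })
            pcp_rows.append({"patient_id": pid, "has_in_system_pcp": True,
                             "as_of_date": INDEX_DATE})
            sink.visit(pid, "outpatient", pd.Timestamp("2018-06-15"), "C1")
            attrs = PatientAttrs(pid, birth, sex, bool(i % 7 == 0))
            branch.fn(attrs, sink, rng, polarity == "positive")
            expected = (branch.expected_positive if polarity == "positive"
                        else branch.expected_near_miss)
            manifest.append({"patient_id": pid, "branch": branch_name,
                             "polarity": polarity, **expected})
    ds = EHRDataset(
        patients=pd.DataFrame(patients_rows),
        visits=pd.DataFrame(sink.visits),
        diagnoses=pd.DataFrame(sink.diagnoses) if sink.diagnoses else empty_table("diagnoses"),
        labs=pd.DataFrame(sink.labs) if sink.labs else empty_table("labs"),
        medications=(pd.DataFrame(sink.medications) if sink.medications
                     else empty_table("medications")),
        pcp=pd.DataFrame(pcp_rows),
        pregnancies=(pd.DataFrame(sink.pregnancies) if sink.pregnancies
                     else empty_table("pregnancies")),
        facilities=facilities,
        registry=empty_table("registry"),
    )
    validate_dataset(ds)
    return ds, pd.DataFrame(manifest)
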