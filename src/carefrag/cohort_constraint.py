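"""Constraint-based patient selection and care-fragmentation metrics.

The selection rule is a conjunction: the patient has an in-system primary
care physician AND lives within ``d`` km (inclusive; geodesic distance) of
at least one in-system hospital. ``d_km=None`` means unbounded — distance
is irrelevant and the rule reduces to holding an in-system PCP.

Fragmentation metrics count hospital visits (emergency + inpatient) in the
all-payer registry over a follow-up window: the in-system share is
numerator/denominator x 100. Percentages are rounded half-up to two
decimals for reports; the raw fraction is always retained. A zero
denominator makes the percentage undefined (``None``), never 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .ehr_model import EHRDataset
from .errors import CarefragError
from .geodesy import GeoPoint, min_hospital_distance_km

logger = logging.getLogger(__name__)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (decimal, not binary, semantics)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FragmentationFraction:
    """A numerator/denominator pair with its percentage.

    Used both for visit fractions (in-system / all hospital visits) and the
    fulfilling-patient fraction n0/m0.
    """

    numerator: int
    denominator: int

    def __post_init__(self):
        if not (0 <= self.numerator <= self.denominator or self.denominator == 0):
            raise CarefragError(
                f"invalid fraction {self.numerator}/{self.denominator}"
            )

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def percentage(self) -> float | None:
        if not self.defined:
            return None
        return self.numerator / self.denominator * 100.0

    @property
    def percentage_2dp(self) -> float | None:
        p = self.percentage
        return None if p is None else round_half_up(p, 2)

    def __str__(self) -> str:
        if not self.defined:
            return f"{self.numerator}/{self.denominator} (undefined)"
        return f"{self.numerator}/{self.denominator} ({self.percentage_2dp:.2f}%)"


@dataclass(frozen=True)
class FollowUpWindow:
    start: pd.Timestamp
    end: pd.Timestamp
    label: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if self.start > self.end:
            raise CarefragError(f"window {self.label}: start after end")

    @classmethod
    def from_index_date(cls, index_date, months: int, label: str | None = None):
        start = pd.Timestamp(index_date)
        end = start + pd.DateOffset(months=months) - pd.Timedelta(days=1)
        return cls(start, end, label or f"{months}m")


@dataclass(frozen=True)
class ConstraintParams:
    """d_km=None is the unbounded sentinel (PCP-only selection)."""

    d_km: float | None = 8.0
    pcp_as_of_date: pd.Timestamp | None = None

    def __post_init__(self):
        if self.d_km is not None and self.d_km < 0:
            raise CarefragError(f"d_km must be >= 0, got {self.d_km}")


@dataclass
class SelectionResult:
    selected: set
    fraction: FragmentationFraction
    warnings: list = field(default_factory=list)


def in_system_hospitals(facilities: pd.DataFrame) -> pd.DataFrame:
    hosp = facilities[facilities["in_system"] & facilities["is_hospital"]]
    if hosp.empty:
        raise CarefragError("no in-system hospitals in the facility table")
    return hosp


def patient_min_distances_km(patients: pd.DataFrame, facilities: pd.DataFrame) -> pd.Series:
    """Minimum home-to-in-system-hospital distance per patient (km).

    NaN where home coordinates are missing. Computed once and reused by the
    sweep, which only thresholds.
    """
    hosp = in_system_hospitals(facilities)
    points = [GeoPoint(float(r.lat), float(r.lon)) for r in hosp.itertuples()]
    out = {}
    for row in patients.itertuples():
        if pd.isna(row.home_lat) or pd.isna(row.home_lon):
            out[row.patient_id] = np.nan
            continue
        home = GeoPoint(float(row.home_lat), float(row.home_lon))
        out[row.patient_id] = min_hospital_distance_km(home, points)
    return pd.Series(out, name="min_distance_km")


def pcp_flags(pcp: pd.DataFrame, as_of_date=None) -> pd.Series:
    """has_in_system_pcp per patient, using the latest row at or before
    ``as_of_date`` (or the latest row overall)."""
    df = pcp
    if as_of_date is not None:
        df = df[df["as_of_date"] <= pd.Timestamp(as_of_date)]
    df = df.sort_values("as_of_date").drop_duplicates("patient_id", keep="last")
    return df.set_index("patient_id")["has_in_system_pcp"]


def fulfills_constraint(has_pcp, min_distance_km, params: ConstraintParams) -> bool:
    """The conjunction for one patient. Missing PCP row (None) or missing
    home coordinates (NaN distance) evaluate to not fulfilling."""
    if has_pcp is None or pd.isna(has_pcp) or not bool(has_pcp):
        return False
    if params.d_km is None:
        return True
    if min_distance_km is None or pd.isna(min_distance_km):
        return False
    return float(min_distance_km) <= params.d_km


def select_subcohort(patient_ids, ds: EHRDataset, params: ConstraintParams,
                     distances: pd.Series | None = None) -> SelectionResult:
    """Subset of ``patient_ids`` fulfilling the constraint, plus n0/m0."""
    ids = sorted(set(patient_ids))
    unknown = set(ids) - set(ds.patients["patient_id"])
    if unknown:
        raise CarefragError(f"unknown patient ids: {sorted(unknown)[:5]}")
    warnings = []
    if distances is None:
        pats = ds.patients[ds.patients["patient_id"].isin(ids)]
        distances = patient_min_distances_km(pats, ds.facilities)
    flags = pcp_flags(ds.pcp, params.pcp_as_of_date)
    selected = set()
    n_missing_pcp = n_missing_home = 0
    for pid in ids:
        has_pcp = flags.get(pid)
        if has_pcp is None:
            n_missing_pcp += 1
        dist = distances.get(pid, np.nan)
        if pd.isna(dist):
            n_missing_home += 1
        if fulfills_constraint(has_pcp, dist, params):
            selected.add(pid)
    if n_missing_pcp:
        msg = f"{n_missing_pcp} patients with no PCP row treated as not fulfilling"
        warnings.append(msg)
        logger.warning(msg)
    if n_missing_home:
        msg = f"{n_missing_home} patients with missing home coordinates"
        warnings.append(msg)
        logger.warning(msg)
    if not ids:
        warnings.append("empty patient set: fulfilling fraction undefined")
    return SelectionResult(selected, FragmentationFraction(len(selected), len(ids)), warnings)


def dedupe_registry(registry: pd.DataFrame) -> pd.DataFrame:
    """Collapse exact duplicate rows (same patient, date, type, facility).
    A same-day emergency + inpatient pair remains two visits."""
    return registry.drop_duplicates(
        subset=["patient_id", "date", "visit_type", "facility_id"]
    )


def fragmentation(registry: pd.DataFrame, patient_subset, window: FollowUpWindow,
                  facilities: pd.DataFrame,
                  facility_filter: str | None = None) -> FragmentationFraction:
    """In-system share of the subset's hospital visits in the window.

    The denominator counts all registry visits by subset patients dated in
    the window; the numerator counts those at an in-system facility, or at
    the single facility named by ``facility_filter`` (per-hospital view).
    """
    reg = dedupe_registry(registry)
    subset = set(patient_subset)
    in_window = (
        reg["patient_id"].isin(subset)
        & (reg["date"] >= window.start)
        & (reg["date"] <= window.end)
    )
    visits = reg[in_window]
    if facility_filter is not None:
        num = int((visits["facility_id"] == facility_filter).sum())
    else:
        in_system = set(facilities.loc[facilities["in_system"], "facility_id"])
        num = int(visits["facility_id"].isin(in_system).sum())
    return FragmentationFraction(num, int(len(visits)))


def sweep(d_grid, patient_ids, ds: EHRDataset, registry: pd.DataFrame,
          windows: list[FollowUpWindow],
          distances: pd.Series | None = None) -> pd.DataFrame:
    """Fulfilling percentage and per-window in-system percentages for each
    d in a strictly increasing grid (``None`` = unbounded as last entry).

    Asserts nesting: the fulfilling percentage is nondecreasing in d.
    """
    finite = [d for d in d_grid if d is not None]
    if any(b <= a for a, b in zip(finite, finite[1:])):
        raise CarefragError("d_grid must be strictly increasing")
    ids = sorted(set(patient_ids))
    if distances is None:
        pats = ds.patients[ds.patients["patient_id"].isin(ids)]
        distances = patient_min_distances_km(pats, ds.facilities)
    rows = []
    prev_pct = -1.0
    for d in d_grid:
        params = ConstraintParams(d_km=d)
        res = select_subcohort(ids, ds, params, distances=distances)
        pct = res.fraction.percentage
        if pct is not None:
            if pct < prev_pct - 1e-9:
                raise CarefragError("fulfilling percentage decreased along the sweep")
            prev_pct = pct
        row = {
            "d_km": np.inf if d is None else d,
            "fulfilling_n": res.fraction.numerator,
            "fulfilling_m": res.fraction.denominator,
            "fulfilling_pct": res.fraction.percentage_2dp,
        }
        for w in windows:
            frac = fragmentation(registry, res.selected, w, ds.facilities)
            row[f"in_system_n_{w.label}"] = frac.numerator
            row[f"in_system_m_{w.label}"] = frac.denominator
            row[f"in_system_pct_{w.label}"] = frac.percentage_2dp
        rows.append(row)
    return pd.DataFrame(rows)


DISEASES = ("asthma", "ckd", "copd", "t1d", "t2d")


def subgroup_report(ds: EHRDataset, registry: pd.DataFrame, labels: pd.DataFrame,
                    params: ConstraintParams, windows: list[FollowUpWindow],
                    distances: pd.Series | None = None) -> pd.DataFrame:
    """Per-subgroup report: fulfilling fraction, and for each window the
    in-system share for all subgroup patients and for the fulfilling subset."""
    if distances is None:
        ids = labels["patient_id"]
        pats = ds.patients[ds.patients["patient_id"].isin(set(ids))]
        distances = patient_min_distances_km(pats, ds.facilities)
    rows = []
    for disease in DISEASES:
        members = list(labels.loc[labels[disease], "patient_id"])
        res = select_subcohort(members, ds, params, distances=distances)
        row = {
            "subgroup": disease,
            "fulfilling_n": res.fraction.numerator,
            "fulfilling_m": res.fraction.denominator,
            "fulfilling_pct": res.fraction.percentage_2dp,
        }
        for w in windows:
            all_frac = fragmentation(registry, members, w, ds.facilities)
            sel_frac = fragmentation(registry, res.selected, w, ds.facilities)
            row[f"all_in_system_n_{w.label}"] = all_frac.numerator
            row[f"all_in_system_m_{w.label}"] = all_frac.denominator
            row[f"all_in_system_pct_{w.label}"] = all_frac.percentage_2dp
            row[f"fulfilling_in_system_n_{w.label}"] = sel_frac.numerator
            row[f"fulfilling_in_system_m_{w.label}"] = sel_frac.denominator
            row[f"fulfilling_in_system_pct_{w.label}"] = sel_frac.percentage_2dp
        rows.append(row)
    return pd.DataFrame(rows)


def per_hospital_report(registry: pd.DataFrame, patient_subset,
                        windows: list[FollowUpWindow], facilities: pd.DataFrame,
                        hospital_ids=None) -> pd.DataFrame:
    """Per in-system hospital share of the subset's hospital visits.

    For each window the per-hospital numerators sum to the system numerator
    (same denominator m of all visits anywhere).
    """
    hosp = in_system_hospitals(facilities)
    if hospital_ids is None:
        hospital_ids = list(hosp["facility_id"])
    else:
        unknown = set(hospital_ids) - set(hosp["facility_id"])
        if unknown:
            raise CarefragError(f"not in-system hospitals: {sorted(unknown)}")
    rows = []
    for hid in hospital_ids:
        row = {"facility_id": hid}
        for w in windows:
            frac = fragmentation(registry, patient_subset, w, facilities,
                                 facility_filter=hid)
            row[f"n_{w.label}"] = frac.numerator
            row[f"m_{w.label}"] = frac.denominator
            row[f"pct_{w.label}"] = frac.percentage_2dp
        rows.append(row)
    return pd.DataFrame(rows)
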